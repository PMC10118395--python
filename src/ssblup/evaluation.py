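"""Post-processing of evaluation results.

Rebases breeding values to a common base cohort and expresses them in
genetic standard deviations, standardizes SNP effects by the marker
genetic standard deviation for genome scans, and summarizes genetic
trends by birth year. Optional Manhattan-style and trend plots.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DataError
from .genotype import SnpCovariance
from .mme import EvaluationResult
from .pedigree import Pedigree

log = logging.getLogger(__name__)


def rebase_and_scale(
    result: EvaluationResult,
    ped: Pedigree,
    base_ids,
    G0: np.ndarray,
) -> pd.DataFrame:
    """Express breeding values relative to a base cohort, in genetic SD units.

    Per trait: subtract the mean (G)EBV of the base-cohort animals and
    divide by sqrt(G0[i, i]). Returns a long table with columns
    ``animal_id, birth_year, trait, gebv_raw, gebv_sd``. Rebasing is an
    affine map, so differences and rankings between animals are
    invariant to the base-cohort choice.
    """
    base_ids = list(base_ids)
    if not base_ids:
        raise DataError("base cohort is empty")
    base_idx = ped.indices_of(base_ids)
    sd = np.sqrt(np.diag(np.asarray(G0, dtype=float)))
    rows = []
    for ti, tr in enumerate(result.traits):
        vals = result.u[:, ti]
        base_mean = vals[base_idx].mean()
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": result.animal_ids,
                    "birth_year": ped.birth_year,
                    "trait": tr,
                    "gebv_raw": vals,
                    "gebv_sd": (vals - base_mean) / sd[ti],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def standardize_snp_effects(
    g_hat: np.ndarray,
    snp_cov: SnpCovariance,
    markers: pd.DataFrame,
    traits,
) -> pd.DataFrame:
    """SNP-effect scan table with effects in marker genetic SD units.

    ``effect_std[j, i] = g_hat[j, i] / sigma_SNP,i`` with sigma_SNP,i
    the square root of the i-th diagonal of the marker covariance, so
    effects are directly comparable across traits. Rows are ordered by
    chromosome then position.
    """
    g_hat = np.asarray(g_hat, dtype=float)
    sd = np.sqrt(np.diag(snp_cov.sigma))
    if (sd <= 0).any():
        raise DataError("marker genetic SD is zero (k = 1?); cannot standardize")
    if len(markers) != g_hat.shape[0]:
        raise DataError("marker table and effect matrix sizes differ")
    rows = []
    for ti, tr in enumerate(traits):
        df = markers[["marker_id", "chromosome", "position"]].copy()
        df["trait"] = tr
        df["effect_raw"] = g_hat[:, ti]
        df["effect_std"] = g_hat[:, ti] / sd[ti]
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    if not np.isfinite(out["effect_std"]).all():
        raise DataError("non-finite standardized SNP effects")
    return out.sort_values(["trait", "chromosome", "position"], kind="stable").reset_index(
        drop=True
    )


def genetic_trend(
    gebv_table: pd.DataFrame,
    cohort_ids,
    cohort: str = "cohort",
) -> pd.DataFrame:
    """Mean rebased GEBV (SD units) of a cohort by birth year.

    ``gebv_table`` is the long table from :func:`rebase_and_scale`;
    ``cohort_ids`` restricts to the cohort of interest (e.g. steers
    with their own carcass records). Years without members are omitted.
    """
    sub = gebv_table[gebv_table["animal_id"].isin(set(cohort_ids))]
    if sub.empty:
        return pd.DataFrame(columns=["birth_year", "trait", "cohort", "mean_gebv_sd", "n"])
    out = (
        sub.groupby(["birth_year", "trait"], as_index=False)
        .agg(mean_gebv_sd=("gebv_sd", "mean"), n=("gebv_sd", "size"))
        .assign(cohort=cohort)
    )
    return out[["birth_year", "trait", "cohort", "mean_gebv_sd", "n"]]


def plot_snp_scan(scan: pd.DataFrame, trait: str, path):  # pragma: no cover
    """Manhattan-style plot of |standardized SNP effects| for one trait."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = scan[scan["trait"] == trait].sort_values(["chromosome", "position"])
    x = np.arange(len(sub))
    fig, ax = plt.subplots(figsize=(10, 3))
    for i, (_, grp) in enumerate(sub.groupby("chromosome", sort=True)):
        xi = x[sub["chromosome"].to_numpy() == grp["chromosome"].iloc[0]]
        ax.scatter(xi, grp["effect_std"].abs(), s=4, color=f"C{i % 2}")
    ax.set_xlabel("marker (by chromosome, position)")
    ax.set_ylabel(r"$|\hat g| / \sigma_{SNP}$")
    ax.set_title(trait)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trend(trend: pd.DataFrame, trait: str, path):  # pragma: no cover
    """Genetic-trend line plot (mean GEBV in genetic SD by birth year)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for coh, grp in trend[trend["trait"] == trait].groupby("cohort"):
        grp = grp.sort_values("birth_year")
        ax.plot(grp["birth_year"], grp["mean_gebv_sd"], marker="o", label=str(coh))
    ax.set_xlabel("birth year")
    ax.set_ylabel("mean GEBV (genetic SD)")
    ax.set_title(trait)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
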