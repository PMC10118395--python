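"""Forward-validation machinery.

Simulates an evaluation from an earlier date by removing recent
phenotypes, selects validation cohorts, and compares full against
truncated evaluations: the LR regression test on breeding values,
SNP-effect agreement, and per-birth-year prediction correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .pedigree import Pedigree

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TruncationScheme:
    """Remove phenotype records of animals born after ``cutoff_birth_year``.

    Genotypes and pedigree are never truncated.
    """

    cutoff_birth_year: int


def truncate_data(
    phenotypes: pd.DataFrame, ped: Pedigree, scheme: TruncationScheme
) -> pd.DataFrame:
    """Phenotype table restricted to animals born on or before the cutoff."""
    idx = ped.indices_of(phenotypes["animal_id"].tolist())
    keep = ped.birth_year[idx] <= scheme.cutoff_birth_year
    out = phenotypes.loc[keep].reset_index(drop=True)
    log.info(
        "truncation at %d removed %d of %d records",
        scheme.cutoff_birth_year,
        len(phenotypes) - len(out),
        len(phenotypes),
    )
    return out


def select_validation_cohort(
    ped: Pedigree,
    genotyped_ids,
    phenotypes_full: pd.DataFrame,
    scheme: TruncationScheme,
    stratum: str = "both",
) -> list[str]:
    """Validation animals: genotyped, phenotyped in the full data, born after the cutoff.

    ``stratum`` selects ``"cows"``, ``"steers"`` or ``"both"``; bulls
    are never validation animals. Raises on an empty cohort.
    """
    if stratum not in ("cows", "steers", "both"):
        raise DataError(f"unknown validation stratum {stratum!r}")
    phenotyped = set(phenotypes_full["animal_id"])
    gset = set(genotyped_ids)
    wanted = {"cows": {"cow"}, "steers": {"steer"}, "both": {"cow", "steer"}}[stratum]
    cohort = [
        a
        for i, a in enumerate(ped.ids)
        if a in gset
        and a in phenotyped
        and ped.birth_year[i] > scheme.cutoff_birth_year
        and ped.animal_type[i] in wanted
    ]
    if not cohort:
        raise DataError(
            f"empty validation cohort (stratum={stratum}, cutoff={scheme.cutoff_birth_year})"
        )
    return cohort


def _pivot(gebv: pd.DataFrame, ids: list[str], trait: str) -> np.ndarray:
    sub = gebv[(gebv["trait"] == trait) & (gebv["animal_id"].isin(ids))]
    s = sub.set_index("animal_id")["gebv_sd"]
    missing = [a for a in ids if a not in s.index]
    if missing:
        raise DataError(f"animals without GEBV for trait {trait}: {missing[:10]}")
    return s.loc[ids].to_numpy(dtype=float)


def lr_test(
    gebv_full: pd.DataFrame,
    gebv_truncated: pd.DataFrame,
    cohort: list[str],
) -> pd.DataFrame:
    """LR-method regression of full-data on truncated-data predictions.

    Ordinary least squares per trait over the validation cohort, with
    the full evaluation as response and the truncated one as predictor
    (both rebased to a shared base and in genetic SD units): the
    intercept b0 measures bias, the slope b1 inflation/deflation, and
    R^2 — the squared Pearson correlation — relates to accuracy.
    """
    if len(cohort) < 3:
        raise DataError(f"validation cohort of {len(cohort)} is too small for the LR test")
    if len(cohort) < 10:
        log.warning("validation cohort of only %d animals; LR statistics unstable", len(cohort))
    traits = sorted(gebv_full["trait"].unique())
    rows = []
    for tr in traits:
        yf = _pivot(gebv_full, cohort, tr)
        xt = _pivot(gebv_truncated, cohort, tr)
        b0, b1, r2 = _ols(xt, yf)
        rows.append({"trait": tr, "b0": b0, "b1": b1, "r2": r2, "n": len(cohort)})
    return pd.DataFrame(rows)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Simple regression of y on x; exact (0, 1, 1) for identical inputs.

    Centered sums are shared between numerator and denominator so that
    bit-identical inputs yield bit-exact identity statistics.
    """
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0:
        raise DataError("predictor breeding values are constant; slope undefined")
    if syy == 0.0:
        raise DataError("response breeding values are constant; R^2 undefined")
    sxy = float(xc @ yc)
    b1 = sxy / sxx
    b0 = float(y.mean() - b1 * x.mean())
    r2 = sxy * sxy / (sxx * syy)
    return b0, b1, r2


def effect_agreement(
    g_full: np.ndarray, g_truncated: np.ndarray, traits
) -> pd.DataFrame:
    """Correlation and regression slope of SNP effects, full on truncated."""
    g_full = np.asarray(g_full, dtype=float)
    g_truncated = np.asarray(g_truncated, dtype=float)
    if g_full.shape != g_truncated.shape:
        raise DataError("SNP effect matrices differ in shape (marker panels must match)")
    rows = []
    for ti, tr in enumerate(traits):
        f, t_ = g_full[:, ti], g_truncated[:, ti]
        if f.std() == 0.0 or t_.std() == 0.0:
            raise DataError(f"constant SNP-effect vector for trait {tr}")
        _, slope, r2 = _ols(t_, f)
        corr = float(np.sign(slope) * np.sqrt(r2))
        rows.append({"trait": tr, "correlation": corr, "slope": slope})
    return pd.DataFrame(rows)


def correlation_by_birth_year(
    gebv_full: pd.DataFrame,
    gebv_truncated: pd.DataFrame,
    ped: Pedigree,
    cohort_ids,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-birth-year Pearson correlation between full and truncated GEBV.

    Years with fewer than ``min_n`` cohort members are flagged
    (``small=True``) and reported with a NaN correlation.
    """
    ids = list(cohort_ids)
    idx = ped.indices_of(ids)
    years = ped.birth_year[idx]
    traits = sorted(gebv_full["trait"].unique())
    rows = []
    for year in np.unique(years):
        members = [a for a, y in zip(ids, years) if y == year]
        small = len(members) < min_n
        for tr in traits:
            if small:
                corr = np.nan
            else:
                f = _pivot(gebv_full, members, tr)
                t_ = _pivot(gebv_truncated, members, tr)
                corr = float(np.corrcoef(f, t_)[0, 1])
            rows.append(
                {
                    "birth_year": int(year),
                    "trait": tr,
                    "n": len(members),
                    "correlation": corr,
                    "small": small,
                }
            )
    return pd.DataFrame(rows)
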