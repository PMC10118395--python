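"""SNP genotype handling for single-step genomic evaluation.

Covers genotype storage (0/1/2 allele dosages with missing as NaN),
observed allele frequencies, mean-dosage imputation, column centering,
the marker-variance scaling that splits additive genetic variance
between markers and the residual polygenic term, and parentage
verification through opposing homozygotes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .pedigree import MISSING, Pedigree

log = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Animals x markers allele-dosage codes; missing calls are NaN."""

    animal_ids: list[str]
    marker_ids: list[str]
    chromosome: np.ndarray
    position: np.ndarray
    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.animal_ids), len(self.marker_ids)):
            raise DataError(
                f"genotype codes shape {self.codes.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.marker_ids)} markers"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise DataError("marker ids are not unique")
        if self.m == 0:
            raise DataError("genotype matrix has no markers")
        obs = self.codes[~np.isnan(self.codes)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise DataError("genotype codes outside [0, 2]")

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    @property
    def m(self) -> int:
        return len(self.marker_ids)

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "chromosome": self.chromosome,
                "position": self.position,
            }
        )


@dataclass
class AlleleFrequencies:
    """Observed alternate-allele frequencies with a monomorphic flag."""

    p: np.ndarray
    monomorphic: np.ndarray


@dataclass
class SnpCovariance:
    """Per-marker genetic covariance of SNP effects across traits.

    ``sigma = (1 - k) * G0 / D`` with ``D = sum_j 2 p_j (1 - p_j)``:
    the marker share (1 - k) of the additive genetic covariance spread
    over the expected marker heterozygosity.
    """

    sigma: np.ndarray
    D: float
    k: float


def compute_allele_frequencies(
    genotypes: GenotypeMatrix, clamp: bool = True
) -> AlleleFrequencies:
    """Observed allele frequencies p_j = mean(non-missing codes at j) / 2.

    Frequencies are clamped away from 0/1 (by half an allele count) so
    monomorphic markers keep a nonzero variance downstream; the raw
    monomorphic status is still flagged.
    """
    codes = genotypes.codes
    n_obs = (~np.isnan(codes)).sum(axis=0)
    bad = n_obs == 0
    if bad.any():
        ids = [genotypes.marker_ids[j] for j in np.flatnonzero(bad)[:20]]
        raise DataError(f"markers with no non-missing calls: {ids}")
    with np.errstate(invalid="ignore"):
        p = np.nanmean(codes, axis=0) / 2.0
    monomorphic = (p == 0.0) | (p == 1.0)
    if clamp:
        lo = 0.5 / (2.0 * n_obs)
        p = np.clip(p, lo, 1.0 - lo)
    if monomorphic.any():
        log.info("%d monomorphic markers (frequency clamped)", int(monomorphic.sum()))
    return AlleleFrequencies(p=p, monomorphic=monomorphic)


def impute_missing(genotypes: GenotypeMatrix, freqs: AlleleFrequencies) -> GenotypeMatrix:
    """Replace missing calls at marker j with the mean dosage 2 p_j.

    A deliberately simple stand-in for haplotype-based imputation:
    fractional dosages are allowed downstream and column means are
    preserved.
    """
    codes = genotypes.codes.copy()
    miss = np.isnan(codes)
    if miss.any():
        fill = np.broadcast_to(2.0 * freqs.p, codes.shape)
        codes[miss] = fill[miss]
    return GenotypeMatrix(
        animal_ids=genotypes.animal_ids,
        marker_ids=genotypes.marker_ids,
        chromosome=genotypes.chromosome,
        position=genotypes.position,
        codes=codes,
    )


def center_genotypes(genotypes: GenotypeMatrix, freqs: AlleleFrequencies) -> np.ndarray:
    """Centered genotype matrix Z = codes - 2 p, one column per marker."""
    if np.isnan(genotypes.codes).any():
        raise DataError("center_genotypes requires imputed (no-missing) genotypes")
    return genotypes.codes - 2.0 * freqs.p


def snp_variance(G0: np.ndarray, k: float, p: np.ndarray) -> SnpCovariance:
    """Marker-effect covariance from the additive covariance and the RPG split.

    The residual polygenic fraction ``k`` of the additive genetic
    (co)variance ``G0`` stays on the pedigree; the remaining ``1 - k``
    is spread over markers: ``sigma = (1 - k) G0 / D`` with
    ``D = sum_j 2 p_j (1 - p_j)``.
    """
    if not 0.0 <= k <= 1.0:
        raise DataError(f"RPG fraction k={k} outside [0, 1]")
    p = np.asarray(p, dtype=float)
    D = float(np.sum(2.0 * p * (1.0 - p)))
    if D == 0.0:
        raise DataError("all markers monomorphic: sum 2p(1-p) is zero")
    G0 = np.asarray(G0, dtype=float)
    return SnpCovariance(sigma=(1.0 - k) * G0 / D, D=D, k=k)


def verify_parentage(
    genotypes: GenotypeMatrix,
    ped: Pedigree,
    conflict_threshold: float = 0.01,
    min_markers: int = 100,
) -> pd.DataFrame:
    """Opposing-homozygote screen of genotyped parent-offspring duos.

    For each genotyped animal with a genotyped sire (resp. dam), counts
    markers where one member is homozygous reference (0) and the other
    homozygous alternate (2). A duo is flagged as conflicting when the
    opposing-homozygote rate exceeds ``conflict_threshold``. Duos with
    fewer than ``min_markers`` jointly called markers are skipped with
    a warning. Returns one row per checked duo with columns
    ``animal_id, parent_id, side, n_checked, n_opposing, rate, conflict``.
    """
    gset = {a: i for i, a in enumerate(genotypes.animal_ids)}
    codes = genotypes.codes
    rows = []
    for a, ai in gset.items():
        pi = ped.index.get(a)
        if pi is None:
            continue
        for side, parent in (("sire", ped.sire[pi]), ("dam", ped.dam[pi])):
            if parent == MISSING:
                continue
            pid = ped.ids[parent]
            if pid not in gset:
                continue
            ca = codes[ai]
            cp = codes[gset[pid]]
            joint = ~np.isnan(ca) & ~np.isnan(cp)
            n_checked = int(joint.sum())
            if n_checked < min_markers:
                log.warning(
                    "duo (%s, %s) skipped: only %d jointly called markers", a, pid, n_checked
                )
                continue
            opp = int(
                (((ca == 0) & (cp == 2)) | ((ca == 2) & (cp == 0)))[joint].sum()
            )
            rate = opp / n_checked
            rows.append(
                {
                    "animal_id": a,
                    "parent_id": pid,
                    "side": side,
                    "n_checked": n_checked,
                    "n_opposing": opp,
                    "rate": rate,
                    "conflict": rate > conflict_threshold,
                }
            )
    report = pd.DataFrame(
        rows,
        columns=["animal_id", "parent_id", "side", "n_checked", "n_opposing", "rate", "conflict"],
    )
    if len(report):
        for side in ("sire", "dam"):
            part = report[report["side"] == side]
            if len(part):
                log.info(
                    "parentage check %s side: %d duos, %.2f%% in conflict",
                    side,
                    len(part),
                    100.0 * part["conflict"].mean(),
                )
    return report
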