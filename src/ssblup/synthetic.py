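"""Synthetic breeding-population generator.

Generates multi-generation pedigrees with selected sires, marker
genotypes by Mendelian gene dropping with one crossover per chromosome
per meiosis, true SNP and residual polygenic effects that mirror the
generative structure of the single-step marker-effect model
(tbv = Z g + a, with a carrying the RPG fraction k of additive
variance along the pedigree), and one slaughter record per cow or
steer with herd-year, year-season and sex effects plus a linear age
covariate.

The default scenario emulates a beef-cattle carcass evaluation: four
traits with heritabilities between 0.28 and 0.48, moderate positive
genetic correlations except negative backfat pairs, a minority of
animals genotyped skewed to recent birth years, and a few
large-effect regions on three chromosomes for the first trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .genotype import GenotypeMatrix, snp_variance
from .mme import TRAITS_DEFAULT, VarianceComponents
from .pedigree import (
    MISSING,
    Pedigree,
    PhantomGroups,
    assign_phantom_groups,
)

log = logging.getLogger(__name__)


def default_variance_components(k: float = 0.2) -> VarianceComponents:
    """Plausible carcass-trait covariance structure (CW, EMA, BF, MS).

    Heritabilities 0.40/0.35/0.28/0.48 (within the 0.28-0.48 range of
    routine carcass evaluations), moderate positive genetic
    correlations except low negative BF-EMA and BF-MS, and mild
    positive residual correlations. Units: kg, cm^2, mm, score.
    """
    sigma_p = np.array([30.0, 8.0, 4.0, 2.0])
    h2 = np.array([0.40, 0.35, 0.28, 0.48])
    rg = np.array(
        [
            [1.00, 0.45, 0.30, 0.30],
            [0.45, 1.00, -0.10, 0.35],
            [0.30, -0.10, 1.00, -0.15],
            [0.30, 0.35, -0.15, 1.00],
        ]
    )
    re = np.array(
        [
            [1.00, 0.30, 0.20, 0.15],
            [0.30, 1.00, 0.05, 0.20],
            [0.20, 0.05, 1.00, 0.00],
            [0.15, 0.20, 0.00, 1.00],
        ]
    )
    su = sigma_p * np.sqrt(h2)
    se = sigma_p * np.sqrt(1.0 - h2)
    G0 = rg * np.outer(su, su)
    R0 = re * np.outer(se, se)
    return VarianceComponents(G0=G0, R0=R0, k=k)


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults give the standard scenario."""

    traits: tuple = TRAITS_DEFAULT
    n_founder_males: int = 40
    n_founder_females: int = 400
    n_generations: int = 4  # cohorts beyond the founder cohort
    n_sires: int = 40
    dams_per_sire: int = 10
    offspring_per_dam: int = 1
    # genotyping probability per cohort (founders first); bulls genotyped
    # with p_genotyped_bulls regardless of cohort
    p_genotyped: tuple = (0.02, 0.05, 0.12, 0.25, 0.55)
    p_genotyped_bulls: float = 0.9
    m_markers: int = 1000
    n_chromosomes: int = 10
    n_large_qtl: int = 3
    large_effect_multiplier: float = 16.0
    large_qtl_trait: int = 0
    large_qtl_chromosomes: tuple = (3, 5, 8)
    vc: VarianceComponents = field(default_factory=default_variance_components)
    base_year: int = 2008
    year_step: int = 2
    n_herds: int = 8
    herd_sd_frac: float = 0.4  # herd-year effect SD as fraction of phenotypic SD
    season_sd_frac: float = 0.15
    sex_effect_frac: float = 0.5  # steer minus cow shift, in phenotypic SD
    age_mean: float = 30.0  # months at slaughter
    age_sd: float = 2.0
    age_slopes: tuple = (2.0, 0.4, 0.2, 0.1)  # trait units per month of age
    selection: str = "index"  # "none" or "index" (truncation on sires)
    selection_index_weights: tuple = (1.0, 0.0, 0.0, 1.0)  # on genetic-SD scale
    selection_accuracy: float = 0.8
    p_missing_genotype: float = 0.01
    genotyping_error_rate: float = 0.0
    group_year_bins: tuple | None = None  # phantom-group year-bin edges
    # founder haplotypes are mosaics of a small ancestral pool, giving the
    # local linkage disequilibrium that lets marker scans localize signal
    n_ancestral_haplotypes: int = 20
    haplotype_switch_prob: float = 0.05  # per marker; mean segment ~20 markers
    qtl_min_maf: float = 0.2  # major genes segregate at intermediate frequency

    def phenotypic_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vc.G0) + np.diag(self.vc.R0))


@dataclass
class SimulatedPopulation:
    """Pedigree, genotypes, true effects and derived truth of one simulation."""

    config: SimulationConfig
    ped: Pedigree
    groups: PhantomGroups
    haplotypes: np.ndarray  # (n, 2, m) uint8, all animals
    codes_all: np.ndarray  # (n, m) dosage codes, all animals, no missing
    founder_freqs: np.ndarray
    marker_chrom: np.ndarray
    marker_pos: np.ndarray
    g_true: np.ndarray  # (m, t)
    a_true: np.ndarray  # (n, t)
    tbv: np.ndarray  # (n, t)
    genotyped_ids: list[str]
    qtl_markers: np.ndarray  # indices of planted large-effect markers
    qtl_regions: list[tuple[int, int, int]]  # (chromosome, lo, hi) marker index ranges

    def observed_genotypes(self, rng: np.random.Generator | None = None) -> GenotypeMatrix:
        """Genotype matrix of the genotyped subset, with missingness/errors applied."""
        cfg = self.config
        idx = self.ped.indices_of(self.genotyped_ids)
        codes = self.codes_all[idx].astype(float)
        if rng is not None:
            if cfg.genotyping_error_rate > 0:
                err = rng.random(codes.shape) < cfg.genotyping_error_rate
                codes[err] = rng.integers(0, 3, size=int(err.sum())).astype(float)
            if cfg.p_missing_genotype > 0:
                codes[rng.random(codes.shape) < cfg.p_missing_genotype] = np.nan
        return GenotypeMatrix(
            animal_ids=list(self.genotyped_ids),
            marker_ids=[f"snp{j}" for j in range(self.codes_all.shape[1])],
            chromosome=self.marker_chrom,
            position=self.marker_pos,
            codes=codes,
        )


def _marker_map(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    chrom = np.repeat(
        np.arange(1, cfg.n_chromosomes + 1),
        int(np.ceil(cfg.m_markers / cfg.n_chromosomes)),
    )[: cfg.m_markers]
    pos = np.concatenate(
        [np.arange((chrom == c).sum()) * 100000 + 100000 for c in np.unique(chrom)]
    )
    return chrom, pos


def _gamete(hap: np.ndarray, chrom_slices, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a parent's two haplotypes: one crossover per chromosome."""
    m = hap.shape[1]
    out = np.empty(m, dtype=np.uint8)
    for lo, hi in chrom_slices:
        ln = hi - lo
        start = int(rng.integers(0, 2))
        xo = int(rng.integers(1, ln)) if ln > 1 else 1
        out[lo : lo + xo] = hap[start, lo : lo + xo]
        out[lo + xo : hi] = hap[1 - start, lo + xo : hi]
    return out


def _inbreeding_one(i: int, sire: np.ndarray, dam: np.ndarray, dvec: np.ndarray) -> float:
    """F of animal i from its ancestors' Mendelian variances (Meuwissen-Luo step)."""
    if sire[i] == MISSING and dam[i] == MISSING:
        return 0.0
    contrib: dict[int, float] = {i: 1.0}
    a_ii = 0.0
    while contrib:
        j = max(contrib)
        r = contrib.pop(j)
        a_ii += r * r * dvec[j]
        if sire[j] != MISSING:
            contrib[sire[j]] = contrib.get(sire[j], 0.0) + 0.5 * r
        if dam[j] != MISSING:
            contrib[dam[j]] = contrib.get(dam[j], 0.0) + 0.5 * r
    return a_ii - 1.0


def simulate_population(cfg: SimulationConfig, seed: int) -> SimulatedPopulation:
    """Pedigree + genotypes + true genetic effects under the configured design.

    Founder marker genotypes are drawn from per-marker frequencies
    ~ U(0.05, 0.95); descendants by gene dropping with one crossover
    per chromosome per meiosis. True SNP effects are N(0, Sigma_SNP)
    with planted large-effect markers for one trait, rescaled per trait
    so the realized marker variance equals (1 - k) G0_ii at founder
    frequencies. Residual polygenic effects follow the pedigree
    gene-flow recursion (parent average plus Mendelian sampling with
    the exact inbreeding-adjusted variance) scaled to k * G0. Fully
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    t = cfg.vc.n_traits
    if len(cfg.traits) != t:
        raise DataError("trait names and variance components disagree")
    if cfg.n_sires > cfg.n_founder_males:
        raise DataError("mating design infeasible: more sires than founder males")
    n_off = cfg.n_sires * cfg.dams_per_sire * cfg.offspring_per_dam

    chrom, pos = _marker_map(cfg)
    m = cfg.m_markers
    chrom_slices = [
        (int(np.flatnonzero(chrom == c)[0]), int(np.flatnonzero(chrom == c)[-1]) + 1)
        for c in np.unique(chrom)
    ]
    p_anc = rng.uniform(0.05, 0.95, size=m)

    # --- pedigree containers
    n_founders = cfg.n_founder_males + cfg.n_founder_females
    n_total = n_founders + cfg.n_generations * n_off
    hap = np.zeros((n_total, 2, m), dtype=np.uint8)
    ids = [f"A{i:06d}" for i in range(n_total)]
    sire = np.full(n_total, MISSING, dtype=np.int64)
    dam = np.full(n_total, MISSING, dtype=np.int64)
    sex = np.empty(n_total, dtype=object)
    birth_year = np.empty(n_total, dtype=np.int64)
    animal_type = np.empty(n_total, dtype=object)
    Fcoef = np.zeros(n_total)
    dvec = np.ones(n_total)  # Mendelian sampling variance coefficient
    a_true = np.zeros((n_total, t))
    tbv = np.zeros((n_total, t))
    La = np.linalg.cholesky(cfg.vc.k * cfg.vc.G0) if cfg.vc.k > 0 else np.zeros((t, t))

    # --- founders: mosaics of a small ancestral haplotype pool, so nearby
    # markers are in linkage disequilibrium as on a real SNP chip
    K = max(2, cfg.n_ancestral_haplotypes)
    ancestral = (rng.random((K, m)) < p_anc).astype(np.uint8)
    males: list[int] = []
    females: list[int] = []
    for i in range(n_founders):
        is_male = i < cfg.n_founder_males
        sex[i] = "M" if is_male else "F"
        birth_year[i] = cfg.base_year
        animal_type[i] = "steer" if is_male else "cow"  # promoted to bull if selected
        for h in (0, 1):
            idx = np.empty(m, dtype=np.int64)
            for lo, hi in chrom_slices:
                mc = hi - lo
                draws = rng.integers(0, K, mc)
                switch = rng.random(mc) < cfg.haplotype_switch_prob
                switch[0] = True  # fresh draw at each chromosome start
                last = np.maximum.accumulate(np.where(switch, np.arange(mc), -1))
                idx[lo:hi] = draws[last]
            hap[i, h] = ancestral[idx, np.arange(m)]
        (males if is_male else females).append(i)

    # realized founder frequencies anchor the true-effect scaling and centering
    p0 = hap[:n_founders].sum(axis=(0, 1)) / (2.0 * n_founders)

    # --- true SNP effects with planted large-effect (major gene) markers
    het = 2.0 * p0 * (1.0 - p0)
    if het.sum() == 0.0:
        raise DataError("all simulated markers are monomorphic in the founders")
    sig = snp_variance(cfg.vc.G0, cfg.vc.k, np.clip(p0, 1e-3, 1 - 1e-3))
    L = np.linalg.cholesky(sig.sigma) if cfg.vc.k < 1.0 else np.zeros((t, t))
    g_true = rng.standard_normal((m, t)) @ L.T
    qtl_regions: list[tuple[int, int, int]] = []
    qtl_markers = np.empty(0, dtype=int)
    if cfg.n_large_qtl > 0 and cfg.vc.k < 1.0:
        if max(cfg.large_qtl_chromosomes) > cfg.n_chromosomes:
            raise DataError(
                "large_qtl_chromosomes outside the simulated genome "
                f"(n_chromosomes={cfg.n_chromosomes})"
            )
        per = max(1, cfg.n_large_qtl // max(1, len(cfg.large_qtl_chromosomes)))
        picks = []
        for c in cfg.large_qtl_chromosomes:
            lo, hi = chrom_slices[int(c) - 1]
            span = hi - lo
            rlo = lo + span // 3
            rhi = lo + 2 * span // 3
            qtl_regions.append((int(c), rlo, rhi))
            cand = np.arange(rlo, rhi)
            maf = np.minimum(p0[cand], 1.0 - p0[cand])
            common = cand[maf >= cfg.qtl_min_maf]
            if len(common) < per:  # fall back to the most polymorphic markers
                common = cand[np.argsort(-maf)][: max(per, 1)]
            picks.append(rng.choice(common, size=per, replace=False))
        qtl_markers = np.sort(np.concatenate(picks))
        # fixed magnitude with random sign so planted markers are the
        # top-|effect| markers of the trait by construction
        sd_qtl = float(np.sqrt(sig.sigma[cfg.large_qtl_trait, cfg.large_qtl_trait]))
        signs = rng.choice([-1.0, 1.0], size=qtl_markers.size)
        g_true[qtl_markers, cfg.large_qtl_trait] = (
            signs * cfg.large_effect_multiplier * sd_qtl
        )
    # rescale so the realized founder marker variance matches (1-k) G0_ii
    for ti in range(t):
        realized = float(het @ g_true[:, ti] ** 2)
        if realized > 0:
            target = (1.0 - cfg.vc.k) * cfg.vc.G0[ti, ti]
            g_true[:, ti] *= np.sqrt(target / realized)

    a_true[:n_founders] = rng.standard_normal((n_founders, t)) @ La.T
    z0 = hap[:n_founders].sum(axis=1).astype(float) - 2.0 * p0
    tbv[:n_founders] = z0 @ g_true + a_true[:n_founders]

    w = np.asarray(cfg.selection_index_weights, dtype=float) / np.sqrt(np.diag(cfg.vc.G0))

    def _select_sires(cands: list[int]) -> list[int]:
        if cfg.selection == "none" or len(cands) <= cfg.n_sires:
            perm = rng.permutation(len(cands))
            return [cands[j] for j in perm[: cfg.n_sires]]
        idx_arr = np.asarray(cands)
        crit = tbv[idx_arr] @ w
        if cfg.selection_accuracy < 1.0:
            rho = cfg.selection_accuracy
            noise_sd = crit.std() * np.sqrt(max(1.0 / rho**2 - 1.0, 0.0))
            crit = crit + rng.standard_normal(len(crit)) * noise_sd
        top = idx_arr[np.argsort(-crit)[: cfg.n_sires]]
        return [int(j) for j in top]

    # --- descendant generations
    nxt = n_founders
    for gen in range(1, cfg.n_generations + 1):
        year = cfg.base_year + gen * cfg.year_step
        sires = _select_sires(males)
        for s in sires:
            animal_type[s] = "bull"
        n_dams_needed = cfg.n_sires * cfg.dams_per_sire
        if len(females) >= n_dams_needed:
            perm = rng.permutation(len(females))
            dams = [females[j] for j in perm[:n_dams_needed]]
        else:
            dams = [females[int(j)] for j in rng.integers(0, len(females), n_dams_needed)]
        new_males: list[int] = []
        new_females: list[int] = []
        di = 0
        for s in sires:
            for _ in range(cfg.dams_per_sire):
                d = dams[di]
                di += 1
                for _ in range(cfg.offspring_per_dam):
                    i = nxt
                    nxt += 1
                    sire[i], dam[i] = s, d
                    birth_year[i] = year
                    is_male = rng.random() < 0.5
                    sex[i] = "M" if is_male else "F"
                    animal_type[i] = "steer" if is_male else "cow"
                    hap[i, 0] = _gamete(hap[s], chrom_slices, rng)
                    hap[i, 1] = _gamete(hap[d], chrom_slices, rng)
                    dvec[i] = 0.5 - 0.25 * (Fcoef[s] + Fcoef[d])
                    Fcoef[i] = _inbreeding_one(i, sire, dam, dvec)
                    a_true[i] = 0.5 * (a_true[s] + a_true[d]) + (
                        rng.standard_normal(t) @ La.T
                    ) * np.sqrt(dvec[i])
                    z_i = hap[i].sum(axis=0).astype(float) - 2.0 * p0
                    tbv[i] = z_i @ g_true + a_true[i]
                    (new_males if is_male else new_females).append(i)
        males, females = new_males, new_females

    path = np.where(sex == "M", "sire_path", "dam_path")
    ped = Pedigree(
        ids=ids,
        sire=sire,
        dam=dam,
        birth_year=birth_year,
        sex=sex,
        path=path,
        animal_type=animal_type,
    )
    groups = assign_phantom_groups(
        ped,
        year_bins=list(cfg.group_year_bins) if cfg.group_year_bins else None,
    )

    codes_all = hap.sum(axis=1).astype(np.int8)

    # --- genotyped subset: per-cohort probabilities, bulls near-certain
    p_gen = list(cfg.p_genotyped)
    while len(p_gen) < cfg.n_generations + 1:
        p_gen.append(p_gen[-1])
    cohort = (birth_year - cfg.base_year) // max(cfg.year_step, 1)
    genotyped = rng.random(n_total) < np.asarray(p_gen)[cohort]
    genotyped |= (animal_type == "bull") & (rng.random(n_total) < cfg.p_genotyped_bulls)
    genotyped_ids = [ids[i] for i in np.flatnonzero(genotyped)]

    return SimulatedPopulation(
        config=cfg,
        ped=ped,
        groups=groups,
        haplotypes=hap,
        codes_all=codes_all,
        founder_freqs=p0,
        marker_chrom=chrom,
        marker_pos=pos,
        g_true=g_true,
        a_true=a_true,
        tbv=tbv,
        genotyped_ids=genotyped_ids,
        qtl_markers=qtl_markers,
        qtl_regions=qtl_regions,
    )


def simulate_phenotypes(
    pop: SimulatedPopulation,
    seed: int,
    return_components: bool = False,
):
    """One slaughter record per cow and steer.

    y = herd-year + year-season + sex + beta * (age - mean_age) + tbv + e
    with e ~ N(0, R0) across traits; bulls get no record.
    """
    cfg = pop.config
    rng = np.random.default_rng(seed)
    ped = pop.ped
    t = cfg.vc.n_traits
    sp_sd = cfg.phenotypic_sd()

    rec = np.flatnonzero(np.isin(ped.animal_type, ["cow", "steer"]))
    n_rec = rec.size
    slaughter_year = ped.birth_year[rec] + 2
    herd = rng.integers(0, cfg.n_herds, n_rec)
    season = rng.integers(1, 5, n_rec)
    hy_labels = [f"h{h}_y{y}" for h, y in zip(herd, slaughter_year)]
    ys_labels = [f"y{y}_q{q}" for y, q in zip(slaughter_year, season)]
    age = rng.normal(cfg.age_mean, cfg.age_sd, n_rec)

    def _level_effects(labels: list[str], sd_frac: float) -> np.ndarray:
        eff = {
            lev: rng.standard_normal(t) * (sd_frac * sp_sd)
            for lev in sorted(set(labels))
        }
        return np.vstack([eff[lab] for lab in labels])

    fixed = _level_effects(hy_labels, cfg.herd_sd_frac)
    fixed += _level_effects(ys_labels, cfg.season_sd_frac)
    sex_shift = cfg.sex_effect_frac * sp_sd
    is_steer = (ped.animal_type[rec] == "steer").astype(float)[:, None]
    fixed = fixed + is_steer * sex_shift
    beta = np.asarray(cfg.age_slopes, dtype=float)
    fixed = fixed + np.outer(age - cfg.age_mean, beta)

    if np.allclose(cfg.vc.R0, 0.0):
        e = np.zeros((n_rec, t))
    else:
        e = rng.standard_normal((n_rec, t)) @ np.linalg.cholesky(cfg.vc.R0).T
    y = fixed + pop.tbv[rec] + e

    df = pd.DataFrame(
        {
            "animal_id": [ped.ids[i] for i in rec],
            "birth_year": ped.birth_year[rec],
            "herd_year": hy_labels,
            "year_season": ys_labels,
            "sex": ped.animal_type[rec],
            "age": age,
        }
    )
    for ti, tr in enumerate(cfg.traits):
        df[tr] = y[:, ti]
    if return_components:
        return df, {"fixed": fixed, "tbv": pop.tbv[rec], "residual": e}
    return df


@dataclass
class Scenario:
    """A full synthetic dataset bundle ready for the four-evaluation study."""

    config: SimulationConfig
    pop: SimulatedPopulation
    phenotypes: pd.DataFrame
    genotypes: GenotypeMatrix
    vc: VarianceComponents
    cutoff_year: int
    base_cohort_year: int
    seed: int


def make_paper_like_scenario(seed: int, **overrides) -> Scenario:
    """Desk-scale default bundle.

    ~2,000 animals over 5 cohorts, ~500 genotyped (skewed to recent
    birth years), 1,000 markers on 10 chromosomes, k = 0.2, three
    planted large-effect regions for the first trait, and a truncation
    cutoff that removes the last cohort's phenotypes. The common base
    cohort for rebasing is the last cohort born before the cutoff with
    carcass records.
    """
    cfg = SimulationConfig(**overrides) if overrides else SimulationConfig()
    pop = simulate_population(cfg, seed=seed)
    phen = simulate_phenotypes(pop, seed=seed + 1)
    last_year = int(pop.ped.birth_year.max())
    cutoff = last_year - cfg.year_step
    rng = np.random.default_rng(seed + 2)
    genotypes = pop.observed_genotypes(rng=rng)
    return Scenario(
        config=cfg,
        pop=pop,
        phenotypes=phen,
        genotypes=genotypes,
        vc=cfg.vc,
        cutoff_year=cutoff,
        base_cohort_year=cutoff,
        seed=seed,
    )
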