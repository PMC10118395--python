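"""End-to-end orchestration of the four-evaluation comparison study.

Runs single-step and conventional evaluations on the full and
truncated datasets from one shared set of inputs, rebases everything
to a common base cohort, and derives the validation summaries: LR
regression tests, SNP-effect agreement, per-birth-year prediction
correlations, genome scans and genetic trends.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConvergenceError, DataError
from .evaluation import genetic_trend, rebase_and_scale, standardize_snp_effects
from .genotype import (
    GenotypeMatrix,
    center_genotypes,
    compute_allele_frequencies,
    impute_missing,
    snp_variance,
)
from .mme import (
    EvaluationResult,
    ModelSpec,
    VarianceComponents,
    assemble_conventional,
    assemble_ssgblup,
    assemble_ssnpblup,
    build_design,
    solve_direct,
    solve_pcg,
)
from .pedigree import (
    Pedigree,
    PhantomGroups,
    build_a22,
    build_a_inverse,
    compute_inbreeding,
)
from .validation import (
    TruncationScheme,
    correlation_by_birth_year,
    effect_agreement,
    lr_test,
    select_validation_cohort,
    truncate_data,
)

log = logging.getLogger(__name__)


@dataclass
class EvaluationContext:
    """Phenotype-independent structures shared by all four evaluations."""

    ped: Pedigree
    groups: PhantomGroups | None
    a_inverse: object
    a22: np.ndarray
    Z: np.ndarray
    geno_idx: np.ndarray
    genotyped_ids: list[str]
    marker_frame: pd.DataFrame
    snp_cov: object
    vc: VarianceComponents
    traits: tuple


def prepare_context(
    ped: Pedigree,
    genotypes: GenotypeMatrix,
    vc: VarianceComponents,
    traits,
    groups: PhantomGroups | None = None,
) -> EvaluationContext:
    """Allele frequencies, imputation, centering, A-inverse, A22, marker variance."""
    inb = compute_inbreeding(ped)
    a_inv = build_a_inverse(ped, inbreeding=inb, groups=groups)
    a22 = build_a22(ped, genotypes.animal_ids)
    freqs = compute_allele_frequencies(genotypes)
    imputed = impute_missing(genotypes, freqs)
    Z = center_genotypes(imputed, freqs)
    cov = snp_variance(vc.G0, vc.k, freqs.p)
    geno_idx = ped.indices_of(genotypes.animal_ids)
    return EvaluationContext(
        ped=ped,
        groups=groups,
        a_inverse=a_inv,
        a22=a22,
        Z=Z,
        geno_idx=geno_idx,
        genotyped_ids=list(genotypes.animal_ids),
        marker_frame=genotypes.marker_frame(),
        snp_cov=cov,
        vc=vc,
        traits=tuple(traits),
    )


def evaluate(
    ctx: EvaluationContext,
    phenotypes: pd.DataFrame,
    model_kind: str,
    tol: float = 1e-10,
    max_iter: int = 10000,
    solver: str = "pcg",
    model_spec: ModelSpec | None = None,
) -> EvaluationResult:
    """Assemble and solve one evaluation of the requested model kind."""
    spec = model_spec or ModelSpec(traits=ctx.traits)
    design = build_design(phenotypes, spec, ctx.ped)
    if model_kind == "conventional":
        mme = assemble_conventional(design, ctx.ped, ctx.a_inverse, ctx.vc)
    elif model_kind == "ssnpblup":
        mme = assemble_ssnpblup(
            design,
            ctx.ped,
            ctx.a_inverse,
            ctx.a22,
            ctx.Z,
            ctx.vc,
            ctx.snp_cov,
            ctx.geno_idx,
            marker_ids=list(ctx.marker_frame["marker_id"]),
        )
    elif model_kind == "ssgblup":
        mme = assemble_ssgblup(
            design, ctx.ped, ctx.a_inverse, ctx.a22, ctx.Z, ctx.vc, ctx.snp_cov, ctx.geno_idx
        )
    else:
        raise DataError(f"unknown model kind {model_kind!r}")
    if solver == "direct":
        res = solve_direct(mme)
    else:
        res = solve_pcg(mme, tol=tol, max_iter=max_iter)
        if not res.converged:
            raise ConvergenceError(
                f"{model_kind} evaluation did not converge "
                f"(residual {res.final_residual:.2e} after {res.iterations} iterations)"
            )
    log.info(
        "%s: %d equations, %d iterations, residual %.2e",
        model_kind,
        mme.dimension,
        res.iterations,
        res.final_residual,
    )
    return res


@dataclass
class StudyResults:
    """All artifacts of the four-evaluation forward-validation study."""

    gebv: dict  # (model, dataset) -> rebased long GEBV table
    raw: dict  # (model, dataset) -> EvaluationResult
    lr: pd.DataFrame
    agreement: pd.DataFrame
    year_correlations: pd.DataFrame
    scans: dict  # dataset -> standardized SNP scan (single-step runs)
    trends: pd.DataFrame
    cohorts: dict  # stratum -> validation animal ids
    cutoff_year: int
    base_cohort_year: int


def _base_cohort(ped: Pedigree, phenotypes_full: pd.DataFrame, base_year: int) -> list[str]:
    phenotyped = set(phenotypes_full["animal_id"])
    ids = [
        a
        for i, a in enumerate(ped.ids)
        if ped.birth_year[i] == base_year and a in phenotyped
    ]
    if not ids:
        raise DataError(f"no base-cohort animals born {base_year} with records")
    return ids


def run_study(
    ped: Pedigree,
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    vc: VarianceComponents,
    traits,
    cutoff_year: int,
    base_cohort_year: int,
    groups: PhantomGroups | None = None,
    tol: float = 1e-10,
    max_iter: int = 10000,
    single_step_kind: str = "ssnpblup",
    strata: tuple = ("cows", "steers", "both"),
) -> StudyResults:
    """The four-evaluation comparison on one dataset.

    Single-step and conventional BLUP are each run on the full and the
    truncated data (records of animals born after ``cutoff_year``
    removed; pedigree and genotypes kept). Both models share identical
    cohorts and the common base (animals born in ``base_cohort_year``
    with records in the full data), so their LR statistics are directly
    comparable.
    """
    ctx = prepare_context(ped, genotypes, vc, traits, groups=groups)
    scheme = TruncationScheme(cutoff_birth_year=cutoff_year)
    phen_trunc = truncate_data(phenotypes, ped, scheme)
    base_ids = _base_cohort(ped, phenotypes, base_cohort_year)

    datasets = {"full": phenotypes, "truncated": phen_trunc}
    models = {"ssm": single_step_kind, "conv": "conventional"}
    raw: dict = {}
    gebv: dict = {}
    for mname, kind in models.items():
        for dname, phen in datasets.items():
            res = evaluate(ctx, phen, kind, tol=tol, max_iter=max_iter)
            raw[(mname, dname)] = res
            gebv[(mname, dname)] = rebase_and_scale(res, ped, base_ids, vc.G0)

    # LR tests per stratum, both models on identical cohorts
    lr_rows = []
    cohorts = {}
    for stratum in strata:
        try:
            cohort = select_validation_cohort(
                ped, genotypes.animal_ids, phenotypes, scheme, stratum=stratum
            )
        except DataError:
            log.warning("no validation animals in stratum %s", stratum)
            continue
        cohorts[stratum] = cohort
        for mname in models:
            res = lr_test(gebv[(mname, "full")], gebv[(mname, "truncated")], cohort)
            res.insert(0, "stratum", stratum)
            res.insert(1, "model", mname.upper())
            lr_rows.append(res)
    lr = pd.concat(lr_rows, ignore_index=True) if lr_rows else pd.DataFrame()

    # SNP-effect agreement and scans (single-step marker-effect runs only)
    agreement = pd.DataFrame()
    scans = {}
    if single_step_kind == "ssnpblup":
        gf = raw[("ssm", "full")].g
        gt = raw[("ssm", "truncated")].g
        if gf is not None and gt is not None:
            agreement = effect_agreement(gf, gt, traits)
            scans = {
                d: standardize_snp_effects(raw[("ssm", d)].g, ctx.snp_cov, ctx.marker_frame, traits)
                for d in datasets
            }

    # per-birth-year correlations: phenotyped steers, and all genotyped animals
    phenotyped = set(phenotypes["animal_id"])
    steer_ids = [
        a
        for i, a in enumerate(ped.ids)
        if ped.animal_type[i] == "steer" and a in phenotyped
    ]
    yc_rows = []
    for cname, ids in (
        ("steers_with_records", steer_ids),
        ("genotyped_all", list(genotypes.animal_ids)),
    ):
        for mname in models:
            yc = correlation_by_birth_year(
                gebv[(mname, "full")], gebv[(mname, "truncated")], ped, ids
            )
            yc.insert(0, "cohort", cname)
            yc.insert(1, "model", mname.upper())
            yc_rows.append(yc)
    year_correlations = pd.concat(yc_rows, ignore_index=True)

    # genetic trends of the single-step full evaluation
    cow_ids = [
        a for i, a in enumerate(ped.ids) if ped.animal_type[i] == "cow" and a in phenotyped
    ]
    trends = pd.concat(
        [
            genetic_trend(gebv[("ssm", "full")], steer_ids, "steers_with_records"),
            genetic_trend(gebv[("ssm", "full")], cow_ids, "cows_with_records"),
            genetic_trend(gebv[("ssm", "full")], list(genotypes.animal_ids), "genotyped_all"),
        ],
        ignore_index=True,
    )

    return StudyResults(
        gebv=gebv,
        raw=raw,
        lr=lr,
        agreement=agreement,
        year_correlations=year_correlations,
        scans=scans,
        trends=trends,
        cohorts=cohorts,
        cutoff_year=cutoff_year,
        base_cohort_year=base_cohort_year,
    )


def write_study(study: StudyResults, outdir, meta: dict | None = None) -> None:
    """Write all study tables as TSV with '#' unit/metadata headers."""
    from .io import write_table

    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_lines = [f"{k}: {v}" for k, v in (meta or {}).items()]
    for (mname, dname), table in study.gebv.items():
        write_table(
            table,
            outdir / f"gebv_{mname}_{dname}.tsv",
            [
                f"model {mname}, dataset {dname}",
                "gebv_raw in trait units; gebv_sd rebased to the base cohort,"
                " in genetic standard deviations",
                f"base cohort: born {study.base_cohort_year} with records",
                *meta_lines,
            ],
        )
    if len(study.lr):
        write_table(
            study.lr,
            outdir / "lr_results.tsv",
            ["LR test: full regressed on truncated, genetic-SD units", *meta_lines],
        )
    if len(study.agreement):
        write_table(
            study.agreement,
            outdir / "effect_agreement.tsv",
            ["SNP-effect correlation and slope, full vs truncated", *meta_lines],
        )
    for dname, scan in study.scans.items():
        write_table(
            scan,
            outdir / f"snp_scan_{dname}.tsv",
            ["standardized SNP effects (units of marker genetic SD)", *meta_lines],
        )
    write_table(
        study.year_correlations,
        outdir / "year_correlations.tsv",
        ["per-birth-year correlation of full vs truncated predictions", *meta_lines],
    )
    write_table(
        study.trends,
        outdir / "trends.tsv",
        ["mean GEBV by birth year, genetic-SD units", *meta_lines],
    )
    conv = {
        f"{m}_{d}": {
            "iterations": study.raw[(m, d)].iterations,
            "residual": study.raw[(m, d)].final_residual,
            "converged": bool(study.raw[(m, d)].converged),
        }
        for (m, d) in study.raw
    }
    (outdir / "run_log.json").write_text(
        json.dumps(
            {"meta": meta or {}, "convergence": conv, "written": time.strftime("%F %T")},
            indent=2,
        )
    )
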