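import numpy as np
import pandas as pd
import pytest

from ssblup.errors import DataError
from ssblup.genotype import snp_variance
from ssblup.mme import (
    ModelSpec,
    VarianceComponents,
    assemble_conventional,
    assemble_ssgblup,
    assemble_ssnpblup,
    build_design,
    prediction_error_variance,
    solve_direct,
    solve_pcg,
)
from ssblup.pedigree import (
    PedigreeRecord,
    build_a22,
    build_a_inverse,
    sort_and_validate,
)
from ssblup.pipeline import evaluate, prepare_context
from ssblup.synthetic import default_variance_components, simulate_phenotypes, simulate_population

from conftest import random_pedigree, small_config
from oracles import dense_mme_oracle


def _single_trait_vc(su2=1.0, se2=2.0):
    return VarianceComponents(G0=np.array([[su2]]), R0=np.array([[se2]]), k=0.2)


def _pheno(ped, y, **cols):
    n = len(y)
    base = {
        "animal_id": [ped.ids[i] for i in range(n)],
        "herd_year": cols.get("herd_year", ["h1"] * n),
        "year_season": cols.get("year_season", ["s1"] * n),
        "sex": cols.get("sex", ["steer"] * n),
        "age": cols.get("age", np.linspace(28, 32, n)),
    }
    df = pd.DataFrame(base)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != n:
        y = y.T
    for ti in range(y.shape[1]):
        df[f"T{ti}"] = y[:, ti]
    return df


class TestBuildDesign:
    def test_level_counting_fully_crossed(self):
        recs = [PedigreeRecord(f"a{i}", None, None, 2000, "M") for i in range(8)]
        ped = sort_and_validate(recs)
        df = _pheno(
            ped,
            np.arange(8.0),
            herd_year=["h1", "h1", "h2", "h2"] * 2,
            year_season=["s1", "s2"] * 4,
            sex=["cow", "steer"] * 4,
        )
        spec = ModelSpec(traits=("T0",))
        d = build_design(df, spec, ped)
        # 2 + 2 + 2 class equations and 1 covariate per trait
        class_blocks = [b for b in d.blocks if b[0] != "covariate"]
        assert len(class_blocks) == 6
        assert sum(1 for b in d.blocks if b[0] == "covariate") == 1
        # one reference level fixed at zero per effect after the first
        assert len(d.constrained) == 2

    def test_single_level_effect_still_solvable(self):
        recs = [PedigreeRecord(f"a{i}", None, None, 2000, "M") for i in range(4)]
        ped = sort_and_validate(recs)
        df = _pheno(ped, [1.0, 2.0, 3.0, 4.0])
        d = build_design(df, ModelSpec(traits=("T0",)), ped)
        mme = assemble_conventional(d, ped, build_a_inverse(ped), _single_trait_vc())
        res = solve_direct(mme)
        assert np.isfinite(res.u).all()

    def test_incidence_reproduces_assignment(self):
        rng = np.random.default_rng(0)
        recs = [PedigreeRecord(f"a{i}", None, None, 2000, "M") for i in range(30)]
        ped = sort_and_validate(recs)
        hy = [f"h{rng.integers(3)}" for _ in range(30)]
        df = _pheno(ped, rng.normal(size=30), herd_year=hy)
        d = build_design(df, ModelSpec(traits=("T0",)), ped)
        W = d.W_fixed.toarray()
        for r, lab in enumerate(hy):  # exhaustive scan of record-to-level coding
            col = d.blocks.index(("herd_year", lab))
            assert W[r, col] == 1.0

    def test_missing_trait_value_rejected(self):
        recs = [PedigreeRecord(f"a{i}", None, None, 2000, "M") for i in range(3)]
        ped = sort_and_validate(recs)
        df = _pheno(ped, [1.0, np.nan, 3.0])
        with pytest.raises(DataError, match="all-or-none"):
            build_design(df, ModelSpec(traits=("T0",)), ped)


class TestConventional:
    def test_single_founder_shrinkage_closed_form(self):
        # no fixed effects, one record y on one founder: u = y / (1 + lambda)
        ped = sort_and_validate([PedigreeRecord("1", None, None, 0, "M")])
        y = 3.0
        su2, se2 = 1.0, 2.0
        df = pd.DataFrame({"animal_id": ["1"], "T0": [y]})
        spec = ModelSpec(traits=("T0",), class_effects=(), covariates=())
        d = build_design(df, spec, ped)
        mme = assemble_conventional(d, ped, build_a_inverse(ped), _single_trait_vc(su2, se2))
        res = solve_direct(mme)
        lam = se2 / su2
        assert res.u[0, 0] == pytest.approx(y / (1 + lam))

    def test_diagonal_covariances_decouple_traits(self):
        ped = random_pedigree(2, n=40, n_founders=8)
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(40, 2)) * 3
        df = _pheno(ped, Y, herd_year=[f"h{i % 2}" for i in range(40)])
        G0 = np.diag([1.0, 2.0])
        R0 = np.diag([2.0, 1.0])
        vc2 = VarianceComponents(G0=G0, R0=R0, k=0.2)
        spec2 = ModelSpec(traits=("T0", "T1"))
        ai = build_a_inverse(ped)
        res2 = solve_direct(assemble_conventional(build_design(df, spec2, ped), ped, ai, vc2))
        for ti in range(2):
            vc1 = VarianceComponents(
                G0=G0[ti : ti + 1, ti : ti + 1], R0=R0[ti : ti + 1, ti : ti + 1], k=0.2
            )
            df1 = df.drop(columns=[f"T{1 - ti}"]).rename(columns={f"T{ti}": "T0"})
            spec1 = ModelSpec(traits=("T0",))
            res1 = solve_direct(
                assemble_conventional(build_design(df1, spec1, ped), ped, ai, vc1)
            )
            np.testing.assert_allclose(res2.u[:, ti], res1.u[:, 0], atol=1e-10)

    def test_matches_dense_gls_oracle_two_traits(self):
        ped = random_pedigree(4, n=30, n_founders=6, p_known=1.0)
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(30, 2))
        hy = [f"h{rng.integers(2)}" for _ in range(30)]
        sx = ["cow" if i % 2 else "steer" for i in range(30)]
        df = _pheno(ped, Y, herd_year=hy, sex=sx)
        G0 = np.array([[1.0, 0.3], [0.3, 2.0]])
        R0 = np.array([[2.0, 0.5], [0.5, 3.0]])
        vc = VarianceComponents(G0=G0, R0=R0, k=0.2)
        spec = ModelSpec(traits=("T0", "T1"))
        mme = assemble_conventional(
            build_design(df, spec, ped), ped, build_a_inverse(ped), vc
        )
        res = solve_direct(mme)
        from oracles import relationship_oracle
        from ssblup.pedigree import MISSING

        sire = {a: (ped.ids[ped.sire[i]] if ped.sire[i] != MISSING else None) for i, a in enumerate(ped.ids)}
        dam = {a: (ped.ids[ped.dam[i]] if ped.dam[i] != MISSING else None) for i, a in enumerate(ped.ids)}
        A = relationship_oracle(sire, dam, list(ped.ids))
        _, u_oracle = dense_mme_oracle(
            df, ("T0", "T1"), ("herd_year", "year_season", "sex"), ("age",),
            ped, np.linalg.inv(A), G0, R0,
        )
        assert np.abs(res.u - u_oracle).max() < 1e-8

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(DataError, match="positive definite"):
            VarianceComponents(G0=np.array([[-1.0]]), R0=np.array([[1.0]]))


class TestSolvers:
    def test_pcg_identity_system_converges_immediately(self, small_pop):
        ctx = small_pop["ctx"]
        phen = small_pop["phen"]
        from ssblup.mme import MixedModelEquations
        import scipy.sparse as sp

        mme = assemble_conventional(
            build_design(phen, ModelSpec(traits=small_pop["cfg"].traits), ctx.ped),
            ctx.ped, ctx.a_inverse, ctx.vc,
        )
        rhs = np.arange(mme.dimension, dtype=float)
        ident = MixedModelEquations(
            C=sp.identity(mme.dimension, format="csr").tobsr(blocksize=(mme.t, mme.t)),
            rhs=rhs, t=mme.t, traits=mme.traits, design=mme.design,
            model_kind="conventional", n_fixed_blocks=mme.n_fixed_blocks,
            n_animals=mme.n_animals, n_groups=mme.n_groups, m=0,
            constrained=[], vc=mme.vc, animal_ids=mme.animal_ids,
        )
        res = solve_pcg(ident)
        assert res.iterations == 1 and res.converged

    @pytest.mark.parametrize("kind", ["conventional", "ssnpblup", "ssgblup"])
    def test_pcg_matches_direct(self, small_pop, kind):
        ctx, phen = small_pop["ctx"], small_pop["phen"]
        rd = evaluate(ctx, phen, kind, solver="direct")
        rp = evaluate(ctx, phen, kind, solver="pcg")
        gsd = np.sqrt(np.diag(ctx.vc.G0))
        assert (np.abs(rd.u - rp.u) / gsd).max() < 1e-8

    def test_solution_invariant_to_record_permutation(self, small_pop):
        ctx, phen = small_pop["ctx"], small_pop["phen"]
        rng = np.random.default_rng(8)
        shuffled = phen.sample(frac=1.0, random_state=8).reset_index(drop=True)
        r1 = evaluate(ctx, phen, "ssnpblup", solver="direct")
        r2 = evaluate(ctx, shuffled, "ssnpblup", solver="direct")
        np.testing.assert_allclose(r1.u, r2.u, atol=1e-8)

    def test_solution_invariant_to_marker_permutation(self, small_pop):
        import copy

        ctx, phen = small_pop["ctx"], small_pop["phen"]
        rng = np.random.default_rng(9)
        perm = rng.permutation(ctx.Z.shape[1])
        ctx2 = copy.copy(ctx)
        ctx2.Z = ctx.Z[:, perm]
        cov = ctx.snp_cov
        ctx2.marker_frame = ctx.marker_frame.iloc[perm].reset_index(drop=True)
        r1 = evaluate(ctx, phen, "ssnpblup", solver="direct")
        r2 = evaluate(ctx2, phen, "ssnpblup", solver="direct")
        np.testing.assert_allclose(r1.u, r2.u, atol=1e-8)
        np.testing.assert_allclose(r1.g[perm], r2.g, atol=1e-8)

    def test_direct_refuses_oversized_system(self, small_pop):
        ctx, phen = small_pop["ctx"], small_pop["phen"]
        mme = assemble_conventional(
            build_design(phen, ModelSpec(traits=small_pop["cfg"].traits), ctx.ped),
            ctx.ped, ctx.a_inverse, ctx.vc,
        )
        mme_big = mme
        mme_big.n_animals = 10**6  # fake dimension check
        with pytest.raises(DataError, match="too large"):
            solve_direct(mme_big)

    def test_more_records_never_worse_reliability(self):
        # prediction error variance shrinks (or holds) when records are added
        cfg = small_config(n_founder_males=6, n_founder_females=20, n_generations=2,
                          n_sires=6, dams_per_sire=3, m_markers=60, n_chromosomes=3,
                          large_qtl_chromosomes=(1, 2, 3), n_large_qtl=3,
                          p_genotyped=(0.5, 0.5, 0.5))
        pop = simulate_population(cfg, seed=21)
        phen = simulate_phenotypes(pop, seed=22)
        geno = pop.observed_genotypes()
        ctx = prepare_context(pop.ped, geno, cfg.vc, cfg.traits, groups=pop.groups)
        spec = ModelSpec(traits=cfg.traits)
        d_all = build_design(phen, spec, pop.ped)
        d_half = build_design(phen.iloc[: len(phen) // 2], spec, pop.ped)
        pev_all = prediction_error_variance(
            assemble_conventional(d_all, pop.ped, ctx.a_inverse, ctx.vc)
        )
        pev_half = prediction_error_variance(
            assemble_conventional(d_half, pop.ped, ctx.a_inverse, ctx.vc)
        )
        assert (pev_all <= pev_half + 1e-9).all()


class TestSingleStepModels:
    def test_k_zero_rejected(self, small_pop):
        ctx, phen = small_pop["ctx"], small_pop["phen"]
        vc0 = VarianceComponents(G0=ctx.vc.G0, R0=ctx.vc.R0, k=0.0)
        d = build_design(phen, ModelSpec(traits=small_pop["cfg"].traits), ctx.ped)
        with pytest.raises(DataError, match="k > 0"):
            assemble_ssnpblup(
                d, ctx.ped, ctx.a_inverse, ctx.a22, ctx.Z, vc0,
                ctx.snp_cov, ctx.geno_idx,
            )

    def test_k_one_collapses_to_conventional(self, small_pop):
        ctx, phen = small_pop["ctx"], small_pop["phen"]
        cfg = small_pop["cfg"]
        vc1 = default_variance_components(k=1.0)
        ctx1 = prepare_context(
            small_pop["pop"].ped, small_pop["geno"], vc1, cfg.traits,
            groups=small_pop["pop"].groups,
        )
        conv = evaluate(ctx1, phen, "conventional", solver="direct")
        ssm = evaluate(ctx1, phen, "ssnpblup", solver="direct")
        ssg = evaluate(ctx1, phen, "ssgblup", solver="direct")
        assert np.abs(ssm.u - conv.u).max() < 1e-8
        assert np.abs(ssg.u - conv.u).max() < 1e-8
        assert np.all(ssm.g == 0.0)

    def test_decomposition_identity(self, small_pop):
        ctx, phen = small_pop["ctx"], small_pop["phen"]
        res = evaluate(ctx, phen, "ssnpblup", solver="pcg")
        lhs = res.u[ctx.geno_idx]
        rhs = ctx.Z @ res.g + res.a
        assert np.abs(lhs - rhs).max() < 10 * 1e-10

    @pytest.mark.parametrize("k", [0.1, 0.2, 0.5])
    def test_marker_and_hmatrix_models_agree(self, k):
        cfg = small_config(vc=default_variance_components(k=k))
        pop = simulate_population(cfg, seed=31)
        phen = simulate_phenotypes(pop, seed=32)
        geno = pop.observed_genotypes(np.random.default_rng(33))
        ctx = prepare_context(pop.ped, geno, cfg.vc, cfg.traits, groups=pop.groups)
        r1 = evaluate(ctx, phen, "ssnpblup", solver="direct")
        r2 = evaluate(ctx, phen, "ssgblup", solver="direct")
        gsd = np.sqrt(np.diag(cfg.vc.G0))
        assert (np.abs(r1.u - r2.u) / gsd).max() < 1e-6
        for ti in range(len(cfg.traits)):
            assert np.corrcoef(r1.u[:, ti], r2.u[:, ti])[0, 1] > 0.9999
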