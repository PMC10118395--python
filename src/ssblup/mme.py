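"""Multi-trait mixed-model equations for pedigree and single-step models.

Assembles and solves the sparse symmetric systems for three model
kinds sharing one design:

* conventional multi-trait animal-model BLUP (pedigree prior only),
* single-step SNP BLUP (ssSNPBLUP): SNP effects g are explicit
  unknowns and a genotyped animal's breeding value decomposes as
  u = Z g + a with a residual polygenic (RPG) term a carrying the
  fraction k of additive variance,
* single-step GBLUP (ssGBLUP): the equivalent H-matrix formulation,
  kept as an independent cross-check of the marker-effect model.

Equations are ordered block-major with the t traits of one effect
level adjacent, so every prior is a Kronecker product of a scalar
structure matrix with the 4x4 (co)variance inverse and the solver can
use an exact t x t (and exact marker-block) preconditioner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .errors import ConvergenceError, DataError
from .genotype import SnpCovariance
from .pedigree import Pedigree, RelationshipInverse

log = logging.getLogger(__name__)

TRAITS_DEFAULT = ("CW", "EMA", "BF", "MS")


def _check_spd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DataError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise DataError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(M)
    except np.linalg.LinAlgError as e:
        raise DataError(f"{name} is not positive definite") from e
    return M


@dataclass
class VarianceComponents:
    """Additive genetic covariance G0, residual covariance R0, RPG fraction k."""

    G0: np.ndarray
    R0: np.ndarray
    k: float = 0.2

    def __post_init__(self):
        self.G0 = _check_spd(self.G0, "G0")
        self.R0 = _check_spd(self.R0, "R0")
        if self.G0.shape != self.R0.shape:
            raise DataError("G0 and R0 dimensions differ")
        if not 0.0 <= self.k <= 1.0:
            raise DataError(f"k={self.k} outside [0, 1]")

    @property
    def n_traits(self) -> int:
        return self.G0.shape[0]

    @property
    def heritabilities(self) -> np.ndarray:
        g = np.diag(self.G0)
        return g / (g + np.diag(self.R0))


@dataclass
class ModelSpec:
    """Trait list and fixed-effect structure of the evaluation model."""

    traits: tuple = TRAITS_DEFAULT
    class_effects: tuple = ("herd_year", "year_season", "sex")
    covariates: tuple = ("age",)


@dataclass
class Design:
    """Record-level design: class-effect coding, covariates, responses.

    ``blocks`` lists the fixed-effect scalar blocks (all class levels,
    then covariates); ``constrained`` marks the reference level of each
    class effect after the first, whose equations are fixed at zero for
    identifiability.
    """

    spec: ModelSpec
    blocks: list[tuple[str, str]]
    constrained: list[int]
    levels: dict[str, list]
    rec_animal: np.ndarray
    W_fixed: sp.csr_matrix
    Y: np.ndarray
    covariate_means: dict[str, float]
    animal_ids: list[str]

    @property
    def n_records(self) -> int:
        return self.Y.shape[0]

    @property
    def n_fixed_blocks(self) -> int:
        return len(self.blocks)


def build_design(phenotypes: pd.DataFrame, spec: ModelSpec, ped: Pedigree) -> Design:
    """Code class effects and covariates into sparse incidence structures.

    Requires one complete record per animal (all traits observed, all
    class labels and covariates present). Class levels are coded in
    sorted label order so equation numbering is reproducible under any
    record permutation. The first level of every class effect after the
    first is constrained to zero (reference coding; the first effect
    carries the cell means); singleton levels are allowed but logged.
    """
    ph = phenotypes
    for tr in spec.traits:
        if tr not in ph.columns:
            raise DataError(f"phenotype table lacks trait column {tr!r}")
        if ph[tr].isna().any():
            raise DataError(
                f"trait {tr!r} has missing values; carcass records are all-or-none"
            )
    for col in (*spec.class_effects, *spec.covariates, "animal_id"):
        if col not in ph.columns:
            raise DataError(f"phenotype table lacks column {col!r}")
        if ph[col].isna().any():
            raise DataError(f"column {col!r} has missing values")
    if ph["animal_id"].duplicated().any():
        dup = ph.loc[ph["animal_id"].duplicated(), "animal_id"].tolist()[:10]
        raise DataError(f"multiple records per animal: {dup}")

    rec_animal = ped.indices_of(ph["animal_id"].tolist())

    blocks: list[tuple[str, str]] = []
    constrained: list[int] = []
    levels: dict[str, list] = {}
    col_of: dict[tuple[str, str], int] = {}
    for e_i, eff in enumerate(spec.class_effects):
        levs = sorted(ph[eff].astype(str).unique())
        levels[eff] = levs
        counts = ph[eff].astype(str).value_counts()
        singles = [l for l in levs if counts[l] == 1]
        if singles:
            log.info("effect %s has %d singleton levels", eff, len(singles))
        for l_i, lev in enumerate(levs):
            col_of[(eff, lev)] = len(blocks)
            if e_i > 0 and l_i == 0:
                constrained.append(len(blocks))
                log.info("constraining %s level %r to zero (reference)", eff, lev)
            blocks.append((eff, lev))
    covariate_means = {}
    cov_cols = {}
    for cov in spec.covariates:
        covariate_means[cov] = float(ph[cov].mean())
        cov_cols[cov] = len(blocks)
        blocks.append(("covariate", cov))

    n_rec = len(ph)
    rows, cols, vals = [], [], []
    cset = set(constrained)
    for eff in spec.class_effects:
        labs = ph[eff].astype(str).tolist()
        for r, lab in enumerate(labs):
            c = col_of[(eff, lab)]
            if c not in cset:
                rows.append(r), cols.append(c), vals.append(1.0)
    for cov in spec.covariates:
        x = ph[cov].to_numpy(dtype=float) - covariate_means[cov]
        rows += list(range(n_rec))
        cols += [cov_cols[cov]] * n_rec
        vals += list(x)
    W_fixed = sp.coo_matrix(
        (vals, (rows, cols)), shape=(n_rec, len(blocks))
    ).tocsr()

    Y = ph[list(spec.traits)].to_numpy(dtype=float)
    return Design(
        spec=spec,
        blocks=blocks,
        constrained=constrained,
        levels=levels,
        rec_animal=rec_animal,
        W_fixed=W_fixed,
        Y=Y,
        covariate_means=covariate_means,
        animal_ids=ph["animal_id"].tolist(),
    )


@dataclass
class MixedModelEquations:
    """Sparse symmetric coefficient matrix, right-hand side, equation map."""

    C: sp.bsr_matrix
    rhs: np.ndarray
    t: int
    traits: tuple
    design: Design
    model_kind: str
    n_fixed_blocks: int
    n_animals: int
    n_groups: int
    m: int
    constrained: list[int]
    vc: VarianceComponents
    animal_ids: list[str]
    geno_idx: np.ndarray | None = None
    Z: np.ndarray | None = None
    marker_ids: list[str] | None = None
    marker_precision: np.ndarray | None = None  # scalar g-block, for the preconditioner

    @property
    def n_blocks(self) -> int:
        return self.n_fixed_blocks + self.n_animals + self.n_groups + self.m

    @property
    def dimension(self) -> int:
        return self.n_blocks * self.t

    @property
    def animal_offset(self) -> int:
        return self.n_fixed_blocks

    @property
    def marker_offset(self) -> int:
        return self.n_fixed_blocks + self.n_animals + self.n_groups


def _assemble(
    design: Design,
    ped: Pedigree,
    a_inverse: RelationshipInverse,
    vc: VarianceComponents,
    model_kind: str,
    prior_extra: list[tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
    m: int = 0,
    **meta,
) -> MixedModelEquations:
    """Shared assembly: data part + kron(scalar prior, G0^-1) + constraints."""
    t = vc.n_traits
    if len(design.spec.traits) != t:
        raise DataError("trait count of design and variance components differ")
    n = a_inverse.n_animals
    ng = a_inverse.n_groups
    if n != ped.n:
        raise DataError("A-inverse dimension does not match pedigree")
    nf = design.n_fixed_blocks
    n_blocks = nf + n + ng + m
    R0inv = np.linalg.inv(vc.R0)
    G0inv = np.linalg.inv(vc.G0)

    # --- data part: W holds fixed + animal incidences per record
    n_rec = design.n_records
    Wf = design.W_fixed.tocoo()
    rows = np.concatenate([Wf.row, np.arange(n_rec)])
    cols = np.concatenate([Wf.col, nf + design.rec_animal])
    vals = np.concatenate([Wf.data, np.ones(n_rec)])
    W = sp.coo_matrix((vals, (rows, cols)), shape=(n_rec, n_blocks)).tocsr()
    WtW = (W.T @ W).tocoo()

    # --- scalar prior: pedigree block at the animal offset, plus extras
    A = a_inverse.matrix.tocoo()
    constrained = list(design.constrained)
    p_rows = [A.row + nf]
    p_cols = [A.col + nf]
    p_vals = [A.data]
    if prior_extra:
        for r, c, v in prior_extra:
            p_rows.append(r), p_cols.append(c), p_vals.append(v)
    P = sp.coo_matrix(
        (np.concatenate(p_vals), (np.concatenate(p_rows), np.concatenate(p_cols))),
        shape=(n_blocks, n_blocks),
    ).tocsr()

    C = sp.kron(WtW, R0inv, format="csr") + sp.kron(P, G0inv, format="csr")

    # --- constrained equations: zero row/col already (no incidences), identity diag
    if constrained:
        eye_idx = np.concatenate([np.arange(b * t, (b + 1) * t) for b in constrained])
        C = (
            C
            + sp.coo_matrix(
                (np.ones(eye_idx.size), (eye_idx, eye_idx)), shape=C.shape
            ).tocsr()
        )

    B = W.T @ (design.Y @ R0inv)
    rhs = np.asarray(B).ravel()

    return MixedModelEquations(
        C=C.tobsr(blocksize=(t, t)),
        rhs=rhs,
        t=t,
        traits=tuple(design.spec.traits),
        design=design,
        model_kind=model_kind,
        n_fixed_blocks=nf,
        n_animals=n,
        n_groups=ng,
        m=m,
        constrained=constrained,
        vc=vc,
        animal_ids=list(ped.ids),
        **meta,
    )


def assemble_conventional(
    design: Design,
    ped: Pedigree,
    a_inverse: RelationshipInverse,
    vc: VarianceComponents,
) -> MixedModelEquations:
    """Multi-trait pedigree BLUP: data part plus A^-1 (x) G0^-1 prior on u."""
    return _assemble(design, ped, a_inverse, vc, model_kind="conventional")


def _dense_block_coo(rows_idx, cols_idx, M):
    """COO triplets for a dense block M placed at scalar indices (rows_idx, cols_idx)."""
    r = np.repeat(np.asarray(rows_idx), len(cols_idx))
    c = np.tile(np.asarray(cols_idx), len(rows_idx))
    return r, c, np.asarray(M, dtype=float).ravel()


def assemble_ssnpblup(
    design: Design,
    ped: Pedigree,
    a_inverse: RelationshipInverse,
    a22: np.ndarray,
    Z: np.ndarray,
    vc: VarianceComponents,
    snp_cov: SnpCovariance,
    geno_idx: np.ndarray,
    marker_ids: list[str] | None = None,
) -> MixedModelEquations:
    """Single-step SNP BLUP with explicit marker effects.

    Unknowns are (fixed effects, u for all animals and groups, g). The
    prior precision, scaled by 1/sigma_u^2 per trait via G0^-1, is

        u,u   : A^-1, plus (1/k - 1) A22^-1 on the genotyped block
        u_g,g : -A22^-1 Z / k
        g,g   : Z' A22^-1 Z / k + D/(1-k) I

    which encodes u_g = Z g + a with Var(a) = k A22 sigma_u^2 and
    Var(g_j) = sigma_SNP^2. At k = 1 the marker effects carry no
    variance and the model reduces to conventional BLUP (g dropped);
    k = 0 leaves the RPG precision undefined — use ssGBLUP instead.
    """
    k = vc.k
    if k == 0.0:
        raise DataError("ssSNPBLUP requires k > 0 (RPG precision undefined at k=0)")
    if k == 1.0:
        log.info("k = 1: marker variance is zero; reducing to conventional BLUP")
        mme = _assemble(design, ped, a_inverse, vc, model_kind="ssnpblup")
        mme.geno_idx = np.asarray(geno_idx, dtype=np.int64)
        mme.Z = np.asarray(Z, dtype=float)
        mme.marker_ids = marker_ids
        return mme

    geno_idx = np.asarray(geno_idx, dtype=np.int64)
    Z = np.asarray(Z, dtype=float)
    n2, m = Z.shape
    if len(geno_idx) != n2 or a22.shape != (n2, n2):
        raise DataError("genotyped index, Z and A22 dimensions are inconsistent")
    a22_inv = np.linalg.inv(a22)
    nf = design.n_fixed_blocks
    n = a_inverse.n_animals
    ng = a_inverse.n_groups
    mo = nf + n + ng  # first marker scalar block

    u_g = nf + geno_idx
    g_cols = mo + np.arange(m)
    AZ = a22_inv @ Z
    Ms = (Z.T @ AZ) / k + (snp_cov.D / (1.0 - k)) * np.eye(m)

    extras = []
    extras.append(_dense_block_coo(u_g, u_g, (1.0 / k - 1.0) * a22_inv))
    extras.append(_dense_block_coo(u_g, g_cols, -AZ / k))
    extras.append(_dense_block_coo(g_cols, u_g, -AZ.T / k))
    extras.append(_dense_block_coo(g_cols, g_cols, Ms))

    return _assemble(
        design,
        ped,
        a_inverse,
        vc,
        model_kind="ssnpblup",
        prior_extra=extras,
        m=m,
        geno_idx=geno_idx,
        Z=Z,
        marker_ids=marker_ids,
        marker_precision=Ms,
    )


def assemble_ssgblup(
    design: Design,
    ped: Pedigree,
    a_inverse: RelationshipInverse,
    a22: np.ndarray,
    Z: np.ndarray,
    vc: VarianceComponents,
    snp_cov: SnpCovariance,
    geno_idx: np.ndarray,
) -> MixedModelEquations:
    """Single-step GBLUP via the H-matrix inverse.

    H^-1 = A^-1 + [[0, 0], [0, Gw^-1 - A22^-1]] on the genotyped block,
    with G = Z Z' / D and Gw = (1 - k) G + k A22. Algebraically
    equivalent to :func:`assemble_ssnpblup` for the breeding values, so
    the two serve as mutual oracles.
    """
    geno_idx = np.asarray(geno_idx, dtype=np.int64)
    Z = np.asarray(Z, dtype=float)
    n2 = len(geno_idx)
    k = vc.k
    G = (Z @ Z.T) / snp_cov.D
    Gw = (1.0 - k) * G + k * a22
    try:
        cho = sla.cho_factor(Gw)
    except np.linalg.LinAlgError as e:
        raise DataError(
            "blended genomic relationship Gw is singular; clamp allele "
            "frequencies or increase the RPG fraction k"
        ) from e
    Gw_inv = sla.cho_solve(cho, np.eye(n2))
    a22_inv = np.linalg.inv(a22)
    u_g = design.n_fixed_blocks + geno_idx
    extras = [_dense_block_coo(u_g, u_g, Gw_inv - a22_inv)]
    mme = _assemble(
        design,
        ped,
        a_inverse,
        vc,
        model_kind="ssgblup",
        prior_extra=extras,
        geno_idx=geno_idx,
        Z=Z,
    )
    return mme


# ---------------------------------------------------------------------------
# solvers


@dataclass
class EvaluationResult:
    """Solutions of one evaluation plus convergence diagnostics.

    ``u`` holds one row per pedigree animal (its (G)EBV per trait);
    for ssSNPBLUP ``g`` are the marker effects and ``a = u_g - Z g``
    the residual polygenic effects of the genotyped animals.
    """

    traits: tuple
    animal_ids: list[str]
    fixed: pd.DataFrame
    covariates: pd.DataFrame
    u: np.ndarray
    group_effects: np.ndarray
    g: np.ndarray | None
    a: np.ndarray | None
    geno_idx: np.ndarray | None
    model_kind: str
    iterations: int
    converged: bool
    final_residual: float

    def gebv_frame(self, ped: Pedigree | None = None) -> pd.DataFrame:
        recs = []
        for ti, tr in enumerate(self.traits):
            recs.append(
                pd.DataFrame(
                    {
                        "animal_id": self.animal_ids,
                        "trait": tr,
                        "gebv_raw": self.u[:, ti],
                    }
                )
            )
        out = pd.concat(recs, ignore_index=True)
        if ped is not None:
            by = pd.Series(ped.birth_year, index=pd.Index(ped.ids, name="animal_id"))
            out["birth_year"] = out["animal_id"].map(by)
        return out


def _unpack(x: np.ndarray, mme: MixedModelEquations, iters: int, converged: bool, resid: float) -> EvaluationResult:
    t = mme.t
    X = x.reshape(mme.n_blocks, t)
    design = mme.design
    nf = mme.n_fixed_blocks
    fixed_rows = []
    cov_rows = []
    for b, (kind, key) in enumerate(design.blocks):
        for ti, tr in enumerate(mme.traits):
            if kind == "covariate":
                cov_rows.append({"covariate": key, "trait": tr, "estimate": X[b, ti]})
            else:
                fixed_rows.append(
                    {"effect": kind, "level": key, "trait": tr, "estimate": X[b, ti]}
                )
    u = X[nf : nf + mme.n_animals].copy()
    groups = X[nf + mme.n_animals : nf + mme.n_animals + mme.n_groups].copy()
    g = a = None
    if mme.model_kind == "ssnpblup" and mme.geno_idx is not None:
        if mme.m:
            g = X[mme.marker_offset :].copy()
        else:  # k = 1 reduction: markers carry no effect
            g = np.zeros((mme.Z.shape[1], t)) if mme.Z is not None else None
        if g is not None and mme.Z is not None:
            a = u[mme.geno_idx] - mme.Z @ g
    return EvaluationResult(
        traits=mme.traits,
        animal_ids=mme.animal_ids,
        fixed=pd.DataFrame(fixed_rows, columns=["effect", "level", "trait", "estimate"]),
        covariates=pd.DataFrame(cov_rows, columns=["covariate", "trait", "estimate"]),
        u=u,
        group_effects=groups,
        g=g,
        a=a,
        geno_idx=mme.geno_idx,
        model_kind=mme.model_kind,
        iterations=iters,
        converged=converged,
        final_residual=resid,
    )


def solve_direct(mme: MixedModelEquations) -> EvaluationResult:
    """Direct factorization solution; oracle for the iterative solver.

    Dense Cholesky/LU below ~6,000 equations, sparse LU up to 20,000.
    """
    dim = mme.dimension
    if dim > 20000:
        raise DataError(f"system dimension {dim} too large for solve_direct")
    if dim <= 6000:
        x = np.linalg.solve(mme.C.toarray(), mme.rhs)
    else:
        x = sp.linalg.spsolve(mme.C.tocsc(), mme.rhs)
    resid = float(np.linalg.norm(mme.C @ x - mme.rhs) / np.linalg.norm(mme.rhs))
    return _unpack(x, mme, iters=0, converged=True, resid=resid)


def _block_preconditioner(mme: MixedModelEquations):
    """Exact t x t diagonal blocks; exact dense marker block when present."""
    t = mme.t
    nb = mme.n_blocks
    C = mme.C  # BSR with blocksize (t, t)
    diag_blocks = np.empty((nb, t, t))
    indptr, indices, data = C.indptr, C.indices, C.data
    for b in range(nb):
        sl = slice(indptr[b], indptr[b + 1])
        hit = np.flatnonzero(indices[sl] == b)
        diag_blocks[b] = data[sl][hit[0]] if hit.size else np.eye(t)
    inv_blocks = np.linalg.inv(diag_blocks)

    mo = mme.marker_offset
    use_marker_block = mme.m > 0 and mme.marker_precision is not None
    if use_marker_block:
        cho_M = sla.cho_factor(mme.marker_precision)
        G0 = mme.vc.G0

    def apply(r: np.ndarray) -> np.ndarray:
        R = r.reshape(nb, t)
        out = np.einsum("bij,bj->bi", inv_blocks, R)
        if use_marker_block:
            # inverse of (Ms kron G0^-1) applied to the marker segment
            out[mo:] = sla.cho_solve(cho_M, R[mo:]) @ G0
        return out.ravel()

    return apply


def solve_pcg(
    mme: MixedModelEquations,
    tol: float = 1e-10,
    max_iter: int = 10000,
    raise_on_failure: bool = False,
) -> EvaluationResult:
    """Preconditioned conjugate gradients with block-diagonal preconditioner.

    Converges when the relative residual ||C x - rhs|| / ||rhs|| drops
    below ``tol``. Non-convergence returns the last iterate flagged
    (or raises if ``raise_on_failure``).
    """
    C = mme.C
    b = mme.rhs
    Mapply = _block_preconditioner(mme)
    x = np.zeros_like(b)
    r = b.copy()
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return _unpack(x, mme, 0, True, 0.0)
    z = Mapply(r)
    p = z.copy()
    rz = float(r @ z)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Cp = C @ p
        alpha = rz / float(p @ Cp)
        x += alpha * p
        r -= alpha * Cp
        resid = np.linalg.norm(r) / bnorm
        if resid < tol:
            converged = True
            break
        z = Mapply(r)
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
    resid = float(np.linalg.norm(C @ x - b) / bnorm)
    if not converged:
        log.warning("PCG stopped at %d iterations, relative residual %.3e", it, resid)
        if raise_on_failure:
            raise ConvergenceError(
                f"PCG did not reach tol={tol} in {max_iter} iterations (residual {resid:.3e})"
            )
    return _unpack(x, mme, it, converged, resid)


def prediction_error_variance(mme: MixedModelEquations) -> np.ndarray:
    """Per-animal, per-trait prediction error variance from the dense inverse.

    Only feasible for systems small enough for a dense inverse; used as
    a model-based reliability proxy in diagnostics and tests.
    """
    dim = mme.dimension
    if dim > 6000:
        raise DataError(f"system dimension {dim} too large for a dense inverse")
    Cinv = np.linalg.inv(mme.C.toarray())
    t = mme.t
    nf = mme.n_fixed_blocks
    pev = np.empty((mme.n_animals, t))
    for i in range(mme.n_animals):
        for ti in range(t):
            e = (nf + i) * t + ti
            pev[i, ti] = Cinv[e, e]
    return pev
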