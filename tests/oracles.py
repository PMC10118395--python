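"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own algebra: the relationship
oracle is a memoized textbook recursion, and the dense mixed-model
oracle assembles the normal equations by explicit loops over records
and effects in trait-major blocks before solving with numpy.
"""

from __future__ import annotations

import numpy as np


def relationship_oracle(sire: dict, dam: dict, order: list) -> np.ndarray:
    """Dense additive relationship matrix by the recursive definition.

    ``sire``/``dam`` map id -> parent id (or None); ``order`` is a
    parents-first list of ids.
    """
    pos = {a: i for i, a in enumerate(order)}
    memo: dict[tuple[int, int], float] = {}

    def a(i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        jid = order[j]
        s, d = sire.get(jid), dam.get(jid)
        if i == j:
            val = 1.0
            if s is not None and d is not None:
                val += 0.5 * a(pos[s], pos[d])
        else:
            val = 0.0
            if s is not None:
                val += 0.5 * a(i, pos[s])
            if d is not None:
                val += 0.5 * a(i, pos[d])
        memo[key] = val
        return val

    n = len(order)
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            A[i, j] = A[j, i] = a(i, j)
    return A


def dense_mme_oracle(
    phenotypes,
    traits,
    class_effects,
    covariates,
    ped,
    A_inv_dense: np.ndarray,
    G0: np.ndarray,
    R0: np.ndarray,
    constrained_first_levels: bool = True,
):
    """Generalized-least-squares solution of the multi-trait animal model.

    Builds the full dense coefficient matrix with explicit per-record
    loops, trait-major within each effect level, mirroring the model
    (not the implementation): class effects with reference coding
    (first level of every effect after the first fixed at zero), a
    centered covariate per trait, and the A^-1 (x) G0^-1 prior.
    Returns (fixed_block_solutions, u) with u of shape (n, t).
    """
    t = len(traits)
    n = A_inv_dense.shape[0]
    levels = {e: sorted(phenotypes[e].astype(str).unique()) for e in class_effects}
    cols = []  # (kind, key)
    dropped = set()
    for e_i, e in enumerate(class_effects):
        for l_i, lev in enumerate(levels[e]):
            if constrained_first_levels and e_i > 0 and l_i == 0:
                dropped.add((e, lev))
            cols.append((e, lev))
    for c in covariates:
        cols.append(("covariate", c))
    nf = len(cols)
    colpos = {kc: i for i, kc in enumerate(cols)}
    means = {c: float(phenotypes[c].mean()) for c in covariates}

    dim = (nf + n) * t
    C = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    R0inv = np.linalg.inv(R0)
    G0inv = np.linalg.inv(G0)

    for _, row in phenotypes.iterrows():
        w = np.zeros(nf + n)
        for e in class_effects:
            kc = (e, str(row[e]))
            if kc not in dropped:
                w[colpos[kc]] = 1.0
        for c in covariates:
            w[colpos[("covariate", c)]] = row[c] - means[c]
        w[nf + ped.index[row["animal_id"]]] = 1.0
        y = np.array([row[tr] for tr in traits], dtype=float)
        nz = np.flatnonzero(w)
        for p in nz:
            for q in nz:
                C[p * t : (p + 1) * t, q * t : (q + 1) * t] += w[p] * w[q] * R0inv
            rhs[p * t : (p + 1) * t] += w[p] * (R0inv @ y)

    for i in range(n):
        for j in range(n):
            if A_inv_dense[i, j] != 0.0:
                C[
                    (nf + i) * t : (nf + i + 1) * t,
                    (nf + j) * t : (nf + j + 1) * t,
                ] += A_inv_dense[i, j] * G0inv

    for e, lev in dropped:
        p = colpos[(e, lev)]
        C[p * t : (p + 1) * t, p * t : (p + 1) * t] += np.eye(t)

    x = np.linalg.solve(C, rhs)
    X = x.reshape(nf + n, t)
    return X[:nf], X[nf:]
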