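"""Pedigree algebra for animal-model genetic evaluation.

Provides topological ordering and validation of pedigrees, phantom
(unknown) parent group assignment, inbreeding coefficients by the
Meuwissen–Luo recursion, the sparse inverse of the numerator
relationship matrix A (Henderson rules with inbreeding, Westell/Quaas
extension for phantom groups), and the dense relationship block A22
among genotyped animals computed by the tabular method on the
ancestor-restricted pedigree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import PedigreeError

log = logging.getLogger(__name__)

#: sentinel index for a missing parent
MISSING = -1


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal in the pedigree.

    ``sire_id``/``dam_id`` are ``None`` when the parent is unknown.
    ``sex`` is ``"M"`` or ``"F"``; ``animal_type`` is one of
    ``bull``/``cow``/``steer``; ``selection_path`` is an arbitrary
    category label used for phantom-group definitions.
    """

    animal_id: str
    sire_id: str | None
    dam_id: str | None
    birth_year: int
    sex: str
    selection_path: str = ""
    animal_type: str = ""


class Pedigree:
    """Topologically ordered pedigree with dense 0-based integer links.

    Every parent precedes its offspring; external ids are preserved in
    ``ids`` and ``index``. Construct via :func:`sort_and_validate`.
    """

    def __init__(self, ids, sire, dam, birth_year, sex, path, animal_type):
        self.ids: list[str] = list(ids)
        self.sire = np.asarray(sire, dtype=np.int64)
        self.dam = np.asarray(dam, dtype=np.int64)
        self.birth_year = np.asarray(birth_year, dtype=np.int64)
        self.sex = np.asarray(sex, dtype=object)
        self.selection_path = np.asarray(path, dtype=object)
        self.animal_type = np.asarray(animal_type, dtype=object)
        self.index: dict[str, int] = {a: i for i, a in enumerate(self.ids)}
        if not (self.sire < np.arange(self.n)).all() or not (
            self.dam < np.arange(self.n)
        ).all():
            raise PedigreeError("pedigree is not in parents-first order")

    @property
    def n(self) -> int:
        return len(self.ids)

    def indices_of(self, animal_ids) -> np.ndarray:
        """Map external ids to row indices; unknown ids raise with the offenders."""
        missing = [a for a in animal_ids if a not in self.index]
        if missing:
            raise PedigreeError(f"unknown animal ids: {missing[:20]}")
        return np.asarray([self.index[a] for a in animal_ids], dtype=np.int64)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Pedigree(n={self.n})"


def sort_and_validate(records: list[PedigreeRecord]) -> Pedigree:
    """Order records parents-first and validate structural invariants.

    Raises :class:`PedigreeError` on duplicate ids, unresolvable parent
    ids, sex conflicts (an id used both as sire and dam, or a parent
    whose recorded sex contradicts its role), and pedigree cycles (the
    error names one animal on the cycle).
    """
    ids = [r.animal_id for r in records]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for a in ids:
            if a in seen:
                dups.append(a)
            seen.add(a)
        raise PedigreeError(f"duplicate animal ids: {dups[:20]}")
    byid = {r.animal_id: r for r in records}

    unresolved = sorted(
        {p for r in records for p in (r.sire_id, r.dam_id) if p is not None and p not in byid}
    )
    if unresolved:
        raise PedigreeError(f"parent ids without a pedigree record: {unresolved[:20]}")

    sires = {r.sire_id for r in records if r.sire_id is not None}
    dams = {r.dam_id for r in records if r.dam_id is not None}
    both = sorted(sires & dams)
    if both:
        raise PedigreeError(f"ids used as both sire and dam: {both[:20]}")
    for p in sorted(sires):
        if byid[p].sex == "F":
            raise PedigreeError(f"animal {p} recorded female but used as sire")
    for p in sorted(dams):
        if byid[p].sex == "M":
            raise PedigreeError(f"animal {p} recorded male but used as dam")

    # Kahn's algorithm, stable in input order.
    pos = {a: i for i, a in enumerate(ids)}
    children: dict[str, list[str]] = {a: [] for a in ids}
    indeg = {a: 0 for a in ids}
    for r in records:
        for p in (r.sire_id, r.dam_id):
            if p is not None:
                children[p].append(r.animal_id)
                indeg[r.animal_id] += 1
    import heapq

    heap = [pos[a] for a in ids if indeg[a] == 0]
    heapq.heapify(heap)
    order: list[str] = []
    while heap:
        a = ids[heapq.heappop(heap)]
        order.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, pos[c])
    if len(order) < len(ids):
        stuck = next(a for a in ids if indeg[a] > 0)
        raise PedigreeError(f"pedigree cycle detected involving animal {stuck}")

    newidx = {a: i for i, a in enumerate(order)}

    def _pidx(p):
        return MISSING if p is None else newidx[p]

    recs = [byid[a] for a in order]
    return Pedigree(
        ids=order,
        sire=[_pidx(r.sire_id) for r in recs],
        dam=[_pidx(r.dam_id) for r in recs],
        birth_year=[r.birth_year for r in recs],
        sex=[r.sex for r in recs],
        path=[r.selection_path for r in recs],
        animal_type=[r.animal_type for r in recs],
    )


# ---------------------------------------------------------------------------
# phantom parent groups


@dataclass
class PhantomGroups:
    """Assignment of every missing-parent slot to a phantom parent group.

    ``labels`` lists ``(path, (year_lo, year_hi))`` per group;
    ``sire_group``/``dam_group`` give per-animal group indices
    (``MISSING`` where the parent is a real animal).
    """

    labels: list[tuple[str, tuple[int, int]]]
    sire_group: np.ndarray
    dam_group: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)


def default_path_of_slot(role: str, animal_index: int, ped: Pedigree) -> str:
    """Default selection-path label for a missing-parent slot.

    The four classical selection paths follow from the parent role
    (sire/dam) crossed with the sex of the offspring carrying the
    missing slot.
    """
    return f"{role}_of_{ped.sex[animal_index]}"


def assign_phantom_groups(
    ped: Pedigree,
    path_defs=None,
    year_bins=None,
) -> PhantomGroups:
    """Assign each missing sire/dam slot to one phantom parent group.

    Groups are the cross product of the selection paths in use and the
    birth-year bins in use, so their count is ``|paths| x |bins|``.
    ``year_bins`` is a sorted list of bin edges defining half-open
    intervals ``[e_i, e_{i+1})``; birth years outside all bins are
    clamped to the nearest boundary bin with a logged warning.
    ``path_defs`` is a callable ``(role, animal_index, ped) -> label``
    and defaults to role x offspring-sex (four paths).
    """
    if path_defs is None:
        path_defs = default_path_of_slot
    years = ped.birth_year
    if year_bins is None:
        year_bins = [int(years.min()), int(years.max()) + 1]
    year_bins = sorted(int(e) for e in year_bins)
    if len(year_bins) < 2:
        raise PedigreeError("year_bins needs at least two edges")
    bins = [(year_bins[i], year_bins[i + 1]) for i in range(len(year_bins) - 1)]

    def _bin_of(year: int) -> int:
        if year < year_bins[0]:
            log.warning("birth year %d below all bins; clamped to first bin", year)
            return 0
        if year >= year_bins[-1]:
            log.warning("birth year %d beyond all bins; clamped to last bin", year)
            return len(bins) - 1
        return int(np.searchsorted(year_bins, year, side="right") - 1)

    slots: list[tuple[str, int, str, int]] = []  # (role, animal, path, bin)
    for i in range(ped.n):
        if ped.sire[i] == MISSING:
            slots.append(("sire", i, path_defs("sire", i, ped), _bin_of(int(years[i]))))
        if ped.dam[i] == MISSING:
            slots.append(("dam", i, path_defs("dam", i, ped), _bin_of(int(years[i]))))

    sire_group = np.full(ped.n, MISSING, dtype=np.int64)
    dam_group = np.full(ped.n, MISSING, dtype=np.int64)
    if not slots:
        return PhantomGroups(labels=[], sire_group=sire_group, dam_group=dam_group)

    paths_in_use = sorted({s[2] for s in slots})
    bins_in_use = sorted({s[3] for s in slots})
    labels = [(p, bins[b]) for p in paths_in_use for b in bins_in_use]
    key = {(p, b): g for g, (p, b) in enumerate((p, b) for p in paths_in_use for b in bins_in_use)}
    for role, i, p, b in slots:
        g = key[(p, b)]
        if role == "sire":
            sire_group[i] = g
        else:
            dam_group[i] = g
    return PhantomGroups(labels=labels, sire_group=sire_group, dam_group=dam_group)


# ---------------------------------------------------------------------------
# inbreeding and relationship algebra


def _mendelian_variance(F: np.ndarray, s: int, d: int) -> float:
    """Within-family (Mendelian sampling) variance given parent inbreeding.

    Unknown or phantom-group parents contribute as unknown.
    """
    if s != MISSING and d != MISSING:
        return 0.5 - 0.25 * (F[s] + F[d])
    if s != MISSING:
        return 0.75 - 0.25 * F[s]
    if d != MISSING:
        return 0.75 - 0.25 * F[d]
    return 1.0


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients by the Meuwissen–Luo recursion.

    F_i = a(sire_i, dam_i) / 2 where a is the additive relationship;
    founders (and animals with any unknown/phantom parent pair) fall
    back on the usual unknown-parent conventions. Runs in
    O(n x ancestors) without forming the dense A.
    """
    n = ped.n
    F = np.zeros(n)
    d = np.zeros(n)  # Mendelian sampling variance, filled in order
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        d[i] = _mendelian_variance(F, sire[i], dam[i])
        if sire[i] == MISSING and dam[i] == MISSING:
            F[i] = 0.0
            continue
        # A_ii = sum_j L_ij^2 d_j over ancestors j of i (including i)
        contrib: dict[int, float] = {i: 1.0}
        a_ii = 0.0
        while contrib:
            j = max(contrib)
            r = contrib.pop(j)
            a_ii += r * r * d[j]
            if sire[j] != MISSING:
                contrib[sire[j]] = contrib.get(sire[j], 0.0) + 0.5 * r
            if dam[j] != MISSING:
                contrib[dam[j]] = contrib.get(dam[j], 0.0) + 0.5 * r
        F[i] = a_ii - 1.0
    return F


@dataclass
class RelationshipInverse:
    """Sparse symmetric inverse of the numerator relationship matrix.

    Rows 0..n_animals-1 are animals in pedigree order; the trailing
    ``n_groups`` rows are phantom parent groups.
    """

    matrix: sp.csr_matrix
    n_animals: int
    n_groups: int

    @property
    def dimension(self) -> int:
        return self.n_animals + self.n_groups


def build_a_inverse(
    ped: Pedigree,
    inbreeding: np.ndarray | None = None,
    groups: PhantomGroups | None = None,
    use_inbreeding: bool = True,
    group_prior: float = 1.0,
) -> RelationshipInverse:
    """Sparse A-inverse by Henderson's rules with inbreeding.

    Phantom parent groups enter via the Westell/Quaas rules: a missing
    parent slot is replaced by its group column, group rows receive the
    same rule contributions, and the Mendelian-variance coefficient
    treats group parents as unknown.

    Purely fixed group equations are confounded with the general mean
    (and, with few founder cohorts, with each other), which leaves the
    mixed-model equations singular or so ill-conditioned that iterative
    and direct solutions drift apart along the near-null directions.
    Group effects are therefore treated as random genetic groups:
    ``group_prior`` is added to each group diagonal, i.e. a
    N(0, G0 / group_prior) prior per group in the multi-trait system.
    ``group_prior=0`` recovers the fixed-group (singular) treatment.
    """
    n = ped.n
    if use_inbreeding:
        F = compute_inbreeding(ped) if inbreeding is None else np.asarray(inbreeding, float)
    else:
        F = np.zeros(n)
    ng = groups.n if groups is not None else 0
    dim = n + ng

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def _slot(i: int, which: str) -> int:
        """Equation column for a parent slot, or MISSING."""
        p = ped.sire[i] if which == "sire" else ped.dam[i]
        if p != MISSING:
            return int(p)
        if groups is not None:
            g = groups.sire_group[i] if which == "sire" else groups.dam_group[i]
            if g != MISSING:
                return n + int(g)
        return MISSING

    for i in range(n):
        b = 1.0 / _mendelian_variance(F, ped.sire[i], ped.dam[i])
        p1 = _slot(i, "sire")
        p2 = _slot(i, "dam")
        rows.append(i), cols.append(i), vals.append(b)
        for p in (p1, p2):
            if p != MISSING:
                rows += [i, p]
                cols += [p, i]
                vals += [-b / 2.0, -b / 2.0]
        for pa in (p1, p2):
            for pb in (p1, p2):
                if pa != MISSING and pb != MISSING:
                    rows.append(pa), cols.append(pb), vals.append(b / 4.0)

    A_inv = sp.coo_matrix((vals, (rows, cols)), shape=(dim, dim)).tocsr()
    if ng and group_prior > 0.0:
        prior = sp.coo_matrix(
            (np.full(ng, group_prior), (np.arange(n, dim), np.arange(n, dim))),
            shape=(dim, dim),
        )
        A_inv = (A_inv + prior).tocsr()
    return RelationshipInverse(matrix=A_inv, n_animals=n, n_groups=ng)


def tabular_relationship(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    Quadratic in pedigree size; intended for desk-scale pedigrees and
    as the engine behind :func:`build_a22`.
    """
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if i:
            row = np.zeros(i)
            if s != MISSING:
                row += 0.5 * A[s, :i]
            if d != MISSING:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s != MISSING and d != MISSING) else 0.0)
    return A


def build_a22(ped: Pedigree, genotyped_ids) -> np.ndarray:
    """Dense relationship matrix among genotyped animals.

    Computed by the tabular method on the pedigree restricted to the
    genotyped animals and their ancestors, which reproduces the
    corresponding sub-block of the full A exactly.
    """
    gidx = ped.indices_of(genotyped_ids)
    keep = np.zeros(ped.n, dtype=bool)
    stack = list(gidx)
    while stack:
        i = stack.pop()
        if keep[i]:
            continue
        keep[i] = True
        for p in (ped.sire[i], ped.dam[i]):
            if p != MISSING and not keep[p]:
                stack.append(int(p))
    sub = np.flatnonzero(keep)  # ascending => still parents-first
    remap = {int(old): new for new, old in enumerate(sub)}

    def _rm(p):
        return MISSING if p == MISSING else remap[int(p)]

    rped = Pedigree(
        ids=[ped.ids[i] for i in sub],
        sire=[_rm(ped.sire[i]) for i in sub],
        dam=[_rm(ped.dam[i]) for i in sub],
        birth_year=ped.birth_year[sub],
        sex=ped.sex[sub],
        path=ped.selection_path[sub],
        animal_type=ped.animal_type[sub],
    )
    A = tabular_relationship(rped)
    pos = np.asarray([remap[int(i)] for i in gidx])
    return A[np.ix_(pos, pos)]
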