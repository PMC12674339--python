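"""Pedigree algebra.

Tabular additive relationship matrices, inbreeding coefficients and the
Henderson sparse inverse of the numerator relationship matrix, with
Mendelian-sampling variances adjusted for parental inbreeding.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

log = logging.getLogger(__name__)

UNKNOWN: int = -1

#: strings accepted as "parent unknown" in pedigree files
MISSING_PARENT_CODES = frozenset({"", "0", "na", "nan", "none", ".", "-"})


class PedigreeError(ValueError):
    pass


@dataclass(frozen=True)
class Pedigree:
    """Topologically ordered pedigree.

    Animals are coded ``0..n-1`` in an order where every known parent
    precedes its offspring; ``sire``/``dam`` hold parent codes with
    :data:`UNKNOWN` (-1) for missing parents.
    """

    ids: tuple[str, ...]
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self) -> None:
        sire = np.asarray(self.sire, dtype=np.int64)
        dam = np.asarray(self.dam, dtype=np.int64)
        object.__setattr__(self, "sire", sire)
        object.__setattr__(self, "dam", dam)
        n = len(self.ids)
        if sire.shape != (n,) or dam.shape != (n,):
            raise PedigreeError("sire/dam arrays must match the id list length")
        idx = np.arange(n)
        for name, par in (("sire", sire), ("dam", dam)):
            bad = (par != UNKNOWN) & ((par < 0) | (par >= idx))
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise PedigreeError(
                    f"{name} of animal {self.ids[i]!r} does not precede it; "
                    "pedigree must be topologically ordered"
                )
        if len(set(self.ids)) != n:
            raise PedigreeError("duplicate animal ids in pedigree")
        object.__setattr__(self, "_code", {a: i for i, a in enumerate(self.ids)})

    @property
    def n(self) -> int:
        return len(self.ids)

    def code(self, animal_id: str) -> int:
        try:
            return self._code[animal_id]
        except KeyError:
            raise PedigreeError(f"animal id {animal_id!r} not in pedigree") from None

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._code

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "Pedigree":
        """Build a pedigree from (animal, sire, dam) string triples.

        Parents never listed as animals are added as founders; rows may
        appear in any order (a topological sort is applied). Duplicate
        animal ids and ancestry cycles raise :class:`PedigreeError`.
        """
        def norm(x: object) -> str | None:
            s = str(x).strip()
            return None if s.lower() in MISSING_PARENT_CODES else s

        animals: list[str] = []
        parents: dict[str, tuple[str | None, str | None]] = {}
        for row in records:
            a, s, d = (str(row[0]).strip(), norm(row[1]), norm(row[2]))
            if not a or a.lower() in MISSING_PARENT_CODES:
                raise PedigreeError(f"invalid animal id {row[0]!r}")
            if a in parents:
                raise PedigreeError(f"duplicate animal id {a!r} in pedigree")
            parents[a] = (s, d)
            animals.append(a)

        # parents that only ever appear as parents become founders
        for a in list(animals):
            for p in parents[a]:
                if p is not None and p not in parents:
                    parents[p] = (None, None)
                    animals.append(p)

        # Kahn topological sort: parents before offspring
        pending = {a: sum(p is not None for p in parents[a]) for a in animals}
        children: dict[str, list[str]] = {a: [] for a in animals}
        for a in animals:
            for p in parents[a]:
                if p is not None:
                    children[p].append(a)
        order = [a for a in animals if pending[a] == 0]
        head = 0
        placed = set(order)
        while head < len(order):
            for c in children[order[head]]:
                pending[c] -= 1
                if pending[c] == 0 and c not in placed:
                    order.append(c)
                    placed.add(c)
            head += 1
        if len(order) != len(animals):
            cyc = sorted(set(animals) - placed)
            raise PedigreeError(
                f"pedigree contains an ancestry cycle involving: {', '.join(cyc)}"
            )

        code = {a: i for i, a in enumerate(order)}
        sire = np.full(len(order), UNKNOWN, dtype=np.int64)
        dam = np.full(len(order), UNKNOWN, dtype=np.int64)
        for a in order:
            s, d = parents[a]
            if s is not None:
                sire[code[a]] = code[s]
            if d is not None:
                dam[code[a]] = code[d]
        return cls(ids=tuple(order), sire=sire, dam=dam)


def tabular_a(ped: Pedigree) -> np.ndarray:
    """Dense additive (numerator) relationship matrix by the tabular method."""
    n = ped.n
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            row = 0.5 * (A[s, :i] + A[d, :i])
            aii = 1.0 + 0.5 * A[s, d]
        elif s != UNKNOWN:
            row = 0.5 * A[s, :i]
            aii = 1.0
        elif d != UNKNOWN:
            row = 0.5 * A[d, :i]
            aii = 1.0
        else:
            row = None
            aii = 1.0
        if row is not None:
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = aii
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F_i = A_ii - 1 (tabular method)."""
    return np.diag(tabular_a(ped)) - 1.0


def mendelian_sampling_variances(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """d_i used in the sparse A-inverse, adjusted for parental inbreeding."""
    sire, dam = ped.sire, ped.dam
    d = np.ones(ped.n)
    both = (sire != UNKNOWN) & (dam != UNKNOWN)
    d[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
    one_s = (sire != UNKNOWN) & (dam == UNKNOWN)
    d[one_s] = 0.75 - 0.25 * F[sire[one_s]]
    one_d = (sire == UNKNOWN) & (dam != UNKNOWN)
    d[one_d] = 0.75 - 0.25 * F[dam[one_d]]
    return d


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse inverse of the numerator relationship matrix (Henderson rules).

    Contributions per animal i with Mendelian-sampling variance d_i:
    ``1/d_i`` at (i,i), ``-0.5/d_i`` at (i, parent) and ``0.25/d_i`` at each
    (parent, parent) pair of known parents.
    """
    if F is None:
        F = inbreeding(ped)
    d = mendelian_sampling_variances(ped, F)
    if np.any(d <= 0):
        i = int(np.flatnonzero(d <= 0)[0])
        raise PedigreeError(
            f"non-positive Mendelian sampling variance for animal {ped.ids[i]!r}"
        )
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)
        if r != c:
            rows.append(c)
            cols.append(r)
            vals.append(v)

    for i in range(ped.n):
        b = 1.0 / d[i]
        add(i, i, b)
        pars = [p for p in (int(ped.sire[i]), int(ped.dam[i])) if p != UNKNOWN]
        for p in pars:
            add(i, p, -0.5 * b)
        if len(pars) == 2:
            s, p2 = pars
            add(s, s, 0.25 * b)
            add(p2, p2, 0.25 * b)
            add(s, p2, 0.25 * b)
        elif len(pars) == 1:
            add(pars[0], pars[0], 0.25 * b)
    M = sp.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n))
    return M.tocsr()


def a_submatrix(ped: Pedigree, ids: Sequence[int] | Sequence[str]) -> np.ndarray:
    """Additive relationship matrix restricted to the given animals (A22).

    ``ids`` may be integer codes or string animal ids; the diagonal of the
    result is 1 + F_i.
    """
    codes = np.array(
        [ped.code(a) if isinstance(a, str) else int(a) for a in ids], dtype=np.int64
    )
    if codes.size and (codes.min() < 0 or codes.max() >= ped.n):
        bad = codes[(codes < 0) | (codes >= ped.n)][0]
        raise PedigreeError(f"animal code {bad} not in pedigree")
    A = tabular_a(ped)
    return A[np.ix_(codes, codes)]
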