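"""Pedigrees and the additive (numerator) relationship matrix.

A pedigree is an ordered set of (individual, sire, dam) triples; unknown
parents are encoded as the empty string in files and as index ``-1``
internally.  The additive relationship matrix **A** — twice the kinship
coefficient, with diagonal 1 + F where F is the inbreeding coefficient — is
built with the tabular method, processing individuals in topological order
(parents before offspring):

    A_ii = 1 + 0.5 * A_{s(i), d(i)}
    A_ij = 0.5 * (A_{j, s(i)} + A_{j, d(i)})   for j ordered before i,

with unknown parents contributing zero.  A links repeated phenotypes on
relatives to additive genetic variance in the animal models of
:mod:`colonyqg.animal_model`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .errors import (
    CyclicPedigreeError,
    DuplicateRecordError,
    InconsistentPedigreeError,
    InvalidArgumentError,
)

UNKNOWN = ""  # file-level sentinel for an unknown parent


@dataclass(frozen=True)
class RelatednessMatrix:
    """Dense additive relationship matrix indexed by pedigree ids."""

    ids: tuple
    values: np.ndarray  # (n, n) symmetric, diagonal = 1 + F

    def __post_init__(self):
        object.__setattr__(self, "_index", {i: k for k, i in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    def loc(self, id_i, id_j) -> float:
        """Relatedness between two named individuals."""
        try:
            return float(self.values[self._index[id_i], self._index[id_j]])
        except KeyError as exc:
            raise InconsistentPedigreeError(f"unknown individual: {exc.args[0]}")

    def indices_of(self, ids) -> np.ndarray:
        """Row/column positions of the given ids (errors on unknown ids)."""
        missing = [i for i in ids if i not in self._index]
        if missing:
            raise InconsistentPedigreeError(
                f"{len(missing)} individual(s) not in relationship matrix, "
                f"e.g. {missing[:5]}"
            )
        return np.array([self._index[i] for i in ids], dtype=np.intp)

    @property
    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F = diag(A) - 1."""
        return np.diag(self.values) - 1.0

    def write_mtx(self, path) -> None:
        """Export as a Matrix Market file (sparse coordinate format)."""
        mmwrite(str(path), sparse.coo_matrix(self.values))

    @staticmethod
    def read_mtx(path, ids) -> "RelatednessMatrix":
        values = np.asarray(mmread(str(path)).todense())
        return RelatednessMatrix(ids=tuple(ids), values=values)


class Pedigree:
    """Topologically sorted pedigree with cycle and duplicate detection.

    Parents named but never listed as individuals are auto-promoted to
    founders.  Construction is order-invariant: any permutation of the same
    triples yields the same sorted pedigree.
    """

    def __init__(self, individuals, sires, dams, sex=None):
        ids = [str(i) for i in individuals]
        if len(set(ids)) != len(ids):
            seen, dups = set(), []
            for i in ids:
                if i in seen:
                    dups.append(i)
                seen.add(i)
            raise DuplicateRecordError(f"duplicate individual id(s): {dups[:5]}")

        sires = [("" if s is None or (isinstance(s, float) and np.isnan(s)) else str(s)) for s in sires]
        dams = [("" if d is None or (isinstance(d, float) and np.isnan(d)) else str(d)) for d in dams]
        if not (len(ids) == len(sires) == len(dams)):
            raise InvalidArgumentError("individuals, sires and dams must have equal length")

        parent_of = dict(zip(ids, zip(sires, dams)))
        # auto-promote unlisted parents to founders
        for s, d in list(parent_of.values()):
            for p in (s, d):
                if p and p not in parent_of:
                    parent_of[p] = ("", "")

        order = self._topological_order(parent_of)
        self._ids = tuple(order)
        index = {i: k for k, i in enumerate(order)}
        self._index = index
        self._sire = np.array(
            [index[parent_of[i][0]] if parent_of[i][0] else -1 for i in order],
            dtype=np.intp,
        )
        self._dam = np.array(
            [index[parent_of[i][1]] if parent_of[i][1] else -1 for i in order],
            dtype=np.intp,
        )
        self.sex = dict(sex) if sex else {}

    @staticmethod
    def _topological_order(parent_of) -> list:
        """Kahn's algorithm over parent->child edges; ties broken by id."""
        children = {i: [] for i in parent_of}
        n_parents = {}
        for i, (s, d) in parent_of.items():
            known = [p for p in (s, d) if p]
            n_parents[i] = len(known)
            for p in known:
                children[p].append(i)
        ready = sorted(i for i, k in n_parents.items() if k == 0)
        order = []
        while ready:
            ready.sort()
            i = ready.pop(0)
            order.append(i)
            for c in children[i]:
                n_parents[c] -= 1
                if n_parents[c] == 0:
                    ready.append(c)
        if len(order) != len(parent_of):
            # every remaining individual lies on or above a cycle; walk parents
            remaining = set(parent_of) - set(order)
            start = sorted(remaining)[0]
            seen, path = {}, []
            node = start
            while node not in seen:
                seen[node] = len(path)
                path.append(node)
                s, d = parent_of[node]
                node = next(p for p in (s, d) if p and p in remaining)
            cycle = path[seen[node]:] + [node]
            raise CyclicPedigreeError(cycle)
        return order

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, item) -> bool:
        return str(item) in self._index

    @property
    def ids(self) -> tuple:
        return self._ids

    @property
    def sire_index(self) -> np.ndarray:
        return self._sire

    @property
    def dam_index(self) -> np.ndarray:
        return self._dam

    def parents_of(self, individual):
        k = self._index[str(individual)]
        s, d = self._sire[k], self._dam[k]
        return (
            self._ids[s] if s >= 0 else None,
            self._ids[d] if d >= 0 else None,
        )

    @property
    def founders(self) -> tuple:
        return tuple(
            i
            for i, s, d in zip(self._ids, self._sire, self._dam)
            if s < 0 and d < 0
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self._ids,
                "sire": [self._ids[s] if s >= 0 else UNKNOWN for s in self._sire],
                "dam": [self._ids[d] if d >= 0 else UNKNOWN for d in self._dam],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    # -- derived quantities ------------------------------------------------
    def depths(self) -> np.ndarray:
        """Generation depth per individual: founders 0, else 1 + max(parent depths)."""
        depth = np.zeros(len(self), dtype=np.intp)
        for k in range(len(self)):
            s, d = self._sire[k], self._dam[k]
            cand = [depth[p] + 1 for p in (s, d) if p >= 0]
            depth[k] = max(cand) if cand else 0
        return depth

    def stats(self) -> dict:
        """Size, maximum depth and number of known parent links.

        Depth counts parent-offspring links on the longest founder-to-
        descendant path, so a founder-only pedigree has depth 0.
        """
        return {
            "size": len(self),
            "max_depth": int(self.depths().max()) if len(self) else 0,
            "n_paternities": int((self._sire >= 0).sum()),
            "n_maternities": int((self._dam >= 0).sum()),
        }

    def prune(self, phenotyped_ids) -> "Pedigree":
        """Restrict to phenotyped individuals and all of their ancestors.

        Phenotyped ids absent from the pedigree are retained as founders
        with a warning, so downstream models never lose a phenotyped record.
        """
        phenotyped = [str(i) for i in phenotyped_ids]
        if not phenotyped:
            raise InvalidArgumentError("phenotyped_ids must be non-empty")
        missing = sorted(set(phenotyped) - set(self._index))
        if missing:
            warnings.warn(
                f"{len(missing)} phenotyped id(s) absent from pedigree, retained "
                f"as founders: {missing[:5]}",
                stacklevel=2,
            )
        keep = set()
        stack = [i for i in phenotyped if i in self._index]
        while stack:
            i = stack.pop()
            if i in keep:
                continue
            keep.add(i)
            for p in self.parents_of(i):
                if p is not None:
                    stack.append(p)
        rows = [i for i in self._ids if i in keep] + missing
        kept = set(rows)
        sires, dams = [], []
        for i in rows:
            if i in self._index:
                s, d = self.parents_of(i)
            else:
                s = d = None
            sires.append(s if s in kept else "")
            dams.append(d if d in kept else "")
        sex = {i: self.sex[i] for i in rows if i in self.sex}
        return Pedigree(rows, sires, dams, sex=sex)

    def a_matrix(self) -> RelatednessMatrix:
        """Additive relationship matrix by the tabular method, O(n^2) memory."""
        n = len(self)
        A = np.zeros((n, n))
        s, d = self._sire, self._dam
        for i in range(n):
            si, di = s[i], d[i]
            if si >= 0 and di >= 0:
                A[i, i] = 1.0 + 0.5 * A[si, di]
            else:
                A[i, i] = 1.0
            if i:
                row = np.zeros(i)
                if si >= 0:
                    row += 0.5 * A[:i, si]
                if di >= 0:
                    row += 0.5 * A[:i, di]
                A[i, :i] = row
                A[:i, i] = row
        return RelatednessMatrix(ids=self._ids, values=A)


def read_pedigree(path) -> Pedigree:
    """Read a three-column CSV (id, sire, dam; empty field = unknown parent)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise InvalidArgumentError(
            f"pedigree file needs 3 columns (id, sire, dam), got {df.shape[1]}"
        )
    ids, sires, dams = (df.iloc[:, k].tolist() for k in range(3))
    return Pedigree(ids, sires, dams)
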