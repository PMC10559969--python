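"""Numerator relationship matrix for a sire--maternal-grandsire pedigree.

Cows are linked to ancestors only through their sire and maternal grandsire
(MGS); dams are not tracked as individuals.  Additive genetic effects then
follow the linear recursion

    u_x = 1/2 u_sire + 1/4 u_mgs + phi_x,

so relationships obey  a(x, y) = 1/2 a(s, y) + 1/4 a(m, y)  for any earlier
animal y, the diagonal accrues  a(x, x) = 1 + 1/4 a(s, m),  and the
Mendelian-sampling variance is  d_x = 1 - 1/4 a(s, s) - 1/16 a(m, m)
(dropping the term of any unknown parent; 11/16 for a non-inbred known
sire/MGS pair).  The sparse inverse is assembled animal by animal from the
same recursion, exactly as Henderson's rules are for a sire--dam pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse


class PedigreeError(ValueError):
    pass


def _clean_id(x):
    if x is None or (isinstance(x, float) and np.isnan(x)) or pd.isna(x):
        return None
    s = str(x).strip()
    return s if s and s.lower() not in ("nan", "none", "unknown", "0") else None


@dataclass
class PedigreeTable:
    """Topologically ordered pedigree with integer sire/MGS pointers.

    ``sire`` / ``mgs`` hold the position of the parent in ``ids`` or -1 when
    unknown; parents always precede offspring.
    """

    ids: list
    sire: np.ndarray
    mgs: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([pos[str(a)] for a in animal_ids], dtype=np.int64)
        except KeyError as e:
            raise PedigreeError(f"animal not in pedigree: {e.args[0]!r}") from None

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PedigreeTable":
        """Validate, complete founders, and topologically sort a pedigree.

        ``frame`` needs columns ``animal_id``, ``sire_id``, ``mgs_id`` (empty
        or NaN marks an unknown parent).  Sires/MGS referenced without a row
        of their own are added as founders.  A cycle raises ``PedigreeError``
        naming the animals involved.
        """
        animals: dict[str, tuple] = {}
        for _, row in frame.iterrows():
            a = _clean_id(row["animal_id"])
            if a is None:
                raise PedigreeError("blank animal id in pedigree")
            if a in animals:
                raise PedigreeError(f"duplicate pedigree row for {a!r}")
            animals[a] = (_clean_id(row.get("sire_id")), _clean_id(row.get("mgs_id")))
        # referenced-but-absent ancestors become founders
        for s, m in list(animals.values()):
            for p in (s, m):
                if p is not None and p not in animals:
                    animals[p] = (None, None)

        # Kahn's algorithm: parents first
        children: dict[str, list] = {a: [] for a in animals}
        indeg = {a: 0 for a in animals}
        for a, (s, m) in animals.items():
            for p in {p for p in (s, m) if p is not None}:
                children[p].append(a)
                indeg[a] += 1
        order = [a for a in animals if indeg[a] == 0]
        head = 0
        while head < len(order):
            a = order[head]
            head += 1
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
        if len(order) != len(animals):
            cyc = sorted(a for a in animals if indeg[a] > 0)
            raise PedigreeError(f"pedigree contains a cycle involving: {cyc}")

        pos = {a: i for i, a in enumerate(order)}
        sire = np.array(
            [pos[animals[a][0]] if animals[a][0] is not None else -1 for a in order],
            dtype=np.int64,
        )
        mgs = np.array(
            [pos[animals[a][1]] if animals[a][1] is not None else -1 for a in order],
            dtype=np.int64,
        )
        return cls(ids=order, sire=sire, mgs=mgs)

    @classmethod
    def from_csv(cls, path) -> "PedigreeTable":
        return cls.from_frame(pd.read_csv(path, dtype=str))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.ids,
                "sire_id": [self.ids[s] if s >= 0 else "" for s in self.sire],
                "mgs_id": [self.ids[m] if m >= 0 else "" for m in self.mgs],
            }
        )

    def mendelian_variances(self) -> np.ndarray:
        """Per-animal Mendelian-sampling variance d (in units of sigma_a^2)."""
        cached = getattr(self, "_d_cache", None)
        if cached is not None:
            return cached
        diag = self._diagonal()
        d = np.ones(len(self))
        for i in range(len(self)):
            s, m = self.sire[i], self.mgs[i]
            if s >= 0:
                d[i] -= 0.25 * diag[s]
            if m >= 0:
                d[i] -= 0.0625 * diag[m]
        object.__setattr__(self, "_d_cache", d)
        return d

    def _diagonal(self) -> np.ndarray:
        """Diagonal of A without keeping the full matrix (needs a(s, m))."""
        cached = getattr(self, "_diag_cache", None)
        if cached is not None:
            return cached
        # relationships between parents are needed; fall back to full build
        # only when any animal has both parents known
        if np.any((self.sire >= 0) & (self.mgs >= 0)):
            diag = np.diag(build_A(self).matrix).copy()
        else:
            diag = np.ones(len(self))
        object.__setattr__(self, "_diag_cache", diag)
        return diag


@dataclass
class RelationshipMatrix:
    """Additive relationships (or their inverse) among ordered animals."""

    ids: list
    matrix: object  # ndarray (A) or scipy sparse (A-inverse)
    is_inverse: bool
    log_det: float  # log|A| in both cases

    def submatrix(self, animal_ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.ids)}
        idx = np.array([pos[str(a)] for a in animal_ids], dtype=np.int64)
        M = self.matrix.toarray() if sparse.issparse(self.matrix) else self.matrix
        return M[np.ix_(idx, idx)]

    def to_triplets(self, path) -> None:
        """Write a sparse triplet (row-id, col-id, value) file for inspection."""
        M = self.matrix if sparse.issparse(self.matrix) else sparse.coo_matrix(self.matrix)
        M = M.tocoo()
        with open(path, "w") as fh:
            fh.write("row_id,col_id,value\n")
            for i, j, v in zip(M.row, M.col, M.data):
                if i <= j and v != 0.0:
                    fh.write(f"{self.ids[i]},{self.ids[j]},{v:.10g}\n")


def build_A(pedigree: PedigreeTable) -> RelationshipMatrix:
    """Dense numerator relationship matrix by the tabular recursion."""
    n = len(pedigree)
    A = np.zeros((n, n))
    logdet = 0.0
    for i in range(n):
        s, m = pedigree.sire[i], pedigree.mgs[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if m >= 0:
            row += 0.25 * A[m, :i]
        A[i, :i] = row
        A[:i, i] = row
        asm = A[s, m] if (s >= 0 and m >= 0) else 0.0
        A[i, i] = 1.0 + 0.25 * asm
        d = 1.0
        if s >= 0:
            d -= 0.25 * A[s, s]
        if m >= 0:
            d -= 0.0625 * A[m, m]
        logdet += np.log(d)
    return RelationshipMatrix(ids=list(pedigree.ids), matrix=A, is_inverse=False, log_det=logdet)


def build_A_inverse(pedigree: PedigreeTable) -> RelationshipMatrix:
    """Sparse inverse of A assembled directly from per-animal rules.

    For each animal x with parent coefficient vector k (1/2 on the sire, 1/4
    on the MGS) and Mendelian variance d_x, add (e_x - k)(e_x - k)'/d_x.
    Diagonals a(s, s), a(m, m) needed for d_x come from the tabular
    recursion's diagonal.
    """
    n = len(pedigree)
    diag = pedigree._diagonal()
    rows, cols, vals = [], [], []
    logdet = 0.0
    for i in range(n):
        s, m = pedigree.sire[i], pedigree.mgs[i]
        d = 1.0
        if s >= 0:
            d -= 0.25 * diag[s]
        if m >= 0:
            d -= 0.0625 * diag[m]
        logdet += np.log(d)
        w = 1.0 / d
        members = [(i, 1.0)]
        if s >= 0:
            members.append((s, -0.5))
        if m >= 0:
            members.append((m, -0.25))
        for a, ca in members:
            for b, cb in members:
                rows.append(a)
                cols.append(b)
                vals.append(w * ca * cb)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(ids=list(pedigree.ids), matrix=Ainv, is_inverse=True, log_det=logdet)
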