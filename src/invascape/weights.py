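"""Polygon-contiguity spatial weights.

Weights encode which areal units are neighbors.  Queen contiguity counts
any shared boundary point (edge or corner); rook requires a shared edge of
positive length.  The binary adjacency is always symmetric; row
standardization divides each unit's weights by its neighbor count so the
spatial lag ``Wy`` is a neighbor average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from shapely.strtree import STRtree

from invascape.errors import DegenerateWeightsError, SystemValidationError
from invascape.units import UnitSystem, _AREA_TOL


@dataclass
class SpatialWeights:
    """Sparse neighbor structure over a fixed ordering of unit ids.

    ``neighbors[i]`` holds the integer indices of unit *i*'s neighbors in
    ``ids`` order.  ``style`` is ``"binary"`` (w_ij = 1) or ``"row"``
    (w_ij = 1/|neighbors(i)|).  Units without neighbors are islands: their
    rows are all zeros under either style.
    """

    ids: list[str]
    neighbors: list[np.ndarray]
    style: str = "binary"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.neighbors):
            raise ValueError("ids and neighbor lists differ in length")
        if self.style not in ("binary", "row"):
            raise ValueError(f"unknown weights style {self.style!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def islands(self) -> list[str]:
        return [self.ids[i] for i, nb in enumerate(self.neighbors) if len(nb) == 0]

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    def index_of(self) -> dict[str, int]:
        return {uid: i for i, uid in enumerate(self.ids)}

    # -------------------------------------------------------------- matrices

    def sparse(self) -> sp.csr_matrix:
        key = ("sparse", self.style)
        if key not in self._cache:
            rows, cols, vals = [], [], []
            for i, nb in enumerate(self.neighbors):
                if len(nb) == 0:
                    continue
                w = 1.0 / len(nb) if self.style == "row" else 1.0
                rows.extend([i] * len(nb))
                cols.extend(nb.tolist())
                vals.extend([w] * len(nb))
            self._cache[key] = sp.csr_matrix(
                (vals, (rows, cols)), shape=(self.n, self.n)
            )
        return self._cache[key]

    def dense(self) -> np.ndarray:
        return self.sparse().toarray()

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of the (possibly non-symmetric) weight matrix."""
        key = ("eigs", self.style)
        if key not in self._cache:
            self._cache[key] = np.linalg.eigvals(self.dense())
        return self._cache[key]

    # ------------------------------------------------ Cliff–Ord sum terms

    def moments(self) -> tuple[float, float, float]:
        """Return (S0, S1, S2): the Cliff–Ord weight sums.

        S0 = ΣΣ w_ij;  S1 = ½ ΣΣ (w_ij + w_ji)²;
        S2 = Σ_i (w_i· + w_·i)² with w_i· the i-th row sum.
        """
        key = ("moments", self.style)
        if key not in self._cache:
            w = self.sparse()
            s0 = float(w.sum())
            wpt = (w + w.T).tocsr()
            s1 = 0.5 * float(wpt.multiply(wpt).sum())
            rs = np.asarray(w.sum(axis=1)).ravel()
            cs = np.asarray(w.sum(axis=0)).ravel()
            s2 = float(((rs + cs) ** 2).sum())
            self._cache[key] = (s0, s1, s2)
        return self._cache[key]

    # ---------------------------------------------------------- restriction

    def subset(self, keep_ids) -> "SpatialWeights":
        """Restrict the adjacency to ``keep_ids`` (original order kept).

        The binary adjacency is intersected with the kept set; if this
        object is row-standardized the restricted rows are re-standardized.
        """
        keep = set(keep_ids)
        idx = [i for i, uid in enumerate(self.ids) if uid in keep]
        remap = {old: new for new, old in enumerate(idx)}
        new_nb = [
            np.array([remap[j] for j in self.neighbors[i] if j in remap], dtype=int)
            for i in idx
        ]
        return SpatialWeights(
            ids=[self.ids[i] for i in idx], neighbors=new_nb, style=self.style
        )

    # ---------------------------------------------------------------- export

    def to_neighbor_list(self, path) -> None:
        """Write a plain-text neighbor list: ``unit_id: nbr*w nbr*w ...``."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# style={self.style} n={self.n}\n")
            for i, uid in enumerate(self.ids):
                nb = self.neighbors[i]
                w = 1.0 / len(nb) if (self.style == "row" and len(nb)) else 1.0
                items = " ".join(f"{self.ids[j]}*{w:.6g}" for j in nb)
                fh.write(f"{uid}: {items}\n")


def build_contiguity(units: UnitSystem, rule: str = "queen") -> SpatialWeights:
    """Binary contiguity weights from a polygon partition.

    queen: any shared boundary point makes two units neighbors.
    rook: a shared boundary of positive length is required.
    Overlapping polygons of positive area violate the partition invariant.
    """
    if rule not in ("queen", "rook"):
        raise ValueError(f"rule must be 'queen' or 'rook', got {rule!r}")
    if len(units) < 2:
        raise DegenerateWeightsError(
            f"system {units.system_id!r} has {len(units)} unit(s); "
            "contiguity needs at least two"
        )
    geoms = units.geometries
    tree = STRtree(geoms)
    qi, qj = tree.query(geoms, predicate="intersects")
    nbrs: list[set[int]] = [set() for _ in geoms]
    for i, j in zip(qi, qj):
        if i >= j:
            continue
        inter = geoms[i].intersection(geoms[j])
        if inter.area > _AREA_TOL * min(geoms[i].area, geoms[j].area):
            a, b = units.table.index[i], units.table.index[j]
            raise SystemValidationError(
                f"units {a!r} and {b!r} overlap with positive area"
            )
        if inter.is_empty:
            continue
        if rule == "rook" and inter.length <= 0:
            continue
        nbrs[i].add(j)
        nbrs[j].add(i)
    neighbors = [np.array(sorted(s), dtype=int) for s in nbrs]
    return SpatialWeights(ids=units.unit_ids, neighbors=neighbors, style="binary")


def row_standardize(w: SpatialWeights) -> SpatialWeights:
    """Row-standardized view: each nonzero row scaled to sum to one.

    Idempotent; island rows stay all-zero.
    """
    if w.style == "row":
        return w
    return SpatialWeights(ids=list(w.ids), neighbors=list(w.neighbors), style="row")
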