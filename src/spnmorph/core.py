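"""Core containers for neuronal reconstructions.

A reconstruction is a rooted tree of 3D sample points with radii, in the
7-column SWC convention (type 1 = soma, 2 = axon, 3 = dendrite).  All
coordinates and radii are in micrometres.  After standardisation the soma is a
single spherical node at the origin and every dendrite attaches to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

SOMA = 1
AXON = 2
DENDRITE = 3


class StructuralError(ValueError):
    """Raised when a node table does not describe a valid rooted tree."""


@dataclass(frozen=True)
class SwcNode:
    """One SWC sample point."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class SomaContour:
    """Closed 2D soma outline used for Feret-diameter measurements."""

    points: np.ndarray  # (n, 2), μm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")
        if len(self.points) < 3:
            raise ValueError("a soma contour needs at least 3 points")


class Reconstruction:
    """Rooted tree of SWC nodes held as parallel arrays.

    Parameters
    ----------
    ids, types, xyz, radius, parent_ids
        Parallel arrays describing the node table.  ``parent_ids`` uses the
        SWC convention of −1 for the root.
    provenance
        Free-form metadata (species, corrections applied, seeds).
    """

    def __init__(
        self,
        ids: np.ndarray,
        types: np.ndarray,
        xyz: np.ndarray,
        radius: np.ndarray,
        parent_ids: np.ndarray,
        provenance: dict | None = None,
        validate: bool = True,
    ) -> None:
        self.ids = np.asarray(ids, dtype=np.int64)
        self.types = np.asarray(types, dtype=np.int64)
        self.xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        self.radius = np.asarray(radius, dtype=float)
        self.parent_ids = np.asarray(parent_ids, dtype=np.int64)
        self.provenance = dict(provenance or {})
        self._index: dict[int, int] | None = None
        self._parent_index: np.ndarray | None = None
        self._children: list[list[int]] | None = None
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    # construction helpers
    @classmethod
    def from_nodes(cls, nodes: Iterable[SwcNode], provenance: dict | None = None,
                   validate: bool = True) -> "Reconstruction":
        rows = list(nodes)
        return cls(
            ids=np.array([n.id for n in rows], dtype=np.int64),
            types=np.array([n.type_code for n in rows], dtype=np.int64),
            xyz=np.array([[n.x, n.y, n.z] for n in rows], dtype=float),
            radius=np.array([n.radius for n in rows], dtype=float),
            parent_ids=np.array([n.parent_id for n in rows], dtype=np.int64),
            provenance=provenance,
            validate=validate,
        )

    def copy(self) -> "Reconstruction":
        return Reconstruction(
            self.ids.copy(), self.types.copy(), self.xyz.copy(),
            self.radius.copy(), self.parent_ids.copy(),
            provenance=dict(self.provenance), validate=False,
        )

    def nodes(self) -> list[SwcNode]:
        return [
            SwcNode(int(i), int(t), float(p[0]), float(p[1]), float(p[2]),
                    float(r), int(pid))
            for i, t, p, r, pid in zip(self.ids, self.types, self.xyz,
                                       self.radius, self.parent_ids)
        ]

    # ------------------------------------------------------------------
    # indexing
    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[int, int]:
        if self._index is None:
            self._index = {int(i): k for k, i in enumerate(self.ids)}
        return self._index

    @property
    def parent_index(self) -> np.ndarray:
        """Row index of each node's parent (−1 for the root)."""
        if self._parent_index is None:
            idx = self.index
            out = np.empty(self.n_nodes, dtype=np.int64)
            for k, pid in enumerate(self.parent_ids):
                out[k] = -1 if pid == -1 else idx[int(pid)]
            self._parent_index = out
        return self._parent_index

    @property
    def children(self) -> list[list[int]]:
        """Row indices of each node's children, in file order."""
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for k, p in enumerate(self.parent_index):
                if p >= 0:
                    ch[p].append(k)
            self._children = ch
        return self._children

    def invalidate_caches(self) -> None:
        self._index = None
        self._parent_index = None
        self._children = None

    # ------------------------------------------------------------------
    # validation
    def validate(self) -> None:
        ids = self.ids
        if len(np.unique(ids)) != len(ids):
            dup = ids[np.argmax(np.bincount(ids - ids.min()) > 1)]
            raise StructuralError(f"duplicate node id {int(dup)}")
        if np.any(self.radius <= 0):
            bad = int(self.ids[np.argmax(self.radius <= 0)])
            raise ValueError(f"non-positive radius at node {bad}")
        idx = self.index
        roots = 0
        for k, pid in enumerate(self.parent_ids):
            pid = int(pid)
            if pid == -1:
                roots += 1
                continue
            if pid == int(self.ids[k]):
                raise StructuralError(f"node {pid} is its own parent")
            if pid not in idx:
                raise StructuralError(
                    f"node {int(self.ids[k])} has unknown parent {pid}")
        if roots != 1:
            raise StructuralError(f"expected exactly one root, found {roots}")
        # acyclicity / connectivity: every node must reach the root
        pidx = self.parent_index
        state = np.zeros(self.n_nodes, dtype=np.int8)  # 0 new, 1 open, 2 done
        for k in range(self.n_nodes):
            path = []
            j = k
            while j >= 0 and state[j] == 0:
                state[j] = 1
                path.append(j)
                j = pidx[j]
            if j >= 0 and state[j] == 1:
                raise StructuralError(
                    f"cycle detected through node {int(self.ids[j])}")
            for p in path:
                state[p] = 2

    # ------------------------------------------------------------------
    # geometry
    @property
    def root_index(self) -> int:
        return int(np.argmax(self.parent_ids == -1))

    @property
    def soma_mask(self) -> np.ndarray:
        return self.types == SOMA

    @property
    def dendrite_mask(self) -> np.ndarray:
        return self.types == DENDRITE

    @property
    def is_standardized(self) -> bool:
        return (int(self.soma_mask.sum()) == 1
                and bool(np.allclose(self.xyz[self.root_index], 0.0)))

    @property
    def soma_center(self) -> np.ndarray:
        return self.xyz[self.soma_mask].mean(axis=0)

    @property
    def soma_radius(self) -> float:
        pts = self.xyz[self.soma_mask]
        if len(pts) == 1:
            return float(self.radius[self.soma_mask][0])
        c = pts.mean(axis=0)
        return float(np.linalg.norm(pts - c, axis=1).mean())

    def edge_lengths(self) -> np.ndarray:
        """Length of the edge to each node's parent (0 for the root)."""
        pidx = self.parent_index
        out = np.zeros(self.n_nodes)
        has = pidx >= 0
        out[has] = np.linalg.norm(
            self.xyz[has] - self.xyz[pidx[has]], axis=1)
        return out

    def total_dendritic_length(self) -> float:
        """Sum of dendrite–dendrite edge lengths (soma-attached edge excluded)."""
        pidx = self.parent_index
        el = self.edge_lengths()
        mask = (self.types == DENDRITE)
        mask &= np.where(pidx >= 0, self.types[np.maximum(pidx, 0)] == DENDRITE,
                         False)
        return float(el[mask].sum())

    def path_distances(self) -> np.ndarray:
        """Arc distance from the soma along the dendrite, per node.

        The first dendritic node of each primary dendrite (the node attached
        to the soma) is at distance 0; soma nodes are at 0.
        """
        pidx = self.parent_index
        el = self.edge_lengths()
        pd = np.zeros(self.n_nodes)
        order = topological_order(pidx)
        for k in order:
            p = pidx[k]
            if p < 0 or self.types[p] == SOMA or self.types[k] != DENDRITE:
                pd[k] = 0.0
            else:
                pd[k] = pd[p] + el[k]
        return pd

    def drop_axon(self) -> "Reconstruction":
        """Return a copy without axonal nodes (and their subtrees)."""
        keep = np.ones(self.n_nodes, dtype=bool)
        pidx = self.parent_index
        for k in topological_order(pidx):
            if self.types[k] == AXON or (pidx[k] >= 0 and not keep[pidx[k]]):
                keep[k] = False
        return self._subset(keep)

    def _subset(self, keep: np.ndarray) -> "Reconstruction":
        return Reconstruction(
            self.ids[keep], self.types[keep], self.xyz[keep],
            self.radius[keep], self.parent_ids[keep],
            provenance=dict(self.provenance), validate=False,
        )


def topological_order(parent_index: np.ndarray) -> np.ndarray:
    """Row indices ordered so every parent precedes its children."""
    n = len(parent_index)
    children: list[list[int]] = [[] for _ in range(n)]
    root = -1
    for k, p in enumerate(parent_index):
        if p < 0:
            root = k
        else:
            children[p].append(k)
    out = np.empty(n, dtype=np.int64)
    stack = [root]
    i = 0
    while stack:
        k = stack.pop()
        out[i] = k
        i += 1
        stack.extend(reversed(children[k]))
    if i != n:
        raise StructuralError("node table is not a connected tree")
    return out
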