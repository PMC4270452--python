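"""Gap-junction network inference from cell positions via Voronoi tessellation.

Every cell of the culture (astrocytes, neurons, unclassified) enters the
tessellation, so that a neuron or unclassified cell sitting between two
astrocytes breaks their adjacency.  Two astrocytes are coupled iff their
Voronoi regions, clipped to the field rectangle, share a border of positive
length; degenerate point contacts do not count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, QhullError
from shapely.geometry import LineString, box

from .culture import Culture

__all__ = ["AstrocyteNetwork", "build_voronoi_network", "voronoi_adjacency", "network_stats"]

_MIN_BORDER_UM = 1e-9


@dataclass(frozen=True)
class AstrocyteNetwork:
    """Symmetric, irreflexive gap-junction adjacency over astrocytes.

    ``astrocyte_ids`` are the culture cell ids; ``edges`` is an (m, 2) array
    of *indices into astrocyte_ids* with each undirected pair listed once
    (i < j).  ``stimulated`` is a boolean mask over astrocytes and encodes
    the a=0/1 stimulation indicator of the IP3 balance equation.
    """

    astrocyte_ids: tuple[int, ...]
    positions: np.ndarray            # (n, 2) um
    edges: np.ndarray                # (m, 2) int indices, i < j
    stimulated: np.ndarray           # (n,) bool

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        e = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        stim = np.asarray(self.stimulated, dtype=bool)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "stimulated", stim)
        n = len(self.astrocyte_ids)
        if pos.shape[0] != n or stim.shape[0] != n:
            raise ValueError("positions/stimulated size mismatch")
        if e.size:
            if np.any(e[:, 0] == e[:, 1]):
                raise ValueError("self-pairs are not allowed")
            if e.min() < 0 or e.max() >= n:
                raise ValueError("edge index out of range")
            key = e.min(axis=1) * n + e.max(axis=1)
            if np.unique(key).size != e.shape[0]:
                raise ValueError("duplicate edges")

    @property
    def n_astrocytes(self) -> int:
        return len(self.astrocyte_ids)

    @property
    def stimulated_ids(self) -> tuple[int, ...]:
        return tuple(np.asarray(self.astrocyte_ids)[self.stimulated])

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_astrocytes, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_astrocytes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    # -- I/O ---------------------------------------------------------------
    def to_files(self, edge_path: str | Path, node_path: str | Path) -> None:
        ids = np.asarray(self.astrocyte_ids)
        pd.DataFrame(
            {"id_a": ids[self.edges[:, 0]] if self.edges.size else [],
             "id_b": ids[self.edges[:, 1]] if self.edges.size else []}
        ).to_csv(edge_path, sep="\t", index=False)
        pd.DataFrame(
            {"id": ids, "x_um": self.positions[:, 0], "y_um": self.positions[:, 1],
             "stimulated": self.stimulated}
        ).to_csv(node_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, edge_path: str | Path, node_path: str | Path) -> "AstrocyteNetwork":
        nodes = pd.read_csv(node_path, sep="\t")
        edges = pd.read_csv(edge_path, sep="\t")
        ids = tuple(int(i) for i in nodes["id"])
        index = {cid: k for k, cid in enumerate(ids)}
        e = np.array(
            [sorted((index[int(a)], index[int(b)])) for a, b in
             zip(edges["id_a"], edges["id_b"])],
            dtype=int,
        ).reshape(-1, 2)
        return cls(ids, nodes[["x_um", "y_um"]].to_numpy(float),
                   e, nodes["stimulated"].to_numpy(bool))


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    if points.shape[0] < 3:
        return True
    d = points - points[0]
    cross = d[1, 0] * d[1:, 1] - d[1, 1] * d[1:, 0]
    return bool(np.all(np.abs(cross) <= tol * max(1.0, np.abs(d).max()) ** 2))


def _ridge_segments(vor: Voronoi, bounds: tuple[float, float, float, float]):
    """Yield (site_i, site_j, shapely segment) for every Voronoi ridge,
    with unbounded ridges extended far past the field and then clipped."""
    xmin, ymin, xmax, ymax = bounds
    span = max(xmax - xmin, ymax - ymin)
    far = 10.0 * span + 1.0
    center = vor.points.mean(axis=0)
    clip = box(xmin, ymin, xmax, ymax)
    for (i, j), verts in zip(vor.ridge_points, vor.ridge_vertices):
        v1, v2 = verts
        if v1 >= 0 and v2 >= 0:
            seg = LineString([vor.vertices[v1], vor.vertices[v2]])
        else:
            vfin = vor.vertices[v2 if v1 < 0 else v1]
            t = vor.points[j] - vor.points[i]
            t = t / np.linalg.norm(t)
            normal = np.array([-t[1], t[0]])
            midpoint = 0.5 * (vor.points[i] + vor.points[j])
            direction = normal if np.dot(midpoint - center, normal) > 0 else -normal
            seg = LineString([vfin, vfin + direction * far])
        yield int(i), int(j), seg.intersection(clip)


def voronoi_adjacency(
    points: np.ndarray, bounds: tuple[float, float, float, float]
) -> set[tuple[int, int]]:
    """Pairs of point indices whose Voronoi regions share a border of
    positive length inside the bounding rectangle."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = points.shape[0]
    if n < 2:
        return set()
    if n == 2 or _collinear(points):
        warnings.warn(
            "fewer than 3 non-collinear cells: falling back to 1D nearest-neighbour "
            "adjacency along the line", stacklevel=2)
        # project on the principal direction; consecutive cells share a border
        d = points - points.mean(axis=0)
        axis = d[np.argmax(np.linalg.norm(d, axis=1))]
        nrm = np.linalg.norm(axis)
        axis = axis / nrm if nrm > 0 else np.array([1.0, 0.0])
        order = np.argsort(points @ axis)
        return {tuple(sorted((int(order[k]), int(order[k + 1])))) for k in range(n - 1)}
    try:
        vor = Voronoi(points)
    except QhullError:
        warnings.warn("degenerate point set: falling back to pairwise rule", stacklevel=2)
        return voronoi_adjacency(points + 1e-6 * np.random.default_rng(0).normal(size=points.shape),
                                 bounds)
    adj: set[tuple[int, int]] = set()
    for i, j, seg in _ridge_segments(vor, bounds):
        if seg.length > _MIN_BORDER_UM:
            adj.add((min(i, j), max(i, j)))
    return adj


def build_voronoi_network(culture: Culture) -> AstrocyteNetwork:
    """Infer the gap-junction coupling topology of a culture.

    All cells enter the tessellation; only astrocyte-astrocyte shared borders
    become edges, so interposed neurons/unclassified cells separate
    astrocytes.
    """
    if len(culture) == 0:
        raise ValueError("culture has no cells")
    pos = culture.positions
    if culture.spec is not None:
        bounds = (0.0, 0.0, culture.spec.field_width_um, culture.spec.field_height_um)
    else:
        pad = 1.0 + 0.05 * float(np.ptp(pos, axis=0).max() if len(culture) > 1 else 1.0)
        bounds = (pos[:, 0].min() - pad, pos[:, 1].min() - pad,
                  pos[:, 0].max() + pad, pos[:, 1].max() + pad)

    astro_idx = [k for k, c in enumerate(culture.cells) if c.cell_class == "astrocyte"]
    astro_rank = {k: r for r, k in enumerate(astro_idx)}
    adj = voronoi_adjacency(pos, bounds) if len(culture) > 1 else set()
    edges = sorted(
        (astro_rank[i], astro_rank[j])
        for i, j in adj
        if i in astro_rank and j in astro_rank
    )
    cells = [culture.cells[k] for k in astro_idx]
    return AstrocyteNetwork(
        astrocyte_ids=tuple(c.cell_id for c in cells),
        positions=pos[astro_idx].reshape(-1, 2),
        edges=np.array(edges, dtype=int).reshape(-1, 2),
        stimulated=np.array([c.stimulated for c in cells], dtype=bool),
    )


def network_stats(net: AstrocyteNetwork) -> dict:
    """Degree histogram and connected-component size histogram."""
    if net.n_astrocytes == 0:
        return {"degree_histogram": {}, "component_size_histogram": {},
                "n_astrocytes": 0, "n_edges": 0}
    deg = net.degrees()
    comp_sizes = [len(c) for c in nx.connected_components(net.graph())]
    dh = {int(k): int(v) for k, v in zip(*np.unique(deg, return_counts=True))}
    ch = {int(k): int(v) for k, v in zip(*np.unique(comp_sizes, return_counts=True))}
    return {
        "degree_histogram": dh,
        "component_size_histogram": ch,
        "n_astrocytes": net.n_astrocytes,
        "n_edges": int(net.edges.shape[0]),
    }
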