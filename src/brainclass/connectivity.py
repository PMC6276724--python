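"""White-matter connectivity metrics on triangulated cortical surfaces.

The central quantity is the per-vertex connectivity density (CD): the number
of retained streamlines linking a small geodesic neighborhood of a vertex to
the rest of the surface, normalized by the neighborhood area and by the total
connection count.  Supporting operations cover streamline filtering by
turning angle, per-streamline mean fractional anisotropy (FA), endpoint
snapping into a vertex-level connectivity matrix, geodesic neighborhoods,
Gaussian surface smoothing, and parcel aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "CorticalMesh",
    "Streamline",
    "StreamlineSet",
    "ConnectivityMatrix",
    "VertexMetrics",
    "turning_angles",
    "filter_streamlines",
    "streamline_mean_fa",
    "build_connectivity_matrix",
    "geodesic_neighborhood",
    "compute_vertex_metrics",
    "smooth_vertex_map",
    "aggregate_to_parcels",
]

_DEGENERATE_AREA = 1e-12


@dataclass(eq=False)
class CorticalMesh:
    """Triangulated surface with per-vertex area weights.

    Parameters
    ----------
    vertices : (V, 3) float array, coordinates in mm.
    faces : (F, 3) int array of vertex index triples.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidInputError("vertices must be an (V, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise InvalidInputError("faces must be an (F, 3) array")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= self.n_vertices
        ):
            raise InvalidInputError("face indices out of range")
        if np.any(self.triangle_areas < _DEGENERATE_AREA):
            bad = np.where(self.triangle_areas < _DEGENERATE_AREA)[0]
            raise InvalidInputError(f"degenerate (zero-area) triangles: {bad.tolist()}")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @cached_property
    def triangle_areas(self) -> np.ndarray:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    @cached_property
    def vertex_areas(self) -> np.ndarray:
        """One third of the summed area of triangles incident to each vertex."""
        areas = np.zeros(self.n_vertices)
        per_face = self.triangle_areas / 3.0
        for k in range(3):
            np.add.at(areas, self.faces[:, k], per_face)
        return areas

    @property
    def total_area(self) -> float:
        return float(self.triangle_areas.sum())

    @cached_property
    def edge_graph(self) -> sp.csr_matrix:
        """Sparse symmetric graph of mesh edges weighted by Euclidean length."""
        i = np.concatenate([self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]])
        j = np.concatenate([self.faces[:, 1], self.faces[:, 2], self.faces[:, 0]])
        w = np.linalg.norm(self.vertices[i] - self.vertices[j], axis=1)
        g = sp.coo_matrix((w, (i, j)), shape=(self.n_vertices, self.n_vertices))
        g = g.maximum(g.T)  # symmetrize; duplicate edges collapse to one weight
        return g.tocsr()

    def geodesic_distances(
        self, indices: Sequence[int] | None = None, limit: float = np.inf
    ) -> np.ndarray:
        """Shortest-path distances along mesh edges (Dijkstra).

        Entries beyond ``limit`` are ``inf``.  Returns an array of shape
        (len(indices), V), or (V, V) when ``indices`` is None.
        """
        return dijkstra(
            self.edge_graph, directed=False, indices=indices, limit=limit
        )


@dataclass(eq=False)
class Streamline:
    """Ordered 3-D polyline with one FA sample per point."""

    points: np.ndarray
    fa: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidInputError("streamline points must be an (P, 3) array")
        if self.points.shape[0] < 2:
            raise InvalidInputError("streamline needs at least 2 points")
        if self.fa is not None:
            self.fa = np.asarray(self.fa, dtype=float)
            if self.fa.shape != (self.points.shape[0],):
                raise InvalidInputError("one FA sample per streamline point required")
            if np.any((self.fa < 0) | (self.fa > 1)):
                raise InvalidInputError("FA samples must lie in [0, 1]")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(eq=False)
class StreamlineSet:
    """Immutable ordered collection of streamlines."""

    streamlines: tuple[Streamline, ...] = ()

    def __post_init__(self) -> None:
        self.streamlines = tuple(self.streamlines)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[Streamline]:
        return iter(self.streamlines)

    def __getitem__(self, idx: int) -> Streamline:
        return self.streamlines[idx]


@dataclass(eq=False)
class ConnectivityMatrix:
    """Vertex-by-vertex streamline count matrix with provenance.

    ``pairs`` holds one (i, j) vertex pair per retained streamline, aligned
    with ``kept_indices`` into the originating streamline set.
    """

    matrix: sp.csr_matrix
    pairs: np.ndarray
    kept_indices: np.ndarray
    n_unmapped: int = 0
    n_self_loops: int = 0

    @property
    def n_connections(self) -> int:
        """Total retained streamline count (= sum of the upper triangle)."""
        return int(self.pairs.shape[0])

    @property
    def n_nonzero_pairs(self) -> int:
        """Number of distinct connected vertex pairs."""
        return int(sp.triu(self.matrix, k=1).nnz)


@dataclass(eq=False)
class VertexMetrics:
    """Per-vertex connectivity density and mean-FA maps."""

    cd: np.ndarray
    mean_fa: np.ndarray
    empty_neighborhood: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


def turning_angles(points: np.ndarray) -> np.ndarray:
    """Angles (degrees) between consecutive segments of a polyline."""
    points = np.asarray(points, dtype=float)
    d = np.diff(points, axis=0)
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms == 0):
        raise InvalidInputError("polyline has repeated consecutive points")
    u = d / norms[:, None]
    cosines = np.clip(np.sum(u[:-1] * u[1:], axis=1), -1.0, 1.0)
    return np.degrees(np.arccos(cosines))


def filter_streamlines(
    streamlines: StreamlineSet,
    max_turning_angle: float = 60.0,
    literal_angle_rule: bool = False,
) -> StreamlineSet:
    """Drop streamlines by turning angle.

    Default rule: retain a streamline iff every turning angle between
    consecutive segments is <= ``max_turning_angle``.  The literal rule
    (``literal_angle_rule=True``) instead discards a streamline whenever any
    of its turning angles falls below the threshold.
    """
    if not 0 < max_turning_angle < 180:
        raise ConfigurationError("max_turning_angle must be in (0, 180)")
    kept = []
    for s in streamlines:
        angles = turning_angles(s.points)
        if angles.size == 0:
            retain = True  # 2-point line has no turning angle
        elif literal_angle_rule:
            retain = bool(np.all(angles >= max_turning_angle))
        else:
            retain = bool(np.all(angles <= max_turning_angle))
        if retain:
            kept.append(s)
    return StreamlineSet(tuple(kept))


def streamline_mean_fa(streamline: Streamline) -> float:
    """Arithmetic mean of the FA samples along one streamline."""
    if streamline.fa is None:
        raise InvalidInputError("streamline carries no FA samples")
    return float(np.mean(streamline.fa))


def build_connectivity_matrix(
    mesh: CorticalMesh, streamlines: StreamlineSet, snap_radius: float = 2.0
) -> ConnectivityMatrix:
    """Snap streamline endpoints to nearest mesh vertices and count pairs.

    Streamlines whose endpoints both snap to the same vertex (self loops) or
    with any endpoint farther than ``snap_radius`` from every vertex are
    dropped; both events are tallied on the returned object.
    """
    if snap_radius <= 0:
        raise ConfigurationError("snap_radius must be positive")
    n = mesh.n_vertices
    if len(streamlines) == 0:
        return ConnectivityMatrix(
            sp.csr_matrix((n, n), dtype=int),
            np.zeros((0, 2), dtype=int),
            np.zeros(0, dtype=int),
        )
    tree = cKDTree(mesh.vertices)
    ends = np.array([[s.points[0], s.points[-1]] for s in streamlines])
    dists, idx = tree.query(ends.reshape(-1, 3))
    dists = dists.reshape(-1, 2)
    idx = idx.reshape(-1, 2)
    mapped = np.all(dists <= snap_radius, axis=1)
    loops = mapped & (idx[:, 0] == idx[:, 1])
    keep = mapped & ~loops
    pairs = idx[keep]
    kept_indices = np.where(keep)[0]
    if pairs.shape[0]:
        data = np.ones(pairs.shape[0], dtype=int)
        m = sp.coo_matrix(
            (np.concatenate([data, data]),
             (np.concatenate([pairs[:, 0], pairs[:, 1]]),
              np.concatenate([pairs[:, 1], pairs[:, 0]]))),
            shape=(n, n),
        ).tocsr()
    else:
        m = sp.csr_matrix((n, n), dtype=int)
    return ConnectivityMatrix(
        m,
        pairs,
        kept_indices,
        n_unmapped=int(np.sum(~mapped)),
        n_self_loops=int(np.sum(loops)),
    )


def geodesic_neighborhood(
    mesh: CorticalMesh, vertex: int, radius: float = 5.0
) -> np.ndarray:
    """Vertices within graph-geodesic distance ``radius`` of ``vertex``.

    Distances are shortest paths along mesh edges with Euclidean weights.
    The seed vertex is always a member.
    """
    if radius <= 0:
        raise ConfigurationError("radius must be positive")
    if not 0 <= vertex < mesh.n_vertices:
        raise InvalidInputError(f"vertex {vertex} out of range")
    d = mesh.geodesic_distances(indices=[vertex], limit=radius)[0]
    return np.where(np.isfinite(d))[0]


def compute_vertex_metrics(
    mesh: CorticalMesh,
    matrix: ConnectivityMatrix,
    fa_per_streamline: np.ndarray | Sequence[float],
    radius: float = 5.0,
    denominator: str = "streamlines",
) -> VertexMetrics:
    """Connectivity density and mean FA at every vertex.

    For a vertex v with geodesic neighborhood N(v):
    CD(v) = #{streamlines with exactly one endpoint in N(v)}
            / area(N(v)) / total connection count.
    mean_fa(v) = mean FA over streamlines with at least one endpoint in N(v),
    zero (and flagged) when there are none.

    ``denominator`` selects the total-connection normalizer: retained
    streamline count (default) or the number of distinct connected vertex
    pairs (``"entries"``).
    """
    if denominator not in ("streamlines", "entries"):
        raise ConfigurationError("denominator must be 'streamlines' or 'entries'")
    fa = np.asarray(fa_per_streamline, dtype=float)
    if fa.shape[0] != matrix.n_connections:
        raise InvalidInputError("fa_per_streamline must align with retained pairs")
    n = mesh.n_vertices
    cd = np.zeros(n)
    mean_fa = np.zeros(n)
    empty = np.ones(n, dtype=bool)
    total = (
        matrix.n_connections
        if denominator == "streamlines"
        else matrix.n_nonzero_pairs
    )
    if total == 0:
        warnings.warn("no connections; CD map is identically zero", stacklevel=2)
        return VertexMetrics(cd, mean_fa, empty)
    dist = mesh.geodesic_distances(limit=radius)
    areas = mesh.vertex_areas
    pairs = matrix.pairs
    for v in range(n):
        member = np.isfinite(dist[v])
        in0 = member[pairs[:, 0]]
        in1 = member[pairs[:, 1]]
        crossing = int(np.sum(in0 ^ in1))
        touching = in0 | in1
        nbhd_area = float(areas[member].sum())
        cd[v] = crossing / nbhd_area / total
        if np.any(touching):
            mean_fa[v] = float(fa[touching].mean())
            empty[v] = False
    return VertexMetrics(cd, mean_fa, empty)


def smooth_vertex_map(
    mesh: CorticalMesh, values: np.ndarray, fwhm: float = 5.0
) -> np.ndarray:
    """Normalized geodesic Gaussian smoothing of a per-vertex map.

    sigma = fwhm / (2 sqrt(2 ln 2)); the kernel support is truncated at
    3 sigma, so FWHM below the minimum edge length returns the input.
    """
    if fwhm <= 0:
        raise ConfigurationError("fwhm must be positive")
    values = np.asarray(values, dtype=float)
    if values.shape != (mesh.n_vertices,):
        raise InvalidInputError("one value per vertex required")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    dist = mesh.geodesic_distances(limit=3.0 * sigma)
    with np.errstate(invalid="ignore"):
        w = np.where(np.isfinite(dist), np.exp(-(dist**2) / (2.0 * sigma**2)), 0.0)
    return (w @ values) / w.sum(axis=1)


def aggregate_to_parcels(
    mesh: CorticalMesh,
    values: np.ndarray,
    parcellation: np.ndarray | pd.Series,
) -> pd.Series:
    """Area-weighted mean of a vertex map within each parcel."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(parcellation)
    if values.shape != (mesh.n_vertices,) or labels.shape != (mesh.n_vertices,):
        raise InvalidInputError("values and parcellation must cover all vertices")
    bad = np.where(pd.isna(labels) | (labels.astype(float) < 0))[0]
    if bad.size:
        raise InvalidInputError(f"unlabeled vertices: {bad.tolist()}")
    labels = labels.astype(int)
    w = mesh.vertex_areas
    df = pd.DataFrame({"parcel": labels, "wv": w * values, "w": w})
    g = df.groupby("parcel").sum()
    out = g["wv"] / g["w"]
    out.name = "value"
    return out
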