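"""Synthetic case-control cohorts, regional feature tables, and toy geometry.

The generators provide every input the downstream analysis needs: a covariate
table with a four-cell diagnosis-by-sex design, a subjects x (region, measure)
feature matrix with configurable group / sex / interaction / age / site / head
size effects under additive Gaussian noise, and small analytic sphere meshes
with straight-line streamlines for the connectivity stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import as_rng
from .connectivity import CorticalMesh, Streamline, StreamlineSet
from .exceptions import ConfigurationError

__all__ = [
    "MEASURES",
    "DIAGNOSES",
    "SEXES",
    "EffectSpec",
    "generate_cohort",
    "generate_feature_table",
    "feature_columns",
    "generate_toy_brain",
]

MEASURES: tuple[str, ...] = ("thickness", "area", "volume", "curvature", "CD")
#: measures that scale with head size and are divided by TICV downstream
TICV_SCALED_MEASURES: tuple[str, ...] = ("area", "volume")
DIAGNOSES: tuple[str, str] = ("ASD", "TD")
SEXES: tuple[str, str] = ("M", "F")
#: four-cell design order used throughout: (diagnosis, sex)
CELLS: tuple[tuple[str, str], ...] = (
    ("ASD", "M"),
    ("ASD", "F"),
    ("TD", "M"),
    ("TD", "F"),
)


@dataclass(frozen=True)
class EffectSpec:
    """Linear-additive effect structure for synthetic feature tables.

    With all coefficients zero this is the null configuration: i.i.d.
    Gaussian features with no group structure.  ``baseline`` and ``noise_sd``
    may be scalars or per-feature arrays of length ``n_regions * 5``.
    """

    baseline: float | np.ndarray = 2.5
    noise_sd: float | np.ndarray = 1.0
    beta_dx: float = 0.0
    beta_sex: float = 0.0
    beta_int: float = 0.0
    beta_age: float = 0.0
    site_offsets: tuple[float, ...] | None = None
    affected_fraction: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.noise_sd) <= 0):
            raise ConfigurationError("noise_sd must be strictly positive")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ConfigurationError("affected_fraction must lie in [0, 1]")

    @property
    def is_null(self) -> bool:
        return (
            self.beta_dx == self.beta_sex == self.beta_int == self.beta_age == 0.0
            and not any(self.site_offsets or ())
        )


def generate_cohort(
    n_per_cell: tuple[int, int, int, int],
    n_sites: int = 1,
    age_range: tuple[float, float] = (8.0, 18.0),
    seed: int = 0,
    ticv_mean: float = 1.5e6,
    ticv_sd: float = 1.5e5,
) -> pd.DataFrame:
    """Build a covariate table for a four-cell diagnosis-by-sex design.

    ``n_per_cell`` gives the counts for (ASD-M, ASD-F, TD-M, TD-F).  Ages are
    uniform over ``age_range``, sites are assigned uniformly at random, and
    TICV is drawn from a truncated normal kept strictly positive.
    """
    if len(n_per_cell) != 4 or any(int(c) < 1 for c in n_per_cell):
        raise ConfigurationError("all four cell counts must be >= 1")
    if n_sites < 1:
        raise ConfigurationError("n_sites must be >= 1")
    lo, hi = age_range
    if not (0 < lo < hi):
        raise ConfigurationError("age_range must be a positive non-empty interval")
    if ticv_mean <= 0 or ticv_sd <= 0:
        raise ConfigurationError("ticv_mean and ticv_sd must be positive")
    rng = as_rng(seed)
    diagnosis, sex = [], []
    for (dx, sx), count in zip(CELLS, n_per_cell):
        diagnosis += [dx] * int(count)
        sex += [sx] * int(count)
    n = len(diagnosis)
    ticv = rng.normal(ticv_mean, ticv_sd, size=n)
    # resample the rare non-positive draws so the invariant ticv > 0 holds
    while np.any(ticv <= 0):
        bad = ticv <= 0
        ticv[bad] = rng.normal(ticv_mean, ticv_sd, size=int(bad.sum()))
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "diagnosis": pd.Categorical(diagnosis, categories=list(DIAGNOSES)),
            "sex": pd.Categorical(sex, categories=list(SEXES)),
            "age": rng.uniform(lo, hi, size=n),
            "site": rng.integers(1, n_sites + 1, size=n),
            "ticv": ticv,
        }
    ).set_index("subject_id")


def feature_columns(n_regions: int) -> list[str]:
    """Column names ``<region>__<measure>``, measure varying fastest."""
    return [
        f"region{r + 1:03d}__{m}" for r in range(n_regions) for m in MEASURES
    ]


def generate_feature_table(
    cohort: pd.DataFrame,
    spec: EffectSpec = EffectSpec(),
    n_regions: int = 165,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the subjects x (region, measure) feature matrix.

    Each cell is baseline + beta_dx*1[ASD] + beta_sex*1[F] +
    beta_int*1[ASD]*1[F] + beta_age*age + site offset + Gaussian noise, with
    group effects restricted to a random ``affected_fraction`` of features.
    Area and volume columns are then scaled by ticv / mean(ticv) so the TICV
    normalization stage has real work to do.
    """
    if n_regions < 1:
        raise ConfigurationError("n_regions must be >= 1")
    n_features = n_regions * len(MEASURES)
    for name, value in (("baseline", spec.baseline), ("noise_sd", spec.noise_sd)):
        arr = np.asarray(value, dtype=float)
        if arr.ndim > 0 and arr.shape != (n_features,):
            raise ConfigurationError(f"{name} length must equal n_regions * 5")
    baseline = np.broadcast_to(np.asarray(spec.baseline, float), (n_features,))
    noise_sd = np.broadcast_to(np.asarray(spec.noise_sd, float), (n_features,))
    rng = as_rng(seed)
    n = len(cohort)
    n_affected = int(round(spec.affected_fraction * n_features))
    affected = np.zeros(n_features, dtype=bool)
    affected[rng.choice(n_features, size=n_affected, replace=False)] = True

    is_asd = (cohort["diagnosis"].to_numpy() == "ASD").astype(float)
    is_f = (cohort["sex"].to_numpy() == "F").astype(float)
    age = cohort["age"].to_numpy(dtype=float)
    site = cohort["site"].to_numpy(dtype=int)

    x = baseline[None, :] + rng.normal(0.0, 1.0, size=(n, n_features)) * noise_sd
    group_effect = (
        spec.beta_dx * is_asd + spec.beta_sex * is_f + spec.beta_int * is_asd * is_f
    )
    x[:, affected] += group_effect[:, None]
    x += spec.beta_age * age[:, None]
    if spec.site_offsets is not None:
        offsets = np.asarray(spec.site_offsets, dtype=float)
        if site.max() > len(offsets):
            raise ConfigurationError("site_offsets shorter than the number of sites")
        x += offsets[site - 1][:, None]

    cols = feature_columns(n_regions)
    scaled = np.array(
        [c.split("__")[1] in TICV_SCALED_MEASURES for c in cols]
    )
    ticv = cohort["ticv"].to_numpy(dtype=float)
    x[:, scaled] *= (ticv / ticv.mean())[:, None]
    return pd.DataFrame(x, index=cohort.index, columns=cols)


def _icosphere(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere via recursive edge subdivision of an icosahedron."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    for _ in range(subdivisions):
        vlist = list(verts)
        midpoint: dict[tuple[int, int], int] = {}

        def mid(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in midpoint:
                p = vlist[i] + vlist[j]
                vlist.append(p / np.linalg.norm(p))
                midpoint[key] = len(vlist) - 1
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=int)
    return verts, faces


def generate_toy_brain(
    n_vertices: int,
    n_streamlines: int,
    seed: int = 0,
    radius: float = 10.0,
    n_parcels: int = 8,
    points_per_streamline: int = 10,
    fa_range: tuple[float, float] = (0.2, 0.8),
) -> tuple[CorticalMesh, StreamlineSet, np.ndarray]:
    """Tessellated sphere, straight streamlines between vertices, parcels.

    The mesh is the smallest icosphere with at least ``n_vertices`` vertices,
    scaled to ``radius`` mm.  Streamlines are straight polylines joining two
    distinct random vertices (endpoints exactly on vertices) carrying a
    constant-plus-jitter FA profile in [0, 1].  The parcellation partitions
    vertices into ``n_parcels`` longitudinal sectors by azimuth.
    """
    if n_vertices < 4:
        raise ConfigurationError("n_vertices must be >= 4 (tetrahedron minimum)")
    if n_streamlines < 0:
        raise ConfigurationError("n_streamlines must be >= 0")
    if radius <= 0 or n_parcels < 1:
        raise ConfigurationError("radius must be positive and n_parcels >= 1")
    rng = as_rng(seed)
    sub = 0
    while 10 * 4**sub + 2 < n_vertices:
        sub += 1
    verts, faces = _icosphere(sub)
    mesh = CorticalMesh(verts * radius, faces)

    streamlines = []
    for _ in range(n_streamlines):
        i, j = rng.choice(mesh.n_vertices, size=2, replace=False)
        t = np.linspace(0.0, 1.0, points_per_streamline)
        pts = (1 - t)[:, None] * mesh.vertices[i] + t[:, None] * mesh.vertices[j]
        base = rng.uniform(*fa_range)
        fa = np.clip(base + rng.normal(0, 0.02, size=points_per_streamline), 0, 1)
        streamlines.append(Streamline(pts, fa))

    azimuth = np.mod(np.arctan2(verts[:, 1], verts[:, 0]), 2 * np.pi)
    parcels = np.minimum(
        (azimuth / (2 * np.pi) * n_parcels).astype(int), n_parcels - 1
    )
    return mesh, StreamlineSet(tuple(streamlines)), parcels
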