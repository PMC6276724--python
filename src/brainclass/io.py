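"""Plain-text readers and writers for the pipeline's exchange formats.

Tables travel as TSV with a one-line header, meshes as Wavefront OBJ,
streamlines as a documented long-format TSV (one row per polyline point:
streamline_id, point_index, x, y, z, fa), parcellations as a two-column TSV,
and trained SVM models as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import CorticalMesh, Streamline, StreamlineSet
from .exceptions import InvalidInputError
from .svm import KernelSpec, SVMModel

__all__ = [
    "write_cohort", "read_cohort",
    "write_features", "read_features",
    "write_obj", "read_obj",
    "write_streamlines_tsv", "read_streamlines_tsv",
    "write_parcellation", "read_parcellation",
    "write_svm_model", "read_svm_model",
]


def write_cohort(cohort: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    _write_tsv(cohort.reset_index(), path, header)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["diagnosis"] = pd.Categorical(df["diagnosis"], categories=["ASD", "TD"])
    df["sex"] = pd.Categorical(df["sex"], categories=["M", "F"])
    return df.set_index("subject_id")


def write_features(table: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    _write_tsv(table.reset_index(), path, header)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#").set_index("subject_id")


def _write_tsv(df: pd.DataFrame, path: str | Path, header: str | None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def write_obj(mesh: CorticalMesh, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.12g} {v[1]:.12g} {v[2]:.12g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def read_obj(path: str | Path) -> CorticalMesh:
    verts, faces = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(p) for p in parts[1:4]])
        elif parts[0] == "f":
            # keep only the vertex index of each face token (OBJ allows v/vt/vn)
            faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    if not verts:
        raise InvalidInputError(f"no vertices found in {path}")
    return CorticalMesh(np.array(verts), np.array(faces, dtype=int))


def write_streamlines_tsv(streamlines: StreamlineSet, path: str | Path) -> None:
    rows = []
    for sid, s in enumerate(streamlines):
        fa = s.fa if s.fa is not None else np.full(s.n_points, np.nan)
        for pid, (pt, f) in enumerate(zip(s.points, fa)):
            rows.append((sid, pid, pt[0], pt[1], pt[2], f))
    df = pd.DataFrame(
        rows, columns=["streamline_id", "point_index", "x", "y", "z", "fa"]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_streamlines_tsv(path: str | Path) -> StreamlineSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, g in df.groupby("streamline_id", sort=True):
        g = g.sort_values("point_index")
        fa = g["fa"].to_numpy(dtype=float)
        out.append(
            Streamline(
                g[["x", "y", "z"]].to_numpy(dtype=float),
                None if np.isnan(fa).all() else fa,
            )
        )
    return StreamlineSet(tuple(out))


def write_parcellation(parcels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"vertex_id": np.arange(len(parcels)), "parcel_id": parcels}
    ).to_csv(path, sep="\t", index=False)


def read_parcellation(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", comment="#").sort_values("vertex_id")
    return df["parcel_id"].to_numpy(dtype=int)


def write_svm_model(model: SVMModel, path: str | Path) -> None:
    payload = {
        "kernel": {
            "kind": model.kernel.kind,
            "sigma": model.kernel.sigma,
            "degree": model.kernel.degree,
            "offset": model.kernel.offset,
        },
        "support_vectors": model.support_vectors.tolist(),
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "first_label": model.first_label,
        "second_label": model.second_label,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_svm_model(path: str | Path) -> SVMModel:
    payload = json.loads(Path(path).read_text())
    return SVMModel(
        support_vectors=np.array(payload["support_vectors"], dtype=float).reshape(
            len(payload["weights"]), -1
        ),
        weights=np.array(payload["weights"], dtype=float),
        bias=float(payload["bias"]),
        kernel=KernelSpec(**payload["kernel"]),
        first_label=payload["first_label"],
        second_label=payload["second_label"],
    )
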