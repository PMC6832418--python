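"""Point-cloud and feature-table I/O.

Supported cloud formats:

* plain XYZ text — one point per line, ``x y z [label]``, whitespace or
  comma separated, ``#`` comments skipped;
* PLY — a single ``vertex`` element with ``x, y, z`` float properties and
  an optional integer ``label`` property, in the ascii or
  binary_little_endian dialects.

Feature matrices travel as CSV with header ``X,Y,Z,L1,PL1,SPH1,HOR1,
PERCZ1,L2,...`` so they can be inspected or re-joined to the cloud with
ordinary tools.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import PointCloud


class PointCloudFormatError(ValueError):
    """Raised when a cloud file cannot be parsed."""


# ---------------------------------------------------------------------------
# XYZ text
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path, has_label: bool = False) -> PointCloud:
    """Read a plain-text XYZ cloud.

    Each non-comment line must have at least 3 numeric fields (4 with
    ``has_label``); extra fields are ignored.  Point order is preserved.
    """
    path = Path(path)
    coords: list[tuple[float, float, float]] = []
    labels: list[int] = []
    n_fields = 4 if has_label else 3
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = re.split(r"[,\s]+", line)
            if len(fields) < n_fields:
                raise PointCloudFormatError(
                    f"{path}:{lineno}: expected at least {n_fields} fields, "
                    f"got {len(fields)}: {raw.rstrip()!r}"
                )
            try:
                x, y, z = (float(v) for v in fields[:3])
                if has_label:
                    labels.append(int(float(fields[3])))
            except ValueError as exc:
                raise PointCloudFormatError(
                    f"{path}:{lineno}: non-numeric field in {raw.rstrip()!r}"
                ) from exc
            coords.append((x, y, z))
    if not coords:
        raise PointCloudFormatError(f"{path}: no points found")
    return PointCloud(
        np.asarray(coords, dtype=np.float64),
        np.asarray(labels, dtype=np.int64) if has_label else None,
    )


def write_xyz(cloud: PointCloud, path: str | Path, fmt: str = "%.6f") -> None:
    """Write a cloud as plain XYZ text (label appended when present)."""
    path = Path(path)
    with open(path, "w") as fh:
        for i in range(len(cloud)):
            line = " ".join(fmt % v for v in cloud.coords[i])
            if cloud.labels is not None:
                line += f" {cloud.labels[i]}"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}

_LABEL_PROPERTY_NAMES = ("label", "scalar_label", "class", "classification")


def read_ply(path: str | Path) -> PointCloud:
    """Read a PLY cloud (ascii or binary_little_endian vertex element)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise PointCloudFormatError(f"{path}: not a PLY file")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        while True:
            line = fh.readline()
            if not line:
                raise PointCloudFormatError(f"{path}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if tokens[1] == "list":
                    raise PointCloudFormatError(
                        f"{path}: list properties are not supported"
                    )
                elements[-1][2].append((tokens[2], _PLY_DTYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise PointCloudFormatError(f"{path}: unsupported PLY format {fmt!r}")

        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise PointCloudFormatError(f"{path}: no vertex element")
        _, count, props = vertex
        names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise PointCloudFormatError(
                    f"{path}: vertex element lacks required property {axis!r}"
                )
        if elements.index(vertex) != 0:
            raise PointCloudFormatError(
                f"{path}: vertex must be the first element"
            )

        dtype = np.dtype([(name, "<" + kind) for name, kind in props])
        if fmt == "binary_little_endian":
            data = np.fromfile(fh, dtype=dtype, count=count)
        else:
            rows = []
            while len(rows) < count:
                line = fh.readline()
                if not line:
                    break
                if line.strip():
                    rows.append(tuple(line.split()[: len(props)]))
            data = np.array(rows, dtype=dtype)
        if len(data) != count:
            raise PointCloudFormatError(
                f"{path}: expected {count} vertices, read {len(data)}"
            )

    coords = np.column_stack(
        [data["x"], data["y"], data["z"]]
    ).astype(np.float64)
    labels = None
    for cand in _LABEL_PROPERTY_NAMES:
        if cand in names:
            labels = data[cand].astype(np.int64)
            break
    return PointCloud(coords, labels)


def write_ply(
    cloud: PointCloud, path: str | Path, binary: bool = False
) -> None:
    """Write a cloud as PLY (double-precision coords, int32 label).

    ``binary`` selects binary_little_endian; the default is ascii.
    """
    path = Path(path)
    props = [("x", "f8"), ("y", "f8"), ("z", "f8")]
    if cloud.labels is not None:
        props.append(("label", "i4"))
    dtype = np.dtype([(n, "<" + k) for n, k in props])
    data = np.empty(len(cloud), dtype=dtype)
    data["x"], data["y"], data["z"] = cloud.coords.T
    if cloud.labels is not None:
        data["label"] = cloud.labels

    ply_types = {"f8": "double", "i4": "int"}
    header = ["ply"]
    header.append(
        "format binary_little_endian 1.0" if binary else "format ascii 1.0"
    )
    header.append(f"element vertex {len(cloud)}")
    header += [f"property {ply_types[k]} {n}" for n, k in props]
    header.append("end_header")

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            data.tofile(fh)
        else:
            for row in data:
                vals = [repr(float(row[n])) for n, k in props if k == "f8"]
                if cloud.labels is not None:
                    vals.append(str(int(row["label"])))
                fh.write((" ".join(vals) + "\n").encode("ascii"))


# ---------------------------------------------------------------------------
# Feature CSV
# ---------------------------------------------------------------------------

def write_features_csv(
    cloud: PointCloud,
    features: pd.DataFrame,
    path: str | Path,
    include_label: bool = True,
) -> None:
    """Write coordinates + feature columns (+ label when present) as CSV."""
    out = pd.DataFrame(cloud.coords, columns=["X", "Y", "Z"])
    out = pd.concat([out, features.reset_index(drop=True)], axis=1)
    if include_label and cloud.labels is not None:
        out["label"] = cloud.labels
    out.to_csv(path, index=False)


def read_features_csv(path: str | Path) -> tuple[PointCloud, pd.DataFrame]:
    """Read a feature CSV back into a (cloud, feature-table) pair."""
    table = pd.read_csv(path)
    for col in ("X", "Y", "Z"):
        if col not in table.columns:
            raise PointCloudFormatError(f"{path}: missing coordinate column {col}")
    labels = (
        table["label"].to_numpy(dtype=np.int64) if "label" in table else None
    )
    cloud = PointCloud(table[["X", "Y", "Z"]].to_numpy(), labels)
    feature_cols = [
        c for c in table.columns if c not in ("X", "Y", "Z", "label")
    ]
    return cloud, table[feature_cols]
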