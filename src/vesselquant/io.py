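"""File I/O: skeleton point lists (CSV, VTK legacy polydata), binary
volumes (MetaImage .mha via SimpleITK), and surface meshes (STL via
trimesh, VTK legacy POLYGONS via the built-in parser).

Coordinates are physical mm throughout. Volumes are returned indexed
[x, y, z] (x-fastest axis order) with their spacing and origin, matching
how the rest of the package addresses them.
"""

from __future__ import annotations

import os
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import MalformedInputError, UnsupportedFormatError
from .model import SkeletonPointSet, validate_point_set

# ---------------------------------------------------------------------------
# CSV point lists: columns x,y,z[,r], header optional
# ---------------------------------------------------------------------------


def read_points_csv(path) -> SkeletonPointSet:
    """Read one branch from a CSV with columns x,y,z and optional r (mm)."""
    import pandas as pd

    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error wrapping
        raise MalformedInputError(f"cannot parse {path}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if not {"x", "y", "z"}.issubset(cols):
        # headerless file: try again with positional columns
        df = pd.read_csv(path, header=None)
        if df.shape[1] < 3:
            raise MalformedInputError(
                f"malformed row in {path}: need at least x,y,z columns")
        names = ["x", "y", "z", "r"][: df.shape[1]]
        df.columns = names + list(df.columns[len(names):])
    for col in ("x", "y", "z"):
        if df[col].isna().any():
            row = int(df[col].isna().idxmax()) + 1
            raise MalformedInputError(f"malformed row {row} in {path}")
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    radii = df["r"].to_numpy(dtype=float) if "r" in df.columns else None
    return validate_point_set(pts, radii)


def write_points_csv(point_set: SkeletonPointSet, path) -> None:
    import pandas as pd

    data = {"x": point_set.points[:, 0], "y": point_set.points[:, 1],
            "z": point_set.points[:, 2]}
    if point_set.radii is not None:
        data["r"] = point_set.radii
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# VTK legacy ASCII polydata: POINTS + LINES (polylines) or POLYGONS (meshes)
# ---------------------------------------------------------------------------


def _tokens(lines: List[str]):
    for ln in lines:
        for tok in ln.split():
            yield tok


def read_polydata_vtk(path) -> Tuple[np.ndarray, List[List[int]],
                                     List[List[int]]]:
    """Parse a VTK legacy ASCII polydata file.

    Returns (points, polylines, polygons): the (n, 3) point array, the LINES
    records as lists of point ids, and the POLYGONS records likewise.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 4 or not lines[0].startswith("# vtk DataFile"):
        raise UnsupportedFormatError(f"{path} is not a VTK legacy file")
    if lines[2].strip().upper() != "ASCII":
        raise UnsupportedFormatError("only ASCII VTK legacy files supported")
    body = lines[3:]
    points = None
    polylines: List[List[int]] = []
    polygons: List[List[int]] = []
    i = 0
    while i < len(body):
        parts = body[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n = int(parts[1])
            vals = []
            i += 1
            while len(vals) < 3 * n and i < len(body):
                vals.extend(float(v) for v in body[i].split())
                i += 1
            if len(vals) < 3 * n:
                raise MalformedInputError(f"POINTS truncated in {path}")
            points = np.asarray(vals[:3 * n], dtype=float).reshape(n, 3)
        elif key in ("LINES", "POLYGONS"):
            n_cells = int(parts[1])
            n_ints = int(parts[2])
            vals = []
            i += 1
            while len(vals) < n_ints and i < len(body):
                vals.extend(int(v) for v in body[i].split())
                i += 1
            if len(vals) < n_ints:
                raise MalformedInputError(f"{key} truncated in {path}")
            cells = []
            pos = 0
            for _ in range(n_cells):
                cnt = vals[pos]
                cells.append(vals[pos + 1: pos + 1 + cnt])
                pos += cnt + 1
            (polylines if key == "LINES" else polygons).extend(cells)
        else:
            i += 1
            continue
    if points is None:
        raise MalformedInputError(f"no POINTS section in {path}")
    return points, polylines, polygons


def write_polylines_vtk(points: np.ndarray,
                        polylines: Sequence[Sequence[int]], path) -> None:
    """Write polylines as VTK legacy ASCII polydata (POINTS + LINES)."""
    points = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("vesselquant skeleton polylines\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for q in points:
            fh.write(f"{q[0]:.9g} {q[1]:.9g} {q[2]:.9g}\n")
        n_ints = sum(len(pl) + 1 for pl in polylines)
        fh.write(f"LINES {len(polylines)} {n_ints}\n")
        for pl in polylines:
            fh.write(" ".join([str(len(pl))] + [str(int(i)) for i in pl]))
            fh.write("\n")


def read_points(path, fmt: Optional[str] = None):
    """Read skeleton point set(s) from CSV or VTK legacy polydata.

    CSV returns a single :class:`SkeletonPointSet`. VTK returns
    ``(point_sets, points, edges)``: one point set per polyline plus the raw
    point array and edge list for ``topology.build_graph(mode='edges')``.
    """
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower()
        fmt = {"csv": "csv", ".csv": "csv", ".vtk": "vtk"}.get(ext)
    if fmt == "csv":
        return read_points_csv(path)
    if fmt == "vtk":
        points, polylines, _ = read_polydata_vtk(path)
        sets = [validate_point_set(points[pl]) for pl in polylines
                if len(pl) >= 2]
        edges = [(pl[i], pl[i + 1]) for pl in polylines
                 for i in range(len(pl) - 1)]
        return sets, points, edges
    raise UnsupportedFormatError(f"unsupported format for {path}")


# ---------------------------------------------------------------------------
# MetaImage volumes via SimpleITK
# ---------------------------------------------------------------------------


def read_volume(path) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a MetaImage (.mha/.mhd) volume.

    Returns ``(array, spacing, origin)`` with the array indexed [x, y, z]
    and spacing/origin in mm (per-axis, same order).
    """
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        msg = str(exc)
        if "File cannot be read" in msg or "does not exist" in msg:
            raise MalformedInputError(f"payload not found: {msg}") from exc
        raise UnsupportedFormatError(msg) from exc
    arr = sitk.GetArrayFromImage(img)  # indexed [z, y, x]
    arr = np.ascontiguousarray(arr.transpose(2, 1, 0))  # -> [x, y, z]
    return arr, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin())


def write_volume(array: np.ndarray, spacing, origin, path,
                 compress: bool = False) -> None:
    """Write an [x, y, z]-indexed array as MetaImage with physical
    spacing/origin."""
    import SimpleITK as sitk

    arr = np.ascontiguousarray(
        np.asarray(array).astype(np.uint8).transpose(2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path), useCompression=compress)


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------


def read_mesh(path):
    """Read a triangle mesh from STL (via trimesh) or VTK legacy POLYGONS.

    Returns a ``trimesh.Trimesh``.
    """
    import trimesh

    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".stl":
        return trimesh.load(str(path), file_type="stl", process=False)
    if ext == ".vtk":
        points, _, polygons = read_polydata_vtk(path)
        if not polygons:
            raise MalformedInputError(f"no POLYGONS in {path}")
        if any(len(c) != 3 for c in polygons):
            raise MalformedInputError("unsupported cell type: "
                                      "non-triangular POLYGONS")
        return trimesh.Trimesh(vertices=points,
                               faces=np.asarray(polygons), process=False)
    raise UnsupportedFormatError(f"unsupported mesh format {ext!r}")
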