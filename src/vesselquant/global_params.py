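"""Global vessel descriptors from segmentation products.

Surface area is the total area of the triangular facets of the segmentation
mesh; volume is the voxel-counting volume of the binary segmentation
(foreground count times the physical voxel volume). Both are literal
discrete definitions — no surface smoothing or partial-volume correction —
so they are exactly reproducible from the segmentation products alone.
"""

from __future__ import annotations

import numpy as np

from .errors import MalformedInputError


def surface_area(mesh) -> float:
    """Total area of all triangular facets, in mm².

    ``mesh`` is a ``trimesh.Trimesh`` or a ``(vertices, faces)`` pair with
    faces of length 3. Degenerate (zero-area) triangles contribute 0.
    """
    if hasattr(mesh, "vertices") and hasattr(mesh, "faces"):
        vertices = np.asarray(mesh.vertices, dtype=float)
        faces = np.asarray(mesh.faces)
    else:
        vertices, faces = mesh
        vertices = np.asarray(vertices, dtype=float)
        faces = np.asarray(faces)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MalformedInputError("unsupported cell type: faces must be "
                                  "triangles")
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    cross = np.cross(b - a, c - a)
    return float(0.5 * np.sum(np.linalg.norm(cross, axis=1)))


def voxel_volume(volume: np.ndarray, spacing, threshold=None) -> float:
    """Voxel-counting volume: foreground voxels x (sx * sy * sz), in mm³.

    ``volume`` must be binary (two distinct values at most) unless a
    ``threshold`` is given, in which case voxels > threshold count as
    foreground.
    """
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError("spacing must be a positive 3-vector")
    vol = np.asarray(volume)
    if threshold is not None:
        fg = vol > threshold
    else:
        values = np.unique(vol)
        if len(values) > 2:
            raise MalformedInputError(
                "labels not binary: pass threshold= to binarize")
        fg = vol != values.min() if len(values) == 2 else vol != 0
    return float(np.count_nonzero(fg)) * float(np.prod(spacing))
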