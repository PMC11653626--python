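"""Registration-adjacent voxel utilities.

The registration algorithm itself (diffeomorphic Demons / SyN) is consumed,
not implemented: this module evaluates registration quality (Dice score,
mean contour distance), interpolates voxel displacement fields to mesh
nodes, and selects the dilation phases from a lumen volume curve.

Grid convention: world coordinates in mm, voxel centers at
origin + index * spacing with zero-based indices.  Nodes exactly on the
last lattice plane are accepted (closed upper bound).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


@dataclass
class VoxelMask:
    """Binary voxel mask with grid metadata."""

    data: np.ndarray           # (nx, ny, nz) bool
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("mask must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be strictly positive")


@dataclass
class VoxelDisplacementField:
    """Per-voxel 3-component displacement (mm) with grid metadata."""

    data: np.ndarray           # (nx, ny, nz, 3)
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise ValueError("field must be (nx, ny, nz, 3)")
        if not np.isfinite(self.data).all():
            raise ValueError("displacement field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be strictly positive")


@dataclass
class VolumeCurve:
    """Per-phase lumen volume over one cardiac cycle (cyclic phase index)."""

    volumes_mm3: np.ndarray

    def __post_init__(self) -> None:
        self.volumes_mm3 = np.asarray(self.volumes_mm3, dtype=float)
        if self.volumes_mm3.ndim != 1:
            raise ValueError("volumes must be 1D")
        if (self.volumes_mm3 <= 0).any():
            raise ValueError("all volumes must be > 0")

    @property
    def n_phases(self) -> int:
        return self.volumes_mm3.size


def _check_same_grid(a, b) -> None:
    if a.data.shape[:3] != b.data.shape[:3] or a.spacing != b.spacing \
            or a.origin != b.origin:
        raise ValueError("grids differ (shape/spacing/origin)")


def dice_score(a: VoxelMask, b: VoxelMask) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); 1 for identical non-empty masks."""
    _check_same_grid(a, b)
    na, nb = int(a.data.sum()), int(b.data.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def _boundary_points(mask: VoxelMask) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask.data)
    surf = mask.data & ~eroded
    idx = np.argwhere(surf)
    return np.asarray(mask.origin) + idx * np.asarray(mask.spacing)


def mean_contour_distance(a: VoxelMask, b: VoxelMask) -> float:
    """Symmetric mean nearest-surface distance between mask boundaries (mm)."""
    _check_same_grid(a, b)
    pa, pb = _boundary_points(a), _boundary_points(b)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("mean contour distance undefined for empty mask")
    dab = cKDTree(pb).query(pa)[0]
    dba = cKDTree(pa).query(pb)[0]
    return 0.5 * (float(dab.mean()) + float(dba.mean()))


# ---------------------------------------------------------------------------
# trilinear interpolation of displacement to nodes
# ---------------------------------------------------------------------------

def interpolate_node_displacement(field: VoxelDisplacementField,
                                  nodes: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the voxel displacement field at nodes.

    The displacement at a point is blended from the 8 enclosing lattice
    corners with weights (1-x_d) or x_d per axis, where x_d is the
    fractional position inside the voxel cell; the deformed position is
    node + displacement.  Points outside the lattice raise with their
    coordinates.
    """
    pts = np.atleast_2d(np.asarray(nodes, dtype=float))
    spacing = np.asarray(field.spacing)
    origin = np.asarray(field.origin)
    shape = np.asarray(field.data.shape[:3])
    rel = (pts - origin) / spacing
    eps = 1e-9
    bad = np.any((rel < -eps) | (rel > (shape - 1) + eps), axis=1)
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"node {pts[i]} lies outside the displacement grid")
    rel = np.clip(rel, 0.0, shape - 1)
    i0 = np.minimum(rel.astype(int), shape - 2)
    frac = rel - i0                      # (x_d, y_d, z_d) per point
    out = np.zeros((pts.shape[0], 3))
    for dx in (0, 1):
        wx = frac[:, 0] if dx else 1.0 - frac[:, 0]
        for dy in (0, 1):
            wy = frac[:, 1] if dy else 1.0 - frac[:, 1]
            for dz in (0, 1):
                wz = frac[:, 2] if dz else 1.0 - frac[:, 2]
                w = (wx * wy * wz)[:, None]
                out += w * field.data[i0[:, 0] + dx, i0[:, 1] + dy,
                                      i0[:, 2] + dz]
    return out if np.asarray(nodes).ndim == 2 else out[0]


# ---------------------------------------------------------------------------
# dilation-phase selection
# ---------------------------------------------------------------------------

def select_dilation_phases(curve: VolumeCurve
                           ) -> Tuple[int, int, List[int]]:
    """Begin/peak phase of the dilation run from a cyclic volume curve.

    The peak is the phase of maximum volume; the beginning is found by
    walking cyclically backward from the peak while the volume does not
    increase (so plateaus of equal minima resolve to the earliest phase
    reached).  Returns (begin, peak, ordered phase list begin -> peak).
    """
    v = curve.volumes_mm3
    p = v.size
    if p < 4:
        raise ValueError("need at least 4 phases")
    if np.ptp(v) == 0:
        raise ValueError("no dilation detectable: volume curve is constant")
    peak = int(np.argmax(v))
    begin = peak
    for _ in range(p - 1):
        prev = (begin - 1) % p
        if v[prev] <= v[begin]:
            begin = prev
        else:
            break
    phases = []
    k = begin
    while True:
        phases.append(k)
        if k == peak:
            break
        k = (k + 1) % p
    return begin, peak, phases


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def save_displacement_nifti(field: VoxelDisplacementField, path: str) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = field.spacing
    affine[:3, 3] = field.origin
    nib.save(nib.Nifti1Image(field.data.astype(np.float32), affine), path)


def load_displacement_nifti(path: str) -> VoxelDisplacementField:
    import nibabel as nib

    img = nib.load(path)
    aff = img.affine
    return VoxelDisplacementField(
        data=np.asarray(img.dataobj, dtype=float),
        spacing=(float(aff[0, 0]), float(aff[1, 1]), float(aff[2, 2])),
        origin=tuple(float(x) for x in aff[:3, 3]))


def save_mask_metaimage(mask: VoxelMask, path: str) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(mask.data.transpose(2, 1, 0).astype(np.uint8))
    img.SetSpacing(mask.spacing)
    img.SetOrigin(mask.origin)
    sitk.WriteImage(img, path)


def load_mask_metaimage(path: str) -> VoxelMask:
    import SimpleITK as sitk

    img = sitk.ReadImage(path)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelMask(data=data > 0, spacing=tuple(img.GetSpacing()),
                     origin=tuple(img.GetOrigin()))
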