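"""Reading CT volumes and masks, HU thresholding, and 2D slice-pattern extraction.

Conventions
-----------
Volumes are stored as 3D arrays with axes ``(x, y, z)`` where the third axis is
the axial (slice) direction; ``spacing = (dx, dy, dz)`` is in millimetres per
voxel along each axis.  NIfTI images are reoriented to closest-canonical (RAS)
on load so that the third stored axis is superior–inferior; NRRD images are
transposed from SimpleITK's ``(z, y, x)`` array order.

A voxel with 0-based index ``i`` along an axis with spacing ``h`` has its
physical centre at ``(i + 0.5) * h`` mm, so rasterized point patterns are
translation-consistent with the voxel grid.

Low attenuation areas (LAAs) are lung voxels with HU strictly below −950 on
inspiration; gas trapping uses HU < −856 on expiration.  Thresholding is only
ever applied inside the lung mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

LAA_THRESHOLD_HU = -950.0
GAS_TRAPPING_THRESHOLD_HU = -856.0

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_NRRD_SUFFIXES = (".nrrd", ".nhdr")


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 entries, got {spacing}")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive and finite, got {spacing}")
    return spacing


@dataclass(frozen=True)
class CTVolume:
    """A CT volume in Hounsfield Units with physical voxel spacing."""

    hu: np.ndarray
    spacing: tuple[float, float, float]
    axis_order: str = "xyz-axial"

    def __post_init__(self):
        hu = np.asarray(self.hu, dtype=float)
        if hu.ndim != 3 or hu.size == 0:
            raise ValueError("hu must be a non-empty 3D array")
        if not np.all(np.isfinite(hu)):
            raise ValueError("hu values must be finite")
        object.__setattr__(self, "hu", hu)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape


@dataclass(frozen=True)
class BinaryMask:
    """A boolean indicator grid (lung, LAA, or gas-trapping) sharing CT geometry."""

    indicator: np.ndarray
    spacing: tuple[float, float, float]
    role: str = "lung"

    def __post_init__(self):
        ind = np.asarray(self.indicator)
        if ind.dtype != bool:
            if not np.isin(ind, (0, 1)).all():
                raise ValueError("indicator must be boolean or 0/1")
            ind = ind.astype(bool)
        if ind.ndim != 3 or ind.size == 0:
            raise ValueError("indicator must be a non-empty 3D array")
        object.__setattr__(self, "indicator", ind)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.indicator.shape

    @property
    def n_voxels(self) -> int:
        return int(self.indicator.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass(frozen=True)
class Window2D:
    """A 2D observation window: the in-plane lung region of one axial slice."""

    grid: np.ndarray           # (nx, ny) boolean
    spacing: tuple[float, float]  # (dx, dy) mm

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=bool)
        if grid.ndim != 2:
            raise ValueError("window grid must be 2D")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 2 or not all(s > 0 for s in spacing):
            raise ValueError(f"in-plane spacing must be two positive numbers, got {spacing}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_area(self) -> float:
        """Area of one in-plane voxel (mm^2)."""
        return self.spacing[0] * self.spacing[1]

    @property
    def area(self) -> float:
        """Total lung area |W| of the window (mm^2)."""
        return float(self.grid.sum()) * self.voxel_area

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    def cell_centers(self) -> np.ndarray:
        """Physical centres (mm) of the window's voxels, shape (n, 2)."""
        ij = np.argwhere(self.grid)
        return (ij + 0.5) * np.asarray(self.spacing)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of (n, 2) mm coordinates in the window."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.floor(points / np.asarray(self.spacing)).astype(int)
        inside = (
            (idx[:, 0] >= 0)
            & (idx[:, 1] >= 0)
            & (idx[:, 0] < self.grid.shape[0])
            & (idx[:, 1] < self.grid.shape[1])
        )
        out = np.zeros(len(points), dtype=bool)
        if inside.any():
            out[inside] = self.grid[idx[inside, 0], idx[inside, 1]]
        return out


@dataclass(frozen=True)
class SlicePattern:
    """LAA voxel-centre locations (mm) within the lung window of one axial slice."""

    points: np.ndarray  # (n, 2) mm
    window: Window2D
    slice_index: int = 0

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        pts = np.unique(pts, axis=0) if len(pts) else pts
        if len(pts) and not self.window.contains(pts).all():
            raise ValueError("all pattern points must lie inside the window")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def lung_area(self) -> float:
        return self.window.area

    @property
    def voxel_area(self) -> float:
        return self.window.voxel_area


# ---------------------------------------------------------------------------
# File I/O


def _read_nrrd_header_text(path: Path) -> str:
    with open(path, "rb") as fh:
        raw = fh.read(1 << 16)
    head = raw.split(b"\n\n", 1)[0]
    return head.decode("latin-1", errors="replace")


def load_volume(path) -> CTVolume:
    """Load a NIfTI or NRRD volume as a :class:`CTVolume`.

    Spacing must be present and strictly positive in the file metadata; a
    missing/zero spacing is a hard error because every downstream metric has
    physical units.
    """
    arr, spacing = _load_array(path)
    return CTVolume(hu=arr.astype(float), spacing=spacing)


def load_mask(path, role: str = "lung") -> BinaryMask:
    """Load a NIfTI or NRRD indicator volume as a :class:`BinaryMask`."""
    arr, spacing = _load_array(path)
    return BinaryMask(indicator=arr > 0.5, spacing=spacing, role=role)


def _load_array(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        import nibabel as nib

        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"{path} is not a 3D volume (ndim={data.ndim})")
        spacing = _check_spacing(img.header.get_zooms()[:3])
        return np.asarray(data, dtype=float), spacing
    if name.endswith(_NRRD_SUFFIXES):
        import SimpleITK as sitk

        header = _read_nrrd_header_text(path)
        if "spacings" not in header and "space directions" not in header:
            raise ValueError(f"{path}: NRRD header carries no voxel spacing metadata")
        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise ValueError(f"{path} is not a 3D volume")
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        spacing = _check_spacing(img.GetSpacing())  # (dx, dy, dz)
        return np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(float), spacing
    raise ValueError(f"unrecognized volumetric format: {path}")


def save_volume(path, volume: CTVolume) -> None:
    """Write a CT volume to NIfTI or NRRD."""
    _save_array(path, volume.hu.astype(np.float32), volume.spacing)


def save_mask(path, mask: BinaryMask) -> None:
    """Write a binary mask to NIfTI or NRRD as an 8-bit indicator."""
    _save_array(path, mask.indicator.astype(np.uint8), mask.spacing)


def _save_array(path, arr: np.ndarray, spacing) -> None:
    path = Path(path)
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        import nibabel as nib

        affine = np.diag(list(spacing) + [1.0])
        img = nib.Nifti1Image(arr, affine)
        img.header.set_zooms(spacing)
        nib.save(img, str(path))
        return
    if name.endswith(_NRRD_SUFFIXES):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in spacing))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unrecognized output format: {path}")


# ---------------------------------------------------------------------------
# Thresholding and burden percentages


def _role_for_threshold(threshold_hu: float) -> str:
    if threshold_hu == LAA_THRESHOLD_HU:
        return "LAA"
    if threshold_hu == GAS_TRAPPING_THRESHOLD_HU:
        return "gas-trapping"
    return f"threshold<{threshold_hu:g}"


def make_threshold_mask(ct: CTVolume, lung: BinaryMask, threshold_hu: float) -> BinaryMask:
    """Indicator of lung voxels with HU strictly below ``threshold_hu``.

    The strict inequality means a boundary voxel with HU exactly equal to the
    threshold is *not* included.
    """
    if ct.shape != lung.shape:
        raise ValueError(f"shape mismatch: ct {ct.shape} vs lung {lung.shape}")
    if ct.spacing != lung.spacing:
        raise ValueError(f"spacing mismatch: ct {ct.spacing} vs lung {lung.spacing}")
    indicator = lung.indicator & (ct.hu < float(threshold_hu))
    return BinaryMask(indicator=indicator, spacing=ct.spacing,
                      role=_role_for_threshold(float(threshold_hu)))


def compute_pct_laa(laa: BinaryMask, lung: BinaryMask) -> float:
    """Percentage of lung voxels that are LAA: 100 * |LAA| / |lung|."""
    if laa.shape != lung.shape:
        raise ValueError("LAA and lung masks must share shape")
    if (laa.indicator & ~lung.indicator).any():
        raise ValueError("LAA mask must be a subset of the lung mask")
    n_lung = lung.n_voxels
    if n_lung == 0:
        raise ValueError("lung mask is empty")
    return 100.0 * laa.n_voxels / n_lung


def compute_pct_gas_trapping(exp_ct: CTVolume, lung: BinaryMask) -> float:
    """Percentage of expiratory lung voxels with HU < −856 (gas trapping)."""
    gt = make_threshold_mask(exp_ct, lung, GAS_TRAPPING_THRESHOLD_HU)
    return compute_pct_laa(gt, lung)


def extract_slice_patterns(
    laa: BinaryMask,
    lung: BinaryMask,
    min_lung_voxels: int = 100,
) -> list[SlicePattern]:
    """One :class:`SlicePattern` per axial slice with at least ``min_lung_voxels``
    lung voxels.

    Slices below the lung-voxel threshold (near the apices/bases, where the fit
    would be unstable) are omitted and logged.  Points are placed at voxel
    centres: ``(index + 0.5) * spacing``.
    """
    if laa.shape != lung.shape:
        raise ValueError("LAA and lung masks must share shape")
    if (laa.indicator & ~lung.indicator).any():
        raise ValueError("LAA mask must be a subset of the lung mask")
    dx, dy, _ = lung.spacing
    patterns: list[SlicePattern] = []
    for z in range(lung.shape[2]):
        lung2d = lung.indicator[:, :, z]
        n_lung = int(lung2d.sum())
        if n_lung < min_lung_voxels:
            if n_lung:
                logger.info("slice %d omitted: %d lung voxels < %d", z, n_lung, min_lung_voxels)
            continue
        ij = np.argwhere(laa.indicator[:, :, z])
        points = (ij + 0.5) * np.array([dx, dy])
        window = Window2D(grid=lung2d, spacing=(dx, dy))
        patterns.append(SlicePattern(points=points, window=window, slice_index=z))
    return patterns
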