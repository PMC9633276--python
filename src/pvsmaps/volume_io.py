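"""Volumetric image I/O, mask algebra and intensity normalization.

Everything downstream of this module operates on two light containers:
:class:`Volume` (a 3D scalar grid with voxel geometry) and :class:`Mask`
(a binary grid sharing that geometry). Geometry mismatches between paired
objects are always an error, never silently resampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

MASK_LABELS = frozenset(
    {
        "brain",
        "GM",
        "WM",
        "deep_GM",
        "ventricles",
        "brainstem",
        "cerebellum",
        "CSF",
        "parenchyma",
        "PVS_manual",
        "PVS_auto",
        "search",
    }
)


@dataclass
class Volume:
    """A 3D scalar image with voxel geometry.

    Parameters
    ----------
    data : ndarray
        3D array of intensities, any units. Non-finite values are rejected
        at load time (or zero-filled with a warning, see :func:`read_nifti`).
    voxel_size : ndarray
        Edge length in mm along each axis; all entries must be positive.
    affine : ndarray
        4x4 voxel-to-world transform.
    id : str
        Free-text provenance label.
    """

    data: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim}D")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be three positive lengths (mm)")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data contains non-finite values")
        if not np.allclose(self.voxel_size, self.voxel_size[0]):
            logger.warning(
                "anisotropic voxels %s for %r; morphology operates in voxel space",
                self.voxel_size,
                self.id,
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class Mask:
    """A binary 3D grid sharing geometry with a paired :class:`Volume`."""

    data: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    label: str = "brain"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Mask data must be 3D, got {self.data.ndim}D")
        if self.data.dtype != bool:
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"Mask values must be in {{0,1}}, got {vals[:10]}")
            self.data = self.data.astype(bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be three positive lengths (mm)")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}; expected one of {sorted(MASK_LABELS)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def volume_mm3(self) -> float:
        return self.count * self.voxel_volume_mm3


def check_same_geometry(a: Volume | Mask, b: Volume | Mask) -> None:
    """Raise ``ValueError`` unless the two grids share shape and affine."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.affine, b.affine, atol=1e-5):
        raise ValueError("affine mismatch between paired grids")


def read_nifti(path: str | Path, expect: str = "volume", label: str = "brain") -> Volume | Mask:
    """Read a NIfTI-1/2 file as a :class:`Volume` or :class:`Mask`.

    Masks are binarized at > 0.5; the number of voxels altered by
    binarization is logged. Non-finite voxels in a volume are zero-filled
    with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if expect not in ("volume", "mask"):
        raise ValueError("expect must be 'volume' or 'mask'")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of header errors
        raise IOError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    affine = np.asarray(img.affine, dtype=float)
    if expect == "mask":
        binary = data > 0.5
        changed = int(np.count_nonzero((data != 0) != binary) + np.count_nonzero((data != 0) & (data != 1)))
        if changed:
            logger.info("%s: binarized %d non-{0,1} voxels at >0.5", path.name, changed)
        return Mask(binary, voxel_size=voxel_size, affine=affine, label=label)
    data = np.asarray(data, dtype=np.float64)
    bad = ~np.isfinite(data)
    if bad.any():
        logger.warning("%s: zero-filled %d non-finite voxels", path.name, int(bad.sum()))
        data = np.where(bad, 0.0, data)
    return Volume(data, voxel_size=voxel_size, affine=affine, id=path.stem)


def write_nifti(obj: Volume | Mask, path: str | Path) -> Path:
    """Write a Volume (float32) or Mask (uint8) to ``path``."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(obj, Mask):
        arr = obj.data.astype(np.uint8)
    else:
        arr = np.asarray(obj.data, dtype=np.float32)
    img = nib.Nifti1Image(arr, obj.affine)
    img.header.set_zooms(tuple(obj.voxel_size))
    nib.save(img, str(path))
    return path


def structuring_element(connectivity: int = 6) -> np.ndarray:
    """3x3x3 structuring element: 6 (faces) or 26 (full cube) connected."""
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def dilate(mask: Mask, voxels: int, connectivity: int = 6) -> Mask:
    """Dilate a mask by ``voxels`` iterations of a unit structuring element.

    Applying the operation n times with 1 voxel equals applying it once
    with n, so "dilated by three voxels" composes as expected.
    """
    if voxels < 1:
        raise ValueError("dilation radius must be >= 1 voxel")
    out = ndimage.binary_dilation(
        mask.data, structure=structuring_element(connectivity), iterations=voxels
    )
    return replace(mask, data=out)


def intersect(a: Mask, b: Mask, label: str | None = None) -> Mask:
    """Voxelwise logical AND of two masks with identical geometry."""
    check_same_geometry(a, b)
    return replace(a, data=a.data & b.data, label=label or a.label)


def union(a: Mask, b: Mask, label: str | None = None) -> Mask:
    """Voxelwise logical OR of two masks with identical geometry."""
    check_same_geometry(a, b)
    return replace(a, data=a.data | b.data, label=label or a.label)


def subtract(a: Mask, b: Mask, label: str | None = None) -> Mask:
    """Voxels of ``a`` not in ``b``."""
    check_same_geometry(a, b)
    return replace(a, data=a.data & ~b.data, label=label or a.label)


def normalize_intensity(
    vol: Volume, within: Mask, lo_pct: float = 1.0, hi_pct: float = 99.0
) -> Volume:
    """Map intensities inside ``within`` linearly onto [0, 1].

    The ``lo_pct`` percentile of in-mask intensities maps to 0 and
    ``hi_pct`` to 1; results are clipped to [0, 1] and voxels outside the
    mask are set to 0. Robust percentiles (default 1st/99th) make the
    mapping insensitive to extreme voxels, and the output is invariant to
    any positive affine rescaling of the input intensities.
    """
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValueError("need 0 <= lo_pct < hi_pct <= 100")
    check_same_geometry(vol, within)
    inside = vol.data[within.data]
    if inside.size == 0:
        raise ValueError("normalization mask is empty")
    lo, hi = np.percentile(inside, [lo_pct, hi_pct])
    if hi <= lo:
        raise ValueError("constant image inside normalization mask (zero intensity range)")
    scaled = np.clip((vol.data - lo) / (hi - lo), 0.0, 1.0)
    scaled[~within.data] = 0.0
    return replace(vol, data=scaled, id=f"{vol.id}:norm")
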