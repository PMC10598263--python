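"""GTV-guided CT slice pre-processing.

Turns a (CT volume, GTV mask) pair into the single 180x180 image in [0, 1]
that the outcome-prediction CNN consumes:

    in-plane resampling -> mask to the GTV -> largest-GTV-area slice ->
    crop about the tumor centroid -> Hounsfield windowing to [0, 1] ->
    Gaussian smoothing -> clip.

Windowing clips HU to [level - width/2, level + width/2] and rescales
linearly, emphasising the tissue band of interest; the three window settings
used throughout the package are level/width 0/1000, 50/350 and 125/350.
Masked-out background is filled with the lower window bound so it maps to 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import AlignmentError, ConfigurationError, DegenerateInputError

HU_MIN, HU_MAX = -1024.0, 3071.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CTVolume:
    """3D stack of Hounsfield-unit voxels with (dz, dy, dx) spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ConfigurationError(f"CTVolume must be 3D, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ConfigurationError("CTVolume contains non-finite HU values")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"spacing components must be positive: {self.spacing}")
        object.__setattr__(self, "voxels", vox)

    @property
    def shape(self):
        return self.voxels.shape


@dataclass(frozen=True)
class GTVMask:
    """Binary tumor mask aligned voxel-for-voxel with its CTVolume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ConfigurationError(f"GTVMask must be 3D, got shape {vox.shape}")
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ConfigurationError(f"mask values must be binary, found {uniq[:5]}")
        object.__setattr__(self, "voxels", vox.astype(np.uint8))

    @property
    def shape(self):
        return self.voxels.shape


@dataclass(frozen=True)
class WindowSpec:
    """Hounsfield window: center ``level`` and full ``width``, both in HU."""

    level: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ConfigurationError(f"window width must be > 0, got {self.width}")

    @property
    def lo(self) -> float:
        return self.level - self.width / 2.0

    @property
    def hi(self) -> float:
        return self.level + self.width / 2.0


#: The three window settings compared in the windowing experiment.
WINDOW_WIDE = WindowSpec(level=0.0, width=1000.0)
WINDOW_SOFT_TISSUE = WindowSpec(level=50.0, width=350.0)
WINDOW_BEST = WindowSpec(level=125.0, width=350.0)


@dataclass(frozen=True)
class PreprocessConfig:
    window: WindowSpec = WINDOW_BEST
    gaussian_sigma: float = 1.0
    crop_size: int = 180
    mask_fill_policy: str = "lower_window_bound"
    png_bit_depth: int = 8
    target_inplane_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        if self.crop_size < 2 or self.crop_size % 2 != 0:
            raise ConfigurationError(f"crop_size must be even and >= 2, got {self.crop_size}")
        if self.gaussian_sigma < 0:
            raise ConfigurationError("gaussian_sigma must be >= 0")
        if self.mask_fill_policy != "lower_window_bound":
            raise ConfigurationError(f"unknown mask_fill_policy {self.mask_fill_policy!r}")
        if self.png_bit_depth != 8:
            raise ConfigurationError("only 8-bit PNG output is supported")


@dataclass(frozen=True)
class TumorSlice:
    """Pre-processed crop_size x crop_size image in [0, 1] plus provenance."""

    pixels: np.ndarray
    source_slice_index: int
    tumor_center: tuple[int, int]

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ConfigurationError(f"TumorSlice pixels must be square 2D, got {px.shape}")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ConfigurationError("TumorSlice pixels must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _check_aligned(vol: CTVolume, mask: GTVMask):
    if vol.shape != mask.shape or vol.spacing != mask.spacing:
        raise AlignmentError(
            f"volume {vol.shape}/{vol.spacing} and mask {mask.shape}/{mask.spacing} differ"
        )


def resample_inplane(vol: CTVolume, mask: GTVMask, target_dy_dx=(1.0, 1.0)):
    """Resample rows/cols to the target spacing (mm); slices are untouched.

    The image is interpolated linearly, the mask nearest-neighbour so it
    stays binary. Output in-plane spacing is exactly the target.
    """
    _check_aligned(vol, mask)
    ty, tx = float(target_dy_dx[0]), float(target_dy_dx[1])
    if ty <= 0 or tx <= 0:
        raise ConfigurationError(f"target spacing must be positive: {target_dy_dx}")
    dz, dy, dx = vol.spacing
    if dy == ty and dx == tx:
        return vol, mask
    zoom = (1.0, dy / ty, dx / tx)
    vox = ndimage.zoom(vol.voxels.astype(np.float32), zoom, order=1, mode="nearest")
    mvox = ndimage.zoom(mask.voxels, zoom, order=0, mode="nearest")
    spacing = (dz, ty, tx)
    return CTVolume(vox, spacing), GTVMask(mvox, spacing)


def mask_volume(vol: CTVolume, mask: GTVMask, fill_hu: float) -> CTVolume:
    """Keep voxels inside the GTV, set everything outside to ``fill_hu``."""
    _check_aligned(vol, mask)
    if mask.voxels.sum() == 0:
        raise DegenerateInputError("GTV mask is empty")
    vox = np.where(mask.voxels.astype(bool), vol.voxels, np.float32(fill_hu))
    return CTVolume(vox.astype(np.float32), vol.spacing)


def select_largest_gtv_slice(mask: GTVMask) -> int:
    """Index of the slice with the largest GTV area; ties -> lowest index."""
    counts = mask.voxels.reshape(mask.shape[0], -1).sum(axis=1)
    if counts.sum() == 0:
        raise DegenerateInputError("GTV mask is empty")
    # uniform in-plane spacing: area = count * dy*dx, so argmax over counts
    return int(np.argmax(counts))


def tumor_center(mask_slice: np.ndarray) -> tuple[int, int]:
    """Rounded (half-up) centroid of the nonzero pixels of a 2D mask."""
    mask_slice = np.asarray(mask_slice)
    rows, cols = np.nonzero(mask_slice)
    if rows.size == 0:
        raise DegenerateInputError("mask slice is empty")
    cr, cc = rows.mean(), cols.mean()
    return int(np.floor(cr + 0.5)), int(np.floor(cc + 0.5))


def crop_about_center(img: np.ndarray, center, crop_size: int, pad_value=0.0) -> np.ndarray:
    """Half-open crop of rows/cols [c - crop_size/2, c + crop_size/2).

    Regions outside the image are filled with ``pad_value``, so any center
    is valid.
    """
    if crop_size % 2 != 0:
        raise ConfigurationError("crop_size must be even")
    img = np.asarray(img)
    half = crop_size // 2
    r0, c0 = int(center[0]) - half, int(center[1]) - half
    out = np.full((crop_size, crop_size), pad_value, dtype=img.dtype)
    rs, re = max(r0, 0), min(r0 + crop_size, img.shape[0])
    cs, ce = max(c0, 0), min(c0 + crop_size, img.shape[1])
    if rs < re and cs < ce:
        out[rs - r0 : re - r0, cs - c0 : ce - c0] = img[rs:re, cs:ce]
    return out


def window_normalize(img: np.ndarray, w: WindowSpec) -> np.ndarray:
    """Clip to [level - width/2, level + width/2] and map linearly onto [0, 1]."""
    img = np.asarray(img, dtype=np.float32)
    if not np.all(np.isfinite(img)):
        raise ConfigurationError("window_normalize requires finite input")
    return (np.clip(img, w.lo, w.hi) - w.lo) / np.float32(w.width)


def gaussian_smooth(img: np.ndarray, sigma: float) -> np.ndarray:
    """2D Gaussian filter with reflective boundaries; sigma = 0 is identity."""
    if sigma < 0:
        raise ConfigurationError("sigma must be >= 0")
    img = np.asarray(img, dtype=np.float32)
    if sigma == 0:
        return img
    return ndimage.gaussian_filter(img, sigma=sigma, mode="reflect")


def quantize_png8(img: np.ndarray) -> np.ndarray:
    """Map [0, 1] to integers 0..255 with round-half-up."""
    img = np.asarray(img)
    if img.min() < 0.0 or img.max() > 1.0:
        raise ConfigurationError("quantize_png8 input must lie in [0, 1]")
    return np.floor(img * 255.0 + 0.5).astype(np.uint8)


def write_png(img_u8: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(img_u8, dtype=np.uint8), mode="L").save(path, format="PNG")


def read_png(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def png_roundtrip(img_u8: np.ndarray) -> np.ndarray:
    """Write/read through an in-memory PNG; lossless for 8-bit grayscale."""
    buf = io.BytesIO()
    Image.fromarray(np.asarray(img_u8, dtype=np.uint8), mode="L").save(buf, format="PNG")
    buf.seek(0)
    with Image.open(buf) as im:
        return np.asarray(im, dtype=np.uint8)


def preprocess_case(vol: CTVolume, mask: GTVMask, cfg: PreprocessConfig = PreprocessConfig()) -> TumorSlice:
    """Full per-patient pipeline producing the CNN input image."""
    vol, mask = resample_inplane(vol, mask, cfg.target_inplane_spacing)
    fill = cfg.window.lo  # background maps to 0 after windowing
    masked = mask_volume(vol, mask, fill_hu=fill)
    k = select_largest_gtv_slice(mask)
    center = tumor_center(mask.voxels[k])
    crop = crop_about_center(masked.voxels[k], center, cfg.crop_size, pad_value=fill)
    img = window_normalize(crop, cfg.window)
    img = gaussian_smooth(img, cfg.gaussian_sigma)
    img = np.clip(img, 0.0, 1.0)
    return TumorSlice(pixels=img, source_slice_index=k, tumor_center=center)


# ---------------------------------------------------------------------------
# NIfTI adapters (real-data path)
# ---------------------------------------------------------------------------

def load_nifti_pair(image_path, mask_path) -> tuple[CTVolume, GTVMask]:
    """Load an image/mask NIfTI pair, reordered to (slices, rows, cols)."""
    import nibabel as nib

    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    ivox = np.asanyarray(img.dataobj, dtype=np.float32)
    mvox = (np.asanyarray(msk.dataobj) > 0.5).astype(np.uint8)
    zooms = img.header.get_zooms()[:3]
    # nibabel axes are (x, y, z); present as (slices=z, rows=y, cols=x)
    ivox = np.transpose(ivox, (2, 1, 0))
    mvox = np.transpose(mvox, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(ivox, spacing), GTVMask(mvox, spacing)


def save_nifti_pair(vol: CTVolume, mask: GTVMask, image_path, mask_path) -> None:
    import nibabel as nib

    _check_aligned(vol, mask)
    dz, dy, dx = vol.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    ivox = np.transpose(vol.voxels, (2, 1, 0)).astype(np.float32)
    mvox = np.transpose(mask.voxels, (2, 1, 0)).astype(np.uint8)
    nib.save(nib.Nifti1Image(ivox, affine), str(image_path))
    nib.save(nib.Nifti1Image(mvox, affine), str(mask_path))
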