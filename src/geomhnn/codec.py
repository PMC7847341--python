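"""Image I/O and bipolar encoding utilities.

Gray-scale images are handled as 2-D float64 arrays with values in [0, 1]
(the native domain being 8-bit, 0..255).  Because the Hopfield machinery is
a bipolar system admitting only −1/+1 states, an 8-bit image is decomposed
into eight sign planes (one per bit position).  The module also provides the
patch partitioning, per-patch normalization and the ternary ON/OFF
encoding that feed the network training path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "write_image",
    "as_gray",
    "bitplane_decompose",
    "bitplane_recompose",
    "PatchGrid",
    "partition",
    "assemble",
    "normalize_patch",
    "denormalize_patch",
    "TernaryCode",
    "onoff_encode",
    "quantize8",
]

# Rec. 601 luminance weights for RGB -> gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


def as_gray(pixels: np.ndarray) -> np.ndarray:
    """Validate and coerce an array into the [0, 1] gray-image contract."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a nonempty 2-D gray image, got shape {arr.shape}")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("gray image values must lie in [0, 1]")
    return arr


def read_image(path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF as a [0, 1] gray image.

    RGB(A) inputs are collapsed to luminance (Rec. 601); the alpha channel,
    if present, is dropped.  Values are scaled by 1/255.
    """
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not read image {path!r}: {exc}") from exc
    if raw.dtype == np.bool_:
        raw = raw.astype(np.uint8) * 255
    if raw.dtype != np.uint8:
        raise ValueError(
            f"unsupported bit depth {raw.dtype} in {path!r}: only 8-bit images are handled"
        )
    arr = raw.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image shape {raw.shape} in {path!r}")
    return np.clip(arr / 255.0, 0.0, 1.0)


def write_image(path, img: np.ndarray) -> None:
    """Write a [0, 1] gray image as an 8-bit raster (format from extension)."""
    iio.imwrite(path, quantize8(as_gray(img)))


def quantize8(img: np.ndarray) -> np.ndarray:
    """Quantize [0, 1] floats to uint8 with round-half-up."""
    return np.floor(np.clip(img, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def bitplane_decompose(img: np.ndarray) -> np.ndarray:
    """Split an image into 8 bipolar bit planes.

    Returns an array of shape (8, H, W) with entries in {−1, +1}; plane k
    (k=0 is the least significant bit) is +1 where bit k of the quantized
    8-bit value is set.
    """
    q = quantize8(as_gray(img))
    ks = np.arange(8, dtype=np.uint8)
    bits = (q[None, :, :] >> ks[:, None, None]) & 1
    return bits.astype(np.int8) * 2 - 1


def bitplane_recompose(planes: np.ndarray) -> np.ndarray:
    """Invert :func:`bitplane_decompose`; exact on all 8-bit inputs."""
    planes = np.asarray(planes)
    if planes.ndim != 3 or planes.shape[0] != 8:
        raise ValueError(f"expected an (8, H, W) plane stack, got shape {planes.shape}")
    if not np.isin(planes, (-1, 1)).all():
        raise ValueError("bit-plane entries must be exactly -1 or +1")
    bits = (planes > 0).astype(np.uint16)
    ks = np.arange(8, dtype=np.uint16)
    value = (bits * (1 << ks)[:, None, None]).sum(axis=0)
    return value.astype(np.float64) / 255.0


@dataclass(frozen=True)
class PatchGrid:
    """Row-major tiling of a reflect-padded image into equal patches."""

    patch_rows: int
    patch_cols: int
    patch_h: int
    patch_w: int
    orig_shape: tuple[int, int]
    pad: tuple[int, int]  # rows, cols added at the bottom/right
    pad_mode: str = "reflect"
    patches: tuple = field(default=(), repr=False)  # ((row_slice, col_slice), ...)

    @property
    def n_patches(self) -> int:
        return self.patch_rows * self.patch_cols

    @property
    def padded_shape(self) -> tuple[int, int]:
        return (self.orig_shape[0] + self.pad[0], self.orig_shape[1] + self.pad[1])


def partition(img: np.ndarray, patch_rows: int = 22, patch_cols: int = 20) -> tuple[np.ndarray, PatchGrid]:
    """Tile an image into ``patch_rows x patch_cols`` patches (default 440).

    The image is reflect-padded at the bottom/right so each dimension
    divides evenly.  Returns the padded image and the patch layout.
    """
    img = as_gray(img)
    h, w = img.shape
    if patch_rows < 1 or patch_cols < 1:
        raise ValueError("patch grid dimensions must be >= 1")
    if patch_rows * patch_cols > h * w:
        raise ValueError(
            f"{patch_rows * patch_cols} patches exceed the {h * w} available pixels"
        )
    ph = -(-h // patch_rows)  # ceil division
    pw = -(-w // patch_cols)
    pad_r = ph * patch_rows - h
    pad_c = pw * patch_cols - w
    padded = np.pad(img, ((0, pad_r), (0, pad_c)), mode="reflect") if (pad_r or pad_c) else img
    slices = tuple(
        (slice(r * ph, (r + 1) * ph), slice(c * pw, (c + 1) * pw))
        for r in range(patch_rows)
        for c in range(patch_cols)
    )
    grid = PatchGrid(
        patch_rows=patch_rows,
        patch_cols=patch_cols,
        patch_h=ph,
        patch_w=pw,
        orig_shape=(h, w),
        pad=(pad_r, pad_c),
        patches=slices,
    )
    return padded, grid


def assemble(patches, grid: PatchGrid, unpad: bool = True) -> np.ndarray:
    """Reassemble patches (in row-major order) into a full image."""
    out = np.empty(grid.padded_shape, dtype=np.float64)
    if len(patches) != grid.n_patches:
        raise ValueError(f"expected {grid.n_patches} patches, got {len(patches)}")
    for patch, (rs, cs) in zip(patches, grid.patches):
        out[rs, cs] = patch
    if unpad:
        out = out[: grid.orig_shape[0], : grid.orig_shape[1]]
    return out


def normalize_patch(patch: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardize a patch to zero mean / unit variance, then rescale to [0, 1].

    Returns ``(normalized, mean, var)`` where mean/var are the original
    sample statistics needed for inversion.  A constant patch (variance 0)
    is returned unchanged with ``var = 0.0`` as the degenerate flag.
    """
    patch = as_gray(patch)
    if patch.size < 2:
        raise ValueError("patch must have at least 2 pixels")
    mean = float(patch.mean())
    var = float(patch.var())
    if var == 0.0:
        return patch.copy(), mean, 0.0
    z = (patch - mean) / np.sqrt(var)
    norm = (z - z.min()) / (z.max() - z.min())
    return norm, mean, var


def denormalize_patch(norm: np.ndarray, mean: float, var: float) -> np.ndarray:
    """Invert :func:`normalize_patch`.

    The forward map is affine, so its coefficients are recoverable from the
    stored (mean, var) and the normalized output's own sample statistics.
    """
    norm = np.asarray(norm, dtype=np.float64)
    if var == 0.0:
        return norm.copy()
    nvar = float(norm.var())
    scale = np.sqrt(var / nvar)
    offset = mean - float(norm.mean()) * scale
    return norm * scale + offset


@dataclass(frozen=True)
class TernaryCode:
    """OFF / no-firing / ON states of a patch, with the tertile cut points."""

    states: np.ndarray  # entries in {-1, 0, +1}
    thresholds: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)


def onoff_encode(patch: np.ndarray) -> TernaryCode:
    """Ternary-encode intensities by equal-width tertiles.

    The interval [0, 1/3) maps to −1 (OFF), [1/3, 2/3) to 0 (no firing)
    and [2/3, 1] to +1 (ON), mirroring the ON/OFF response of retinal
    ganglion cells that motivates the encoding.
    """
    patch = as_gray(patch)
    lo, hi = 1.0 / 3.0, 2.0 / 3.0
    states = np.zeros(patch.shape, dtype=np.int8)
    states[patch < lo] = -1
    states[patch >= hi] = 1
    return TernaryCode(states=states, thresholds=(lo, hi))
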