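"""Perceptual evaluation suite: entropy, VIF, WPSNR, GLCM contrast and
homogeneity, with mean/sigma aggregation over image sets.

Entropy, contrast and homogeneity are no-reference measures of the test
image; VIF and WPSNR compare it against a reference.  All five are
computed on the 8-bit quantization of the [0, 1] images.

VIF here is the pixel-domain multi-scale variant: at each scale the test
image is modeled locally as a gain g times the reference plus residual
noise, and the metric is the ratio of the information the test channel
carries about the (Gaussian-modeled) source to the information the
reference carries.  Identity gives 1; contrast amplification can push it
above 1; blur and noise pull it toward 0.

WPSNR weights the squared error by a noise-visibility function
w = 1 / (1 + theta * local_variance), de-emphasizing errors hidden in
textured regions where the eye is less sensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage

from .codec import as_gray, quantize8

__all__ = [
    "MetricReport",
    "AggregateReport",
    "entropy",
    "glcm",
    "contrast",
    "homogeneity",
    "vif",
    "wpsnr",
    "evaluate",
    "aggregate",
]

DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class MetricReport:
    entropy: float
    vif: float
    wpsnr: float
    contrast: float
    homogeneity: float


@dataclass(frozen=True)
class AggregateReport:
    mean: MetricReport
    std: MetricReport


def entropy(img: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin intensity histogram."""
    counts = np.bincount(quantize8(as_gray(img)).ravel(), minlength=256)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def glcm(
    img: np.ndarray,
    offsets=DEFAULT_OFFSETS,
    levels: int = 256,
    symmetric: bool = True,
) -> np.ndarray:
    """Normalized gray-level co-occurrence table, averaged over offsets.

    Intensities are requantized to ``levels`` gray levels.  An offset
    larger than the image is skipped with a warning; counting a pair at
    (r, c) and (r+dr, c+dc), optionally symmetrized, then normalized to
    total mass 1.
    """
    img = as_gray(img)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    q = np.minimum((img * levels).astype(np.intp), levels - 1)
    h, w = q.shape
    total = np.zeros((levels, levels), dtype=np.float64)
    used = 0
    for dr, dc in offsets:
        if abs(dr) >= h or abs(dc) >= w:
            warnings.warn(f"offset {(dr, dc)} exceeds image size {q.shape}; skipped")
            continue
        rs = slice(max(-dr, 0), h - max(dr, 0))
        cs = slice(max(-dc, 0), w - max(dc, 0))
        a = q[rs, cs].ravel()
        b = q[rs.start + dr : rs.stop + dr, cs.start + dc : cs.stop + dc].ravel()
        table = np.zeros((levels, levels), dtype=np.float64)
        np.add.at(table, (a, b), 1.0)
        if symmetric:
            table = table + table.T
        total += table / table.sum()
        used += 1
    if used == 0:
        raise ValueError("no offset fits inside the image")
    return total / used


def contrast(g: np.ndarray) -> float:
    """GLCM contrast sum p(a,b) (a-b)^2."""
    g = np.asarray(g, dtype=np.float64)
    idx = np.arange(g.shape[0])
    diff2 = (idx[:, None] - idx[None, :]) ** 2
    return float((g * diff2).sum())


def homogeneity(g: np.ndarray) -> float:
    """GLCM homogeneity sum p(a,b) / (1 + |a-b|)."""
    g = np.asarray(g, dtype=np.float64)
    idx = np.arange(g.shape[0])
    kernel = 1.0 / (1.0 + np.abs(idx[:, None] - idx[None, :]))
    return float((g * kernel).sum())


def _local_stats(ref, test, sigma):
    mu_r = ndimage.gaussian_filter(ref, sigma, mode="reflect")
    mu_t = ndimage.gaussian_filter(test, sigma, mode="reflect")
    var_r = ndimage.gaussian_filter(ref * ref, sigma, mode="reflect") - mu_r**2
    var_t = ndimage.gaussian_filter(test * test, sigma, mode="reflect") - mu_t**2
    cov = ndimage.gaussian_filter(ref * test, sigma, mode="reflect") - mu_r * mu_t
    return np.maximum(var_r, 0.0), np.maximum(var_t, 0.0), cov


def vif(ref: np.ndarray, test: np.ndarray, n_scales: int = 4, sigma_n_sq: float = 2.0) -> float:
    """Pixel-domain multi-scale visual information fidelity.

    Per scale: local gain g = cov / (var_ref + eps), residual
    sv = var_test - g*cov; the metric is
    sum log2(1 + g^2 var_ref / (sv + sigma_n^2)) over pixels and scales,
    divided by sum log2(1 + var_ref / sigma_n^2).  Computed on the 0-255
    scale.  vif(x, x) = 1; a constant test image scores ~0; values above 1
    indicate amplified local contrast.
    """
    ref = as_gray(ref) * 255.0
    test_a = as_gray(test) * 255.0
    if ref.shape != test_a.shape:
        raise ValueError("reference and test images must share dimensions")
    if min(ref.shape) < 32:
        raise ValueError("VIF needs images at least 32x32")
    eps = 1e-10
    num = 0.0
    den = 0.0
    for scale in range(n_scales):
        if scale > 0:
            ref = ndimage.gaussian_filter(ref, 1.0, mode="reflect")[::2, ::2]
            test_a = ndimage.gaussian_filter(test_a, 1.0, mode="reflect")[::2, ::2]
            if min(ref.shape) < 8:
                break
        var_r, var_t, cov = _local_stats(ref, test_a, sigma=2.0)
        g = cov / (var_r + eps)
        sv = np.maximum(var_t - g * cov, 0.0)
        num += float(np.log2(1.0 + g**2 * var_r / (sv + sigma_n_sq)).sum())
        den += float(np.log2(1.0 + var_r / sigma_n_sq).sum())
    return num / den if den > 0 else 0.0


def wpsnr(ref: np.ndarray, test: np.ndarray, cap_db: float = 100.0) -> float:
    """Noise-visibility-weighted PSNR in dB on the 0-255 scale.

    Weights w = 1 / (1 + theta * local_variance) with theta normalized by
    the maximum local variance of the reference; a variance-free reference
    reduces to plain PSNR.  Identical images return ``cap_db``.
    """
    ref = as_gray(ref) * 255.0
    test_a = as_gray(test) * 255.0
    if ref.shape != test_a.shape:
        raise ValueError("reference and test images must share dimensions")
    mu = ndimage.uniform_filter(ref, size=3, mode="reflect")
    local_var = np.maximum(ndimage.uniform_filter(ref * ref, size=3, mode="reflect") - mu**2, 0.0)
    vmax = local_var.max()
    weights = 1.0 / (1.0 + local_var / vmax) if vmax > 0 else np.ones_like(ref)
    wmse = float((weights * (ref - test_a) ** 2).sum() / weights.sum())
    if wmse == 0.0:
        return float(cap_db)
    return float(min(10.0 * np.log10(255.0**2 / wmse), cap_db))


def evaluate(
    ref: np.ndarray,
    test: np.ndarray,
    glcm_levels: int = 256,
    glcm_offsets=DEFAULT_OFFSETS,
    vif_scales: int = 4,
    vif_sigma_n_sq: float = 2.0,
    wpsnr_cap_db: float = 100.0,
) -> MetricReport:
    """All five metrics for one (reference, test) pair.

    Entropy, contrast and homogeneity are computed on the test image;
    VIF and WPSNR on the pair.
    """
    g = glcm(test, offsets=glcm_offsets, levels=glcm_levels)
    return MetricReport(
        entropy=entropy(test),
        vif=vif(ref, test, n_scales=vif_scales, sigma_n_sq=vif_sigma_n_sq),
        wpsnr=wpsnr(ref, test, cap_db=wpsnr_cap_db),
        contrast=contrast(g),
        homogeneity=homogeneity(g),
    )


def aggregate(reports, sample_std: bool = False) -> AggregateReport:
    """Per-metric mean and standard deviation over a set of reports.

    Population sigma (divisor n) by default; ``sample_std`` switches to
    the n-1 divisor.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report to aggregate")
    ddof = 1 if sample_std else 0
    names = [f.name for f in fields(MetricReport)]
    cols = {n: np.array([getattr(r, n) for r in reports]) for n in names}
    mean = MetricReport(**{n: float(cols[n].mean()) for n in names})
    if len(reports) == 1:
        std = MetricReport(**{n: 0.0 for n in names})
    else:
        std = MetricReport(**{n: float(cols[n].std(ddof=ddof)) for n in names})
    return AggregateReport(mean=mean, std=std)
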