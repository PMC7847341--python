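"""Deterministic synthetic phantoms and degradations.

Real medical test sets (brain MRI, breast/liver/skin cancer images) are
emulated by parametric phantoms: a smooth background carrying a few bright
elliptical or rectangular structures with oriented edges and a low-level
band-limited texture.  Degradations model the acquisition defects the
enhancement targets: Gaussian blur, mid-anchored contrast compression,
gamma shift and additive Gaussian noise.  Everything is reproducible from
the spec seeds, so tests and the acceptance run need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .codec import as_gray
from .hopfield import HopfieldNet
from .mpf import gibbs_sample

__all__ = [
    "Shape",
    "PhantomSpec",
    "DegradeSpec",
    "make_phantom",
    "degrade",
    "make_ising_dataset",
    "standard_phantom_spec",
    "standard_degrade_spec",
]


@dataclass(frozen=True)
class Shape:
    """One rendered structure: ellipse, axis-aligned rectangle, or linear ramp."""

    kind: str  # ellipse | rectangle | ramp
    center: tuple[float, float]
    axes: tuple[float, float]  # semi-axes (ellipse), half-sides (rectangle/ramp)
    intensity: float

    def __post_init__(self):
        if self.kind not in ("ellipse", "rectangle", "ramp"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("shape intensity must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    size: tuple[int, int] = (220, 200)
    shapes: tuple[Shape, ...] = ()
    background: float = 0.2
    texture_amp: float = 0.05
    seed: int = 7


@dataclass(frozen=True)
class DegradeSpec:
    blur_sigma: float = 0.0
    gamma: float = 1.0
    contrast_scale: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 11

    def __post_init__(self):
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur_sigma and noise_sigma must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0.0 < self.contrast_scale <= 1.0:
            raise ValueError("contrast_scale must be in (0, 1]")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render a phantom: shapes over background plus band-limited texture."""
    h, w = spec.size
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    img = np.full((h, w), spec.background)
    for shape in spec.shapes:
        cr, cs = shape.center
        ar, ac = shape.axes
        if not (0 <= cr - ar and cr + ar < h and 0 <= cs - ac and cs + ac < w):
            raise ValueError(f"shape {shape} does not fit inside the {spec.size} canvas")
        if shape.kind == "ellipse":
            mask = ((rr - cr) / ar) ** 2 + ((cc - cs) / ac) ** 2 <= 1.0
            img[mask] = shape.intensity
        elif shape.kind == "rectangle":
            mask = (np.abs(rr - cr) <= ar) & (np.abs(cc - cs) <= ac)
            img[mask] = shape.intensity
        else:  # ramp: intensity fades linearly left-to-right across the box
            mask = (np.abs(rr - cr) <= ar) & (np.abs(cc - cs) <= ac)
            t = (cc - (cs - ac)) / (2.0 * ac)
            img[mask] = spec.background + (shape.intensity - spec.background) * t[mask]
    if spec.texture_amp > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.standard_normal((h, w))
        band = ndimage.gaussian_filter(noise, 1.5, mode="reflect")
        band /= max(np.abs(band).max(), 1e-12)
        img = img + spec.texture_amp * band
    return np.clip(img, 0.0, 1.0)


def degrade(img: np.ndarray, spec: DegradeSpec) -> np.ndarray:
    """Blur, compress contrast about 0.5, gamma-shift and add noise.

    With all parameters at identity the input is returned bit-exactly.
    """
    img = as_gray(img)
    out = img
    if spec.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, spec.blur_sigma, mode="reflect")
    if spec.contrast_scale != 1.0:
        out = 0.5 + spec.contrast_scale * (out - 0.5)
    if spec.gamma != 1.0:
        out = np.clip(out, 0.0, 1.0) ** spec.gamma
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        out = out + spec.noise_sigma * rng.standard_normal(out.shape)
    if out is img:
        return img.copy()
    return np.clip(out, 0.0, 1.0)


def make_ising_dataset(n_nodes: int, coupling: float, n_samples: int, seed: int = 0):
    """Planted nearest-neighbor ring Ising model plus Gibbs samples.

    Builds theta with weight ``coupling`` on every ring edge (i, i+1 mod n)
    and zero biases, then draws ``n_samples`` Gibbs samples from it.
    Returns ``(net, samples)``.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    w = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        j = (i + 1) % n_nodes
        w[i, j] = coupling
        w[j, i] = coupling
    net = HopfieldNet(weights=w)
    samples = gibbs_sample(net, n_samples, burn_in=200, seed=seed)
    return net, samples


def standard_phantom_spec() -> PhantomSpec:
    """The brain-like 220x200 fixture: skull ellipse, two lesions, a ramp."""
    return PhantomSpec(
        size=(220, 200),
        shapes=(
            Shape("ellipse", center=(110.0, 100.0), axes=(90.0, 80.0), intensity=0.45),
            Shape("ellipse", center=(80.0, 70.0), axes=(18.0, 12.0), intensity=0.85),
            Shape("ellipse", center=(140.0, 130.0), axes=(10.0, 16.0), intensity=0.75),
            Shape("ramp", center=(110.0, 100.0), axes=(20.0, 40.0), intensity=0.65),
        ),
        background=0.2,
        texture_amp=0.05,
        seed=7,
    )


def standard_degrade_spec() -> DegradeSpec:
    """The fixture degradation: blur 1.5, contrast 0.4, noise 0.01, seed 11."""
    return DegradeSpec(blur_sigma=1.5, gamma=1.0, contrast_scale=0.4, noise_sigma=0.01, seed=11)
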