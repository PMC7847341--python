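"""Local orientation, directional gradient energy, and the coupling field.

The enhancement network couples neighboring pixels through a spatially
varying parameter kappa.  Pixels on strongly oriented structure (edges)
should be coupled weakly so edges survive the smoothing; flat regions
should be coupled strongly.  The orientation of local structure is taken
from the windowed structure tensor; the "directional energy" at a pixel is
the squared projection of the intensity gradient onto the dominant local
orientation, averaged over a small window.  kappa is then a decreasing
function of that energy.

The module also houses two small combinatorial pieces the update schedule
relies on: the alternating (-1)^(i+j) sign matrix that defines the
checkerboard sequencing, and the parity branch formula giving the class
count Q from the hyperplane dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "WindowSpec",
    "OrientationField",
    "KappaField",
    "image_gradient",
    "structure_orientation",
    "directional_energy",
    "windowed_directional_energy",
    "kappa_field",
    "sign_matrix",
    "class_count",
]


@dataclass(frozen=True)
class WindowSpec:
    """Smoothing window: gaussian (truncated to `size`) or flat box."""

    shape: str = "gaussian"
    size: int = 5
    sigma: float = 1.0

    def __post_init__(self):
        if self.shape not in ("gaussian", "box"):
            raise ValueError(f"unknown window shape {self.shape!r}")
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError("window size must be odd and >= 1")


def _smooth(arr: np.ndarray, window: WindowSpec) -> np.ndarray:
    if window.size == 1:
        return arr
    if window.shape == "box":
        return ndimage.uniform_filter(arr, size=window.size, mode="reflect")
    radius = window.size // 2
    return ndimage.gaussian_filter(arr, sigma=window.sigma, radius=radius, mode="reflect")


@dataclass
class OrientationField:
    """Per-pixel dominant orientation and windowed directional energy."""

    chi_hat: np.ndarray  # (H, W, 2) unit vectors
    dir_energy: np.ndarray  # (H, W) >= 0
    window: WindowSpec


@dataclass
class KappaField:
    """Spatially varying coupling, 0 < kappa <= kappa0."""

    kappa0: float
    kappa: np.ndarray

    def __post_init__(self):
        if self.kappa0 <= 0:
            raise ValueError("kappa0 must be positive")
        k = np.asarray(self.kappa, dtype=np.float64)
        if (k <= 0).any() or (k > self.kappa0 + 1e-12).any():
            raise ValueError("kappa must lie in (0, kappa0]")
        self.kappa = k


def image_gradient(img: np.ndarray, operator: str = "central") -> tuple[np.ndarray, np.ndarray]:
    """Row/column intensity gradients by central differences or Sobel."""
    img = np.asarray(img, dtype=np.float64)
    if operator == "central":
        gr, gc = np.gradient(img)
    elif operator == "sobel":
        gr = ndimage.sobel(img, axis=0, mode="reflect") / 8.0
        gc = ndimage.sobel(img, axis=1, mode="reflect") / 8.0
    else:
        raise ValueError(f"unknown gradient operator {operator!r}")
    return gr, gc


def structure_orientation(
    img: np.ndarray,
    window: WindowSpec = WindowSpec(),
    gradient_operator: str = "central",
) -> OrientationField:
    """Dominant local orientation from the windowed structure tensor.

    chi_hat is the eigenvector of the larger eigenvalue of
    J = W * [g g^T]; its sign is fixed so the first nonzero component is
    >= 0.  On a constant image the tensor vanishes and chi_hat falls back
    to (1, 0) everywhere with zero directional energy.
    """
    img = np.asarray(img, dtype=np.float64)
    if min(img.shape) < window.size:
        raise ValueError(
            f"image shape {img.shape} smaller than window size {window.size}"
        )
    gr, gc = image_gradient(img, gradient_operator)
    j_rr = _smooth(gr * gr, window)
    j_cc = _smooth(gc * gc, window)
    j_rc = _smooth(gr * gc, window)

    # closed-form eigendecomposition of the symmetric 2x2 field
    half_tr = 0.5 * (j_rr + j_cc)
    half_diff = 0.5 * (j_rr - j_cc)
    root = np.sqrt(half_diff**2 + j_rc**2)
    lam1 = half_tr + root
    # eigenvector of lam1: (j_rc, lam1 - j_rr) when the tensor has an
    # off-diagonal part; for a diagonal tensor (axis-aligned structure,
    # including the constant-image case) it is the axis of the larger entry
    offdiag = np.abs(j_rc) > 1e-300
    axis_r = j_rr >= j_cc
    v_r = np.where(offdiag, j_rc, np.where(axis_r, 1.0, 0.0))
    v_c = np.where(offdiag, lam1 - j_rr, np.where(axis_r, 0.0, 1.0))
    norm = np.hypot(v_r, v_c)
    degenerate = norm < 1e-12
    v_r = np.where(degenerate, 1.0, v_r)
    v_c = np.where(degenerate, 0.0, v_c)
    norm = np.where(degenerate, 1.0, norm)
    chi = np.stack([v_r / norm, v_c / norm], axis=-1)

    # deterministic sign: first nonzero component >= 0
    flip = (chi[..., 0] < 0) | ((chi[..., 0] == 0) & (chi[..., 1] < 0))
    chi[flip] *= -1.0

    field = OrientationField(chi_hat=chi, dir_energy=np.zeros(img.shape), window=window)
    field.dir_energy = windowed_directional_energy(img, field, gradient_operator)
    return field


def directional_energy(grad, chi_hat) -> float:
    """Squared projection of a gradient onto a unit orientation, (g.chi)^2."""
    grad = np.asarray(grad, dtype=np.float64)
    chi_hat = np.asarray(chi_hat, dtype=np.float64)
    if abs(np.linalg.norm(chi_hat) - 1.0) > 1e-6:
        raise ValueError("chi_hat must be a unit vector")
    return float(np.dot(grad, chi_hat) ** 2)


def windowed_directional_energy(
    img: np.ndarray,
    orient: OrientationField,
    gradient_operator: str = "central",
) -> np.ndarray:
    """Window-average of the pointwise directional energy map."""
    img = np.asarray(img, dtype=np.float64)
    if orient.chi_hat.shape[:2] != img.shape:
        raise ValueError("orientation field does not match the image")
    gr, gc = image_gradient(img, gradient_operator)
    pointwise = (gr * orient.chi_hat[..., 0] + gc * orient.chi_hat[..., 1]) ** 2
    return np.maximum(_smooth(pointwise, orient.window), 0.0)


def kappa_field(kappa0: float, dir_energy: np.ndarray) -> KappaField:
    """Modulate the coupling down where oriented gradient energy is high.

    kappa(i) = kappa0 / (1 + e(i)/mean(e)); a zero energy map gives the
    uniform field kappa0.  High-energy (edge) pixels thus receive weak
    smoothing coupling, preserving the edge.
    """
    if kappa0 <= 0:
        raise ValueError("kappa0 must be positive")
    e = np.asarray(dir_energy, dtype=np.float64)
    if (e < 0).any():
        raise ValueError("directional energy must be nonnegative")
    mean = e.mean()
    kappa = np.full(e.shape, kappa0) if mean == 0 else kappa0 / (1.0 + e / mean)
    return KappaField(kappa0=kappa0, kappa=kappa)


def sign_matrix(rows: int, cols: int) -> np.ndarray:
    """The alternating sign matrix s(i,j) = (-1)^(i+j), s(0,0) = +1.

    Its +1/-1 cells are the two parities of the checkerboard update
    schedule: within one parity no two 4-neighbors appear.
    """
    if rows < 1 or cols < 1:
        raise ValueError("sign matrix dimensions must be >= 1")
    i = np.arange(rows)[:, None]
    j = np.arange(cols)[None, :]
    return (1 - 2 * ((i + j) % 2)).astype(np.int8)


def class_count(n: int) -> int:
    """Number of intensity classes Q for hyperplane dimension n.

    Parity branch: n+3 when n+1 is odd, n+2 when n+1 is even.  The default
    image setting n=2 gives Q=5.
    """
    if n < 1:
        raise ValueError("hyperplane dimension must be >= 1")
    return n + 3 if (n + 1) % 2 == 1 else n + 2
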