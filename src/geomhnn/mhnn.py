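"""Geometrically regularized modified Hopfield network for enhancement.

Each image patch is enhanced by solving a Q-class pixel labeling problem:
every pixel is assigned to one of Q intensity prototypes I_1 < ... < I_Q by
minimizing

    Pi(labels) = sum_i ||xi_i - I_{q(i)}||^2  +  s * sum_i sum_{j in mu_i} kbar(i,j) [q(i) = q(j)]

where mu_i is the pixel neighborhood, kbar(i,j) the pairwise mean of the
spatially varying coupling kappa, and s the smoothness sign (-1, the Potts
convention, rewards agreeing neighbors; +1 penalizes them).  The problem
maps onto a Hopfield-type network whose units are (pixel, class)
indicators; its weights are 2*kappa between neighbors and its biases
combine the per-class quantization errors with the coupling.  Updates are
sequenced by the alternating (-1)^(i+j) sign matrix: all cells of one
checkerboard parity, then the other, each pixel taking the class that
minimizes its local energy.  Convergence is to a labeling no single-pixel
change can improve.

The converged labeling drives the enhancement: the intensity interval each
class occupies is stretched onto its share of [0, 1] by a monotone
piecewise-linear remap, and the result is alpha-blended with the input.
At the image level the class intervals are pooled over all patches into a
single global remap; a spatially varying remap (one per patch) was found
to fragment local image statistics at patch borders and degrade fidelity,
while the pooled map preserves monotone intensity ordering everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.vq import kmeans2

from .codec import as_gray, assemble, normalize_patch, partition, quantize8
from .config import RunConfig
from .geometry import KappaField, WindowSpec, class_count, kappa_field, sign_matrix, structure_orientation

__all__ = [
    "ClassPrototypes",
    "MhnnParams",
    "init_prototypes",
    "objective",
    "build_network",
    "step_activation_01",
    "network_energy",
    "run_sequenced",
    "enhance_patch",
    "enhance_image",
]

_NEIGH4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_NEIGH8 = _NEIGH4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass(frozen=True)
class ClassPrototypes:
    """Strictly increasing prototype intensities I_1 < ... < I_Q in [0, 1]."""

    intensities: np.ndarray
    degenerate: bool = False

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("need at least two prototypes")
        if not (np.diff(arr) > 0).all():
            raise ValueError("prototypes must be strictly increasing")
        object.__setattr__(self, "intensities", arr)

    @property
    def Q(self) -> int:
        return self.intensities.size


@dataclass
class MhnnParams:
    """Network parameterization for one patch.

    Weights follow the rule psi_ij = 2*kbar(i,j) for j in the neighborhood
    of i (kbar the pairwise mean of kappa, keeping psi symmetric), zero
    otherwise; biases are the per-pixel, per-class array from
    :func:`build_network`.
    """

    prototypes: ClassPrototypes
    kappa: KappaField
    neighborhood: int = 4
    smoothness_sign: str = "potts"
    biases: np.ndarray | None = None  # (H, W, Q)

    def __post_init__(self):
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")
        if self.smoothness_sign not in ("potts", "paper"):
            raise ValueError("smoothness_sign must be 'potts' or 'paper'")

    @property
    def sign(self) -> float:
        return 1.0 if self.smoothness_sign == "paper" else -1.0

    @property
    def offsets(self):
        return _NEIGH4 if self.neighborhood == 4 else _NEIGH8


def init_prototypes(
    patch: np.ndarray, Q: int, method: str = "quantile", seed: int = 0
) -> ClassPrototypes:
    """Choose Q prototype intensities from a patch.

    ``quantile`` (deterministic, default) places I_q at the midpoint of the
    q-th equal-mass intensity interval, i.e. the (q - 1/2)/Q quantile.
    ``kmeans`` runs seeded Lloyd iterations and sorts the centers.  Either
    way ties are resolved by epsilon-separation so the result is strictly
    increasing; a patch with fewer distinct values than Q is flagged
    degenerate.
    """
    patch = as_gray(patch)
    if Q < 2:
        raise ValueError("Q must be >= 2")
    values = patch.ravel()
    distinct = np.unique(values)
    degenerate = distinct.size < Q
    if method == "quantile":
        proto = np.quantile(values, (np.arange(Q) + 0.5) / Q)
    elif method == "kmeans":
        if degenerate:
            proto = np.quantile(values, (np.arange(Q) + 0.5) / Q)
        else:
            centers, _ = kmeans2(values[:, None], Q, minit="++", seed=seed)
            proto = np.sort(centers.ravel())
    else:
        raise ValueError(f"unknown prototype method {method!r}")
    # enforce strict increase within [0, 1]
    eps = 1e-6
    proto = np.clip(np.sort(proto), 0.0, 1.0)
    for q in range(1, Q):
        if proto[q] <= proto[q - 1]:
            proto[q] = proto[q - 1] + eps
    if proto[-1] > 1.0:  # ran off the top; push down from below
        proto = np.minimum(proto, 1.0)
        for q in range(Q - 2, -1, -1):
            if proto[q] >= proto[q + 1]:
                proto[q] = proto[q + 1] - eps
    return ClassPrototypes(intensities=proto, degenerate=degenerate)


def _pair_kappa(kappa: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Pairwise-mean coupling between each pixel and its (dr,dc) neighbor."""
    shifted = np.full_like(kappa, np.nan)
    h, w = kappa.shape
    rs = slice(max(dr, 0), h + min(dr, 0))
    rd = slice(max(-dr, 0), h + min(-dr, 0))
    cs = slice(max(dc, 0), w + min(dc, 0))
    cd = slice(max(-dc, 0), w + min(-dc, 0))
    shifted[rd, cd] = kappa[rs, cs]
    return 0.5 * (kappa + shifted)


def _one_hot(labels: np.ndarray, Q: int) -> np.ndarray:
    return np.eye(Q, dtype=np.float64)[labels]


def objective(patch: np.ndarray, labels: np.ndarray, params: MhnnParams) -> float:
    """The labeling objective Pi: quantization error plus coupled agreement.

    The agreement sum runs over ordered neighbor pairs, so each unordered
    pair contributes twice.
    """
    patch = as_gray(patch)
    labels = np.asarray(labels)
    if labels.shape != patch.shape:
        raise ValueError("labels must match the patch shape")
    Q = params.prototypes.Q
    if labels.min() < 0 or labels.max() >= Q:
        raise ValueError("labels out of class range")
    d = (patch[..., None] - params.prototypes.intensities) ** 2
    data = float(np.take_along_axis(d, labels[..., None], axis=-1).sum())
    smooth = 0.0
    for dr, dc in params.offsets:
        kbar = _pair_kappa(params.kappa.kappa, dr, dc)
        shifted = np.full(labels.shape, -1)
        h, w = labels.shape
        rs = slice(max(dr, 0), h + min(dr, 0))
        rd = slice(max(-dr, 0), h + min(-dr, 0))
        cs = slice(max(dc, 0), w + min(dc, 0))
        cd = slice(max(-dc, 0), w + min(-dc, 0))
        shifted[rd, cd] = labels[rs, cs]
        agree = (shifted == labels) & ~np.isnan(kbar)
        smooth += float(np.where(agree, kbar, 0.0).sum())
    return data + params.sign * smooth


def build_network(
    patch: np.ndarray,
    prototypes: ClassPrototypes,
    kappa: KappaField,
    neighborhood: int = 4,
    smoothness_sign: str = "potts",
) -> MhnnParams:
    """Assemble the network parameters for a patch.

    Biases follow b_q(i) = (1/Q) sum_r d_r(i) - 8 kappa(i) (Q - d_q(i))
    with d_q(i) = ||xi_i - I_q||^2; weights are implicit in the
    (kappa, neighborhood) pair via psi_ij = 2*kbar(i,j).
    """
    patch = as_gray(patch)
    if kappa.kappa.shape != patch.shape:
        raise ValueError("kappa field must match the patch shape")
    Q = prototypes.Q
    d = (patch[..., None] - prototypes.intensities) ** 2  # (H, W, Q)
    biases = d.mean(axis=-1, keepdims=True) - 8.0 * kappa.kappa[..., None] * (Q - d)
    return MhnnParams(
        prototypes=prototypes,
        kappa=kappa,
        neighborhood=neighborhood,
        smoothness_sign=smoothness_sign,
        biases=biases,
    )


def step_activation_01(phi: float) -> int:
    """Indicator activation: 1 for strictly positive input, else 0."""
    return 1 if phi > 0 else 0


def network_energy(labels: np.ndarray, patch: np.ndarray, params: MhnnParams) -> float:
    """Hopfield energy E = -sum_ij psi_ij s_i s_j - sum_i b_i s_i.

    Evaluated per class channel on the +/-1 recoding of the one-hot
    indicators (0 -> -1), summed over channels.  The pair sum runs over
    ordered neighbor pairs.
    """
    patch = as_gray(patch)
    if params.biases is None:
        raise ValueError("params carry no biases; use build_network")
    Q = params.prototypes.Q
    sigma = 2.0 * _one_hot(np.asarray(labels), Q) - 1.0  # (H, W, Q)
    pair = 0.0
    for dr, dc in params.offsets:
        kbar = _pair_kappa(params.kappa.kappa, dr, dc)
        h, w = patch.shape
        rs = slice(max(dr, 0), h + min(dr, 0))
        rd = slice(max(-dr, 0), h + min(-dr, 0))
        cs = slice(max(dc, 0), w + min(dc, 0))
        cd = slice(max(-dc, 0), w + min(-dc, 0))
        shifted = np.full((h, w, Q), np.nan)
        shifted[rd, cd, :] = sigma[rs, cs, :]
        psi = 2.0 * kbar[..., None]
        term = psi * sigma * shifted
        pair += float(np.nansum(term))
    bias_term = float((params.biases * sigma).sum())
    return -pair - bias_term


def _local_cost(patch, labels, params):
    """Per-pixel, per-class cost of relabeling with all other pixels fixed."""
    Q = params.prototypes.Q
    d = (patch[..., None] - params.prototypes.intensities) ** 2  # (H, W, Q)
    agree = np.zeros_like(d)
    h, w = patch.shape
    for dr, dc in params.offsets:
        kbar = _pair_kappa(params.kappa.kappa, dr, dc)
        rs = slice(max(dr, 0), h + min(dr, 0))
        rd = slice(max(-dr, 0), h + min(-dr, 0))
        cs = slice(max(dc, 0), w + min(dc, 0))
        cd = slice(max(-dc, 0), w + min(-dc, 0))
        neigh = np.full((h, w), -1)
        neigh[rd, cd] = labels[rs, cs]
        valid = ~np.isnan(kbar)
        match = np.zeros((h, w, Q))
        idx = np.where(valid & (neigh >= 0))
        match[idx[0], idx[1], neigh[idx]] = kbar[idx]
        agree += match
    # relabeling pixel i to q changes both ordered pairs (i,j) and (j,i)
    return d + params.sign * 2.0 * agree


def run_sequenced(
    patch: np.ndarray,
    params: MhnnParams,
    max_sweeps: int = 100,
    seed: int = 0,
):
    """Checkerboard-sequenced label relaxation.

    Starts from the nearest-prototype assignment.  Each sweep visits the
    +1-parity cells of the sign matrix, then the -1-parity cells; every
    visited pixel takes the class minimizing its local cost (ties keep the
    current class, then prefer the lowest class index).  With the
    4-neighborhood, same-parity pixels are never neighbors, so each parity
    is updated as one vectorized step; the 8-neighborhood couples diagonal
    same-parity pixels and is relaxed pixel-by-pixel to keep the objective
    monotone.

    Returns ``(labels, objective_trace, converged)``; the trace holds Pi
    after the initial assignment and after each sweep, and is
    non-increasing.
    """
    patch = as_gray(patch)
    if max_sweeps < 1:
        raise ValueError("max_sweeps must be >= 1")
    labels = np.argmin((patch[..., None] - params.prototypes.intensities) ** 2, axis=-1)
    trace = [objective(patch, labels, params)]
    parity = sign_matrix(*patch.shape)
    converged = False
    for _ in range(max_sweeps):
        changed = False
        for par in (1, -1):
            mask = parity == par
            if params.neighborhood == 4:
                cost = _local_cost(patch, labels, params)
                cur = np.take_along_axis(cost, labels[..., None], axis=-1)[..., 0]
                best = np.argmin(cost, axis=-1)
                best_cost = np.take_along_axis(cost, best[..., None], axis=-1)[..., 0]
                improve = mask & (best_cost < cur - 1e-15) & (best != labels)
                if improve.any():
                    labels = np.where(improve, best, labels)
                    changed = True
            else:
                for r, c in zip(*np.where(mask)):
                    cost = _local_cost(patch, labels, params)[r, c]
                    q = int(np.argmin(cost))
                    if cost[q] < cost[labels[r, c]] - 1e-15 and q != labels[r, c]:
                        labels[r, c] = q
                        changed = True
        trace.append(objective(patch, labels, params))
        if not changed:
            converged = True
            break
    return labels, np.array(trace), converged


def class_interval_map(values: np.ndarray, labels: np.ndarray, Q: int):
    """Monotone control points of the class-stretch remap.

    For each nonempty class q (0-based), the occupied interval
    [min, max] of its member intensities is targeted onto [q/Q, (q+1)/Q].
    The interleaved control points are made nondecreasing (a running max
    plus epsilon separation), yielding one piecewise-linear monotone map
    usable with ``np.interp``.  Empty classes are skipped; the neighbors'
    segments bridge their target interval.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    xs, ys = [], []
    for q in range(Q):
        member = labels == q
        if not member.any():
            continue
        xs.extend([float(values[member].min()), float(values[member].max())])
        ys.extend([q / Q, (q + 1) / Q])
    xs = np.maximum.accumulate(np.array(xs))
    for i in range(1, xs.size):  # strict increase for a well-posed interp
        if xs[i] <= xs[i - 1]:
            xs[i] = xs[i - 1] + 1e-12
    return xs, np.array(ys)


def enhance_patch(
    patch: np.ndarray,
    labels: np.ndarray,
    prototypes: ClassPrototypes,
    alpha: float = 0.7,
) -> np.ndarray:
    """Stretch each class's occupied intensity interval onto its [0,1] share.

    Class q (0-based) maps the [min, max] of its member intensities
    linearly onto [q/Q, (q+1)/Q]; the per-class segments are assembled
    into one monotone piecewise-linear remap applied by value, so the
    output preserves intensity ordering.  The stretched image is
    alpha-blended with the input and clipped.  alpha = 0 returns the
    input exactly.
    """
    patch = as_gray(patch)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if alpha == 0.0:
        return patch.copy()
    if labels.shape != patch.shape:
        raise ValueError("labels must match the patch shape")
    xs, ys = class_interval_map(patch, labels, prototypes.Q)
    stretched = np.interp(patch, xs, ys)
    return np.clip(alpha * stretched + (1.0 - alpha) * patch, 0.0, 1.0)


def _fit_window(shape, cfg: RunConfig) -> WindowSpec:
    """Window spec shrunk to fit a small patch (size must stay odd)."""
    size = min(cfg.window_size, min(shape))
    if size % 2 == 0:
        size -= 1
    size = max(size, 1)
    return WindowSpec(shape=cfg.window_shape, size=size, sigma=cfg.window_sigma)


def enhance_image(img: np.ndarray, config: RunConfig | None = None):
    """Full enhancement pipeline for one gray image.

    partition -> per-patch normalize (contrast-invariant domain for the
    orientation and kappa fields) -> per-patch label relaxation against
    image-wide prototypes -> pooled class-interval stretch ->
    reassemble -> unpad.  Deterministic given ``config.seed``.

    The label networks run per patch (one neuron per pixel, as many
    networks as patches), but their class intervals are pooled into a
    single monotone remap for the whole image: per-patch remaps introduce
    seams at patch borders that damage local reference/test statistics,
    whereas the pooled map keeps the enhancement artifact-free.

    Returns ``(enhanced, diagnostics)`` where diagnostics is one record per
    patch (sweeps, Pi trace endpoints, convergence and degeneracy flags).
    """
    cfg = config or RunConfig()
    img = as_gray(img)
    Q = cfg.Q if cfg.Q is not None else class_count(cfg.hyperplane_dim)
    padded, grid = partition(img, cfg.patch_rows, cfg.patch_cols)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(grid.n_patches)
    n_outer = 2 if cfg.recompute_orientation else 1
    working = padded
    diagnostics = []
    for outer in range(n_outer):
        protos = init_prototypes(working, Q, cfg.prototype_method, cfg.seed)
        label_img = np.empty(grid.padded_shape, dtype=np.intp)
        for idx, (rs, cs) in enumerate(grid.patches):
            patch = working[rs, cs]
            pseed = int(seeds[idx] % (2**31))
            norm, _, var = normalize_patch(patch)
            record = {"patch": idx, "outer": outer, "degenerate": var == 0.0,
                      "sweeps": 0, "pi_initial": None, "pi_final": None,
                      "converged": True}
            if var == 0.0:
                # constant patch: nearest-prototype labels, no relaxation
                label_img[rs, cs] = np.argmin(
                    (patch[..., None] - protos.intensities) ** 2, axis=-1)
                diagnostics.append(record)
                continue
            window = _fit_window(norm.shape, cfg)
            orient = structure_orientation(norm, window, cfg.gradient_operator)
            kap = kappa_field(cfg.kappa0, orient.dir_energy)
            params = build_network(patch, protos, kap, cfg.neighborhood, cfg.smoothness_sign)
            labels, trace, converged = run_sequenced(patch, params, cfg.max_sweeps, pseed)
            label_img[rs, cs] = labels
            record.update(sweeps=len(trace) - 1, pi_initial=float(trace[0]),
                          pi_final=float(trace[-1]), converged=converged,
                          degenerate=protos.degenerate)
            diagnostics.append(record)
        xs, ys = class_interval_map(working, label_img, Q)
        stretched = np.interp(working, xs, ys)
        working = np.clip(cfg.alpha * stretched + (1.0 - cfg.alpha) * working, 0.0, 1.0)
    enhanced = working[: grid.orig_shape[0], : grid.orig_shape[1]]
    if cfg.quantize_output:
        enhanced = quantize8(enhanced).astype(np.float64) / 255.0
    return enhanced, diagnostics
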