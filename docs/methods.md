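# Methods

This note defines exactly what `geomhnn` computes. Images are 2-D float64
arrays with values in [0, 1]; 8-bit files are mapped by v/255 on read and by
round-half-up quantization on write.

## 1. Classical Hopfield network (`geomhnn.hopfield`)

A network is a symmetric weight matrix ψ (zero diagonal in the bipolar mode)
plus a bias vector ℘. For a bipolar state δ ∈ {−1, +1}ⁿ:

- local field: φ_i = Σ_j ψ_ij δ_j + ℘_i
- energy: E(δ) = −½ Σ_ij ψ_ij δ_i δ_j − Σ_i ℘_i δ_i
- step activation: δ_i ← sign(φ_i), with δ_i unchanged at φ_i = 0

Asynchronous relaxation visits nodes one at a time (sequential, random, or
checkerboard order for grid-shaped states) and repeats until a full sweep
changes nothing. Each accepted flip changes the energy by −δ_i′φ_i ≤ 0, so
the recorded per-sweep energy trace is non-increasing and the dynamics reach
a fixed point that no single flip can improve. Hebbian storage of patterns
γ¹…γᵖ sets ψ_ij = Σ_k γ_i^k γ_j^k for i ≠ j. A continuous mode replaces the
step with the logistic function 1/(1+exp(−(φ−shift))).

## 2. Geometry: orientation, directional energy, κ (`geomhnn.geometry`)

Gradients g = (g_r, g_c) come from central differences (default) or a
Sobel operator scaled by 1/8. The structure tensor J = W ∗ (g gᵀ) is the
elementwise window-smoothing (Gaussian, truncated to an odd size, or box) of
the gradient outer product. χ̂ is the unit eigenvector of J's larger
eigenvalue, computed in closed form; for a diagonal tensor it is the axis of
the larger diagonal entry, and on constant images it falls back to (1, 0).
Its sign is fixed so the first nonzero component is ≥ 0.

The *directional energy* at a pixel is e = W ∗ (g·χ̂)², the window average
of the squared projection of the gradient onto the dominant orientation. The
coupling field is

κ(i) = κ₀ / (1 + e(i) / mean(e)),   so 0 < κ ≤ κ₀,

with κ ≡ κ₀ when the energy map is identically zero. Pixels on oriented
structure get small κ (weak smoothing; edges survive); flat regions get
large κ.

Two combinatorial helpers live here as well: the alternating sign matrix
s(i,j) = (−1)^(i+j), whose two parities define the checkerboard update
schedule, and the class-count branch Q(n) = n+3 if n+1 is odd else n+2
(the default hyperplane dimension n = 2 gives Q = 5).

## 3. Modified network for pixel labeling (`geomhnn.mhnn`)

Given Q strictly increasing intensity prototypes I₀ < … < I_{Q−1}
(equal-mass quantiles by default, or 1-D k-means), a labeling q assigns each
pixel one class. The objective is

Π(q) = Σ_i ‖ξ_i − I_{q(i)}‖² + s · Σ_i Σ_{j∈μ(i)} κ̄(i,j) · [q(i) = q(j)]

where ξ_i is the pixel intensity, μ(i) the 4- or 8-neighborhood,
κ̄(i,j) = (κ(i)+κ(j))/2, and s = −1 by default (agreement between neighbors
is *rewarded*, a Potts-type smoothing prior; s = +1 is also available).

The labeling is relaxed as a network whose per-pixel, per-class biases are

℘_q(i) = (1/Q) Σ_r d_r(i) − 8 κ(i) (Q − d_q(i)),  d_r(i) = ‖ξ_i − I_r‖²,

with pairwise weights 2κ̄(i,j) on neighboring pixels. Updates are
checkerboard-sequenced: pixels of one parity of the sign matrix are updated
in parallel (their costs are independent under the 4-neighborhood), then the
other parity; under the 8-neighborhood the update is pixel-by-pixel inside
each parity. Each update picks the class minimizing the local cost
d_q(i) + s Σ_{j∈μ(i)} κ̄(i,j)[q(j) = q], so Π never increases, and the run
stops at a labeling no single-pixel relabel can improve. As κ → 0 the
neighborhood term vanishes and the labeling reduces exactly to
nearest-prototype quantization. Initialization is nearest-prototype.

### Enhancement (`enhance_image`)

1. Partition the image into a patch grid (default 22 × 20 patches) with
   reflect padding.
2. Per patch: min–max normalize (a contrast-invariant domain used only for
   geometry), estimate χ̂ and the directional energy there, build κ, then
   relax the labeling network on the raw patch against one *global*
   prototype set estimated from the whole image.
3. Pool all labels: for each class q collect the interval of raw intensities
   it occupies across the image and map it linearly onto [q/Q, (q+1)/Q]; the
   control points are made strictly increasing, giving one global monotone
   piecewise-linear intensity map.
4. Blend: output = α · stretched + (1−α) · input (α = 0.7 by default),
   clipped to [0, 1] and quantized to 8-bit levels (so α = 0 is the exact
   identity on 8-bit input).

A single global map rather than per-patch maps is deliberate: spatially
varying maps introduce patch seams that destroy reference fidelity (VIF)
even while raising contrast. Per-patch work still matters — it supplies the
spatially adaptive, orientation-aware labels the map is built from. Each
patch contributes one diagnostics record (objective before/after, sweeps,
convergence, degeneracy).

## 4. Minimum probability flow (`geomhnn.mpf`)

For bipolar data X = {x¹…xᵐ} and parameters (ψ, ℘), the MPF objective sums
probability flow from each datum to its one-flip neighbors:

K(ψ, ℘) = (1/m) Σ_x Σ_i exp(−x_i φ_i(x)),  φ_i = Σ_j ψ_ij x_j + ℘_i,

since flipping bit i changes the energy by 2 x_i φ_i. K avoids the
partition function, is convex in the parameters, and its gradient is
analytic: with t_i(x) = exp(−x_i φ_i(x)) and g = −(t ⊙ x)ᵀX/m, the weight
gradient is g + gᵀ with the diagonal forced to zero and the bias gradient is
the column mean of −t ⊙ x. `fit_mpf` runs gradient descent with a
backtracking line search; the fitted object is a standard `HopfieldNet`.
`gibbs_sample` draws from the associated Boltzmann distribution by
sitewise sweeps with P(x_i = +1 | rest) = σ(2φ_i), and the planted-model
helper builds a ring Ising network for recovery experiments.

## 5. Metrics (`geomhnn.metrics`)

- **Entropy**: Shannon entropy (bits) of the 256-bin histogram.
- **GLCM**: images are requantized to `levels` gray values; co-occurrences
  are counted for each offset, symmetrized, normalized per offset and
  averaged (default offsets (0,1), (1,0), (1,1), (1,−1)). Contrast is
  Σ p(a,b)(a−b)², homogeneity Σ p(a,b)/(1+|a−b|).
- **VIF** (pixel domain, 4 scales): at each scale the reference/test pair is
  low-passed and downsampled by 2; local means, variances and covariance
  (Gaussian windows, σ = 2, on the 0–255 scale) give per-pixel gain
  g = cov/(var_ref+ε) and residual variance, and the ratio of summed
  log-information terms (visual noise σ²_n = 2) across scales is the score.
  Identical images score 1, an uninformative constant scores ≈ 0.
- **WPSNR**: squared error weighted by the noise visibility function
  w = 1/(1 + var_local/var_max) (3×3 local variance), expressed in dB on
  the 0–255 scale and capped at 100 dB; on a variance-free reference it
  reduces to plain PSNR.
- `evaluate` bundles the five values; `aggregate` reports mean and
  population (default) or sample standard deviation across reports.

## 6. Determinism

Every stochastic choice descends from explicit integer seeds: phantom
texture and degradation noise from their spec seeds, per-patch update
schedules from a seed sequence spawned off the run seed, k-means and Gibbs
sampling from caller seeds. Two runs with the same inputs and configuration
produce byte-identical images and diagnostics.
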