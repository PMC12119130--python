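# Methods

## Data model

An IMS dataset is a matrix `M ∈ R^{m×n}`, rows = pixel spectra, columns =
m/z-bins; all intensities are finite and non-negative. Acquisition-time
clipping (`clip`) zeroes entries below a threshold `k`; the clipped matrix is
stored sparse and its nonzero pattern is, by default, taken as the
observation set `Ω` — the honest view that a clipped entry is *missing*,
not zero. For synthetic experiments where true zeros must remain
distinguishable from missing values, an explicit `ObservationMask` can be
supplied instead. The clipping threshold is an **absolute** intensity; when a
relative ion count is meant, callers convert (e.g. `k = c · base_peak`).

Coordinates are 0-based `(x, y)` with `x` the grid column, row-major
linearization; intensities are persisted as 4-byte floats, the width all
storage accounting assumes.

### 5–95%-TIC normalization

Each spectrum is divided by the sum of its **nonzero** intensities lying
between its own 5th and 95th intensity percentiles (linear-interpolation
percentiles). Trimming removes base-peak and near-noise leverage. Rows whose
trimmed sum is zero pass through unchanged with a warning. The operation is
idempotent to 1e-9 because the trimmed sum of a normalized row is exactly 1.

## Solvers

### Singular value thresholding (SVT)

For `min ‖X‖* s.t. P_Ω(X) = P_Ω(M)` the solver iterates

```
X_k = shrink(Y_{k−1}, τ),   Y_k = Y_{k−1} + δ · P_Ω(M − X_k),
Y_0 = k₀ · δ · P_Ω(M),  k₀ = ⌈τ / (δ‖P_Ω(M)‖₂)⌉,
```

where `shrink` soft-thresholds singular values at `τ`. The dual `Y` lives
only on `Ω` (asserted by the test suite), the primal is kept factored, and
residuals are evaluated entry-wise on `Ω`, so no dense `m×n` array appears on
the iterative path. Stopping: relative Frobenius residual on `Ω` ≤ `tol`
(default 1e-4) or `max_iter`; a residual exceeding 10× its initial value for
50 consecutive iterations raises a divergence error with diagnostics.

Parameter surfaces: `tau=None`/`delta=None` select the canonical auto-rules
`τ = 5√(mn)`, `δ = 1.2/p` (`p` = sampling fraction), appropriate for
**uniform** sampling. The preset configurations in `svt.PRESETS` /
`fpc.PRESETS` carry the published experiment settings (SVT: δ=1, τ=1e-3 for
the threshold-sampling runs; δ=1.7, τ=0.5 for the large TOF runs; FPC: δ=1.4,
τ=1e-3 and δ=1, τ=1.5e-2 respectively). Those τ values are orders of
magnitude below the canonical recommendation; with them SVT behaves as a
near-interpolator whose rank is controlled post hoc by
`baselines.truncate_rank` (mirroring the published protocol of truncating
solutions to a fixed rank). Both surfaces are exposed; neither is rescaled to
agree with the other. Note that the aggressive auto-step `δ = 1.2/p` can
oscillate on strongly coherent threshold-sampled masks — for scheme-α data
use the δ=1 preset.

### Fixed point continuation (FPC)

For the noise-tolerant program `min ‖X‖* s.t. ‖P_Ω(M−X)‖_F² ≤ σ` the solver
runs proximal gradient steps `X_{k+1} = shrink(X_k − δ·P_Ω(X_k − M), δτ)`
from `X_0 = 0`, stopping when the observed squared residual reaches `σ`, the
relative iterate change falls below `tol`, or `max_iter`. τ is held fixed
(single-knob interface; a continuation schedule can be layered on by the
caller re-invoking with decreasing τ). `σ` defaults to 0; the recommended
setting from a noise estimate `sd` is `σ = |Ω|·sd²`. Auto-rules: `δ = 1`
(safe for the unit-Lipschitz masked gradient), `τ = 0.01·‖P_Ω(M)‖₂`
(separates signal singular values from the noise floor). Debiasing is off:
at full observation the fixed point is the soft-thresholded SVD, whose
singular values sit exactly `δτ` below the truncated SVD's.

Two execution modes: *dense* (reference; keeps an `m×n` iterate and refuses
matrices above `dense_budget_gb`, default 1 GB, reporting the required
footprint) and *factored* (iterate as factors plus a sparse gradient on `Ω`,
shrinkage applied to a sparse-plus-low-rank linear operator). The modes agree
to 1e-6 on small instances (tested).

### Partial SVD

`svd_shrink` uses a dense LAPACK SVD when `min(m,n) ≤ 400`; above that it
grows an iterative partial SVD (ARPACK on the sparse matrix or on the
sparse-plus-low-rank operator) by `svd_rank_increment` (default 10) until the
smallest retained singular value crosses τ, falling back to a dense SVD only
if the spectrum never crosses τ at full rank. Non-finite input is rejected;
ARPACK non-convergence is reported with the achieved count.

### Divide-factor-conquer (DFC)

`partition_columns(n, t, seed)` shuffles columns and splits them into `t`
blocks whose sizes differ by at most one. Each block is completed
independently (blocks are independent; execution order cannot affect
results). The conquer step sketches the concatenated block reconstructions
with per-block Gaussian test matrices (`ℓ = Σ block ranks + oversampling`,
oversampling 10), orthonormalizes the sketch (QR), projects every block onto
the resulting basis and takes a small SVD of the projected matrix. Whenever
`ℓ` covers the true combined rank — always the case here, since block ranks
are known — randomized range finding is exact up to floating point, which is
why `t=1` reproduces the base solver to 1e-8 and why the merge is
permutation-equivariant. The final rank is at most the summed block ranks,
truncatable via `rank_cap`; singular values below `1e-12·s₁` are dropped.

## Baselines

Peak picking operates on the dataset-wide summed spectrum (column sums):
`top_bins` takes the `k` largest, `local_maxima` first restricts candidates
to bins strictly exceeding both neighbours; ties break toward the lower bin
index. The reduced representation is the `m×k` column slice (optionally
integrated over ±halfwidth windows, off by default). For error comparisons
the non-selected columns count as zero — the footprint-matched convention.
Truncated SVD uses the dense GESDD path below min-dimension 500 and ARPACK
above; Eckart–Young guarantees it dominates every same-rank column selection,
which the suite verifies by brute force on small instances.

## Metrics

Reconstruction, imputation and global errors are
`‖P_S(M̃ − X)‖_F / ‖P_S(M̃)‖_F × 100%` for `S = Ω, Ω^c`, all entries; they are
evaluated in 256-row blocks against the factored model, never densifying
`X`. A zero-norm reference subset raises `DegenerateSubsetError` rather than
returning a number. The squared global error decomposes exactly over the
disjoint supports (tested to 1e-9 relative). Spectral error scores are the
same relative error per spectrum, restricted either to the dataset-wide
top-`k` bins by summed intensity or to each spectrum's own top-`k` bins;
rows with zero restricted norm are flagged, not scored.

Storage accounting: GB = 1e9 bytes, 4-byte values; dense = `m·n`,
`k`-peak picking = `m·k`, rank-`k` two-factor = `(m+n)·k` (singular values
are negligible and uncounted); compression factors are rounded half away
from zero to integers. These conventions reproduce every printed
footprint/compression pair of both published dataset geometries. Two caveats
are deliberate: the published rank-100 truncated-SVD row is
footprint-*matched* to the 123-peak representation rather than following the
two-factor rule, and the published sparse-format compression factors are
internally inconsistent with the published sparse footprint under any single
bytes-per-nonzero convention, so sparse CSC footprints are reported under
this package's own convention (4-byte value + 4-byte row index per nonzero,
8-byte column pointers) and never asserted against the published numbers.

## Phantom generator

The phantom is `truth = A·Bᵀ`: `A` (pixels × regions) holds smoothed,
rectified Voronoi-cell region images with within-region texture —
spatially coherent, essentially disjoint compartments; `B` (bins × regions)
holds sums of Gaussian peak profiles (default width 2 bins), each peak
assigned to one region, every region owning at least one peak. Near-isobar
pairs are planted as peak pairs separated by 1.5σ (closer than the 3σ
resolution limit) with equal amplitude and *different* regions: they merge in
the summed spectrum but their ion images decorrelate (|Pearson r| < 0.5,
tested). Dense Gaussian noise is added at `noise_sd` × signal RMS, then
clipping is applied **after** noise, at the intensity quantile retaining
`clip_density` of all entries (±0.5 percentage points verified; defaults:
40×40 grid, 500 bins, rank 4, 24 peaks, 1% noise, 8.9% density — the
sampling rate of clipped TOF acquisitions). Same seed ⇒ bit-identical
phantom.

What the phantom does **not** emulate: isotope envelopes, mass-accuracy
drift and peak-shape differences between TOF and FT-ICR instruments,
chemical/speckle noise, and the heavy-tailed intensity distributions of real
tissue. Passing the property suite therefore demonstrates correctness of the
solvers and metrics under the stated low-rank-plus-noise-plus-clipping
model, not reconstruction quality on any particular real dataset. One
numerical consequence of the noiseless phantom: far from peaks the Gaussian
tails underflow toward zero, so density quantiles taken on *noiseless*
phantoms can land in the denormal range and make imputation denominators
degenerate — realistic (noisy) settings avoid this, and the degenerate case
raises an explicit signal rather than a number.

## Problem sizes and tolerances

The property suite runs at deliberately compact sizes chosen to exercise
every code path while keeping the default test run fast: 60×60 / 60×90
completion instances over 3–5 seeds, 10×8 brute-force subset oracles over
50 instances, 40×40×500 phantoms. Orthonormality of factors is enforced to
1e-8; factor round-trips are exact at float32; solver stopping tolerances
default to 1e-4 (SVT, relative on Ω) and 1e-6 iterate change (FPC in
noise-budget mode).

## Known limitations

- SVT with the published tiny-τ settings interpolates rather than
  regularizes; rank control then rests entirely on post-hoc truncation.
- The canonical auto-step `δ = 1.2/p` assumes incoherent uniform sampling
  and can oscillate under threshold (scheme-α) sampling.
- Imputation of threshold-clipped entries is intrinsically poor (they are
  missing-not-at-random); the package reports it honestly rather than
  correcting for it.
- Out-of-core execution is limited to chunked column reading from the HDF5
  store; there is no distributed solver.
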