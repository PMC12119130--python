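# msicomplete

Sparse-format-aware low-rank matrix completion for imaging mass spectrometry
(IMS) data reduction.

## The problem

An IMS experiment records a full mass spectrum at every pixel of a tissue
section, producing a matrix `M ∈ R^{m×n}` with `m` pixels (spectra) as rows
and `n` m/z-bins as columns; a column rearranged onto the pixel grid is an
*ion image*. Modern instruments routinely produce matrices with hundreds of
thousands of rows and columns — terabytes in dense form — so the data are
reduced, classically by **peak picking**: keeping only a few hundred selected
m/z-bins. Peak picking discards everything between the picked bins, silently
losing low-intensity species and near-isobars (distinct species at almost the
same m/z).

Many instruments additionally **clip** intensities at acquisition time,

```
f(M)_ij = M_ij  if M_ij ≥ k,   else 0,
```

leaving ~9% of entries stored and the rest *missing*, not zero. `msicomplete`
treats them as such: with `Ω` the index set of observed entries and
`P_Ω` the sampling operator that zeroes everything outside `Ω`, it seeks a
low-rank matrix `X` approximating `M` through nuclear-norm minimization

```
min ‖X‖*  s.t.  P_Ω(X) = P_Ω(M)          (SVT — equality constrained)
min ‖X‖*  s.t.  ‖P_Ω(M) − P_Ω(X)‖_F² ≤ σ  (FPC — tolerates dense noise)
```

solved by **singular value thresholding** (SVT: sparse dual on `Ω`, shrinkage
on singular values) and **fixed point continuation** (FPC: proximal gradient
with a noise-energy budget σ). A **divide-factor-conquer** (DFC) wrapper
splits the columns into blocks, completes each block independently, and
merges the block factors by randomized projection, so matrices that cannot be
SVD'd whole remain tractable. The resulting factorization `X = U·diag(s)·Vᵀ`
stores `(m+n)·r` values instead of `m·n` — a footprint comparable to peak
picking while preserving the *full* spectral profile at every pixel.

The package also ships the comparison baselines (peak picking over the summed
spectrum, truncated SVD), the standard evaluation arithmetic (reconstruction
/ imputation / global relative Frobenius errors, per-spectrum spectral error
scores, storage footprints and compression factors), a phantom generator
with exact ground truth, imzML import, an HDF5 sparse store, and a CLI.

## Worked example

```python
import numpy as np
from msicomplete import (PhantomSpec, SolverConfig, make_phantom, svt_complete,
                         model_error, pick_peaks, storage_accounting)
from msicomplete.baselines import truncate_rank

# rank-4 phantom: 40x40 pixels, 500 bins, 1% noise, clipped to 8.9% density
ph = make_phantom(PhantomSpec(grid=(40, 40), n_bins=500, n_regions=4,
                              n_peaks=24, noise_sd=0.01, clip_density=0.089, seed=0))
res = svt_complete(ph.observed, ph.mask,
                   SolverConfig(delta=1.0, tau=1e-3, tol=1e-4, max_iter=300))
F = truncate_rank(res.factors, 4)
truth = ph.observed.replace_values(np.maximum(ph.truth, 0.0))
for subset in ("observed", "missing", "all"):
    print(subset, model_error(truth, F, ph.mask, subset))
```

prints (formatted):

```
observed: 1600 pixels x 500 bins, retained density 0.089, clip threshold 0.262
SVT solution rank 138, truncated to rank 4
   observed error vs ground truth:   1.95%
    missing error vs ground truth:  83.82%
        all error vs ground truth:   7.16%
  peak picking (4 bins) global error:  77.95%
rank-4 two-factor footprint: 33.6 kB (compression x95 vs dense)
```

Reading: the completion fits the observed (high-intensity) entries to ~2%,
imputes the clipped low-intensity entries only roughly (they are
threshold-sampled, the hardest regime for completion), yet the *global* error
stays at 7% because clipped entries carry little Frobenius mass — while peak
picking at the same rank loses 78% of the spectral energy outright.

## Command line

```bash
msicomplete simulate --spec spec.json --out phantom.h5
msicomplete mask phantom.h5 --scheme beta --fraction 0.089 --seed 1 --out mask.h5
msicomplete factorize phantom.h5 --method svt --mask-file mask.h5 --out factors.h5
msicomplete evaluate phantom.h5 factors.h5 --mask-file mask.h5
msicomplete render phantom.h5 --bin 120 --out ion.png
```

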