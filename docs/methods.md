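# Methods

## Reconstruction model

A hyperspectral Raman acquisition is held as a matrix `X` with one row
per pixel (row-major over the spatial grid) and one column per
wavenumber channel. Chemical sparsity — the assumption that every
pixel spectrum is a nonnegative mixture of a few pure-component
spectra — makes `X` approximately low-rank, which is what random
spectral under-sampling exploits. Sampling keeps an exact count of
`round((1 − s)·L)` channels per spectrum, drawn uniformly without
replacement and independently across pixels (an entrywise Bernoulli
scheme is also provided); independent per-pixel masks maximize the
incoherence the completion relies on, and the exact count makes the
acquisition saving exactly `1/(1 − s)`.

Recovery minimizes the unconstrained Lagrangian
`F(X) = ½‖P_Ω(X − M)‖²_F + λ‖X‖_*` by FISTA. The proximal operator of
the nuclear norm is singular value thresholding (soft-thresholding of
the singular values); the gradient operator `P_Ω` is a projection, so
its Lipschitz constant is 1 and any step ≤ 1 is safe (default 1).
Momentum follows `t_{k+1} = (1 + √(1 + 4t_k²))/2`; when a momentum step
increases the objective, the iteration restarts with a plain proximal
step from the previous iterate, which is monotone by construction, so
the reported objective trace never increases. Iteration stops when the
relative objective change falls below `tol` (default 1e-6) or at
`max_iter` (default 500); non-convergence is reported in the result,
not raised. Initialization is the zero-filled observed matrix; a
warm-start argument supports continuation. Full SVDs are used
throughout (the spectral dimension in all study conditions is ≤ 512
columns, where a full factorization is both exact and fast).

Two rules choose λ. The default is `λ = c·σ_max(P_Ω(M))` with
`c = 0.01` — scale-equivariant and cheap; the alternative hides a
further 10 % of the observed entries and scans
`λ/σ_max ∈ logspace(−5, −1)` descending with warm starts, returning the
λ with the lowest held-out error. Continuation matters: without warm
starts the small-λ end of the grid is under-converged at a fixed
iteration budget and the scan systematically over-picks λ.

The library-level `complete_cube` clamps observed entries back to their
measured values by default (observations are trusted). The study
sweeps instead score the solver's low-rank estimate at every entry —
that is what a downstream consumer of a compressive acquisition sees,
and the raw-vs-processed ordering effect on tissue data lives exactly
in what that estimate keeps or drops.

## Preprocessing chain

Default order: baseline → despike → smooth → normalize, applied
independently per spectrum.

- **Baseline**: clipped-refit polynomial. Fit a degree-`poly_order`
  polynomial, replace every point above the fit by the fit, refit;
  20 iterations. Default degree 3: it matches the curvature scale of
  fluorescence backgrounds, and measurably preserves broad Raman bands
  that a degree-5 fit starts to eat (on the synthetic mixtures the
  degree-5 fit bowed ~0.1 of the unit peak scale into the overlapped
  1640/1660 region, capping full-chain fidelity at ~0.95 correlation
  with the generating signal; degree 3 keeps it above 0.997).
- **Despike**: a channel is replaced by its 5-point running median only
  when its deviation from that median exceeds `k·σ̂` with `k = 8`. The
  robust scale `σ̂` is estimated from first differences
  (`MAD(Δy)·1.4826/√2`), not from the median residual itself — the
  residual has an atom at zero (the center point frequently *is* the
  window median), which depresses its MAD and caused false corrections
  of ordinary noise at the same `k`.
- **Smoothing**: Savitzky–Golay, window 9, order 3, polynomial edge
  handling. Exact on polynomials up to the filter order.
- **Normalization**: divide by the per-spectrum maximum (exact max 1).

## Evaluation endpoints

**Concentration regression.** PLS (latent variables maximizing the
covariance between spectra and water fraction; 2 components by default,
the chemical rank of a two-component mixture) validated
leave-one-concentration-out: all replicates of one level are held out
together, so every spectrum is predicted by a model that never saw its
level. Reported: held-out R², per-level CV (`100·sd/mean`, sample sd),
and the LoQ — the smallest tested level `c*` such that every tested
level ≥ `c*` keeps CV < 2 %. This tail-based reading (rather than
"first passing level") lets a single failing lowest level move the LoQ
up exactly one grid step.

**Cell imaging.** k = 2 clustering of the fully preprocessed spectra
gives the cell-vs-background map; pixel agreement with the ground
truth after label alignment is the cell-boundary accuracy. Drug
detection thresholds the intensity at the channel nearest 1168 cm⁻¹ on
the *shape-preserving* stage of the chain (baseline/despike/smooth,
before max-normalization: normalizing near-empty background spectra
amplifies pure noise to unit scale and erases the absolute intensity
scale a peak threshold needs). The default threshold rule is
`mean + 3·sd` — an outlier rule, because a 3 %-prevalence class cannot
dominate an intensity histogram: an Otsu split on this three-population
histogram separates background from cell instead, and at high sparsity
it always labels the upper noise tail as drug. Drug accuracy is
recall on true drug pixels, so an empty detection scores exactly 0 %.

**Tissue imaging.** PCA on the spectra (first 10 scores) followed by
k = 3 clustering; labels aligned to the truth by exhaustive permutation
(k ≤ 8, lexicographic tie-break) or Hungarian assignment above.
Loading similarity between the sparsified run and the level-0 reference
is |cosine| per component with a 0.95 threshold; the reported prefix is
the number of leading components that match. The two sweep orderings
differ only in where the mask is applied: `raw_first` masks the raw
spectra, completes, then preprocesses; `processed_first` preprocesses
first and masks the cleaned spectra.

k-means uses Lloyd iterations from 10 seeded random initializations
(lowest inertia wins); PCA loadings carry a deterministic sign
convention (largest-magnitude element positive).

## Synthetic data generator

Endmembers are sums of Lorentzian peaks (the natural Raman lineshape;
Gaussian available) with band positions borrowed from standard
biological assignments (phenylalanine 1003, CH₂ 1440–1450, amide I
~1660, lipid 1064/1298 cm⁻¹). The default axis spans the fingerprint
region 600–1800 cm⁻¹ with 300 channels (4 cm⁻¹ sampling). All draws
come from a seeded generator: identical specs reproduce identical data.

- **Mixtures**: `f/100·water + (1 − f/100)·protein` for water fractions
  60–80 % in 2 % steps, 10 replicates per level, additive noise
  sd 0.01 and a mild baseline (0.05) by default. The water stand-in's
  broad OH-bend band uses a Gaussian profile: Lorentzian tails of a
  100 cm⁻¹-wide band would raise the inter-peak floor everywhere, which
  no polynomial baseline can leave untouched.
- **Cell scene** (32×36 px): an elliptical cell (cytoplasm) on a weak
  background; the drug class occupies 3 % of pixels as contiguous blobs
  grown inside the cytoplasm, its spectrum `0.6·cytoplasm + probe`. The
  probe signature is deliberately trace-level — a 1168 cm⁻¹ marker of
  amplitude 0.35 and width 12 cm⁻¹ (3 channels) against cytoplasm bands
  of ~0.9 — so detection genuinely hinges on a narrow minor peak, the
  regime in which rare-component recovery is hard. Noise sd 0.04.
- **Tissue scene** (65×145 px full size; 16×36 in tests and sweeps):
  three layered classes with wavy boundaries under a per-pixel smooth
  fluorescence curve (cubic with random nonnegative coefficients,
  amplitude 20× the peak scale — typical of visible-excitation tissue
  autofluorescence) plus shot-like noise (sd `0.05·√signal`). The
  cubic baseline is exactly removable by the degree-3 baseline fit and
  spans ≤ 4 extra singular directions.
- **Spikes**: optional single-channel positive excursions, one per
  pixel with a given probability.

With baseline and noise off, every generated matrix has numerical rank
equal to its number of distinct class spectra — the oracle the
completion tests lean on.

What the generator does *not* emulate: instrument optics and spatial
point-spread, wavenumber calibration error, detector nonlinearity,
spatially correlated noise, or the measured spectra of any real
substance. Passing sweeps on this generator demonstrate that the
pipeline reproduces the *mechanisms* — low-rank recovery, rare-signal
loss under thresholding, fluorescence-dominated reconstruction — not
that any particular instrument would yield the same numbers.

## Problem sizes and numerical choices

The sweeps run at 32×36×300 (cell), 16×36×300 (tissue) and 110×300
(mixtures) with 10 seeds per level and a 300-iteration completion
budget; these sizes keep a full sweep in the minutes range on a single
CPU while preserving every qualitative effect. Degenerate inputs are
rejected loudly (empty mask rows, non-positive normalization maxima
with pixel coordinates, zero-variance targets). Label-alignment ties
break to the lexicographically smallest permutation; the completion
benchmark uses `tol = 1e-12` and holdout λ, where recovery of rank-≤3
40×60 matrices from 50 % sampling is ~2·10⁻⁵ median relative error.

## Known limitations

- Nuclear-norm completion shrinks whatever energy sits below λ; a
  component present in a few pixels only (the drug blobs) is the first
  casualty as sparsity grows. This is a property of the method, and the
  cell study is designed to expose rather than hide it.
- Minimum-nuclear-norm recovery of individually missing entries is not
  guaranteed when the missing entry is the dominant element of its
  matrix (the completion legitimately prefers a smaller value); the
  unit tests encode a case where recovery provably holds.
- The raw-first tissue arm depends on the fluorescence-to-peak ratio;
  with a background only a few times the peak scale, per-spectrum
  preprocessing after completion can still rescue the clustering.
- The LoQ is only resolved to the tested concentration grid, and is
  undefined ("none") when even the highest level fails the CV rule.
- Delimited-table ingestion covers generic external spectra; no vendor
  instrument formats are parsed.
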