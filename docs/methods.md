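# Methods

## Spatial point-pattern statistics

The condensation readout treats detected chromatin dots as a 2D point
pattern in a rectangular observation window (a nucleus crop or ROI). Two
summaries are computed from the ordered pair distances:

- **g(r)** (radial distribution function): the density of pairs in the ring
  [r, r + Δr) relative to the uniform expectation,
  g(r) = [S/(N−1)] · 1/(π(2rΔr + Δr²)) · (1/N) · n_ordered(r ≤ r_ij < r+Δr).
  Ring membership is half-open (ties go to the left-closed ring), and the
  ring width Δr defaults to 0.2 μm.
- **K/L/H**: K(r) = S/(N(N−1)) · n_ordered(r_ij ≤ r); L(r) = √(K/π);
  H(r) = L(r) − r. L is monotone by construction, so the peaked statistic is
  H; its argmax (excluding r = 0) is reported as the cluster scale, and only
  when max H > 0 — under CSR, H fluctuates around 0 and no scale is
  reported.

**No edge correction is applied.** The window area S is the only geometry
term, so both estimators are biased low at radii comparable to the window
size (for a 100 μm window the bias at r = 2 μm is ≈ 2–3%). A warning is
emitted when r_max exceeds half the shorter window side. Analyses should
keep r_max well below the window scale, as all defaults do.

Both estimators are validated against an independent brute-force O(N²) pair
enumeration (counts exact, values to 1e−12 relative) and against analytic
expectations: g ≡ 1 and L ≡ r under CSR, and the closed-form Thomas-process
K(r) = πr² + (1/κ)(1 − e^{−r²/4σ²}).

**Dot detection** converts 8-bit images to patterns: threshold (Otsu by
default, overridable), 8-connected components, minimum area 4 px,
intensity-weighted centroids in μm. Equivalent diameter per component is
2·√(area/π). ROI-based summaries compute the statistics per rectangular ROI
with the ROI-local window area (whole-image area analysis is available by
passing one full-frame ROI), then average curves pointwise, retaining
per-ROI curves and the pointwise SD.

## Synthetic point patterns

- **CSR**: exactly n i.i.d. uniform points (binomial process) — the null
  for an unclustered pattern. Defaults: 100×100 μm, n = 5000, matching the
  scale of a nucleus-sized field with thousands of detected dots.
- **Thomas process**: Poisson(κ·S) parents uniform in the window, each with
  Poisson(μ) offspring displaced by isotropic Gaussian(σ). Chosen as the
  condensation model because its K-function is closed-form, so cluster
  statistics have an analytic oracle. Defaults κ = 0.02 /μm², μ = 50,
  σ = 0.15 μm give ≈ 2500 points in 50×50 μm with sub-micron clusters, the
  regime where the H-peak sits at a few hundred nanometers. Offspring
  falling outside the window are **discarded** (no toroidal wrap), matching
  the uncorrected estimators downstream; with σ approaching the window size
  this thins the pattern toward a near-uniform remainder.

## Contact-matrix model and statistics

The simulator draws symmetric Poisson counts around
λ_ij = depth · s^(−α) · τ^[same TAD] · (1 + A·e_i·e_j), s = |i−j| in bins
(clipped to 1 on the diagonal). `depth` is the expected count at one-bin
separation; defaults depth = 100–300 give realistically noisy matrices at
10 kb bins. τ ≥ 1 multiplies within-TAD pairs; e ∈ {±1} with amplitude
A ∈ [0, 1) plants a compartment checkerboard.

- **Balancing** is iterative correction: marginals are equalized until
  their coefficient of variation < 1e−5 (≤ 200 iterations), then scaled so
  unmasked rows sum to 1. Low-coverage bins are masked when their log10
  marginal falls over 5 MADs below the median; because the MAD collapses on
  near-uniform coverage (and would then mask perfectly healthy bins), the
  masking margin is floored at 0.5 dex (~3-fold below median). Masked bins
  are NaN in the balanced matrix and excluded from every downstream
  statistic.
- **P(s)**: mean contact value per log-spaced separation bin (8 per
  decade), pooled across chromosomes and normalized to sum to 1 over the
  included separations; the normalization makes the curve invariant to
  sequencing depth. The decay exponent is estimated by a log–log linear fit
  over mid-range separations (defaults 30 kb – 1 Mb in the recovery
  analyses) where neither the diagonal nor the chromosome end dominates.
- **Insulation**: for each bin, the mean contact in the w×w diamond
  crossing it (w = window/bin_size, defaults 500 kb / 10 kb), as log2 over
  the chromosome-wide diamond mean. On a uniform matrix the score is
  exactly 0; it is undefined (NaN) within w bins of the chromosome ends; a
  diamond with zero total contact scores −inf, the perfectly insulating
  limit. Insulation accepts balanced or raw matrices: balancing exists to
  remove experimental coverage bias, and applying it to a simulated matrix
  with uniform detection efficiency redistributes genuinely TAD-structured
  coverage — empirically this flattens the insulation valley floor and
  displaces minima by ~3 bins from planted boundaries — so recovery
  analyses on simulated matrices score the raw counts, while the CLI
  balances file input by default.
- **Boundaries**: local minima of the insulation track, with strength
  defined as topographic prominence (the smaller rise from the minimum to
  its bounding maxima on either side, within the contiguous defined
  segment). On a clean V-shaped valley this equals the rise to the nearest
  flanking maxima; under Poisson noise it ignores sub-threshold wiggles
  inside a valley instead of truncating at them. Boundaries with
  strength > 0.1 (log2 units) are retained.
- **Boundary matching**: each boundary bin is extended ±50 kb into a 110 kb
  zone (half-open intervals); zones that overlap are candidate matches,
  resolved one-to-one greedily by increasing center distance. One-to-one
  matching guarantees the Venn arithmetic |A| = shared + A-specific exactly.
- **Compartments**: observed/expected (expected = per-separation mean over
  unmasked pairs), Pearson correlation of O/E columns over unmasked bins,
  leading eigenvector by full symmetric eigendecomposition. The sign of an
  eigenvector is arbitrary, so orientation requires a covariate (planted
  labels for synthetic data, GC content for real data): the track is
  flipped to correlate positively with it, or flagged unoriented. A bin is
  A where e1 > 0 and B where e1 < 0. When the leading eigenvalue is less
  than twice the second, no dominant compartment signal exists and the
  track is flagged low-confidence (the A = 0 null lands here).
- **Switches and strength**: switch fractions are counted over bins
  assigned in both oriented tracks. Compartment strength is the mean O/E
  within AA, BB and across AB pairs at |i−j| ≥ 2 bins (excluding the
  diagonal region).

## FRAP

Double normalization, in this order: (1) bleach-correct the bleach-ROI
trace by mean_pre(R)/R(t) using the unbleached reference ROI — a shared
multiplicative acquisition decay cancels exactly here; (2) anchor so the
pre-bleach mean of the corrected trace is 1 and its post-bleach minimum
is 0. The minimum is taken over corrected values so reference noise cannot
shift the anchor; both anchors hold to 1e−12 by construction. A flat trace
(denominator 0) is rejected as "no bleach detected".

The optional fit is nonlinear least squares of
V(t) = M·(1 − e^{−t·ln2/t_half}) on post-bleach frames, with t measured
from the first post-bleach frame and M bounded to [0, 1.5]. The simulator's
defaults (M = 0.6, τ = 10 s, bleach depth 0.8, 5 pre + 60 post frames at
1 s) emulate a one-minute recovery movie; with 2% Gaussian noise the fitted
M is unbiased to within ±0.01 over seeds.

## What the generators do and do not emulate

The synthetic data reproduce the statistical structure the estimators
assume — uniform or Thomas-clustered dots, power-law contact decay with
block TADs and a two-state checkerboard, single-exponential FRAP recovery —
with Poisson count noise and Gaussian intensity noise. They do **not**
model microscope PSFs or segmentation artifacts, polymer dynamics, loop
anchors/peaks, translocations, copy-number or mappability-driven coverage
bias, multi-exponential or diffusion-limited FRAP kinetics. Passing
recovery tests therefore demonstrates the correctness of the estimators
under their stated assumptions, not robustness to every artifact of real
data.

## Problem sizes and numerical choices

Validation analyses use desk-scale sizes chosen to keep Monte-Carlo error
well inside the tolerances: 10 seeds × 5000 points for the CSR null,
20 seeds of the default Thomas process for the closed-form K comparison,
5 seeds of 500-bin chromosomes for boundary recovery (10 boundaries planted
inside the insulation-defined region, since scores are undefined within
w = 50 bins of the ends), 300-bin chromosomes for compartment recovery, and
20 FRAP traces for mobile-fraction recovery. Ties at ring edges go left;
eigendecomposition uses LAPACK `eigh` on the dense correlation matrix
(matrices here are ≤ a few thousand bins); the balancing fixed point leaves
an already-doubly-stochastic matrix unchanged. All generators are
bit-reproducible per seed.

## Known limitations

- No edge correction in g/K (documented bias at large r).
- Insulation and boundary statistics are single-chromosome; pooling across
  chromosomes is the caller's loop.
- The compartment eigenvector is computed at the analysis bin size directly
  (10 kb by default); very sparse real matrices may need coarser bins,
  which is a parameter, not a code change.
- The one-tailed Mann–Whitney comparison of insulation distributions is a
  convenience wrapper around scipy and assumes independent samples; bins
  are spatially correlated, so its p-values on per-bin scores are
  optimistic and should be interpreted per replicate, not per bin.
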