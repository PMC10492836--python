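# chromoquant

Quantitative analysis of drug-induced chromatin condensation and 3D-genome
reorganization. The package targets the workflow used to characterize
chromatin after treatment with condensation-inducing drugs such as
adriamycin (doxorubicin): super-resolution images of stained nuclei show
chromatin collapsing into micron-scale puncta, while Hi-C shows weakened TAD
boundaries, A/B compartment switching and strengthened B–B contacts, and
FRAP reports the mobility of molecules inside the condensates. It is aimed
at imaging and chromosome-conformation labs that need these statistics on
desk-scale data, together with synthetic ground-truth generators to validate
every stage.

## What it computes

**Spatial condensation statistics** on 2D dot patterns (from TSV point sets
or 8-bit TIFF images via dot detection). For N points in a window of area S:

- radial distribution function, in rings of width Δr (default 0.2 μm):

  g(r) = [S/(N−1)] · 1/(π(2rΔr + Δr²)) · (1/N) Σᵢ Σ_{j≠i} δ(r − r_{i,j})

  with g ≡ 1 under complete spatial randomness (CSR);
- Ripley's K(r) = S/(N(N−1)) · #{ordered pairs with r_{i,j} ≤ r},
  L(r) = √(K/π), and the centered H(r) = L(r) − r whose peak location is the
  characteristic cluster radius;
- per-component equivalent diameters and area fraction from dot detection.

**Hi-C conformational statistics** on per-chromosome contact matrices
(dense TSV, default 10 kb bins): iterative-correction balancing,
contact-probability decay P(s), diamond insulation scores (500 kb window),
TAD boundary calling by insulation minima with prominence strength
(> 0.1 = high confidence), boundary matching between conditions via 110 kb
boundary zones (bin ± 50 kb, partial overlap, one-to-one), A/B compartments
from the first eigenvector of the O/E correlation matrix, compartment switch
fractions and within/between-compartment contact strength.

**FRAP normalization**: bleach-ROI traces are corrected with an unbleached
reference region and double-normalized so the pre-bleach mean is 1 and the
lowest post-bleach intensity is 0; an optional exponential fit reports the
mobile fraction and half-time.

**Synthetic data** with known ground truth for all of the above: CSR and
Thomas-clustered point patterns (the Thomas process has the closed-form
K(r) = πr² + (1/κ)(1 − e^{−r²/4σ²}), giving an analytic oracle), contact
matrices with power-law decay, planted TAD blocks and a planted
two-compartment checkerboard under Poisson sampling, and FRAP traces with
exponential recovery plus acquisition photobleaching.

## Worked example

Simulate a clustered nuclear dot pattern and measure its cluster scale:

```sh
chromoquant simulate-points --kind thomas --seed 7 --out dots.tsv
chromoquant lfunction dots.tsv --rmax-um 2 --out lfn.tsv
# cluster_scale_um	0.6
```

The H(r) = L(r) − r curve of this pattern (κ = 0.02 parents/μm², μ = 50
offspring, σ = 0.15 μm) peaks at 0.6 μm — the radius at which clustering is
strongest; a CSR pattern would report `NA`.

Simulate a chromosome with seven planted TAD boundaries and call them back:

```sh
chromoquant simulate-hic --n-bins 500 --depth 300 \
    --tad-boundaries 60,120,180,240,300,360,420 --tad-enrichment 3 \
    --seed 7 --out m.tsv
chromoquant boundaries m.tsv --raw --out b.bed
# n_boundaries	7
head -3 b.bed
# chrS	600000	610000	boundary_60	0.752711
# chrS	1200000	1210000	boundary_120	1.077747
# chrS	1800000	1810000	boundary_180	1.094775
```

All seven planted boundaries are recovered at their planted bins (BED
coordinates are 0-based half-open; the score column is the insulation-valley
prominence, all well above the 0.1 high-confidence threshold).

Simulate and normalize a FRAP trace (true mobile fraction 0.6, τ = 10 s,
with noise and acquisition photobleaching), then fit the recovery:

```sh
chromoquant simulate-frap --noise-sd 0.02 --seed 7 --out f.tsv
chromoquant frap-normalize f.tsv --fit --out fn.tsv
# mobile_fraction	0.6182803074552433
# half_time_s	7.195045679686501
```

The fitted mobile fraction is within noise of the simulated 0.6 (the true
half-time is τ·ln2 ≈ 6.93 s).

The same stages are available as library functions (`chromoquant.compute_rdf`,
`compute_k_l`, `insulation`, `call_boundaries`, `compartments`, …) and as a
config-driven pipeline (`chromoquant run config.yaml`) that writes a JSON
manifest with parameter values and output checksums for reproducibility.

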