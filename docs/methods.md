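# Methods

## The profiling model

A treatment's effect on a bacterial population is summarised by the joint
distribution of per-cell cytological parameters (shape descriptors and
per-channel fluorescence statistics). The working assumption of the
concordance analysis is purely geometric: treatments with the same
mechanism of action produce overlapping per-cell distributions, and
treatments with different mechanisms produce separated ones. No
parametric form is assumed at analysis time; the confidence ellipses are
moment-based summaries of each treatment's first two principal-component
scores.

### Pairwise PCA

PCA is computed per treatment *pair*, not globally: the query's cells and
one reference's cells are pooled, each parameter is centred by the pooled
mean and scaled by the pooled sample SD (n−1 denominator), and the
standardised matrix is decomposed by SVD. Pooled centring/scaling puts
both treatments into a single comparable space; a per-treatment
standardisation would erase exactly the between-treatment displacement
the method measures. Zero-variance parameters are dropped with a warning
before scaling (a constant column has no standardised value). Each
loading column's sign is fixed so that its largest-magnitude entry is
positive, removing the arbitrary sign of singular vectors so repeated
runs and platform changes give identical score orientations.

Only PC1–PC2 are used downstream. This is a deliberate reduction: the
ellipse-overlap statistic is defined in the plane, and the dominant
between-treatment displacement loads on the leading components.

### Confidence ellipses

For one treatment's scores, the ellipse centre is the mean, the shape
matrix is the sample covariance S, and a point x is inside iff
(x−x̄)ᵀS⁻¹(x−x̄) ≤ r². Two radius rules are provided:

- `t` (default): r² = 2(n−1)/(n−2) · F(level; 2, n−2) — the small-sample
  construction used by common plotting software; correct coverage for
  bivariate-normal scores at moderate n.
- `normal`: r² = χ²(level; 2) — the large-sample rule; at n → ∞ the two
  radii coincide (tested), and on 10⁴ standard-normal scores the normal
  ellipse contains 95% ± 1% of its own points.

Collinear scores (singular S) are an error rather than a degenerate
ellipse: they indicate an upstream problem (e.g. one effective
parameter), and any membership answer would be arbitrary.

### Concordance

Membership is evaluated for every cell of both treatments in the pair
(the union universe), and concordance = |inside both| / |inside either|,
with 0 reported (plus a warning) if the union is empty. The statistic is
symmetric, lies in [0,1], equals 1 for identical score sets and 0 for
well-separated ones, is invariant to relabeling, to parameter column
order and to affine rescaling of any parameter (absorbed by
standardisation), and decreases in expectation as the distance between
treatment means grows — all property-tested, the last against a
Monte-Carlo oracle using analytic ellipses for known Gaussians.

Concordance is computed once on pooled cells (replicates are labels, not
strata); per-replicate averaging is a possible variant but is not
implemented.

### Ranking

`rank_references` (and the `BCPConcordance` model wrapping it) balances
each pair by seeded subsampling to the pair's smallest treatment, runs
the pairwise PCA → ellipse → concordance chain, and sorts by descending
proportion. Per-pair seeds are drawn from one root seed, so a ranking is
reproducible from its provenance record.

## Quality control

Three filters run in a fixed order, each only deleting rows:

1. **Missing data** — any cell with ≥ 1 missing parameter is removed.
2. **Outliers** — per treatment, a cell is removed when |value − mean| >
   k·SD in *any* parameter (default k = 5). Statistics come from the
   pre-removal table in a single pass; the filter is therefore not
   idempotent in general (removing a gross outlier tightens the SD), and
   a constructed counter-example in the tests documents this. Sample SD
   (n−1) is used; zero SD removes nothing on that parameter; a treatment
   with < 2 cells is kept whole with a warning. On clean Gaussian data
   the 5-SD rule removes essentially nothing (P(|z| > 5) ≈ 5.7×10⁻⁷ per
   entry).
3. **Balanced subsample** — n cells per treatment drawn uniformly
   without replacement, seeded; `n=None` uses the smallest per-treatment
   count, so the sparsest treatment sets the common size.

## Imaging front end

Synthetic scenes render rod cells as capsules (spherocylinders — the
idealised *B. subtilis* footprint): a pixel belongs to a cell when its
centre is within width/2 of the cell's central axis segment. Rendering
is additive over a constant background; a nucleoid is an inner capsule
at 60% scale drawn on the DNA channel only when the cell has one.
Coordinates are 0-based (row, col), origin top-left. Cells whose
bounding circle leaves the frame are rejected; overlaps are allowed but
flagged.

Segmentation thresholds the membrane channel (Otsu by default —
parameter-free and adequate for two-level synthetic scenes), labels
8-connected components, optionally expands each object by up to
`expansion_px` (bounded by the phase image where present: new pixels
must stay within the cell interior's phase mean ± 3 SD), and discards
border-touching objects because truncated cells corrupt shape
statistics. Nucleoids are detected the same way on the DNA channel and
assigned to the cell whose mask contains their centroid; cells without a
nucleoid are excluded from feature extraction (the DNA-presence gate).

The default parameter registry emits 39 measures: area, perimeter,
moment-based major/minor axis, eccentricity, solidity, extent,
orientation, form factor (4πA/P²), compactness (P²/4πA), and maximal /
minimal caliper (Feret) diameters; plus, per fluorescence channel
(membrane, dna, permeability): mean, median, SD, min, max, integrated
intensity, mass displacement (distance between intensity-weighted and
binary centroids), and the two quartiles. The registry is configurable;
the 39-parameter default is a reconstruction of a typical
CellProfiler-style measurement set — the count, not the identity of
each measure, is the stable contract. Intensity statistics refuse
channels flagged as deconvolved, since deconvolution redistributes
photon counts and breaks intensity comparability.

A convention worth knowing: the moment-based minor axis of a flat-profile
shape such as a capsule exceeds its geometric width (a uniform
cross-section of width w has moment axis 2w/√3 ≈ 1.15 w). The caliper
diameters (`feret_min`, `feret_max`) are the measures that track the
geometric length and width.

## Synthetic-data model

Feature tables: each treatment's cells are i.i.d. multivariate normal
with a specified mean vector and covariance; replicate labels (default
4, matching a typical four-experiment design) are assigned round-robin
and carry no random effect, because the analysis pools cells across
replicates. Contamination is layered on top: entry-wise
missing-completely-at-random blanks, and gross outliers that displace a
cell by `outlier_scale`·SD (default 10) in exactly one random parameter —
single-parameter contamination makes the k-SD filter's action exactly
predictable in tests. The `moa_panel_specs` defaults (300 cells per
treatment, 0.5% missingness, 1% outliers, five off-mechanism references
shifted 2 SD along two parameter axes each) emulate a realistically
sized profiling experiment in which a few hundred cells per treatment
survive imaging.

What the generator does *not* model — and what passing tests therefore
do not show about real data: non-Gaussian and skewed parameter
distributions, correlations induced by optics (PSF blur, uneven
illumination), replicate-level batch effects, segmentation errors on
touching cells, and any particular real antibiotic's effect size. The
Gaussian mean-shift panel validates the machinery (coverage, overlap
arithmetic, ranking behaviour), not biological effect sizes.

Plates are step functions (blank OD at and above the true MIC, growth OD
below, Gaussian read noise, default growth margin 0.05 OD as the numeric
proxy for "no visible growth"); MIC calls are reported only at the
plate's discrete twofold steps, never interpolated. Dose-response curves
follow the 4PL exactly plus Gaussian noise in percent units.

## 4PL fitting

v(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill), fitted by
least squares on log10 concentration from a fixed 5 × 8 grid of
(log-IC50, Hill) starts with data-driven top/bottom initialisation — a
deterministic multi-start that avoids the local minima of single-start
logistic fits. The exponent is clipped at ±300 to avoid overflow at
extreme starts. Hill is unconstrained in sign; because (IC50, hill, top,
bottom) and (IC50, −hill, bottom, top) describe the same curve, results
are canonicalised to top ≥ bottom. Flat viability or fewer than five
distinct concentrations are rejected as unidentifiable. Noiseless data
are recovered to ≈ machine precision; at 5% noise on a 12-point series
the median relative IC50 error stays below 10% (simulated over 50
seeds).

## Formula arithmetic

Monoisotopic masses come from an embedded table of most-abundant-isotope
masses (CODATA/AME values, ≥ 6 dp); only monoisotopic (not average)
masses are implemented, matching HRESIMS usage. The deprotonated ion is
m/z = M − m(H) + m(e⁻): the electron-mass correction is included, which
is what reproduces four-decimal literature "calcd" values for [M−H]⁻.
Degree of unsaturation = (2C + 2 + N − H − X)/2 with halogens counted
like hydrogen and divalent elements ignored.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make their standard errors
comfortably smaller than the asserted tolerances: 10⁴ points for
ellipse-coverage and moment-convergence checks, 5×10³ per group for the
concordance-versus-oracle grid (binomial SE ≈ 0.005 against a ±0.02
band), 20 seeds for panel-ranking stability, 50 seeds for noisy IC50
recovery, and 100 seeds for noisy MIC recovery. PSD validation of
covariance inputs tolerates eigenvalues down to −10⁻⁸·‖Σ‖ (floating
round-off); ellipse shape matrices must be strictly positive definite.

## Known limitations

- The phase-guided expansion rule (interior mean ± 3 SD) is a simple
  stand-in for proprietary pipeline behaviour; with strong phase texture
  it may under- or over-expand.
- Nucleoid→cell association is by centroid containment only; a nucleoid
  straddling two touching cells is assigned to whichever mask contains
  its centroid.
- The concordance statistic is a fixed-level overlap measure, not a
  calibrated probability of shared mechanism; ranking, not the absolute
  proportion, is the intended readout.
- Images are single-plane; no z-stacks, PSF or deconvolution modelling.
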