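# Methods

## The measurement problem

A mass-cytometry screen of hundreds of protein targets cannot stain every
antibody on every cell: the pool is split across K staining panels, each
combining a **conserved core** (stained on all panels) with
panel-specific **screen markers**.  Any two screen markers from different
panels are never co-measured on a cell, so cell-level co-expression is
unobservable for most marker pairs.  The pipeline's central object is
therefore the **stitched cluster profile**: cells from all panels are
micro-clustered on the conserved core, and each micro-cluster is assigned
the median of every marker over its measured cells.  Because every
micro-cluster contains cells from every panel, the resulting cluster ×
marker matrix is complete (up to support thresholds) and serves as the
co-expression landscape for meta-clustering, redundancy analysis and
marker selection.

## Models and procedures

**Transform and scaling.** Raw ion counts are variance-stabilized with
asinh(x / c), cofactor c = 5 (the mass-cytometry standard).  Each marker
is then divided by its 99.9th percentile over measured cells and clipped
at 1.  Percentiles use linear interpolation between order statistics;
the divisors are returned so runs are auditable.  Per-marker positivity
("detected in at least 0.1% of cells", boundary inclusive) uses cutoffs
derived, by default, as the 99.5th percentile of a designated
negative-control cell set, with per-marker overrides — a stringent rule
that limits false-positive detection calls without inventing per-marker
constants.

**Micro-clustering.** Default is a g × g self-organizing map
(g = ceil(sqrt(k))) trained batch-wise with a Gaussian neighborhood
shrinking geometrically from g/2 to 0.5 over 20 epochs, followed by
best-matching-unit assignment; empty nodes are dropped and the smallest
clusters merged into their nearest code vector until at most k remain.
Training subsamples at most 20,000 cells (assignment always uses all
cells).  k-means is available as an alternative.  Cells are sorted by id
internally, so both algorithms are deterministic for a fixed seed and
invariant to row order.  The library default k = 400 follows published
practice for ~500k-cell screens; analyses should keep cluster sizes
large enough that per-panel support stays in the tens (see "Bridging
support" below).

**Median bridging.** Cluster medians use the lower-of-two-middles
convention for even counts, so every stitched value is an observed
intensity (ecosystem median conventions differ; this one is fixed and
documented).  An entry with fewer than `min_support` (default 5)
measured cells is recorded missing rather than estimated.

**Meta-clustering.** A k-nearest-neighbor graph (default k = 15,
Euclidean distance; ties broken by cluster index) over the stitched
median vectors, followed by Leiden community detection
(RB-configuration/modularity objective, default resolution 1.0, fixed
seed).  Missing stitched entries are handled by NaN-aware
pairwise-complete distances by default — no value is ever imputed into
the stitched matrix; alternatively all markers with any missing entry
can be dropped.  The number of meta-clusters is an outcome, never a
target.

**Differential testing.** Two-sample Kolmogorov–Smirnov tests between
equally subsampled groups (default subsample: the smaller of 2000 and
the thinnest per-marker measured count), Bonferroni correction over the
per-pair marker family, significance at corrected p < 0.05.  The exact
KS null is used up to n = 200 per group: we measured the asymptotic
tail p-values to be ~25% anticonservative at n = 100, enough to push
the family-wise error above its nominal level; beyond n = 200 the
asymptotic distribution is accurate and fast.

**Minimal-panel nomination.** Greedy set-cover: starting from forced
markers (by convention the conserved gating markers, mirroring how
published panels combine "conventional gating" and "top differential"
columns), repeatedly add the marker separating the most not-yet-covered
cluster pairs, excluding candidates whose |Pearson r| against the
selected set (cluster-level, pairwise-complete) exceeds the redundancy
cap (default 0.8).  Ties break by (coverage gain, max |r|, name), making
the output invariant to marker order.

**Gating.** Immunophenotypes are conjunctions of threshold predicates
(pos/hi: value > t; neg/lo: value ≤ t; med: low < value ≤ high — tie
directions fixed so counts are bit-stable), optionally nested under
parent gates, evaluated in declared precedence order; every cell gets
exactly one label ("ungated" if none match).  The gate table shipped in
the test suite encodes the conventional HSPC scheme; the LMPP gate is
Lin⁻CD34⁺CD38^lo CD90⁻CD45RA⁺ (the common literature definition —
published tables sometimes misprint LMPP identically to HSC).

**Bimodal cutoffs.** For markers like TdT or CD84 a two-component
Gaussian mixture is fitted; the cutoff is the intensity between the
component means where the posterior responsibility crosses 0.5.  The
separation score |μ₂ − μ₁| / sqrt((σ₁² + σ₂²)/2) plus a density-valley
check (mixture density at the cutoff must be < 0.8 of the smaller mode
density) flags unimodal data as low-confidence — a two-component fit of
unimodal data otherwise produces a spurious "cutoff" in a region as
dense as the modes.

**Surrogate ranking.** Candidates are ranked lexicographically: a clean
bimodal split (not low-confidence) is required before |r| is compared,
because a correlated but smeared marker cannot be drawn as a sort gate.
Gate quality is reported as enrichment fold, capture and contamination,
computed as exact rationals on counts.

**Limiting dilution.** Single-hit model P(respond | dose d) =
1 − e^(−f·d).  The MLE solves the score equation on the log-f scale
(Brent bracketing from single-dose closed forms f = −ln(1 − r/n)/d,
tolerance 1e-10); the likelihood is strictly concave in log f for
non-boundary data, and the estimate agrees with a dense grid-search
oracle to < 1e-6 relative in every tested instance.  Wald 95% intervals
on log f use the observed information −f̂²·ℓ″(f̂).  All-negative or
all-positive data are flagged boundary and given one-sided exact bounds
instead of a numeric MLE.  Group comparison is the likelihood-ratio
test against a pooled single-f fit, referred to χ²₁.  Cloning summaries
use exact rational arithmetic before any rounding.

## Synthetic study conditions

The generator draws each marker directly on the asinh scale from a
two-component normal mixture (negative/positive), with
population-specific positive fractions, a per-(donor, marker) additive
normal shift, clipping at zero, and panel assignment independent of
population.  The canonical "well-separated" scenario mirrors the screen
structure: 11 conserved markers, 15 panels × 5 screen markers, 3 donors,
5 populations in geometrically decaying proportions, each population
carrying a distinct binary conserved signature (positive fraction 0.95
vs 0.02, positive mode asinh 4.5 vs negative 0.3 — modes ~8 component
SDs apart) plus two population-specific screen markers; remaining screen
markers are unstructured noise (positive fraction 0.3 everywhere).

What this emulates: split-panel structure, bimodal marker distributions,
donor shifts, unequal population sizes.  What it does not: doublets,
spillover, barcoding errors, acquisition drift, or the continuum between
progenitor states in real bone marrow — real data are a harder
clustering problem than these separated blobs, so recovery figures here
validate the machinery, not expected field performance.

**Bridging support.** The validation scenario uses 50,000 cells with 200
micro-clusters (~250 cells per cluster, ~17 per panel); the published
analysis it emulates had ~1288 cells per cluster (~86 per panel).  At
400 clusters on 50,000 cells (~8 per panel), medians of mixture-valued
markers flip between modes often enough to perturb the landscape — the
cells-per-cluster ratio, not the cluster count, is the quantity to
preserve when scaling down.  Relatedly, the sample median of a bimodal
marker at support ~30 has a normalized-scale dispersion of ~0.02 and a
small but non-negligible probability of landing in the wrong mode; the
stitched-median consistency experiment therefore reports deviation
quantiles alongside the maximum (median ≈ 0.009, 99th percentile ≈
0.03–0.05 normalized units at support ≥ 30).

Validation problem sizes (one CPU, a few minutes total): 50,000-cell
recovery run; 2000 null replicates for the KS family-wise error; 500
replicates for limiting-dilution coverage; 1000 for the LR-test type-I
rate; 1000 random masks for the exact gate identities.

## Numerical and design choices

* Randomness: one root seed per run, expanded into independent
  per-stage seeds via a seed sequence; all recorded in run metadata.
* Euclidean kNN distance (correlation distance is a plausible
  alternative; Euclidean on normalized medians is the default).
* Percentile interpolation rule declared (linear between order
  statistics) because dialects differ across ecosystems.
* Gate thresholds are config inputs on the asinh scale; "med" bands are
  two-sided intervals (no canonical numeric definition of e.g.
  CD123^med exists).
* Paired t-tests are two-sided; frequency ratios are scale-invariant
  (percent or proportion inputs give identical ratios).
* The published 23-marker panel is accepted as a forced list rather
  than a quantity the greedy selector must reproduce — the original
  selection criteria are not fully algorithmic.
* File formats: CSV/parquet tables with NA for unmeasured entries; the
  measured mask is always re-derived from the panel design and
  validated against the NA pattern on load.  FCS ingestion is out of
  scope for this build.

## Known limitations

* Meta-cluster counts depend on the Leiden resolution; on blob-like
  synthetic data resolution 1.0 recovers planted populations, but real
  continua need resolution chosen by the analyst.
* The SOM is a compact batch implementation adequate for conserved-core
  micro-clustering; it does not reproduce any specific published SOM
  implementation node-for-node.
* Boundary limiting-dilution groups (0% or 100% response) get one-sided
  bounds only; comparisons involving them need exact methods outside
  the LR test.
* Percentile normalization is per-dataset; cross-batch harmonization is
  not attempted.
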