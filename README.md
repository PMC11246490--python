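# cytostitch

Analysis pipeline for **split-panel single-cell proteomic screens** of
hematopoietic stem and progenitor cells (HSPCs), with the follow-up
statistics used to characterize sorted progenitor populations.

Mass cytometry measures ~40 antibodies per cell, so screening hundreds of
protein targets requires splitting one cell pool across K staining
panels.  Every panel carries a conserved core of markers (CD34, CD38,
CD45RA, ...) while each panel adds its own screen targets — meaning no
single cell carries all measurements.  `cytostitch` reassembles such a
screen into one co-expression landscape and carries the analysis through
to sortable populations:

1. **Preprocess** — asinh(x/5) transform, per-marker scaling to the
   99.9th percentile, positivity calls ("detected in ≥ 0.1% of cells"),
   and boolean immunophenotype gating (HSC / MPP / LMPP / CMP / GMP /
   MEP / CLP style gate trees).
2. **Panel integration** — micro-cluster all cells on the conserved
   markers (self-organizing map or k-means), bridge every screen marker
   across panels by per-cluster medians, then Leiden-cluster the
   k-nearest-neighbor graph of median vectors into meta-clusters.
3. **Marker selection** — Pearson redundancy at cluster level,
   two-sample Kolmogorov–Smirnov differential tests between equally
   subsampled meta-clusters (Bonferroni-corrected, exact null for
   n ≤ 200), and greedy minimal-panel nomination that recapitulates the
   full clustering with a fraction of the markers.
4. **Surrogate discovery** — rank surface markers as live-sort proxies
   for an intracellular target (the motivating case: CD84^lo as a proxy
   for TdT⁺ lymphoid-primed GMPs) by cell-level correlation and
   mixture-model bimodality; quantify gates by exact enrichment-fold,
   capture and contamination ratios; cross-donor frequency statistics
   with paired t-tests.
5. **Limiting dilution** — single-hit Poisson estimation of progenitor
   frequency f from dose/response well counts, P(respond | dose d) =
   1 − e^(−f·d) (a binomial GLM with complementary log-log link, offset
   log d, slope fixed at 1), Wald intervals on log f, pairwise
   likelihood-ratio tests, and single-cell cloning summaries.

A first-class synthetic-data module (`cytostitch.synth`) generates
screens with known population structure (two-component asinh-scale
mixtures per marker and population, donor effects, panel assignment) and
well plates with known frequency, so every stage is testable without any
external download.

## Worked example

Simulate a 3-panel screen, stitch it, and fit limiting-dilution data:

```
$ cytostitch integrate demo_expression.csv --design design.yaml \
      --k-micro 30 --knn 8 --seed 3
30 micro-clusters -> 3 meta-clusters

$ cytostitch lda fit wells.csv
CD84lo: f = 0.1926 (95% CI 0.1609 - 0.2306)
CLP: f = 0.01062 (95% CI 0.008667 - 0.01301)

$ cytostitch lda compare wells.csv CD84lo CLP
chi2(1) = 400.7, p = 3.82e-89
```

The `integrate` line reports that the three simulated populations were
recovered as three meta-clusters from 30 conserved-marker micro-clusters.
The `lda fit` lines estimate that roughly one cell in five of the CD84^lo
population is an active T-cell progenitor versus one in ~94 for CLPs —
an ~18-fold difference that the likelihood-ratio test shows is not
sampling noise.

The same functionality is available as a library:

```python
from cytostitch import (simulate_screen, percentile_normalize,
                        micro_cluster, aggregate_medians, meta_cluster)
from cytostitch.synth import well_separated_screen_config

cfg = well_separated_screen_config(n_cells=50_000, seed=1)
table, truth = simulate_screen(cfg)
norm, _ = percentile_normalize(table)
micro = micro_cluster(norm, cfg.panel_design.conserved_markers, k=200, seed=2)
profile = aggregate_medians(micro, norm)          # the stitched landscape
meta = meta_cluster(profile, k_neighbors=15, seed=3)
```

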