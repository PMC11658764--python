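# nanocal

Quantitative single-cell analysis of integrin (LFA-1) nanocluster formation
and calcium signalling in time-lapse fluorescence microscopy of crawling
leukocytes — with a fully ground-truthed synthetic-data generator, so every
stage of the pipeline is testable without downloading any imaging data.

## Who this is for

Groups imaging immune cells under flow (e.g. neutrophils crawling on
E-selectin/ICAM-1/chemokine substrates) who record multi-channel confocal
movies — a cytosolic Ca²⁺ reporter such as GCaMP, a labelled β₂ integrin,
optionally F-actin or another protein of interest — and want reproducible,
scriptable versions of the standard readouts:

* **Nanocluster segmentation** — automatic (Otsu) thresholding of the
  integrin channel, connected components, and a physical size gate:
  a region is a nanocluster iff its area is at least **0.15 µm²**
  (2 pixels at the 0.284 µm/px calibration the defaults assume).
* **Compartment intensities** — mean fluorescence intensity (MFI,
  summed intensity / mask area) of any channel inside the nanocluster
  mask and inside the "cluster-negative" compartment (cell mask minus
  cluster mask), averaged over minute windows 0–1, 5–6, 9–10.
* **Spatial aggregation** — Ripley's K over nanocluster centroids,

      K(r) = N⁻¹ ΣᵢΣⱼ≠ᵢ 1[dist(i, j) ≤ r],    r = 0.5 … 5.5 µm,

  with N the number of points, Euclidean distance and ordered pairs.
  A Monte-Carlo envelope from random locations drawn on the cell mask is
  affinely rescaled so its upper bound is +1 and lower bound −1; values
  above 1 mean aggregation, below −1 dispersion. The **aggregation
  index** is the mean number of supra-envelope radii per cell/timepoint
  (cells with < 10 nanoclusters are excluded).
* **Ca²⁺ flickers** — per-cell mean-intensity traces, robust
  running-median baseline, MAD noise scale, events gated at **z ≥ 3**
  (one-sided normal p < 0.01), superimposed events merged through a
  temporal-overlap graph, per-event amplitude / FWHM / AUC and per-cell
  flickers·min⁻¹.
* **Cell shape** — area, perimeter, circularity 4π·area/perimeter² and
  solidity area/convex-area from the cell mask.
* **Kinetic trace metrics** — for flow-cytometry-style ratio traces
  (e.g. Indo-1 375/525 nm): baseline MFI₀₋₃₀ₛ, peak ratio
  MFI_peak/MFI₀₋₃₀ₛ, and the AUC from the peak to the half-decay time.

The synthetic-data module generates 0.284 µm/px movies of ~10–14 µm cells
with punctate nanoclusters under three spatial regimes (random, clustered,
dispersed), programmable Ca²⁺ enrichment at cluster sites, and injected
Ca²⁺ transients of known onset, amplitude and FWHM.

## Worked example

The bundled demo builds two synthetic cohorts — "WT-like" (clustered
nanoclusters, 2× Ca²⁺ enrichment at cluster sites, high F-actin) and
"KO-like" (spatially random, no enrichment, fewer clusters, low F-actin) —
and runs the complete pipeline on both:

```bash
nanocal demo-fig4 --seed 1
```

```
 cohort    regime  enrichment  mean_cluster_count  ca_mfi_in_cluster  ca_mfi_negative  aggregation_index  actin_per_cell_area  n_cells
WT-like clustered         2.0           18.533333         100.119047        45.407624               1.75            36.071711        4
KO-like       csr         1.0           11.880556          52.150703        52.139064               0.00            25.003769        4
```

Reading the table: WT-like cells carry more nanoclusters per frame
(18.5 vs 11.9), their in-cluster Ca²⁺ MFI is roughly twice the
cluster-negative MFI (100 vs 45; the KO-like cohort shows no contrast,
52 vs 52), their nanoclusters sit above the random envelope at 1.75 radii
per timepoint on average (0 for the random cohort), and their F-actin
intensity per cell area is higher (36 vs 25). All four contrasts point in
the WT > KO direction, as programmed into the generator.

Other entry points:

```bash
nanocal run --input synthetic --seed 3 --out out/          # full CSV bundle
nanocal run --input movie.tif --config cfg.yaml --out out/ # analyze a movie
nanocal synth --regime clustered --seed 7 --out synth/     # movie + truth
```

`nanocal run` writes `clusters.csv`, `window_summary.csv`, `ripley.csv`,
`aggregation_index.csv`, `events.csv`, `flicker_summary.csv`, `shapes.csv`
and a `manifest.json` (config snapshot, seed, row counts); runs with the
same seed are byte-identical.

As a library:

```python
from nanocal import (AnalysisConfig, auto_threshold, extract_nanoclusters,
                     ripley_k, mc_envelope, normalize_k, detect_events)
```

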