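# cyanomd

Single-cell image analysis of **thylakoid microdomains** in cyanobacteria
(*Synechocystis* sp. PCC 6803 carrying YFP-tagged photosystem I).

Cyanobacterial thylakoid membranes are organized into sub-micrometer
*microdomains* (MDs) — regions with characteristic ratios of photosystem II
(PSII), photosystem I (PSI) and phycobilisomes (PBS) that show up as distinct
colors in three-channel confocal composites (red = PSII autofluorescence,
green = PSI-YFP, blue = PBS autofluorescence). `cyanomd` is a tested,
reusable pipeline for the population-scale quantification of that
organization across a multi-day acclimation experiment from continuous light
(CL) to a 12/12 h sinusoidal light–dark (L-D) cycle:

* a **synthetic-data generator** emulating the study imagery — 8-bit
  multichannel frames of ring-shaped (peripheral thylakoid) cells in four
  shape classes, patchy microdomain textures, a sinusoidal diel light regime
  peaking at 100 µmol photons m⁻² s⁻¹, multi-day per-channel intensity
  trends, and Gaussian-peak 77 K spectra — all seeded and shipping pixel-exact
  ground truth;
* **segmentation** (Otsu on the summed channels, hole filling, 4-connected
  labeling, distance-transform watershed for oversized mergers) and
  **string-cell pairing** from the transmission channel;
* **shape morphometry and typing** — circularity `4π·area/perimeter²`,
  roundness `4·area/(π·major_axis²)`, Feret diameter (max boundary-pair
  distance), constriction detection — classifying cells as
  regular / elongated / dividing / string;
* **microdomain mapping** — per-cell channel normalization and a seven-class
  dominance classifier (red, green, blue, yellow, magenta, cyan, white) with
  per-cell composition fractions and a heterogeneity (CV) index;
* **quantification** — per-cell total/mean fluorescence, small/large size
  bins (1.2–1.6 / 1.601–2.5 µm), population histograms with width metrics,
  and per-day diel aggregation with min/max ranges;
* **spectral ratios** — F730/F695 (PSI/PSII), F660/F695 (PBS decoupling),
  A630/A682 (PBS/chlorophyll);
* **statistics** — Student's t-test, one-way ANOVA, and Duncan's multiple
  range test with compact-letter groupings at p < 0.05.

## Worked example

```python
import cyanomd as cm

series = cm.generate_diel_series(
    cm.CL_TO_LD_PRESET, timepoints_per_day=3, seed=0, n_cells=80,
    shape=(640, 640), days=[1, 14],
)
summary = cm.diel_aggregate(series)
print(summary.per_day[["day", "mean_psii", "mean_psi", "mean_pbs"]])
print(f"PSI decline: {summary.percent_decline('psi'):.1f}%")
```

prints

```
 day  mean_psii  mean_psi  mean_pbs
   1  58.601454 49.110168 55.446619
  14  51.994164 39.096050 54.354888
PSI decline: 20.4%
```

i.e. after segmenting every frame and averaging per-cell mean fluorescence
per day, the PSI channel fell 20.4 % between day 1 and day 14 — recovering
the 20 % decline the default acclimation preset encodes (PSII encodes 10 %,
PBS stays flat). The `examples/` directory has one short narrative script per
capability (rendering + segmentation, shape typing, microdomain composition,
diel acclimation, spectra + statistics); each prints the numbers it computes
and a line on what they mean. A thin CLI mirrors the pipeline:
`cyanomd generate | segment | analyze | spectra | stats | run-all`.

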