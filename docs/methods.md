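# Methods

This note documents the models, defaults and numerical choices behind
`cyanomd`, and what the synthetic benchmark does and does not establish about
real confocal data.

## The synthetic imaging model

Real input to this kind of analysis is an 8-bit, 512×512-class confocal frame
with three fluorescence channels (PSII chlorophyll autofluorescence, PSI-YFP,
PBS autofluorescence) and an optional transmission channel. No public image
data exist for the original experiment, so the package ships a generator that
emulates the *statistical structure* the analysis assumes, with pixel-exact
ground truth.

**Geometry.** Each cell is a filled elliptical body; the thylakoid signal is
rendered only on a peripheral ring (annulus) of the body, obtained by
morphological erosion with a disk of the ring thickness (default 3 px). The
ring model reflects the peripheral localization of cyanobacterial thylakoids;
cell interiors are dark. Four shape classes are rendered:

* *regular* — circle, diameter 1.5–2.4 µm;
* *elongated* — ellipse, major axis 3.0–3.8 µm, aspect ratio 2.4–2.8;
* *dividing* — ellipse (3.1–3.8 × 1.7–2.0 µm) with a Gaussian waist
  (σ = 0.15 × semi-major) of fractional depth 0.32–0.45;
* *string* — two daughter rings separated by a 2–4 px gap in fluorescence but
  bridged by a band in the transmission channel (post-division doublets are
  separate in thylakoid signal yet still connected in bright-field).

Shape parameter ranges were chosen so that each rendered class actually
satisfies its own classification box (ground-truth consistency): e.g. an
aspect ratio below ~2.3 puts an ellipse's circularity above the 0.8
elongated/regular boundary, so elongated cells are sampled at ≥ 2.4.

**Pixel size.** 0.08 µm/px by default and configurable throughout; all length
thresholds are honored in µm. Cells are placed on a jittered 64-px grid so
that footprints can never collide; the renderer still rejects overlapping
specs as a guard.

**Microdomain texture.** Per cell, 2–5 Gaussian patches (default radius
0.3 µm) with per-channel enrichment weights modulate the ring as
`1 + h · Σ w_p · bump_p`, then the field is normalized to unit mean over the
ring. The normalization makes the configured baseline *exactly* the true ring
mean regardless of patch contrast `h`, which is what lets intensity trends and
heterogeneity trends be dialed independently. `h = 0` yields a perfectly
uniform ring.

**Brightness model.** Per-cell brightness is lognormal with unit mean
(σ = 0.25 by default, per channel), standing in for the large unquantified
cell-to-cell variability of real populations. Channel baselines default to
(130, 110, 125) for (PSII, PSI, PBS) — chosen to keep patch peaks comfortably
inside the 8-bit range, as a microscopist would set gain to avoid saturation,
because clipping would bias mean-intensity recovery. Gaussian read noise
(σ = 6 intensity units) is added everywhere and the frame is clipped to
[0, 255].

**Acclimation presets.** The default CL→L-D preset spans 14 days and encodes
the reported trend directions as generator truth: PSI population mean ramps
log-linearly to 0.8× (a 20 % decline), PSII to 0.9× (10 %), PBS stays at
1.0×; PSI patch contrast relaxes from 0.8 to 0.3 (spatial homogenization),
PSII from 0.6 to 0.45, PBS constant; a transient PBS-decoupling bump
(Gaussian in time, peak 0.3 at day 3, width 1.5 days) drives the 77 K
F660/F695 ratio. Companion presets hold the start (`cl`), the end (`ld`,
with tighter dispersion σ = 0.15 to encode the reported histogram narrowing),
or everything (`identity`) fixed.

**Diel schedule.** Light follows a half-wave sinusoid over the 12 h light
phase (dark 0–12 h, light 12–24 h), peaking at 100 µmol photons m⁻² s⁻¹
mid-phase. Six acquisition slots per day by default, at evenly spaced hours.
The cell-type mixture shifts toward elongated/dividing cells around hours
12–14 (the pre-division pile-up); intensities themselves carry no within-day
modulation, so day min/max ranges under a stationary preset reflect sampling
error only. Per-timepoint seeds derive from the experiment seed and the
(day, slot) pair, so rendering a subset of days is bit-identical to the full
run.

**77 K spectra.** Three Gaussian peaks at 660 (PBS), 695 (PSII) and 730 nm
(PSI), common width σ = 10 nm; decoupling multiplies the 660 nm amplitude by
`1 + g·d` with gain g = 1. Peak widths and gain are free choices; only the
monotone behavior of the ratios is treated as meaningful. Absorbance spectra
are two Gaussians at 630 (PBS) and 682 nm (chlorophyll Qy), σ = 18 nm.

**What the generator does not emulate:** optical point-spread blur, focal
drift and z-structure, photobleaching, autofluorescence background gradients,
cell motion or overlap, and day-to-day instrument drift. Tests passing on
this benchmark show the *pipeline math* is correct under the stated
statistical structure, not that segmentation or typing would reach the same
accuracy on real confocal frames, where boundary ambiguity dominates.

## Segmentation

Otsu thresholding runs on the *sum* of the three fluorescence channels: a
microdomain-rich cell is by definition dim in some channel, but never in the
sum. Holes (ring interiors) are filled, components labeled 4-connected
(conservative separation of near-touching cells), and components outside
[0.8, 12] µm² are discarded.

Watershed splitting is applied only to components larger than
`split_min_area_um2` (default 7 µm²) — the plausible mergers of touching
cells — seeded from distance-transform maxima at least 0.8 µm apart.
Applying the watershed to every component would shred dividing cells, whose
waisted distance transform has two lobes ~1.7 µm apart; gating on area keeps
them intact while still separating true mergers, since any single cell the
generator produces stays below ~6 µm². On well-separated synthetic fields the
gate never fires and segmentation is exact.

String pairing thresholds the transmission channel (Otsu), assigns each
fluorescence mask to the transmission component covering most of it, and
pairs masks sharing a component, nearest centroids first, each mask in at
most one pair.

## Shape metrics and typing

* Circularity uses the Crofton perimeter estimator with 4 directions,
  clamped to ≤ 1. The estimator is fixed and documented because circularity
  is threshold-sensitive to the perimeter formula: the 4-direction Crofton
  measure of a ≥ 50 px-radius rasterized disk is within ~1 % of the true
  circumference, so ideal disks sit at circularity ≈ 0.99.
* Roundness takes the major axis from the second-moment (best-fit ellipse)
  estimate, so it equals minor/major for a true ellipse.
* Feret diameter is the maximum pairwise distance between boundary-pixel
  centers, computed over the convex hull of the boundary; tests verify exact
  equality with the exhaustive all-pairs oracle, including on disconnected
  doublets.
* Constriction detection measures the transverse width profile at 25
  stations along the principal axis and fires when an interior local minimum
  in the *middle third* of the profile drops at least 20 % below the mean of
  its flanking maxima. The middle-third restriction rejects rasterization
  jitter at the taper of plain ellipses; the 20 % depth threshold is a free
  parameter (no published value exists) and is exposed in config.

Typing applies the printed threshold boxes with a fixed precedence
**string > dividing > elongated > regular**. The boxes overlap (a cell with
circularity 0.75 and Feret 3.0 µm satisfies both elongated and dividing), and
the original workflow resolved overlaps by manual re-assignment; a
deterministic precedence rule replaces that. Feret thresholds (2.2, 2.8) are
interpreted in µm — the cells themselves are only 1.2–2.5 µm across, so pixel
units would be meaningless. String members are measured as the union of
their pair, which is what pushes a doublet's circularity below the 0.7 gate
(two disjoint disks measure ≈ 0.5).

## Microdomain mapping

Channels are normalized per cell to their robust (99th percentile) maximum
within the mask — per cell rather than per frame, so dim cells still exhibit
microdomains. A channel is *dominant* at a pixel when its normalized value
reaches τ (default 0.5; any fixed τ ∈ (0,1) preserves all partition and
monotonicity properties). The dominant subset maps to the additive RGB color
(7 nonempty subsets → 7 classes); a pixel with no dominant channel takes the
arg-max channel's primary color so the classes partition the thylakoid area.
Pixels whose maximum normalized channel stays below 0.25 (ring interior)
remain background. Heterogeneity is the coefficient of variation of raw
channel intensity over thylakoid pixels, requiring ≥ 10 pixels.

## Quantification

Per-cell totals and means use raw (un-normalized) intensities over the full
filled mask; total = mean × area exactly. Histograms are built from per-cell
*means* on a fixed 0–255 axis (32 bins) to decouple brightness from cell
size; whether the original figures used totals or means is not stated, so
this is a config switch. Size bins use the equivalent spherical diameter
`2·√(area/π)` with small = 1.2–1.6 µm and large = 1.601–2.5 µm; cells outside
[1.2, 2.5] µm are excluded and counted separately. Percent decline is
`100·(1 − mean_end/mean_start)` on day-averaged values. A timepoint with zero
segmented cells is recorded as missing, never as zero.

## Statistics

The t-test (classical unpaired Student by default — whether the original
analysis paired or Welch-corrected is not stated) and the ANOVA p-value come
from scipy; the ANOVA sum-of-squares decomposition is computed in-package
because Duncan's test consumes MS_within and df_within, and is cross-checked
against `scipy.stats.f_oneway`. Degenerate zero-variance inputs return
(0, 1) by convention.

Duncan's multiple range test sorts group means descending and compares every
ordered span of p means against the critical range
`R_p = q*(α_p, p, df) · √(MS_within/n_h)`, with protection level
`α_p = 1 − (1−α)^(p−1)`, studentized-range quantiles from
`scipy.stats.studentized_range` (validated in tests against an independent
numerical-integration oracle to 10⁻³), and n_h the harmonic mean of group
sizes when unbalanced. Spans inside a non-significant span are declared
non-significant (stepwise protection); letters mark the maximal homogeneous
spans, hence are always contiguous in the mean ordering. Timepoints are also
compared against a configurable reference day by plain t-tests at p < 0.05
with *no* multiple-testing correction across timepoints, mirroring the
original reporting convention.

## Problem sizes

The acceptance recovery uses 20 replicate seeds of a 14-day series with 6
timepoints/day and 300 cells per timepoint on a 1152² canvas, rendering and
segmenting only the first and last days (the only days entering the
end-to-start decline); per-timepoint seeding makes this exactly equivalent to
analyzing those days within full runs. At this scale each replicate carries
~3 600 segmented cells per day-pair and the per-seed decline estimates
scatter by roughly ±1.5 percentage points, so the 20-seed mean is stable to a
few tenths of a point. Unit and property tests run on 40–60-cell fields at
640–768 px.

## Known limitations

* Segmentation has no model of genuinely touching or overlapping cells; the
  area-gated watershed is exercised only synthetically.
* The microdomain classifier is a hard threshold on normalized intensity; it
  inherits τ-sensitivity and does not model the partial-volume mixing a real
  point-spread function introduces.
* The heterogeneity CV conflates patch contrast with patch count and noise;
  it is a direction-of-change index, not an absolute measure.
* Spectral ratios are read from band means; no deconvolution into component
  bands is attempted, so overlapping-peak bias is absorbed into the ratio.
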