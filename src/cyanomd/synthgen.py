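"""Synthetic three-channel cyanobacterial imagery, diel series and 77 K spectra.

The generator emulates confocal acquisitions of *Synechocystis* PSI-YFP cells:
512x512-class 8-bit frames with three fluorescence channels (PSII chlorophyll
autofluorescence, PSI-YFP, PBS autofluorescence) and an optional transmission
channel.  Thylakoid signal is rendered as a peripheral ring (annulus) following
the cell outline; microdomain heterogeneity is laid down as smooth patches of
channel-specific enrichment on that ring.  Every generator is deterministic
under a seed, and every rendered frame ships with pixel-exact ground truth so
the downstream segmentation/typing/quantification stages can be validated
without any acquired data.

Channel order is fixed throughout the package: index 0 = PSII, 1 = PSI,
2 = PBS (the red/green/blue display convention of the composite images).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile

CHANNEL_NAMES: tuple[str, str, str] = ("psii", "psi", "pbs")
SHAPE_CLASSES: tuple[str, ...] = ("regular", "elongated", "dividing", "string")

#: default physical pixel pitch, um per pixel
DEFAULT_PIXEL_SIZE_UM = 0.08
#: default thylakoid ring thickness, px
DEFAULT_RING_THICKNESS_PX = 3


class CollisionError(ValueError):
    """Two non-string cell footprints overlap on the canvas."""


class PatchPlacementError(ValueError):
    """A microdomain patch center falls outside its cell."""


# ---------------------------------------------------------------------------
# shape / pattern / regime specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellShapeSpec:
    """Geometry of one synthetic cell.

    Axes are full lengths in micrometres; ``center`` is (x, y) in pixels.
    ``constriction_depth`` (dividing only) is the fractional waist depth;
    ``gap_px`` (string only) separates the two daughter rings.
    """

    shape_class: str
    center: tuple[float, float]
    major_axis_um: float
    minor_axis_um: float
    orientation_rad: float = 0.0
    constriction_depth: float = 0.0
    gap_px: int = 0

    def __post_init__(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(f"unknown shape_class {self.shape_class!r}")
        if not (self.major_axis_um >= self.minor_axis_um > 0):
            raise ValueError("require major_axis >= minor_axis > 0")
        if (self.constriction_depth > 0) != (self.shape_class == "dividing"):
            raise ValueError("constriction_depth > 0 iff shape_class == 'dividing'")
        if not (0 <= self.constriction_depth < 1):
            raise ValueError("constriction_depth must lie in [0, 1)")
        if (self.gap_px >= 1) != (self.shape_class == "string"):
            raise ValueError("gap_px >= 1 iff shape_class == 'string'")


@dataclass(frozen=True)
class MDPatternSpec:
    """Microdomain texture of one cell's thylakoid ring.

    ``channel_weights`` holds one (PSII, PSI, PBS) enrichment triple per patch.
    ``baseline`` is the per-channel ring intensity (8-bit units) around which
    patches modulate; ``heterogeneity = 0`` yields a perfectly uniform ring.
    The patch field is normalized to unit mean over the ring so that the
    baseline *is* the true ring-mean intensity regardless of heterogeneity.
    ``centers_um``, if given, are (x, y) offsets from the cell center in um;
    otherwise patch centers are drawn on the ring from the render seed.
    """

    n_patches: int
    patch_radius_um: float
    channel_weights: tuple[tuple[float, float, float], ...]
    baseline: tuple[float, float, float]
    heterogeneity: float = 0.0
    centers_um: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_patches < 0:
            raise ValueError("n_patches must be >= 0")
        if len(self.channel_weights) != self.n_patches:
            raise ValueError("one channel_weights triple required per patch")
        if any(w < 0 for triple in self.channel_weights for w in triple):
            raise ValueError("channel weights must be >= 0")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be >= 0")
        if self.centers_um is not None and len(self.centers_um) != self.n_patches:
            raise ValueError("one center per patch when centers_um is given")


@dataclass(frozen=True)
class LightRegime:
    """Diel light profile: half-wave sinusoid in the light phase, dark otherwise."""

    light_h: float = 12.0
    dark_h: float = 12.0
    peak: float = 100.0  # umol photons m^-2 s^-1
    period_h: float = 24.0

    def __post_init__(self) -> None:
        if not math.isclose(self.light_h + self.dark_h, self.period_h):
            raise ValueError("light_h + dark_h must equal period_h")
        if self.peak < 0:
            raise ValueError("peak must be >= 0")


def light_intensity(t_h: float, regime: LightRegime = LightRegime()) -> float:
    """Irradiance at ``t_h`` hours into the diel cycle.

    The dark phase occupies [0, dark_h); the light phase follows as a half-wave
    sine peaking at ``regime.peak`` mid-phase.  Times outside [0, 24) wrap.
    """
    t = float(t_h) % regime.period_h
    if t < regime.dark_h:
        return 0.0
    return regime.peak * math.sin(math.pi * (t - regime.dark_h) / regime.light_h)


# ---------------------------------------------------------------------------
# acclimation presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcclimationPreset:
    """Multi-day population trends imposed on the generator.

    Start/end multipliers scale the per-channel population mean ring intensity
    (log-linear interpolation in between); heterogeneity start/end values scale
    microdomain patch contrast per channel.  ``pbs_decoupling_by_day`` drives
    the 660 nm emission gain of :func:`generate_spectrum`.
    """

    days: int = 14
    start_multiplier: tuple[float, float, float] = (1.0, 1.0, 1.0)
    end_multiplier: tuple[float, float, float] = (0.9, 0.8, 1.0)
    heterogeneity_start: tuple[float, float, float] = (0.6, 0.8, 0.5)
    heterogeneity_end: tuple[float, float, float] = (0.45, 0.3, 0.5)
    dispersion_sigma: float = 0.25
    base_intensity: tuple[float, float, float] = (130.0, 110.0, 125.0)
    light: LightRegime = field(default_factory=LightRegime)
    decoupling_peak_day: float = 3.0
    decoupling_peak_value: float = 0.3
    decoupling_width_days: float = 1.5

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("preset must span at least one day")
        if any(m <= 0 for m in self.start_multiplier + self.end_multiplier):
            raise ValueError("intensity multipliers must be > 0")
        if not (0 <= self.decoupling_peak_value <= 1):
            raise ValueError("decoupling fraction must lie in [0, 1]")

    def multiplier(self, day: int) -> np.ndarray:
        """Per-channel mean multiplier on 1-based ``day`` (log-linear ramp)."""
        s = np.asarray(self.start_multiplier, dtype=float)
        e = np.asarray(self.end_multiplier, dtype=float)
        if self.days == 1:
            return s
        frac = (day - 1) / (self.days - 1)
        return s * (e / s) ** frac

    def heterogeneity(self, day: int) -> np.ndarray:
        s = np.asarray(self.heterogeneity_start, dtype=float)
        e = np.asarray(self.heterogeneity_end, dtype=float)
        if self.days == 1:
            return s
        frac = (day - 1) / (self.days - 1)
        return s + (e - s) * frac

    def pbs_decoupling(self, day: float) -> float:
        """Transient decoupling bump peaking mid-acclimation, in [0, 1]."""
        z = (day - self.decoupling_peak_day) / self.decoupling_width_days
        return float(self.decoupling_peak_value * math.exp(-0.5 * z * z))


#: continuous-light-to-light-dark acclimation with the reported trend
#: directions: PSI mean falls 20%, PSII falls 10%, PBS stays flat; PSI
#: microdomain contrast relaxes; a transient PBS-decoupling bump around day 3.
CL_TO_LD_PRESET = AcclimationPreset()

#: stationary control: nothing drifts between the first and last day.
IDENTITY_PRESET = AcclimationPreset(
    end_multiplier=(1.0, 1.0, 1.0),
    heterogeneity_end=(0.6, 0.8, 0.5),
    decoupling_peak_value=0.0,
)

#: continuous-light steady state: start-of-experiment conditions held flat
#: (high PSI patch contrast, no decoupling transient).
CL_PRESET = AcclimationPreset(
    end_multiplier=(1.0, 1.0, 1.0),
    heterogeneity_end=(0.6, 0.8, 0.5),
    decoupling_peak_value=0.0,
)

#: light-dark steady state: end-of-acclimation conditions held flat
#: (relaxed PSI contrast, narrower brightness spread).
LD_PRESET = AcclimationPreset(
    start_multiplier=(0.9, 0.8, 1.0),
    heterogeneity_start=(0.45, 0.3, 0.5),
    dispersion_sigma=0.15,
    decoupling_peak_value=0.0,
)

PRESETS: dict[str, AcclimationPreset] = {
    "cl_to_ld": CL_TO_LD_PRESET,
    "identity": IDENTITY_PRESET,
    "cl": CL_PRESET,
    "ld": LD_PRESET,
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MultiChannelImage:
    """Three fluorescence channels (PSII, PSI, PBS) plus optional transmission."""

    channels: np.ndarray  # (3, H, W) uint8
    transmission: np.ndarray | None = None  # (H, W) uint8
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[CHANNEL_NAMES.index(name)]


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _body_halfwidth(u: np.ndarray, a: float, b: float, depth: float) -> np.ndarray:
    """Half-width profile of a cell body along its major axis.

    ``a``/``b`` are semi-axes in px; ``depth`` carves a Gaussian waist at the
    midpoint (dividing cells).  Returns 0 outside [-a, a].
    """
    base = np.where(np.abs(u) < a, b * np.sqrt(np.clip(1 - (u / a) ** 2, 0, 1)), 0.0)
    if depth > 0:
        # narrow waist so the flanking lobes keep nearly the full width
        notch_sigma = 0.15 * a
        base = base * (1 - depth * np.exp(-0.5 * (u / notch_sigma) ** 2))
    return base


def _ellipse_masks(
    shape: tuple[int, int],
    center_xy: tuple[float, float],
    a_px: float,
    b_px: float,
    theta: float,
    depth: float,
    ring_px: float,
) -> tuple[np.ndarray, np.ndarray, tuple[slice, slice]]:
    """Rasterize one (possibly waisted) elliptical body.

    Returns (fill, ring) boolean arrays over a local bounding-box window plus
    the window slices into the full canvas.
    """
    cx, cy = center_xy
    pad = int(math.ceil(a_px)) + 3
    r0 = max(int(math.floor(cy)) - pad, 0)
    r1 = min(int(math.ceil(cy)) + pad + 1, shape[0])
    c0 = max(int(math.floor(cx)) - pad, 0)
    c1 = min(int(math.ceil(cx)) + pad + 1, shape[1])
    rows = np.arange(r0, r1)[:, None] - cy
    cols = np.arange(c0, c1)[None, :] - cx
    # local frame: u along the major axis, v perpendicular
    u = cols * math.cos(theta) + rows * math.sin(theta)
    v = -cols * math.sin(theta) + rows * math.cos(theta)
    w = _body_halfwidth(u, a_px, b_px, depth)
    fill = (w > 0) & (np.abs(v) <= w)
    # uniform-thickness closed annulus via morphological erosion of the body
    from scipy.ndimage import binary_erosion
    from skimage.morphology import disk

    inner = binary_erosion(fill, structure=disk(int(round(ring_px))))
    ring = fill & ~inner
    return fill, ring, (slice(r0, r1), slice(c0, c1))


def _spec_bodies(
    spec: CellShapeSpec, pixel_size_um: float
) -> list[tuple[tuple[float, float], float, float, float, float]]:
    """Decompose a spec into one or two (center, a_px, b_px, theta, depth) bodies."""
    a = spec.major_axis_um / (2 * pixel_size_um)
    b = spec.minor_axis_um / (2 * pixel_size_um)
    theta = spec.orientation_rad
    if spec.shape_class != "string":
        return [(spec.center, a, b, theta, spec.constriction_depth)]
    # string: two daughter bodies along the orientation axis, gap_px apart
    half = a / 2
    offset = half + spec.gap_px / 2
    dx, dy = offset * math.cos(theta), offset * math.sin(theta)
    cx, cy = spec.center
    return [
        ((cx - dx, cy - dy), half, min(b, half), theta, 0.0),
        ((cx + dx, cy + dy), half, min(b, half), theta, 0.0),
    ]


def render_image(
    specs: Sequence[CellShapeSpec],
    patterns: Sequence[MDPatternSpec],
    noise_sd: float = 6.0,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    ring_thickness_px: float = DEFAULT_RING_THICKNESS_PX,
    include_transmission: bool = True,
    transmission_level: float = 180.0,
) -> tuple[MultiChannelImage, np.ndarray, pd.DataFrame]:
    """Render a field of cells; return image, ground-truth labels and truth table.

    Each cell is an annulus of thylakoid signal following its body outline;
    per-pixel channel intensity = baseline x (mean-normalized patch field),
    plus Gaussian noise, clipped to [0, 255].  The label raster marks *filled*
    cell bodies (what segmentation should recover); a string spec contributes
    two labels sharing one ``spec_id``.  The truth table has one row per label
    with shape class, geometry and the true per-channel ring-mean intensity.

    Overlapping bodies from different specs raise :class:`CollisionError`;
    a supplied patch center outside its cell raises :class:`PatchPlacementError`.
    """
    if len(specs) != len(patterns):
        raise ValueError("one MDPatternSpec required per CellShapeSpec")
    rng = np.random.default_rng(seed)
    H, W = shape
    signal = np.zeros((3, H, W), dtype=float)
    labels = np.zeros((H, W), dtype=np.int32)
    trans = np.zeros((H, W), dtype=float)
    rows: list[dict] = []
    next_label = 1
    for spec_id, (spec, pat) in enumerate(zip(specs, patterns)):
        bodies = _spec_bodies(spec, pixel_size_um)
        body_labels: list[int] = []
        for (cxy, a, b, theta, depth) in bodies:
            fill, ring, win = _ellipse_masks(shape, cxy, a, b, theta, depth, ring_thickness_px)
            if np.any(labels[win][fill]):
                raise CollisionError(f"cell spec {spec_id} overlaps a previously placed cell")
            if not ring.any():
                raise ValueError(f"cell spec {spec_id} rasterizes to an empty ring")
            lab = next_label
            next_label += 1
            body_labels.append(lab)
            labels[win][fill] = lab
            trans[win][fill] = transmission_level

            ring_rc = np.nonzero(ring)
            n_ring = ring_rc[0].size
            # patch enrichment field over the ring, unit mean per channel
            field_c = np.ones((3, n_ring), dtype=float)
            if pat.heterogeneity > 0 and pat.n_patches > 0:
                rr = ring_rc[0] + win[0].start
                cc = ring_rc[1] + win[1].start
                if pat.centers_um is not None:
                    centers = []
                    for (ox, oy) in pat.centers_um:
                        px = cxy[0] + ox / pixel_size_um
                        py = cxy[1] + oy / pixel_size_um
                        ir = int(round(py)) - win[0].start
                        ic = int(round(px)) - win[1].start
                        if (
                            ir < 0 or ic < 0 or ir >= fill.shape[0] or ic >= fill.shape[1]
                            or not fill[ir, ic]
                        ):
                            raise PatchPlacementError(
                                f"patch at offset ({ox}, {oy}) um lies outside cell spec {spec_id}"
                            )
                        centers.append((py, px))
                    centers_arr = np.asarray(centers, dtype=float)
                else:
                    pick = rng.integers(0, n_ring, size=pat.n_patches)
                    centers_arr = np.column_stack([rr[pick], cc[pick]]).astype(float)
                sigma = max(pat.patch_radius_um / pixel_size_um, 0.5)
                d2 = (
                    (rr[None, :] - centers_arr[:, 0:1]) ** 2
                    + (cc[None, :] - centers_arr[:, 1:2]) ** 2
                )
                bumps = np.exp(-0.5 * d2 / sigma**2)  # (n_patches, n_ring)
                wts = np.asarray(pat.channel_weights, dtype=float)  # (n_patches, 3)
                field_c = 1.0 + pat.heterogeneity * (wts.T @ bumps)
                field_c /= field_c.mean(axis=1, keepdims=True)
            base = np.asarray(pat.baseline, dtype=float)
            rr_g = ring_rc[0] + win[0].start
            cc_g = ring_rc[1] + win[1].start
            for ch in range(3):
                signal[ch, rr_g, cc_g] = base[ch] * field_c[ch]
            rows.append(
                {
                    "label": lab,
                    "spec_id": spec_id,
                    "shape_class": spec.shape_class,
                    "center_x": cxy[0],
                    "center_y": cxy[1],
                    "major_axis_um": 2 * a * pixel_size_um,
                    "minor_axis_um": 2 * b * pixel_size_um,
                    "true_mean_psii": base[0],
                    "true_mean_psi": base[1],
                    "true_mean_pbs": base[2],
                    "ring_area_px": int(n_ring),
                    "fill_area_px": int(fill.sum()),
                }
            )
        if spec.shape_class == "string":
            # transmission bridge joining the daughters
            (c0, a0, b0, theta, _), (c1, *_rest) = bodies[0], bodies[1]
            n_steps = max(int(2 * (abs(c1[0] - c0[0]) + abs(c1[1] - c0[1]))) + 2, 4)
            ts = np.linspace(0, 1, n_steps)
            bx = c0[0] + (c1[0] - c0[0]) * ts
            by = c0[1] + (c1[1] - c0[1]) * ts
            half_w = max(int(round(b0 / 2)), 2)
            for x, y in zip(bx, by):
                r0 = max(int(y) - half_w, 0)
                r1 = min(int(y) + half_w + 1, H)
                c0_ = max(int(x) - half_w, 0)
                c1_ = min(int(x) + half_w + 1, W)
                trans[r0:r1, c0_:c1_] = np.maximum(trans[r0:r1, c0_:c1_], transmission_level)
            rows[-1]["string_partner"] = body_labels[0]
            rows[-2]["string_partner"] = body_labels[1]

    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
        trans = trans + rng.normal(0.0, noise_sd, size=trans.shape)
    img8 = np.clip(np.rint(signal), 0, 255).astype(np.uint8)
    trans8 = np.clip(np.rint(trans), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(rows)
    if "string_partner" in truth.columns:
        truth["string_partner"] = truth["string_partner"].fillna(0).astype(int)
    elif len(truth):
        truth["string_partner"] = 0
    image = MultiChannelImage(
        channels=img8,
        transmission=trans8 if include_transmission else None,
        pixel_size_um=pixel_size_um,
    )
    return image, labels, truth


# ---------------------------------------------------------------------------
# random cell populations
# ---------------------------------------------------------------------------

def _diel_type_probs(hour: float) -> np.ndarray:
    """Cell-type mixture over the diel cycle.

    Elongating/dividing cells accumulate toward hours 12-14 (late light phase),
    mirroring the observed pile-up before division; strings follow shortly after.
    """
    bump = math.exp(-0.5 * ((hour - 13.0) / 3.0) ** 2)
    p = np.array(
        [
            0.70 - 0.20 * bump,  # regular
            0.14 + 0.10 * bump,  # elongated
            0.10 + 0.07 * bump,  # dividing
            0.06 + 0.03 * bump,  # string
        ]
    )
    return p / p.sum()


def sample_population(
    rng: np.random.Generator,
    n_cells: int,
    shape: tuple[int, int],
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    type_probs: np.ndarray | None = None,
) -> list[CellShapeSpec]:
    """Draw non-overlapping cell specs on a jittered grid covering the canvas."""
    if type_probs is None:
        type_probs = _diel_type_probs(6.0)
    H, W = shape
    cell_pitch = 64
    n_rows, n_cols = H // cell_pitch, W // cell_pitch
    if n_rows * n_cols < n_cells:
        raise ValueError(
            f"canvas {shape} holds at most {n_rows * n_cols} cells; requested {n_cells}"
        )
    slots = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    pick = rng.choice(len(slots), size=n_cells, replace=False)
    specs: list[CellShapeSpec] = []
    classes = rng.choice(4, size=n_cells, p=type_probs)
    for k, slot_i in enumerate(pick):
        r, c = slots[slot_i]
        cx = (c + 0.5) * cell_pitch + rng.uniform(-2, 2)
        cy = (r + 0.5) * cell_pitch + rng.uniform(-2, 2)
        theta = rng.uniform(0, math.pi)
        cls = SHAPE_CLASSES[classes[k]]
        if cls == "regular":
            d = rng.uniform(1.5, 2.4)
            specs.append(CellShapeSpec("regular", (cx, cy), d, d, theta))
        elif cls == "elongated":
            major = rng.uniform(3.0, 3.8)
            minor = major / rng.uniform(2.4, 2.8)
            specs.append(CellShapeSpec("elongated", (cx, cy), major, minor, theta))
        elif cls == "dividing":
            major = rng.uniform(3.1, 3.8)
            minor = rng.uniform(1.7, 2.0)
            depth = rng.uniform(0.32, 0.45)
            specs.append(
                CellShapeSpec("dividing", (cx, cy), major, minor, theta, constriction_depth=depth)
            )
        else:
            major = rng.uniform(3.0, 3.6)
            minor = rng.uniform(1.4, 1.7)
            specs.append(
                CellShapeSpec("string", (cx, cy), major, minor, theta, gap_px=int(rng.integers(2, 5)))
            )
    return specs


def sample_patterns(
    rng: np.random.Generator,
    specs: Sequence[CellShapeSpec],
    mean_intensity: np.ndarray,
    heterogeneity: np.ndarray,
    dispersion_sigma: float,
    patch_radius_um: float = 0.3,
) -> list[MDPatternSpec]:
    """Draw one microdomain pattern per cell.

    Per-cell brightness is lognormal with unit mean (sigma = ``dispersion_sigma``)
    independently per channel, so the population mean ring intensity equals
    ``mean_intensity`` exactly in expectation.
    """
    patterns: list[MDPatternSpec] = []
    for _spec in specs:
        if dispersion_sigma > 0:
            cell_f = rng.lognormal(-0.5 * dispersion_sigma**2, dispersion_sigma, size=3)
        else:
            cell_f = np.ones(3)
        n_patches = int(rng.integers(2, 6))
        weights = tuple(tuple(rng.uniform(0.1, 1.0, size=3)) for _ in range(n_patches))
        base = tuple(np.clip(mean_intensity * cell_f, 1.0, 240.0))
        het = float(np.mean(heterogeneity))  # patch field shared; contrast per channel below
        patterns.append(
            MDPatternSpec(
                n_patches=n_patches,
                patch_radius_um=patch_radius_um,
                channel_weights=tuple(
                    tuple(np.asarray(w) * heterogeneity / max(het, 1e-9)) for w in weights
                ),
                baseline=base,
                heterogeneity=het,
            )
        )
    return patterns


# ---------------------------------------------------------------------------
# diel series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimepointSpec:
    """One acquisition slot of a diel series (rendered lazily)."""

    day: int
    hour: float
    time_h: float  # absolute hours since experiment start
    light: float
    seed: int


@dataclass
class DielSeries:
    """A multi-day acquisition schedule plus the generator state to render it.

    Frames are rendered on demand (one ~1 Mpx three-channel frame per
    timepoint) to keep multi-day series memory-bounded.
    """

    preset: AcclimationPreset
    timepoints: list[TimepointSpec]
    n_cells: int
    shape: tuple[int, int]
    pixel_size_um: float
    noise_sd: float

    def render_timepoint(
        self, tp: TimepointSpec
    ) -> tuple[MultiChannelImage, np.ndarray, pd.DataFrame]:
        rng = np.random.default_rng(tp.seed)
        specs = sample_population(
            rng, self.n_cells, self.shape, self.pixel_size_um, _diel_type_probs(tp.hour)
        )
        mean_intensity = np.asarray(self.preset.base_intensity) * self.preset.multiplier(tp.day)
        patterns = sample_patterns(
            rng,
            specs,
            mean_intensity,
            self.preset.heterogeneity(tp.day),
            self.preset.dispersion_sigma,
        )
        return render_image(
            specs,
            patterns,
            noise_sd=self.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            shape=self.shape,
            pixel_size_um=self.pixel_size_um,
        )

    def __iter__(self) -> Iterator[tuple[MultiChannelImage, float, float]]:
        for tp in self.timepoints:
            img, _, _ = self.render_timepoint(tp)
            yield img, tp.time_h, tp.light


def generate_diel_series(
    preset: AcclimationPreset,
    timepoints_per_day: int = 6,
    seed: int = 0,
    n_cells: int = 300,
    shape: tuple[int, int] = (1152, 1152),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    noise_sd: float = 6.0,
    days: Sequence[int] | None = None,
) -> DielSeries:
    """Lay out a diel acquisition schedule under ``preset``.

    Timepoints sit at evenly spaced hours of each 24 h cycle.  ``days`` selects
    a subset of 1-based days; per-timepoint seeds derive from ``seed`` and the
    (day, slot) pair, so a subset renders bit-identical frames to the full run.
    """
    if preset.days < 1:
        raise ValueError("preset must span at least one day")
    if timepoints_per_day < 1:
        raise ValueError("timepoints_per_day must be >= 1")
    day_list = list(range(1, preset.days + 1)) if days is None else sorted(days)
    if any(d < 1 or d > preset.days for d in day_list):
        raise ValueError("days outside the preset's span")
    hours = [(k + 0.5) * 24.0 / timepoints_per_day for k in range(timepoints_per_day)]
    tps: list[TimepointSpec] = []
    for day in day_list:
        for k, hour in enumerate(hours):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(day, k))
            tp_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
            tps.append(
                TimepointSpec(
                    day=day,
                    hour=hour,
                    time_h=(day - 1) * 24.0 + hour,
                    light=light_intensity(hour, preset.light),
                    seed=tp_seed,
                )
            )
    return DielSeries(
        preset=preset,
        timepoints=tps,
        n_cells=n_cells,
        shape=shape,
        pixel_size_um=pixel_size_um,
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# 77 K spectra
# ---------------------------------------------------------------------------

#: emission peak centers, nm: PBS terminal emitters, PSII (CP47), PSI
EMISSION_PEAKS_NM = {"pbs": 660.0, "psii": 695.0, "psi": 730.0}
DEFAULT_PEAK_SIGMA_NM = 10.0
#: gain applied to the 660 nm peak per unit decoupling fraction
DEFAULT_DECOUPLING_GAIN = 1.0


def generate_spectrum(
    psii_amp: float,
    psi_amp: float,
    pbs_amp: float,
    decoupling: float = 0.0,
    grid: np.ndarray | None = None,
    sigma_nm: float = DEFAULT_PEAK_SIGMA_NM,
    decoupling_gain: float = DEFAULT_DECOUPLING_GAIN,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Synthetic 77 K emission spectrum: three Gaussians at 660/695/730 nm.

    PBS decoupling scales the 660 nm peak by ``1 + gain * decoupling`` —
    energetically disconnected phycobilisomes fluoresce instead of transferring
    to the photosystems.  Returns a :class:`cyanomd.spectra.Spectrum`.
    """
    from .spectra import Spectrum  # local import to avoid a cycle

    if min(psii_amp, psi_amp, pbs_amp) < 0:
        raise ValueError("amplitudes must be >= 0")
    if not (0 <= decoupling <= 1):
        raise ValueError("decoupling must lie in [0, 1]")
    if grid is None:
        grid = np.arange(600.0, 780.5, 0.5)
    grid = np.asarray(grid, dtype=float)
    if grid[0] > EMISSION_PEAKS_NM["pbs"] - 1 or grid[-1] < EMISSION_PEAKS_NM["psi"] + 1:
        raise ValueError("grid must cover the 660, 695 and 730 nm peak centers")
    amps = {
        "pbs": pbs_amp * (1.0 + decoupling_gain * decoupling),
        "psii": psii_amp,
        "psi": psi_amp,
    }
    intens = np.zeros_like(grid)
    for key, center in EMISSION_PEAKS_NM.items():
        intens += amps[key] * np.exp(-0.5 * ((grid - center) / sigma_nm) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intens = np.clip(intens + rng.normal(0, noise_sd, size=intens.shape), 0, None)
    return Spectrum(wavelength_nm=grid, intensity=intens, kind="emission")


def generate_absorbance_spectrum(
    pbs_amp: float,
    chl_amp: float,
    grid: np.ndarray | None = None,
    sigma_nm: float = 18.0,
):
    """Synthetic room-temperature absorbance: PBS band at 630 nm, Chl Qy at 682 nm."""
    from .spectra import Spectrum

    if grid is None:
        grid = np.arange(550.0, 750.5, 0.5)
    grid = np.asarray(grid, dtype=float)
    intens = pbs_amp * np.exp(-0.5 * ((grid - 630.0) / sigma_nm) ** 2) + chl_amp * np.exp(
        -0.5 * ((grid - 682.0) / sigma_nm) ** 2
    )
    return Spectrum(wavelength_nm=grid, intensity=intens, kind="absorbance")


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def write_image(path: str | Path, image: MultiChannelImage, metadata: dict | None = None) -> None:
    """Write a multi-page TIFF (PSII, PSI, PBS[, transmission]) plus a sidecar
    ``.meta.txt`` with pixel size and any extra key/value metadata."""
    path = Path(path)
    pages = [image.channels[i] for i in range(3)]
    if image.transmission is not None:
        pages.append(image.transmission)
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    lines = [f"pixel_size_um={image.pixel_size_um}"]
    order = "psii,psi,pbs" + (",transmission" if image.transmission is not None else "")
    lines.append(f"channel_order={order}")
    for k, v in (metadata or {}).items():
        lines.append(f"{k}={v}")
    path.with_suffix(path.suffix + ".meta.txt").write_text("\n".join(lines) + "\n")


def read_image(path: str | Path) -> MultiChannelImage:
    """Read a multi-page TIFF written by :func:`write_image`."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] not in (3, 4):
        raise ValueError(f"expected a 3- or 4-page TIFF, got shape {stack.shape}")
    pixel_size = DEFAULT_PIXEL_SIZE_UM
    meta = path.with_suffix(path.suffix + ".meta.txt")
    if meta.exists():
        for line in meta.read_text().splitlines():
            if line.startswith("pixel_size_um="):
                pixel_size = float(line.split("=", 1)[1])
    trans = stack[3] if stack.shape[0] == 4 else None
    return MultiChannelImage(channels=stack[:3], transmission=trans, pixel_size_um=pixel_size)


def write_ground_truth(path: str | Path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, index=False)


def preset_to_dict(preset: AcclimationPreset) -> dict:
    d = dataclasses.asdict(preset)
    d["light"] = dataclasses.asdict(preset.light)
    return d
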