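"""Seven-class thylakoid microdomain mapping.

Each thylakoid pixel is normalized per cell and per channel, then colored by
which channels are "dominant" (>= a threshold tau of the cell's robust
maximum) under additive RGB logic with the display convention red = PSII,
green = PSI, blue = PBS:

    red     PSII only          yellow   PSII + PSI
    green   PSI only           magenta  PSII + PBS
    blue    PBS only           cyan     PSI  + PBS
                               white    all three

A pixel inside a cell with no dominant channel takes the arg-max channel's
primary color, so the seven classes partition the cell's thylakoid area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segment import CellMask
from .synthgen import MultiChannelImage

MD_CLASSES: tuple[str, ...] = (
    "background", "red", "green", "blue", "yellow", "magenta", "cyan", "white",
)
#: label value per class name (background = 0)
MD_LABELS: dict[str, int] = {name: i for i, name in enumerate(MD_CLASSES)}
#: dominance subset (PSII, PSI, PBS) -> class name; arg-max fallback uses singles
_SUBSET_TO_CLASS: dict[tuple[bool, bool, bool], str] = {
    (True, False, False): "red",
    (False, True, False): "green",
    (False, False, True): "blue",
    (True, True, False): "yellow",
    (True, False, True): "magenta",
    (False, True, True): "cyan",
    (True, True, True): "white",
}
#: indexed-color palette for MD map export (RGB per label)
MD_PALETTE: dict[str, tuple[int, int, int]] = {
    "background": (0, 0, 0),
    "red": (255, 0, 0),
    "green": (0, 255, 0),
    "blue": (0, 0, 255),
    "yellow": (255, 255, 0),
    "magenta": (255, 0, 255),
    "cyan": (0, 255, 255),
    "white": (255, 255, 255),
}

DEFAULT_TAU = 0.5
#: fraction of the normalized scale below which an in-mask pixel is not
#: counted as thylakoid signal
DEFAULT_FOREGROUND_FLOOR = 0.25


@dataclass
class MDComposition:
    """Per-class fraction of a cell's thylakoid area."""

    fractions: dict[str, float]
    dominant_class: str
    n_thylakoid_px: int


def normalize_channels(image: MultiChannelImage, mask: CellMask) -> np.ndarray:
    """Per-cell, per-channel normalization to the robust (99th pct) maximum.

    Returns an (n_pixels, 3) array in [0, 1] aligned with ``mask.pixels``.
    A channel that is identically zero within the mask stays all-zero.
    """
    if mask.area_px == 0:
        raise ValueError("empty mask")
    rr, cc = mask.pixels
    vals = image.channels[:, rr, cc].astype(float)  # (3, n)
    out = np.zeros_like(vals)
    for ch in range(3):
        robust_max = np.percentile(vals[ch], 99)
        if robust_max > 0:
            out[ch] = np.clip(vals[ch] / robust_max, 0.0, 1.0)
    return out.T


def classify_md(normalized: np.ndarray, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Label normalized (n, 3) triples with MD class indices.

    A channel is dominant when its normalized value >= ``tau``; the label is
    the additive color of the dominant subset, falling back to the arg-max
    channel's primary color when no channel clears ``tau``.
    """
    if not (0 < tau < 1):
        raise ValueError("tau must lie in (0, 1)")
    normalized = np.atleast_2d(np.asarray(normalized, dtype=float))
    dom = normalized >= tau
    labels = np.empty(len(normalized), dtype=np.int32)
    none = ~dom.any(axis=1)
    if none.any():
        arg = normalized[none].argmax(axis=1)
        single = np.array([MD_LABELS["red"], MD_LABELS["green"], MD_LABELS["blue"]])
        labels[none] = single[arg]
    some = ~none
    if some.any():
        keys = dom[some]
        lut = np.zeros(8, dtype=np.int32)
        for subset, name in _SUBSET_TO_CLASS.items():
            lut[subset[0] * 4 + subset[1] * 2 + subset[2]] = MD_LABELS[name]
        code = keys[:, 0] * 4 + keys[:, 1] * 2 + keys[:, 2]
        labels[some] = lut[code]
    return labels


def md_map(
    image: MultiChannelImage,
    mask: CellMask,
    tau: float = DEFAULT_TAU,
    foreground_floor: float = DEFAULT_FOREGROUND_FLOOR,
) -> np.ndarray:
    """Full-frame MD label raster for one cell (0 = background).

    Pixels whose maximum normalized channel stays below ``foreground_floor``
    (the dim ring interior) remain background.
    """
    norm = normalize_channels(image, mask)
    thylakoid = norm.max(axis=1) >= foreground_floor
    out = np.zeros(mask.shape, dtype=np.int32)
    if thylakoid.any():
        labels = classify_md(norm[thylakoid], tau)
        rr, cc = mask.pixels
        out[rr[thylakoid], cc[thylakoid]] = labels
    return out


def md_composition(mdmap: np.ndarray, mask: CellMask) -> MDComposition:
    """Per-class fractions of the cell's thylakoid (non-background) pixels."""
    if mask.area_px == 0:
        raise ValueError("empty mask")
    rr, cc = mask.pixels
    labs = mdmap[rr, cc]
    labs = labs[labs != 0]
    if labs.size == 0:
        raise ValueError("cell has no thylakoid pixels in the MD map")
    counts = np.bincount(labs, minlength=len(MD_CLASSES))
    fractions = {name: counts[MD_LABELS[name]] / labs.size for name in MD_CLASSES[1:]}
    dominant = max(fractions, key=fractions.get)
    return MDComposition(fractions=fractions, dominant_class=dominant, n_thylakoid_px=int(labs.size))


def heterogeneity_index(
    image: MultiChannelImage,
    mask: CellMask,
    channel: str,
    foreground_floor: float = DEFAULT_FOREGROUND_FLOOR,
) -> float:
    """Coefficient of variation of one channel over the cell's thylakoid pixels.

    Operationalizes "more/less homogeneous distribution" of a complex in the
    membrane.  Requires >= 10 thylakoid pixels; a zero mean yields NaN.
    """
    norm = normalize_channels(image, mask)
    thylakoid = norm.max(axis=1) >= foreground_floor
    if thylakoid.sum() < 10:
        raise ValueError("need at least 10 thylakoid pixels")
    rr, cc = mask.pixels
    from .synthgen import CHANNEL_NAMES

    vals = image.channels[CHANNEL_NAMES.index(channel), rr[thylakoid], cc[thylakoid]].astype(float)
    mean = vals.mean()
    if mean == 0:
        return float("nan")
    return float(vals.std() / mean)


def write_md_map(path, mdmap: np.ndarray) -> None:
    """Write an MD map as an RGB single-page TIFF using the documented palette."""
    import tifffile

    rgb = np.zeros((*mdmap.shape, 3), dtype=np.uint8)
    for name, lab in MD_LABELS.items():
        rgb[mdmap == lab] = MD_PALETTE[name]
    tifffile.imwrite(path, rgb, photometric="rgb")
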