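"""Shape descriptors and four-way cell typing.

Three classical ImageJ-style descriptors drive the typing:

* circularity = 4*pi*area / perimeter^2 (Crofton perimeter, 4 directions),
  clamped to <= 1;
* roundness = 4*area / (pi * major_axis^2), major axis from the best-fit
  ellipse (second image moments) — equals minor/major for a true ellipse;
* Feret diameter = the longest distance between any two boundary points,
  computed over the convex hull of the boundary pixels.

Cells are classified regular / elongated / dividing / string with a fixed
precedence (string > dividing > elongated > regular) because the printed
threshold boxes overlap; the precedence rule replaces any manual
re-assignment with a deterministic one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

from .segment import CellMask

CELL_TYPES: tuple[str, ...] = ("regular", "elongated", "dividing", "string")


@dataclass(frozen=True)
class ShapeThresholds:
    """Classification thresholds; Feret bounds are micrometres."""

    regular_circularity: float = 0.8
    elongated_circularity: float = 0.8
    elongated_roundness: float = 0.9
    elongated_feret_um: float = 2.2
    dividing_circularity: float = 0.85
    dividing_feret_um: float = 2.8
    string_circularity: float = 0.7
    constriction_depth: float = 0.2


@dataclass
class ShapeMetrics:
    circularity: float
    roundness: float
    feret_um: float
    major_axis_um: float
    has_constriction: bool = False
    is_string_member: bool = False


def boundary_pixels(mask_arr: np.ndarray) -> np.ndarray:
    """(N, 2) row/col coordinates of the mask's inner boundary pixels."""
    from scipy.ndimage import binary_erosion

    eroded = binary_erosion(mask_arr, structure=np.ones((3, 3), dtype=bool))
    rr, cc = np.nonzero(mask_arr & ~eroded)
    return np.column_stack([rr, cc])


def feret_diameter_px(mask_arr: np.ndarray) -> float:
    """Max pairwise distance between boundary pixel centers (hull-accelerated)."""
    pts = boundary_pixels(mask_arr).astype(float)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear point sets
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def shape_metrics(mask: CellMask, pixel_size_um: float | None = None) -> ShapeMetrics:
    """Compute circularity, roundness and Feret diameter for one mask.

    The mask may be disconnected (a merged string doublet): area and perimeter
    then sum over the parts and the Feret spans both, which is exactly what
    pushes a doublet's circularity below the string threshold.
    """
    px = mask.pixel_size_um if pixel_size_um is None else pixel_size_um
    if px <= 0:
        raise ValueError("pixel size must be > 0")
    if mask.area_px < 2:
        raise ValueError("degenerate mask: need at least 2 pixels for a perimeter")
    arr = _crop(mask)
    area = float(arr.sum())
    perim = float(measure.perimeter_crofton(arr, directions=4))
    if perim <= 0:
        raise ValueError("degenerate mask: zero perimeter")
    circularity = min(4.0 * np.pi * area / perim**2, 1.0)
    major_px = _major_axis_px(arr)
    roundness = min(4.0 * area / (np.pi * major_px**2), 1.0) if major_px > 0 else 1.0
    feret = feret_diameter_px(arr) * px
    return ShapeMetrics(
        circularity=circularity,
        roundness=roundness,
        feret_um=feret,
        major_axis_um=major_px * px,
    )


def _crop(mask: CellMask) -> np.ndarray:
    r0, c0, r1, c1 = mask.bbox
    out = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
    out[mask.pixels[0] - r0 + 1, mask.pixels[1] - c0 + 1] = True
    return out


def _major_axis_px(arr: np.ndarray) -> float:
    props = measure.regionprops(arr.astype(np.uint8))
    # disconnected doublets: take the moments of the whole pixel set
    if len(props) != 1:
        rr, cc = np.nonzero(arr)
        coords = np.column_stack([rr, cc]).astype(float)
        coords -= coords.mean(axis=0)
        cov = coords.T @ coords / len(coords)
        evals = np.linalg.eigvalsh(cov)
        return float(4.0 * np.sqrt(max(evals[-1], 0.0)))
    return float(props[0].axis_major_length)


def detect_constriction(
    mask: CellMask,
    depth_threshold: float = 0.2,
    n_stations: int = 25,
) -> bool:
    """Detect a division waist from the width profile along the major axis.

    The mask's pixels are rotated into the principal frame; at >= 20 stations
    along the major axis the perpendicular width (max - min of the transverse
    coordinate) is measured.  A constriction is an interior local minimum at
    most ``(1 - depth_threshold)`` times the mean of its flanking maxima.
    Masks spanning fewer than 5 populated stations report False.
    """
    rr, cc = mask.pixels
    coords = np.column_stack([rr, cc]).astype(float)
    coords -= coords.mean(axis=0)
    cov = coords.T @ coords / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    u = coords @ axis
    v = coords @ evecs[:, 0]
    u_min, u_max = u.min(), u.max()
    if u_max - u_min < 5:
        return False
    edges = np.linspace(u_min, u_max, n_stations + 1)
    widths = np.full(n_stations, np.nan)
    idx = np.clip(np.searchsorted(edges, u, side="right") - 1, 0, n_stations - 1)
    for k in range(n_stations):
        sel = idx == k
        if sel.sum() >= 2:
            widths[k] = v[sel].max() - v[sel].min()
    valid = ~np.isnan(widths)
    if valid.sum() < 5:
        return False
    w = widths[valid]
    # a division waist sits between the two lobes: only interior minima in the
    # middle third of the profile count, which rejects the taper of a plain
    # ellipse where rasterization jitter mimics shallow dips
    lo, hi = len(w) // 3, len(w) - len(w) // 3
    for i in range(max(lo, 1), min(hi, len(w) - 1)):
        if not (w[i] <= w[i - 1] and w[i] <= w[i + 1]):
            continue
        left_max = w[:i].max()
        right_max = w[i + 1:].max()
        flank = 0.5 * (left_max + right_max)
        if left_max > w[i] and right_max > w[i] and w[i] <= (1 - depth_threshold) * flank:
            return True
    return False


def classify_cell(m: ShapeMetrics, thresholds: ShapeThresholds = ShapeThresholds()) -> str:
    """Map shape metrics to one of the four cell types (total function).

    Precedence string > dividing > elongated > regular resolves the
    overlapping threshold boxes deterministically.
    """
    t = thresholds
    if m.is_string_member and m.circularity < t.string_circularity:
        return "string"
    if m.has_constriction and m.circularity < t.dividing_circularity and m.feret_um > t.dividing_feret_um:
        return "dividing"
    if (
        m.circularity < t.elongated_circularity
        and m.roundness < t.elongated_roundness
        and m.feret_um > t.elongated_feret_um
    ):
        return "elongated"
    return "regular"


def analyze_shapes(
    masks: list,
    string_pairs: list[tuple[int, int]],
    pixel_size_um: float | None = None,
    thresholds: ShapeThresholds = ShapeThresholds(),
) -> dict[int, tuple[ShapeMetrics, str]]:
    """Metrics + type for every mask; string pairs are measured as their union.

    Both members of a detected string pair receive the union's metrics and
    (if it passes the circularity gate) the ``string`` type.
    """
    from .segment import merge_masks

    by_label = {m.label: m for m in masks}
    in_pair: dict[int, int] = {}
    for a, b in string_pairs:
        in_pair[a] = b
        in_pair[b] = a
    out: dict[int, tuple[ShapeMetrics, str]] = {}
    done: set[int] = set()
    for m in masks:
        if m.label in done:
            continue
        if m.label in in_pair:
            partner = by_label[in_pair[m.label]]
            union = merge_masks(m, partner)
            metrics = shape_metrics(union, pixel_size_um)
            metrics.is_string_member = True
            metrics.has_constriction = False
            ctype = classify_cell(metrics, thresholds)
            out[m.label] = (metrics, ctype)
            out[partner.label] = (metrics, ctype)
            done.update((m.label, partner.label))
        else:
            metrics = shape_metrics(m, pixel_size_um)
            metrics.has_constriction = detect_constriction(m, thresholds.constriction_depth)
            ctype = classify_cell(metrics, thresholds)
            out[m.label] = (metrics, ctype)
            done.add(m.label)
    return out
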