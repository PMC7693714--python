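"""Single-cell segmentation of multichannel fluorescence frames.

Cells are found by Otsu thresholding the summed fluorescence channels (a cell
dark in one channel — a microdomain by definition has channel-poor zones — is
still bright in the sum), filling the thylakoid-ring interior, and labeling
4-connected components.  Oversized components, the plausible mergers of
touching cells, are split by a distance-transform watershed whose seeds keep a
minimum 0.8 um separation.  String-cell doublets — separate in fluorescence
but bridged in the transmission image — are paired afterwards from the
transmission channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation as sk_seg
from skimage.feature import peak_local_max

from .synthgen import MultiChannelImage

#: components above this area (um^2) are candidates for watershed splitting;
#: single Synechocystis cells stay well below it.
DEFAULT_SPLIT_MIN_AREA_UM2 = 7.0
#: minimum watershed seed separation (um), to avoid shredding elongated cells
DEFAULT_SEED_SEPARATION_UM = 0.8


@dataclass
class CellMask:
    """One segmented cell: a 4-connected set of pixels on the frame grid."""

    label: int
    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols), 0-based
    shape: tuple[int, int]  # frame shape the coordinates refer to
    pixel_size_um: float

    @property
    def area_px(self) -> int:
        return int(self.pixels[0].size)

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.pixels[0].mean()), float(self.pixels[1].mean())

    def to_array(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        out[self.pixels] = True
        return out

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        r, c = self.pixels
        return int(r.min()), int(c.min()), int(r.max()) + 1, int(c.max()) + 1


def merge_masks(a: CellMask, b: CellMask, label: int | None = None) -> CellMask:
    """Union of two disjoint masks from the same frame (string doublets)."""
    if a.shape != b.shape:
        raise ValueError("masks come from different frames")
    rows = np.concatenate([a.pixels[0], b.pixels[0]])
    cols = np.concatenate([a.pixels[1], b.pixels[1]])
    return CellMask(
        label=label if label is not None else a.label,
        pixels=(rows, cols),
        shape=a.shape,
        pixel_size_um=a.pixel_size_um,
    )


def _label_to_masks(labeled: np.ndarray, pixel_size_um: float) -> list[CellMask]:
    masks = []
    for p in measure.regionprops(labeled):
        coords = p.coords
        masks.append(
            CellMask(int(p.label), (coords[:, 0], coords[:, 1]), labeled.shape, pixel_size_um)
        )
    masks.sort(key=lambda m: m.label)
    return masks


def segment_cells(
    image: MultiChannelImage,
    min_area_um2: float = 0.8,
    max_area_um2: float = 12.0,
    split_min_area_um2: float = DEFAULT_SPLIT_MIN_AREA_UM2,
    seed_separation_um: float = DEFAULT_SEED_SEPARATION_UM,
) -> list[CellMask]:
    """Segment single cells from the three summed fluorescence channels.

    Returns masks sorted by label; labels are assigned in raster order of the
    component centroids, so re-running on the same frame is deterministic.
    An all-zero frame yields an empty list.
    """
    if not min_area_um2 < max_area_um2:
        raise ValueError("min_area_um2 must be < max_area_um2")
    px = image.pixel_size_um
    summed = image.channels.astype(np.float64).sum(axis=0)
    if summed.max() <= 0:
        return []
    thresh = filters.threshold_otsu(summed)
    fg = summed > thresh
    fg = ndimage.binary_fill_holes(fg)
    fg = morphology.remove_small_objects(fg, max_size=max(int(min_area_um2 / px**2 / 4), 1))
    labeled = measure.label(fg, connectivity=1)

    # split only oversized components (likely touching cells)
    split_px = split_min_area_um2 / px**2
    min_dist = max(int(round(seed_separation_um / px)), 1)
    sizes = np.bincount(labeled.ravel())
    big = [lab for lab in range(1, sizes.size) if sizes[lab] > split_px]
    if big:
        next_label = labeled.max() + 1
        for lab in big:
            comp = labeled == lab
            dist = ndimage.distance_transform_edt(comp)
            peaks = peak_local_max(dist, min_distance=min_dist, labels=comp, exclude_border=False)
            if len(peaks) <= 1:
                continue
            markers = np.zeros_like(labeled)
            for k, (r, c) in enumerate(peaks):
                markers[r, c] = k + 1
            parts = sk_seg.watershed(-dist, markers=markers, mask=comp, connectivity=1)
            labeled[comp] = 0
            for k in range(1, parts.max() + 1):
                labeled[parts == k] = next_label
                next_label += 1

    # area filter + deterministic relabeling by centroid raster order
    min_px, max_px = min_area_um2 / px**2, max_area_um2 / px**2
    props = measure.regionprops(labeled)
    kept = [p for p in props if min_px <= p.area <= max_px]
    kept.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    out = np.zeros_like(labeled)
    for new_lab, p in enumerate(kept, start=1):
        rr, cc = p.coords[:, 0], p.coords[:, 1]
        out[rr, cc] = new_lab
    return _label_to_masks(out, px)


def detect_string_pairs(
    masks: list[CellMask],
    transmission: np.ndarray | None,
) -> list[tuple[int, int]]:
    """Pair masks that are disjoint in fluorescence but share one transmission body.

    Each mask joins at most one pair; when a transmission component covers more
    than two masks, nearest centroids pair up first.  A missing transmission
    channel yields no pairs and a warning.
    """
    if transmission is None:
        warnings.warn("no transmission channel; string detection skipped", stacklevel=2)
        return []
    if not masks:
        return []
    trans = transmission.astype(np.float64)
    if trans.max() <= 0:
        return []
    fg = trans > filters.threshold_otsu(trans)
    comp = measure.label(fg, connectivity=1)
    by_comp: dict[int, list[CellMask]] = {}
    for m in masks:
        rr, cc = m.pixels
        labs, counts = np.unique(comp[rr, cc], return_counts=True)
        nz = labs != 0
        if not nz.any():
            continue
        home = int(labs[nz][np.argmax(counts[nz])])
        by_comp.setdefault(home, []).append(m)
    pairs: list[tuple[int, int]] = []
    for members in by_comp.values():
        if len(members) < 2:
            continue
        free = {m.label: m for m in members}
        # greedy nearest-centroid matching
        cand = []
        mem = list(members)
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                ci, cj = mem[i].centroid, mem[j].centroid
                d = (ci[0] - cj[0]) ** 2 + (ci[1] - cj[1]) ** 2
                cand.append((d, mem[i].label, mem[j].label))
        for _, la, lb in sorted(cand):
            if la in free and lb in free:
                pairs.append((min(la, lb), max(la, lb)))
                del free[la], free[lb]
    return sorted(pairs)


def masks_to_label_raster(masks: list[CellMask], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=np.int32)
    for m in masks:
        out[m.pixels] = m.label
    return out


def match_to_ground_truth(
    masks: list[CellMask],
    truth_labels: np.ndarray,
    min_jaccard: float = 0.7,
) -> pd.DataFrame:
    """Greedy best-overlap matching of segmented masks to ground-truth labels.

    Returns one row per segmented mask with its best-overlap truth label and
    Jaccard index; ``matched`` marks Jaccard >= ``min_jaccard`` with each truth
    label claimed at most once.
    """
    truth_sizes = np.bincount(truth_labels.ravel())
    rows = []
    for m in masks:
        rr, cc = m.pixels
        labs, counts = np.unique(truth_labels[rr, cc], return_counts=True)
        nz = labs != 0
        if not nz.any():
            rows.append({"label": m.label, "truth_label": 0, "jaccard": 0.0})
            continue
        best = np.argmax(counts[nz])
        tl = int(labs[nz][best])
        inter = int(counts[nz][best])
        union = m.area_px + int(truth_sizes[tl]) - inter
        rows.append({"label": m.label, "truth_label": tl, "jaccard": inter / union})
    df = pd.DataFrame(rows)
    df["matched"] = False
    claimed: set[int] = set()
    for i in df.sort_values("jaccard", ascending=False).index:
        tl = df.at[i, "truth_label"]
        if tl != 0 and tl not in claimed and df.at[i, "jaccard"] >= min_jaccard:
            df.at[i, "matched"] = True
            claimed.add(tl)
    return df
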