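"""Microdomain classes: the seven-color logic, partition invariants, and the
heterogeneity index."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cyanomd as cm
from cyanomd.microdomains import (
    MD_CLASSES,
    MD_LABELS,
    classify_md,
    heterogeneity_index,
    md_composition,
    md_map,
    normalize_channels,
)

from conftest import UNIFORM_PATTERN, render_single


def _patchy_cell(heterogeneity, noise_sd=0.0, seed=2):
    spec = cm.CellShapeSpec("regular", (60, 60), 2.4, 2.4)
    pat = cm.MDPatternSpec(
        4,
        0.35,
        ((1.0, 0.1, 0.1), (0.1, 1.0, 0.1), (0.1, 0.1, 1.0), (0.8, 0.8, 0.1)),
        (120, 110, 125),
        heterogeneity,
    )
    image, labels, _ = render_single(spec, pat, noise_sd=noise_sd, seed=seed)
    masks = cm.segment_cells(image)
    assert len(masks) == 1
    return image, masks[0]


class TestClassifyMD:
    def test_seven_distinct_classes_over_dominance_subsets(self):
        """All 7 nonempty dominance subsets map to 7 distinct non-background labels."""
        labels = set()
        for subset in itertools.product([0.9, 0.1], repeat=3):
            if subset == (0.1, 0.1, 0.1):
                continue
            labels.add(int(classify_md(np.array(subset), tau=0.5)[0]))
        assert len(labels) == 7
        assert 0 not in labels  # background never produced inside a mask

    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((0.9, 0.1, 0.1), "red"),  # PSII-only dominance
            ((0.9, 0.9, 0.9), "white"),  # all three high
            ((0.9, 0.1, 0.9), "magenta"),  # PSII + PBS
            ((0.1, 0.9, 0.9), "cyan"),  # PSI + PBS
            ((0.9, 0.9, 0.1), "yellow"),  # PSII + PSI
        ],
    )
    def test_color_convention(self, triple, expected):
        assert classify_md(np.array(triple), tau=0.5)[0] == MD_LABELS[expected]

    def test_argmax_fallback_never_background(self):
        lab = classify_md(np.array([0.3, 0.2, 0.1]), tau=0.5)[0]
        assert lab == MD_LABELS["red"]

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            classify_md(np.array([0.5, 0.5, 0.5]), tau=1.5)

    @given(
        vals=st.lists(
            st.tuples(*[st.floats(0, 1)] * 3), min_size=1, max_size=20
        ),
        tau=st.floats(0.05, 0.95),
    )
    @settings(max_examples=200, deadline=None)
    def test_permutation_equivariance(self, vals, tau):
        """Permuting the three channels permutes the color labels accordingly."""
        from hypothesis import assume

        arr = np.array(vals)
        # the arg-max fallback is only equivariant when the maximum is unique
        sub = arr[arr.max(axis=1) < tau]
        assume(
            sub.size == 0
            or all((row == row.max()).sum() == 1 for row in sub)
        )
        perm = (1, 2, 0)  # PSII->PSI->PBS->PSII
        color_perm = {
            "red": "green", "green": "blue", "blue": "red",
            "yellow": "cyan", "cyan": "magenta", "magenta": "yellow",
            "white": "white",
        }
        base = classify_md(arr, tau)
        permuted = classify_md(arr[:, list(perm)], tau)
        # build the inverse mapping: channel permutation by `perm` means
        # channel i of the permuted input is channel perm[i] of the original,
        # so original color c maps to color_perm^{-1}[c]
        inv = {MD_LABELS[b]: MD_LABELS[a] for a, b in color_perm.items()}
        assert [inv[int(l)] for l in base] == [int(l) for l in permuted]

    def test_raising_tau_never_increases_white_fraction(self):
        image, mask = _patchy_cell(0.9)
        fracs = []
        for tau in (0.3, 0.5, 0.7, 0.9):
            comp = md_composition(md_map(image, mask, tau=tau), mask)
            fracs.append(comp.fractions["white"])
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestNormalization:
    def test_uniform_ring_normalizes_to_one(self):
        spec = cm.CellShapeSpec("regular", (60, 60), 2.0, 2.0)
        image, _, _ = render_single(spec)
        mask = cm.segment_cells(image)[0]
        norm = normalize_channels(image, mask)
        ring = norm[norm.max(axis=1) > 0]
        assert np.all(ring >= 0.99)

    def test_scale_invariance(self):
        # dim cell so doubling stays inside the 8-bit range
        spec = cm.CellShapeSpec("regular", (60, 60), 2.4, 2.4)
        pat = cm.MDPatternSpec(
            2, 0.35, ((1.0, 0.2, 0.1), (0.1, 1.0, 0.3)), (60, 55, 62), 0.8
        )
        image, _, _ = render_single(spec, pat)
        mask = cm.segment_cells(image)[0]
        assert int(image.channels.max()) * 2 <= 255
        doubled = cm.MultiChannelImage(
            (image.channels.astype(np.uint16) * 2).astype(np.uint8),
            image.transmission,
            image.pixel_size_um,
        )
        np.testing.assert_allclose(
            normalize_channels(image, mask), normalize_channels(doubled, mask), atol=1e-12
        )

    def test_zero_channel_stays_zero(self):
        spec = cm.CellShapeSpec("regular", (60, 60), 2.0, 2.0)
        pat = cm.MDPatternSpec(0, 0.3, (), (120.0, 110.0, 0.0))
        image, _, _ = render_single(spec, pat)
        mask = cm.segment_cells(image)[0]
        norm = normalize_channels(image, mask)
        assert norm[:, 2].max() == 0.0

    def test_enriched_patch_exceeds_interpatch_zone(self):
        """The enriched channel normalizes higher at patch centers than between."""
        spec = cm.CellShapeSpec("regular", (60, 60), 2.4, 2.4)
        pat = cm.MDPatternSpec(
            1, 0.3, ((0.0, 1.0, 0.0),), (120, 110, 125), 1.5, centers_um=((0.0, 1.05),)
        )
        image, _, _ = render_single(spec, pat)
        mask = cm.segment_cells(image)[0]
        norm = normalize_channels(image, mask)
        thyl = norm.max(axis=1) > 0.25
        psi = norm[thyl, 1]
        assert psi.max() > psi.min() + 0.3


class TestComposition:
    def test_fractions_partition_to_one(self):
        image, mask = _patchy_cell(0.9, noise_sd=5.0)
        comp = md_composition(md_map(image, mask), mask)
        assert sum(comp.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(f >= 0 for f in comp.fractions.values())

    def test_all_white_map(self):
        image, mask = _patchy_cell(0.0)  # uniform: every channel at its max
        comp = md_composition(md_map(image, mask), mask)
        assert comp.fractions["white"] == pytest.approx(1.0)
        assert comp.dominant_class == "white"

    def test_one_pixel_per_class_uniform_fractions(self):
        mdmap = np.zeros((3, 3), dtype=np.int32)
        rr = np.array([0, 0, 0, 1, 1, 1, 2])
        cc = np.array([0, 1, 2, 0, 1, 2, 0])
        for i in range(7):
            mdmap[rr[i], cc[i]] = i + 1
        from cyanomd.segment import CellMask

        mask = CellMask(1, (rr, cc), (3, 3), 0.08)
        comp = md_composition(mdmap, mask)
        for name in MD_CLASSES[1:]:
            assert comp.fractions[name] == pytest.approx(1 / 7)

    def test_empty_mask_rejected(self):
        from cyanomd.segment import CellMask

        empty = CellMask(1, (np.array([], int), np.array([], int)), (4, 4), 0.08)
        with pytest.raises(ValueError):
            md_composition(np.zeros((4, 4), dtype=np.int32), empty)


class TestHeterogeneityIndex:
    def test_uniform_ring_zero_cv(self):
        spec = cm.CellShapeSpec("regular", (60, 60), 2.0, 2.0)
        image, _, _ = render_single(spec)
        mask = cm.segment_cells(image)[0]
        assert heterogeneity_index(image, mask, "psi") == pytest.approx(0.0, abs=1e-9)

    def test_cv_monotone_in_generator_contrast(self):
        _, m0 = _patchy_cell(0.0)
        img0, m0 = _patchy_cell(0.0)
        img1, m1 = _patchy_cell(1.0)
        assert heterogeneity_index(img1, m1, "psi") > heterogeneity_index(img0, m0, "psi")

    def test_cl_preset_psi_cv_exceeds_ld_preset(self):
        """Continuous-light conditions show patchier PSI than light-dark."""
        from cyanomd.synthgen import CL_PRESET, LD_PRESET, generate_diel_series

        cvs = {}
        for name, preset in (("cl", CL_PRESET), ("ld", LD_PRESET)):
            series = generate_diel_series(preset, 1, seed=8, n_cells=40, shape=(640, 640))
            image, _, _ = series.render_timepoint(series.timepoints[0])
            masks = cm.segment_cells(image)
            vals = []
            for m in masks:
                try:
                    vals.append(heterogeneity_index(image, m, "psi"))
                except ValueError:
                    pass
            cvs[name] = np.mean(vals)
        assert cvs["cl"] > cvs["ld"]
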