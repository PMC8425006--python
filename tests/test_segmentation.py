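"""Nucleus/cell/cytoplasm segmentation against generator ground truth."""

import numpy as np
import pytest

from ermorph import (
    LabelMap,
    derive_cytoplasm,
    remove_border_cells,
    segment_cells,
    segment_field,
    segment_nuclei,
)
from ermorph.synthetic_data import _ellipse_mask, oval_nuclei_image

from conftest import jaccard, match_truth_cells


def _disc(shape, cy, cx, r):
    return _ellipse_mask(shape, cy, cx, r, r, 0.0)


class TestSegmentNuclei:
    def test_three_separated_ovals(self):
        img, truth = oval_nuclei_image()
        nuclei = segment_nuclei(img, pixel_size_um=1.0, min_nucleus_area_um2=60)
        assert len(nuclei) == 3
        for lab in np.unique(truth)[1:]:
            got = nuclei.labels[truth == lab]
            got = got[got > 0]
            assert got.size > 0 and len(np.unique(got)) == 1

    def test_all_zero_image(self):
        with pytest.warns(UserWarning, match="constant"):
            nuclei = segment_nuclei(np.zeros((64, 64)), pixel_size_um=1.0)
        assert len(nuclei) == 0

    def test_touching_ovals_split_in_two(self):
        """Two nuclei joined by a thin neck must be split by the seeded
        watershed into exactly two labels."""
        shape = (96, 96)
        img = np.full(shape, 50.0)
        a = _ellipse_mask(shape, 48, 30, 16, 13, 0.0)
        b = _ellipse_mask(shape, 48, 62, 16, 13, 0.0)
        img[a | b] = 3000.0
        nuclei = segment_nuclei(img, pixel_size_um=1.0, min_nucleus_area_um2=60)
        assert len(nuclei) == 2

    def test_translation_equivariance_of_foreground(self):
        img, _ = oval_nuclei_image()
        shifted = np.roll(img, (9, -6), axis=(0, 1))
        seg_a = segment_nuclei(img, pixel_size_um=1.0).labels > 0
        seg_b = segment_nuclei(shifted, pixel_size_um=1.0).labels > 0
        np.testing.assert_array_equal(np.roll(seg_a, (9, -6), axis=(0, 1)), seg_b)


class TestSegmentCells:
    def test_single_cell_recovers_footprint(self):
        shape = (128, 128)
        cell = _disc(shape, 64, 64, 50)
        membrane = np.where(cell, 800.0, 50.0)
        nucleus_img = np.where(_disc(shape, 64, 64, 18), 3000.0, 50.0)
        nuclei = segment_nuclei(nucleus_img, pixel_size_um=1.0, min_nucleus_area_um2=60)
        cells = segment_cells(membrane, nuclei)
        assert len(cells) == 1
        assert jaccard(cells.labels > 0, cell) >= 0.9

    def test_noiseless_field_jaccard(self, noiseless_field):
        """Every clean generated cell is recovered with Jaccard >= 0.9."""
        field, truth = noiseless_field
        seg = segment_field(
            field.channels["nucleus"], field.channels["er"],
            truth.params.pixel_size_um, membrane_channel=field.channels["membrane"],
        )
        mapping = match_truth_cells(truth, seg.cells)
        for c in truth.cells:
            if c.intended_fate is not None:
                continue
            sl = mapping[c.label]
            assert sl is not None
            assert jaccard(seg.cells.labels == sl, truth.cell_mask(c.label)) >= 0.9

    def test_two_disjoint_footprints_bijective(self):
        shape = (128, 192)
        cells_true = [_disc(shape, 64, 50, 40), _disc(shape, 64, 140, 40)]
        membrane = np.full(shape, 50.0)
        nucleus_img = np.full(shape, 50.0)
        for i, cm in enumerate(cells_true):
            membrane[cm] = 800.0
            nucleus_img[_disc(shape, 64, 50 + 90 * i, 14)] = 3000.0
        nuclei = segment_nuclei(nucleus_img, pixel_size_um=1.0, min_nucleus_area_um2=60)
        cells = segment_cells(membrane, nuclei)
        assert len(nuclei) == len(cells) == 2
        for n in nuclei.ids:  # label-preserving growth: nucleus n seeds cell n
            assert ((nuclei.labels == n) & ~(cells.labels == n)).sum() == 0

    def test_no_seeds_no_cells(self):
        nuclei = LabelMap(np.zeros((32, 32), np.int32), 1.0)
        cells = segment_cells(np.random.default_rng(0).uniform(0, 1, (32, 32)), nuclei)
        assert len(cells) == 0


class TestCytoplasmAndBorder:
    def test_concentric_discs_annulus(self):
        shape = (96, 96)
        cells = LabelMap(_disc(shape, 48, 48, 30).astype(np.int32), 1.0)
        nuclei = LabelMap(_disc(shape, 48, 48, 10).astype(np.int32), 1.0)
        cyto = derive_cytoplasm(cells, nuclei, {1: 1})
        expected = np.pi * (30**2 - 10**2)
        assert (cyto.labels == 1).sum() == pytest.approx(expected, rel=0.05)

    def test_nucleus_equals_cell_gives_empty_cytoplasm(self):
        shape = (64, 64)
        m = _disc(shape, 32, 32, 20).astype(np.int32)
        cyto = derive_cytoplasm(LabelMap(m, 1.0), LabelMap(m.copy(), 1.0), {1: 1})
        assert (cyto.labels == 1).sum() == 0

    def test_cytoplasm_arithmetic_on_field(self, noiseless_field):
        """cytoplasm area = cell area − nucleus area, exactly, per cell."""
        field, truth = noiseless_field
        px = truth.params.pixel_size_um
        seg = segment_field(
            field.channels["nucleus"], field.channels["er"], px,
            membrane_channel=field.channels["membrane"],
        )
        for n, c in seg.nucleus_to_cell.items():
            cell_a = (seg.cells.labels == c).sum()
            nuc_a = ((seg.nuclei.labels == n) & (seg.cells.labels == c)).sum()
            cyto_a = (seg.cytoplasm.labels == c).sum()
            n_in_cell = sum(
                ((seg.nuclei.labels == m) & (seg.cells.labels == c)).sum()
                for m, cc in seg.nucleus_to_cell.items() if cc == c
            )
            assert cyto_a == cell_a - n_in_cell
            assert nuc_a > 0

    def test_remove_border_cells(self):
        shape = (64, 64)
        lab = np.zeros(shape, np.int32)
        lab[_disc(shape, 32, 32, 10)] = 1  # interior
        lab[:5, 20:30] = 2  # touches top edge
        out = remove_border_cells(LabelMap(lab, 1.0))
        assert list(out.ids) == [1]
        single = np.zeros(shape, np.int32)
        single[_disc(shape, 32, 32, 10)] = 1
        np.testing.assert_array_equal(
            remove_border_cells(LabelMap(single, 1.0)).labels, single
        )

    def test_border_preset_cell_is_discarded(self):
        from ermorph import GeneratorParams, generate_field

        field, truth = generate_field(
            GeneratorParams(seed=5, n_cells=3, defects={0: "border"},
                            poisson_gain=0.0, read_noise_sd=0.0)
        )
        seg = segment_field(
            field.channels["nucleus"], field.channels["er"],
            truth.params.pixel_size_um, membrane_channel=field.channels["membrane"],
        )
        border_truth = truth.cell_mask(1)
        # the border-crossing footprint must not survive segmentation
        surviving = seg.cells.labels[border_truth]
        assert (surviving > 0).mean() < 0.5
        assert len(seg.cells) == 2


class TestContainmentInvariants:
    def test_nucleus_inside_cell_everywhere(self, clean_field):
        field, truth = clean_field
        seg = segment_field(
            field.channels["nucleus"], field.channels["er"],
            truth.params.pixel_size_um, membrane_channel=field.channels["membrane"],
        )
        for n, c in seg.nucleus_to_cell.items():
            nuc = seg.nuclei.labels == n
            assert (nuc & (seg.cells.labels != c)).sum() == 0
        # cells pairwise disjoint by construction of a label map; check
        # nuclei too
        assert (np.bincount(seg.nuclei.labels.ravel())[1:] >= 0).all()
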