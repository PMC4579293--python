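"""Visitation-map dissection: thresholding, overlap, composites, protocol."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tractdissect as td
from tractdissect.masks import ROIMask
from tractdissect.dissection import (
    StreamlineMask,
    composite,
    dice,
    dissect_pathway,
    overlap_bidirectional,
    threshold_map,
)
from tractdissect.tracker import TrackerConfig, VisitationMap


def vmap_from(counts):
    counts = np.asarray(counts, dtype=np.int32)
    n = int(counts.max(initial=0))
    return VisitationMap(counts, n_seed_samples=max(n, 1) * 2, n_retained=max(n, 1))


class TestThreshold:
    def test_boundary_is_inclusive(self):
        counts = np.zeros((4, 1, 1), np.int32)
        counts[:, 0, 0] = [100, 10, 9, 0]
        mask = threshold_map(vmap_from(counts), 0.10)
        assert mask.grid[:, 0, 0].tolist() == [True, True, False, False]

    def test_fraction_one_keeps_only_argmax(self):
        counts = np.zeros((3, 1, 1), np.int32)
        counts[:, 0, 0] = [5, 9, 3]
        mask = threshold_map(vmap_from(counts), 1.0)
        assert mask.grid[:, 0, 0].tolist() == [False, True, False]

    def test_uniform_map_keeps_everything(self):
        counts = np.full((3, 2, 2), 7, np.int32)
        assert threshold_map(vmap_from(counts), 0.9999).grid.all()

    def test_empty_map_errors(self):
        with pytest.raises(ValueError, match="empty tractogram"):
            threshold_map(vmap_from(np.zeros((2, 2, 2))), 0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        counts=st.lists(st.integers(0, 50), min_size=4, max_size=12),
        f1=st.floats(0.05, 1.0),
        f2=st.floats(0.05, 1.0),
    )
    def test_monotone_in_fraction(self, counts, f1, f2):
        if max(counts) == 0:
            counts[0] = 1
        lo, hi = min(f1, f2), max(f1, f2)
        counts = np.asarray(counts, np.int32).reshape(-1, 1, 1)
        m_lo = threshold_map(vmap_from(counts), lo).grid
        m_hi = threshold_map(vmap_from(counts), hi).grid
        assert np.all(m_hi <= m_lo)


class TestOverlap:
    @staticmethod
    def rois(shape):
        a = np.zeros(shape, bool)
        b = np.zeros(shape, bool)
        a[0, 0, 0] = True
        b[-1, 0, 0] = True
        return ROIMask(a, "waypoint", "a"), ROIMask(b, "waypoint", "b")

    def test_self_overlap_is_binarisation(self):
        counts = np.random.default_rng(0).integers(0, 4, (5, 4, 3)).astype(np.int32)
        vm = vmap_from(counts)
        roi_a, roi_b = self.rois(counts.shape)
        mask, _ = overlap_bidirectional(vm, vm, roi_a, roi_b)
        assert np.array_equal(mask.grid, counts > 0)

    def test_disjoint_maps_give_empty_discontinuous(self):
        a = np.zeros((4, 2, 2), np.int32)
        b = np.zeros((4, 2, 2), np.int32)
        a[0] = 3
        b[2] = 3
        roi_a, roi_b = self.rois(a.shape)
        mask, cont = overlap_bidirectional(vmap_from(a), vmap_from(b), roi_a, roi_b)
        assert not mask.grid.any()
        assert cont is False

    def test_continuity_requires_single_component_touching_both(self):
        shape = (6, 1, 1)
        counts = np.zeros(shape, np.int32)
        counts[:, 0, 0] = [1, 1, 1, 1, 1, 1]
        roi_a, roi_b = self.rois(shape)
        _, cont = overlap_bidirectional(vmap_from(counts), vmap_from(counts), roi_a, roi_b)
        assert cont is True
        broken = counts.copy()
        broken[3] = 0  # snap the chain
        _, cont = overlap_bidirectional(vmap_from(broken), vmap_from(broken), roi_a, roi_b)
        assert cont is False

    def test_grid_mismatch_errors(self):
        roi_a, roi_b = self.rois((2, 2, 2))
        with pytest.raises(ValueError, match="different grids"):
            overlap_bidirectional(vmap_from(np.ones((2, 2, 2))), vmap_from(np.ones((3, 2, 2))),
                                  roi_a, roi_b)


class TestComposite:
    @staticmethod
    def masks_with_voxel_in(n_present, n_total=12, shape=(3, 3, 3)):
        out = []
        for i in range(n_total):
            g = np.zeros(shape, bool)
            g[0, 0, 0] = i < n_present
            g[1, 1, 1] = True  # unanimous voxel
            out.append(StreamlineMask(g))
        return out

    def test_unanimity_reproduces_the_mask(self):
        masks = [StreamlineMask(np.random.default_rng(1).random((4, 4, 4)) > 0.5)] * 12
        out = composite(masks, 0.75)
        assert np.array_equal(out.grid, masks[0].grid)

    @pytest.mark.parametrize(
        "present, fraction, kept",
        [(9, 0.75, True), (9, 8 / 12, True), (7, 8 / 12, False), (8, 8 / 12, True)],
    )
    def test_at_least_count_rule(self, present, fraction, kept):
        out = composite(self.masks_with_voxel_in(present), fraction)
        assert bool(out.grid[0, 0, 0]) is kept
        assert out.grid[1, 1, 1]

    def test_single_mask_identity(self):
        m = StreamlineMask(np.random.default_rng(2).random((3, 3, 3)) > 0.4)
        assert np.array_equal(composite([m], 0.9).grid, m.grid)

    def test_mixed_grids_error(self):
        with pytest.raises(ValueError, match="common grid"):
            composite([StreamlineMask(np.ones((2, 2, 2), bool)),
                       StreamlineMask(np.ones((3, 2, 2), bool))], 0.5)

    @settings(derandomize=True, max_examples=40)
    @given(f1=st.floats(0.05, 1.0), f2=st.floats(0.05, 1.0), present=st.integers(0, 12))
    def test_monotone_in_fraction(self, f1, f2, present):
        lo, hi = min(f1, f2), max(f1, f2)
        masks = self.masks_with_voxel_in(present)
        assert np.all(composite(masks, hi).grid <= composite(masks, lo).grid)


@pytest.fixture(scope="module")
def protocol_masks(small_phantom):
    _, _, gt = small_phantom
    return {"sc": gt.rois["sc"], "pulvinar": gt.rois["pulvinar"], "amygdala": gt.rois["amygdala"]}


class TestDissectPathway:
    def test_pulvinar_waypoint_has_minimal_effect(self, small_field, protocol_masks):
        cfg = TrackerConfig(samples_per_seed_voxel=100, rng_seed=4)
        with_wp = dissect_pathway(small_field, protocol_masks, cfg,
                                  options={"use_pulvinar_waypoint": True})
        without = dissect_pathway(small_field, protocol_masks, cfg,
                                  options={"use_pulvinar_waypoint": False})
        assert dice(with_wp.sc_amygdala.grid, without.sc_amygdala.grid) >= 0.8

    def test_overlap_of_opposing_runs_is_continuous(self, small_field, protocol_masks, small_phantom):
        cfg = TrackerConfig(samples_per_seed_voxel=100, rng_seed=4)
        res = dissect_pathway(small_field, protocol_masks, cfg, options={"compute_overlap": True})
        assert res.overlap is not None
        assert res.continuous is True

    def test_exclusion_soundness_voxelwise(self, small_field, protocol_masks, small_phantom):
        """A run with an extra exclusion mask never gains visitation anywhere."""
        spec, _, gt = small_phantom
        from tractdissect.tracker import track
        cfg = TrackerConfig(samples_per_seed_voxel=60, rng_seed=9)
        amyg = protocol_masks["amygdala"]
        plain = track(small_field, protocol_masks["sc"],
                      waypoints=[amyg.with_role("waypoint")], termination=amyg, config=cfg)
        excl_grid = np.zeros(spec.grid_shape, bool)
        excl_grid[:, 16, :4] = True
        excl = track(small_field, protocol_masks["sc"],
                     waypoints=[amyg.with_role("waypoint")], termination=amyg,
                     exclusions=[ROIMask(excl_grid, "exclusion")], config=cfg)
        assert np.all(excl.counts <= plain.counts)


def test_dice_definition():
    a = np.zeros((3, 3, 1), bool)
    b = np.zeros((3, 3, 1), bool)
    a[:2] = True  # 6 voxels
    b[1:] = True  # 6 voxels, overlap 3
    assert dice(a, b) == pytest.approx(0.5)
    assert dice(a, a) == 1.0
    assert dice(a, np.zeros_like(a)) == 0.0
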