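"""Center-of-gravity profiles, variability tables and offset ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tractdissect.stats import (
    CoGProfile,
    cog_profile,
    compare_offsets,
    variability_table,
)

AFF = np.eye(4)


def profile_from_values(subject, xs, slices=None, **labels):
    slices = slices if slices is not None else np.arange(len(xs))
    return CoGProfile(np.asarray(slices), np.asarray(xs, float),
                      np.zeros(len(xs)), subject=subject, **labels)


class TestCoG:
    def test_single_voxel_gives_its_center(self):
        grid = np.zeros((7, 5, 7), bool)
        grid[3, 2, 4] = True
        prof = cog_profile(grid, [2], AFF)
        assert prof.x_mm[0] == 3.0 and prof.z_mm[0] == 4.0

    def test_symmetric_pair_gives_midpoint(self):
        grid = np.zeros((9, 3, 9), bool)
        grid[2, 1, 5] = grid[6, 1, 5] = True
        prof = cog_profile(grid, [1], AFF)
        assert prof.x_mm[0] == 4.0

    def test_cylinder_tracks_analytic_centerline(self):
        """Per-slice CoG of a straight radius-2 cylinder stays within half a
        voxel of the true axis."""
        shape = (15, 20, 15)
        grid = np.zeros(shape, bool)
        ii, kk = np.meshgrid(np.arange(shape[0]), np.arange(shape[2]), indexing="ij")
        disc = (ii - 7.3) ** 2 + (kk - 6.8) ** 2 <= 2.0**2
        for y in range(shape[1]):
            grid[:, y, :] = disc
        prof = cog_profile(grid, range(shape[1]), AFF)
        assert np.all(np.abs(prof.x_mm - 7.3) <= 0.5)
        assert np.all(np.abs(prof.z_mm - 6.8) <= 0.5)

    @settings(derandomize=True, max_examples=25)
    @given(dx=st.integers(-3, 3), dz=st.integers(-3, 3))
    def test_translation_equivariance(self, dx, dz):
        grid = np.zeros((12, 4, 12), bool)
        grid[4:7, 2, 5:8] = True
        shifted = np.roll(np.roll(grid, dx, axis=0), dz, axis=2)
        a = cog_profile(grid, [2], AFF)
        b = cog_profile(shifted, [2], AFF)
        assert b.x_mm[0] - a.x_mm[0] == pytest.approx(dx)
        assert b.z_mm[0] - a.z_mm[0] == pytest.approx(dz)

    def test_empty_slice_is_reported(self):
        grid = np.zeros((4, 4, 4), bool)
        grid[1, 1, 1] = True
        with pytest.raises(ValueError, match="slice 2"):
            cog_profile(grid, [1, 2], AFF)

    def test_weighted_centroid_option(self):
        grid = np.zeros((5, 3, 5), bool)
        grid[1, 1, 2] = grid[3, 1, 2] = True
        weights = np.zeros((5, 3, 5))
        weights[1, 1, 2] = 3.0
        weights[3, 1, 2] = 1.0
        prof = cog_profile(grid, [1], AFF, weights=weights)
        assert prof.x_mm[0] == pytest.approx(1.5)


class TestVariabilityTable:
    def test_identical_subjects_have_zero_sd(self):
        profs = [profile_from_values(f"s{i}", [3.0, 4.0, 5.0], hemisphere="L") for i in range(5)]
        table = variability_table(profs, [0, 1, 2]).table
        assert np.allclose(table.loc[[0, 1, 2], "L_x_sd"], 0.0)
        assert table.loc["Mean", "L_x_sd"] == 0.0

    def test_two_subject_offset_gives_sqrt2(self):
        profs = [profile_from_values("a", [0.0] * 4, hemisphere="L"),
                 profile_from_values("b", [2.0] * 4, hemisphere="L")]
        table = variability_table(profs, range(4)).table
        assert np.allclose(table.loc[[0, 1, 2, 3], "L_x_sd"], np.sqrt(2.0))

    def test_sampling_distribution_of_sd_at_n12(self):
        """12 subjects jittered by N(0, 1 mm): mean per-slice SD near 1 mm."""
        rng = np.random.default_rng(2024)
        profs = []
        truth = np.linspace(10, 12, 8)
        for i in range(12):
            for hemi in ("L", "R"):
                profs.append(CoGProfile(np.arange(8), truth + rng.normal(0, 1, 8),
                                        truth + rng.normal(0, 1, 8),
                                        subject=f"s{i}", hemisphere=hemi))
        table = variability_table(profs, range(8)).table
        assert 0.7 <= table.loc["Mean", "mean_x_sd"] <= 1.3
        assert 0.7 <= table.loc["Mean", "mean_z_sd"] <= 1.3

    def test_voxel_unit_report(self):
        profs = [profile_from_values("a", [0.0] * 2, hemisphere="L"),
                 profile_from_values("b", [4.0] * 2, hemisphere="L")]
        vt = variability_table(profs, range(2), voxel_size_mm=2.0)
        assert vt.unit == "voxel"
        assert vt.table.loc[0, "L_x_sd"] == pytest.approx(np.sqrt(8.0) / 2.0)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(5)
        profs = [profile_from_values(f"s{i}", rng.normal(0, 1, 5), hemisphere="L") for i in range(6)]
        t1 = variability_table(profs, range(5)).table
        t2 = variability_table(profs[::-1], range(5)).table
        assert np.allclose(t1.values, t2.values)

    def test_fewer_than_two_subjects_errors(self):
        with pytest.raises(ValueError, match="two subjects"):
            variability_table([profile_from_values("only", [1.0], hemisphere="L")], [0])


def brute_force_streamline_f(values):
    """Literal sums-of-squares two-factor ANOVA on (2, n, m) values: the
    streamline effect tested against the streamline-by-participant MS."""
    a, n, m = values.shape
    grand = values.sum() / values.size
    ss_s = sum(
        n * m * (values[i].mean() - grand) ** 2 for i in range(a)
    )
    ss_int = 0.0
    for i in range(a):
        for j in range(n):
            ss_int += m * (values[i, j].mean() - values[i].mean() - values[:, j].mean() + grand) ** 2
    return (ss_s / (a - 1)) / (ss_int / ((a - 1) * (n - 1)))


class TestCompareOffsets:
    @staticmethod
    def paired_profiles(va, vb, slices=None):
        pa = [profile_from_values(f"s{i}", row, slices, streamline="A") for i, row in enumerate(va)]
        pb = [profile_from_values(f"s{i}", row, slices, streamline="B") for i, row in enumerate(vb)]
        return pa, pb

    def test_identical_streamlines_give_zero(self):
        rng = np.random.default_rng(0)
        va = rng.normal(0, 1, (5, 4))
        pa, pb = self.paired_profiles(va, va)
        res = compare_offsets(pa, pb, "x")
        assert res.mean_offset == 0.0
        assert res.F == 0.0
        assert res.p_value == 1.0

    def test_pure_shift_is_degenerate_with_exact_offset(self):
        va = np.tile(np.arange(4.0), (6, 1))
        pa, pb = self.paired_profiles(va, va + 3.0)
        res = compare_offsets(pa, pb, "x")
        assert res.mean_offset == pytest.approx(-3.0)
        assert res.degenerate is True
        assert np.isinf(res.F)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 5), m=st.integers(2, 4))
    def test_matches_brute_force_oracle(self, seed, n, m):
        rng = np.random.default_rng(seed)
        va = rng.normal(0, 1, (n, m))
        vb = rng.normal(0.5, 1, (n, m))
        pa, pb = self.paired_profiles(va, vb)
        res = compare_offsets(pa, pb, "x")
        expected = brute_force_streamline_f(np.stack([va, vb]))
        assert res.F == pytest.approx(expected, abs=1e-8)
        assert res.df == (1, n - 1)

    def test_subject_mismatch_errors(self):
        pa, _ = self.paired_profiles(np.zeros((3, 2)), np.zeros((3, 2)))
        _, pb = self.paired_profiles(np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="subject sets differ"):
            compare_offsets(pa, pb, "x")

    def test_recovers_known_offset_with_noise(self):
        rng = np.random.default_rng(77)
        base = rng.normal(20, 2, (12, 1)) + np.zeros((12, 8))
        va = base + rng.normal(0, 1, (12, 8))
        vb = base - 5.4 + rng.normal(0, 1, (12, 8))
        pa, pb = self.paired_profiles(va, vb)
        res = compare_offsets(pa, pb, "x")
        assert abs(res.mean_offset - 5.4) <= 3 * res.se_offset
        assert res.p_value < 0.001
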