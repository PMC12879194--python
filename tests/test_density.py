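"""KDE, highest-density contours, depth profiles, quintile statistics."""

import numpy as np
import pandas as pd
import pytest

from chronotopy import (
    ProfilePeak,
    ProfileSimConfig,
    colocalize_profiles,
    composition_anova,
    compress_profile,
    depth_histogram,
    hdr_levels,
    kde2d,
    make_depth_profiles,
    quintile_stats,
    quintile_weights_table,
)
from chronotopy.errors import ConfigurationError, DegenerateBandwidthError


class TestKde2d:
    def test_default_grid_is_100_by_100(self, rng):
        g = kde2d(rng.normal(size=(50, 2)))
        assert g.z.shape == (100, 100)
        assert len(g.x) == len(g.y) == 100

    def test_density_integrates_to_one(self, rng):
        g = kde2d(rng.normal(size=(500, 2)) * [1.0, 3.0])
        assert g.riemann_mass() == pytest.approx(1.0, abs=0.01)

    def test_coincident_cluster_peak_closed_form(self):
        h = 0.7
        pts = np.zeros((2, 2))
        g = kde2d(pts, bandwidth=(h, h), lims=(-3, 3, -3, 3), resolution=101)
        peak = g.evaluate([[0.0, 0.0]])[0]
        assert peak == pytest.approx(1.0 / (2 * np.pi * h**2), rel=1e-12)
        assert g.z.max() == pytest.approx(peak, rel=1e-9)

    def test_auto_bandwidth_degenerate_points_rejected(self):
        with pytest.raises(DegenerateBandwidthError):
            kde2d(np.ones((5, 2)))


class TestHdrLevels:
    def test_full_fraction_includes_everyone(self, rng):
        pts = rng.normal(size=(40, 2))
        levels = hdr_levels(pts, fractions=[1.0])
        assert levels.members[1.0].all()

    def test_hand_quantile_with_tie_rule(self):
        pts = np.zeros((4, 2))
        dens = np.array([1.0, 2.0, 3.0, 4.0])
        levels = hdr_levels(pts, density_at_points=dens, fractions=[0.5])
        assert levels.thresholds[0.5] == 3.0
        np.testing.assert_array_equal(levels.members[0.5], [False, False, True, True])

    def test_nesting_and_threshold_monotonicity(self, rng):
        pts = rng.normal(size=(300, 2))
        levels = hdr_levels(pts)
        fr = levels.fractions  # sorted descending
        for a_big, a_small in zip(fr, fr[1:]):
            assert levels.thresholds[a_small] >= levels.thresholds[a_big]
            inner, outer = levels.members[a_small], levels.members[a_big]
            assert (outer | ~inner).all()  # inner subset of outer

    def test_coverage_tracks_fraction_on_large_sample(self, rng):
        pts = rng.standard_normal((2000, 2))
        levels = hdr_levels(pts)
        for a in levels.fractions:
            assert levels.coverage(a) == pytest.approx(a, abs=0.02)

    def test_empty_fractions_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            hdr_levels(rng.normal(size=(10, 2)), fractions=[])


class TestDepthHistogram:
    def test_default_is_200_bins_and_counts_conserved(self, rng):
        y = rng.uniform(-2000, 2000, size=777)
        prof = depth_histogram(y)
        assert prof.n_bins == 200
        assert prof.values.sum() == 777

    def test_bin_one_is_dorsal_most(self):
        prof = depth_histogram([1999.0, -1999.0], n_bins=200)
        assert prof.values[0] == 1
        assert prof.values[-1] == 1

    def test_uniform_draws_roughly_flat(self, rng):
        # multinomial oracle: 10k uniform draws over 200 bins -> 50 per bin
        # with sd = sqrt(n p (1-p)) ~ 7; every bin within 5 sd of expectation
        y = rng.uniform(-2000, 2000, size=10_000)
        prof = depth_histogram(y)
        n, p = 10_000, 1 / 200
        sd = np.sqrt(n * p * (1 - p))
        assert np.abs(prof.values - n * p).max() < 5 * sd

    def test_out_of_range_clipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            prof = depth_histogram([2500.0, -2500.0])
        assert "clipped" in caplog.text
        assert prof.values.sum() == 2
        assert prof.values[0] == 1 and prof.values[-1] == 1

    def test_smoothing_retains_raw_counts(self, rng):
        y = rng.uniform(-2000, 2000, size=500)
        prof = depth_histogram(y, smooth=True)
        assert prof.smoothed is not None
        assert prof.values.sum() == 500  # raw untouched


class TestCompressProfile:
    def test_hand_prorated_compression(self):
        comp = compress_profile([1.0, 3.0, 5.0, 7.0], n_bins_common=2)
        np.testing.assert_allclose(comp.raw_sums, [4.0, 12.0])
        np.testing.assert_allclose(comp.weights, [0.25, 0.75])

    def test_identity_compression_preserves_shape(self, rng):
        v = rng.uniform(0.1, 1.0, size=80)
        comp = compress_profile(v, n_bins_common=80)
        np.testing.assert_allclose(comp.weights, v / v.sum(), atol=1e-12)

    def test_fractional_straddling_conserves_total(self, rng):
        v = rng.uniform(0, 5, size=237)  # not divisible by 80
        comp = compress_profile(v, n_bins_common=80)
        assert comp.raw_sums.sum() == pytest.approx(v.sum(), rel=1e-12)
        assert comp.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_dorsal_view_has_56_bins(self, rng):
        comp = compress_profile(rng.uniform(0, 1, 200))
        assert len(comp.dorsal_view) == 56

    def test_quintiles_are_five_groups_of_16(self, rng):
        comp = compress_profile(rng.uniform(0, 1, 200))
        q = comp.quintiles()
        assert len(q) == 5
        assert q.sum() == pytest.approx(1.0, abs=1e-9)

    def test_upsampling_refused(self):
        with pytest.raises(ValueError, match="upsample"):
            compress_profile([1.0, 2.0], n_bins_common=80)


class TestColocalizeProfiles:
    def test_self_product_idempotent(self, rng):
        mask = (rng.uniform(size=30) > 0.5).astype(float)
        np.testing.assert_array_equal(colocalize_profiles(mask, mask), mask)

    def test_disjoint_masks_give_zero(self):
        a = np.array([1.0, 1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, 1.0])
        assert colocalize_profiles(a, b).sum() == 0

    def test_overlap_window_only(self):
        a = np.zeros(20)
        a[5:13] = 1
        b = np.zeros(20)
        b[10:16] = 1
        prod = colocalize_profiles(a, b)
        np.testing.assert_array_equal(np.nonzero(prod)[0], [10, 11, 12])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            colocalize_profiles(np.zeros(5), np.zeros(6))


class TestQuintileStats:
    def _table_from_q1(self, ctrl_q1, mut_q1):
        rows = []
        for gt, q1s in (("ctrl", ctrl_q1), ("mut", mut_q1)):
            for rep, w1 in enumerate(q1s, start=1):
                rest = (1.0 - w1) / 4.0
                for qi, w in enumerate([w1] + [rest] * 4, start=1):
                    rows.append(
                        {
                            "genotype": gt,
                            "cell_type": "m",
                            "replicate": rep,
                            "quintile": qi,
                            "weight": w,
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_profiles_give_null_genotype_effect(self):
        table = self._table_from_q1([0.30, 0.32, 0.31], [0.30, 0.32, 0.31])
        res = quintile_stats(table)
        f = res.anova.loc["C(genotype)", "F"]
        p = res.anova.loc["C(genotype)", "PR(>F)"]
        assert f == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_shifted_quintile_flagged_in_posthoc(self):
        table = self._table_from_q1([0.30, 0.32, 0.31], [0.50, 0.52, 0.51])
        res = quintile_stats(table)
        q1 = res.posthoc.query("quintile == 1").iloc[0]
        assert q1["p_adj"] < 0.001
        inter = res.anova.loc["C(genotype):C(quintile)", "PR(>F)"]
        assert inter < 0.001

    def test_synthetic_genotype_shift_detected_and_no_shift_clean(self):
        shifted = make_depth_profiles(
            ProfileSimConfig(
                peaks={
                    ("ctrl", "m"): (ProfilePeak(40.0, 12.0, 1.0),),
                    ("mut", "m"): (ProfilePeak(70.0, 12.0, 1.0),),
                },
                noise_sd=0.02,
                n_replicates=3,
                seed=8,
            )
        )
        res = quintile_stats(quintile_weights_table(shifted))
        assert res.anova.loc["C(genotype):C(quintile)", "PR(>F)"] < 0.001

        flat = make_depth_profiles(
            ProfileSimConfig(
                peaks={
                    ("ctrl", "m"): (ProfilePeak(40.0, 12.0, 1.0),),
                    ("mut", "m"): (ProfilePeak(40.0, 12.0, 1.0),),
                },
                noise_sd=0.02,
                n_replicates=3,
                seed=8,
            )
        )
        res0 = quintile_stats(quintile_weights_table(flat))
        assert res0.anova.loc["C(genotype):C(quintile)", "PR(>F)"] > 0.05

    def test_three_way_anova_includes_cell_type_terms(self):
        prof = make_depth_profiles(ProfileSimConfig(seed=2))
        res = quintile_stats(quintile_weights_table(prof))
        assert "C(genotype):C(quintile):C(cell_type)" in res.anova.index
        assert not res.posthoc.empty

    def test_composition_anova_tukey_per_cell_type(self, rng):
        rows = []
        for gt, shift in (("wt", 0.0), ("ko", 0.15)):
            for rep in range(1, 4):
                rows.append(
                    {"genotype": gt, "cell_type": "A", "replicate": rep,
                     "frequency": 0.5 + shift + rng.normal(0, 0.01)}
                )
                rows.append(
                    {"genotype": gt, "cell_type": "B", "replicate": rep,
                     "frequency": 0.5 - shift + rng.normal(0, 0.01)}
                )
        res = composition_anova(pd.DataFrame(rows))
        assert res.anova.loc["C(cell_type):C(genotype)", "PR(>F)"] < 0.001
        assert set(res.posthoc["cell_type"]) == {"A", "B"}
        assert (res.posthoc["p_adj"] < 0.01).all()
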