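"""Section registration: rigid rotation, template warp, overlays, downsampling."""

import numpy as np
import pandas as pd
import pytest

from chronotopy import (
    AnchorRole,
    SectionLandmarks,
    SectionSimConfig,
    TemplateSpec,
    downsample_matched,
    make_cell_table,
    make_section,
    mirror_overlay,
    normalize_section,
    rotate_to_midline,
    warp_to_template,
)
from chronotopy.errors import FrameMismatchError, LandmarkOrderError
from chronotopy.register import get_frame, set_frame


def _landmarks_from_spec(spec: TemplateSpec, frame="raw", **moves) -> SectionLandmarks:
    anchors = dict(spec.anchor_positions())
    for role_name, xy in moves.items():
        anchors[AnchorRole[role_name]] = xy
    return SectionLandmarks("toy", anchors, frame=frame)


class TestRotateToMidline:
    def test_identity_when_already_vertical(self):
        spec = TemplateSpec()
        lm = _landmarks_from_spec(spec)
        cells = make_cell_table([0.3], [0.2])
        rot, _ = rotate_to_midline(cells, lm)
        assert rot.loc[0, "x"] == pytest.approx(0.3, abs=1e-12)
        assert rot.loc[0, "y"] == pytest.approx(0.2, abs=1e-12)

    def test_45_degree_rotation_matches_trigonometry(self):
        spec = TemplateSpec()
        lm = _landmarks_from_spec(spec, DC_base=(1.0, 1.0), DV_junction=(0.0, 0.0))
        cells = make_cell_table([1.0], [0.0])
        rot, rlm = rotate_to_midline(cells, lm)
        assert rot.loc[0, "x"] == pytest.approx(0.70711, abs=1e-5)
        assert rot.loc[0, "y"] == pytest.approx(0.70711, abs=1e-5)
        assert rlm.xy(AnchorRole.DC_base) == pytest.approx((0.0, 1.41421), abs=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_preserves_distances(self, seed):
        gen = np.random.default_rng(seed)
        raw, lm, _ = make_section(
            SectionSimConfig(
                n_cells=50, rotation_deg=float(gen.uniform(-60, 60)), seed=seed
            )
        )
        rot, _ = rotate_to_midline(raw, lm)
        before = raw[["x", "y"]].to_numpy()
        after = rot[["x", "y"]].to_numpy()
        d0 = np.linalg.norm(before[:, None] - before[None, :], axis=-1)
        d1 = np.linalg.norm(after[:, None] - after[None, :], axis=-1)
        assert np.max(np.abs(d0 - d1)) < 1e-9

    def test_coincident_midline_anchors_rejected(self):
        spec = TemplateSpec()
        with pytest.raises(ValueError, match="distinct"):
            _landmarks_from_spec(spec, DC_base=(0.0, 0.0), DV_junction=(0.0, 0.0))


class TestWarpToTemplate:
    def test_anchors_pinned_to_template_positions(self, clean_section):
        _, raw, lm, _ = clean_section
        spec = TemplateSpec()
        cells, anchors = normalize_section(raw, lm, spec)
        assert anchors.xy(AnchorRole.DH_dorsal_R)[1] == pytest.approx(2000.0, abs=1e-9)
        assert anchors.xy(AnchorRole.DH_dorsal_L)[1] == pytest.approx(2000.0, abs=1e-9)
        assert anchors.xy(AnchorRole.DH_lateral_L) == pytest.approx(
            (-2000.0, spec.y_lat), abs=1e-9
        )
        assert anchors.xy(AnchorRole.DH_lateral_R) == pytest.approx(
            (2000.0, spec.y_lat), abs=1e-9
        )
        assert anchors.xy(AnchorRole.VH_ventral_L)[1] == pytest.approx(-2000.0, abs=1e-9)
        assert anchors.xy(AnchorRole.DC_base) == pytest.approx(
            (0.0, spec.y_dc), abs=1e-9
        )
        assert anchors.xy(AnchorRole.DV_junction) == pytest.approx((0.0, 0.0), abs=1e-9)
        assert anchors.xy(AnchorRole.VH_lateral_R) == pytest.approx(
            (spec.x_vlat, spec.y_vlat), abs=1e-9
        )

    def test_cell_at_lateral_anchor_maps_to_anchor(self):
        spec = TemplateSpec()
        lm = _landmarks_from_spec(spec)
        # distort the raw lateral anchor, then place a cell exactly on it
        anchors = dict(spec.anchor_positions())
        anchors[AnchorRole.DH_lateral_L] = (-1500.0, 700.0)
        lm = SectionLandmarks("toy", anchors, frame="rotated")
        cells = set_frame(make_cell_table([-1500.0], [700.0]), "rotated")
        out, _ = warp_to_template(cells, lm, spec)
        assert out.loc[0, "x"] == pytest.approx(-2000.0, abs=1e-9)
        assert out.loc[0, "y"] == pytest.approx(spec.y_lat, abs=1e-9)

    def test_midline_midpoint_interpolates_between_levels(self):
        spec = TemplateSpec()
        lm = SectionLandmarks("toy", spec.anchor_positions(), frame="rotated")
        y_mid_raw = (spec.y_dc + spec.y_lat) / 2  # raw == template geometry here
        cells = set_frame(make_cell_table([0.0], [y_mid_raw]), "rotated")
        out, _ = warp_to_template(cells, lm, spec)
        assert out.loc[0, "y"] == pytest.approx((spec.y_dc + spec.y_lat) / 2, abs=1e-9)
        assert out.loc[0, "x"] == 0.0

    def test_non_monotone_landmarks_named_in_error(self):
        spec = TemplateSpec()
        anchors = dict(spec.anchor_positions())
        # push the lateral DH anchor above the DC base -> order violation
        anchors[AnchorRole.DH_lateral_L] = (-2000.0, spec.y_dc + 50.0)
        lm = SectionLandmarks("toy", anchors, frame="rotated")
        cells = set_frame(make_cell_table([0.0], [0.0]), "rotated")
        with pytest.raises(LandmarkOrderError, match="DH_lateral_L"):
            warp_to_template(cells, lm, spec)


class TestNormalizeSection:
    @pytest.mark.parametrize("rotation", [-55.0, -20.0, 0.0, 33.0, 59.0])
    def test_roundtrip_recovery_at_zero_jitter(self, rotation):
        cfg = SectionSimConfig(
            n_cells=200, rotation_deg=rotation, jitter_sd=0.0, seed=int(rotation) + 60
        )
        raw, lm, truth = make_section(cfg)
        cells, _ = normalize_section(raw, lm)
        err = np.abs(
            cells[["x", "y"]].to_numpy() - truth[["x", "y"]].to_numpy()
        ).max()
        assert err <= 1e-6

    def test_roundtrip_error_scales_with_jitter(self):
        cfg = SectionSimConfig(n_cells=500, rotation_deg=25.0, jitter_sd=20.0, seed=2)
        raw, lm, truth = make_section(cfg)
        cells, _ = normalize_section(raw, lm)
        resid = cells[["x", "y"]].to_numpy() - truth[["x", "y"]].to_numpy()
        rmse = np.sqrt((resid**2).mean())
        # jitter of 20 raw units cannot blow up beyond a few multiples
        assert 1.0 < rmse < 100.0

    def test_mirror_symmetric_section_stays_symmetric(self):
        spec = TemplateSpec()
        lm = SectionLandmarks("toy", spec.anchor_positions(), frame="raw")
        xs = np.array([300.0, -300.0, 1200.0, -1200.0])
        ys = np.array([500.0, 500.0, -300.0, -300.0])
        cells = make_cell_table(xs, ys)
        out, _ = normalize_section(cells, lm, spec)
        got = out[["x", "y"]].to_numpy()
        np.testing.assert_allclose(got[0, 0], -got[1, 0], atol=1e-9)
        np.testing.assert_allclose(got[0, 1], got[1, 1], atol=1e-9)
        np.testing.assert_allclose(got[2, 0], -got[3, 0], atol=1e-9)
        np.testing.assert_allclose(got[2, 1], got[3, 1], atol=1e-9)

    def test_dorsoventral_rank_order_preserved(self, clean_section):
        _, raw, lm, _ = clean_section
        cells, _ = normalize_section(raw, lm)
        right = (raw["x"].to_numpy() > 0) & (cells["x"].to_numpy() > 0)
        # order in raw y (after undoing the rigid motion it equals rotated y)
        rot, _ = rotate_to_midline(raw, lm)
        order_before = np.argsort(rot.loc[right, "y"].to_numpy())
        order_after = np.argsort(cells.loc[right, "y"].to_numpy())
        np.testing.assert_array_equal(order_before, order_after)


class TestLandmarkSchema:
    def test_exactly_ten_roles_required(self):
        spec = TemplateSpec()
        anchors = dict(spec.anchor_positions())
        del anchors[AnchorRole.VH_lateral_L]
        with pytest.raises(ValueError, match="10 anchor roles"):
            SectionLandmarks("toy", anchors)

    def test_duplicate_role_in_table_rejected(self):
        spec = TemplateSpec()
        df = SectionLandmarks("toy", spec.anchor_positions()).to_frame()
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicated"):
            SectionLandmarks.from_frame(dup)

    def test_roundtrip_through_table(self):
        spec = TemplateSpec()
        lm = SectionLandmarks("toy", spec.anchor_positions())
        again = SectionLandmarks.from_frame(lm.to_frame())
        assert again.anchors == lm.anchors


class TestMirrorOverlay:
    def _template_cells(self, xs, ys, genotype):
        return set_frame(
            make_cell_table(xs, ys, genotype=genotype), "template"
        )

    def test_reflection_rules(self):
        ref = self._template_cells([1500.0], [300.0], "wt")
        alt = self._template_cells([-700.0], [-100.0], "ko")
        out = mirror_overlay(ref, alt)
        assert out.loc[out.overlay_side == "ref", "x"].iloc[0] == -1500.0
        assert out.loc[out.overlay_side == "alt", "x"].iloc[0] == 700.0
        assert set(out["y"]) == {300.0, -100.0}

    def test_y_multiset_unchanged(self, rng):
        ys = rng.normal(size=30)
        ref = self._template_cells(rng.normal(size=30), ys, "wt")
        alt = self._template_cells(rng.normal(size=30), ys[::-1], "ko")
        out = mirror_overlay(ref, alt)
        assert sorted(out["y"]) == sorted(np.concatenate([ys, ys[::-1]]))

    def test_frame_mismatch_rejected(self):
        ref = self._template_cells([1.0], [1.0], "wt")
        alt = make_cell_table([1.0], [1.0])  # raw frame
        with pytest.raises(FrameMismatchError):
            mirror_overlay(ref, alt)


class TestDownsampleMatched:
    def _typed_table(self, n_a, n_b):
        df = make_cell_table(
            np.arange(n_a + n_b, dtype=float), np.zeros(n_a + n_b)
        )
        df["type_label"] = ["A"] * n_a + ["B"] * n_b
        return df

    def test_exact_ratio_per_type(self):
        out = downsample_matched(self._typed_table(600, 400), alt_total=500, seed=1)
        assert (out["type_label"] == "A").sum() == 300
        assert (out["type_label"] == "B").sum() == 200

    def test_equal_totals_is_identity(self):
        df = self._typed_table(30, 20)
        out = downsample_matched(df, alt_total=50, seed=0)
        pd.testing.assert_frame_equal(
            out.sort_values("x").reset_index(drop=True),
            df.sort_values("x").reset_index(drop=True),
        )

    def test_upsampling_refused_with_warning(self, caplog):
        df = self._typed_table(10, 10)
        with caplog.at_level("WARNING"):
            out = downsample_matched(df, alt_total=100, seed=0)
        assert len(out) == 20
        assert "cannot upsample" in caplog.text

    def test_seed_determinism(self):
        df = self._typed_table(600, 400)
        a = downsample_matched(df, 500, seed=9)
        b = downsample_matched(df, 500, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_total_close_to_target(self, rng):
        df = make_cell_table(rng.normal(size=999), rng.normal(size=999))
        df["type_label"] = rng.choice(list("ABCD"), size=999)
        out = downsample_matched(df, alt_total=400, seed=3)
        assert abs(len(out) - 400) <= 2  # (number of types) / 2
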