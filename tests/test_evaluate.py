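"""Error metrics, boxplot statistics, Spearman correlation and ANOVA."""

import numpy as np
import pandas as pd
import pytest

from rigval import (
    Camera,
    CameraIntrinsics,
    CameraPose,
    DetectionSet,
    ErrorTable,
    Pose3DSeries,
    RigCalibration,
    RigidPose,
    angle_error,
    bias_variance,
    boxplot_stats,
    config_anova,
    deviation_from_reference,
    enumerate_configs,
    error_vs_image_center,
    interkeypoint_error,
    make_xyz_object,
    place_object,
)
from rigval.evaluate import (
    ERROR_COLUMNS,
    InsufficientDataError,
    parse_symmetry_class,
    spearman_rho,
)


def series_from_points(points: dict, frames=None, jitter=None, rng=None) -> Pose3DSeries:
    """Build a Pose3DSeries from {keypoint: xyz} replicated over frames."""
    frames = frames if frames is not None else [0]
    rows = []
    for f in frames:
        for k, p in points.items():
            p = np.asarray(p, dtype=float)
            if jitter is not None:
                p = p + rng.normal(0, jitter, 3)
            rows.append((f, k, *p, 4, 0.1, True))
    return Pose3DSeries(
        pd.DataFrame(
            rows,
            columns=["frame", "keypoint", "x", "y", "z", "n_cameras_used",
                     "reprojection_rms", "valid"],
        )
    )


def error_table(values_by_class: dict, rng=None, metric="reference_deviation") -> ErrorTable:
    rows = []
    for label, values in values_by_class.items():
        for i, v in enumerate(values):
            signed = v if metric == "interkeypoint" else np.nan
            rows.append((i, "kp", label, label, signed, abs(v), metric))
    return ErrorTable(pd.DataFrame(rows, columns=ERROR_COLUMNS))


# ---------------------------------------------------------------------------
# configuration enumeration
# ---------------------------------------------------------------------------

class TestEnumerateConfigs:
    def test_subset_count_and_classes(self, small_rig):
        configs = enumerate_configs(small_rig, bottom_id="cam_3")
        assert len(configs) == 11  # 6 pairs + 4 triples + 1 quad
        labels = {c.symmetry_class for c in configs}
        assert labels == {"2s", "1s+b", "3s", "2s+b", "3s+b"}

    def test_pair_and_triple_grouping(self, small_rig):
        configs = enumerate_configs(small_rig, bottom_id="cam_3")
        pairs = [c for c in configs if c.n_cameras == 2]
        triples = [c for c in configs if c.n_cameras == 3]
        assert {c.symmetry_class for c in pairs} == {"2s", "1s+b"}
        assert {c.symmetry_class for c in triples} == {"3s", "2s+b"}
        assert sum(c.symmetry_class == "2s" for c in pairs) == 3
        assert sum(c.symmetry_class == "1s+b" for c in pairs) == 3

    def test_unknown_bottom_id(self, small_rig):
        from rigval import ConfigurationError

        with pytest.raises(ConfigurationError):
            enumerate_configs(small_rig, bottom_id="cam_99")

    def test_class_label_round_trip(self):
        assert parse_symmetry_class("2s") == (2, False)
        assert parse_symmetry_class("3s+b") == (3, True)


# ---------------------------------------------------------------------------
# inter-keypoint error
# ---------------------------------------------------------------------------

class TestInterkeypointError:
    def test_ground_truth_placement_gives_zero(self):
        spec = make_xyz_object()
        placed = place_object(spec, RigidPose.identity())
        series = series_from_points(placed, frames=range(5))
        tab = interkeypoint_error(series, spec).table
        assert len(tab) == 5 * 6
        assert np.allclose(tab["signed_error"], 0.0, atol=1e-12)

    def test_uniform_scaling_gives_proportional_error(self):
        spec = make_xyz_object()
        scaled = {k: 1.01 * v for k, v in spec.keypoints.items()}
        tab = interkeypoint_error(series_from_points(scaled), spec).table
        for row in tab.itertuples():
            a, b = row.label.split("|")
            assert row.signed_error == pytest.approx(
                0.01 * spec.pair_distance(a, b), abs=1e-9
            )

    def test_matches_brute_force_on_random_perturbation(self):
        spec = make_xyz_object(letter_offset=6.0)
        rng = np.random.default_rng(0)
        pts = {k: v + rng.normal(0, 2, 3) for k, v in spec.keypoints.items()}
        tab = interkeypoint_error(series_from_points(pts), spec).table
        for row in tab.itertuples():
            a, b = row.label.split("|")
            direct = np.linalg.norm(pts[a] - pts[b]) - spec.pair_distance(a, b)
            assert row.signed_error == pytest.approx(direct, abs=1e-9)
            assert row.abs_error == pytest.approx(abs(direct), abs=1e-9)

    def test_invalid_endpoint_excluded(self):
        spec = make_xyz_object()
        series = series_from_points(place_object(spec, RigidPose.identity()))
        series.table.loc[series.table["keypoint"] == "X", "valid"] = False
        tab = interkeypoint_error(series, spec).table
        assert not tab["label"].str.contains("X").any()
        assert len(tab) == 3  # pairs among origin, Y, Z


# ---------------------------------------------------------------------------
# deviation from reference
# ---------------------------------------------------------------------------

class TestDeviationFromReference:
    def test_self_comparison_exactly_zero(self):
        spec = make_xyz_object()
        series = series_from_points(place_object(spec, RigidPose.identity()),
                                    frames=range(10))
        tab = deviation_from_reference(series, series).table
        assert (tab["abs_error"] == 0.0).all()

    def test_translation_three_four_five(self):
        spec = make_xyz_object()
        base = place_object(spec, RigidPose.identity())
        moved = {k: v + np.array([3.0, 4.0, 0.0]) for k, v in base.items()}
        tab = deviation_from_reference(
            series_from_points(moved), series_from_points(base)
        ).table
        assert np.allclose(tab["abs_error"], 5.0, atol=1e-12)

    def test_matches_direct_norm_oracle(self):
        rng = np.random.default_rng(1)
        a = {f"k{i}": rng.normal(0, 20, 3) for i in range(5)}
        b = {k: v + rng.normal(0, 3, 3) for k, v in a.items()}
        tab = deviation_from_reference(
            series_from_points(a), series_from_points(b)
        ).table
        for row in tab.itertuples():
            assert row.abs_error == pytest.approx(
                np.linalg.norm(a[row.label] - b[row.label]), abs=1e-9
            )


# ---------------------------------------------------------------------------
# bias / variance
# ---------------------------------------------------------------------------

class TestBiasVariance:
    def test_constant_offset(self):
        tab = error_table({"3s+b": [2.0] * 8}, metric="interkeypoint")
        tab.table["label"] = "a|b"
        (bv,) = bias_variance(tab)
        assert bv.bias == pytest.approx(2.0)
        assert bv.variance == pytest.approx(0.0)

    def test_gaussian_noise_sampling_bounds(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0.0, 1.0, 10_000)
        tab = error_table({"3s+b": vals}, metric="interkeypoint")
        tab.table["label"] = "a|b"
        (bv,) = bias_variance(tab)
        assert abs(bv.bias) < 0.03
        assert 0.95 < bv.variance < 1.05

    def test_hand_computed_toy_table(self):
        vals = [1.0, 2.0, 3.0, 4.0, 10.0]
        tab = error_table({"3s+b": vals}, metric="interkeypoint")
        tab.table["label"] = "a|b"
        (bv,) = bias_variance(tab)
        assert bv.bias == pytest.approx(4.0)  # mean
        assert bv.variance == pytest.approx(np.var(vals, ddof=1))
        assert bv.variance == pytest.approx(12.5)

    def test_single_observation_flagged(self):
        tab = error_table({"3s+b": [1.0]}, metric="interkeypoint")
        (bv,) = bias_variance(tab)
        assert not bv.variance_defined


# ---------------------------------------------------------------------------
# angle error
# ---------------------------------------------------------------------------

class TestAngleError:
    VP = [(("origin", "X"), ("origin", "Y"))]

    def test_ground_truth_placement_zero(self):
        spec = make_xyz_object()
        series = series_from_points(place_object(spec, RigidPose.identity()),
                                    frames=range(4))
        tab = angle_error(series, spec, self.VP).table
        assert np.allclose(tab["abs_error"], 0.0, atol=1e-9)

    def test_default_rod_angle_is_ninety_degrees(self):
        spec = make_xyz_object()
        from rigval.evaluate import _angle_deg

        assert _angle_deg(
            spec.keypoints["X"] - spec.keypoints["origin"],
            spec.keypoints["Y"] - spec.keypoints["origin"],
        ) == pytest.approx(90.0)

    def test_matches_arccos_oracle_on_perturbation(self):
        spec = make_xyz_object()
        rng = np.random.default_rng(3)
        pts = {k: v + rng.normal(0, 1.5, 3) for k, v in spec.keypoints.items()}
        tab = angle_error(series_from_points(pts), spec, self.VP).table
        va = pts["X"] - pts["origin"]
        vb = pts["Y"] - pts["origin"]
        obs = np.degrees(
            np.arccos(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
        )
        assert tab["abs_error"].iloc[0] == pytest.approx(abs(obs - 90.0), abs=1e-9)


# ---------------------------------------------------------------------------
# boxplot statistics
# ---------------------------------------------------------------------------

def boxplot_oracle(values):
    """Independent quartile computation: h = (n-1)p interpolation on the
    sorted sample, whiskers at the extreme data inside the 1.5 IQR fences."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)

    def q(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    q1, med, q3 = q(0.25), q(0.5), q(0.75)
    iqr = q3 - q1
    inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
    n_out = n - len(inside)
    return inside[0], q1, med, q3, inside[-1], iqr, n_out


class TestBoxplotStats:
    def test_constant_vector(self):
        st = boxplot_stats([3.0] * 7)
        assert st.Q0 == st.Q1 == st.median == st.Q3 == st.Q4 == 3.0
        assert st.IQR == 0.0
        assert st.n_outliers == 0

    def test_one_to_hundred_matches_oracle(self):
        vals = np.arange(1.0, 101.0)
        st = boxplot_stats(vals)
        q0, q1, med, q3, q4, iqr, n_out = boxplot_oracle(vals)
        assert (st.Q0, st.Q1, st.median, st.Q3, st.Q4, st.IQR, st.n_outliers) == (
            q0, q1, med, q3, q4, iqr, n_out
        )
        assert st.Q1 == pytest.approx(25.75)
        assert st.median == pytest.approx(50.5)

    def test_random_samples_match_oracle(self):
        rng = np.random.default_rng(4)
        for n in (1, 2, 5, 30, 101):
            vals = rng.lognormal(0, 1, n)
            st = boxplot_stats(vals)
            q0, q1, med, q3, q4, iqr, n_out = boxplot_oracle(vals)
            assert st.Q0 == pytest.approx(q0, abs=1e-9)
            assert st.Q1 == pytest.approx(q1, abs=1e-9)
            assert st.median == pytest.approx(med, abs=1e-9)
            assert st.Q3 == pytest.approx(q3, abs=1e-9)
            assert st.Q4 == pytest.approx(q4, abs=1e-9)
            assert st.n_outliers == n_out

    def test_appended_outlier_counted_and_whisker_unmoved(self):
        vals = list(np.arange(1.0, 101.0))
        base = boxplot_stats(vals)
        spiked = boxplot_stats(vals + [base.Q3 + 1.6 * base.IQR])
        assert spiked.n_outliers == base.n_outliers + 1
        assert spiked.Q4 == 100.0  # largest non-outlier

    def test_ordering_invariant(self):
        rng = np.random.default_rng(5)
        st = boxplot_stats(rng.normal(size=500))
        assert st.Q0 <= st.Q1 <= st.median <= st.Q3 <= st.Q4
        assert st.IQR == pytest.approx(st.Q3 - st.Q1)

    def test_empty_input_raises(self):
        with pytest.raises(InsufficientDataError):
            boxplot_stats([])


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def rank_then_pearson(x, y):
    """Brute-force Spearman: tie-averaged ranks then Pearson correlation."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(100.0)
        rho, _ = spearman_rho(x, np.exp(x / 30.0))
        assert rho == pytest.approx(1.0)

    def test_matches_rank_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 10, 50).astype(float)  # heavy ties
        y = x + rng.integers(0, 5, 50)
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(rank_then_pearson(x, y), abs=1e-12)

    def test_null_distribution_at_large_n(self):
        rng = np.random.default_rng(7)
        rho, p = spearman_rho(rng.normal(size=2000), rng.normal(size=2000))
        assert abs(rho) < 0.06  # 99% null bound ~ 2.58/sqrt(n-1)
        assert p > 0.001


class TestErrorVsImageCenter:
    def _scenario(self):
        """One camera sees both pair endpoints; midpoint distance from the
        principal point grows linearly with frame index."""
        intr = CameraIntrinsics(1000.0, 1000.0, 640.0, 400.0)
        cams = [
            Camera("cam_0", intr, CameraPose(np.eye(3), np.zeros(3))),
            Camera("cam_1", intr, CameraPose(np.eye(3), [-100.0, 0.0, 0.0])),
        ]
        rig = RigCalibration(cams)
        n = 40
        det_rows, err_rows = [], []
        for f in range(n):
            r = 10.0 * (f + 1)
            det_rows.append((f, "cam_0", "a", 640.0 + r - 1, 400.0, 1.0, False))
            det_rows.append((f, "cam_0", "b", 640.0 + r + 1, 400.0, 1.0, False))
            err_rows.append((f, "a|b", "3s+b", "x", r / 100.0, r / 100.0,
                             "interkeypoint"))
        det = DetectionSet(
            pd.DataFrame(det_rows, columns=["frame", "camera_id", "keypoint",
                                            "u", "v", "confidence", "missing"])
        )
        errors = ErrorTable(pd.DataFrame(err_rows, columns=ERROR_COLUMNS))
        return errors, det, rig

    def test_error_equal_to_covariate_gives_rho_one(self):
        errors, det, rig = self._scenario()
        res = error_vs_image_center(errors, det, rig)
        assert res.rho == pytest.approx(1.0)
        assert res.n == 40

    def test_border_flagging(self):
        errors, det, rig = self._scenario()
        res = error_vs_image_center(errors, det, rig, border_threshold=205.0)
        # radii 10, 20, ..., 400: those > 205 are 210..400, i.e. 20 frames
        assert res.n_flagged_beyond_border == 20

    def test_insufficient_data(self):
        errors, det, rig = self._scenario()
        small = ErrorTable(errors.table.iloc[:2].copy())
        with pytest.raises(InsufficientDataError):
            error_vs_image_center(small, det, rig)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def balanced_twoway_oracle(groups: dict):
    """Closed-form balanced two-way ANOVA with interaction.

    ``groups`` maps (level_a, level_b) -> 1D samples of equal length."""
    cells = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    r = len(next(iter(cells.values())))
    a_levels = sorted({a for a, _ in cells})
    b_levels = sorted({b for _, b in cells})
    a_n, b_n = len(a_levels), len(b_levels)
    grand = np.mean([v.mean() for v in cells.values()])
    mean_a = {a: np.mean([cells[(a, b)].mean() for b in b_levels]) for a in a_levels}
    mean_b = {b: np.mean([cells[(a, b)].mean() for a in a_levels]) for b in b_levels}
    ss_a = r * b_n * sum((mean_a[a] - grand) ** 2 for a in a_levels)
    ss_b = r * a_n * sum((mean_b[b] - grand) ** 2 for b in b_levels)
    ss_ab = r * sum(
        (cells[(a, b)].mean() - mean_a[a] - mean_b[b] + grand) ** 2
        for a in a_levels
        for b in b_levels
    )
    ss_e = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
    df_a, df_b = a_n - 1, b_n - 1
    df_ab = df_a * df_b
    df_e = a_n * b_n * (r - 1)
    ms_e = ss_e / df_e
    return (ss_a / df_a / ms_e, ss_b / df_b / ms_e, ss_ab / df_ab / ms_e)


class TestConfigAnova:
    def test_matches_closed_form_balanced_design(self):
        """Type-II F statistics equal the hand-computed balanced two-way
        decomposition (type II == type I/III in a balanced design)."""
        rng = np.random.default_rng(8)
        r = 50
        groups = {
            (2, "no_bottom"): rng.normal(3.0, 1.0, r),
            (2, "with_bottom"): rng.normal(2.0, 1.0, r),
            (3, "no_bottom"): rng.normal(1.5, 1.0, r),
            (3, "with_bottom"): rng.normal(1.2, 1.0, r),
        }
        label = {
            (2, "no_bottom"): "2s",
            (2, "with_bottom"): "1s+b",
            (3, "no_bottom"): "3s",
            (3, "with_bottom"): "2s+b",
        }
        tab = error_table({label[k]: np.abs(v) for k, v in groups.items()})
        res = config_anova(tab)
        f_a, f_b, f_ab = balanced_twoway_oracle(
            {k: np.abs(v) for k, v in groups.items()}
        )
        assert res.F_camera_number == pytest.approx(f_a, abs=1e-9)
        assert res.F_configuration == pytest.approx(f_b, abs=1e-9)
        assert res.F_interaction == pytest.approx(f_ab, abs=1e-9)
        assert not res.main_effects_only

    def test_planted_shift_detected_by_tukey(self):
        rng = np.random.default_rng(9)
        base = {"3s": 0.0, "2s+b": 0.0, "3s+b": 0.0, "2s": 10.0, "1s+b": 10.0}
        tab = error_table(
            {lbl: np.abs(rng.normal(3.0 + off, 2.0, 200)) for lbl, off in base.items()}
        )
        # no (4 cameras, no bottom) cell exists, so the interaction is not
        # estimable and the main-effects fallback is expected
        with pytest.warns(UserWarning, match="main effects"):
            res = config_anova(tab)
        assert res.F_camera_number > 100
        two_cam = {"2s", "1s+b"}
        for row in res.tukey_table.itertuples():
            crosses = (row.group_a in two_cam) != (row.group_b in two_cam)
            if crosses:
                assert row.adjusted_p < 0.001
                assert abs(row.mean_difference_mm) > 5.0

    def test_empty_cell_falls_back_to_main_effects(self):
        rng = np.random.default_rng(10)
        tab = error_table(
            {
                "2s": np.abs(rng.normal(2, 1, 40)),
                "1s+b": np.abs(rng.normal(2, 1, 40)),
                "3s+b": np.abs(rng.normal(1, 1, 40)),  # no (4, no_bottom) cell
            }
        )
        with pytest.warns(UserWarning, match="main effects"):
            res = config_anova(tab)
        assert res.main_effects_only
        assert np.isnan(res.F_interaction)

    def test_single_factor_level_raises(self):
        rng = np.random.default_rng(11)
        tab = error_table({"2s": np.abs(rng.normal(size=20)),
                           "1s+b": np.abs(rng.normal(size=20))})
        with pytest.raises(InsufficientDataError):
            config_anova(tab)


def test_statistics_invariant_under_frame_relabeling_and_row_permutation():
    rng = np.random.default_rng(12)
    spec = make_xyz_object()
    pts = {k: v + rng.normal(0, 1, 3) for k, v in spec.keypoints.items()}
    series = series_from_points(pts, frames=range(20))
    tab1 = interkeypoint_error(series, spec).table

    shuffled = series.table.sample(frac=1.0, random_state=1).reset_index(drop=True)
    remap = {f: 1000 - f for f in range(20)}
    shuffled["frame"] = shuffled["frame"].map(remap)
    tab2 = interkeypoint_error(Pose3DSeries(shuffled), spec).table

    s1 = boxplot_stats(tab1["abs_error"])
    s2 = boxplot_stats(tab2["abs_error"])
    assert s1 == s2
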