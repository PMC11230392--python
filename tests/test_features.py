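"""The 52-measure catalog: closed forms, invariances, standardization."""

import numpy as np
import pandas as pd
import pytest

from foragekit import features as feat
from foragekit.geometry import ArenaGeometry, Rect

from conftest import make_trajectory, straight_path


def _featurize(points, geometry, phase="Exploration", dt=0.2):
    traj = make_trajectory(points, phase=phase, dt=dt)
    ann = traj.copy()
    ann["zone"] = geometry.annotate(ann["x_cm"], ann["y_cm"])
    return feat.compute_features(ann, geometry, phase)


class TestCatalog:
    def test_exactly_52_unique_measures(self):
        cat = feat.measure_catalog()
        assert len(cat) == 52
        assert len({m.name for m in cat}) == 52

    def test_all_four_families_present(self):
        cat = feat.measure_catalog()
        by_cat = {}
        for m in cat:
            by_cat.setdefault(m.category, []).append(m)
        assert set(by_cat) == set(feat.CATEGORIES)
        assert all(len(v) > 0 for v in by_cat.values())


class TestClosedForms:
    def test_straight_constant_speed_path(self, geometry):
        # 10 cm/s straight for 30 s from the tunnel exit: path length
        # 300 cm, mean speed 10, tortuosity within 1% of 1
        ex, ey = geometry.entry_point
        pts = straight_path((ex, ey + 0.5), (ex, ey + 0.5 + 300), 10.0)
        big = ArenaGeometry(arena_bounds=Rect(0, 0, 400, 400),
                            pot_centers={"Pot1": (350, 30), "Pot2": (30, 350),
                                         "Pot3": (350, 350), "Pot4": (330, 30)},
                            pot_radius_cm=5)
        f = _featurize(pts, big)
        assert f["path_length_cm"] == pytest.approx(300.0, rel=0.01)
        assert f["speed_mean"] == pytest.approx(10.0, rel=0.01)
        assert f["tortuosity"] == pytest.approx(1.0, rel=0.01)

    def test_out_and_back_tortuosity_two(self, geometry):
        ex, ey = geometry.entry_point
        out = straight_path((ex, ey + 0.5), (ex, ey + 50), 10.0)
        back = out[::-1][1:]
        f = _featurize(np.vstack([out, back]), geometry)
        assert f["path_length_cm"] == pytest.approx(2 * (50 - ey - 0.5), rel=0.02)
        assert f["tortuosity"] == pytest.approx(2.0, rel=0.02)

    def test_no_pot_visit_censoring(self, geometry):
        # excursion that never enters a pot: all pot times 0, latency
        # censored at the excursion duration, first pot index 0
        c = geometry.arena_centroid
        pts = [c] * 40
        f = _featurize(pts, geometry)
        for p in ("pot1", "pot2", "pot3", "pot4"):
            assert f[f"{p}_time_s"] == 0.0
        assert f["pot_latency_s"] == pytest.approx(f["duration_s"])
        assert f["first_pot_index"] == 0.0

    def test_too_few_samples_rejected(self, geometry):
        with pytest.raises(ValueError, match="3 samples"):
            _featurize([(30, 20), (31, 20)], geometry)

    def test_tortuosity_capped_when_stationary(self, geometry):
        ex, ey = geometry.entry_point
        rng = np.random.default_rng(0)
        pts = np.array([ex, ey]) + rng.normal(0, 0.1, (50, 2))
        f = _featurize(pts, geometry)
        assert f["tortuosity"] == feat.TORTUOSITY_CAP


def _random_excursion(rng, n=120):
    """Smooth random walk inside the arena for invariance checks."""
    steps = rng.normal(0, 1.2, (n, 2)).cumsum(axis=0)
    pts = np.array([30.0, 10.0]) + steps
    return np.clip(pts, 2, 58)


class TestInvariances:
    """Frame invariances hold for all 52 measures (geometry moves too)."""

    @pytest.mark.parametrize("case_seed", [0, 1, 2])
    def test_translation_invariance(self, case_seed):
        rng = np.random.default_rng(case_seed)
        pts = _random_excursion(rng)
        g0 = ArenaGeometry()
        f0 = _featurize(pts, g0)
        dx, dy = 13.0, -7.0
        g1 = ArenaGeometry(
            arena_bounds=Rect(0 + dx, 0 + dy, 60 + dx, 60 + dy),
            home_zone=Rect(24 + dx, -20 + dy, 36 + dx, -8 + dy),
            tunnel_zone=Rect(27 + dx, -8 + dy, 33 + dx, 0 + dy),
            pot_centers={k: (v[0] + dx, v[1] + dy)
                         for k, v in g0.pot_centers.items()})
        f1 = _featurize(pts + [dx, dy], g1)
        for name in feat.MEASURE_NAMES:
            assert f1[name] == pytest.approx(f0[name], rel=1e-6, abs=1e-6), name

    @pytest.mark.parametrize("case_seed", [0, 1])
    def test_scale_covariance(self, case_seed):
        rng = np.random.default_rng(case_seed)
        pts = _random_excursion(rng)
        c = 2.0
        g0 = ArenaGeometry()
        g1 = ArenaGeometry(
            arena_bounds=Rect(0, 0, 60 * c, 60 * c),
            home_zone=Rect(24 * c, -20 * c, 36 * c, -8 * c),
            tunnel_zone=Rect(27 * c, -8 * c, 33 * c, 0),
            pot_centers={k: (v[0] * c, v[1] * c) for k, v in g0.pot_centers.items()},
            pot_radius_cm=5 * c)
        f0 = _featurize(pts, g0)
        f1 = _featurize(pts * c, g1)
        length_like = {"path_length_cm", "max_displacement_cm", "wall_dist_mean_cm",
                       "food_pot_min_dist_cm"}
        speed_like = {"speed_mean", "speed_median", "speed_max", "speed_sd",
                      "entry_speed", "exit_speed"}
        unitless = {"tortuosity", "straightness_1s_mean", "arena_time_fraction",
                    "heading_circ_var", "clockwise_fraction", "revisit_index",
                    "speed_entropy", "meander_rad_per_cm"}
        for name in length_like:
            assert f1[name] == pytest.approx(c * f0[name], rel=1e-6), name
        for name in speed_like:
            assert f1[name] == pytest.approx(c * f0[name], rel=1e-6), name
        for name in unitless - {"meander_rad_per_cm"}:
            assert f1[name] == pytest.approx(f0[name], rel=1e-6, abs=1e-9), name
        # meander is turning per unit length: scales by 1/c
        assert f1["meander_rad_per_cm"] == pytest.approx(f0["meander_rad_per_cm"] / c,
                                                         rel=1e-6)

    @pytest.mark.parametrize("case_seed", [0, 1, 2])
    def test_time_reversal(self, case_seed, geometry):
        rng = np.random.default_rng(case_seed)
        pts = _random_excursion(rng)
        f0 = _featurize(pts, geometry)
        f1 = _featurize(pts[::-1], geometry)
        assert f1["entry_speed"] == pytest.approx(f0["exit_speed"], rel=1e-6)
        assert f1["exit_speed"] == pytest.approx(f0["entry_speed"], rel=1e-6)
        for name in ("path_length_cm", "duration_s", "pot1_time_s", "pot2_time_s",
                     "pot3_time_s", "pot4_time_s", "center_time_s",
                     "perimeter_time_s", "total_turning_rad", "speed_mean"):
            assert f1[name] == pytest.approx(f0[name], rel=1e-6, abs=1e-9), name

    @pytest.mark.parametrize("case_seed", list(range(6)))
    def test_tortuosity_at_least_one(self, case_seed, geometry):
        rng = np.random.default_rng(case_seed)
        f = _featurize(_random_excursion(rng), geometry)
        assert f["tortuosity"] >= 1.0 - 0.02

    def test_all_measures_finite_on_toy_matrix(self, toy_features):
        assert len(toy_features) > 500
        vals = toy_features[list(feat.MEASURE_NAMES)]
        assert np.isfinite(vals.to_numpy()).all()


class TestStandardize:
    def test_zscore_population_convention(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 6.0, 10.0]})
        std, rec = feat.standardize(df, "zscore")
        # population SD: (1,2,3) → SD sqrt(2/3); z of 1 = -sqrt(3/2)
        assert std["a"].tolist() == pytest.approx(
            [-np.sqrt(1.5), 0.0, np.sqrt(1.5)])
        assert std.mean().abs().max() < 1e-9
        assert (std.std(ddof=0) - 1).abs().max() < 1e-9

    def test_zero_variance_column_dropped_and_recorded(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [4.0, 4.0, 4.0]})
        std, rec = feat.standardize(df)
        assert rec.dropped == ["c"]
        assert list(std.columns) == ["a"]

    def test_all_constant_is_error(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError, match="constant"):
            feat.standardize(df)

    def test_stored_parameters_reproduce_bitwise(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(2, 3, (20, 4)), columns=list("abcd"))
        std, rec = feat.standardize(df)
        again = feat.apply_standardization(df, rec)
        assert (std.to_numpy() == again.to_numpy()).all()

    def test_robust_method(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(0, 1, 50)})
        std, rec = feat.standardize(df, "robust")
        assert rec.method == "robust"
        med = df["a"].median()
        mad = 1.4826 * (df["a"] - med).abs().median()
        assert std["a"].iloc[0] == pytest.approx((df["a"].iloc[0] - med) / mad)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="zscore"):
            feat.standardize(pd.DataFrame({"a": [1.0, 2.0]}), "minmax")
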