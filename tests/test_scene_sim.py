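import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fruitgauge import (
    CameraPose,
    FruitState,
    PsiSeries,
    SimConfig,
    growth_rate,
    project_scene,
    sample_flatness,
    sample_pose,
    simulate_fruit_trajectories,
    simulate_psi_series,
)
from fruitgauge.scene_sim import UnknownTreeError

SEASON_60D = (dt.date(2023, 7, 1), dt.date(2023, 8, 30))


# ---------------------------------------------------------------------------
# water potential
# ---------------------------------------------------------------------------

class TestPsiSeries:
    def test_no_stress_tree_stays_at_baseline(self):
        cfg = SimConfig(seed=1, n_trees=1, psi_noise_sd=0.0, rain_events=(),
                        drying_rates={"T01": 0.0})
        series = simulate_psi_series(cfg, "T01")
        assert np.allclose(series.psi, -0.4)

    def test_same_seed_reproduces_series(self):
        cfg = SimConfig(seed=42, n_trees=2)
        s1 = simulate_psi_series(cfg, "T02")
        s2 = simulate_psi_series(cfg, "T02")
        assert s1.dates == s2.dates
        assert np.array_equal(s1.psi, s2.psi)

    def test_linear_decline_clips_at_floor(self):
        # 0.03 MPa/day over 60 days from -0.4 would reach -2.2; floor at -2.0
        cfg = SimConfig(seed=1, n_trees=1, psi_noise_sd=0.0, rain_events=(),
                        season=SEASON_60D, drying_rates={"T01": 0.03})
        series = simulate_psi_series(cfg, "T01")
        assert series.dates[-1] == SEASON_60D[1]
        assert series.psi[-1] == pytest.approx(-2.0)
        assert series.psi.min() >= -2.0

    def test_rain_event_resets_to_baseline(self):
        rain_day = dt.date(2023, 7, 21)
        cfg = SimConfig(seed=1, n_trees=1, psi_noise_sd=0.0, season=SEASON_60D,
                        rain_events=(rain_day,), drying_rates={"T01": 0.05})
        series = simulate_psi_series(cfg, "T01")
        frame = series.to_frame().set_index("date")
        # latent resets on the rain day; first sample at/after it is near -0.4
        after = frame[frame.index >= rain_day].iloc[0]
        days_since = (after.name - rain_day).days
        assert after["psi_MPa"] >= -0.4 - 0.05 * days_since - 1e-9

    def test_unknown_tree_and_empty_season_raise(self):
        cfg = SimConfig(seed=1, n_trees=1)
        with pytest.raises(UnknownTreeError):
            simulate_psi_series(cfg, "T99")
        with pytest.raises(ValueError):
            SimConfig(seed=1, season=(dt.date(2023, 7, 1), dt.date(2023, 7, 1)))

    def test_sampling_gaps_within_protocol(self):
        cfg = SimConfig(seed=7, n_trees=1)
        series = simulate_psi_series(cfg, "T01")
        gaps = np.diff([(d - series.dates[0]).days for d in series.dates])
        assert (gaps >= 1).all() and (gaps <= 14).all()
        # all interior gaps follow the 7-10 day cadence
        assert (gaps[:-1] >= 7).all() and (gaps[:-1] <= 10).all()


# ---------------------------------------------------------------------------
# growth law
# ---------------------------------------------------------------------------

class TestGrowthRate:
    def test_anchor_floor_and_interpolation(self, config):
        assert growth_rate(-0.8, config) == pytest.approx(0.25)
        assert growth_rate(-2.0, config) == pytest.approx(0.0)
        # linear interpolation with alpha = 0.25/1.2
        assert growth_rate(-0.4, config) == pytest.approx(0.25 / 1.2 * 1.6)

    def test_positive_psi_rejected(self, config):
        with pytest.raises(ValueError):
            growth_rate(0.1, config)

    def test_monotone_in_psi(self, config):
        grid = np.linspace(-2.5, 0.0, 101)
        rates = growth_rate(grid, config)
        assert (np.diff(rates) >= 0).all()
        assert (rates >= 0).all()


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _flat_psi(tree_id, level, n_days):
    start = dt.date(2023, 8, 1)
    dates = [start, start + dt.timedelta(days=n_days)]
    return PsiSeries(tree_id=tree_id, dates=dates, psi=np.array([level, level]))


class TestTrajectories:
    def test_growth_at_anchor_psi(self):
        cfg = SimConfig(seed=5, n_trees=1, fruits_per_tree=3)
        traj = simulate_fruit_trajectories(_flat_psi("T01", -0.8, 20), cfg)
        growth = traj.groupby("fruit_id")["diameter_eq"].agg(lambda s: s.iloc[-1] - s.iloc[0])
        assert np.allclose(growth, 20 * 0.25)

    def test_zero_growth_at_floor(self):
        cfg = SimConfig(seed=5, n_trees=1, fruits_per_tree=2)
        traj = simulate_fruit_trajectories(_flat_psi("T01", -2.0, 30), cfg)
        growth = traj.groupby("fruit_id")["diameter_eq"].agg(lambda s: s.iloc[-1] - s.iloc[0])
        assert np.allclose(growth, 0.0)

    def test_identical_seeds_give_identical_trajectories(self):
        cfg = SimConfig(seed=5, n_trees=1, fruits_per_tree=2)
        t1 = simulate_fruit_trajectories(_flat_psi("T01", -1.0, 40), cfg)
        t2 = simulate_fruit_trajectories(_flat_psi("T01", -1.0, 40), cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_diameters_non_decreasing(self, config):
        series = simulate_psi_series(config, "T03")
        traj = simulate_fruit_trajectories(series, config)
        for _, sub in traj.groupby("fruit_id"):
            assert (np.diff(sub["diameter_eq"]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# flatness
# ---------------------------------------------------------------------------

class TestFlatness:
    def test_population_correlation_calibrated(self, config, rng):
        # larger fruit are more oblate; corr(diameter, 1-k) ~ 0.46
        d = rng.uniform(30, 90, 3000)
        f_index = 1 - sample_flatness(d, config, rng=rng)
        r = stats.pearsonr(d, f_index)[0]
        assert 0.36 <= r <= 0.56

    def test_zero_noise_degenerates_to_perfect_correlation(self, config, rng):
        d = rng.uniform(30, 90, 500)
        cfg = config.replace(flatness_noise_sd=0.0, flatness_k_range=(0.0, 1.2))
        f_index = 1 - sample_flatness(d, cfg, rng=rng)
        assert stats.pearsonr(d, f_index)[0] == pytest.approx(1.0)

    def test_zero_beta_decouples_diameter(self, config, rng):
        d = rng.uniform(30, 90, 3000)
        cfg = config.replace(flatness_beta=0.0)
        f_index = 1 - sample_flatness(d, cfg, rng=rng)
        assert abs(stats.pearsonr(d, f_index)[0]) < 0.08

    def test_k_respects_physical_range(self, config, rng):
        k = sample_flatness(rng.uniform(30, 90, 1000), config, rng=rng)
        assert (k >= 0.6).all() and (k <= 1.05).all()


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def _fruit(d, k=1.0):
    return FruitState("F1", "T01", dt.date(2023, 9, 1), d, k)


class TestProjectScene:
    def test_marker_area_closed_form(self, config):
        pose = CameraPose(distance_mm=90.0, angle_deg=0.0, focal_px=600.0)
        obs = project_scene(_fruit(40), pose, config, round_px=False)
        assert obs.area_marker_px == pytest.approx((15 * 600 / 90) ** 2)  # 10,000

    def test_sphere_is_angle_insensitive(self, config):
        p0 = CameraPose(90.0, 0.0, 3024.0)
        p20 = CameraPose(90.0, 20.0, 3024.0)
        a0 = project_scene(_fruit(50, k=1.0), p0, config, round_px=False).area_fruit_px
        a20 = project_scene(_fruit(50, k=1.0), p20, config, round_px=False).area_fruit_px
        assert a0 == pytest.approx(a20, rel=1e-12)

    def test_inverse_square_distance_law(self, config):
        near = CameraPose(90.0, 5.0, 3024.0)
        far = CameraPose(180.0, 5.0, 3024.0)
        m_near = project_scene(_fruit(40), near, config, round_px=False).area_marker_px
        m_far = project_scene(_fruit(40), far, config, round_px=False).area_marker_px
        assert m_far == pytest.approx(m_near / 4)

    def test_grazing_angle_rejected(self, config):
        with pytest.raises(ValueError):
            project_scene(_fruit(40), CameraPose(90.0, 90.0, 3024.0), config)

    def test_far_field_ratio_closed_form(self, config):
        # k=1, k*d/2 << D: ratio -> pi*(d/2)^2 / (s^2 cos(theta))
        pose = CameraPose(50_000.0, 15.0, 3024.0)
        obs = project_scene(_fruit(60, k=1.0), pose, config, round_px=False)
        expected = math.pi * 30 ** 2 / (15 ** 2 * math.cos(math.radians(15)))
        assert obs.ratio == pytest.approx(expected, rel=2e-3)


class TestSamplePose:
    def test_support_and_determinism(self, config):
        rng = np.random.default_rng(8)
        poses = [sample_pose(config, "high", rng) for _ in range(10_000)]
        d = np.array([p.distance_mm for p in poses])
        a = np.array([p.angle_deg for p in poses])
        assert d.min() >= 80 and d.max() <= 100
        assert a.min() >= 0 and a.max() <= 20
        p1 = sample_pose(config, "low", np.random.default_rng(5))
        p2 = sample_pose(config, "low", np.random.default_rng(5))
        assert p1 == p2
        assert p1.focal_px == config.focal_px["low"]

    def test_mean_distance_uniform(self, config):
        rng = np.random.default_rng(9)
        d = np.array([sample_pose(config, "high", rng).distance_mm for _ in range(100_000)])
        assert 89 <= d.mean() <= 91


# ---------------------------------------------------------------------------
# simulator bias structure
# ---------------------------------------------------------------------------

def _pose_sweep(config, d, k, n=250, seed=17):
    rng = np.random.default_rng(seed)
    fruit = _fruit(d, k)
    marker, ratio = [], []
    for _ in range(n):
        obs = project_scene(fruit, sample_pose(config, "high", rng), config,
                           round_px=False)
        marker.append(obs.area_marker_px)
        ratio.append(obs.ratio)
    return np.array(marker), np.array(ratio)


class TestBiasStructure:
    @pytest.mark.parametrize("d", [40.0, 60.0, 80.0])
    def test_marker_area_anticorrelates_with_ratio(self, config, d):
        marker, ratio = _pose_sweep(config, d, k=0.9)
        assert stats.pearsonr(marker, ratio)[0] <= -0.5

    def test_ratio_slope_steeper_for_larger_fruit(self, config):
        m40, r40 = _pose_sweep(config, 40.0, k=0.9)
        m60, r60 = _pose_sweep(config, 60.0, k=0.9)
        s40 = stats.linregress(m40, r40).slope
        s60 = stats.linregress(m60, r60).slope
        assert abs(s60) > abs(s40)

    def test_flatness_heterogeneity_weakens_pooled_correlation(self, config):
        m_single, r_single = _pose_sweep(config, 60.0, k=0.9, n=300)
        rng = np.random.default_rng(23)
        marker, ratio = [], []
        for k in rng.uniform(0.65, 1.05, 12):  # pooled fruits, same diameter
            m, r = _pose_sweep(config, 60.0, k=k, n=25, seed=int(rng.integers(1 << 30)))
            marker.append(m)
            ratio.append(r)
        pooled = stats.pearsonr(np.concatenate(marker), np.concatenate(ratio))[0]
        single = stats.pearsonr(m_single, r_single)[0]
        assert abs(pooled) < abs(single)
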