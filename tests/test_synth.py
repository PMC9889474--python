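"""Synthetic cohort generator: lesion evolution, outcomes, re-test masks."""
import numpy as np
import pytest
from scipy.stats import spearmanr

from deltarad.grid import mask_volume_ml
from deltarad.synth import (
    CohortConfig,
    GridSpec,
    LesionParams,
    ProgressionProfile,
    perturb_mask_for_retest,
    simulate_cohort,
    simulate_lesion_pair,
    simulate_survival,
)


def _params(radius=10.0, center=30.0, **kw):
    defaults = dict(
        center_mm=np.full(3, center),
        radii_mm=np.full(3, radius),
        core_intensity=40.0,
        texture_scale_mm=3.0,
        texture_amplitude=50.0,
        rim_gradient=0.3,
    )
    defaults.update(kw)
    return LesionParams(**defaults)


class TestLesionPair:
    def test_zero_rates_preserve_mask(self):
        pair = simulate_lesion_pair(
            _params(), ProgressionProfile(0, 0, 0), 64, GridSpec((60, 60, 60)), seed=3
        )
        assert pair.f0_mask.n_voxels == pair.f1_mask.n_voxels

    def test_volume_growth_oracle(self):
        # 1%/day over 50 days: 10 mL -> 15 mL within voxelization tolerance
        radius = (10_000 * 3 / (4 * np.pi)) ** (1 / 3)  # 10 mL sphere
        pair = simulate_lesion_pair(
            _params(radius=radius, center=40.0),
            ProgressionProfile(0.01, 0, 0),
            50,
            GridSpec((80, 80, 80)),
            seed=3,
        )
        assert mask_volume_ml(pair.f0_mask) == pytest.approx(10.0, rel=0.03)
        assert mask_volume_ml(pair.f1_mask) == pytest.approx(15.0, rel=0.03)

    def test_bit_identical_under_same_seed(self):
        a = simulate_lesion_pair(_params(), ProgressionProfile(0.002, -0.001, 0.001),
                                 30, GridSpec((60, 60, 60)), seed=9)
        b = simulate_lesion_pair(_params(), ProgressionProfile(0.002, -0.001, 0.001),
                                 30, GridSpec((60, 60, 60)), seed=9)
        assert np.array_equal(a.f0.values, b.f0.values)
        assert np.array_equal(a.f1.values, b.f1.values)

    def test_margin_violation_raises(self):
        with pytest.raises(ValueError, match="margin"):
            simulate_lesion_pair(
                _params(radius=12.0, center=15.0), ProgressionProfile(0, 0, 0),
                30, GridSpec((40, 40, 40)), seed=1,
            )

    def test_chest_wall_clips_lung_mask(self):
        spec = GridSpec((64, 64, 64), chest_wall=True)
        pair = simulate_lesion_pair(_params(center=32.0), ProgressionProfile(0, 0, 0),
                                    30, spec, seed=2)
        assert not pair.lung_mask.values.all()
        assert np.all(pair.lung_mask.values[pair.f0_mask.values])


class TestSurvival:
    def test_no_censoring_means_all_events(self):
        outs = [simulate_survival(0.5, 10.0, np.inf, s) for s in range(50)]
        assert all(o.event for o in outs)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            simulate_survival(0.0, 0.0, 10.0, 1)

    def test_cox_recovers_planted_log_hazard(self):
        # two groups with hazard ratio e^1 -> estimated log-HR ~ 1
        from lifelines import CoxPHFitter
        import pandas as pd

        rng = np.random.default_rng(11)
        n = 2000
        g = rng.random(n) < 0.5
        outs = [simulate_survival(1.0 if gi else 0.0, 12.0, 60.0, rng) for gi in g]
        df = pd.DataFrame({
            "t": [o.time_months for o in outs],
            "e": [int(o.event) for o in outs],
            "g": g.astype(float),
        })
        cph = CoxPHFitter().fit(df, "t", "e")
        assert cph.params_["g"] == pytest.approx(1.0, abs=0.15)

    def test_event_fraction_calibration(self):
        # default scale/censor-window -> ~83% progression events
        cfg = CohortConfig()
        rng = np.random.default_rng(2)
        lo, hi = cfg.texture_amplitude_range
        events = []
        for _ in range(2000):
            amp_z = 2 * (rng.uniform(lo, hi) - lo) / (hi - lo) - 1
            prof = ProgressionProfile(
                rng.normal(cfg.volume_rate_mean + cfg.baseline_link * cfg.volume_rate_sd * amp_z,
                           cfg.volume_rate_sd),
                rng.normal(0, cfg.texture_rate_sd),
                rng.normal(cfg.peri_link * cfg.peri_rate_sd * amp_z, cfg.peri_rate_sd),
                weights=cfg.risk_weights,
            )
            o = simulate_survival(prof.latent_risk, cfg.baseline_scale_months,
                                  cfg.censor_window_months, rng)
            events.append(o.event)
        assert np.mean(events) == pytest.approx(0.83, abs=0.03)


class TestRetestMask:
    def test_zero_jitter_identity(self, sphere10):
        assert perturb_mask_for_retest(sphere10, 0.0, seed=1) is sphere10

    def test_dice_floor_held(self, sphere10):
        for seed in range(5):
            out = perturb_mask_for_retest(sphere10, 1.0, seed=seed)
            inter = (out.values & sphere10.values).sum()
            dice = 2 * inter / (out.n_voxels + sphere10.n_voxels)
            assert dice >= 0.90

    def test_deterministic(self, sphere10):
        a = perturb_mask_for_retest(sphere10, 1.0, seed=4)
        b = perturb_mask_for_retest(sphere10, 1.0, seed=4)
        assert np.array_equal(a.values, b.values)

    def test_perturbation_not_degenerate(self, sphere10):
        flipped = [
            int(np.logical_xor(
                perturb_mask_for_retest(sphere10, 1.0, seed=s).values, sphere10.values
            ).sum())
            for s in range(5)
        ]
        assert max(flipped) > 0


class TestCohort:
    def test_counts_and_csv_rows(self, small_cohort, tmp_path):
        from deltarad.synth import write_cohort
        import pandas as pd

        assert len(small_cohort) == 22
        write_cohort(small_cohort[:3], tmp_path)
        clin = pd.read_csv(tmp_path / "clinical.csv")
        assert len(clin) == 3
        assert set(clin.columns) >= {"patient_id", "sex", "age", "tki_drug", "baseline_volume_ml"}
        assert (tmp_path / small_cohort[0].patient_id / "F0.nii.gz").exists()

    def test_interval_bounds(self, small_cohort):
        ivs = [p.scan_pair.interval_days for p in small_cohort]
        assert min(ivs) >= 16 and max(ivs) <= 128

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="10"):
            simulate_cohort(CohortConfig(n_train=5, n_valid=5), seed=1)

    def test_determinism(self):
        cfg = CohortConfig(n_train=10, n_valid=10)
        a = simulate_cohort(cfg, seed=77)
        b = simulate_cohort(cfg, seed=77)
        assert all(
            np.array_equal(x.scan_pair.f0.values, y.scan_pair.f0.values)
            and x.outcome.time_months == y.outcome.time_months
            for x, y in zip(a, b)
        )

    def test_planted_monotonicity(self):
        # latent risk anti-correlates with observed event times
        cfg = CohortConfig()
        rng = np.random.default_rng(8)
        lo, hi = cfg.texture_amplitude_range
        risks, times = [], []
        for _ in range(500):
            amp_z = 2 * (rng.uniform(lo, hi) - lo) / (hi - lo) - 1
            prof = ProgressionProfile(
                rng.normal(cfg.volume_rate_mean + cfg.baseline_link * cfg.volume_rate_sd * amp_z,
                           cfg.volume_rate_sd),
                rng.normal(0, cfg.texture_rate_sd),
                rng.normal(cfg.peri_link * cfg.peri_rate_sd * amp_z, cfg.peri_rate_sd),
                weights=cfg.risk_weights,
            )
            o = simulate_survival(prof.latent_risk, cfg.baseline_scale_months,
                                  cfg.censor_window_months, rng)
            if o.event:
                risks.append(prof.latent_risk)
                times.append(o.time_months)
        res = spearmanr(risks, times)
        assert res.statistic < 0 and res.pvalue < 0.01

    def test_volume_rate_recovered_from_masks(self, small_cohort):
        # true per-day volume delta from the masks matches the planted rate
        checked = 0
        for p in small_cohort:
            if p.scan_pair.f0_mask.n_voxels < 4000:  # >= ~10 mm radius
                continue
            v0 = mask_volume_ml(p.scan_pair.f0_mask)
            v1 = mask_volume_ml(p.scan_pair.f1_mask)
            rate = (v1 - v0) / (v0 * p.scan_pair.interval_days)
            planted = p.profile.volume_rate_per_day
            if abs(planted) < 5e-4:
                continue
            assert rate == pytest.approx(planted, rel=0.10, abs=2e-4)
            checked += 1
        assert checked >= 3

    def test_latent_risk_is_deterministic_in_rates(self):
        p = ProgressionProfile(0.001, -0.002, 0.003, weights=(10, 20, 30))
        assert p.latent_risk == pytest.approx(10 * 0.001 + 20 * -0.002 + 30 * 0.003)
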