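"""Kinetics inference: rescaling, product-limit survival, exponential fits."""

import math

import numpy as np
import pytest
import scipy.stats

import resetmetad as rm
from resetmetad.engine import TrajectoryRecord
from resetmetad.experiments import run_ensemble
from resetmetad.inference import (SegmentRecord, fit_exponential_survival,
                                  infer_mfpt, prediction_error,
                                  rescale_trajectory, segments_from_records,
                                  survival_from_segments, tradeoff_scan)


def _record(fpt_steps, exposure_fs, seg_steps=None, seg_tau=None, n_resets=0,
            censored=0):
    seg_steps = np.asarray(seg_steps if seg_steps is not None else [fpt_steps],
                           dtype=np.int64)
    seg_tau = np.asarray(seg_tau if seg_tau is not None else [exposure_fs])
    return TrajectoryRecord(traj_id=0, seed=0, fpt_steps=fpt_steps,
                            fpt_fs=float(fpt_steps), n_resets=n_resets,
                            censored=censored, exposure_fs=exposure_fs,
                            segment_steps=seg_steps, segment_tau_fs=seg_tau)


class TestRescaling:
    def test_zero_bias_rescaling_is_identity(self, two_wells, thermo, tw_stop):
        """Without metadynamics the exposure integral is just elapsed time."""
        rec = rm.run_trajectory(two_wells, thermo, tw_stop, (3.0, 0.0), seed=3,
                                record_segments=True)
        assert rec.exposure_fs == pytest.approx(rec.fpt_fs)
        assert rescale_trajectory(rec) == pytest.approx(rec.fpt_ns)

    def test_constant_bias_scales_exponentially(self):
        v0 = 2.0
        rec = _record(1000, 1000.0 * math.exp(v0))
        assert rescale_trajectory(rec) == pytest.approx(
            1e-6 * 1000 * math.exp(v0))

    def test_rejects_reset_or_censored_trajectories(self):
        with pytest.raises(ValueError):
            rescale_trajectory(_record(10, 10.0, n_resets=2))
        with pytest.raises(ValueError):
            rescale_trajectory(_record(10, 10.0, censored=1))

    def test_rescaled_never_shorter_than_wall_time(self):
        with pytest.raises(ValueError):
            SegmentRecord(duration_ns=1.0, rescaled_ns=0.5, event=True)


class TestSurvival:
    def test_km_equals_empirical_when_uncensored(self):
        rng = np.random.default_rng(10)
        taus = rng.exponential(1.0, 50)
        segs = [SegmentRecord(t, t, True) for t in taus]
        curve = survival_from_segments(segs)
        srt = np.sort(taus)
        for i, t in enumerate(srt):
            empirical = (taus > t).mean()
            j = np.searchsorted(curve.times_ns, t)
            assert curve.survival[j] == pytest.approx(empirical, abs=1e-12)

    def test_hand_worked_product_limit_table(self):
        """3 events and 2 censorings at known times vs the hand-computed KM."""
        segs = [SegmentRecord(1.0, 1.0, True),
                SegmentRecord(1.5, 1.5, False),
                SegmentRecord(2.0, 2.0, True),
                SegmentRecord(3.0, 3.0, False),
                SegmentRecord(4.0, 4.0, True)]
        curve = survival_from_segments(segs)
        s = dict(zip(curve.times_ns, curve.survival))
        assert s[1.0] == pytest.approx(4 / 5)
        assert s[2.0] == pytest.approx(4 / 5 * 2 / 3)
        assert s[4.0] == pytest.approx(0.0, abs=1e-12)

    def test_all_censored_curve_is_flat_and_unfittable(self):
        segs = [SegmentRecord(1.0, 1.0, False) for _ in range(10)]
        curve = survival_from_segments(segs)
        assert not curve.fittable
        assert np.all(curve.survival == 1.0)
        with pytest.raises(ValueError):
            fit_exponential_survival(curve)

    def test_discard_censored_switch(self):
        segs = [SegmentRecord(1.0, 1.0, True), SegmentRecord(2.0, 2.0, False)]
        curve = survival_from_segments(segs, discard_censored=True)
        assert curve.n_segments == 1


class TestExponentialFit:
    def test_recovers_rate_from_synthetic_exponential(self):
        k = 2.0
        rng = np.random.default_rng(1)
        taus = rng.exponential(1 / k, 10_000)
        segs = [SegmentRecord(t, t, True) for t in taus]
        res = fit_exponential_survival(survival_from_segments(segs))
        assert res.rate_per_ns == pytest.approx(k, rel=0.05)
        assert res.r_squared > 0.99
        assert res.ks_score > 0.95

    def test_scale_free_window_self_consistency(self):
        """Restricting the window to the shortest decile leaves k unchanged
        (the exponential is memoryless/scale-free)."""
        k = 1.0
        rng = np.random.default_rng(2)
        taus = rng.exponential(1 / k, 20_000)
        curve = survival_from_segments([SegmentRecord(t, t, True) for t in taus])
        full = fit_exponential_survival(curve)
        q10 = np.quantile(taus, 0.1)
        short = fit_exponential_survival(curve, window=(0.0, q10))
        assert short.rate_per_ns == pytest.approx(full.rate_per_ns, rel=0.1)

    def test_plateau_flagged_by_low_quality_scores(self):
        """A sub-population that never transitions leaves a survival plateau."""
        rng = np.random.default_rng(3)
        taus = rng.exponential(1.0, 2000)
        reachable = [SegmentRecord(t, t, True) for t in taus]
        stuck = [SegmentRecord(8.0, 8.0, False) for _ in range(1000)]
        curve = survival_from_segments(reachable + stuck)
        res = fit_exponential_survival(curve, window=(0.0, 8.0))
        clean = fit_exponential_survival(survival_from_segments(reachable))
        assert res.r_squared < clean.r_squared
        assert res.ks_score < clean.ks_score - 0.05

    def test_too_few_events_rejected(self):
        segs = [SegmentRecord(1.0, 1.0, True), SegmentRecord(2.0, 2.0, True)]
        with pytest.raises(ValueError):
            fit_exponential_survival(survival_from_segments(segs))


class TestPredictionError:
    @pytest.mark.parametrize("true,est,expected", [
        (5.0, 5.0, 0.0),
        (5.0, 10.0, 1.0),
        (5.0, 2.5, 0.5),
    ])
    def test_printed_formula(self, true, est, expected):
        assert prediction_error(true, est) == expected

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(ValueError):
            prediction_error(0.0, 1.0)


class TestPipeline:
    def test_recovers_mfpt_of_resetted_exponential_process(self):
        """Sharp resetting chops an exponential process into censored segments;
        the KM + exponential-fit pipeline recovers the true MFPT."""
        k = 0.5          # ns^-1, true rate
        period = 0.8     # ns, sharp resetting period
        rng = np.random.default_rng(4)
        records = []
        for j in range(3000):
            tau = rng.exponential(1 / k)
            n_full = int(tau // period)
            seg_steps = [int(period * 1e6)] * n_full + [int((tau % period) * 1e6)]
            seg_tau = [s * 1.0 for s in seg_steps]
            records.append(TrajectoryRecord(
                traj_id=j, seed=j, fpt_steps=int(tau * 1e6), fpt_fs=tau * 1e6,
                n_resets=n_full, censored=0, exposure_fs=seg_tau[-1],
                segment_steps=np.array(seg_steps, dtype=np.int64),
                segment_tau_fs=np.array(seg_tau)))
        res = infer_mfpt(records)
        sem = (1 / k) / math.sqrt(3000)
        assert abs(res.tau_est_ns - 1 / k) < max(2 * sem, 0.05 / k)

    def test_rescaled_fpts_match_unbiased_distribution_at_slow_pace(
            self, two_wells, thermo, tw_stop, tw_baseline):
        """iMetaD validity: with the optimal CV and slow deposition (5 hills/ns;
        faster deposition visibly over-deposits), rescaled FPTs are
        statistically compatible with the unbiased FPT distribution."""
        md = rm.MetaDConfig(pace=200_000, sigma=1.3)
        recs = run_ensemble(two_wells, thermo, tw_stop, (3.0, 0.0), 100,
                            seed=31, cv=rm.CVSpec(0.0), metad=md,
                            max_steps=10 ** 8, record_segments=True)
        rescaled = [rescale_trajectory(r) for r in recs if r.censored == 0]
        stat, pval = scipy.stats.ks_2samp(rescaled, tw_baseline.uncensored_ns)
        assert pval > 0.01

    def test_tradeoff_scan_runs_and_is_deterministic(self, two_wells, thermo,
                                                     tw_stop):
        md = rm.MetaDConfig(pace=100, sigma=1.3)
        kw = dict(
            potential=two_wells, thermo=thermo, stop=tw_stop,
            init_position=(3.0, 0.0), cv=rm.CVSpec(0.0), metad_template=md,
            bias_rates_per_ns=[1e4], resetting_periods_ns=[0.05],
            sr_bias_rate_per_ns=1e4, tau_true_ns=7.5, n_traj=30, seed=5,
            max_steps=10 ** 7)
        a = tradeoff_scan(**kw)
        b = tradeoff_scan(**kw)
        assert a.equals(b)
        assert set(a["branch"]) == {"imetad", "imetad+sr"}
        assert (a["speedup"] > 1).all()
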