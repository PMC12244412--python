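"""Synthetic generator: determinism, calibration, planted structure."""

import numpy as np
import pytest
from scipy import stats

import cuedreach as cr
from cuedreach.behavior import WindowSpec, window_reach_rate
from cuedreach.session import events_from_session
from cuedreach.synth import GLM_LAGS, default_group_kernels


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = cr.BehaviorGenConfig(n_trials=40, cue_gain=5.0,
                                   reinforcement_delta=0.3,
                                   inhibition_prob=0.3)
        s1, t1 = cr.generate_session(cfg, seed=5)
        s2, t2 = cr.generate_session(cfg, seed=5)
        for a, b in zip(s1.trials, s2.trials):
            assert a.t_cue == b.t_cue
            assert [r.t_arm for r in a.reaches] == [r.t_arm for r in b.reaches]
            assert [r.outcome for r in a.reaches] == [r.outcome
                                                      for r in b.reaches]
            assert a.inhibition_window == b.inhibition_window
        assert t1.trial_classes == t2.trial_classes

    def test_different_seeds_differ(self):
        cfg = cr.BehaviorGenConfig(n_trials=40)
        s1, _ = cr.generate_session(cfg, seed=1)
        s2, _ = cr.generate_session(cfg, seed=2)
        r1 = [r.t_arm for t in s1.trials for r in t.reaches]
        r2 = [r.t_arm for t in s2.trials for r in t.reaches]
        assert r1 != r2

    def test_spike_and_photometry_determinism(self):
        s, _ = cr.generate_session(cr.BehaviorGenConfig(n_trials=20,
                                                        cue_gain=5.0), seed=3)
        u1, _ = cr.generate_population_spikes(
            s, cr.SpikeGenConfig(n_units=3), seed=9)
        u2, _ = cr.generate_population_spikes(
            s, cr.SpikeGenConfig(n_units=3), seed=9)
        for a, b in zip(u1, u2):
            assert np.array_equal(a.spike_times, b.spike_times)
        p1, _ = cr.generate_photometry(s, seed=4)
        p2, _ = cr.generate_photometry(s, seed=4)
        assert np.array_equal(p1.samples, p2.samples)


@pytest.fixture(scope="module")
def big_batch():
    trials = []
    for seed in range(30):
        s, _ = cr.generate_session(cr.BehaviorGenConfig(n_trials=400),
                                   seed=seed)
        trials.extend(s.trials)
    return trials


class TestTrialStructure:
    def test_catch_fraction(self, big_batch):
        frac = np.mean([t.catch for t in big_batch])
        n = len(big_batch)
        tol = 3 * np.sqrt(0.1 * 0.9 / n)
        assert frac == pytest.approx(0.10, abs=tol)

    def test_pellet_occupancy_at_cue(self, big_batch):
        frac = np.mean([t.pellet_presented for t in big_batch])
        n = len(big_batch)
        tol = 3 * np.sqrt(0.3 * 0.7 / n)
        assert frac == pytest.approx(0.30, abs=tol)

    def test_catch_trials_never_have_pellet(self, big_batch):
        assert all(not t.pellet_presented for t in big_batch if t.catch)

    def test_iti_mixture_distribution(self, big_batch):
        cfg = cr.BehaviorGenConfig()
        # inter-cue interval minus the fixed pellet/travel segments = ITI
        cues = np.array([t.t_cue for t in big_batch[:10000]])
        # restrict to within-session consecutive pairs
        itis = []
        for seed in range(5):
            s, _ = cr.generate_session(cr.BehaviorGenConfig(n_trials=2000),
                                       seed=100 + seed)
            c = np.array([t.t_cue for t in s.trials])
            itis.extend(np.diff(c) - cfg.pellet_retract_s
                        - cfg.pellet_travel_s)
        itis = np.asarray(itis)

        def mixture_cdf(x):
            # uniform(0, 3.5) plus, w.p. 0.7, uniform(9.5, 13)
            short = stats.uniform(0, 3.5)
            a = 0.3 * short.cdf(x)
            conv = np.clip((x - 9.5) / 3.5, 0, None)  # heuristic grid
            # exact CDF by numeric convolution of the two uniforms
            grid = np.linspace(0, 3.5, 1001)
            fx = np.atleast_1d(x)[:, None] - grid[None, :]
            b = 0.7 * stats.uniform(9.5, 3.5).cdf(fx).mean(axis=1)
            return a + b

        d, p = stats.kstest(itis, mixture_cdf)
        assert p > 0.01

    def test_baseline_reach_rate(self):
        rates = []
        for seed in range(30):
            s, _ = cr.generate_session(cr.BehaviorGenConfig(n_trials=100),
                                       seed=200 + seed)
            rates.append(window_reach_rate(s.trials,
                                           WindowSpec().uncued_window))
        mean = np.mean(rates)
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(mean - 0.25) < 3 * se + 0.005

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            cr.generate_session(cr.BehaviorGenConfig(catch_prob=1.5))
        with pytest.raises(ValueError):
            cr.generate_session(cr.BehaviorGenConfig(baseline_rate=-1.0))


class TestReinforcementPlanting:
    def test_null_model_symmetry(self):
        # cue_gain 1, delta 0: cued and uncued rates match within 3 SE
        cued, uncued = [], []
        for seed in range(60):
            s, _ = cr.generate_session(cr.BehaviorGenConfig(n_trials=100),
                                       seed=300 + seed)
            spec = WindowSpec()
            cued.append(window_reach_rate(s.trials, spec.cued_window))
            uncued.append(window_reach_rate(s.trials, spec.uncued_window))
        diff = np.array(cued) - np.array(uncued)
        se = diff.std(ddof=1) / np.sqrt(diff.size)
        assert abs(diff.mean()) < 3 * se + 1e-6

    def test_states_recorded_and_gated(self):
        cfg = cr.BehaviorGenConfig(n_trials=200, cue_gain=6.0,
                                   reinforcement_delta=0.5,
                                   inhibition_prob=1.0,
                                   update_gate="reach_overlap")
        _, truth = cr.generate_session(cfg, seed=7)
        # inhibition spans the cued window, so cued-success updates
        # whose reach falls inside it are blocked
        from cuedreach.behavior import TrialClass

        for k, cls in enumerate(truth.trial_classes):
            if cls is TrialClass.cued_success and truth.update_applied[k]:
                pass  # allowed: reach may fall outside the inhibition window
        blocked = [k for k, cls in enumerate(truth.trial_classes)
                   if cls is TrialClass.cued_success
                   and not truth.update_applied[k]]
        assert blocked, "inhibition should block some cued-success updates"

    def test_cue_gain_raises_cued_rate(self):
        spec = WindowSpec()
        s, _ = cr.generate_session(
            cr.BehaviorGenConfig(n_trials=400, cue_gain=6.0), seed=8)
        assert (window_reach_rate(s.trials, spec.cued_window)
                > 3 * window_reach_rate(s.trials, spec.uncued_window))


class TestSpikes:
    def test_zero_kernels_give_flat_psth(self):
        from cuedreach.units import psth

        s, _ = cr.generate_session(cr.BehaviorGenConfig(n_trials=60,
                                                        cue_gain=6.0), seed=9)
        kern = {g: {k: np.zeros_like(GLM_LAGS)
                    for k in default_group_kernels()["group1"]}
                for g in ("group1", "group2")}
        units, _ = cr.generate_population_spikes(
            s, cr.SpikeGenConfig(n_units=4, group_fractions=(0.5, 0.5, 0),
                                 kernels=kern,
                                 baseline_range_hz=(2.0, 2.0)), seed=10)
        cues = np.array([t.t_cue for t in s.trials])
        p = psth(units[0], cues, window=(-2.0, 5.0), binwidth=0.5)
        # homogeneous Poisson at 2 Hz: all bins within sampling error
        se = np.sqrt(2.0 / (0.5 * len(cues)))
        assert np.all(np.abs(p.rates - 2.0) < 5 * se)

    def test_group_units_classified_spn(self, spn_population):
        _, units, truth = spn_population
        for u, g in zip(units, truth.unit_groups):
            if g in ("group1", "group2"):
                assert u.unit_class == "SPN"

    def test_planted_psth_contrast(self, spn_population):
        from cuedreach.session import outcome_event_times
        from cuedreach.units import psth

        session, units, truth = spn_population
        ev = outcome_event_times(session)
        succ = np.concatenate([ev["cued_success"], ev["uncued_success"]])
        fail = np.concatenate([ev["cued_failure"], ev["uncued_failure"]])
        g1 = [u for u, g in zip(units, truth.unit_groups) if g == "group1"]
        g2 = [u for u, g in zip(units, truth.unit_groups) if g == "group2"]
        for u in g1:
            ps = psth(u, succ, (0.0, 3.0), 0.5).rates.mean()
            pf = psth(u, fail, (0.0, 3.0), 0.5).rates.mean()
            assert ps > pf
        # group 2 prefers failures on average
        d2 = [psth(u, fail, (1.0, 5.0), 0.5).rates.mean()
              - psth(u, succ, (1.0, 5.0), 0.5).rates.mean() for u in g2]
        assert np.mean(d2) > 0


class TestPhotometryGeneration:
    def test_carrier_power_concentrated_in_band(self):
        s, _ = cr.generate_session(cr.BehaviorGenConfig(n_trials=10), seed=11)
        trace, _ = cr.generate_photometry(s, seed=12)
        f, pxx = __import__("scipy.signal", fromlist=["welch"]).welch(
            trace.samples, fs=trace.fs_hz, nperseg=4096)
        band = (f > 120) & (f < 200)
        out = (f > 250) & (f < 400)
        assert pxx[band].mean() > 50 * pxx[out].mean()

    def test_transient_truth_recorded(self):
        s, _ = cr.generate_session(
            cr.BehaviorGenConfig(n_trials=30, cue_gain=6.0), seed=13)
        _, truth = cr.generate_photometry(s, seed=14)
        n_reaches = sum(len(t.reaches) for t in s.trials)
        assert len(truth.transients) == n_reaches
        signs = {np.sign(a) for _, a in truth.transients}
        assert signs <= {-1.0, 1.0}


def test_session_roundtrip_preserves_statistics(tmp_path):
    from cuedreach import io as cio
    from cuedreach.behavior import dprime

    s, _ = cr.generate_session(
        cr.BehaviorGenConfig(n_trials=80, cue_gain=5.0,
                             inhibition_prob=0.2), seed=15)
    path = tmp_path / "session.csv"
    cio.write_session_csv(s, path)
    back = cio.read_session_csv(path)
    assert back.n_trials == s.n_trials
    assert dprime(back.trials).dprime == pytest.approx(
        dprime(s.trials).dprime, abs=1e-9)
    ev_a = events_from_session(s)
    ev_b = events_from_session(back)
    for k in ev_a:
        assert np.allclose(ev_a[k], ev_b[k], atol=1e-5)
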