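"""Behavioral statistics: trial classification, d', learning metrics."""

import math

import numpy as np
import pytest
from scipy import stats

import cuedreach as cr
from cuedreach.behavior import (MixedModelSpec, QCRules, ReachOutcome,
                                TrialClass, WindowSpec, dprime,
                                fit_condition_mixed_model, learning_stage,
                                new_learning_days, p_cue_given_reach,
                                qc_filter_sessions, session_learned,
                                two_proportion_z, window_reach_rate)
from conftest import make_trial

S = ReachOutcome.success
D = ReachOutcome.drop
PM = ReachOutcome.pellet_missing


class TestClassifyTrial:
    @pytest.mark.parametrize("reaches,kw,expected", [
        # success within 1 s of the cue, nothing before
        ([(0.5, S)], {}, TrialClass.cued_success),
        ([(0.5, D)], {}, TrialClass.cued_failure),
        # success and failure both in the cued window: success wins
        ([(0.3, D), (0.5, S)], {}, TrialClass.cued_success),
        # quiet around the cue, success in the 3.5-7 s window
        ([(5.0, S)], {}, TrialClass.uncued_success),
        ([(3.5, S)], {}, TrialClass.uncued_success),   # closed lower edge
        ([(7.0, S)], {}, TrialClass.uncued_success),   # closed upper edge
        ([(5.0, D)], {}, TrialClass.uncued_failure),
        # failed reach before the cue
        ([(-2.0, PM)], {}, TrialClass.uncued_failure),
        # chewing at trial start voids the pre-cue failure path
        ([(-2.0, PM)], {"chewing_at_start": True}, TrialClass.other),
        # success outside every window
        ([(2.0, S)], {}, TrialClass.other),
        # reach inside the 1.5-s exclusion blocks the uncued classes
        ([(1.2, PM), (5.0, D)], {}, TrialClass.other),
        # pre-cue reach blocks the cued classes
        ([(-1.0, PM), (0.5, S)], {}, TrialClass.other),
        ([], {}, TrialClass.other),
    ])
    def test_classes(self, reaches, kw, expected):
        assert cr.classify_trial(make_trial(reaches=reaches, **kw)) == expected

    def test_cue_omission_is_other(self):
        t = make_trial(reaches=[(0.5, S)])
        t.cue_present = False
        t.t_cue = None
        assert cr.classify_trial(t) == TrialClass.other

    def test_reach_order_never_matters(self):
        rng = np.random.default_rng(0)
        outs = list(ReachOutcome)
        for _ in range(50):
            n = rng.integers(1, 5)
            reaches = [(float(rng.uniform(-3, 8)), outs[rng.integers(4)])
                       for _ in range(n)]
            a = cr.classify_trial(make_trial(reaches=reaches))
            b = cr.classify_trial(make_trial(reaches=reaches[::-1]))
            assert a == b

    def test_duplicate_reach_times_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            cr.classify_trial(make_trial(reaches=[(0.5, S), (0.5, D)]))


class TestWindowReachRate:
    def test_zero_and_hand_value(self):
        quiet = [make_trial() for _ in range(100)]
        assert window_reach_rate(quiet, (0.0, 0.4)) == 0.0
        one_each = [make_trial(reaches=[(0.2, S)]) for _ in range(10)]
        assert window_reach_rate(one_each, (0.0, 0.4)) == pytest.approx(2.5)

    def test_linearity_in_counts(self):
        single = [make_trial(reaches=[(0.1, S)]) for _ in range(5)]
        double = [make_trial(reaches=[(0.1, S), (0.3, PM)])
                  for _ in range(5)]
        r1 = window_reach_rate(single, (0.0, 0.4))
        r2 = window_reach_rate(double, (0.0, 0.4))
        assert r2 == pytest.approx(2 * r1)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            window_reach_rate([], (0.0, 0.4))


class TestDPrime:
    def _session(self, n, hit_k, fa1_k, fa2_k=0):
        trials = []
        for i in range(n):
            reaches = []
            if i < hit_k:
                reaches.append((0.2, S))
            if i < fa1_k:
                reaches.append((-0.2, PM))
            if i < fa2_k:
                reaches.append((-0.8, PM))
            trials.append(make_trial(reaches=reaches))
        return trials

    def test_quantile_oracle(self):
        # hit 841/1000, FA 500/1000: d' = ppf(0.841) - ppf(0.5) ~ 1.00
        res = dprime(self._session(1000, 841, 500), variant="single_fa")
        expect = stats.norm.ppf(0.841) - stats.norm.ppf(0.5)
        assert res.dprime == pytest.approx(expect)
        assert res.dprime == pytest.approx(1.0, abs=0.01)

    def test_equal_rates_give_zero(self):
        res = dprime(self._session(100, 30, 30), variant="single_fa")
        assert res.dprime == pytest.approx(0.0)

    def test_dual_variant_takes_minimum(self):
        trials = self._session(200, 150, 40, 90)
        dual = dprime(trials, variant="dual_fa_min")
        single = dprime(trials, variant="single_fa")
        # second FA window has more reaching -> lower candidate d'
        assert dual.dprime < single.dprime
        z = stats.norm.ppf
        expect = z(150 / 200) - z(90 / 200)
        assert dual.dprime == pytest.approx(expect)

    def test_saturated_rates_are_clipped(self):
        res = dprime(self._session(50, 50, 0), variant="single_fa")
        assert math.isfinite(res.dprime)
        assert res.hit_rate == pytest.approx(1 - 1 / 100)
        assert res.fa_rates[0] == pytest.approx(1 / 100)

    def test_duplication_invariance(self):
        trials = self._session(100, 40, 10)
        d1 = dprime(trials, variant="single_fa").dprime
        d2 = dprime(trials * 3, variant="single_fa").dprime
        assert d2 == pytest.approx(d1)

    def test_no_trials_errors(self):
        with pytest.raises(ValueError):
            dprime([])


@pytest.mark.parametrize("d,stage", [
    (-0.1, "beginner"), (0.0, "beginner"), (0.24, "beginner"),
    (0.25, "intermediate"), (0.3, "intermediate"), (0.74, "intermediate"),
    (0.75, "expert"), (1.6, "expert"),
])
def test_learning_stage_thresholds(d, stage):
    assert learning_stage(d) == stage


def test_learning_stage_rejects_nan():
    with pytest.raises(ValueError):
        learning_stage(float("nan"))


class TestSessionLearned:
    def _periodic(self, n=200):
        # period divides every split point, so all contrasts are exactly 0
        trials = []
        for i in range(n):
            reaches = []
            if i % 10 == 0:
                reaches.append((0.2, S))
            if i % 5 == 1:
                reaches.append((-0.3, PM))
            trials.append(make_trial(reaches=reaches))
        return trials

    def _improving(self, n=200):
        trials = []
        for i in range(n):
            reaches = [(-0.3, PM)] if i % 5 == 1 else []
            if i > n // 2 and i % 2 == 0:
                reaches.append((0.2, S))
            trials.append(make_trial(reaches=sorted(reaches)))
        return trials

    def test_improving_session_flags_learned(self):
        flags = session_learned(self._improving())
        assert flags.learned
        assert flags.delta_d2 > 0.1

    def test_stationary_session_not_learned(self):
        flags = session_learned(self._periodic())
        assert not flags.learned
        assert flags.delta_d2 == pytest.approx(0.0)

    def test_threshold_is_strict(self):
        # all contrasts exactly 0: not learned even at threshold 0
        flags = session_learned(self._periodic(), threshold=0.0)
        assert not flags.learned

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            session_learned([make_trial()] * 3)


class TestNewLearningDays:
    def test_hand_trace(self):
        assert new_learning_days([0.1, 0.3, 0.2, 0.5]) == [1, 2, 4]

    def test_monotone_decreasing_keeps_first(self):
        assert new_learning_days([0.5, 0.4, 0.3]) == [1]

    def test_expert_record_day_excluded(self):
        assert new_learning_days([0.1, 0.8, 0.9, 0.6]) == [1]

    def test_tail_discard_uses_early_trials_only(self):
        # 100 trials; success only in the final 10% -> discarded, d' stays low
        quiet = [make_trial() for _ in range(90)]
        late = [make_trial(reaches=[(0.2, S)]) for _ in range(10)]
        days = new_learning_days([quiet + late])
        d_full = dprime(quiet + late).dprime
        d_trim = dprime(quiet).dprime
        assert d_trim < d_full
        assert days == [1]


class TestPCueGivenReach:
    def test_saturation(self):
        trials = [make_trial(t_cue=10.0 + 30 * i, start=30 * i,
                             end=30 * (i + 1), reaches=[(0.1, S)])
                  for i in range(20)]
        p, sd = p_cue_given_reach(trials, window_s=0.4)
        assert p == 1.0 and sd == 0.0

    def test_monotone_in_window(self):
        rng = np.random.default_rng(3)
        trials = []
        for i in range(200):
            dts = rng.uniform(-3, 8, size=rng.integers(0, 3))
            trials.append(make_trial(
                t_cue=10.0 + 30 * i, start=30 * i, end=30 * (i + 1),
                reaches=[(float(dt), PM) for dt in sorted(dts)]))
        p_small, _ = p_cue_given_reach(trials, window_s=0.4)
        p_large, _ = p_cue_given_reach(trials, window_s=1.5)
        assert p_large >= p_small

    def test_poisson_coverage_fraction(self):
        # uniform reaching: p(preceded) approaches the fraction of session
        # time lying within `window` after a cue
        rng = np.random.default_rng(4)
        window, period, n = 0.4, 20.0, 2000
        trials = []
        for i in range(n):
            dts = np.sort(rng.uniform(-10, 10, size=rng.poisson(2.0)))
            trials.append(make_trial(
                t_cue=10.0 + period * i, start=period * i,
                end=period * (i + 1),
                reaches=[(float(dt), PM) for dt in dts]))
        p, sd = p_cue_given_reach(trials, window_s=window)
        assert p == pytest.approx(window / period, abs=4 * sd + 1e-3)

    def test_no_reaches_errors(self):
        with pytest.raises(ValueError):
            p_cue_given_reach([make_trial()])


class TestTwoProportionZ:
    def test_equal_proportions(self):
        z, p = two_proportion_z(30, 100, 30, 100)
        assert z == 0.0 and p == 1.0

    def test_textbook_pooled_formula(self):
        k1, n1, k2, n2 = 48, 1000, 38, 1000
        z, p = two_proportion_z(k1, n1, k2, n2)
        pool = (k1 + k2) / (n1 + n2)
        z_hand = (k1 / n1 - k2 / n2) / math.sqrt(
            pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert z == pytest.approx(z_hand)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z_hand)))

    def test_antisymmetry(self):
        z1, p1 = two_proportion_z(48, 1000, 38, 1000)
        z2, p2 = two_proportion_z(38, 1000, 48, 1000)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            two_proportion_z(5, 4, 1, 10)


class TestMixedModel:
    def _obs(self, n_mice=6, per=8, effect=0.5, mouse_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for m in range(n_mice):
            u = mouse_sd * rng.standard_normal()
            for j in range(per):
                cond = j % 2
                rows.append((f"m{m}", cond,
                             u + effect * cond + 0.3 * rng.standard_normal()))
        return rows

    def test_matches_ols_without_mouse_variance(self):
        import statsmodels.api as sm

        rows = self._obs(mouse_sd=0.0)
        fit = fit_condition_mixed_model(rows)
        X = sm.add_constant([r[1] for r in rows])
        ols = sm.OLS([r[2] for r in rows], X).fit()
        assert fit.beta1 == pytest.approx(ols.params[1], abs=0.05)

    def test_translation_shifts_intercept_only(self):
        rows = self._obs(mouse_sd=0.4, seed=1)
        base = fit_condition_mixed_model(rows)
        shifted = fit_condition_mixed_model(
            [(m, c, v + 10.0) for m, c, v in rows])
        assert shifted.beta0 == pytest.approx(base.beta0 + 10.0, abs=1e-6)
        assert shifted.beta1 == pytest.approx(base.beta1, abs=1e-6)

    def test_null_effect_p_calibration(self):
        covered = 0
        n_rep = 40
        for s in range(n_rep):
            fit = fit_condition_mixed_model(
                self._obs(effect=0.0, mouse_sd=0.3, seed=100 + s))
            covered += fit.p_value > 0.05
        # ~95% of null fits should not reject at alpha=0.05
        assert covered >= int(0.85 * n_rep)

    def test_single_mouse_falls_back(self):
        with pytest.warns(UserWarning, match="single mouse"):
            fit = fit_condition_mixed_model(self._obs(n_mice=1))
        assert isinstance(fit, MixedModelSpec)
        assert fit.sigma_u2 == 0.0


class TestQCFilter:
    def _clean(self, seed=0):
        session, _ = cr.generate_session(
            cr.BehaviorGenConfig(n_trials=150, cue_gain=4.0), seed=seed)
        return session.trials

    def test_clean_session_kept(self):
        kept, excl = qc_filter_sessions([self._clean()])
        assert kept == [0] and excl == []

    def test_cheating_session_excluded(self):
        # plant heavy reaching immediately before every cue
        trials = []
        for i in range(100):
            trials.append(make_trial(
                t_cue=10.0 + 30 * i, start=30 * i, end=30 * (i + 1),
                reaches=[(-0.3, PM), (-0.1, PM)]))
        kept, excl = qc_filter_sessions([trials],
                                        QCRules(cheat_ratio=2.0))
        assert kept == []
        assert "cheating" in excl[0][1]

    def test_inhibition_excess_excluded(self):
        rng = np.random.default_rng(7)
        trials = []
        for i in range(200):
            inhibited = i % 2 == 0
            reaches = []
            if inhibited and rng.uniform() < 0.6:
                reaches.append((0.2, S))
            elif not inhibited and rng.uniform() < 0.2:
                reaches.append((0.2, S))
            t = make_trial(t_cue=10.0 + 30 * i, start=30 * i,
                           end=30 * (i + 1), reaches=reaches)
            if inhibited:
                t.inhibition_window = (t.t_cue - 0.005, t.t_cue + 0.995)
            trials.append(t)
        kept, excl = qc_filter_sessions([trials])
        assert kept == []
        assert "inhibition" in excl[0][1]
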