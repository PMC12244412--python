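"""Session data model and behavioral signal-detection statistics.

A head-restrained mouse performs a cued forelimb-reaching task: on each
trial a food pellet is presented and a brief (250 ms) cue signals its
availability.  Behavior is quantified by comparing reach rates in a short
window after cue onset against reaching before the cue, via the
signal-detection discriminability index

    d' = z(hit) - z(FA)

where the hit rate is the probability of at least one reach just after the
cue and the false-alarm rate the analogous probability just before it.
This module holds the trial/reach data model, trial classification into
context x outcome types, d' and its learning-stage derivatives, cue-reach
timing probabilities, simple condition-contrast statistics, and the
session-level quality-control filters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ReachOutcome",
    "Reach",
    "Trial",
    "WindowSpec",
    "TrialClass",
    "DPrimeResult",
    "SessionLearnedFlags",
    "MixedModelSpec",
    "QCRules",
    "classify_trial",
    "classify_session",
    "window_reach_rate",
    "dprime",
    "learning_stage",
    "session_learned",
    "new_learning_days",
    "p_cue_given_reach",
    "two_proportion_z",
    "fit_condition_mixed_model",
    "qc_filter_sessions",
]


class ReachOutcome(str, Enum):
    """Outcome of a single reach attempt.

    Anything other than ``success`` (a consumed pellet) is a failure:
    a dropped pellet, a reach that missed the pellet, or a reach made
    while no pellet was present.
    """

    success = "success"
    drop = "drop"
    missed_pellet = "missed_pellet"
    pellet_missing = "pellet_missing"


@dataclass(frozen=True)
class Reach:
    """A single reach, timestamped at the moment the arm is outstretched."""

    t_arm: float
    outcome: ReachOutcome

    def __post_init__(self) -> None:
        if self.t_arm < 0:
            raise ValueError(f"reach time must be >= 0, got {self.t_arm}")
        object.__setattr__(self, "outcome", ReachOutcome(self.outcome))

    @property
    def is_failure(self) -> bool:
        return self.outcome is not ReachOutcome.success

    @property
    def is_success(self) -> bool:
        return self.outcome is ReachOutcome.success


@dataclass
class Trial:
    """One trial: pellet presentation, cue, reaches and optional inhibition.

    Times are seconds from session start.  ``t_cue`` is ``None`` on
    cue-omission trials.  ``catch`` marks trials where the cue was
    delivered but the pellet deliberately omitted.
    """

    trial_start: float
    trial_end: float
    t_cue: float | None = None
    cue_present: bool = True
    pellet_presented: bool = True
    catch: bool = False
    chewing_at_start: bool = False
    inhibition_window: tuple[float, float] | None = None
    distractor_times: list[float] = field(default_factory=list)
    reaches: list[Reach] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trial_start < self.trial_end:
            raise ValueError("trial_start must precede trial_end")
        if self.cue_present:
            if self.t_cue is None:
                raise ValueError("cue_present trial requires t_cue")
            if not (self.trial_start <= self.t_cue < self.trial_end):
                raise ValueError("t_cue must lie within [trial_start, trial_end)")
        else:
            self.t_cue = None
        if self.inhibition_window is not None:
            a, b = self.inhibition_window
            if not a < b:
                raise ValueError("inhibition window must be ordered")
        if self.catch and self.pellet_presented:
            raise ValueError("catch trial cannot have pellet_presented")

    @property
    def inhibited(self) -> bool:
        return self.inhibition_window is not None

    def sorted_reaches(self) -> list[Reach]:
        """Reaches in time order; raises on duplicated reach times."""
        times = [r.t_arm for r in self.reaches]
        if len(set(times)) != len(times):
            raise ValueError("overlapping reach times in trial")
        return sorted(self.reaches, key=lambda r: r.t_arm)


@dataclass(frozen=True)
class WindowSpec:
    """Analysis windows, all in seconds relative to cue onset.

    Windows are half-open ``[start, end)`` except ``uncued_reach_window``,
    which is closed (a reach "between 3.5 s and 7 s" qualifies at either
    endpoint).  ``pre_cue_scope`` controls what counts as "reaching before
    the cue": the full span from trial start (default) or only the uncued
    window.
    """

    cued_window: tuple[float, float] = (0.0, 0.4)
    uncued_window: tuple[float, float] = (-3.0, -0.25)
    fa_window_1: tuple[float, float] = (-0.4, 0.0)
    fa_window_2: tuple[float, float] = (-1.0, -0.6)
    cued_reach_max: float = 1.0
    post_cue_exclusion: float = 1.5
    uncued_reach_window: tuple[float, float] = (3.5, 7.0)
    pre_cue_scope: str = "full"  # "full" | "uncued_window"

    def __post_init__(self) -> None:
        for name in ("cued_window", "uncued_window", "fa_window_1",
                     "fa_window_2", "uncued_reach_window"):
            a, b = getattr(self, name)
            if not a < b:
                raise ValueError(f"degenerate window {name}: ({a}, {b})")
        if self.pre_cue_scope not in ("full", "uncued_window"):
            raise ValueError("pre_cue_scope must be 'full' or 'uncued_window'")


class TrialClass(str, Enum):
    cued_success = "cued_success"
    cued_failure = "cued_failure"
    uncued_success = "uncued_success"
    uncued_failure = "uncued_failure"
    other = "other"


def _in_half_open(t: float, lo: float, hi: float) -> bool:
    return lo <= t < hi


def classify_trial(trial: Trial, spec: WindowSpec = WindowSpec()) -> TrialClass:
    """Assign one context x outcome class to a trial.

    cued success/failure: no reach before the cue, and a success/failure
    within 1 s of cue onset (success takes precedence if both occur).
    uncued success: no pre-cue reach, no reach within 1.5 s of the cue,
    and a success between 3.5 s and 7 s after the cue.  uncued failure:
    a failed pre-cue reach (unless the mouse was chewing at trial start)
    or a failed reach in the 3.5-7 s window, with no reach within 1.5 s
    of the cue and no success anywhere in the trial.  Everything else,
    including cue-omission trials, is ``other``.
    """
    if not trial.cue_present or trial.t_cue is None:
        return TrialClass.other
    reaches = trial.sorted_reaches()
    tc = trial.t_cue

    if spec.pre_cue_scope == "full":
        pre = [r for r in reaches if trial.trial_start <= r.t_arm < tc]
    else:
        pre = [r for r in reaches
               if _in_half_open(r.t_arm - tc, *spec.uncued_window)]
    post = [(r, r.t_arm - tc) for r in reaches if r.t_arm >= tc]

    any_success = any(r.is_success for r in reaches)
    in_excl = [r for r, dt in post if dt < spec.post_cue_exclusion]

    if not pre:
        cued = [r for r, dt in post if dt < spec.cued_reach_max]
        if any(r.is_success for r in cued):
            return TrialClass.cued_success
        if any(r.is_failure for r in cued):
            return TrialClass.cued_failure
        if not in_excl:
            lo, hi = spec.uncued_reach_window
            window = [r for r, dt in post if lo <= dt <= hi]
            if any(r.is_success for r in window):
                return TrialClass.uncued_success

    # uncued failure: failed reach in the pre-cue span (no chewing) or in
    # the closed uncued reach window; nothing near the cue; no success.
    if not in_excl and not any_success:
        pre_failed = any(r.is_failure for r in pre) and not trial.chewing_at_start
        lo, hi = spec.uncued_reach_window
        win_failed = any(r.is_failure for r, dt in post if lo <= dt <= hi)
        if pre_failed or win_failed:
            return TrialClass.uncued_failure
    return TrialClass.other


def classify_session(trials: Sequence[Trial],
                     spec: WindowSpec = WindowSpec()) -> list[TrialClass]:
    return [classify_trial(t, spec) for t in trials]


def _window_count(trial: Trial, window: tuple[float, float],
                  closed: bool = False) -> int:
    if trial.t_cue is None:
        raise ValueError("trial without a cue has no cue-relative window")
    lo, hi = window
    n = 0
    for r in trial.reaches:
        dt = r.t_arm - trial.t_cue
        if (lo <= dt <= hi) if closed else (lo <= dt < hi):
            n += 1
    return n


def window_reach_rate(trials: Sequence[Trial],
                      window: tuple[float, float]) -> float:
    """Mean reach rate (Hz) in a cue-relative window, averaged over trials."""
    if len(trials) == 0:
        raise ValueError("window_reach_rate requires at least one trial")
    lo, hi = window
    if not hi > lo:
        raise ValueError("window duration must be positive")
    counts = [_window_count(t, window) for t in trials]
    return float(np.mean(counts)) / (hi - lo)


def trial_behavior_vector(trial: Trial,
                          spec: WindowSpec = WindowSpec()) -> tuple[float, float]:
    """Per-trial (cued-window rate, uncued-window rate) in Hz."""
    c_lo, c_hi = spec.cued_window
    u_lo, u_hi = spec.uncued_window
    c = _window_count(trial, spec.cued_window) / (c_hi - c_lo)
    u = _window_count(trial, spec.uncued_window) / (u_hi - u_lo)
    return float(c), float(u)


@dataclass(frozen=True)
class DPrimeResult:
    hit_rate: float
    fa_rates: tuple[float, ...]
    dprime: float
    n_trials: int


def _clip_rate(p: float, n: int) -> float:
    # saturated rates would map to +/- infinity under the quantile transform
    if p <= 0.0:
        return 1.0 / (2 * n)
    if p >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return p


def dprime(trials: Sequence[Trial], spec: WindowSpec = WindowSpec(),
           variant: str = "dual_fa_min") -> DPrimeResult:
    """Discriminability index d' = z(hit) - z(FA) for a set of cue trials.

    The hit rate is the fraction of trials with at least one reach in the
    cued window.  With ``variant="dual_fa_min"`` two false-alarm windows
    are evaluated (0.4 s and 1.0 s before the cue, 400 ms each) and the
    lower of the two candidate d' values is returned, so preemptive
    reaching anywhere shortly before the cue depresses the index.
    ``variant="single_fa"`` uses only the window immediately before the
    cue.  Rates are clipped to (0, 1) before the normal-quantile
    transform (0 -> 1/2N, 1 -> 1 - 1/2N).
    """
    cue_trials = [t for t in trials if t.cue_present]
    n = len(cue_trials)
    if n == 0:
        raise ValueError("dprime requires at least one cue-present trial")
    if variant not in ("dual_fa_min", "single_fa"):
        raise ValueError(f"unknown d' variant: {variant}")

    hit = _clip_rate(
        sum(_window_count(t, spec.cued_window) > 0 for t in cue_trials) / n, n)
    fa_windows = [spec.fa_window_1]
    if variant == "dual_fa_min":
        fa_windows.append(spec.fa_window_2)
    fas, ds = [], []
    for w in fa_windows:
        fa = _clip_rate(sum(_window_count(t, w) > 0 for t in cue_trials) / n, n)
        fas.append(fa)
        ds.append(float(stats.norm.ppf(hit) - stats.norm.ppf(fa)))
    return DPrimeResult(hit_rate=hit, fa_rates=tuple(fas),
                        dprime=min(ds), n_trials=n)


def learning_stage(d: float) -> str:
    """Map a session d' to beginner (<0.25), intermediate, expert (>=0.75)."""
    if not math.isfinite(d):
        raise ValueError("d' must be finite")
    if d < 0.25:
        return "beginner"
    if d < 0.75:
        return "intermediate"
    return "expert"


@dataclass(frozen=True)
class SessionLearnedFlags:
    delta_d1: float  # last 75% minus first 25%
    delta_d2: float  # last 50% minus first 50%
    delta_d3: float  # last 25% minus first 75%
    learned: bool


def session_learned(trials: Sequence[Trial], spec: WindowSpec = WindowSpec(),
                    variant: str = "dual_fa_min",
                    threshold: float = 0.1) -> SessionLearnedFlags:
    """Did performance improve within the session?

    Three split contrasts allow for improvement early or late in the
    session: d'(last 75%) - d'(first 25%), d'(halves), and
    d'(last 25%) - d'(first 75%).  The session counts as learned when any
    contrast strictly exceeds ``threshold`` (0.1 by default).
    """
    trials = [t for t in trials if t.cue_present]
    n = len(trials)
    q1, q2, q3 = n // 4, n // 2, (3 * n) // 4
    if q1 < 1 or n - q3 < 1:
        raise ValueError("too few trials to split the session")

    def d(seg: Sequence[Trial]) -> float:
        return dprime(seg, spec, variant).dprime

    d1 = d(trials[q1:]) - d(trials[:q1])
    d2 = d(trials[q2:]) - d(trials[:q2])
    d3 = d(trials[q3:]) - d(trials[:q3])
    return SessionLearnedFlags(d1, d2, d3, learned=max(d1, d2, d3) > threshold)


def new_learning_days(sessions: Sequence[Sequence[Trial] | float],
                      spec: WindowSpec = WindowSpec(),
                      variant: str = "dual_fa_min",
                      expert_threshold: float = 0.75,
                      discard_tail: float = 0.10) -> list[int]:
    """Select one mouse's "new learning days" (1-based day indices).

    A new learning day is a pre-expert session (d' < 0.75) whose d'
    strictly exceeds that achieved on every previous day.  Each session's
    d' is computed after discarding its final 10% of trials, when mice
    disengage.  ``sessions`` may be trial lists or precomputed d' floats.
    """
    dvals = []
    for s in sessions:
        if isinstance(s, (int, float)):
            dvals.append(float(s))
        else:
            trials = list(s)
            keep = len(trials) - int(math.floor(discard_tail * len(trials)))
            dvals.append(dprime(trials[:keep], spec, variant).dprime)
    days, best = [], -math.inf
    for i, d in enumerate(dvals, start=1):
        if d < expert_threshold and d > best:
            days.append(i)
        best = max(best, d)
    return days


def p_cue_given_reach(trials: Sequence[Trial], window_s: float = 0.4,
                      direction: str = "preceded") -> tuple[float, float]:
    """Probability that a reach was preceded (or followed) by the cue.

    ``preceded``: fraction of reaches with a cue onset within ``window_s``
    at or before the reach.  ``followed``: cue strictly after the reach
    within ``window_s``.  Returns (p, binomial SD = sqrt(p(1-p)/n)).
    """
    if direction not in ("preceded", "followed"):
        raise ValueError("direction must be 'preceded' or 'followed'")
    cue_times = np.array([t.t_cue for t in trials if t.cue_present],
                         dtype=float)
    reach_times = np.array([r.t_arm for t in trials for r in t.reaches],
                           dtype=float)
    if reach_times.size == 0:
        raise ValueError("p_cue_given_reach requires at least one reach")
    k = 0
    for t_arm in reach_times:
        dt = t_arm - cue_times if direction == "preceded" else cue_times - t_arm
        if direction == "preceded":
            hit = np.any((dt >= 0) & (dt < window_s))
        else:
            hit = np.any((dt > 0) & (dt <= window_s))
        k += bool(hit)
    n = reach_times.size
    p = k / n
    return float(p), float(math.sqrt(p * (1 - p) / n))


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion Z-test; returns (z, two-sided p)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    denom = math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if denom == 0.0:
        return 0.0, 1.0
    z = (p1 - p2) / denom
    return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class MixedModelSpec:
    beta0: float
    beta1: float
    sigma_u2: float
    sigma_e2: float
    p_value: float


def fit_condition_mixed_model(
        observations: Iterable[tuple[object, int | bool, float]],
) -> MixedModelSpec:
    """Linear mixed model ``metric ~ condition + (1 | mouse)``.

    ``observations`` are (mouse_id, condition flag, metric) triples, e.g.
    per-session d' changes under control vs inhibition.  A random
    intercept per mouse absorbs baseline differences between animals;
    the p-value tests the fixed condition effect.  With a single mouse
    the random intercept is unidentifiable and the fit falls back to
    ordinary regression with a warning.
    """
    import pandas as pd
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(observations, columns=["mouse", "condition", "metric"])
    if df.empty:
        raise ValueError("no observations")
    df["condition"] = df["condition"].astype(float)
    if df["condition"].nunique() < 2:
        raise ValueError("both conditions must be represented")
    if df["mouse"].nunique() < 2:
        warnings.warn("single mouse: falling back to ordinary regression",
                      stacklevel=2)
        X = sm.add_constant(df["condition"].to_numpy())
        fit = sm.OLS(df["metric"].to_numpy(), X).fit()
        return MixedModelSpec(float(fit.params[0]), float(fit.params[1]),
                              0.0, float(fit.scale), float(fit.pvalues[1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm("metric ~ condition", df, groups=df["mouse"]).fit(
            reml=True)
    return MixedModelSpec(
        beta0=float(fit.params["Intercept"]),
        beta1=float(fit.params["condition"]),
        sigma_u2=float(np.asarray(fit.cov_re)[0, 0]),
        sigma_e2=float(fit.scale),
        p_value=float(fit.pvalues["condition"]),
    )


@dataclass(frozen=True)
class QCRules:
    """Session inclusion rules.

    ``cheat_ratio``: exclude when the reach rate immediately before the
    cue exceeds this multiple of the session's spontaneous baseline
    (uncued-window rate) -- evidence the mouse detects the pellet without
    the cue.  ``inhibition_excess_frac``: exclude when inhibition trials
    show cued reaching exceeding the control rate by more than this
    fraction of the control rate (direct excitation artifact of the
    inhibitory opsin).
    """

    cheat_ratio: float = 2.0
    inhibition_excess_frac: float = 0.20
    min_baseline_hz: float = 0.05


def qc_filter_sessions(
        sessions: Sequence[Sequence[Trial]],
        rules: QCRules = QCRules(),
        spec: WindowSpec = WindowSpec(),
) -> tuple[list[int], list[tuple[int, str]]]:
    """Apply session-level QC; returns (kept indices, [(index, reason)])."""
    kept, excluded = [], []
    for i, trials in enumerate(sessions):
        cue_trials = [t for t in trials if t.cue_present]
        if not cue_trials:
            excluded.append((i, "no cue trials"))
            continue
        baseline = window_reach_rate(cue_trials, spec.uncued_window)
        pre_cue = window_reach_rate(cue_trials, spec.fa_window_1)
        floor = max(baseline, rules.min_baseline_hz)
        if pre_cue > rules.cheat_ratio * floor:
            excluded.append(
                (i, f"cheating: pre-cue rate {pre_cue:.3g} Hz > "
                    f"{rules.cheat_ratio:g} x baseline {baseline:.3g} Hz"))
            continue
        inh = [t for t in cue_trials if t.inhibited]
        con = [t for t in cue_trials if not t.inhibited]
        if inh and con:
            r_inh = window_reach_rate(inh, spec.cued_window)
            r_con = window_reach_rate(con, spec.cued_window)
            if r_inh - r_con > rules.inhibition_excess_frac * r_con:
                excluded.append(
                    (i, f"inhibition-evoked reaching: {r_inh:.3g} Hz vs "
                        f"control {r_con:.3g} Hz"))
                continue
        kept.append(i)
    return kept, excluded
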