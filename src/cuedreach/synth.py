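"""Synthetic sessions, spike trains and photometry with planted truth.

The generator reproduces the statistical skeleton of the cued-reaching
task so every downstream estimator can be validated against known ground
truth:

* trial structure -- a 250-ms cue each trial, 10% catch trials (cue with
  the pellet deliberately omitted), 30% pellet availability at cue time,
  pellet withdrawn 8 s after cue onset, and a two-part inter-trial
  interval (uniform 0-3.5 s, extended by 9.5-13 s with probability 0.7);
* reaching -- an inhomogeneous Poisson process at a low baseline
  (~0.25 Hz), multiplied by ``cue_gain`` inside the 400-ms cued window,
  plus context-specific reinforcement states that jump by
  ``reinforcement_delta`` after a cued (resp. uncued) success and decay
  geometrically trial by trial;
* spikes -- inhomogeneous-Poisson trains whose rates are a baseline plus
  behavioral-event kernels (linear link, floored at zero), with two
  planted kernel groups mimicking success- and failure-preferring SPNs;
* photometry -- a 167-Hz amplitude-modulated carrier sampled at 2 kHz,
  whose envelope carries success peaks (0.83 s after the reach) and
  failure dips (1.6 s after the reach) on top of white noise.

All randomness flows through an explicit integer seed; identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .behavior import Reach, ReachOutcome, Trial, TrialClass, WindowSpec, classify_trial
from .session import EVENT_NAMES, BehavioralSession, events_from_session

__all__ = [
    "BehaviorGenConfig",
    "SpikeGenConfig",
    "PhotometryGenConfig",
    "PlantedTruth",
    "generate_session",
    "generate_population_spikes",
    "generate_photometry",
    "default_group_kernels",
    "GLM_LAGS",
]

# lag grid shared with the event GLM: -2 .. +5 s inclusive at 0.1 s
GLM_BIN_S = 0.1
GLM_LAGS = np.round(np.arange(-20, 51) * GLM_BIN_S, 10)


@dataclass(frozen=True)
class BehaviorGenConfig:
    """Parameters of the synthetic behavioral session.

    Defaults encode the task's trial structure and a naive (beginner)
    mouse: ``cue_gain`` 1 means the cue does not yet drive reaching.
    ``reinforcement_delta`` is the Hz increment added to the cued
    (resp. uncued) reach rate on later trials after a cued (resp.
    uncued) success; the state decays with a half-life of
    ``reinforcement_half_life_trials`` trials.
    """

    n_trials: int = 200
    baseline_rate: float = 0.25           # Hz, spontaneous reaching
    cue_gain: float = 1.0                 # multiplicative, cued window only
    reinforcement_delta: float = 0.0      # Hz per conditioned success
    reinforcement_half_life_trials: float = 1.0
    catch_prob: float = 0.10
    pellet_occupancy: float = 0.30        # P(pellet available at cue time)
    success_prob_given_pellet: float = 0.75
    drop_prob_given_fail: float = 0.5     # split of pellet-present failures
    cue_duration_s: float = 0.25
    pellet_lead_s: float = 0.22           # pellet arrives just before cue
    pellet_retract_s: float = 8.0
    pellet_travel_s: float = 1.5          # presenter travel + pre-cue delay
    iti_uniform_max_s: float = 3.5
    iti_continue_prob: float = 0.70
    iti_extra_s: tuple[float, float] = (9.5, 13.0)
    pre_cue_span_s: float = 3.0           # trial span before the cue
    distractor_rate: float = 0.02         # Hz, random LED flashes
    inhibition_prob: float = 0.0
    inhibition_rel_cue: tuple[float, float] = (-0.005, 0.995)
    # "reach_overlap": inhibition covering the conditioned reach blocks the
    # reinforcement update; "none": inhibition is inert.
    update_gate: str = "reach_overlap"
    gate_pad_s: float = 0.0
    chewing_prob: float = 0.0

    def validate(self) -> None:
        probs = {
            "catch_prob": self.catch_prob,
            "pellet_occupancy": self.pellet_occupancy,
            "success_prob_given_pellet": self.success_prob_given_pellet,
            "drop_prob_given_fail": self.drop_prob_given_fail,
            "iti_continue_prob": self.iti_continue_prob,
            "inhibition_prob": self.inhibition_prob,
            "chewing_prob": self.chewing_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.catch_prob + self.pellet_occupancy > 1.0:
            raise ValueError("catch_prob + pellet_occupancy must be <= 1")
        for name in ("baseline_rate", "cue_gain", "distractor_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.iti_extra_s[0] > self.iti_extra_s[1]:
            raise ValueError("iti_extra_s must be ordered")
        if self.update_gate not in ("reach_overlap", "none"):
            raise ValueError("update_gate must be 'reach_overlap' or 'none'")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside each synthetic artifact."""

    trial_classes: list[TrialClass] = field(default_factory=list)
    cued_state: np.ndarray | None = None     # Hz, per trial
    uncued_state: np.ndarray | None = None
    update_applied: list[bool] = field(default_factory=list)
    reinforcement_delta: float = 0.0
    rate_floor_events: int = 0
    unit_groups: list[str] = field(default_factory=list)
    unit_kernels: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    transients: list[tuple[float, float]] = field(default_factory=list)
    seed: int | None = None


def _draw_poisson_times(rng: np.random.Generator, rate: float,
                        lo: float, hi: float) -> list[float]:
    if rate <= 0.0 or hi <= lo:
        return []
    n = rng.poisson(rate * (hi - lo))
    return sorted(rng.uniform(lo, hi, size=n).tolist()) if n else []


def generate_session(
        cfg: BehaviorGenConfig = BehaviorGenConfig(),
        seed: int = 0,
        spec: WindowSpec = WindowSpec(),
) -> tuple[BehavioralSession, PlantedTruth]:
    """Simulate one behavioral session.

    Reaching is an inhomogeneous Poisson process whose rate is the
    baseline everywhere, scaled by ``cue_gain`` in the cued window and
    augmented by the cued/uncued reinforcement states in their windows.
    Outcomes depend on pellet availability at the reach (the pellet is
    present from shortly before the cue until retraction, unless consumed
    or dropped); reaches with no pellet are ``pellet_missing`` failures.
    After each trial the matching state is incremented if the trial was a
    cued/uncued success -- unless optogenetic inhibition overlapped the
    conditioned reach and the update gate is active.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    truth = PlantedTruth(reinforcement_delta=cfg.reinforcement_delta,
                         seed=seed)
    decay = 0.5 ** (1.0 / cfg.reinforcement_half_life_trials)

    trials: list[Trial] = []
    s_cued = 0.0
    s_uncued = 0.0
    cued_states = np.zeros(cfg.n_trials)
    uncued_states = np.zeros(cfg.n_trials)
    t_cue = cfg.pre_cue_span_s
    floor_events = 0

    for k in range(cfg.n_trials):
        cued_states[k] = s_cued
        uncued_states[k] = s_uncued

        # trial skeleton -------------------------------------------------
        u = rng.uniform()
        if u < cfg.catch_prob:
            catch, pellet = True, False
        else:
            pellet = rng.uniform() < cfg.pellet_occupancy / (1 - cfg.catch_prob)
            catch = False
        iti = rng.uniform(0.0, cfg.iti_uniform_max_s)
        if rng.uniform() < cfg.iti_continue_prob:
            iti += rng.uniform(*cfg.iti_extra_s)
        inter_cue = cfg.pellet_retract_s + iti + cfg.pellet_travel_s
        trial_start = t_cue - cfg.pre_cue_span_s
        trial_end = t_cue + inter_cue - cfg.pre_cue_span_s
        chewing = rng.uniform() < cfg.chewing_prob
        inhibition = None
        if rng.uniform() < cfg.inhibition_prob:
            inhibition = (t_cue + cfg.inhibition_rel_cue[0],
                          t_cue + cfg.inhibition_rel_cue[1])

        # piecewise-constant reach intensity ------------------------------
        b = cfg.baseline_rate
        u_lo, u_hi = spec.uncued_window
        c_lo, c_hi = spec.cued_window
        segments = [
            (trial_start, t_cue + u_lo, b),
            (t_cue + u_lo, t_cue + u_hi, b + s_uncued),
            (t_cue + u_hi, t_cue + c_lo, b),
            (t_cue + c_lo, t_cue + c_hi, b * cfg.cue_gain + s_cued),
            (t_cue + c_hi, trial_end, b),
        ]
        reach_times: list[float] = []
        for lo, hi, rate in segments:
            if rate < 0.0:
                floor_events += 1
                rate = 0.0
            reach_times.extend(_draw_poisson_times(rng, rate, lo, hi))
        reach_times.sort()

        # outcomes --------------------------------------------------------
        pellet_available = pellet
        reaches: list[Reach] = []
        for t_arm in reach_times:
            in_pellet_window = (
                t_cue - cfg.pellet_lead_s <= t_arm < t_cue + cfg.pellet_retract_s
            )
            if pellet_available and in_pellet_window:
                if rng.uniform() < cfg.success_prob_given_pellet:
                    outcome = ReachOutcome.success
                    pellet_available = False
                elif rng.uniform() < cfg.drop_prob_given_fail:
                    outcome = ReachOutcome.drop
                    pellet_available = False
                else:
                    outcome = ReachOutcome.missed_pellet
            else:
                outcome = ReachOutcome.pellet_missing
            reaches.append(Reach(t_arm=t_arm, outcome=outcome))

        distractors = _draw_poisson_times(
            rng, cfg.distractor_rate, trial_start, trial_end)

        trial = Trial(
            trial_start=trial_start, trial_end=trial_end, t_cue=t_cue,
            cue_present=True, pellet_presented=pellet, catch=catch,
            chewing_at_start=chewing, inhibition_window=inhibition,
            distractor_times=list(distractors), reaches=reaches,
        )
        trials.append(trial)
        tclass = classify_trial(trial, spec)
        truth.trial_classes.append(tclass)

        # reinforcement update -------------------------------------------
        applied = False
        if tclass in (TrialClass.cued_success, TrialClass.uncued_success):
            t_arm = next(r.t_arm for r in reaches if r.is_success)
            gated = False
            if cfg.update_gate == "reach_overlap" and inhibition is not None:
                a, bnd = inhibition
                gated = (a <= t_arm + cfg.gate_pad_s) and (t_arm <= bnd)
            if not gated:
                applied = True
        s_cued *= decay
        s_uncued *= decay
        if applied:
            if tclass is TrialClass.cued_success:
                s_cued += cfg.reinforcement_delta
            else:
                s_uncued += cfg.reinforcement_delta
        truth.update_applied.append(applied)
        t_cue += inter_cue

    truth.cued_state = cued_states
    truth.uncued_state = uncued_states
    truth.rate_floor_events = floor_events
    session = BehavioralSession(trials=trials, session_id=f"synth-{seed}")
    return session, truth


# ----------------------------------------------------------------------
# spikes


def default_group_kernels(
        success_amp: float = 2.0,
        failure_amp: float = 1.5,
) -> dict[str, dict[str, np.ndarray]]:
    """Planted event kernels (Hz) for the two SPN groups on the GLM lag grid.

    Group 1 mimics success-preferring units: a transient elevation after
    success and cued success that decays over the post-outcome period.
    Group 2 mimics failure-preferring units: slowly rising, sustained
    elevation after failures and mild suppression after the cue.
    """
    lags = GLM_LAGS
    post = np.clip(lags, 0.0, None)
    active = (lags >= 0.0).astype(float)

    g1_success = success_amp * np.exp(-post / 1.2) * active
    g1_cued_extra = 0.5 * success_amp * np.exp(-post / 1.0) * active
    g2_failure = failure_amp * (1.0 - np.exp(-post / 1.0)) * active
    g2_cue = -0.3 * np.exp(-post / 0.5) * active
    zeros = np.zeros_like(lags)

    g1 = {name: zeros.copy() for name in EVENT_NAMES}
    g1["success"] = g1_success
    g1["cued_success"] = g1_cued_extra
    g2 = {name: zeros.copy() for name in EVENT_NAMES}
    g2["failure_drop"] = g2_failure
    g2["failure_pellet_missing"] = g2_failure.copy()
    g2["cue"] = g2_cue
    return {"group1": g1, "group2": g2}


@dataclass(frozen=True)
class SpikeGenConfig:
    """Synthetic SPN population: group mixture, kernels, baselines."""

    n_units: int = 40
    group_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    kernels: dict[str, dict[str, np.ndarray]] | None = None
    # kept low so group units' realized rates stay under the 4-Hz SPN bound
    # even with sustained positive kernels active much of the session
    baseline_range_hz: tuple[float, float] = (0.5, 2.0)
    kernel_jitter: float = 0.0   # sd of multiplicative per-unit gain spread

    def validate(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if abs(sum(self.group_fractions) - 1.0) > 1e-9:
            raise ValueError("group_fractions must sum to 1")
        if self.baseline_range_hz[0] < 0:
            raise ValueError("negative baseline rate")


def _rate_on_bins(n_bins: int, baseline: float,
                  indicators: dict[str, np.ndarray],
                  kernels: dict[str, np.ndarray]) -> np.ndarray:
    """Linear-link rate per 0.1-s bin: baseline + sum of event kernels."""
    rate = np.full(n_bins, baseline, dtype=float)
    n_lags = GLM_LAGS.size
    lag_bins = np.round(GLM_LAGS / GLM_BIN_S).astype(int)
    for name, kern in kernels.items():
        ind = indicators.get(name)
        if ind is None or not np.any(ind) or not np.any(kern):
            continue
        idx = np.flatnonzero(ind)
        for j, shift in enumerate(lag_bins):
            if kern[j] == 0.0:
                continue
            tgt = idx + shift
            ok = (tgt >= 0) & (tgt < n_bins)
            rate[tgt[ok]] += kern[j]
    return rate


def _event_indicators(events: dict[str, np.ndarray],
                      n_bins: int) -> dict[str, np.ndarray]:
    out = {}
    for name, times in events.items():
        ind = np.zeros(n_bins, dtype=bool)
        bins = np.floor(np.asarray(times) / GLM_BIN_S).astype(int)
        bins = bins[(bins >= 0) & (bins < n_bins)]
        ind[bins] = True
        out[name] = ind
    return out


def generate_population_spikes(
        session: BehavioralSession,
        cfg: SpikeGenConfig = SpikeGenConfig(),
        seed: int = 0,
) -> tuple[list, PlantedTruth]:
    """Draw spike trains for a population of units from a linear-link model.

    Each unit's rate in 0.1-s bins is its baseline plus its group's event
    kernels convolved with the session's behavioral event indicators,
    floored at zero.  Spike counts are Poisson per bin with times uniform
    within the bin.  Waveform widths and mean rates are emitted so the
    unit classifier sees SPN-like group units among TAN/FS distractors.
    """
    from .units import UnitRecording

    cfg.validate()
    rng = np.random.default_rng(seed)
    kernels = cfg.kernels if cfg.kernels is not None else default_group_kernels()
    duration = session.duration
    n_bins = int(math.ceil(duration / GLM_BIN_S))
    indicators = _event_indicators(events_from_session(session), n_bins)

    n1 = int(round(cfg.group_fractions[0] * cfg.n_units))
    n2 = int(round(cfg.group_fractions[1] * cfg.n_units))
    groups = ["group1"] * n1 + ["group2"] * n2
    groups += ["other"] * (cfg.n_units - len(groups))

    truth = PlantedTruth(seed=seed)
    units = []
    floor_events = 0
    for i, group in enumerate(groups):
        baseline = rng.uniform(*cfg.baseline_range_hz)
        if group in kernels:
            gain = 1.0 + cfg.kernel_jitter * rng.standard_normal() \
                if cfg.kernel_jitter > 0 else 1.0
            unit_kern = {k: gain * v for k, v in kernels[group].items()}
            width = float(np.clip(0.32 + 0.04 * rng.standard_normal(),
                                  0.23, 0.5))
        else:
            unit_kern = {k: np.zeros_like(GLM_LAGS) for k in EVENT_NAMES}
            if rng.uniform() < 0.5:   # TAN-like
                baseline = rng.uniform(4.5, 8.0)
                width = float(rng.uniform(0.25, 0.45))
            else:                     # FS-like
                baseline = rng.uniform(2.0, 8.0)
                width = float(rng.uniform(0.10, 0.20))
        rate = _rate_on_bins(n_bins, baseline, indicators, unit_kern)
        neg = rate < 0.0
        floor_events += int(neg.sum())
        rate[neg] = 0.0
        counts = rng.poisson(rate * GLM_BIN_S)
        spikes = []
        for b in np.flatnonzero(counts):
            spikes.extend(
                (b + rng.uniform(size=counts[b])) * GLM_BIN_S)
        st = np.sort(np.asarray(spikes))
        units.append(UnitRecording(
            unit_id=f"u{i:03d}", spike_times=st, width_hm=width,
            recording_duration=duration))
        truth.unit_groups.append(group)
        truth.unit_kernels[f"u{i:03d}"] = unit_kern
    truth.rate_floor_events = floor_events
    return units, truth


# ----------------------------------------------------------------------
# photometry


@dataclass(frozen=True)
class PhotometryGenConfig:
    """Amplitude-modulated photometry carrier with outcome transients."""

    fs_hz: float = 2000.0
    carrier_hz: float = 167.0
    base_amplitude: float = 1.0
    success_amp: float = 0.5       # envelope units, positive peak
    failure_amp: float = -0.5      # negative dip
    success_latency_s: float = 0.83
    failure_latency_s: float = 1.6
    success_width_s: float = 0.25  # Gaussian sd
    failure_width_s: float = 0.35
    noise_sd: float = 0.25
    pad_s: float = 5.0

    def validate(self) -> None:
        if self.fs_hz <= 2 * self.carrier_hz:
            raise ValueError("sample rate must exceed twice the carrier")
        for name in ("success_width_s", "failure_width_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def generate_photometry(
        session: BehavioralSession,
        cfg: PhotometryGenConfig = PhotometryGenConfig(),
        seed: int = 0,
):
    """Simulate the raw modulated photometry voltage for a session.

    The 167-Hz carrier's envelope is a constant baseline plus a Gaussian
    bump 0.83 s after each successful reach and a Gaussian dip 1.6 s
    after each failed reach, with additive white noise on the samples.
    """
    from .photometry import PhotometryTrace

    cfg.validate()
    rng = np.random.default_rng(seed)
    duration = session.duration + cfg.pad_s
    n = int(round(duration * cfg.fs_hz))
    t = np.arange(n) / cfg.fs_hz

    envelope = np.full(n, cfg.base_amplitude)
    truth = PlantedTruth(seed=seed)
    for trial in session.trials:
        for reach in trial.reaches:
            if reach.is_success:
                center = reach.t_arm + cfg.success_latency_s
                amp, width = cfg.success_amp, cfg.success_width_s
            else:
                center = reach.t_arm + cfg.failure_latency_s
                amp, width = cfg.failure_amp, cfg.failure_width_s
            truth.transients.append((center, amp))
            lo = max(0, int((center - 5 * width) * cfg.fs_hz))
            hi = min(n, int((center + 5 * width) * cfg.fs_hz))
            if hi > lo:
                envelope[lo:hi] += amp * np.exp(
                    -0.5 * ((t[lo:hi] - center) / width) ** 2)

    samples = envelope * np.sin(2 * np.pi * cfg.carrier_hz * t)
    samples += cfg.noise_sd * rng.standard_normal(n)
    trace = PhotometryTrace(samples=samples, fs_hz=cfg.fs_hz,
                            carrier_hz=cfg.carrier_hz)
    return trace, truth
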