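"""Single-unit typing, PSTHs, physiology trial typing and data splits.

Units recorded extracellularly in the striatum are classified from two
waveform/rate features into putative cell types; striatal projection
neurons (SPNs) -- broad waveform, low rate -- are the population carried
forward into the kernel-GLM and decoding analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .behavior import Reach

__all__ = [
    "UnitRecording",
    "SplitSpec",
    "classify_unit",
    "psth",
    "physiology_trial_type",
    "train_test_split",
]


def classify_unit(width_hm: float, mean_rate: float) -> str:
    """Classify a unit from waveform width at half-maximum (ms) and rate (Hz).

    SPN: width >= 0.22 ms and rate < 4 Hz.  Tonically active neuron (TAN):
    width >= 0.22 ms and rate >= 4 Hz.  Fast-spiking (FS): width < 0.22 ms
    and rate >= 1.25 Hz.  Otherwise low-firing thin.
    """
    if not (math.isfinite(width_hm) and math.isfinite(mean_rate)):
        raise ValueError("width and rate must be finite")
    if width_hm < 0 or mean_rate < 0:
        raise ValueError("width and rate must be non-negative")
    if width_hm >= 0.22:
        return "SPN" if mean_rate < 4.0 else "TAN"
    return "FS" if mean_rate >= 1.25 else "low_firing_thin"


@dataclass
class UnitRecording:
    """Sorted spike times plus the waveform summaries used for typing."""

    unit_id: str
    spike_times: np.ndarray
    width_hm: float
    recording_duration: float
    mean_rate: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        if st.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if np.any(np.diff(st) <= 0):
            warnings.warn(f"unit {self.unit_id}: sorting spike times",
                          stacklevel=2)
            st = np.unique(st)
        self.spike_times = st
        if self.recording_duration <= 0:
            raise ValueError("recording_duration must be positive")
        if self.mean_rate is None:
            self.mean_rate = st.size / self.recording_duration

    @property
    def unit_class(self) -> str:
        return classify_unit(self.width_hm, self.mean_rate)


@dataclass(frozen=True)
class PSTH:
    bin_centers: np.ndarray
    rates: np.ndarray  # Hz, averaged over events
    n_events: int
    binwidth: float


def psth(unit: UnitRecording, event_times, window: tuple[float, float],
         binwidth: float) -> PSTH:
    """Peri-event time histogram: mean rate per bin across events (Hz)."""
    events = np.asarray(event_times, dtype=float)
    if events.size == 0:
        raise ValueError("psth requires at least one event")
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    lo, hi = window
    n_bins = int(round((hi - lo) / binwidth))
    edges = lo + binwidth * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for t0 in events:
        rel = unit.spike_times - t0
        counts += np.histogram(rel, bins=edges)[0]
    rates = counts / (events.size * binwidth)
    centers = edges[:-1] + binwidth / 2
    return PSTH(centers, rates, int(events.size), float(binwidth))


def physiology_trial_type(reach: Reach, t_cue: float) -> str:
    """Type a reach relative to cue onset for physiology analyses.

    Cued: within [0, 3) s of cue onset.  Ambiguous (excluded): [3, 5) s.
    Uncued: [5, 16] s, a span that also captures reaching before the next
    trial's cue.  Reaches outside these windows (including before this
    cue) are unlabeled; pass the previous trial's cue time to type
    pre-cue reaching.
    """
    dt = reach.t_arm - t_cue
    if 0.0 <= dt < 3.0:
        return "cued"
    if 3.0 <= dt < 5.0:
        return "ambiguous"
    if 5.0 <= dt <= 16.0:
        return "uncued"
    return "unlabeled"


@dataclass(frozen=True)
class SplitSpec:
    """Per-condition train/test trial assignment shared across units."""

    train: dict[str, tuple[int, ...]]
    test: dict[str, tuple[int, ...]]
    seed: int


def train_test_split(trial_ids_per_condition: dict[str, list[int]],
                     seed: int) -> SplitSpec:
    """Stratified 50/50 split of trial ids by condition.

    The same assignment applies to every simultaneously recorded unit, so
    group labels learned on the train half can never leak test-trial
    information.  Odd counts put the extra trial in the test half;
    conditions with fewer than two trials are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    train: dict[str, tuple[int, ...]] = {}
    test: dict[str, tuple[int, ...]] = {}
    for cond in sorted(trial_ids_per_condition):
        ids = list(trial_ids_per_condition[cond])
        if len(ids) < 2:
            warnings.warn(f"condition {cond!r} has <2 trials; excluded",
                          stacklevel=2)
            continue
        perm = rng.permutation(len(ids))
        k = len(ids) // 2
        train[cond] = tuple(sorted(ids[i] for i in perm[:k]))
        test[cond] = tuple(sorted(ids[i] for i in perm[k:]))
    return SplitSpec(train=train, test=test, seed=seed)
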