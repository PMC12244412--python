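"""Session container and behavioral event streams.

The nine behavioral event channels used throughout the physiology
analyses (design-matrix GLM, spike simulation) are derived here from a
session's trials.  Outcome events are timestamped at the moment the arm
is outstretched; "cued" outcome channels fire in addition to the base
outcome channel when the reach falls within 3 s of cue onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import ReachOutcome, Trial

# Event-major order is load-bearing: design-matrix columns follow it.
EVENT_NAMES: tuple[str, ...] = (
    "cue",
    "distractor",
    "reach",
    "success",
    "failure_drop",
    "failure_pellet_missing",
    "cued_success",
    "cued_failure_drop",
    "cued_failure_pellet_missing",
)

CUED_REACH_MAX_S = 3.0  # physiology definition of a cued reach


@dataclass
class BehavioralSession:
    """An ordered list of trials plus session-level metadata."""

    trials: list[Trial]
    session_id: str = "session"
    mouse_id: str = "mouse"

    @property
    def duration(self) -> float:
        return self.trials[-1].trial_end if self.trials else 0.0

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _outcome_channel(outcome: ReachOutcome) -> str:
    # drop and missed_pellet are failures with the pellet present; a reach
    # while no pellet is available is the pellet-missing failure.
    if outcome is ReachOutcome.pellet_missing:
        return "failure_pellet_missing"
    return "failure_drop"


def events_from_session(session: BehavioralSession) -> dict[str, np.ndarray]:
    """Extract the nine behavioral event streams (times in seconds).

    Returns a dict keyed by :data:`EVENT_NAMES`, each value a sorted float
    array.  Every reach contributes a ``reach`` event and exactly one
    outcome event; cued outcomes additionally populate the matching
    ``cued_*`` channel.
    """
    streams: dict[str, list[float]] = {name: [] for name in EVENT_NAMES}
    for trial in session.trials:
        if trial.cue_present and trial.t_cue is not None:
            streams["cue"].append(trial.t_cue)
        streams["distractor"].extend(trial.distractor_times)
        for reach in trial.reaches:
            streams["reach"].append(reach.t_arm)
            cued = (
                trial.cue_present
                and trial.t_cue is not None
                and 0.0 <= reach.t_arm - trial.t_cue < CUED_REACH_MAX_S
            )
            if reach.outcome is ReachOutcome.success:
                streams["success"].append(reach.t_arm)
                if cued:
                    streams["cued_success"].append(reach.t_arm)
            else:
                chan = _outcome_channel(reach.outcome)
                streams[chan].append(reach.t_arm)
                if cued:
                    streams["cued_" + chan].append(reach.t_arm)
    return {k: np.sort(np.asarray(v, dtype=float)) for k, v in streams.items()}


def outcome_event_times(
        session: BehavioralSession) -> dict[str, np.ndarray]:
    """Per-condition arm-outstretched times for tensor/decoding analyses.

    Conditions follow the trial classes: ``cued_success``, ``cued_failure``,
    ``uncued_success``, ``uncued_failure``, assigned per reach using the
    physiology timing convention (cued: within 3 s of the cue; uncued:
    5-16 s after the cue; 3-5 s is ambiguous and dropped).
    """
    from .units import physiology_trial_type

    out: dict[str, list[float]] = {
        "cued_success": [], "cued_failure": [],
        "uncued_success": [], "uncued_failure": [],
    }
    for trial in session.trials:
        if not trial.cue_present or trial.t_cue is None:
            continue
        for reach in trial.reaches:
            typ = physiology_trial_type(reach, trial.t_cue)
            if typ not in ("cued", "uncued"):
                continue
            key = f"{typ}_{'success' if reach.is_success else 'failure'}"
            out[key].append(reach.t_arm)
    return {k: np.asarray(v, dtype=float) for k, v in out.items()}
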