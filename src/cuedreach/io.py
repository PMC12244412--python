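"""File formats: session event tables, spike tables, unit metadata.

Sessions round-trip through two dialects: a flat CSV event table (one
row per event: trial_id, event_type, time_s, outcome, flags) and a
hierarchical JSON document.  Times are serialized as seconds with six
decimal places; trial ids are 0-based.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import Reach, ReachOutcome, Trial
from .session import BehavioralSession

__all__ = [
    "write_session_csv",
    "read_session_csv",
    "write_session_json",
    "read_session_json",
    "write_units",
    "read_units",
]

_EVENT_COLUMNS = ["trial_id", "event_type", "time_s", "outcome", "flags"]


def _fmt(t: float) -> float:
    return float(f"{t:.6f}")


def _session_rows(session: BehavioralSession) -> list[dict]:
    rows = []
    for tid, trial in enumerate(session.trials):
        flags = []
        if trial.catch:
            flags.append("catch")
        if trial.chewing_at_start:
            flags.append("chewing")
        if not trial.cue_present:
            flags.append("no_cue")
        rows.append({"trial_id": tid, "event_type": "trial_start",
                     "time_s": _fmt(trial.trial_start), "outcome": "",
                     "flags": "|".join(flags)})
        if trial.cue_present and trial.t_cue is not None:
            rows.append({"trial_id": tid, "event_type": "cue",
                         "time_s": _fmt(trial.t_cue), "outcome": "",
                         "flags": ""})
        if trial.pellet_presented:
            rows.append({"trial_id": tid, "event_type": "pellet",
                         "time_s": _fmt(trial.t_cue if trial.t_cue is not None
                                        else trial.trial_start),
                         "outcome": "", "flags": ""})
        for t in trial.distractor_times:
            rows.append({"trial_id": tid, "event_type": "distractor",
                         "time_s": _fmt(t), "outcome": "", "flags": ""})
        if trial.inhibition_window is not None:
            a, b = trial.inhibition_window
            rows.append({"trial_id": tid, "event_type": "inhibition_on",
                         "time_s": _fmt(a), "outcome": "", "flags": ""})
            rows.append({"trial_id": tid, "event_type": "inhibition_off",
                         "time_s": _fmt(b), "outcome": "", "flags": ""})
        for r in trial.reaches:
            rows.append({"trial_id": tid, "event_type": "reach",
                         "time_s": _fmt(r.t_arm),
                         "outcome": r.outcome.value, "flags": ""})
        rows.append({"trial_id": tid, "event_type": "trial_end",
                     "time_s": _fmt(trial.trial_end), "outcome": "",
                     "flags": ""})
    return rows


def write_session_csv(session: BehavioralSession, path) -> None:
    df = pd.DataFrame(_session_rows(session), columns=_EVENT_COLUMNS)
    df.to_csv(path, index=False)


def read_session_csv(path) -> BehavioralSession:
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"outcome": str, "flags": str})
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    trials = []
    for tid, g in df.groupby("trial_id", sort=True):
        by_type: dict[str, list] = {}
        for i, row in g.iterrows():
            et = row["event_type"]
            if et not in ("trial_start", "trial_end", "cue", "pellet",
                          "distractor", "inhibition_on", "inhibition_off",
                          "reach"):
                raise ValueError(f"row {i}: unknown event_type {et!r}")
            by_type.setdefault(et, []).append(row)
        try:
            start = float(by_type["trial_start"][0]["time_s"])
            end = float(by_type["trial_end"][0]["time_s"])
        except KeyError as exc:
            raise ValueError(
                f"trial {tid}: missing {exc.args[0]} event") from exc
        flags = set(str(by_type["trial_start"][0]["flags"]).split("|"))
        reaches = []
        for row in by_type.get("reach", ()):
            out = row["outcome"]
            try:
                outcome = ReachOutcome(out)
            except ValueError:
                raise ValueError(
                    f"row {row.name}: unknown outcome {out!r}") from None
            reaches.append(Reach(t_arm=float(row["time_s"]), outcome=outcome))
        times = [r.t_arm for r in reaches]
        if times != sorted(times):
            raise ValueError(f"trial {tid}: unordered reach times")
        inhibition = None
        if "inhibition_on" in by_type:
            inhibition = (float(by_type["inhibition_on"][0]["time_s"]),
                          float(by_type["inhibition_off"][0]["time_s"]))
        cue_rows = by_type.get("cue", ())
        trials.append(Trial(
            trial_start=start, trial_end=end,
            t_cue=float(cue_rows[0]["time_s"]) if cue_rows else None,
            cue_present=bool(cue_rows),
            pellet_presented="pellet" in by_type,
            catch="catch" in flags,
            chewing_at_start="chewing" in flags,
            inhibition_window=inhibition,
            distractor_times=[float(r["time_s"])
                              for r in by_type.get("distractor", ())],
            reaches=reaches,
        ))
    return BehavioralSession(trials=trials,
                             session_id=Path(path).stem)


def write_session_json(session: BehavioralSession, path) -> None:
    doc = {
        "session_id": session.session_id,
        "mouse_id": session.mouse_id,
        "trials": [
            {
                "trial_start": _fmt(t.trial_start),
                "trial_end": _fmt(t.trial_end),
                "t_cue": None if t.t_cue is None else _fmt(t.t_cue),
                "cue_present": t.cue_present,
                "pellet_presented": t.pellet_presented,
                "catch": t.catch,
                "chewing_at_start": t.chewing_at_start,
                "inhibition_window": (None if t.inhibition_window is None
                                      else [_fmt(t.inhibition_window[0]),
                                            _fmt(t.inhibition_window[1])]),
                "distractor_times": [_fmt(x) for x in t.distractor_times],
                "reaches": [{"t_arm": _fmt(r.t_arm),
                             "outcome": r.outcome.value}
                            for r in t.reaches],
            }
            for t in session.trials
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_session_json(path) -> BehavioralSession:
    doc = json.loads(Path(path).read_text())
    trials = []
    for i, td in enumerate(doc["trials"]):
        try:
            trials.append(Trial(
                trial_start=td["trial_start"], trial_end=td["trial_end"],
                t_cue=td.get("t_cue"), cue_present=td["cue_present"],
                pellet_presented=td["pellet_presented"],
                catch=td.get("catch", False),
                chewing_at_start=td.get("chewing_at_start", False),
                inhibition_window=(tuple(td["inhibition_window"])
                                   if td.get("inhibition_window") else None),
                distractor_times=list(td.get("distractor_times", [])),
                reaches=[Reach(t_arm=r["t_arm"],
                               outcome=ReachOutcome(r["outcome"]))
                         for r in td.get("reaches", [])],
            ))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"trial record {i}: {exc}") from exc
    return BehavioralSession(trials=trials,
                             session_id=doc.get("session_id", Path(path).stem),
                             mouse_id=doc.get("mouse_id", "mouse"))


def write_units(units, spikes_path, metadata_path) -> None:
    """Spike table (unit_id, spike_time_s) + unit metadata CSV."""
    spike_rows = []
    meta_rows = []
    for u in units:
        spike_rows.extend({"unit_id": u.unit_id, "spike_time_s": _fmt(t)}
                          for t in u.spike_times)
        meta_rows.append({"unit_id": u.unit_id,
                          "width_ms": round(u.width_hm, 6),
                          "mean_rate_hz": round(u.mean_rate, 6),
                          "recording_duration_s": _fmt(u.recording_duration),
                          "unit_class": u.unit_class})
    pd.DataFrame(spike_rows, columns=["unit_id", "spike_time_s"]).to_csv(
        spikes_path, index=False)
    pd.DataFrame(meta_rows).to_csv(metadata_path, index=False)


def read_units(spikes_path, metadata_path):
    """Load units; re-derives the class and warns on any mismatch."""
    from .units import UnitRecording

    spikes = pd.read_csv(spikes_path)
    meta = pd.read_csv(metadata_path)
    if meta.empty and spikes.empty:
        raise ValueError("no unit data found")
    grouped = {uid: g["spike_time_s"].to_numpy()
               for uid, g in spikes.groupby("unit_id")}
    units = []
    for _, row in meta.iterrows():
        st = np.sort(grouped.get(row["unit_id"], np.empty(0)))
        u = UnitRecording(unit_id=str(row["unit_id"]), spike_times=st,
                          width_hm=float(row["width_ms"]),
                          recording_duration=float(
                              row["recording_duration_s"]),
                          mean_rate=float(row["mean_rate_hz"]))
        if "unit_class" in meta.columns and u.unit_class != row["unit_class"]:
            warnings.warn(
                f"unit {u.unit_id}: stored class {row['unit_class']!r} "
                f"!= recomputed {u.unit_class!r}", stacklevel=2)
        units.append(u)
    return units
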