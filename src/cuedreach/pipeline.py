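"""End-to-end orchestration of a synthetic run with a reproducibility manifest.

``run_pipeline`` executes the requested stages in dependency order --
simulate a session, compute behavioral statistics, the trial-to-trial
reinforcement shift, simulate and analyse spikes (GLM -> kernels ->
grouping -> tensor regression -> decoding), and photometry -- writing
tidy CSV/JSON artifacts plus a manifest recording the config, per-stage
seeds, output digests and timings, sufficient to reproduce the run
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .behavior import WindowSpec, dprime, session_learned
from .reinforcement import conditioned_shift, extract_triplets
from .session import BehavioralSession, outcome_event_times
from .synth import (BehaviorGenConfig, PhotometryGenConfig, SpikeGenConfig,
                    generate_photometry, generate_population_spikes,
                    generate_session)

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

STAGE_ORDER = ("session", "behavior", "reinforcement", "spikes", "glm",
               "photometry")
STAGE_DEPS = {
    "behavior": ("session",),
    "reinforcement": ("session",),
    "spikes": ("session",),
    "glm": ("spikes",),
    "photometry": ("session",),
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "pipeline_out",
    "stages": ["session", "behavior", "reinforcement", "spikes",
               "photometry"],
    "session": {"n_trials": 200, "cue_gain": 6.0,
                "reinforcement_delta": 0.3},
    "spikes": {"n_units": 20},
    "photometry": {},
    "reinforcement": {"condition": "cued_success", "n_boot": 100},
}

_KNOWN_KEYS = set(DEFAULT_CONFIG) | {"glm"}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _validate(config: dict) -> dict:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **config}
    bad = [s for s in cfg["stages"] if s not in STAGE_ORDER]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    return cfg


def run_pipeline(config: dict | str | Path, dry_run: bool = False) -> dict:
    """Run the configured stages; returns the manifest dict.

    ``config`` is a dict or a path to a YAML file.  Unknown keys are
    rejected.  Stages whose dependencies are not scheduled are skipped
    with a notice in the manifest.  ``dry_run`` validates the config and
    reports the stage plan without computing.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    cfg = _validate(dict(config))
    requested = [s for s in STAGE_ORDER if s in cfg["stages"]]
    planned, skipped = [], []
    for s in requested:
        if all(d in planned for d in STAGE_DEPS.get(s, ())):
            planned.append(s)
        else:
            skipped.append((s, f"missing dependency "
                               f"{[d for d in STAGE_DEPS[s] if d not in planned]}"))
    manifest: dict = {"config": cfg, "stages_planned": planned,
                      "stages_skipped": skipped, "seeds": {},
                      "outputs": {}, "timings_s": {},
                      "package_version": _version()}
    if dry_run:
        return manifest

    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(cfg["seed"])
    stage_seeds = {s: int(master.integers(0, 2 ** 31 - 1))
                   for s in STAGE_ORDER}
    spec = WindowSpec()
    session = units = None

    for stage in planned:
        t0 = time.perf_counter()
        seed = stage_seeds[stage]
        manifest["seeds"][stage] = seed
        if stage == "session":
            gen_cfg = BehaviorGenConfig(**cfg["session"])
            session, truth = generate_session(gen_cfg, seed=seed)
            cio.write_session_csv(session, out / "session.csv")
            manifest["outputs"]["session"] = ["session.csv"]
        elif stage == "behavior":
            d = dprime(session.trials, spec)
            learned = session_learned(session.trials, spec)
            pd.DataFrame([{
                "dprime": d.dprime, "hit_rate": d.hit_rate,
                "n_trials": d.n_trials,
                "delta_d1": learned.delta_d1, "delta_d2": learned.delta_d2,
                "delta_d3": learned.delta_d3, "learned": learned.learned,
            }]).to_csv(out / "behavior.csv", index=False)
            manifest["outputs"]["behavior"] = ["behavior.csv"]
        elif stage == "reinforcement":
            rcfg = cfg["reinforcement"]
            tset = extract_triplets(session.trials, rcfg["condition"],
                                    spec=spec)
            if len(tset):
                est = conditioned_shift(tset, n_boot=rcfg["n_boot"],
                                        seed=seed)
                est.to_frame(rcfg["condition"]).to_csv(
                    out / "shift_draws.csv", index=False)
                manifest["outputs"]["reinforcement"] = ["shift_draws.csv"]
            else:
                manifest["outputs"]["reinforcement"] = []
        elif stage == "spikes":
            sp_cfg = SpikeGenConfig(**cfg["spikes"])
            units, _ = generate_population_spikes(session, sp_cfg, seed=seed)
            cio.write_units(units, out / "spikes.csv", out / "units.csv")
            manifest["outputs"]["spikes"] = ["spikes.csv", "units.csv"]
        elif stage == "glm":
            from .glm import EventDesign, bin_spikes, build_design, fit_glm
            from .glm import extract_pop_kernels
            from .session import events_from_session

            design = EventDesign()
            X = build_design(events_from_session(session), session.duration,
                             design)
            rows = []
            for u in units:
                fit = fit_glm(X, bin_spikes(u.spike_times, session.duration),
                              design=design)
                for ev, kern in extract_pop_kernels(fit).items():
                    for lag, c in zip(np.arange(kern.size) * 0.1, kern):
                        rows.append({"unit_id": u.unit_id, "event": ev,
                                     "lag_s": round(float(lag), 4),
                                     "coefficient": c})
            pd.DataFrame(rows).to_csv(out / "kernels.csv", index=False)
            manifest["outputs"]["glm"] = ["kernels.csv"]
        elif stage == "photometry":
            from .photometry import align_transients, demodulate, rolling_zscore

            ph_cfg = PhotometryGenConfig(**cfg["photometry"])
            trace, _ = generate_photometry(session, ph_cfg, seed=seed)
            power = demodulate(trace)
            z = rolling_zscore(power)
            pd.DataFrame({"time_s": z.t, "z": z.power}).to_csv(
                out / "photometry_z.csv", index=False)
            manifest["outputs"]["photometry"] = ["photometry_z.csv"]
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

    manifest["digests"] = {
        name: _digest(out / name)
        for files in manifest["outputs"].values() for name in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return manifest


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("cuedreach")
    except Exception:
        return "unknown"
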