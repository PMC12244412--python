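"""Decode trial condition from group-1 vs group-2 population rates.

The decoding scheme is deliberately simple: for each of the four
behavioral conditions, average the firing rates of the
success-preferring units (group 1) and of the failure-preferring units
(group 2) over the 1-5 s window after the outstretched arm (the first
second is excluded so the cue offset precedes the analysed window).
Bootstrapped (group-2 mean, group-1 mean) points, one per condition per
iteration, are classified three ways -- cued success vs uncued success
vs failure (cued and uncued failures combined) -- with a linear
discriminant; shuffle controls destroy either the group identities or
the condition labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DecodeConfig",
    "pop_rates",
    "bootstrap_scatter",
    "lda_accuracy",
    "shuffle_controls",
    "decode_accuracy",
]

CONDITIONS = ("cued_success", "cued_failure", "uncued_success",
              "uncued_failure")


def three_way_label(condition: str) -> str:
    return "failure" if "failure" in condition else condition


@dataclass(frozen=True)
class DecodeConfig:
    window: tuple[float, float] = (1.0, 5.0)  # s after t_arm
    n_boot: int = 100
    mode: str = "trial_averaged"              # or "single_trial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.mode not in ("trial_averaged", "single_trial"):
            raise ValueError("mode must be trial_averaged or single_trial")


def pop_rates(units, event_times_per_class: dict[str, np.ndarray],
              window: tuple[float, float] = (1.0, 5.0),
              ) -> dict[str, np.ndarray]:
    """Per-unit firing rates (Hz) in the post-outcome window per condition.

    Returns condition -> array (n_units, n_trials) of single-trial rates;
    trial-averaged rates are the row means.  Conditions without events
    are dropped with a warning.  Group labels must come from the training
    split; only test-split event times should be passed here.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive duration")
    out = {}
    for cond, times in event_times_per_class.items():
        times = np.asarray(times, float)
        if times.size == 0:
            warnings.warn(f"condition {cond!r} has no test trials; excluded",
                          stacklevel=2)
            continue
        rates = np.empty((len(units), times.size))
        for i, u in enumerate(units):
            st = u.spike_times
            for j, t0 in enumerate(times):
                n = np.searchsorted(st, t0 + hi) - np.searchsorted(st, t0 + lo)
                rates[i, j] = n / (hi - lo)
        out[cond] = rates
    return out


def bootstrap_scatter(rates_g1: dict[str, np.ndarray],
                      rates_g2: dict[str, np.ndarray],
                      n: int,
                      cfg: DecodeConfig = DecodeConfig()) -> pd.DataFrame:
    """Bootstrap (group-2 mean, group-1 mean) points per condition.

    Each iteration resamples ``n`` units with replacement from each
    group (independently); in single-trial mode one trial is also drawn
    per sampled unit per condition.  Returns a tidy frame with columns
    iteration, condition, g2_rate_hz (x), g1_rate_hz (y).
    """
    if not rates_g1 or not rates_g2:
        raise ValueError("both groups must be non-empty")
    conds = [c for c in CONDITIONS if c in rates_g1 and c in rates_g2]
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for it in range(cfg.n_boot):
        for cond in conds:
            point = []
            for rates in (rates_g2[cond], rates_g1[cond]):
                n_units, n_trials = rates.shape
                pick = rng.integers(0, n_units, size=n)
                if cfg.mode == "single_trial":
                    tr = rng.integers(0, n_trials, size=n)
                    vals = rates[pick, tr]
                else:
                    vals = rates[pick].mean(axis=1)
                point.append(vals.mean())
            rows.append({"iteration": it, "condition": cond,
                         "g2_rate_hz": point[0], "g1_rate_hz": point[1]})
    return pd.DataFrame(rows)


def lda_accuracy(points: pd.DataFrame) -> float:
    """Three-way LDA separation of the bootstrap points.

    Labels are cued success, uncued success and failure (cued and uncued
    failures combined).  The discriminant is fit and scored on the same
    points (resubstitution), so the accuracy measures the geometric
    separation of the clouds.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    labels = points["condition"].map(three_way_label).to_numpy()
    X = points[["g2_rate_hz", "g1_rate_hz"]].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    lda = LinearDiscriminantAnalysis()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lda.fit(X, labels)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; using shrinkage LDA",
                      stacklevel=2)
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(X, labels)
    return float((lda.predict(X) == labels).mean())


def shuffle_controls(rates_g1: dict[str, np.ndarray],
                     rates_g2: dict[str, np.ndarray],
                     n: int,
                     mode: str,
                     cfg: DecodeConfig = DecodeConfig()) -> tuple[
                         dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Return shuffled copies of the group rate tables.

    ``shuffle_group_identity`` pools the units of both groups and deals
    them back into groups of the original sizes at random.
    ``shuffle_condition_labels`` permutes, per unit, which condition its
    rate rows are attributed to.  Marginal rate distributions are
    untouched in both cases.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    conds = [c for c in CONDITIONS if c in rates_g1 and c in rates_g2]
    if mode == "shuffle_group_identity":
        n1 = next(iter(rates_g1.values())).shape[0]
        n2 = next(iter(rates_g2.values())).shape[0]
        perm = rng.permutation(n1 + n2)
        g1, g2 = {}, {}
        for cond in conds:
            pooled_rows = list(rates_g1[cond]) + list(rates_g2[cond])
            g1[cond] = np.array([pooled_rows[i] for i in perm[:n1]])
            g2[cond] = np.array([pooled_rows[i] for i in perm[n1:]])
        return g1, g2
    if mode == "shuffle_condition_labels":
        out = []
        for rates in (rates_g1, rates_g2):
            n_units = next(iter(rates.values())).shape[0]
            shuffled: dict[str, np.ndarray] = {c: [] for c in conds}
            for i in range(n_units):
                perm = rng.permutation(len(conds))
                for j, cond in enumerate(conds):
                    shuffled[cond].append(rates[conds[perm[j]]][i])
            # ragged trial counts across conditions: keep as object rows
            out.append({c: _stack_ragged(v) for c, v in shuffled.items()})
        return out[0], out[1]
    raise ValueError(f"unknown shuffle mode: {mode}")


def _stack_ragged(rows: list[np.ndarray]) -> np.ndarray:
    n = min(r.size for r in rows)
    return np.vstack([r[:n] for r in rows])


def decode_accuracy(rates_g1, rates_g2, n: int,
                    cfg: DecodeConfig = DecodeConfig(),
                    shuffle: str | None = None) -> float:
    """End-to-end accuracy: bootstrap scatter then three-way LDA."""
    if shuffle is not None:
        rates_g1, rates_g2 = shuffle_controls(rates_g1, rates_g2, n,
                                              shuffle, cfg)
    points = bootstrap_scatter(rates_g1, rates_g2, n, cfg)
    return lda_accuracy(points)
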