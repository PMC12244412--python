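"""Trial-to-trial reinforcement statistics via the three-trial bootstrap.

Learning shows up as a change in behavior from one trial to the next.
The estimator here considers sequences of three consecutive trials
(n-1, n, n+1), conditions on the context x outcome class of trial n
(e.g. cued success), and measures the shift of the 2-D behavior vector
(cued-window reach rate, uncued-window reach rate) from trial n-1 to
trial n+1.  Resampling triplets with replacement yields a bootstrap
cloud of shifts; conditioning on trial n+2 instead of n provides the
backwards-time control, and restricting/splitting by optogenetic
inhibition on trial n isolates the circuit dependence of the update.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .behavior import Trial, TrialClass, WindowSpec, classify_session, trial_behavior_vector

__all__ = [
    "TripletSet",
    "ShiftEstimate",
    "extract_triplets",
    "conditioned_shift",
    "shift_histogram",
    "backwards_control",
    "timing_resolved_shift",
]

ANY_REACH = "any_reach"
INTERLEAVE_LOOKAHEAD = range(2, 6)  # inhibition interleaving at n+2..n+5


@dataclass(frozen=True)
class TripletSet:
    """Indices (n-1, n, n+1) of trials whose center matches a condition."""

    triplets: tuple[tuple[int, int, int], ...]
    condition: str
    inhibition_filter: str
    behavior: np.ndarray  # (n_trials, 2): per-trial (cued, uncued) rates

    def __len__(self) -> int:
        return len(self.triplets)


@dataclass(frozen=True)
class ShiftEstimate:
    delta_cued: float
    delta_uncued: float
    draws: np.ndarray  # (n_boot, 2) bootstrap draws of (d_cued, d_uncued)
    se: tuple[float, float]
    n_triplets: int

    def to_frame(self, condition: str = "") -> pd.DataFrame:
        """Tidy frame: one row per bootstrap draw."""
        return pd.DataFrame({
            "condition": condition,
            "iteration": np.arange(len(self.draws)),
            "d_cued_hz": self.draws[:, 0],
            "d_uncued_hz": self.draws[:, 1],
        })


def _condition_matches(tclass: TrialClass, trial: Trial, condition) -> bool:
    if condition == ANY_REACH:
        return len(trial.reaches) > 0
    cond = TrialClass(condition)
    return tclass is cond


def _behavior_matrix(trials: Sequence[Trial],
                     spec: WindowSpec) -> np.ndarray:
    return np.array([trial_behavior_vector(t, spec) for t in trials])


def _interleave_ok(trials: Sequence[Trial], n: int, want_on: bool) -> bool:
    for k in INTERLEAVE_LOOKAHEAD:
        if n + k < len(trials) and trials[n + k].inhibited == want_on:
            return True
    return False


def extract_triplets(
        trials: Sequence[Trial],
        condition: TrialClass | str,
        inhibition_filter: str = "none",
        spec: WindowSpec = WindowSpec(),
        classes: Sequence[TrialClass] | None = None,
        center_offset: int = 0,
) -> TripletSet:
    """Select all (n-1, n, n+1) triplets whose trial n matches a condition.

    ``inhibition_filter``:
      * ``"none"`` -- ignore inhibition;
      * ``"control_interleaved"`` -- trial n without inhibition, but with an
        inhibition trial at position n+2..n+5 (keeps control trials
        interleaved with inhibition trials);
      * ``"inhibition_on"`` -- trial n inhibited, with an inhibition-off
        trial at n+2..n+5.

    ``center_offset`` shifts where the condition is evaluated relative to
    the measured pair: the shift is always measured n-1 -> n+1, but the
    condition applies to trial ``n + center_offset`` (the backwards-time
    control uses ``center_offset=2``).
    """
    if inhibition_filter not in ("none", "control_interleaved",
                                 "inhibition_on"):
        raise ValueError(f"unknown inhibition_filter: {inhibition_filter}")
    if classes is None:
        classes = classify_session(trials, spec)
    behavior = _behavior_matrix(trials, spec)
    cond_name = condition if isinstance(condition, str) else condition.value

    out = []
    for n in range(1, len(trials) - 1):
        m = n + center_offset
        if m >= len(trials):
            continue
        if not _condition_matches(classes[m], trials[m], cond_name):
            continue
        if inhibition_filter == "control_interleaved":
            if trials[m].inhibited or not _interleave_ok(trials, m, True):
                continue
        elif inhibition_filter == "inhibition_on":
            if not trials[m].inhibited or not _interleave_ok(trials, m, False):
                continue
        out.append((n - 1, n, n + 1))
    return TripletSet(triplets=tuple(out), condition=cond_name,
                      inhibition_filter=inhibition_filter, behavior=behavior)


def conditioned_shift(tset: TripletSet, n_boot: int = 100,
                      seed: int = 0) -> ShiftEstimate:
    """Point estimate and bootstrap cloud of the n-1 -> n+1 behavior shift.

    The point estimate is mean(behavior at n+1) - mean(behavior at n-1)
    over all triplets (no resampling).  Each bootstrap iteration resamples
    the m triplets with replacement and recomputes the same difference of
    means.
    """
    if len(tset) == 0:
        raise ValueError("no triplets matching the condition")
    prev_idx = np.array([t[0] for t in tset.triplets])
    next_idx = np.array([t[2] for t in tset.triplets])
    b_prev = tset.behavior[prev_idx]
    b_next = tset.behavior[next_idx]
    point = b_next.mean(axis=0) - b_prev.mean(axis=0)

    rng = np.random.default_rng(seed)
    m = len(tset)
    draws = np.empty((n_boot, 2))
    for i in range(n_boot):
        pick = rng.integers(0, m, size=m)
        draws[i] = b_next[pick].mean(axis=0) - b_prev[pick].mean(axis=0)
    se = draws.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(2)
    return ShiftEstimate(delta_cued=float(point[0]),
                         delta_uncued=float(point[1]),
                         draws=draws, se=(float(se[0]), float(se[1])),
                         n_triplets=m)


def shift_histogram(
        tset: TripletSet, n_boot: int = 1000, seed: int = 0,
        sigma_x: float = 0.0096, sigma_y: float = 0.024,
        bins: int = 101, pad_frac: float = 0.10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed 2-D density of bootstrap shift draws.

    x is the uncued-rate shift, y the cued-rate shift.  The raw 2-D
    histogram of ``n_boot`` bootstrap draws is filtered with an
    axis-aligned Gaussian (SD ``sigma_x`` Hz along x and ``sigma_y`` Hz
    along y) and normalized to integrate to 1.  Returns
    (density[y, x], x_edges, y_edges).
    """
    est = conditioned_shift(tset, n_boot=n_boot, seed=seed)
    x = est.draws[:, 1]
    y = est.draws[:, 0]

    def edges(v: np.ndarray, sigma: float) -> np.ndarray:
        lo, hi = float(v.min()), float(v.max())
        span = max(hi - lo, 4 * sigma, 1e-12)
        pad = pad_frac * span
        return np.linspace(lo - pad, hi + pad, bins + 1)

    x_edges = edges(x, sigma_x)
    y_edges = edges(y, sigma_y)
    hist, _, _ = np.histogram2d(y, x, bins=(y_edges, x_edges))
    dx = x_edges[1] - x_edges[0]
    dy = y_edges[1] - y_edges[0]
    density = gaussian_filter(hist, sigma=(sigma_y / dy, sigma_x / dx),
                              mode="constant")
    total = density.sum() * dx * dy
    if total > 0:
        density /= total
    return density, x_edges, y_edges


def backwards_control(
        trials: Sequence[Trial],
        condition: TrialClass | str,
        n_boot: int = 100,
        seed: int = 0,
        inhibition_filter: str = "none",
        spec: WindowSpec = WindowSpec(),
) -> ShiftEstimate:
    """Backwards-time control: condition the n-1 -> n+1 shift on trial n+2.

    A causal trial-to-trial update acts forwards in time only, so
    conditioning on the class of the *later* trial n+2 should abolish a
    planted forward effect; residual shift indicates correlational
    structure rather than reinforcement.
    """
    tset = extract_triplets(trials, condition, inhibition_filter, spec,
                            center_offset=2)
    return conditioned_shift(tset, n_boot=n_boot, seed=seed)


def timing_resolved_shift(
        trials: Sequence[Trial],
        reach_bins: Sequence[tuple[float, float]],
        spec: WindowSpec = WindowSpec(),
        require_success: bool = True,
) -> pd.DataFrame:
    """Update size vs relative timing of inhibition and reach.

    For each reach-time bin ``(start, width)`` in seconds relative to cue
    onset, triplets are selected where trial n contains a successful
    reach inside the bin, split into control (no inhibition on n) and
    inhibition-on n.  For each split the mean +/- SE across triplets of
    the cued-window rate change (n+1 minus n-1) is reported, together
    with the control-minus-inhibition difference indexed by the lag
    between the midpoint of the inhibition window and the midpoint of the
    reach bin.  Bins with no triplets on either side are reported with
    NaN (missing), not zero.
    """
    classes = classify_session(trials, spec)
    behavior = _behavior_matrix(trials, spec)

    inh_mids = [np.mean(t.inhibition_window) - t.t_cue
                for t in trials if t.inhibited and t.t_cue is not None]
    t_inh_mid = float(np.mean(inh_mids)) if inh_mids else np.nan

    def center_matches(n: int, lo: float, hi: float) -> bool:
        t = trials[n]
        if t.t_cue is None:
            return False
        for r in t.reaches:
            dt = r.t_arm - t.t_cue
            if lo <= dt < hi and (r.is_success or not require_success):
                return True
        return False

    rows = []
    for lo, width in reach_bins:
        hi = lo + width
        mid = lo + width / 2.0
        deltas = {True: [], False: []}
        for n in range(1, len(trials) - 1):
            if not center_matches(n, lo, hi):
                continue
            d_cued = behavior[n + 1, 0] - behavior[n - 1, 0]
            deltas[trials[n].inhibited].append(d_cued)

        def mean_se(vals: list[float]) -> tuple[float, float, int]:
            if not vals:
                return np.nan, np.nan, 0
            arr = np.asarray(vals)
            se = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else np.nan
            return float(arr.mean()), float(se), len(arr)

        con_m, con_se, n_con = mean_se(deltas[False])
        inh_m, inh_se, n_inh = mean_se(deltas[True])
        rows.append({
            "reach_bin_start_s": lo, "reach_bin_width_s": width,
            "reach_bin_mid_s": mid,
            "d_cued_control_hz": con_m, "se_control": con_se,
            "n_control": n_con,
            "d_cued_inhibition_hz": inh_m, "se_inhibition": inh_se,
            "n_inhibition": n_inh,
            "difference_hz": con_m - inh_m,
            "t_inh_minus_reach_s": t_inh_mid - mid,
        })
    return pd.DataFrame(rows)
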