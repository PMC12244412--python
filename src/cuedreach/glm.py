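"""Time-shifted behavioral-event design matrix and per-unit linear GLM.

Neural activity is binned at 0.1 s and regressed, with a linear link,
on indicator regressors formed by shifting each of the nine behavioral
events across a lag grid from 2 s before to 5 s after the event
(9 events x 71 lags = 639 columns).  A hyperparameter sweep over
elastic-net regularization (alpha x l1_ratio, plus plain least squares
at alpha = 0) selects the fit with the best out-of-sample R^2.  The
coefficients assigned to the post-outcome period form each unit's
outcome "kernels".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .session import EVENT_NAMES
from .synth import GLM_BIN_S, GLM_LAGS

__all__ = [
    "EventDesign",
    "GLMConfig",
    "GLMFit",
    "build_design",
    "bin_spikes",
    "fit_glm",
    "r_squared",
    "extract_pop_kernels",
]


@dataclass(frozen=True)
class EventDesign:
    """Lag grid and event-channel order of the design matrix.

    Columns are event-major, lag-minor: all lags of event 0, then all
    lags of event 1, and so on; lags ascend from ``lag_min`` to
    ``lag_max`` inclusive.
    """

    bin_s: float = GLM_BIN_S
    lag_min_s: float = -2.0
    lag_max_s: float = 5.0
    events: tuple[str, ...] = EVENT_NAMES

    @property
    def lags(self) -> np.ndarray:
        n = int(round((self.lag_max_s - self.lag_min_s) / self.bin_s)) + 1
        return np.round(self.lag_min_s + self.bin_s * np.arange(n), 10)

    @property
    def n_columns(self) -> int:
        return len(self.events) * self.lags.size

    def column_index(self, event: str, lag_s: float) -> int:
        e = self.events.index(event)
        lag_idx = int(round((lag_s - self.lag_min_s) / self.bin_s))
        if not 0 <= lag_idx < self.lags.size:
            raise ValueError(f"lag {lag_s} outside the grid")
        return e * self.lags.size + lag_idx


def build_design(event_times: dict[str, np.ndarray], duration: float,
                 design: EventDesign = EventDesign()) -> sparse.csr_matrix:
    """Indicator design matrix (time bins x events*lags), sparse CSR.

    Column (e, tau) carries a 1 in time bin t exactly when event e
    occurred in bin t - tau; shifted bins falling outside the session
    are zero.  Events in the same bin collapse to a single indicator.
    """
    unknown = set(event_times) - set(design.events)
    if unknown:
        raise ValueError(f"unknown event types: {sorted(unknown)}")
    n_bins = int(np.ceil(round(duration / design.bin_s, 9)))
    lag_bins = np.round(design.lags / design.bin_s).astype(int)
    n_lags = lag_bins.size

    rows, cols = [], []
    for e_idx, name in enumerate(design.events):
        times = np.asarray(event_times.get(name, ()), dtype=float)
        if times.size and (times.min() < 0 or times.max() >= duration):
            raise ValueError(f"event {name!r} outside the session span")
        # epsilon guards against times like 28.7 binning down at 0.1 s
        base = np.unique(np.floor(times / design.bin_s + 1e-9).astype(int))
        base = base[(base >= 0) & (base < n_bins)]
        for j, shift in enumerate(lag_bins):
            tgt = base + shift
            tgt = tgt[(tgt >= 0) & (tgt < n_bins)]
            rows.append(tgt)
            cols.append(np.full(tgt.size, e_idx * n_lags + j))
    rows = np.concatenate(rows) if rows else np.empty(0, int)
    cols = np.concatenate(cols) if cols else np.empty(0, int)
    X = sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols)),
        shape=(n_bins, design.n_columns))
    X.data[:] = 1.0  # duplicate events in one bin stay an indicator
    X.sum_duplicates()
    X.data[:] = np.minimum(X.data, 1.0)
    return X


def bin_spikes(spike_times: np.ndarray, duration: float,
               bin_s: float = GLM_BIN_S) -> np.ndarray:
    """Spike counts per time bin (the GLM response variable)."""
    n_bins = int(np.ceil(round(duration / bin_s, 9)))
    edges = bin_s * np.arange(n_bins + 1)
    counts, _ = np.histogram(np.asarray(spike_times, float), bins=edges)
    return counts.astype(float)


def r_squared(y, y_hat) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for constant y")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class GLMConfig:
    """Regularization sweep and validation layout.

    ``alpha = 0`` is ordinary least squares and skips the l1_ratio grid.
    Folds and the held-out test fraction are contiguous blocks in time to
    limit leakage between temporally adjacent bins.
    """

    alphas: tuple[float, ...] = (0.0, 0.01, 0.1, 1.0)
    l1_ratios: tuple[float, ...] = (0.0, 0.1, 0.5, 0.9, 1.0)
    cv_folds: int = 5
    test_fraction: float = 0.10
    seed: int = 0
    max_iter: int = 2000

    def combos(self) -> list[tuple[float, float | None]]:
        out: list[tuple[float, float | None]] = []
        for a in self.alphas:
            if a == 0.0:
                out.append((0.0, None))
            else:
                out.extend((a, l1) for l1 in self.l1_ratios)
        return out


@dataclass
class GLMFit:
    coefficients: np.ndarray  # (n_events, n_lags)
    intercept: float
    alpha: float
    l1_ratio: float | None
    r2_heldout: float
    cv_table: list[tuple[float, float | None, float]]
    design: EventDesign

    def kernel(self, event: str) -> np.ndarray:
        return self.coefficients[self.design.events.index(event)]


def _fit_one(X, y, alpha: float, l1_ratio: float | None,
             max_iter: int) -> tuple[np.ndarray, float]:
    from sklearn.linear_model import ElasticNet, LinearRegression, Ridge

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if alpha == 0.0:
            model = LinearRegression()
        elif l1_ratio == 0.0:
            # coordinate descent is poorly conditioned at pure L2
            model = Ridge(alpha=alpha * X.shape[0], solver="sparse_cg")
        else:
            model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio,
                               max_iter=max_iter)
        model.fit(X, y)
    return np.asarray(model.coef_).ravel(), float(model.intercept_)


def fit_glm(X: sparse.spmatrix, y: np.ndarray,
            cfg: GLMConfig = GLMConfig(),
            design: EventDesign = EventDesign()) -> GLMFit:
    """Sweep the regularization grid and return the best model.

    The final ``test_fraction`` of time bins is held out.  On the
    remaining bins each (alpha, l1_ratio) combination is scored by mean
    R^2 over contiguous cross-validation folds; the argmax combination
    (ties broken toward larger alpha, then larger l1_ratio) is refit on
    all non-held-out bins and reported with its held-out R^2.
    """
    y = np.asarray(y, float)
    if X.shape[0] != y.size:
        raise ValueError("design rows must match response length")
    if X.shape[1] != design.n_columns:
        raise ValueError("design width does not match the event/lag grid")
    zero_cols = np.flatnonzero(np.asarray(abs(X).sum(axis=0)).ravel() == 0)
    if zero_cols.size:
        warnings.warn(f"{zero_cols.size} all-zero design columns retained",
                      stacklevel=2)

    n = y.size
    n_test = max(1, int(round(cfg.test_fraction * n)))
    train_idx = np.arange(n - n_test)
    test_idx = np.arange(n - n_test, n)
    X_tr, y_tr = X[train_idx], y[train_idx]

    folds = np.array_split(np.arange(train_idx.size), cfg.cv_folds)
    scores = []
    for alpha, l1 in cfg.combos():
        fold_r2 = []
        for f in folds:
            mask = np.ones(train_idx.size, bool)
            mask[f] = False
            coef, icpt = _fit_one(X_tr[mask], y_tr[mask], alpha, l1,
                                  cfg.max_iter)
            pred = X_tr[f] @ coef + icpt
            try:
                fold_r2.append(r_squared(y_tr[f], pred))
            except ValueError:
                fold_r2.append(0.0)
        scores.append((alpha, l1, float(np.mean(fold_r2))))

    # argmax CV score, ties toward sparser models (larger alpha, then l1)
    def sort_key(row):
        alpha, l1, s = row
        return (s, alpha, -1.0 if l1 is None else l1)

    best_alpha, best_l1, _ = max(scores, key=sort_key)
    coef, icpt = _fit_one(X_tr, y_tr, best_alpha, best_l1, cfg.max_iter)
    pred_test = X[test_idx] @ coef + icpt
    try:
        r2_test = r_squared(y[test_idx], pred_test)
    except ValueError:
        r2_test = 0.0
    coefs = coef.reshape(len(design.events), design.lags.size)
    return GLMFit(coefficients=coefs, intercept=icpt, alpha=best_alpha,
                  l1_ratio=best_l1, r2_heldout=r2_test, cv_table=scores,
                  design=design)


POP_KERNEL_EVENTS = ("success", "failure", "cued_success", "cued_failure")


def extract_pop_kernels(fit: GLMFit,
                        window: tuple[float, float] = (0.0, 5.0),
                        ) -> dict[str, np.ndarray]:
    """Outcome kernels over the post-outcome period (0-5 s after t_arm).

    The failure kernel is the mean of the two failure-channel kernels
    (dropped pellet and pellet missing); cued failure analogously.
    Returns the four kernels restricted to lags in ``window`` (inclusive,
    51 bins at 0.1 s).
    """
    design = fit.design
    lags = design.lags
    keep = (lags >= window[0] - 1e-9) & (lags <= window[1] + 1e-9)

    def k(event: str) -> np.ndarray:
        return fit.kernel(event)[keep]

    for name in ("success", "failure_drop", "failure_pellet_missing",
                 "cued_success", "cued_failure_drop",
                 "cued_failure_pellet_missing"):
        if name not in design.events:
            raise ValueError(f"fit lacks outcome channel {name!r}")
    return {
        "success": k("success"),
        "failure": 0.5 * (k("failure_drop") + k("failure_pellet_missing")),
        "cued_success": k("cued_success"),
        "cued_failure": 0.5 * (k("cued_failure_drop")
                               + k("cued_failure_pellet_missing")),
    }
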