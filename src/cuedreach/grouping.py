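"""Two-group partition of units from their post-outcome GLM kernels.

Units are summarized by four outcome kernels (success, failure, cued
success, cued failure) over the 5-s post-outcome period.  Smoothed,
max-normalized, concatenated kernel vectors are clustered with k-means
(k=2); two scalar summaries -- the modulation index

    m = (c_2-5s - c_0-2s) / (|c_2-5s| + |c_0-2s|)

averaged over the success kernels, and the sustained metric
s = |c_1-5s| averaged over the failure kernels -- place each unit in a
plane where a linear boundary fitted to the k-means labels on training
data assigns group 1 (success-preferring) vs group 2
(failure-preferring) to any unit, including held-out test data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "KernelVector",
    "KernelMetrics",
    "GroupBoundary",
    "smooth_kernel",
    "prepare_kernel_vectors",
    "kmeans_two",
    "kernel_metrics",
    "boundary_assign",
]

POP_KERNEL_ORDER = ("success", "failure", "cued_success", "cued_failure")


@dataclass(frozen=True)
class KernelVector:
    unit_id: str
    vector: np.ndarray  # concatenated smoothed max-normalized kernels


@dataclass(frozen=True)
class KernelMetrics:
    unit_id: str
    m: float  # modulation index in [-1, 1]; NaN when undefined
    s: float  # sustained metric >= 0


@dataclass(frozen=True)
class GroupBoundary:
    """Linear boundary w . (m, s) + b in the metric plane.

    Units with decision value >= 0 are group 1 (ties go to group 1).
    """

    weights: tuple[float, float]
    bias: float
    train_misassigned: int

    def assign(self, metrics: "KernelMetrics | tuple[float, float]") -> str:
        if isinstance(metrics, KernelMetrics):
            m, s = metrics.m, metrics.s
        else:
            m, s = metrics
        val = self.weights[0] * m + self.weights[1] * s + self.bias
        return "group1" if val >= 0 else "group2"


def smooth_kernel(kernel: np.ndarray, bin_s: float = 0.1,
                  width_s: float = 0.08) -> np.ndarray:
    """Boxcar-smooth a kernel; the window spans ``width_s`` of lag time.

    On grids coarser than the window (e.g. 0.1-s bins with the default
    0.08-s window) this is the identity.
    """
    size = max(1, int(round(width_s / bin_s)))
    if size == 1:
        return np.asarray(kernel, float).copy()
    return uniform_filter1d(np.asarray(kernel, float), size=size,
                            mode="nearest")


def prepare_kernel_vectors(
        kernels_per_unit: dict[str, dict[str, np.ndarray]],
        bin_s: float = 0.1,
        smooth_width_s: float = 0.08,
        per_kernel_norm: bool = False,
) -> list[KernelVector]:
    """Smooth, max-normalize and concatenate each unit's four kernels.

    Units with no positive post-outcome coefficient are excluded (their
    activity is explained by other events, not the outcome).  Default
    normalization divides the concatenated vector by its maximum absolute
    entry, preserving relative kernel amplitudes; ``per_kernel_norm``
    normalizes each kernel separately.
    """
    out = []
    for unit_id in sorted(kernels_per_unit):
        kerns = kernels_per_unit[unit_id]
        smoothed = [smooth_kernel(kerns[name], bin_s, smooth_width_s)
                    for name in POP_KERNEL_ORDER]
        if max(float(k.max()) for k in smoothed) <= 0.0:
            continue
        if per_kernel_norm:
            parts = []
            for k in smoothed:
                peak = np.abs(k).max()
                parts.append(k / peak if peak > 0 else k)
            vec = np.concatenate(parts)
        else:
            vec = np.concatenate(smoothed)
            vec = vec / np.abs(vec).max()
        out.append(KernelVector(unit_id=unit_id, vector=vec))
    return out


def _success_preference(vec: np.ndarray) -> float:
    # success-kernel minus failure-kernel mass of a concatenated vector,
    # used only to give k-means labels a canonical orientation
    n = vec.size // 4
    success = np.concatenate([vec[:n], vec[2 * n:3 * n]])
    failure = np.concatenate([vec[n:2 * n], vec[3 * n:]])
    return float(success.mean() - failure.mean())


def kmeans_two(vectors: list[KernelVector], seed: int = 0,
               restarts: int = 10) -> dict[str, int]:
    """k=2 k-means over kernel vectors; returns unit_id -> label {0, 1}.

    Label 0 is the cluster whose members carry more success-kernel than
    failure-kernel mass (the group-1, success-preferring candidate), so
    labels are invariant to input order and initialization.
    """
    from sklearn.cluster import KMeans

    if len(vectors) < 2:
        raise ValueError("k-means needs at least two vectors")
    X = np.vstack([v.vector for v in vectors])
    if np.allclose(X, X[0]):
        raise ValueError("all kernel vectors identical: single cluster")
    km = KMeans(n_clusters=2, n_init=restarts, random_state=seed)
    raw = km.fit_predict(X)
    mod = np.array([_success_preference(v.vector) for v in vectors])
    means = [mod[raw == c].mean() if np.any(raw == c) else -np.inf
             for c in (0, 1)]
    flip = means[1] > means[0]
    return {v.unit_id: int(raw[i] != 0 if not flip else raw[i] == 0)
            for i, v in enumerate(vectors)}


def _avg(kernel: np.ndarray, lo_s: float, hi_s: float,
         bin_s: float = 0.1, closed_end: bool = False) -> float:
    lags = bin_s * np.arange(kernel.size)
    if closed_end:
        sel = (lags >= lo_s - 1e-9) & (lags <= hi_s + 1e-9)
    else:
        sel = (lags >= lo_s - 1e-9) & (lags < hi_s - 1e-9)
    return float(kernel[sel].mean())


def kernel_metrics(kernels: dict[str, np.ndarray], unit_id: str = "",
                   bin_s: float = 0.1) -> KernelMetrics:
    """Modulation index m and sustained metric s for one unit.

    m contrasts the mean coefficient 2-5 s vs 0-2 s after the reach,
    averaged over the success and cued-success kernels; s is the absolute
    mean coefficient 1-5 s after the reach, averaged over the failure and
    cued-failure kernels.
    """
    ms = []
    for name in ("success", "cued_success"):
        late = _avg(kernels[name], 2.0, 5.0, bin_s, closed_end=True)
        early = _avg(kernels[name], 0.0, 2.0, bin_s)  # [0, 2)
        denom = abs(late) + abs(early)
        ms.append((late - early) / denom if denom > 0 else np.nan)
    ss = [abs(_avg(kernels[name], 1.0, 5.0, bin_s, closed_end=True))
          for name in ("failure", "cued_failure")]
    finite = [v for v in ms if np.isfinite(v)]
    m = float(np.mean(finite)) if finite else float("nan")
    return KernelMetrics(unit_id=unit_id, m=m, s=float(np.mean(ss)))


def boundary_assign(metrics: list[KernelMetrics],
                    labels: dict[str, int]) -> tuple[dict[str, str],
                                                     GroupBoundary]:
    """Fit a linear boundary in the (m, s) plane separating the clusters.

    A two-class linear discriminant is fit to the k-means labels of the
    training units; the frozen line then assigns group1/group2 to any
    unit.  Returns (unit_id -> group for the training units, boundary).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    usable = [mt for mt in metrics if np.isfinite(mt.m) and mt.unit_id in labels]
    if len(usable) < 2:
        raise ValueError("need at least two labeled units with finite metrics")
    X = np.array([[mt.m, mt.s] for mt in usable])
    y = np.array([labels[mt.unit_id] for mt in usable])
    if len(np.unique(y)) < 2:
        raise ValueError("both clusters must be represented")
    lda = LinearDiscriminantAnalysis()
    lda.fit(X, y)
    # sklearn's decision function is positive for class 1; orient so the
    # group-1 candidate (label 0) sits on the non-negative side
    w = -lda.coef_[0]
    b = -float(lda.intercept_[0])
    boundary = GroupBoundary(weights=(float(w[0]), float(w[1])), bias=b,
                             train_misassigned=0)
    assigned = {mt.unit_id: boundary.assign(mt) for mt in usable}
    mis = sum((assigned[mt.unit_id] == "group1") != (labels[mt.unit_id] == 0)
              for mt in usable)
    boundary = GroupBoundary(weights=boundary.weights, bias=boundary.bias,
                             train_misassigned=int(mis))
    return assigned, boundary
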