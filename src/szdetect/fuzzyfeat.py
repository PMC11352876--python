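"""Windowed statistical features, fuzzy C-means clustering, and
membership-based feature selection.

Feature extraction follows population-moment definitions: mean, variance
(the first Hjorth descriptor, "activity"), standard deviation, skewness
``m3 / m2**1.5``, non-excess kurtosis ``m4 / m2**2`` and Shannon entropy in
bits over a 16-bin amplitude histogram spanning the segment's min-max
range.  Fuzzy C-means uses the canonical alternating optimization: centers
are membership^m-weighted means and memberships come from inverse-distance
ratios with exponent ``2 / (m - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import EEGRecord
from .errors import ConfigurationError

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "FeatureMatrix",
    "FCMConfig",
    "FCMResult",
    "window_segments",
    "stat_features",
    "fcm_fit",
    "fcm_memberships",
    "feature_scores",
    "select_features",
]

EPS = 1e-12
ENTROPY_BINS = 16

FEATURE_NAMES = (
    "mean",
    "variance",
    "standard_deviation",
    "skewness",
    "kurtosis",
    "shannon_entropy",
)


@dataclass
class FeatureVector:
    """Statistical descriptors of one windowed segment."""

    mean: float
    variance: float
    standard_deviation: float
    skewness: float
    kurtosis: float
    shannon_entropy: float
    record_id: str = ""
    window_index: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


@dataclass
class FeatureMatrix:
    """Rectangular feature table with aligned labels.

    ``values`` has one row per window; ``labels`` has one entry per row
    (the label of the source record).
    """

    values: np.ndarray
    column_names: tuple[str, ...]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("FeatureMatrix values must be 2-D")
        if self.values.shape[1] != len(self.column_names):
            raise ConfigurationError("column_names length must match column count")
        if self.labels and len(self.labels) != self.values.shape[0]:
            raise ConfigurationError("labels length must match row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass
class FCMConfig:
    """Fuzzy C-means settings: ``c`` clusters with fuzziness ``m > 1``."""

    n_clusters: int = 2
    m: float = 2.0
    tolerance: float = 1e-5
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")
        if not (self.m > 1):
            raise ConfigurationError("fuzziness m must exceed 1")
        if not (self.tolerance > 0):
            raise ConfigurationError("tolerance must be positive")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")


@dataclass
class FCMResult:
    """Fitted centers, row-stochastic memberships and objective trajectory."""

    centers: np.ndarray
    memberships: np.ndarray
    objective_trajectory: list[float]
    m: float = 2.0


def window_segments(
    record: EEGRecord, win: int, overlap_frac: float = 0.0
) -> list[np.ndarray]:
    """Slice a record into windows of exactly ``win`` samples.

    The hop is ``round(win * (1 - overlap_frac))`` clamped to at least one
    sample; the trailing remainder that cannot fill a window is dropped.
    """
    n = len(record)
    if win > n:
        raise ConfigurationError(f"window {win} exceeds record length {n}")
    if not (0 <= overlap_frac < 1):
        raise ConfigurationError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    step = max(1, int(round(win * (1.0 - overlap_frac))))
    return [record.samples[start:start + win] for start in range(0, n - win + 1, step)]


def stat_features(
    segment: Sequence[float] | np.ndarray, record_id: str = "", window_index: int = 0
) -> FeatureVector:
    """Population-moment statistics plus histogram Shannon entropy.

    Zero-variance segments return skewness = kurtosis = 0 by convention and
    entropy 0 (a single occupied bin).  Empty histogram bins contribute 0
    to the entropy sum.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ConfigurationError("stat_features requires at least 2 samples")
    mu = float(x.mean())
    centered = x - mu
    m2 = float(np.mean(centered**2))
    sd = float(np.sqrt(m2))
    if m2 > 0:
        # guard underflow of m2**1.5 / m2**2 for near-constant segments
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            skew = float(np.mean(centered**3) / m2**1.5)
            kurt = float(np.mean(centered**4) / m2**2)
        if not np.isfinite(skew):
            skew = 0.0
        if not np.isfinite(kurt):
            kurt = 0.0
    else:
        skew = 0.0
        kurt = 0.0
    lo, hi = float(x.min()), float(x.max())
    # the span must be wide enough for ENTROPY_BINS finite-width bins
    if hi > lo and (hi - lo) / ENTROPY_BINS > 0:
        counts, _ = np.histogram(x, bins=ENTROPY_BINS, range=(lo, hi))
        p = counts[counts > 0] / x.size
        entropy = float(-np.sum(p * np.log2(p)))
    else:
        entropy = 0.0
    return FeatureVector(mu, m2, sd, skew, kurt, entropy, record_id, window_index)


def _memberships_from_distances(d2: np.ndarray, m: float) -> np.ndarray:
    """Row-stochastic memberships from squared distances, shape (n, c).

    Rows coincident with one or more centers get full membership split
    equally among the zero-distance clusters.
    """
    n, c = d2.shape
    u = np.zeros((n, c))
    zero_rows = (d2 <= EPS).any(axis=1)
    if zero_rows.any():
        hits = d2[zero_rows] <= EPS
        u[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    ok = ~zero_rows
    if ok.any():
        power = 1.0 / (m - 1.0)
        ratio = (d2[ok][:, :, None] / d2[ok][:, None, :]) ** power
        u[ok] = 1.0 / ratio.sum(axis=2)
    return u


def _quantile_centers(X: np.ndarray, c: int) -> np.ndarray:
    """Deterministic, permutation-invariant initial centers from per-column
    quantiles at (k + 0.5) / c."""
    qs = (np.arange(c) + 0.5) / c
    return np.quantile(X, qs, axis=0)


def fcm_fit(X: FeatureMatrix | np.ndarray, config: FCMConfig) -> FCMResult:
    """Fit fuzzy C-means by alternating center / membership updates.

    Initial centers are per-column quantiles of the data, which makes the
    fit deterministic and equivariant under row permutation (permuting the
    input rows permutes the membership rows identically).  Iteration stops
    when the objective improves by less than ``tolerance`` or after
    ``max_iter`` rounds; the recorded objective trajectory is
    non-increasing.
    """
    data = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if data.ndim != 2:
        raise ConfigurationError("fcm_fit requires a 2-D matrix")
    n, _ = data.shape
    c, m = config.n_clusters, config.m
    if c > n:
        raise ConfigurationError(f"n_clusters {c} exceeds row count {n}")
    if c == 1:
        center = data.mean(axis=0, keepdims=True)
        u = np.ones((n, 1))
        d2 = np.sum((data - center) ** 2, axis=1)
        return FCMResult(center, u, [float(d2.sum())], m=m)

    centers = _quantile_centers(data, c)
    trajectory: list[float] = []
    prev = np.inf
    for _ in range(config.max_iter):
        d2 = np.sum((data[:, None, :] - centers[None, :, :]) ** 2, axis=2)
        u = _memberships_from_distances(d2, m)
        um = u**m
        centers = (um.T @ data) / (um.sum(axis=0)[:, None] + EPS)
        d2 = np.sum((data[:, None, :] - centers[None, :, :]) ** 2, axis=2)
        objective = float(np.sum(um * d2))
        trajectory.append(objective)
        if abs(prev - objective) < config.tolerance:
            break
        prev = objective
    u = _memberships_from_distances(d2, m)
    return FCMResult(centers, u, trajectory, m=m)


def fcm_memberships(X: FeatureMatrix | np.ndarray, result: FCMResult) -> np.ndarray:
    """Membership degrees of (possibly new) rows under fitted centers."""
    data = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    d2 = np.sum((data[:, None, :] - result.centers[None, :, :]) ** 2, axis=2)
    return _memberships_from_distances(d2, result.m)


def feature_scores(result: FCMResult, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Per-column cluster-separation scores.

    For each column the score is the mean pairwise distance between cluster
    centers along that column divided by the pooled membership-weighted
    within-cluster spread plus a small guard, so constant columns score 0.
    """
    data = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    centers = result.centers
    um = result.memberships**result.m
    c = centers.shape[0]
    if c < 2:
        return np.zeros(data.shape[1])
    sep = np.zeros(data.shape[1])
    pairs = 0
    for a in range(c):
        for b in range(a + 1, c):
            sep += np.abs(centers[a] - centers[b])
            pairs += 1
    sep /= pairs
    # pooled membership-weighted spread per column
    sq = np.zeros(data.shape[1])
    for k in range(c):
        sq += um[:, k] @ (data - centers[k]) ** 2
    spread = np.sqrt(sq / (um.sum() + EPS))
    return sep / (spread + EPS)


def select_features(result: FCMResult, X: FeatureMatrix, k: int) -> FeatureMatrix:
    """Keep the top-``k`` columns by separation score and append membership
    degrees as additional feature columns.

    Selected columns keep their original relative order; the appended
    columns are named ``membership_0 .. membership_{c-1}``.
    """
    if not (1 <= k <= X.n_cols):
        raise ConfigurationError(f"k must be in [1, {X.n_cols}], got {k}")
    scores = feature_scores(result, X)
    top = np.sort(np.argsort(-scores, kind="stable")[:k])
    u = result.memberships
    if u.shape[0] != X.n_rows:
        raise ConfigurationError("membership rows must match feature rows")
    values = np.hstack([X.values[:, top], u])
    names = tuple(X.column_names[i] for i in top) + tuple(
        f"membership_{j}" for j in range(u.shape[1])
    )
    return FeatureMatrix(values, names, list(X.labels))


def export_features(X: FeatureMatrix, path: str | Path) -> Path:
    """Write a feature matrix as a TSV table with a header row."""
    path = Path(path)
    header = "\t".join(X.column_names) + ("\tlabel" if X.labels else "")
    lines = [header]
    for i in range(X.n_rows):
        row = "\t".join(repr(v) for v in X.values[i])
        if X.labels:
            row += f"\t{X.labels[i]}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
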