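"""Stepwise connectivity: seed-based walk counts across step sizes.

For a seed node s and step size x, the stepwise connectivity value of a
target ROI is the number of walks of edge length x from s to that ROI,
i.e. row s of the x-th power of the (binary) adjacency matrix. Because
walk counts grow exponentially with x, each step's map is standardized
within subject (z across ROIs) before any group analysis; maps saturate
toward the leading eigenvector as x grows, which the convergence curve
diagnoses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .prep import AdjacencyGraph

MAX_EXACT = 2.0**53  # float64 holds integers exactly below this


@dataclass
class StepwiseProfile:
    """Per-seed walk counts and normalized maps for steps 1..max_step."""

    seed: int
    max_step: int
    raw_counts: np.ndarray  # (S, n)
    normalized: np.ndarray  # (S, n) within-subject z per step
    degenerate: np.ndarray  # (S,) bool: step row had zero variance

    @property
    def n_rois(self) -> int:
        return self.raw_counts.shape[1]

    def sum_normalized(self, steps: tuple[int, int] | None = None) -> np.ndarray:
        """Column sums of the normalized maps over an inclusive step range."""
        lo, hi = (1, self.max_step) if steps is None else steps
        if not (1 <= lo <= hi <= self.max_step):
            raise ValueError(f"step range {steps} outside 1..{self.max_step}")
        return self.normalized[lo - 1 : hi].sum(axis=0)


def walk_counts(
    graph: AdjacencyGraph | np.ndarray,
    seed: int,
    max_step: int = 7,
    weighted: bool = False,
) -> np.ndarray:
    """Count walks of length 1..max_step from the seed to every ROI.

    Row x of the result is the seed row of the x-th adjacency-matrix power,
    computed iteratively as vector-matrix products (full powers are never
    formed). Self-walks back to the seed are included at the seed column.
    """
    a = graph.matrix if isinstance(graph, AdjacencyGraph) else np.asarray(graph, float)
    n = a.shape[0]
    if a.shape != (n, n) or np.abs(a - a.T).max(initial=0.0) > 0:
        raise ValueError("graph must be a square symmetric matrix")
    if not 0 <= seed < n:
        raise ValueError(f"seed {seed} out of range for {n} nodes")
    if not 1 <= max_step <= 10:
        raise ValueError("max_step must lie in 1..10")
    if not weighted and not np.isin(a, (0.0, 1.0)).all():
        raise ValueError("graph is not binary; pass weighted=True for weighted powers")
    counts = np.empty((max_step, n))
    v = a[seed].astype(float)
    counts[0] = v
    for x in range(1, max_step):
        v = v @ a
        if not weighted and v.max(initial=0.0) >= MAX_EXACT:
            raise OverflowError(
                f"walk counts exceed 2^53 at step {x + 1}; exactness lost"
            )
        counts[x] = v
    return counts


def normalize_within_subject(raw_counts: np.ndarray):
    """Standardize each step's map to mean 0, population SD 1 across ROIs.

    Degenerate rows (zero variance, e.g. an edgeless graph) are returned as
    all-zeros and flagged rather than raising.
    """
    raw = np.asarray(raw_counts, dtype=float)
    mean = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, keepdims=True)  # population SD (ddof=0)
    degenerate = (sd == 0.0).ravel()
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} step map(s) have zero variance; returned as zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (raw - mean) / safe_sd
    z[degenerate] = 0.0
    return z, degenerate


def stepwise_profile(
    graph: AdjacencyGraph | np.ndarray,
    seed: int,
    max_step: int = 7,
    weighted: bool = False,
) -> StepwiseProfile:
    raw = walk_counts(graph, seed, max_step, weighted=weighted)
    z, degenerate = normalize_within_subject(raw)
    return StepwiseProfile(
        seed=seed, max_step=max_step, raw_counts=raw, normalized=z, degenerate=degenerate
    )


@dataclass
class ConvergenceCurve:
    """Spatial correlation of consecutive group-mean step maps."""

    step_pairs: list  # [(1, 2), (2, 3), ...]
    pearson_r: np.ndarray

    def r(self, x: int, y: int) -> float:
        return float(self.pearson_r[self.step_pairs.index((x, y))])


def convergence_curve(profiles: list) -> ConvergenceCurve:
    """ROI-wise Pearson r between consecutive pairs of group-mean step maps.

    Normalized maps are first averaged across subjects per step; correlation
    of the step-x map with the step-(x+1) map then measures topological
    saturation (r -> 1 once the walk distribution stops changing shape).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 subjects for a convergence curve")
    seeds = {p.seed for p in profiles}
    steps = {p.max_step for p in profiles}
    if len(seeds) != 1 or len(steps) != 1:
        raise ValueError("profiles must share seed and max_step")
    mean_maps = np.mean([p.normalized for p in profiles], axis=0)  # (S, n)
    s = mean_maps.shape[0]
    pairs, rs = [], []
    for x in range(s - 1):
        a, b = mean_maps[x], mean_maps[x + 1]
        if a.std() == 0.0 or b.std() == 0.0:
            raise ValueError(f"zero-variance mean map at step {x + 1} or {x + 2}")
        rs.append(float(np.corrcoef(a, b)[0, 1]))
        pairs.append((x + 1, x + 2))
    return ConvergenceCurve(step_pairs=pairs, pearson_r=np.asarray(rs))


class StepwiseConnectivity(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: adjacency graphs -> stepwise profiles.

    ``transform`` maps a list of binary :class:`AdjacencyGraph` onto a list
    of :class:`StepwiseProfile` for a fixed seed and maximum step size.
    """

    def __init__(self, seed: int = 0, max_step: int = 7, weighted: bool = False):
        self.seed = seed
        self.max_step = max_step
        self.weighted = weighted

    def fit(self, X, y=None):
        if not 1 <= self.max_step <= 10:
            raise ValueError("max_step must lie in 1..10")
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        return [
            stepwise_profile(g, self.seed, self.max_step, weighted=self.weighted)
            for g in X
        ]
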