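"""Connectome preprocessing: Fisher z, proportional thresholding, graphs.

The walk-counting stage operates on a binarized graph obtained by

    fisher_z (functional only) -> threshold_top_fraction -> symmetrize_union
    -> binarize

Row-wise top-k thresholding keeps, for every ROI, the strongest
``fraction`` of its connections (fixed edge density, default 20%). Because
row-wise selection breaks symmetry, edges are re-symmetrized by union: an
edge survives if it was among the top connections of either endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import Connectome

_CLIP = 1.0 - 1e-7


@dataclass
class AdjacencyGraph:
    """Thresholded (optionally binarized) symmetric graph with provenance."""

    matrix: np.ndarray
    modality: str
    provenance: dict = field(default_factory=dict)

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.matrix, (0.0, 1.0)).all())

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def fisher_z(connectome: Connectome) -> np.ndarray:
    """Fisher R-to-Z transform of a functional connectome's off-diagonal.

    Correlations within 1e-7 of +/-1 are clipped before arctanh so the
    transform stays finite; the diagonal stays exactly zero.
    """
    if connectome.modality != "functional":
        raise ValueError("fisher_z applies to functional connectomes only")
    r = np.clip(connectome.matrix, -_CLIP, _CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return z


def _row_k(n: int, fraction: float) -> int:
    """Connections kept per row: round-half-away-from-zero of fraction*(n-1), >= 1."""
    raw = fraction * (n - 1)
    k = int(np.floor(raw + 0.5))
    return max(k, 1)


def threshold_top_fraction(matrix: np.ndarray, fraction: float = 0.20) -> np.ndarray:
    """Keep the top ``fraction`` of off-diagonal values in every row.

    Selection is by signed value; ties at the cutoff are broken toward the
    lower column index so the result is deterministic. Entries not kept are
    set to zero. The output is generally asymmetric; see
    :func:`symmetrize_union`.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes to threshold")
    k = _row_k(n, fraction)
    out = np.zeros_like(m)
    cols = np.arange(n)
    for i in range(n):
        row = m[i].copy()
        row[i] = -np.inf  # never keep the diagonal
        # sort by descending value, then ascending column index on ties
        order = np.lexsort((cols, -row))
        keep = order[:k]
        out[i, keep] = m[i, keep]
    return out


def symmetrize_union(row_thresholded: np.ndarray) -> np.ndarray:
    """Edge (i, j) survives if it survived in row i OR row j; weight = original."""
    t = np.asarray(row_thresholded, dtype=float)
    return np.where(t != 0.0, t, t.T)


def binarize(matrix: np.ndarray, clip_negative: bool = True) -> np.ndarray:
    """Positive entries -> 1; zeros and (when clipping) negatives -> 0."""
    m = np.asarray(matrix, dtype=float)
    if clip_negative:
        return (m > 0.0).astype(float)
    return (m != 0.0).astype(float)


def prep_connectome(
    connectome: Connectome,
    fraction: float = 0.20,
    binary: bool = True,
    rois: np.ndarray | None = None,
) -> AdjacencyGraph:
    """Full preprocessing of one connectome into a walk-count graph.

    Functional matrices are Fisher-z transformed first; structural counts are
    thresholded raw. ``rois`` restricts the analysis to a subset (one
    hemisphere) before thresholding so edge density is fixed within that set.
    """
    m = fisher_z(connectome) if connectome.modality == "functional" else connectome.matrix
    if rois is not None:
        m = m[np.ix_(rois, rois)]
    t = threshold_top_fraction(m, fraction)
    sym = symmetrize_union(t)
    if binary:
        sym = binarize(sym)
    else:
        sym = np.clip(sym, 0.0, None)  # weighted variant drops anti-correlations
    return AdjacencyGraph(
        matrix=sym,
        modality=connectome.modality,
        provenance={
            "fraction": fraction,
            "symmetrization": "union",
            "binarized": binary,
        },
    )


class ConnectomeThresholder(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping :func:`prep_connectome`.

    ``transform`` maps a list of :class:`Connectome` onto a list of
    :class:`AdjacencyGraph` with fixed per-row edge density.
    """

    def __init__(self, fraction: float = 0.20, binary: bool = True, rois=None):
        self.fraction = fraction
        self.binary = binary
        self.rois = rois

    def fit(self, X, y=None):
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must lie in (0, 1)")
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        return [
            prep_connectome(c, fraction=self.fraction, binary=self.binary, rois=self.rois)
            for c in X
        ]
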