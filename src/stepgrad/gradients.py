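"""Connectome gradients: diffusion-map embedding and Procrustes alignment.

A cosine-similarity affinity is built from the thresholded connectivity
matrix, converted to an anisotropic Markov operator (normalization
exponent alpha, default 0.5), and eigendecomposed through its symmetric
conjugate. The non-trivial eigenvectors, scaled by lambda/(1-lambda) at
diffusion time t = 0 (or lambda^t for t > 0), are the gradients: each is a
smooth axis of connectivity variation across ROIs. Subject embeddings are
realigned to their group template by orthogonal Procrustes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class GradientEmbedding:
    """Per-ROI coordinates on ordered gradient components."""

    coordinates: np.ndarray  # (n, G)
    eigenvalues: np.ndarray  # (G,) descending
    pseudo_variance: np.ndarray  # (G,) shares of the retained eigenvalue sum
    scaled: bool = False
    template_group: str = "subject"

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class AlignmentTransform:
    """Orthogonal map aligning a subject embedding to a template."""

    rotation: np.ndarray  # (G, G), orthogonal
    source: str
    target: str


def cosine_affinity(matrix: np.ndarray) -> np.ndarray:
    """Cosine similarity between ROI connectivity profiles (rows).

    Negative similarities are clipped to zero and the diagonal is set to 1,
    which is the self-affinity convention the diffusion operator expects.
    """
    m = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(m, axis=1)
    if (norms == 0.0).any():
        bad = np.flatnonzero(norms == 0.0)
        raise ValueError(f"zero connectivity row(s) {bad.tolist()}: cosine undefined")
    a = (m / norms[:, None]) @ (m / norms[:, None]).T
    a = np.clip(a, 0.0, None)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    out = vectors.copy()
    for g in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, g])))
        if out[i, g] < 0:
            out[:, g] = -out[:, g]
    return out


def diffusion_embedding(
    affinity: np.ndarray,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
    n_components: int = 10,
) -> GradientEmbedding:
    """Diffusion-map embedding of a symmetric non-negative affinity matrix.

    alpha controls the anisotropic density normalization (0.5 balances
    geometry against sampling density); diffusion_time 0 selects the
    multi-scale lambda/(1-lambda) component scaling. The trivial constant
    eigenvector (eigenvalue 1) is discarded; component signs are fixed
    deterministically (largest-magnitude entry positive).
    """
    w = np.asarray(affinity, dtype=float)
    n = w.shape[0]
    if w.shape != (n, n) or np.abs(w - w.T).max() > 1e-10:
        raise ValueError("affinity must be square symmetric")
    if w.min() < 0:
        raise ValueError("affinity must be non-negative")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    n_comp_graph, labels = connected_components(w > 0, directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"affinity graph has {n_comp_graph} connected components "
            f"(sizes {sizes.tolist()}); embed each component separately"
        )
    if n_components >= n:
        raise ValueError("n_components must be smaller than the number of ROIs")
    d = w.sum(axis=1)
    w_alpha = w / np.outer(d**alpha, d**alpha)
    d2 = w_alpha.sum(axis=1)
    # symmetric conjugate of the row-stochastic operator D2^-1 W'
    m = w_alpha / np.sqrt(np.outer(d2, d2))
    evals, evecs = np.linalg.eigh(m)
    order = np.argsort(-evals, kind="stable")
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of the Markov operator
    phi = evecs / np.sqrt(d2)[:, None]
    # drop the trivial stationary component (eigenvalue 1, constant phi)
    lam = evals[1 : n_components + 1]
    phi = phi[:, 1 : n_components + 1]
    if diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam**diffusion_time
    coords = _fix_signs(phi * scale)
    total = lam.sum()
    pseudo_variance = lam / total if total > 0 else np.full_like(lam, np.nan)
    return GradientEmbedding(
        coordinates=coords, eigenvalues=lam, pseudo_variance=pseudo_variance
    )


def embed_matrix(
    prepped: np.ndarray,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
    n_components: int = 10,
) -> GradientEmbedding:
    """cosine_affinity followed by diffusion_embedding."""
    return diffusion_embedding(
        cosine_affinity(prepped),
        alpha=alpha,
        diffusion_time=diffusion_time,
        n_components=n_components,
    )


def procrustes_align(
    subject: GradientEmbedding,
    template: GradientEmbedding,
    source: str = "subject",
):
    """Orthogonal Procrustes: rotate/reflect subject coordinates onto a template.

    No scaling and no centering are applied, so pairwise ROI distances are
    preserved exactly. The transform minimizing the Frobenius distance is
    U V^T from the SVD of X^T Y (subject cross template).
    """
    x, y = subject.coordinates, template.coordinates
    if x.shape != y.shape:
        raise ValueError("subject and template embeddings differ in shape")
    cross = x.T @ y
    if np.linalg.matrix_rank(cross) < cross.shape[0]:
        warnings.warn(
            "rank-deficient cross-product in Procrustes; using pseudo-solution",
            RuntimeWarning,
            stacklevel=2,
        )
    u, _, vt = np.linalg.svd(cross)
    rot = u @ vt
    aligned = replace(subject, coordinates=x @ rot, template_group=template.template_group)
    return aligned, AlignmentTransform(
        rotation=rot, source=source, target=template.template_group
    )


def minmax_scale(embedding: GradientEmbedding, components=(0, 1)) -> GradientEmbedding:
    """Min-max scale selected components to [0, 1] for cross-group comparison."""
    comps = list(components)
    coords = embedding.coordinates[:, comps].copy()
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    if np.any(hi - lo == 0.0):
        bad = [comps[i] for i in np.flatnonzero(hi - lo == 0.0)]
        raise ValueError(f"component(s) {bad} have zero range; cannot min-max scale")
    coords = (coords - lo) / (hi - lo)
    return GradientEmbedding(
        coordinates=coords,
        eigenvalues=embedding.eigenvalues[comps],
        pseudo_variance=embedding.pseudo_variance[comps],
        scaled=True,
        template_group=embedding.template_group,
    )


def group_template(
    prepped_matrices: list,
    group: str,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
    n_components: int = 10,
) -> GradientEmbedding:
    """Template embedding from the entrywise mean of a group's prepped matrices."""
    if len(prepped_matrices) == 0:
        raise ValueError(f"group {group!r} has no subjects")
    mean = np.mean([np.asarray(m, float) for m in prepped_matrices], axis=0)
    emb = embed_matrix(
        mean, alpha=alpha, diffusion_time=diffusion_time, n_components=n_components
    )
    return replace(emb, template_group=group)


class DiffusionGradients(BaseEstimator, TransformerMixin):
    """sklearn-style estimator for diffusion-map connectome gradients.

    ``fit`` builds the template embedding from the entrywise mean of the
    input matrices; ``transform`` embeds each matrix and Procrustes-aligns
    it to that template.

    Attributes
    ----------
    template_ : GradientEmbedding
        Embedding of the mean matrix (fitted template space).
    eigenvalues_, pseudo_variance_ : ndarray
        Spectrum of the template embedding.
    """

    def __init__(
        self,
        alpha: float = 0.5,
        diffusion_time: float = 0.0,
        n_components: int = 10,
        group: str = "template",
    ):
        self.alpha = alpha
        self.diffusion_time = diffusion_time
        self.n_components = n_components
        self.group = group

    def fit(self, X, y=None):
        mats = [np.asarray(m, float) for m in X]
        self.template_ = group_template(
            mats,
            self.group,
            alpha=self.alpha,
            diffusion_time=self.diffusion_time,
            n_components=self.n_components,
        )
        self.eigenvalues_ = self.template_.eigenvalues
        self.pseudo_variance_ = self.template_.pseudo_variance
        self.n_features_in_ = mats[0].shape[0]
        return self

    def transform(self, X):
        out = []
        for m in X:
            emb = embed_matrix(
                np.asarray(m, float),
                alpha=self.alpha,
                diffusion_time=self.diffusion_time,
                n_components=self.n_components,
            )
            aligned, _ = procrustes_align(emb, self.template_)
            out.append(aligned)
        return out
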