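"""PCA of deuterium-positive pixel spectra across uptake cohorts.

Spectra are mean-centred (no variance scaling: they are already
area-normalised and share one intensity scale) and decomposed by SVD.
Component signs are fixed by making the largest-magnitude loading of each
component positive, so scores and loadings are fully reproducible. Cohort
separation on PC1 is summarised as a standardized mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAResult", "fit_pca", "cohort_separation"]


@dataclass
class PCAResult:
    scores: np.ndarray  # n_spectra x n_components
    loadings: np.ndarray  # n_components x n_bins, rows orthonormal
    explained_variance: np.ndarray  # per-component variance (eigenvalues)
    explained_variance_fraction: np.ndarray  # nonincreasing, sums <= 1
    mean: np.ndarray  # the centring spectrum
    labels: np.ndarray | None = None  # cohort label per spectrum


def fit_pca(spectra: np.ndarray, n_components: int, labels=None) -> PCAResult:
    """Mean-centred PCA via SVD.

    Requires n_spectra > n_components >= 1. Deterministic: each component's
    sign is chosen so that its largest-|.| loading is positive.
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2:
        raise ValueError("spectra must be a 2D array (n_spectra x n_bins)")
    n, _ = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n <= n_components:
        raise ValueError(f"need more spectra ({n}) than components ({n_components})")
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape[0] != n:
            raise ValueError("one label per spectrum required")

    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)

    loadings = vt[:n_components]
    scores = u[:, :n_components] * s[:n_components]
    # sign convention: largest-magnitude loading positive
    for i in range(n_components):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]

    eigenvalues = s**2 / (n - 1)
    total = float(eigenvalues.sum())
    fractions = eigenvalues[:n_components] / total if total > 0 else np.zeros(n_components)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance=eigenvalues[:n_components],
        explained_variance_fraction=fractions,
        mean=mean,
        labels=labels,
    )


def cohort_separation(result: PCAResult, label_a, label_b, component: int = 0) -> float:
    """Standardized mean difference of PC scores between two cohorts:
    |mean_a - mean_b| / pooled SD. Symmetric in (a, b); both cohorts need at
    least two members."""
    if result.labels is None:
        raise ValueError("PCA result carries no cohort labels")
    scores = result.scores[:, component]
    a = scores[result.labels == label_a]
    b = scores[result.labels == label_b]
    if a.size < 2 or b.size < 2:
        raise ValueError("each cohort needs at least two spectra")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        return 0.0 if a.mean() == b.mean() else float("inf")
    return float(abs(a.mean() - b.mean()) / np.sqrt(pooled_var))
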