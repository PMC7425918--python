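"""Stage 1 dimension reduction: centered PCA plus backward elimination.

After normalization each dataset is projected onto its principal components;
the trailing (lowest-variance) component is then dropped repeatedly until a
matrix-level one-way ANOVA across the tumor-size classes is significant
(p < alpha).  The loop tests the current width before each drop, so an input
that is already significant is returned untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
from sklearn.decomposition import PCA

from . import selection


@dataclass
class PCAModel:
    """Centered PCA basis with a deterministic sign convention.

    Each component is flipped so that its largest-magnitude loading element is
    positive, making the decomposition reproducible across runs and BLAS
    builds (up to that convention).
    """

    component_loadings: np.ndarray  # (k, n_features), rows orthonormal
    explained_variance: np.ndarray  # non-increasing
    center: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) @ self.component_loadings.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.component_loadings + self.center


@dataclass
class ReducedMatrix:
    """Backward-elimination result: retained score columns and the p-trace."""

    scores: np.ndarray
    retained_count: int
    p_trace: List[Tuple[int, float]] = field(default_factory=list)
    significant: bool = True


def fit_pca(
    matrix: np.ndarray,
    n_components: Optional[int] = None,
    random_state: int = 0,
) -> PCAModel:
    """Standard centered PCA, variance-ordered, sign-fixed.

    Rank-deficient input is handled by truncating to positive-variance
    components.  ``n_components`` caps the retained basis (randomized solver
    for small caps on wide matrices).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("fit_pca requires a 2-D matrix with >= 2 rows and columns")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    solver = "randomized" if (k < min(X.shape) // 5 and min(X.shape) > 200) else "full"
    pca = PCA(n_components=k, svd_solver=solver, random_state=random_state)
    pca.fit(X)
    loadings = pca.components_.copy()
    variances = pca.explained_variance_.copy()
    # drop numerically-zero-variance components (rank deficiency)
    tol = max(variances[0], 0.0) * 1e-12 if variances.size else 0.0
    keep = variances > tol
    loadings, variances = loadings[keep], variances[keep]
    for i in range(loadings.shape[0]):
        if loadings[i, np.argmax(np.abs(loadings[i]))] < 0:
            loadings[i] = -loadings[i]
    return PCAModel(
        component_loadings=loadings,
        explained_variance=variances,
        center=pca.mean_.copy(),
    )


def reduce_by_significance(
    scores: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    min_components: int = 1,
    statistic: Optional[Callable] = None,
) -> ReducedMatrix:
    """Drop trailing PC columns until the class-separation test is significant.

    At each step the matrix-level ANOVA p-value of the current column prefix
    is computed (:func:`msfs.selection.matrix_statistic` by default); the loop
    stops at the first width with ``p < alpha``, else drops the last column.
    If the floor ``min_components`` is reached without significance the floor
    configuration is returned with ``significant=False``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores rows and labels must align")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if statistic is None:
        statistic = selection.matrix_statistic
    p_trace: List[Tuple[int, float]] = []
    ncols = scores.shape[1]
    while True:
        res = statistic(scores[:, :ncols], labels)
        p_trace.append((ncols, float(res.p)))
        if res.p < alpha:
            return ReducedMatrix(scores[:, :ncols], ncols, p_trace, significant=True)
        if ncols <= min_components:
            return ReducedMatrix(scores[:, :ncols], ncols, p_trace, significant=False)
        ncols -= 1
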