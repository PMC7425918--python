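"""Stage 3 statistics: one-way ANOVA ranking and top-k selection.

Candidates (normalization methods in Analysis 1, feature columns in
Analysis 2) are scored with a one-way ANOVA F statistic across the tumor-size
classes; a candidate is admissible when p < alpha and the k admissible
candidates with the highest F are selected.  A whole feature matrix is
collapsed to a single (F, p) pair by standardizing its columns and testing
the per-record row mean (the ``"rowmean"`` mode); a heuristic mean-of-column-F
alternative is available behind the ``mode`` switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int


@dataclass
class SelectionReport:
    """Outcome of one selection round (alpha filter + F ranking)."""

    candidates: List[Tuple[str, AnovaResult]]
    passed_alpha: List[str]
    selected: List[Tuple[str, float]]  # (name, F), F non-increasing
    alpha: float
    k: int
    short: bool = False  # fewer than k candidates passed the alpha filter

    def selected_names(self) -> List[str]:
        return [name for name, _ in self.selected]


def _groups(values: np.ndarray, labels: np.ndarray) -> List[np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and labels must align")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("ANOVA requires at least two classes")
    groups = [values[labels == c] for c in classes]
    if any(g.size < 2 for g in groups):
        raise ValueError("every class needs at least two members")
    return groups


def anova_column(values: np.ndarray, labels: np.ndarray) -> AnovaResult:
    """Classical one-way ANOVA of one scalar column across class labels."""
    groups = _groups(values, labels)
    F, p = stats.f_oneway(*groups)
    n = sum(g.size for g in groups)
    return AnovaResult(
        F=float(F),
        p=float(p),
        df_between=len(groups) - 1,
        df_within=n - len(groups),
    )


def matrix_statistic(
    matrix: np.ndarray, labels: np.ndarray, mode: str = "rowmean"
) -> AnovaResult:
    """Matrix-level (F, p): ANOVA of the standardized row mean.

    Columns are standardized to zero mean and unit (population) sd; constant
    columns are dropped with a warning.  The per-record mean of the
    standardized columns is then tested with :func:`anova_column`.  A
    single-column matrix reduces exactly to ``anova_column``.

    ``mode="mean_f"`` instead averages the per-column F values and reports the
    tail probability of that mean F at the shared degrees of freedom — a
    heuristic summary, not an exact test.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if mode == "mean_f":
        results = [anova_column(X[:, j], labels) for j in range(X.shape[1])]
        mean_f = float(np.mean([r.F for r in results]))
        dfb, dfw = results[0].df_between, results[0].df_within
        return AnovaResult(
            F=mean_f, p=float(stats.f.sf(mean_f, dfb, dfw)), df_between=dfb, df_within=dfw
        )
    if mode != "rowmean":
        raise ValueError(f"unknown matrix_statistic mode {mode!r}")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(
            f"matrix_statistic: dropping {int((~keep).sum())} constant column(s)",
            RuntimeWarning,
        )
    if not np.any(keep):
        raise ValueError("matrix_statistic: all columns are constant")
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    return anova_column(Z.mean(axis=1), labels)


def select_top(
    candidates: Iterable[Tuple[str, AnovaResult]], alpha: float, k: int
) -> SelectionReport:
    """Filter p < alpha, rank by F descending, keep the first k.

    The descending-F sort is stable: candidates with exactly equal F keep
    their input order, so callers control tie placement by enumeration order.
    Fewer than k survivors returns them all with ``short=True``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cand_list = list(candidates)
    passed = [(name, res) for name, res in cand_list if res.p < alpha]
    ranked = sorted(passed, key=lambda item: -item[1].F)  # stable
    selected = [(name, float(res.F)) for name, res in ranked[:k]]
    return SelectionReport(
        candidates=cand_list,
        passed_alpha=[name for name, _ in passed],
        selected=selected,
        alpha=alpha,
        k=k,
        short=len(passed) < k,
    )
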