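"""Stage 4 fusion: SVD collapse of repetition blocks and hybrid assembly.

Each selected feature column spans one value per record; consecutive blocks
of ``block_size`` records share one acquisition configuration (same tumor
size and location, repeated measurements).  A block's rank-1 SVD of its
column is ``sigma * u`` with ``sigma = ||b||`` and ``u = b/||b||``; its scalar
representative is the signed root-mean-square ``sign(mean(b)) * rms(b)``
(non-negative sign when the block mean is exactly zero).  Hybrid datasets
take the first m feature columns in F-rank order; their evaluation F comes
from the matrix-level ANOVA of the repetition-collapsed matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .selection import matrix_statistic


@dataclass
class HybridDataset:
    """Rank-ordered fused feature columns of width m with its evaluation F."""

    columns: Tuple[str, ...]
    values: np.ndarray  # per-record rows x m
    collapsed: np.ndarray  # per-configuration rows x m
    m: int
    eval_F: float
    labels: np.ndarray  # per-record labels
    collapsed_labels: np.ndarray


def collapse_reps(column: np.ndarray, block_size: int) -> np.ndarray:
    """Collapse consecutive repetition blocks to one scalar each.

    Returns ``ceil(len(column) / block_size)`` values; a trailing partial
    block is collapsed as-is with a warning.  The representative of block b
    is ``sign(mean(b)) * sqrt(mean(b**2))``, with + when the mean is 0.
    """
    column = np.asarray(column, dtype=float).ravel()
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n_full, remainder = divmod(column.size, block_size)
    if remainder:
        warnings.warn(
            f"collapse_reps: trailing partial block of {remainder} record(s)",
            RuntimeWarning,
        )
    blocks = [
        column[i * block_size : (i + 1) * block_size]
        for i in range(n_full + (1 if remainder else 0))
    ]
    out = np.empty(len(blocks))
    for i, b in enumerate(blocks):
        rms = np.sqrt(np.mean(b**2))
        sign = 1.0 if b.mean() >= 0 else -1.0
        out[i] = sign * rms
    return out


def _collapse_labels(labels: np.ndarray, block_size: int) -> np.ndarray:
    labels = np.asarray(labels)
    reps = labels.reshape(-1, block_size) if labels.size % block_size == 0 else None
    if reps is not None:
        if not (reps == reps[:, :1]).all():
            raise ValueError("repetition blocks mix class labels; check record order")
        return reps[:, 0]
    n_blocks = int(np.ceil(labels.size / block_size))
    return np.array([labels[i * block_size] for i in range(n_blocks)])


def assemble_hybrid(
    ranked_columns: Sequence[Tuple[str, np.ndarray]],
    m: int,
    labels: np.ndarray,
    block_size: int = 50,
) -> HybridDataset:
    """Fuse the first m rank-ordered feature columns into a hybrid dataset.

    ``ranked_columns`` is the Stage-3 ranking (best first); the hybrid keeps
    that column order.  The evaluation F is the matrix-level ANOVA of the
    repetition-collapsed matrix against the collapsed labels.
    """
    if not 2 <= m <= len(ranked_columns):
        raise ValueError(f"m must lie in [2, {len(ranked_columns)}], got {m}")
    names = tuple(name for name, _ in ranked_columns[:m])
    values = np.column_stack([col for _, col in ranked_columns[:m]])
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("column length and labels must align")
    collapsed = np.column_stack([collapse_reps(values[:, j], block_size) for j in range(m)])
    collapsed_labels = _collapse_labels(labels, block_size)
    eval_F = matrix_statistic(collapsed, collapsed_labels).F
    return HybridDataset(
        columns=names,
        values=values,
        collapsed=collapsed,
        m=m,
        eval_F=float(eval_F),
        labels=labels,
        collapsed_labels=collapsed_labels,
    )


def scan_hybrid_widths(
    ranked_columns: Sequence[Tuple[str, np.ndarray]],
    labels: np.ndarray,
    m_range: Iterable[int] = range(10, 1, -1),
    block_size: int = 50,
    top_n: int = 3,
) -> Tuple[List[Tuple[int, float]], List[int]]:
    """Evaluate hybrid widths and mark the best ``top_n`` by F.

    Returns the list of (m, eval_F) pairs in scan order and the widths of the
    ``top_n`` highest-F hybrids (descending F, stable on ties).
    """
    ms = list(m_range)
    if not ms:
        raise ValueError("m_range must be non-empty")
    if any(m < 2 or m > len(ranked_columns) for m in ms):
        raise ValueError(f"m_range must lie within [2, {len(ranked_columns)}]")
    pairs = [(m, assemble_hybrid(ranked_columns, m, labels, block_size).eval_F) for m in ms]
    top = sorted(pairs, key=lambda mf: -mf[1])[:top_n]
    return pairs, [m for m, _ in top]
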