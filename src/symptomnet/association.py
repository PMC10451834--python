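"""Item-item correlation estimation feeding the network model.

Ordinal questionnaire items are handled with Spearman rank correlation
(average ranks for ties); the same estimator is applied to the
near-continuous intolerance-of-uncertainty dimension scores.  A
positive-definite repair step guarantees the log-determinant objective of
the downstream graphical lasso is finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MIN_EIGENVALUE = 1e-6


@dataclass
class CorrelationEstimate:
    """Symmetric correlation matrix with provenance metadata."""

    matrix: np.ndarray
    labels: list[str]
    method: str = "spearman"
    n: int = 0
    repaired: bool = False

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")


def rank_correlation_matrix(data, items: list[str] | None = None) -> CorrelationEstimate:
    """Pairwise Spearman correlation matrix of the selected items.

    Ties receive average ranks.  Requires >= 10 subjects and >= 2
    non-constant items; a constant column is reported by name.
    """
    cols = items or data.item_labels
    X = data.values[cols].to_numpy(dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError(f"need at least 10 subjects, got {n}")
    if p < 2:
        raise ValueError("need at least 2 items")
    sds = X.std(axis=0)
    if (sds == 0).any():
        bad = [cols[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant column(s), correlation undefined: {bad}")
    # Spearman = Pearson on column-wise average ranks
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    R = np.corrcoef(ranks, rowvar=False)
    R = np.clip(0.5 * (R + R.T), -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return CorrelationEstimate(R, list(cols), "spearman", n=n)


def nearest_positive_definite(
    matrix: np.ndarray, eps: float = MIN_EIGENVALUE
) -> tuple[np.ndarray, bool]:
    """Clip eigenvalues below ``eps`` and rescale back to unit diagonal.

    Returns ``(repaired_matrix, was_repaired)``; an already
    positive-definite input is passed through unchanged.
    """
    m = np.asarray(matrix, dtype=float)
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    if np.linalg.eigvalsh(0.5 * (m + m.T)).min() > eps:
        return m, False
    out = 0.5 * (m + m.T)
    # rescaling to unit diagonal can nudge the spectrum back under the
    # floor, so clip slightly above it and iterate until strictly clear
    for _ in range(100):
        w, v = np.linalg.eigh(out)
        out = (v * np.clip(w, 1.05 * eps, None)) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = 0.5 * (out + out.T)
        np.fill_diagonal(out, 1.0)
        if np.linalg.eigvalsh(out).min() > eps:
            break
    return out, True


def ensure_positive_definite(est: CorrelationEstimate) -> CorrelationEstimate:
    """Return an estimate whose matrix is safely positive definite."""
    fixed, repaired = nearest_positive_definite(est.matrix)
    if not repaired:
        return est
    return CorrelationEstimate(fixed, est.labels, est.method, est.n, repaired=True)
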