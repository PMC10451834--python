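"""Regularized partial-correlation network estimation.

The estimator is the field-standard EBIC graphical lasso: a graphical
lasso is fitted along a logarithmically spaced penalty path and the model
minimizing the extended Bayesian information criterion

    EBIC(lambda) = -2 l(Theta) + E log n + 4 E gamma log p

is selected, where ``E`` counts nonzero upper-triangle precision entries,
``l`` is the Gaussian profile log-likelihood (n/2)(log det Theta -
tr(S Theta)) up to an additive constant, and ``gamma`` (default 0.5)
tunes extra sparsity.  The selected precision matrix is reported as a
weighted network of regularized partial correlations
``w_ij = -theta_ij / sqrt(theta_ii theta_jj)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._solver import glasso
from .association import CorrelationEstimate, ensure_positive_definite, nearest_positive_definite

DEFAULT_GAMMA = 0.5
DEFAULT_N_LAMBDA = 100
DEFAULT_LAMBDA_MIN_RATIO = 0.01
ZERO_TOL = 1e-8


@dataclass
class PrecisionFit:
    """A single penalized precision-matrix fit."""

    theta: np.ndarray
    loglik: float
    lam: float

    @property
    def edge_count(self) -> int:
        p = self.theta.shape[0]
        iu = np.triu_indices(p, k=1)
        return int(np.count_nonzero(self.theta[iu]))

    def partial_correlations(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.theta))
        W = -self.theta / np.outer(d, d)
        np.fill_diagonal(W, 0.0)
        return 0.5 * (W + W.T)


@dataclass
class NetworkModel:
    """Sparse partial-correlation network with selection metadata."""

    nodes: list[str]
    weights: np.ndarray
    lam: float = 0.0
    gamma: float = DEFAULT_GAMMA
    ebic: float = float("nan")
    n: int = 0

    def __post_init__(self) -> None:
        W = self.weights
        if W.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape does not match node list")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        if np.abs(np.diag(W)).max(initial=0.0) > 0:
            raise ValueError("weight matrix diagonal must be zero")

    @property
    def p(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.p, k=1)
        return self.weights[iu]

    def edge_list(self) -> list[tuple[str, str, float]]:
        out = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if w != 0.0:
                    out.append((self.nodes[i], self.nodes[j], float(w)))
        return out

    def submodel(self, nodes: list[str]) -> "NetworkModel":
        idx = [self.nodes.index(nd) for nd in nodes]
        return NetworkModel(
            list(nodes), self.weights[np.ix_(idx, idx)].copy(),
            self.lam, self.gamma, self.ebic, self.n,
        )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "weights": [[float(v) for v in row] for row in self.weights],
            "lambda": float(self.lam),
            "gamma": float(self.gamma),
            "ebic": float(self.ebic) if np.isfinite(self.ebic) else None,
            "edge_count": self.edge_count,
            "n": int(self.n),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        return cls(
            list(d["nodes"]), np.asarray(d["weights"], float),
            d.get("lambda", 0.0), d.get("gamma", DEFAULT_GAMMA),
            d.get("ebic") if d.get("ebic") is not None else float("nan"),
            d.get("n", 0),
        )

    @classmethod
    def from_json(cls, path) -> "NetworkModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# -- single-penalty fit ------------------------------------------------

def glasso_precision(
    S: CorrelationEstimate | np.ndarray,
    lam: float,
    *,
    n: int | None = None,
    warm=None,
) -> PrecisionFit:
    """Graphical lasso at a fixed penalty; the caller must supply a
    positive-definite matrix (see :func:`association.nearest_positive_definite`)."""
    if isinstance(S, CorrelationEstimate):
        mat = S.matrix
    else:
        mat = np.asarray(S, float)
    if np.linalg.eigvalsh(mat).min() <= 0:
        raise ValueError("input matrix is not positive definite; repair it first")
    theta, W, B = glasso(mat, lam, zero_tol=ZERO_TOL, warm=warm)
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise ValueError("estimated precision is not positive definite")
    ll = logdet - float(np.sum(mat * theta))
    fit = PrecisionFit(theta, ll, lam)
    fit._warm = (W, B)  # reusable warm start at the next (smaller) penalty
    return fit


def ebic(
    fit: PrecisionFit,
    n: int,
    gamma: float = DEFAULT_GAMMA,
    p: int | None = None,
) -> float:
    """Extended BIC of a fit: ``-2 l + E log n + 4 E gamma log p``."""
    p = p or fit.theta.shape[0]
    E = fit.edge_count
    ll = 0.5 * n * fit.loglik
    return float(-2.0 * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p))


# -- path estimation ---------------------------------------------------

def lambda_path(
    S: np.ndarray,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> np.ndarray:
    """Log-spaced penalty grid from max off-diagonal |S| downward."""
    p = S.shape[0]
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = float(off.max())
    if lam_max <= 0:
        return np.zeros(1)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def estimate_network(
    data_or_S,
    items: list[str] | None = None,
    gamma: float = DEFAULT_GAMMA,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> NetworkModel:
    """Estimate a partial-correlation network with EBIC model selection.

    Accepts either an :class:`~symptomnet.datasets.ItemDataset` (a Spearman
    correlation matrix is computed internally) or a ready
    :class:`CorrelationEstimate`.  Ties in EBIC break toward the larger
    penalty, i.e. the sparser model.
    """
    if isinstance(data_or_S, CorrelationEstimate):
        est = data_or_S
    else:
        from .association import rank_correlation_matrix

        est = rank_correlation_matrix(data_or_S, items)
    est = ensure_positive_definite(est)
    if est.n <= 1:
        raise ValueError("correlation estimate must carry its sample size n")
    labels = est.labels
    p = len(labels)
    if p < 3:
        raise ValueError("need at least 3 nodes")
    W, lam, eb = _ebic_path_select(
        est.matrix, est.n, gamma, n_lambda, lambda_min_ratio
    )
    return NetworkModel(labels, W, lam, gamma, eb, est.n)


def _ebic_path_select(S, n, gamma, n_lambda, lambda_min_ratio):
    """Fit the penalty path (warm-started, decreasing) and select min EBIC.

    Lean inner loop shared by the public estimator and the resampling hot
    paths: positive definiteness is verified once up front and the EBIC is
    accumulated inline rather than through the per-fit containers.
    """
    from ._solver import GlassoNonConvergence, _ebic_path

    S = np.ascontiguousarray(S, dtype=np.float64)
    p = S.shape[0]
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError("input matrix is not positive definite; repair it first")
    path = lambda_path(S, n_lambda, lambda_min_ratio)
    if path[0] == 0.0:  # no off-diagonal signal at all: empty graph
        return np.zeros_like(S), 0.0, ebic(glasso_precision(S, 0.0), n, gamma, p)
    theta, lam, crit, gap = _ebic_path(
        S, path, float(n), float(gamma), 1e-6, 500, ZERO_TOL
    )
    if not np.isfinite(gap) or gap >= 1e-6:
        raise GlassoNonConvergence(gap, 500)
    d = np.sqrt(np.diag(theta))
    W = -theta / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    W = 0.5 * (W + W.T)
    return W, float(lam), float(crit)


def _fast_network_weights(
    X: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> np.ndarray:
    """Hot-loop variant for resampling: raw matrix in, weight matrix out.

    Identical estimator settings to :func:`estimate_network`, minus the
    container plumbing.  Used by the bootstrap and permutation routines,
    which re-estimate the model tens of thousands of times.  An item that
    is constant within a resample carries no rank information; its
    correlations are set to zero (it simply acquires no edges) instead of
    failing the whole resample.
    """
    ranks = stats.rankdata(X, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.corrcoef(ranks, rowvar=False)
    S = np.nan_to_num(S, nan=0.0)
    S = np.clip(0.5 * (S + S.T), -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    S, _ = nearest_positive_definite(S)
    W, _, _ = _ebic_path_select(S, X.shape[0], gamma, n_lambda, lambda_min_ratio)
    return W


# -- covariate adjustment and similarity -------------------------------

def covariate_adjusted_network(
    data,
    covariate: str,
    items: list[str] | None = None,
    gamma: float = DEFAULT_GAMMA,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> NetworkModel:
    """Estimate the network with one covariate included as an extra node,
    then return the symptom-by-symptom submatrix of weights."""
    import pandas as pd

    from .association import rank_correlation_matrix
    from .datasets import ItemDataset

    if data.covariates is None or covariate not in data.covariates.columns:
        raise ValueError(f"covariate {covariate!r} not present")
    cov = data.covariates[covariate]
    if cov.nunique() < 2:
        raise ValueError(f"covariate {covariate!r} is constant")
    cols = items or data.item_labels
    aug_values = data.values[cols].copy()
    aug = pd.concat([aug_values, cov.rename(covariate)], axis=1)
    # rank correlation tolerates the unrestricted covariate scale, so reuse
    # the estimator on a plain frame rather than the validated container
    X = aug.to_numpy(dtype=float)
    ranks = stats.rankdata(X, axis=0)
    S = np.corrcoef(ranks, rowvar=False)
    S = np.clip(0.5 * (S + S.T), -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    est = CorrelationEstimate(S, list(cols) + [covariate], "spearman", n=len(aug))
    full = estimate_network(est, gamma=gamma, n_lambda=n_lambda,
                            lambda_min_ratio=lambda_min_ratio)
    return full.submodel(list(cols))


def network_similarity(a: NetworkModel, b: NetworkModel) -> tuple[float, float]:
    """Pearson correlation (r, p) of the vectorized edge weights of two
    networks over the same node set."""
    if a.nodes != b.nodes:
        raise ValueError("networks must share node set and order")
    x = a.upper_triangle()
    y = b.upper_triangle()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("similarity undefined: an edge-weight vector is constant")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
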