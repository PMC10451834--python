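"""Bootstrap accuracy and stability diagnostics for estimated networks.

Two resampling schemes are provided.  The nonparametric bootstrap draws
subjects with replacement and re-estimates the network with identical
settings, yielding percentile confidence intervals for every edge weight
and percentile difference tests between edges and between node
centralities.  The case-dropping bootstrap re-estimates the network on
progressively smaller random subsets and summarizes how well subset
centralities correlate with the full-sample ones; its headline number is
the correlation-stability (CS) coefficient: the largest fraction of cases
that can be dropped while the correlation stays >= 0.7 with 95%
probability (0.25 is conventionally acceptable, 0.5 preferred).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .estimation import (
    DEFAULT_GAMMA,
    DEFAULT_LAMBDA_MIN_RATIO,
    DEFAULT_N_LAMBDA,
    _fast_network_weights,
)

DEFAULT_DROPS = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))


@dataclass
class EstimatorConfig:
    """Settings shared by every re-estimation inside a resampling run."""

    gamma: float = DEFAULT_GAMMA
    n_lambda: int = DEFAULT_N_LAMBDA
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO

    def weights(self, X: np.ndarray) -> np.ndarray:
        return _fast_network_weights(
            X, self.gamma, self.n_lambda, self.lambda_min_ratio
        )


@dataclass
class EdgeStabilityReport:
    """Per-edge bootstrap summary plus the raw per-resample draws."""

    nodes: list[str]
    edge_index: list[tuple[int, int]]
    sample: np.ndarray            # observed edge weights, len n_edges
    draws: np.ndarray             # B x n_edges bootstrap edge weights
    strength_draws: np.ndarray    # B x p node strengths
    ei_draws: np.ndarray          # B x p expected influences
    n_skipped: int = 0
    seed: int | None = None

    @property
    def B(self) -> int:
        return self.draws.shape[0]

    def edge_labels(self) -> list[str]:
        return [f"{self.nodes[i]}--{self.nodes[j]}" for i, j in self.edge_index]

    def summary(self) -> dict:
        lo, hi = np.percentile(self.draws, [2.5, 97.5], axis=0)
        return {
            "edges": self.edge_labels(),
            "sample": self.sample.tolist(),
            "boot_mean": self.draws.mean(axis=0).tolist(),
            "ci_lower": lo.tolist(),
            "ci_upper": hi.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1, sort_keys=True)


def _edge_vector(W: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(W.shape[0], k=1)
    return W[iu]


def bootstrap_edge_cis(
    data,
    config: EstimatorConfig | None = None,
    B: int = 1000,
    seed: int = 0,
    items: list[str] | None = None,
) -> EdgeStabilityReport:
    """Nonparametric bootstrap of the network's edge weights.

    Subjects are resampled with replacement ``B`` times and the network
    re-estimated with identical settings each time.  A resample whose
    estimation fails is skipped and counted (reported loudly if more than
    1% are lost).
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstrap resamples")
    config = config or EstimatorConfig()
    cols = items or data.item_labels
    X = data.values[cols].to_numpy(dtype=float)
    n, p = X.shape
    W_obs = config.weights(X)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(p, k=1)
    draws, s_draws, e_draws = [], [], []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            W = config.weights(X[idx])
        except Exception:
            skipped += 1
            continue
        draws.append(W[iu])
        s_draws.append(np.abs(W).sum(axis=1))
        e_draws.append(W.sum(axis=1))
    if skipped > 0.01 * B:
        import logging

        logging.getLogger(__name__).warning(
            "bootstrap_edge_cis: %d/%d resamples failed estimation", skipped, B
        )
    return EdgeStabilityReport(
        list(cols),
        list(zip(*iu)),
        W_obs[iu],
        np.array(draws),
        np.array(s_draws),
        np.array(e_draws),
        n_skipped=skipped,
        seed=seed,
    )


@dataclass
class DifferenceTests:
    """Pairwise percentile difference tests from bootstrap draws.

    ``edge_sig[a, b]`` is True when the 95% bootstrap CI of
    ``edge_a - edge_b`` excludes zero; likewise for node strength and
    expected influence.  The matrices are symmetric with a False diagonal.
    """

    edge_sig: np.ndarray
    strength_sig: np.ndarray
    ei_sig: np.ndarray


def _pairwise_sig(draws: np.ndarray, level: float = 95.0) -> np.ndarray:
    k = draws.shape[1]
    lo_q = (100.0 - level) / 2.0
    hi_q = 100.0 - lo_q
    sig = np.zeros((k, k), dtype=bool)
    for a in range(k):
        diffs = draws[:, a][:, None] - draws[:, a + 1 :]
        if diffs.shape[1] == 0:
            continue
        lo, hi = np.percentile(diffs, [lo_q, hi_q], axis=0)
        flag = (lo > 0) | (hi < 0)
        sig[a, a + 1 :] = flag
        sig[a + 1 :, a] = flag
    return sig


def bootstrap_difference_tests(report: EdgeStabilityReport) -> DifferenceTests:
    """Edge-edge and node-node bootstrap difference tests at the 95% level."""
    return DifferenceTests(
        _pairwise_sig(report.draws),
        _pairwise_sig(report.strength_draws),
        _pairwise_sig(report.ei_draws),
    )


# -- case-dropping stability -------------------------------------------

@dataclass
class CSCurve:
    """Case-dropping stability curve for one centrality index."""

    index: str
    drop_proportions: list[float]
    mean_correlation: list[float]
    prob_above: list[float]
    correlations: list[np.ndarray] = field(default_factory=list)
    r_threshold: float = 0.7
    prob: float = 0.95
    seed: int | None = None
    skipped_fractions: list[float] = field(default_factory=list)

    @property
    def cs_coefficient(self) -> float:
        return cs_coefficient(self, self.r_threshold, self.prob)

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "drop_proportions": self.drop_proportions,
            "mean_correlation": self.mean_correlation,
            "prob_above": self.prob_above,
            "cs_coefficient": self.cs_coefficient,
            "r_threshold": self.r_threshold,
            "prob": self.prob,
        }


def _centrality_vec(W: np.ndarray, index: str) -> np.ndarray:
    if index == "strength":
        return np.abs(W).sum(axis=1)
    if index in ("ei", "expected_influence"):
        return W.sum(axis=1)
    raise ValueError(f"unknown centrality index {index!r}")


def case_dropping_curve(
    data,
    config: EstimatorConfig | None = None,
    index: str = "strength",
    drops: tuple[float, ...] = DEFAULT_DROPS,
    B: int = 1000,
    seed: int = 0,
    items: list[str] | None = None,
) -> CSCurve:
    """Case-dropping bootstrap of a centrality index.

    At each drop fraction, ``B`` subject subsets are drawn without
    replacement, the network re-estimated, and the Pearson correlation of
    subset vs full-sample centralities recorded.  Fractions whose retained
    subset would fall below ``p + 5`` subjects are skipped with a warning.
    """
    config = config or EstimatorConfig()
    cols = items or data.item_labels
    X = data.values[cols].to_numpy(dtype=float)
    n, p = X.shape
    c_full = _centrality_vec(config.weights(X), index)
    rng = np.random.default_rng(seed)
    fracs, means, probs, all_corrs, skipped = [], [], [], [], []
    for frac in drops:
        keep = int(round(n * (1.0 - frac)))
        if keep < p + 5:
            skipped.append(float(frac))
            continue
        corrs = np.full(B, np.nan)
        for b in range(B):
            idx = rng.choice(n, size=keep, replace=False)
            try:
                c_sub = _centrality_vec(config.weights(X[idx]), index)
            except Exception:
                continue  # non-converged subset: excluded from the curve
            if np.std(c_sub) == 0 or np.std(c_full) == 0:
                corrs[b] = 0.0
            else:
                corrs[b] = np.corrcoef(c_full, c_sub)[0, 1]
        good = corrs[~np.isnan(corrs)]
        if len(good) < B / 2:
            skipped.append(float(frac))
            continue
        fracs.append(float(frac))
        means.append(float(np.mean(good)))
        probs.append(float(np.mean(good >= 0.7)))
        all_corrs.append(good)
    if skipped:
        import logging

        logging.getLogger(__name__).warning(
            "case_dropping_curve: skipped fractions %s (subset below p + 5)", skipped
        )
    return CSCurve(
        index, fracs, means, probs, all_corrs, seed=seed, skipped_fractions=skipped
    )


def cs_coefficient(curve: CSCurve, r_threshold: float = 0.7, prob: float = 0.95) -> float:
    """Largest drop fraction whose P(correlation >= r_threshold) clears
    ``prob``; 0 when no fraction qualifies.

    When the curve retains its raw per-subset correlations, any
    ``r_threshold`` can be evaluated; otherwise only the threshold the
    curve was built with (via ``prob_above``) is available.
    """
    if not curve.drop_proportions:
        raise ValueError("empty stability curve")
    if curve.correlations:
        probs = [float(np.mean(c >= r_threshold)) for c in curve.correlations]
    elif r_threshold == curve.r_threshold:
        probs = curve.prob_above
    else:
        raise ValueError(
            "curve carries no raw correlations; only r_threshold="
            f"{curve.r_threshold} can be evaluated"
        )
    best = 0.0
    for frac, pa in zip(curve.drop_proportions, probs):
        if pa >= prob and frac > best:
            best = frac
    return best
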