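"""Synthetic ordinal questionnaire data with known network structure.

The generative model is the standard latent-Gaussian threshold model for
ordinal psychometric items: a ground-truth sparse partial-correlation
network implies a latent multivariate-normal correlation structure;
latent draws are discretized item-by-item into PHQ-style 0-3 categories
(or affinely mapped to the 1-5 scale for the intolerance-of-uncertainty
dimension scores).  Default thresholds are calibrated so the marginal
means and SDs emulate a right-skewed adolescent depression sample.

A controllable between-group difference is injected by multiplying every
true edge weight by a common factor for the second group — the minimal
mechanism that shifts global strength without changing which edges exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import DEFAULT_ITEMS, IU_ITEMS, PHQ_ITEMS, ItemDataset

# Marginal (mean, SD) targets per item for the default calibration:
# a right-skewed undergraduate/adolescent profile in which somatic items
# sit near 0.6-0.8 on the 0-3 scale and suicidal ideation is rarest.
DEFAULT_MARGINALS: dict[str, tuple[float, float]] = {
    "PHQ1": (0.77, 0.83),
    "PHQ2": (0.70, 0.79),
    "PHQ3": (0.64, 0.87),
    "PHQ4": (0.81, 0.87),
    "PHQ5": (0.62, 0.83),
    "PHQ6": (0.57, 0.82),
    "PHQ7": (0.71, 0.87),
    "PHQ8": (0.49, 0.76),
    "PHQ9": (0.27, 0.61),
    "AA": (2.54, 0.79),
    "IA": (2.41, 0.82),
}

MIN_EIG_TARGET = 0.05
PARTIAL_MATCH_TOL = 0.02


class ConstructiveFailure(RuntimeError):
    """The requested network spec admits no positive-definite realization."""


@dataclass
class TrueNetworkSpec:
    """Recipe for a random sparse ground-truth network."""

    p: int = 9
    density: float = 0.3
    weight_range: tuple[float, float] = (0.2, 0.4)
    sign_mix: float = 0.0
    seed: int = 0
    scalable_to: float = 1.0  # guarantee PD after scaling edges by this factor


@dataclass
class TrueNetwork:
    """Realized ground truth: partial-correlation weights, the unit-diagonal
    precision that encodes them, and the implied latent correlation."""

    weights: np.ndarray
    precision: np.ndarray
    correlation: np.ndarray

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def global_strength(self) -> float:
        iu = np.triu_indices(self.p, k=1)
        return float(np.abs(self.weights[iu]).sum())

    def scaled(self, factor: float) -> "TrueNetwork":
        """Truth with every edge weight multiplied by ``factor``; raises if
        the scaled precision is no longer positive definite."""
        return _network_from_partials(self.weights * factor, inflate=False, margin=0.01)


def _network_from_partials(
    P: np.ndarray,
    inflate: bool = True,
    margin: float = MIN_EIG_TARGET,
    tol: float = PARTIAL_MATCH_TOL,
) -> TrueNetwork:
    """Build the precision/correlation pair realizing target partials ``P``.

    A unit-diagonal precision with off-diagonals ``-P`` realizes the
    targets exactly whenever ``I - P`` is positive definite (any rescaled
    precision standardizes back to ``I - P``, so this is the only degree of
    freedom).  When the smallest eigenvalue falls below ``margin`` the
    targets are shrunk uniformly to the feasibility boundary; if the shrink
    moves any partial correlation by more than ``tol`` the spec is declared
    infeasible.  With ``inflate=False`` an indefinite start raises instead
    (used when scaling an existing truth, where the contract is exact
    edge-weight multiplication).
    """
    p = P.shape[0]
    target = P.copy()
    np.fill_diagonal(target, 0.0)
    target = 0.5 * (target + target.T)
    eigs = np.linalg.eigvalsh(target)
    lam_min = 1.0 - float(eigs.max())  # min eigenvalue of I - P
    if lam_min < margin:
        if not inflate:
            raise ConstructiveFailure(
                "scaled precision loses positive definiteness; use a "
                "smaller scale factor or weaker base weights"
            )
        shrink = (1.0 - margin) / float(eigs.max())
        err = (1.0 - shrink) * float(np.abs(target).max())
        if err > tol:
            raise ConstructiveFailure(
                f"target partial correlations are infeasible: realizing them "
                f"within a positive-definite precision would move an edge by "
                f"{err:.3f} (> {tol})"
            )
        target = shrink * target
    omega = np.eye(p) - target
    sigma = np.linalg.inv(omega)
    ds = np.sqrt(np.diag(sigma))
    sigma = sigma / np.outer(ds, ds)
    sigma = 0.5 * (sigma + sigma.T)
    np.fill_diagonal(sigma, 1.0)
    return TrueNetwork(target, omega, sigma)


def make_true_network(spec: TrueNetworkSpec, max_attempts: int = 50) -> TrueNetwork:
    """Sample a sparse ground-truth network from a spec.

    Edge positions are drawn without replacement so the realized density
    is exactly ``round(density * C(p,2))`` edges; weights are uniform in
    magnitude over ``weight_range`` with sign negative with probability
    ``sign_mix``.  A draw whose precision cannot be made positive definite
    within tolerance is rejected and redrawn (deterministically from the
    spec seed); specs where every attempt fails - e.g. full density with
    large weights - raise :class:`ConstructiveFailure`.
    """
    if spec.p < 3:
        raise ValueError("need at least 3 nodes")
    if not 0.0 <= spec.density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    p = spec.p
    iu = np.column_stack(np.triu_indices(p, k=1))
    n_edges = int(round(spec.density * len(iu)))
    last_err: ConstructiveFailure | None = None
    for child in np.random.SeedSequence(spec.seed).spawn(max_attempts):
        rng = np.random.default_rng(child)
        P = np.zeros((p, p))
        if n_edges:
            chosen = rng.choice(len(iu), size=n_edges, replace=False)
            lo, hi = spec.weight_range
            mags = rng.uniform(lo, hi, size=n_edges)
            signs = np.where(rng.random(n_edges) < spec.sign_mix, -1.0, 1.0)
            for (i, j), w in zip(iu[chosen], mags * signs):
                P[i, j] = P[j, i] = w
        try:
            truth = _network_from_partials(P)
            if spec.scalable_to > 1.0:
                truth.scaled(spec.scalable_to)  # raises when scaling breaks PD
            return truth
        except ConstructiveFailure as exc:
            last_err = exc
    raise ConstructiveFailure(
        f"no positive-definite realization found in {max_attempts} draws: {last_err}"
    )


# -- ordinal emulation -------------------------------------------------

@dataclass
class OrdinalEmulationSpec:
    """How latent draws become questionnaire columns.

    ``thresholds`` maps each ordinal (PHQ-style) item to its strictly
    increasing latent cut points (3 cuts -> categories 0..3); ``iu_scale``
    maps each continuous 1-5 item to the (mean, sd) of its affine
    transform.  Items absent from both maps are returned on the latent
    scale unchanged.
    """

    item_labels: list[str]
    n: int = 500
    thresholds: dict[str, np.ndarray] = field(default_factory=dict)
    iu_scale: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for item, t in self.thresholds.items():
            t = np.asarray(t, float)
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"thresholds for {item!r} must be strictly increasing")
            self.thresholds[item] = t


def calibrate_thresholds(mean: float, sd: float) -> np.ndarray:
    """Latent cut points putting a 4-category item at the given mean/SD.

    Models the item as a rounded latent severity ``mu + sigma * Z`` cut at
    0.5, 1.5, 2.5 and solves for (mu, sigma); the three standardized cut
    points are returned.  This two-parameter family reproduces the
    right-skewed marginals typical of community PHQ data.
    """
    cuts = np.array([0.5, 1.5, 2.5])

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        q = stats.norm.cdf((mu - cuts) / sigma)  # P(X > k)
        m = q.sum()
        m2 = q[0] + 3 * q[1] + 5 * q[2]
        var = m2 - m * m
        return np.array([m - mean, np.sqrt(max(var, 1e-12)) - sd])

    sol = optimize.root(moments, x0=np.array([mean, 0.0]), method="hybr")
    if not sol.success:  # pragma: no cover - targets are always feasible here
        raise RuntimeError(f"threshold calibration failed for mean={mean}, sd={sd}")
    mu, log_sigma = sol.x
    return (cuts - mu) / np.exp(log_sigma)


def default_emulation(
    p: int = 11, n: int = 500, item_labels: list[str] | None = None
) -> OrdinalEmulationSpec:
    """Default emulation: PHQ items thresholded to their calibrated skewed
    marginals, AA/IA mapped affinely onto the 1-5 scale.

    For ``p`` = 9 the labels are the PHQ items; for ``p`` = 11 the two
    intolerance-of-uncertainty dimensions are appended; other sizes get
    generic ordinal items sharing a mid-severity PHQ marginal.
    """
    if item_labels is None:
        if p == 9:
            item_labels = list(PHQ_ITEMS)
        elif p == 11:
            item_labels = list(DEFAULT_ITEMS)
        else:
            item_labels = [f"V{i + 1}" for i in range(p)]
    thresholds = {}
    iu_scale = {}
    for lab in item_labels:
        if lab in IU_ITEMS:
            iu_scale[lab] = DEFAULT_MARGINALS[lab]
        else:
            m, s = DEFAULT_MARGINALS.get(lab, (0.65, 0.84))
            thresholds[lab] = calibrate_thresholds(m, s)
    return OrdinalEmulationSpec(item_labels, n, thresholds, iu_scale)


def sample_ordinal_dataset(
    truth: TrueNetwork,
    emulation: OrdinalEmulationSpec,
    seed: int,
    group_label: str | None = None,
) -> ItemDataset:
    """Draw a dataset from the truth under the emulation spec.

    Latent rows are multivariate normal with the implied correlation;
    ordinal items are discretized by their thresholds, 1-5 items mapped by
    ``clip(mean + sd * z, 1, 5)``.  Fully deterministic given the seed.
    """
    labels = emulation.item_labels
    if truth.p != len(labels):
        raise ValueError("truth dimension does not match emulation item labels")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(truth.correlation)
    Z = rng.standard_normal((emulation.n, truth.p)) @ L.T
    cols = {}
    for j, lab in enumerate(labels):
        z = Z[:, j]
        if lab in emulation.thresholds:
            cols[lab] = np.digitize(z, emulation.thresholds[lab]).astype(float)
        elif lab in emulation.iu_scale:
            m, s = emulation.iu_scale[lab]
            cols[lab] = np.clip(m + s * z, 1.0, 5.0)
        else:
            cols[lab] = z
    values = pd.DataFrame(cols, columns=labels)
    group = (
        pd.Series([group_label] * emulation.n, name="group")
        if group_label is not None
        else None
    )
    return ItemDataset(values, group)


def make_two_group_study(
    truth: TrueNetwork,
    emulation: OrdinalEmulationSpec,
    group_scale: float = 1.0,
    n_a: int = 439,
    n_b: int = 1049,
    seed: int = 0,
    labels: tuple[str, str] = ("urban", "rural"),
) -> tuple[ItemDataset, ItemDataset]:
    """Two-group study design: group A from the truth, group B from the
    truth with every edge weight multiplied by ``group_scale``.

    Default sizes mirror a markedly unbalanced urban/rural survey
    (439 vs 1049 subjects).
    """
    truth_b = truth if group_scale == 1.0 else truth.scaled(group_scale)
    em_a = OrdinalEmulationSpec(
        emulation.item_labels, n_a, dict(emulation.thresholds), dict(emulation.iu_scale)
    )
    em_b = OrdinalEmulationSpec(
        emulation.item_labels, n_b, dict(emulation.thresholds), dict(emulation.iu_scale)
    )
    ss = np.random.SeedSequence(seed).spawn(2)
    a = sample_ordinal_dataset(truth, em_a, ss[0], group_label=labels[0])
    b = sample_ordinal_dataset(truth_b, em_b, ss[1], group_label=labels[1])
    return a, b


def concatenate_groups(a: ItemDataset, b: ItemDataset) -> ItemDataset:
    """Stack two group datasets into one labelled dataset."""
    values = pd.concat([a.values, b.values], ignore_index=True)
    if a.group is None or b.group is None:
        raise ValueError("both datasets must carry group labels")
    group = pd.concat([a.group, b.group], ignore_index=True)
    cov = None
    if a.covariates is not None and b.covariates is not None:
        cov = pd.concat([a.covariates, b.covariates], ignore_index=True)
    return ItemDataset(values, group, cov)
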