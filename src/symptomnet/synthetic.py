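"""Synthetic ordinal cohorts with a prescribed partial-correlation network.

The generative model is a Gaussian copula: latent scores are drawn from
a multivariate normal whose correlation matrix implies exactly the
requested partial-correlation network, then each item is discretized at
its latent thresholds. This is precisely the model under which
polychoric estimation is consistent, so pipeline-recovery experiments
on these cohorts are fair tests of the estimator rather than of model
misspecification.

Item thresholds can be given directly or calibrated to target
(mean, sd) moments on the observed 0..K-1 scale. Under latent-normal
discretization every K-point category distribution is reachable, so
calibration works in probability space: a maximum-entropy pmf
p_k proportional to exp(a k + b k^2) matches the mean exactly and the sd as
closely as the integer support allows (the residual is reported, since
published SDs are sometimes infeasible for integer scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root
from scipy.special import ndtri

from .network import NetworkModel
from .polychoric import ThresholdSet
from .scales import DEFAULT_SCALES, ResponseMatrix

__all__ = [
    "CohortSpec",
    "InfeasibleMomentsError",
    "network_to_latent_sigma",
    "calibrate_thresholds",
    "simulate_cohort",
]

class InfeasibleMomentsError(ValueError):
    """The (mean, sd) target cannot be realized on the integer support."""

    def __init__(self, mean, sd, sd_lo, sd_hi):
        self.feasible_sd = (sd_lo, sd_hi)
        super().__init__(
            f"sd={sd:.4g} infeasible for mean={mean:.4g}; "
            f"feasible sd interval is [{sd_lo:.4g}, {sd_hi:.4g}]"
        )


def network_to_latent_sigma(net: NetworkModel | np.ndarray, shrink: float = 1.0) -> np.ndarray:
    """Latent correlation matrix whose partial correlations equal the network.

    Builds the precision K with unit diagonal and K_ij = -w_ij (optionally
    shrunk by ``shrink``), inverts it, and rescales to a correlation
    matrix. Partial correlations are invariant to that rescaling, so the
    round trip is exact. Raises if the implied precision is not positive
    definite (the caller may retry with ``shrink < 1``).
    """
    W = net.weights if isinstance(net, NetworkModel) else np.asarray(net, dtype=float)
    K = np.eye(W.shape[0]) - shrink * W
    eigmin = float(np.linalg.eigvalsh(K).min())
    if eigmin <= 0:
        raise ValueError(
            f"implied precision is not positive definite (min eigenvalue {eigmin:.3e}); "
            "shrink the edge weights"
        )
    sigma = np.linalg.inv(K)
    d = np.sqrt(np.diag(sigma))
    sigma = sigma / np.outer(d, d)
    sigma = (sigma + sigma.T) / 2.0
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _maxent_pmf(K: int, mean: float, var: float) -> np.ndarray:
    """p_k proportional to exp(a k + b k^2) on {0..K-1} matching (mean, var)."""
    k = np.arange(K, dtype=float)

    def moments(params):
        a, b = params
        logits = a * k + b * k * k
        logits -= logits.max()
        p = np.exp(logits)
        p /= p.sum()
        m = p @ k
        v = p @ (k - m) ** 2
        return np.array([m - mean, v - var]), p

    def fun(params):
        return moments(params)[0]

    # start from a discretized-normal guess
    x0 = np.array([mean / max(var, 1e-3), -1.0 / (2.0 * max(var, 1e-3))])
    sol = root(fun, x0, method="hybr", tol=1e-12)
    if not sol.success:
        for scale in (0.1, 1.0, 10.0):
            sol = root(fun, x0 * scale, method="hybr", tol=1e-12)
            if sol.success:
                break
    _, p = moments(sol.x)
    return p


def calibrate_thresholds(
    mean: float,
    sd: float,
    n_categories: int,
    item_id: str = "item",
    on_infeasible: str = "clip",
) -> tuple[ThresholdSet, float]:
    """Latent thresholds whose discretized distribution has the target moments.

    Returns ``(thresholds, sd_residual)`` where the residual is the
    achieved sd minus the target. The mean is matched to ~1e-6; the sd is
    matched exactly when feasible and clipped to the nearest feasible
    value otherwise (``on_infeasible="error"`` raises instead, naming the
    feasible sd interval).
    """
    K = int(n_categories)
    if K < 2:
        raise ValueError("need at least two categories")
    if not 0.0 <= mean <= K - 1:
        raise ValueError(f"mean must lie in [0, {K - 1}]")
    if sd <= 0:
        raise ValueError("sd must be positive")
    frac = mean - np.floor(mean)
    v_min = frac * (1.0 - frac)  # two adjacent support points
    v_max = mean * (K - 1 - mean)  # all mass at the extremes
    target_var = sd * sd
    lo, hi = float(np.sqrt(v_min)), float(np.sqrt(v_max))
    if not (v_min - 1e-12 <= target_var <= v_max + 1e-12):
        if on_infeasible == "error":
            raise InfeasibleMomentsError(mean, sd, lo, hi)
        # clip strictly inside the feasible interval so the maxent solve stays interior
        width = max(v_max - v_min, 1e-12)
        target_var = float(np.clip(target_var, v_min + 1e-4 * width, v_max - 1e-4 * width))
    else:
        width = max(v_max - v_min, 1e-12)
        target_var = float(np.clip(target_var, v_min + 1e-6 * width, v_max - 1e-6 * width))

    p = _maxent_pmf(K, mean, target_var)
    achieved_sd = float(np.sqrt(p @ (np.arange(K) - p @ np.arange(K)) ** 2))
    residual = achieved_sd - sd

    cum = np.cumsum(p)[:-1]
    # all K-1 cuts are kept so category codes keep their face values;
    # (numerically) empty categories get epsilon-width latent intervals
    cuts = []
    prev = -np.inf
    for c in cum:
        t = float(ndtri(np.clip(c, 1e-12, 1.0 - 1e-12)))
        if t <= prev:
            t = prev + 1e-9
        cuts.append(t)
        prev = t
    return ThresholdSet(item_id=item_id, thresholds=tuple(cuts)), float(residual)


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``latent_sigma`` is the latent correlation matrix (e.g. from
    :func:`network_to_latent_sigma`); ``thresholds`` maps each item to
    its :class:`~symptomnet.polychoric.ThresholdSet`. Items are emitted
    in ``item_ids`` order, scored 0..K_i-1.
    """

    n: int
    item_ids: tuple[str, ...]
    latent_sigma: np.ndarray
    thresholds: dict[str, ThresholdSet]
    seed: int = 0
    sd_residuals: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        S = np.asarray(self.latent_sigma, dtype=float)
        p = len(self.item_ids)
        if S.shape != (p, p):
            raise ValueError("latent_sigma shape does not match item count")
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ValueError("latent_sigma must be positive definite")
        missing = [i for i in self.item_ids if i not in self.thresholds]
        if missing:
            raise ValueError(f"items without thresholds: {missing}")
        self.latent_sigma = S

    @classmethod
    def from_network_and_moments(
        cls,
        net: NetworkModel,
        moments: pd.DataFrame,
        n: int,
        seed: int = 0,
        category_counts: dict[str, int] | None = None,
    ) -> "CohortSpec":
        """Build a spec from a network plus per-item (mean, sd) targets.

        ``moments`` is indexed by item id with columns ``mean`` and ``sd``.
        ``category_counts`` maps item -> K (defaults: 7 for MBI*, 4 for PHQ*).
        """
        sigma = network_to_latent_sigma(net)
        thresholds: dict[str, ThresholdSet] = {}
        residuals: dict[str, float] = {}
        for item in net.node_ids:
            if category_counts and item in category_counts:
                K = category_counts[item]
            elif item.upper().startswith("MBI"):
                K = 7
            elif item.upper().startswith("PHQ"):
                K = 4
            else:
                raise ValueError(f"cannot infer category count for {item!r}")
            ts, res = calibrate_thresholds(
                float(moments.loc[item, "mean"]), float(moments.loc[item, "sd"]), K, item_id=item
            )
            thresholds[item] = ts
            residuals[item] = res
        return cls(
            n=n,
            item_ids=tuple(net.node_ids),
            latent_sigma=sigma,
            thresholds=thresholds,
            seed=seed,
            sd_residuals=residuals,
        )


def simulate_cohort(spec: CohortSpec) -> ResponseMatrix:
    """Draw the cohort: latent multivariate normal, discretized per item."""
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(spec.latent_sigma)
    Z = rng.standard_normal((spec.n, len(spec.item_ids))) @ L.T
    data = {}
    for j, item in enumerate(spec.item_ids):
        tau = np.asarray(spec.thresholds[item].thresholds)
        data[item] = np.searchsorted(tau, Z[:, j]).astype(float)
    df = pd.DataFrame(data, index=pd.RangeIndex(spec.n, name="respondent_id"))
    bounds = {}
    for item in spec.item_ids:
        if item.upper().startswith("MBI"):
            bounds[item] = (0, 6)
        elif item.upper().startswith("PHQ"):
            bounds[item] = (0, 3)
        else:
            bounds[item] = (0, spec.thresholds[item].n_categories - 1)
    return ResponseMatrix(data=df, bounds=bounds)
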