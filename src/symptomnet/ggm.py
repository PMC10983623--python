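"""Sparse Gaussian graphical model estimation: graphical lasso + EBIC.

The precision matrix K is estimated by maximizing the L1-penalized
Gaussian log-likelihood

    log det K - tr(S K) - lambda * sum_{i != j} |K_ij|

along a descending penalty path; the Extended Bayesian Information
Criterion

    EBIC = -2 l + E log n + 4 E gamma log p,
    l = (n/2)(log det K - tr(S K)),  E = number of edges,

selects the penalty. The selected precision is reported as a
partial-correlation network, w_ij = -K_ij / sqrt(K_ii K_jj).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import graphical_lasso as _sk_glasso

try:  # warm-startable path solver; fall back to per-penalty calls without it
    from sklearn.covariance._graph_lasso import _graphical_lasso as _sk_glasso_warm
except ImportError:  # pragma: no cover
    _sk_glasso_warm = None

from .network import NetworkModel, default_communities
from .polychoric import PolychoricMatrix, polychoric_matrix

__all__ = [
    "GlassoSolution",
    "EBICScore",
    "glasso",
    "ebic_score",
    "lambda_path",
    "fit_network",
    "fit_ordinal_network",
    "partial_correlations",
    "EDGE_TOL",
]

EDGE_TOL = 1e-8  # |K_ij| above this counts as an edge
DEFAULT_GAMMA = 0.5
DEFAULT_N_LAMBDA = 100
DEFAULT_LAMBDA_MIN_RATIO = 0.01
DUAL_GAP_TOL = 1e-6
# inner coordinate-descent tolerance; must be much tighter than the dual-gap
# target or the outer gap stalls above it
ENET_TOL = 1e-7
MAX_ITER = 500


@dataclass
class GlassoSolution:
    """One point on the graphical-lasso path."""

    penalty: float
    precision: np.ndarray
    covariance_fit: np.ndarray
    converged: bool

    @property
    def edge_count(self) -> int:
        K = self.precision
        return int((np.abs(K[np.triu_indices_from(K, k=1)]) > EDGE_TOL).sum())

    def loglik(self, S: np.ndarray, n: int) -> float:
        K = self.precision
        sign, logdet = np.linalg.slogdet(K)
        if sign <= 0:
            return -np.inf
        return (n / 2.0) * (logdet - float(np.trace(S @ K)))


@dataclass(frozen=True)
class EBICScore:
    gamma: float
    n: int
    p: int
    edge_count: int
    loglik: float

    @property
    def value(self) -> float:
        E = self.edge_count
        return -2.0 * self.loglik + E * np.log(self.n) + 4.0 * E * self.gamma * np.log(self.p)


def _check_pd_correlation(S: np.ndarray) -> None:
    if not np.allclose(S, S.T):
        raise ValueError("S must be symmetric")
    if not np.allclose(np.diag(S), 1.0):
        raise ValueError("S must have a unit diagonal")
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError(
            "S is not positive definite; smooth it first "
            "(polychoric.smooth_correlation_matrix)"
        )


def glasso(
    S: np.ndarray,
    lam: float,
    tol: float = DUAL_GAP_TOL,
    max_iter: int = MAX_ITER,
    cov_init: np.ndarray | None = None,
) -> GlassoSolution:
    """Graphical lasso at one penalty (off-diagonal L1 on the precision).

    ``cov_init`` warm-starts the solver (used along the penalty path).
    """
    S = np.asarray(S, dtype=float)
    _check_pd_correlation(S)
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    if lam == 0.0:
        K = np.linalg.inv(S)
        return GlassoSolution(penalty=0.0, precision=K, covariance_fit=S.copy(), converged=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if _sk_glasso_warm is not None:
                cov, prec, costs, n_iter = _sk_glasso_warm(
                    S, lam, cov_init=cov_init, tol=tol, enet_tol=ENET_TOL, max_iter=max_iter
                )
                converged = n_iter < max_iter
                if not converged:
                    gap = costs[-1][1] if costs else float("nan")
                    raise RuntimeError(
                        f"graphical lasso did not converge at lambda={lam} "
                        f"(dual gap {gap:.3e} after {max_iter} iterations)"
                    )
            else:  # pragma: no cover - older sklearn
                cov, prec = _sk_glasso(S, alpha=lam, tol=tol, enet_tol=ENET_TOL, max_iter=max_iter)
                converged = True
    except FloatingPointError as exc:  # pragma: no cover - pathological input
        raise RuntimeError(f"graphical lasso failed at lambda={lam}: {exc}") from exc
    prec = (prec + prec.T) / 2.0
    return GlassoSolution(penalty=float(lam), precision=prec, covariance_fit=cov, converged=converged)


def ebic_score(sol: GlassoSolution, S: np.ndarray, gamma: float, n: int, p: int) -> EBICScore:
    if not sol.converged:
        raise ValueError("EBIC requires a converged solution")
    return EBICScore(gamma=gamma, n=n, p=p, edge_count=sol.edge_count, loglik=sol.loglik(S, n))


def lambda_path(
    S: np.ndarray,
    n_lambda: int = DEFAULT_N_LAMBDA,
    min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> np.ndarray:
    """Descending log-spaced penalty grid from max|S_ij| (i != j) down."""
    off = np.abs(S[np.triu_indices_from(S, k=1)])
    lam_max = float(off.max())
    if lam_max <= 0:
        return np.array([0.0])
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio), n_lambda)


def partial_correlations(K: np.ndarray) -> np.ndarray:
    """w_ij = -K_ij / sqrt(K_ii K_jj); zero diagonal. Scale-free in K's rows/cols."""
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    W[np.abs(K) <= EDGE_TOL] = 0.0  # keep the support exactly sparse
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return W


def fit_network(
    S,
    n: int,
    gamma: float = DEFAULT_GAMMA,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    communities: dict[str, str] | None = None,
    node_ids=None,
    return_path: bool = False,
):
    """EBIC-selected graphical-lasso network from a correlation matrix.

    ``S`` may be a :class:`~symptomnet.polychoric.PolychoricMatrix` or a
    plain array (then ``node_ids`` names the nodes). Ties in EBIC go to
    the larger penalty (sparser model), making selection deterministic.
    """
    if isinstance(S, PolychoricMatrix):
        node_ids = list(S.item_ids)
        Smat = S.rho
    else:
        Smat = np.asarray(S, dtype=float)
        if node_ids is None:
            node_ids = [f"V{i + 1}" for i in range(Smat.shape[0])]
    _check_pd_correlation(Smat)
    if communities is None:
        try:
            communities = default_communities(node_ids)
        except ValueError:
            communities = {nid: "all" for nid in node_ids}

    lams = lambda_path(Smat, n_lambda=n_lambda, min_ratio=lambda_min_ratio)
    records = []
    best = None
    cov_init = None
    for lam in lams:
        sol = glasso(Smat, float(lam), cov_init=cov_init)
        cov_init = sol.covariance_fit
        score = ebic_score(sol, Smat, gamma=gamma, n=n, p=len(node_ids))
        records.append(
            {"lambda": float(lam), "edge_count": sol.edge_count, "ebic": score.value}
        )
        if best is None or score.value < best[0] - 1e-12:
            best = (score.value, sol)
    _, sol = best

    counts = [r["edge_count"] for r in records]
    degenerate = len(set(counts)) == 1
    W = partial_correlations(sol.precision)
    np.clip(W, -1 + 1e-12, 1 - 1e-12, out=W)
    provenance = {
        "method": "EBIC graphical lasso on polychoric correlations",
        "lambda": sol.penalty,
        "gamma": gamma,
        "n": int(n),
        "n_lambda": int(n_lambda),
        "lambda_min_ratio": float(lambda_min_ratio),
    }
    if degenerate:
        provenance["warning"] = "degenerate penalty path: edge count constant along the grid"
    net = NetworkModel(
        node_ids=tuple(node_ids), weights=W, communities=communities, provenance=provenance
    )
    if return_path:
        import pandas as pd

        return net, pd.DataFrame.from_records(records)
    return net


def fit_ordinal_network(
    responses,
    gamma: float = DEFAULT_GAMMA,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    communities: dict[str, str] | None = None,
) -> NetworkModel:
    """Full pipeline: polychoric matrix then EBIC graphical lasso.

    ``responses`` is a complete ordinal DataFrame (or ResponseMatrix).
    """
    df = getattr(responses, "data", responses)
    S = polychoric_matrix(df)
    return fit_network(
        S,
        n=len(df),
        gamma=gamma,
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
        communities=communities,
    )
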