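"""Polychoric correlation estimation for ordinal items.

The model: each ordinal item is a discretization of a latent standard
normal variable at item-specific thresholds, and each pair of latent
variables is bivariate normal. Estimation is two-stage (Olsson):
thresholds come from the marginal category proportions, then the
correlation maximizes the multinomial likelihood of the two-way
contingency table with cell probabilities given by bivariate-normal
rectangle probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtri
from scipy.stats import spearmanr

from ._bvn import bvn_cdf

__all__ = [
    "ThresholdSet",
    "PolychoricEstimate",
    "PolychoricMatrix",
    "DegenerateItemError",
    "estimate_thresholds",
    "polychoric_rho",
    "polychoric_matrix",
    "smooth_correlation_matrix",
]

RHO_BOUND = 0.999  # optimization domain (-RHO_BOUND, RHO_BOUND)
PD_FLOOR = 1e-6  # minimum eigenvalue enforced on the assembled matrix
_CELL_FLOOR = 1e-12  # probability floor inside the log-likelihood


class DegenerateItemError(ValueError):
    """An item shows a single observed category; no threshold exists."""


@dataclass(frozen=True)
class ThresholdSet:
    """Latent-normal cut points for one item (strictly increasing, K-1 of them)."""

    item_id: str
    thresholds: tuple[float, ...]

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if t.size and not (np.diff(t) > 0).all():
            raise ValueError(f"thresholds for {self.item_id!r} must be strictly increasing")
        object.__setattr__(self, "thresholds", tuple(float(v) for v in t))

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


@dataclass(frozen=True)
class PolychoricEstimate:
    rho: float
    converged: bool
    method: str  # "ml" or "spearman-fallback"
    loglik: float = float("nan")


def estimate_thresholds(category_counts, item_id: str = "item") -> ThresholdSet:
    """Thresholds from marginal counts: Phi^-1 of the cumulative proportions.

    Empty categories are collapsed into their lower neighbour (the lowest
    category collapses upward), so only observed categories contribute cut
    points. A single observed category raises :class:`DegenerateItemError`.
    """
    counts = np.asarray(category_counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("no observations")
    if (counts < 0).any():
        raise ValueError("negative counts")
    counts = counts[counts > 0]  # collapsing empty categories
    if counts.size < 2:
        raise DegenerateItemError(f"item {item_id!r} has a single observed category")
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return ThresholdSet(item_id=item_id, thresholds=tuple(ndtri(cum)))


def _cell_probabilities(tau_r: np.ndarray, tau_c: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of the bivariate normal on the threshold grid."""
    a = np.concatenate(([-np.inf], tau_r, [np.inf]))
    b = np.concatenate(([-np.inf], tau_c, [np.inf]))
    grid = bvn_cdf(a[:, None], b[None, :], rho)
    p = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
    return np.clip(p, 0.0, 1.0)


def polychoric_rho(
    contingency,
    tau_row: ThresholdSet,
    tau_col: ThresholdSet,
    xatol: float = 1e-8,
) -> PolychoricEstimate:
    """ML polychoric correlation for a two-way count table with fixed thresholds.

    Zero-margin rows/columns must already be collapsed (they are when the
    thresholds came from :func:`estimate_thresholds` on the same margins).
    On optimizer failure the Spearman rank correlation of the table is
    returned, flagged as a fallback.
    """
    table = np.asarray(contingency, dtype=float)
    tr = np.asarray(tau_row.thresholds)
    tc = np.asarray(tau_col.thresholds)
    if table.shape != (tr.size + 1, tc.size + 1):
        raise ValueError(
            f"table shape {table.shape} does not match thresholds "
            f"({tr.size + 1} x {tc.size + 1} expected)"
        )

    def nll(rho: float) -> float:
        p = _cell_probabilities(tr, tc, rho)
        return -float(np.sum(table * np.log(np.maximum(p, _CELL_FLOOR))))

    res = minimize_scalar(
        nll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded", options={"xatol": xatol}
    )
    if res.success and np.isfinite(res.fun):
        return PolychoricEstimate(
            rho=float(res.x), converged=True, method="ml", loglik=-float(res.fun)
        )
    # fallback: Spearman correlation of the table's expanded ranks
    rows, cols = np.indices(table.shape)
    w = table.ravel().astype(int)
    rr = np.repeat(rows.ravel(), w)
    cc = np.repeat(cols.ravel(), w)
    rho = float(spearmanr(rr, cc).statistic)
    if not np.isfinite(rho):
        rho = 0.0
    return PolychoricEstimate(rho=rho, converged=False, method="spearman-fallback")


@dataclass
class PolychoricMatrix:
    """Assembled pairwise polychoric correlations, smoothed to positive definite."""

    item_ids: tuple[str, ...]
    rho: np.ndarray
    smoothed: bool
    min_eigenvalue_before: float
    thresholds: dict[str, ThresholdSet] = field(default_factory=dict)
    fallback_pairs: tuple[tuple[str, str], ...] = ()
    max_smoothing_shift: float = 0.0

    def __post_init__(self):
        r = np.asarray(self.rho, dtype=float)
        if r.shape != (len(self.item_ids),) * 2:
            raise ValueError("rho shape mismatch")
        if not np.allclose(r, r.T):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("rho must have unit diagonal")
        if (np.abs(r) > 1 + 1e-12).any():
            raise ValueError("correlations must lie in [-1, 1]")
        self.rho = r

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=list(self.item_ids), columns=list(self.item_ids))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def to_json(self, path=None):
        payload = {
            "item_ids": list(self.item_ids),
            "rho": self.rho.tolist(),
            "smoothed": self.smoothed,
            "min_eigenvalue_before": self.min_eigenvalue_before,
            "fallback_pairs": [list(p) for p in self.fallback_pairs],
            "max_smoothing_shift": self.max_smoothing_shift,
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh)


def smooth_correlation_matrix(R: np.ndarray, floor: float = PD_FLOOR) -> tuple[np.ndarray, float]:
    """Clip eigenvalues at ``floor``, reconstruct, rescale to unit diagonal.

    Rescaling can push the smallest eigenvalue back below the floor, so
    the clip is repeated (with an escalating target) until the floor
    holds. Returns the smoothed matrix and the largest absolute change
    of any off-diagonal entry relative to the input.
    """
    S = np.asarray(R, dtype=float)
    target = floor
    for _ in range(50):
        vals, vecs = np.linalg.eigh(S)
        S = (vecs * np.maximum(vals, target)) @ vecs.T
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        S = (S + S.T) / 2.0
        np.fill_diagonal(S, 1.0)
        if np.linalg.eigvalsh(S).min() >= floor:
            break
        target *= 1.5
    shift = float(np.max(np.abs(S - R)))
    return S, shift


def polychoric_matrix(
    responses,
    pd_floor: float = PD_FLOOR,
    on_degenerate: str = "raise",
) -> PolychoricMatrix:
    """Pairwise polychoric correlation matrix of a complete ordinal table.

    ``responses`` is a pandas DataFrame (respondent x item) or an object
    with a ``.data`` DataFrame attribute. Each unordered pair is estimated
    once. ``on_degenerate`` is ``"raise"`` (default) or ``"drop"`` — drop
    removes single-category items and estimates the rest.
    """
    df = getattr(responses, "data", responses)
    if df.isna().any().any():
        raise ValueError("responses must be complete (listwise-delete first)")
    if df.shape[1] < 2:
        raise ValueError("need at least two items")
    if df.shape[0] < 3:
        raise ValueError("need at least three respondents")

    items = list(df.columns)
    codes: dict[str, np.ndarray] = {}
    ncat: dict[str, int] = {}
    taus: dict[str, ThresholdSet] = {}
    degenerate: list[str] = []
    for item in items:
        col = df[item].to_numpy()
        values, inverse = np.unique(col, return_inverse=True)
        if values.size < 2:
            degenerate.append(item)
            continue
        counts = np.bincount(inverse, minlength=values.size)
        codes[item] = inverse
        ncat[item] = values.size
        taus[item] = estimate_thresholds(counts, item_id=item)
    if degenerate:
        if on_degenerate == "drop":
            items = [i for i in items if i not in degenerate]
            if len(items) < 2:
                raise DegenerateItemError(
                    f"fewer than two non-degenerate items remain; degenerate: {degenerate}"
                )
        else:
            raise DegenerateItemError(
                f"single-category items: {degenerate} (pass on_degenerate='drop' to skip them)"
            )

    p = len(items)
    R = np.eye(p)
    fallbacks: list[tuple[str, str]] = []
    for i in range(p):
        for j in range(i + 1, p):
            a, b = items[i], items[j]
            table = np.zeros((ncat[a], ncat[b]))
            np.add.at(table, (codes[a], codes[b]), 1.0)
            est = polychoric_rho(table, taus[a], taus[b])
            R[i, j] = R[j, i] = est.rho
            if not est.converged:
                fallbacks.append((a, b))

    min_eig = float(np.linalg.eigvalsh(R).min())
    smoothed = False
    shift = 0.0
    if min_eig < pd_floor:
        R, shift = smooth_correlation_matrix(R, floor=pd_floor)
        smoothed = True
    return PolychoricMatrix(
        item_ids=tuple(items),
        rho=R,
        smoothed=smoothed,
        min_eigenvalue_before=min_eig,
        thresholds=taus,
        fallback_pairs=tuple(fallbacks),
        max_smoothing_shift=shift,
    )
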