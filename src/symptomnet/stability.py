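"""Bootstrap accuracy and stability diagnostics for the fitted network.

Three procedures, all re-running the full estimation pipeline
(polychoric correlations then EBIC graphical lasso) on resampled
respondents:

* nonparametric bootstrap of edge weights → per-edge 95% percentile CIs;
* bootstrapped difference tests between edges or between node
  expected-influence values (percentile CI of the difference, no
  multiplicity correction, matching the convention of the case-drop
  stability methodology);
* case-dropping bootstrap → correlation-stability (CS) coefficient: the
  largest share of respondents that can be dropped while the
  correlation between the original and subsample centrality stays at or
  above a threshold (0.7) with a given probability (0.95). CS above 0.5
  is considered ideal and values below 0.25 unacceptable.

Every procedure is deterministic given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ggm
from .centrality import bridge_expected_influence, expected_influence
from .network import NetworkModel

__all__ = [
    "BootstrapSummary",
    "DifferenceTestMatrix",
    "CaseDropCurve",
    "CSCoefficient",
    "edge_ci_bootstrap",
    "difference_test",
    "case_drop_bootstrap",
    "cs_coefficient",
]

DEFAULT_DROP_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.751, 0.05), 2))
MIN_CASES_PER_NODE = 5  # a subsample below 5*p respondents is skipped


def _refit(df: pd.DataFrame, fit_kwargs: dict) -> NetworkModel:
    return ggm.fit_ordinal_network(df, **fit_kwargs)


def _edge_labels(node_ids) -> list[tuple[str, str]]:
    p = len(node_ids)
    return [(node_ids[i], node_ids[j]) for i in range(p) for j in range(i + 1, p)]


def _edge_vector(net: NetworkModel, node_ids) -> np.ndarray:
    W = net.weights_df().reindex(index=list(node_ids), columns=list(node_ids)).to_numpy()
    iu = np.triu_indices(len(node_ids), k=1)
    return W[iu]


@dataclass
class BootstrapSummary:
    """Per-edge point estimates, replicate draws, and 95% percentile CIs."""

    B: int
    seed: int
    node_ids: tuple[str, ...]
    edge_labels: tuple[tuple[str, str], ...]
    point: np.ndarray
    replicates: np.ndarray  # (B_effective, n_edges)
    ci_level: float = 0.95
    n_failures: int = 0

    @property
    def ci_lower(self) -> np.ndarray:
        a = (1.0 - self.ci_level) / 2.0
        return np.quantile(self.replicates, a, axis=0)

    @property
    def ci_upper(self) -> np.ndarray:
        a = (1.0 - self.ci_level) / 2.0
        return np.quantile(self.replicates, 1.0 - a, axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_a": [a for a, _ in self.edge_labels],
                "node_b": [b for _, b in self.edge_labels],
                "weight": self.point,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "boot_sd": self.replicates.std(axis=0, ddof=1),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def edge_ci_bootstrap(
    responses,
    B: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    **fit_kwargs,
) -> BootstrapSummary:
    """Nonparametric bootstrap of edge weights (respondents resampled with replacement).

    Replicates whose pipeline fit fails (e.g. an item collapses to a
    single category in the resample) are dropped and counted; more than
    5% failures triggers a warning.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for stable percentile intervals")
    df = getattr(responses, "data", responses)
    rng = np.random.default_rng(seed)
    net0 = _refit(df, fit_kwargs)
    node_ids = net0.node_ids
    point = _edge_vector(net0, node_ids)

    reps = []
    failures = 0
    n = len(df)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            net_b = _refit(df.iloc[idx], fit_kwargs)
            reps.append(_edge_vector(net_b, node_ids))
        except Exception:
            failures += 1
    if failures > 0.05 * B:
        warnings.warn(
            f"{failures}/{B} bootstrap replicates failed to fit", RuntimeWarning, stacklevel=2
        )
    if not reps:
        raise RuntimeError("all bootstrap replicates failed")
    return BootstrapSummary(
        B=B,
        seed=seed,
        node_ids=node_ids,
        edge_labels=tuple(_edge_labels(node_ids)),
        point=point,
        replicates=np.asarray(reps),
        ci_level=ci_level,
        n_failures=failures,
    )


@dataclass
class DifferenceTestMatrix:
    """Pairwise 'significantly different' flags from bootstrap difference CIs."""

    kind: str  # "edges" or "expected_influence"
    labels: tuple
    flags: np.ndarray  # boolean, symmetric, False diagonal
    alpha: float

    def to_dataframe(self) -> pd.DataFrame:
        lab = [l if isinstance(l, str) else "-".join(l) for l in self.labels]
        return pd.DataFrame(self.flags, index=lab, columns=lab)


def difference_test(replicates, labels, alpha: float = 0.05, kind: str = "edges") -> DifferenceTestMatrix:
    """Flag pairs whose bootstrap percentile CI of the difference excludes 0.

    ``replicates`` is (B, m): bootstrap draws of m objects (edge weights
    or node EI values) from the same resamples.
    """
    R = np.asarray(replicates, dtype=float)
    m = R.shape[1]
    if len(labels) != m:
        raise ValueError("labels do not match replicate columns")
    lo_q, hi_q = alpha / 2.0, 1.0 - alpha / 2.0
    flags = np.zeros((m, m), dtype=bool)
    for i in range(m):
        d = R[:, i][:, None] - R[:, i + 1 :]
        lo = np.quantile(d, lo_q, axis=0)
        hi = np.quantile(d, hi_q, axis=0)
        sig = (lo > 0) | (hi < 0)
        flags[i, i + 1 :] = sig
        flags[i + 1 :, i] = sig
    return DifferenceTestMatrix(kind=kind, labels=tuple(labels), flags=flags, alpha=alpha)


def _statistic_fn(statistic):
    if callable(statistic):
        return statistic, getattr(statistic, "__name__", "custom")
    key = str(statistic).upper()
    if key in ("EI", "EXPECTED_INFLUENCE"):
        return (lambda net: expected_influence(net).values.to_numpy()), "EI"
    if key in ("BEI", "BRIDGE_EXPECTED_INFLUENCE"):
        return (lambda net: bridge_expected_influence(net).values.to_numpy()), "BEI"
    raise ValueError(f"unknown statistic {statistic!r}; use 'EI', 'BEI', or a callable")


@dataclass
class CaseDropCurve:
    """Original-vs-subsample centrality correlations along a drop-proportion grid."""

    statistic: str
    proportions: tuple[float, ...]
    correlations: dict[float, np.ndarray]  # proportion -> replicate correlations (NaN = degenerate)
    replicates: int
    seed: int
    skipped: tuple[float, ...] = ()
    degenerate: bool = False

    def mean_correlations(self) -> pd.Series:
        return pd.Series(
            {p: float(np.nanmean(self.correlations[p])) for p in self.proportions},
            name=f"mean_corr_{self.statistic}",
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.proportions:
            for b, c in enumerate(self.correlations[p]):
                rows.append({"drop_proportion": p, "replicate": b, "correlation": c})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class CSCoefficient:
    statistic: str
    threshold_r: float
    confidence: float
    value: float

    def acceptable(self) -> bool:
        """At or above the conventional 0.25 floor."""
        return self.value >= 0.25

    def ideal(self) -> bool:
        return self.value > 0.5


def case_drop_bootstrap(
    responses,
    statistic="EI",
    grid=DEFAULT_DROP_GRID,
    replicates: int = 250,
    seed: int = 0,
    **fit_kwargs,
):
    """Case-dropping bootstrap of one or several node statistics.

    For each proportion in ``grid`` (strictly increasing, within
    (0, 0.8]), drop that share of respondents without replacement
    ``replicates`` times, refit the pipeline, and record the Pearson
    correlation between the original and subsample statistic across
    nodes. Proportions whose subsample would fall below 5 cases per node
    are skipped with a warning. A constant statistic makes the
    correlation undefined; those replicates are recorded as NaN and the
    curve flagged degenerate.

    ``statistic`` may be ``"EI"``, ``"BEI"``, a callable
    ``net -> vector``, or a sequence of those — a sequence evaluates all
    statistics on the *same* refits and returns ``{name: CaseDropCurve}``.
    """
    grid = tuple(float(g) for g in grid)
    if any(not 0 < g <= 0.8 for g in grid) or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing within (0, 0.8]")
    if replicates < 50:
        raise ValueError("need at least 50 replicates per proportion")
    single = isinstance(statistic, str) or callable(statistic)
    stats = [statistic] if single else list(statistic)
    fns, names = zip(*(_statistic_fn(s) for s in stats))

    df = getattr(responses, "data", responses)
    n, p = df.shape
    net0 = _refit(df, fit_kwargs)
    stat0 = [np.asarray(fn(net0), dtype=float) for fn in fns]
    s0_const = [np.isclose(s.std(), 0.0) for s in stat0]
    rng = np.random.default_rng(seed)

    correlations: list[dict[float, np.ndarray]] = [{} for _ in fns]
    degenerate = list(s0_const)
    kept, skipped = [], []
    for prop in grid:
        n_sub = int(round(n * (1.0 - prop)))
        if n_sub < MIN_CASES_PER_NODE * p:
            skipped.append(prop)
            warnings.warn(
                f"drop proportion {prop} leaves n={n_sub} < {MIN_CASES_PER_NODE * p}; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        cors = np.full((len(fns), replicates), np.nan)
        for b in range(replicates):
            idx = rng.permutation(n)[:n_sub]
            try:
                net_b = _refit(df.iloc[np.sort(idx)], fit_kwargs)
            except Exception:
                continue
            for s, fn in enumerate(fns):
                stat_b = np.asarray(fn(net_b), dtype=float)
                if s0_const[s] or np.isclose(stat_b.std(), 0.0):
                    degenerate[s] = True
                else:
                    cors[s, b] = float(np.corrcoef(stat0[s], stat_b)[0, 1])
        for s in range(len(fns)):
            correlations[s][prop] = cors[s]
        kept.append(prop)
    curves = {
        names[s]: CaseDropCurve(
            statistic=names[s],
            proportions=tuple(kept),
            correlations=correlations[s],
            replicates=replicates,
            seed=seed,
            skipped=tuple(skipped),
            degenerate=degenerate[s],
        )
        for s in range(len(fns))
    }
    return curves[names[0]] if single else curves


def cs_coefficient(curve: CaseDropCurve, r: float = 0.7, conf: float = 0.95) -> CSCoefficient:
    """Largest drop proportion at which >= ``conf`` of replicates correlate >= ``r``.

    Replicates with undefined correlation count as failures. Returns 0
    when no grid proportion qualifies.
    """
    if not curve.proportions:
        raise ValueError("empty case-drop curve")
    value = 0.0
    for prop in curve.proportions:
        cors = curve.correlations[prop]
        share = float(np.mean(np.where(np.isnan(cors), -np.inf, cors) >= r))
        if share >= conf:
            value = max(value, prop)
    return CSCoefficient(statistic=curve.statistic, threshold_r=r, confidence=conf, value=value)
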