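"""Model/Results facade over the estimation pipeline.

``SymptomNetwork`` wraps a complete ordinal response table;
``fit()`` runs polychoric estimation and EBIC graphical-lasso model
selection and returns a ``SymptomNetworkResults`` carrying the
partial-correlation network, centrality and predictability tables, and
bootstrap diagnostics.

Example
-------
>>> from symptomnet import SymptomNetwork, load_fixture_network, simulate_cohort
>>> from symptomnet.synthetic import CohortSpec
>>> from symptomnet.netio import load_item_info
>>> net = load_fixture_network()
>>> spec = CohortSpec.from_network_and_moments(net, load_item_info(), n=616, seed=7)
>>> res = SymptomNetwork(simulate_cohort(spec)).fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ggm, stability
from .centrality import CentralityTable, EdgeRanking, bridge_expected_influence, expected_influence, rank_edges
from .network import NetworkModel, default_communities
from .polychoric import polychoric_matrix
from .predictability import PredictabilityTable, node_predictability, summarize_predictability
from .scales import (
    DEFAULT_SCALES,
    PrevalenceReport,
    ResponseMatrix,
    ScaleDefinition,
    prevalence,
    score_totals,
    validate_responses,
)

__all__ = ["SymptomNetwork", "SymptomNetworkResults"]


def _coerce_responses(df: pd.DataFrame, scales) -> ResponseMatrix:
    """Wrap a DataFrame, falling back to per-item bounds for partial item sets.

    A table with exactly the scales' items gets the instruments' category
    bounds; any other ordinal table gets bounds from the item prefix
    (MBI* 0-6, PHQ* 0-3) or, failing that, the observed range.
    """
    scale_items = {i for sc in scales for i in sc.item_ids}
    if set(df.columns) == scale_items:
        return ResponseMatrix.from_dataframe(df, scales=scales)
    bounds = {}
    for c in df.columns:
        if str(c).upper().startswith("MBI"):
            bounds[c] = (0, 6)
        elif str(c).upper().startswith("PHQ"):
            bounds[c] = (0, 3)
        else:
            col = df[c].dropna()
            bounds[c] = (int(col.min()), int(col.max()))
    return ResponseMatrix(data=df.astype(float), bounds=bounds)


class SymptomNetwork:
    """Ordinal symptom-network model for a respondent-by-item table.

    Parameters
    ----------
    responses : ResponseMatrix or DataFrame
        Complete ordinal responses (run :func:`validate_responses` or use
        :meth:`from_dataframe` for raw tables with missing values).
    communities : mapping, optional
        Node -> community label; inferred from item prefixes by default.
    scales : tuple of ScaleDefinition
        Instruments used for scoring and prevalence.
    """

    def __init__(self, responses, communities=None, scales=DEFAULT_SCALES):
        if isinstance(responses, pd.DataFrame):
            responses = _coerce_responses(responses, scales)
        if not responses.is_complete():
            raise ValueError(
                "responses contain missing values; use SymptomNetwork.from_dataframe "
                "or validate_responses for listwise deletion"
            )
        self.responses = responses
        self.scales = scales
        if communities is None:
            try:
                communities = default_communities(responses.item_ids)
            except ValueError:
                communities = {i: "all" for i in responses.item_ids}
        self.communities = dict(communities)
        self.exclusions = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, communities=None, scales=DEFAULT_SCALES):
        """Build from a raw table, listwise-deleting incomplete respondents."""
        raw = _coerce_responses(df, scales)
        clean, report = validate_responses(raw)
        model = cls(clean, communities=communities, scales=scales)
        model.exclusions = report
        return model

    @property
    def nobs(self) -> int:
        return self.responses.n_respondents

    @property
    def item_ids(self) -> tuple[str, ...]:
        return self.responses.item_ids

    def score(self, scale: ScaleDefinition) -> pd.Series:
        return score_totals(self.responses, scale)

    def prevalence(self, scale: ScaleDefinition, n_total: int | None = None) -> PrevalenceReport:
        return prevalence(self.score(scale), scale, n_total=n_total)

    def fit(
        self,
        gamma: float = ggm.DEFAULT_GAMMA,
        n_lambda: int = ggm.DEFAULT_N_LAMBDA,
        lambda_min_ratio: float = ggm.DEFAULT_LAMBDA_MIN_RATIO,
    ) -> "SymptomNetworkResults":
        """Polychoric correlations, then graphical lasso with EBIC selection."""
        S = polychoric_matrix(self.responses.data)
        net, path = ggm.fit_network(
            S,
            n=self.nobs,
            gamma=gamma,
            n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio,
            communities=self.communities,
            return_path=True,
        )
        return SymptomNetworkResults(model=self, network=net, polychoric=S, ebic_path=path)


class SymptomNetworkResults:
    """Fitted burnout–depression (or any two-community) symptom network."""

    def __init__(self, model: SymptomNetwork, network: NetworkModel, polychoric, ebic_path):
        self.model = model
        self.network = network
        self.polychoric = polychoric
        self.ebic_path = ebic_path

    # --- estimates --------------------------------------------------------
    @property
    def weights(self) -> pd.DataFrame:
        return self.network.weights_df()

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def lambda_(self) -> float:
        return self.network.provenance.get("lambda", float("nan"))

    def expected_influence(self) -> CentralityTable:
        return expected_influence(self.network)

    def bridge_expected_influence(self, partition=None) -> CentralityTable:
        return bridge_expected_influence(self.network, partition=partition)

    def rank_edges(self, scope: str) -> EdgeRanking:
        return rank_edges(self.network, scope)

    def predictability(self) -> PredictabilityTable:
        return node_predictability(self.model.responses.data)

    # --- diagnostics ------------------------------------------------------
    def bootstrap_edges(self, B: int = 1000, seed: int = 0) -> stability.BootstrapSummary:
        return stability.edge_ci_bootstrap(
            self.model.responses.data, B=B, seed=seed, **self._fit_kwargs()
        )

    def edge_difference_test(self, summary: stability.BootstrapSummary, alpha: float = 0.05):
        nz = np.abs(summary.point) > 0
        return stability.difference_test(
            summary.replicates[:, nz],
            [f"{a}-{b}" for (a, b), keep in zip(summary.edge_labels, nz) if keep],
            alpha=alpha,
            kind="edges",
        )

    def ei_difference_test(self, summary: stability.BootstrapSummary, alpha: float = 0.05):
        """Bootstrapped difference test of node expected influence."""
        p = len(summary.node_ids)
        iu = np.triu_indices(p, k=1)
        ei_reps = np.empty((summary.replicates.shape[0], p))
        for b, vec in enumerate(summary.replicates):
            W = np.zeros((p, p))
            W[iu] = vec
            W = W + W.T
            ei_reps[b] = W.sum(axis=1)
        return stability.difference_test(
            ei_reps, list(summary.node_ids), alpha=alpha, kind="expected_influence"
        )

    def case_drop(
        self,
        statistic="EI",
        grid=stability.DEFAULT_DROP_GRID,
        replicates: int = 250,
        seed: int = 0,
    ) -> stability.CaseDropCurve:
        return stability.case_drop_bootstrap(
            self.model.responses.data,
            statistic=statistic,
            grid=grid,
            replicates=replicates,
            seed=seed,
            **self._fit_kwargs(),
        )

    def cs_coefficient(self, curve, r: float = 0.7, conf: float = 0.95) -> stability.CSCoefficient:
        return stability.cs_coefficient(curve, r=r, conf=conf)

    def _fit_kwargs(self) -> dict:
        prov = self.network.provenance
        return {
            "gamma": prov.get("gamma", ggm.DEFAULT_GAMMA),
            "n_lambda": prov.get("n_lambda", ggm.DEFAULT_N_LAMBDA),
            "lambda_min_ratio": prov.get("lambda_min_ratio", ggm.DEFAULT_LAMBDA_MIN_RATIO),
            "communities": dict(self.network.communities),
        }

    # --- simulation -------------------------------------------------------
    def simulate(self, n: int | None = None, seed: int = 0) -> ResponseMatrix:
        """Parametric cohort from the fitted network and estimated thresholds."""
        from .synthetic import CohortSpec, network_to_latent_sigma, simulate_cohort

        sigma = network_to_latent_sigma(self.network)
        spec = CohortSpec(
            n=n or self.nobs,
            item_ids=self.network.node_ids,
            latent_sigma=sigma,
            thresholds={k: v for k, v in self.polychoric.thresholds.items()},
            seed=seed,
        )
        return simulate_cohort(spec)

    # --- reporting --------------------------------------------------------
    def summary(self) -> str:
        ei = self.expected_influence()
        bei = self.bridge_expected_influence()
        pred = self.predictability()
        pmin, pmax, pmean = summarize_predictability(pred)
        lines = []
        title = "Ordinal Symptom Network (EBIC graphical lasso)"
        lines.append(title)
        lines.append("=" * 74)
        lines.append(
            f"Nodes: {self.network.n_nodes:<6} Observations: {self.nobs:<8} "
            f"Edges: {self.network.edge_count}"
        )
        lines.append(
            f"gamma: {self.network.provenance.get('gamma'):<6} "
            f"lambda: {self.lambda_:.4f}   "
            f"polychoric smoothed: {self.polychoric.smoothed}"
        )
        lines.append(f"Predictability: min {pmin:.2f}  max {pmax:.2f}  mean {pmean:.2f}")
        lines.append("-" * 74)
        lines.append(f"{'node':<8}{'community':<14}{'EI':>8}{'BEI':>8}{'R2':>8}{'EI rank':>9}")
        rank = {n: r + 1 for r, n in enumerate(ei.ranking)}
        for node in self.network.node_ids:
            lines.append(
                f"{node:<8}{self.network.communities[node]:<14}"
                f"{ei.values[node]:>8.3f}{bei.values[node]:>8.3f}"
                f"{pred.values[node]:>8.3f}{rank[node]:>9}"
            )
        lines.append("=" * 74)
        return "\n".join(lines)

    # --- plotting (optional convenience) ----------------------------------
    def plot_expected_influence(self, ax=None, bridge: bool = False):
        """Dot plot of (bridge) expected influence, ranked."""
        import matplotlib.pyplot as plt

        table = self.bridge_expected_influence() if bridge else self.expected_influence()
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 6))
        order = list(reversed(table.ranking))
        vals = [table.values[n] for n in order]
        ax.plot(vals, range(len(order)), "o-")
        ax.set_yticks(range(len(order)), order)
        ax.set_xlabel("bridge expected influence" if bridge else "expected influence")
        return ax

    def plot_network(self, ax=None, layout_seed: int = 0):
        """Circle-layout network sketch; edge width follows |weight|."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        p = self.network.n_nodes
        ang = 2 * np.pi * np.arange(p) / p
        xy = np.c_[np.cos(ang), np.sin(ang)]
        for i in range(p):
            for j in range(i + 1, p):
                w = self.network.weights[i, j]
                if w != 0:
                    ax.plot(
                        xy[[i, j], 0],
                        xy[[i, j], 1],
                        color="tab:blue" if w > 0 else "tab:red",
                        lw=6 * abs(w),
                        alpha=min(1.0, 0.2 + abs(w)),
                        zorder=1,
                    )
        colors = {
            c: col
            for c, col in zip(self.network.community_labels, ("gold", "lightgreen", "silver"))
        }
        for i, node in enumerate(self.network.node_ids):
            ax.scatter(*xy[i], s=450, color=colors[self.network.communities[node]], zorder=2)
            ax.annotate(node, xy[i], ha="center", va="center", fontsize=7, zorder=3)
        ax.set_axis_off()
        return ax
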