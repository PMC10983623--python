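"""Expected influence, bridge expected influence, and edge rankings.

Expected influence (EI) of a node is the sum of its signed edge
weights — one-step influence, equal to strength centrality when all
edges are positive. Bridge expected influence (BEI) restricts the sum
to edges crossing to the other community, quantifying how strongly a
symptom links the two syndromes. Rankings are deterministic: value
descending, ties broken lexicographically by node label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import NetworkModel

__all__ = ["CentralityTable", "EdgeRanking", "expected_influence", "bridge_expected_influence", "rank_edges"]


@dataclass
class CentralityTable:
    """Per-node centrality values with a deterministic ranking."""

    statistic: str
    values: pd.Series  # indexed by node id, in network node order

    @property
    def ranking(self) -> tuple[str, ...]:
        order = sorted(self.values.index, key=lambda n: (-self.values[n], n))
        return tuple(order)

    def top(self, k: int) -> tuple[str, ...]:
        return self.ranking[:k]

    def bottom(self, k: int) -> tuple[str, ...]:
        return tuple(reversed(self.ranking[-k:]))

    def to_frame(self, ndigits: int | None = 3) -> pd.DataFrame:
        vals = self.values if ndigits is None else self.values.round(ndigits)
        rank = pd.Series(
            {n: r + 1 for r, n in enumerate(self.ranking)}, name="rank"
        ).reindex(self.values.index)
        df = pd.DataFrame({self.statistic: vals, "rank": rank})
        z = (self.values - self.values.mean()) / self.values.std(ddof=1)
        df[f"{self.statistic}_z"] = z.round(3) if ndigits is not None else z
        return df

    def to_csv(self, path, ndigits: int | None = 3) -> None:
        self.to_frame(ndigits=ndigits).to_csv(path, index_label="node")


@dataclass
class EdgeRanking:
    """Edges of one scope ordered by |weight| descending (ties: lexicographic)."""

    scope: str
    edges: tuple[tuple[str, str, float], ...]

    def top(self, k: int) -> tuple[tuple[str, str, float], ...]:
        return self.edges[:k]


def expected_influence(net: NetworkModel) -> CentralityTable:
    """One-step expected influence: EI(i) = sum_j w_ij."""
    ei = net.weights.sum(axis=1)
    return CentralityTable(
        statistic="expected_influence",
        values=pd.Series(ei, index=list(net.node_ids), name="expected_influence"),
    )


def bridge_expected_influence(
    net: NetworkModel, partition: dict[str, str] | None = None
) -> CentralityTable:
    """BEI(i) = sum of w_ij over nodes j outside i's community."""
    partition = dict(net.communities) if partition is None else dict(partition)
    missing = [n for n in net.node_ids if n not in partition]
    if missing:
        raise ValueError(f"nodes without a community assignment: {missing}")
    comm = np.array([partition[n] for n in net.node_ids])
    bei = np.array(
        [net.weights[i, comm != comm[i]].sum() for i in range(net.n_nodes)]
    )
    return CentralityTable(
        statistic="bridge_expected_influence",
        values=pd.Series(bei, index=list(net.node_ids), name="bridge_expected_influence"),
    )


def rank_edges(net: NetworkModel, scope: str) -> EdgeRanking:
    """Edges within one community (scope = its label) or across ("between")."""
    labels = set(net.community_labels)
    if scope != "between" and scope not in labels:
        raise ValueError(f"unknown scope {scope!r}; expected 'between' or one of {sorted(labels)}")
    selected = []
    for a, b, w in net.edges():
        ca, cb = net.communities[a], net.communities[b]
        if scope == "between":
            if ca != cb:
                selected.append((a, b, w))
        elif ca == scope and cb == scope:
            selected.append((a, b, w))
    selected.sort(key=lambda e: (-abs(e[2]), e[0], e[1]))
    return EdgeRanking(scope=scope, edges=tuple(selected))
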