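"""The partial-correlation network container shared across the package."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["NetworkModel", "default_communities"]


def default_communities(node_ids) -> dict[str, str]:
    """Instrument membership by label prefix: MBI* -> burnout, PHQ* -> depression."""
    out = {}
    for n in node_ids:
        if n.upper().startswith("MBI"):
            out[n] = "burnout"
        elif n.upper().startswith("PHQ"):
            out[n] = "depression"
        else:
            raise ValueError(f"cannot infer community for node {n!r}; pass communities explicitly")
    return out


@dataclass
class NetworkModel:
    """Undirected weighted network of regularized partial correlations.

    ``weights`` is symmetric with zero diagonal and entries in (-1, 1);
    ``communities`` maps every node to its cluster label (here: the
    instrument the item belongs to). ``provenance`` records how the
    network was obtained (estimation settings or "published fixture").
    """

    node_ids: tuple[str, ...]
    weights: np.ndarray
    communities: dict[str, str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.node_ids = tuple(self.node_ids)
        W = np.asarray(self.weights, dtype=float)
        p = len(self.node_ids)
        if W.shape != (p, p):
            raise ValueError(f"weights shape {W.shape} does not match {p} nodes")
        if not np.allclose(W, W.T):
            raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(W), 0.0):
            raise ValueError("diagonal must be zero")
        if (np.abs(W) >= 1).any():
            raise ValueError("edge weights must satisfy |w| < 1")
        missing = [n for n in self.node_ids if n not in self.communities]
        if missing:
            raise ValueError(f"nodes without a community: {missing}")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def community_labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.communities.values())))

    def weights_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.node_ids), columns=list(self.node_ids))

    def edges(self, tol: float = 0.0):
        """Iterate (node_a, node_b, weight) over nonzero unordered pairs."""
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                if abs(self.weights[i, j]) > tol:
                    yield self.node_ids[i], self.node_ids[j], float(self.weights[i, j])

    @property
    def edge_count(self) -> int:
        return sum(1 for _ in self.edges())

    # --- centrality conveniences (delegate to the centrality module) -----
    def expected_influence(self):
        from .centrality import expected_influence

        return expected_influence(self)

    def bridge_expected_influence(self, partition=None):
        from .centrality import bridge_expected_influence

        return bridge_expected_influence(self, partition=partition)

    def rank_edges(self, scope: str):
        from .centrality import rank_edges

        return rank_edges(self, scope)

    # --- serialization ----------------------------------------------------
    def to_csv(self, path) -> None:
        """Labelled square matrix CSV, full precision."""
        self.weights_df().to_csv(path, float_format="%.17g")

    def to_edgelist_tsv(self, path) -> None:
        rows = []
        for a, b, w in self.edges():
            kind = "within" if self.communities[a] == self.communities[b] else "between"
            rows.append((a, b, w, kind))
        pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "scope"]).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )

    def to_json(self, path=None):
        payload = {
            "node_ids": list(self.node_ids),
            "weights": self.weights.tolist(),
            "communities": dict(self.communities),
            "provenance": self.provenance,
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, source) -> "NetworkModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            node_ids=tuple(payload["node_ids"]),
            weights=np.asarray(payload["weights"], dtype=float),
            communities=dict(payload["communities"]),
            provenance=payload.get("provenance", {}),
        )
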