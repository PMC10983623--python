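"""Fixtures, file formats, and run configuration.

Ships the published 24-item burnout–depression edge matrix as a
package fixture in two forms: the raw transcription (which contains
exactly one asymmetric cell pair, MBI1–MBI2 printed as 0.406 in one
triangle and 0.041 in the other) and the corrected symmetric matrix
(resolved to 0.406 — the value consistent with the published edge
ranking and with MBI2 having the highest expected influence). The
correction log travels with the loaded network's provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .network import NetworkModel, default_communities

__all__ = [
    "load_fixture_network",
    "load_item_info",
    "load_adjacency",
    "asymmetric_pairs",
    "RunConfig",
    "STUDY_N",
    "STUDY_PREVALENCE_COUNTS",
    "STUDY_COMPLETED_SURVEYS",
]

#: Cohort facts of the emulated study: 636 completed surveys, 616 retained
#: after listwise deletion; screen-positive counts by instrument.
STUDY_N = 616
STUDY_COMPLETED_SURVEYS = 636
STUDY_PREVALENCE_COUNTS = {"mbi_gs": (297, 616), "phq9": (395, 616)}

FIXTURE_CORRECTION_LOG = (
    "asymmetric pair (MBI1, MBI2): printed 0.406 (row MBI1) vs 0.041 (row MBI2); "
    "resolved to 0.406, consistent with MBI1-MBI2 ranking third among "
    "within-burnout edges and with the published expected-influence order",
)


def _data_path(name: str):
    return resources.files("symptomnet.data").joinpath(name)


def load_item_info() -> pd.DataFrame:
    """Item metadata: content label, published mean/sd, published EI and R^2.

    The published expected-influence column is known to be inconsistent
    with the published edge matrix's row sums and with the study's own
    ranking narrative; it is carried for reference only and should not be
    used as a numerical oracle. The predictability column is the one the
    published 0.67 average derives from.
    """
    with resources.as_file(_data_path("item_moments.csv")) as p:
        return pd.read_csv(p, index_col="item")


def asymmetric_pairs(df: pd.DataFrame, tol: float = 0.0) -> list[tuple[str, str, float, float]]:
    """(row_label, col_label, upper_value, lower_value) where the matrix disagrees."""
    labels = list(df.index)
    M = df.to_numpy(dtype=float)
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if abs(M[i, j] - M[j, i]) > tol:
                out.append((labels[i], labels[j], float(M[i, j]), float(M[j, i])))
    return out


def load_adjacency(
    source,
    asymmetry_policy: str = "error",
    communities: dict[str, str] | None = None,
    provenance: str = "file",
) -> NetworkModel:
    """Load a labelled square adjacency matrix (CSV path or DataFrame).

    ``asymmetry_policy`` resolves disagreeing cell pairs: ``"error"``,
    ``"keep-upper"``, ``"keep-lower"``, or ``"mean"``. The resolved pairs
    are reported in the returned model's provenance.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        # round_trip parsing keeps CSV -> model -> CSV an exact identity
        df = pd.read_csv(source, index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"adjacency must be square, got {df.shape}")
    if list(df.index) != list(df.columns):
        raise ValueError("row and column labels must match (labelled square matrix)")
    if df.index.duplicated().any():
        raise ValueError("duplicate node labels")
    M = df.to_numpy(dtype=float)
    if (np.abs(M) >= 1).any():
        raise ValueError("edge weights must satisfy |w| < 1")
    np.fill_diagonal(M, 0.0)

    pairs = asymmetric_pairs(pd.DataFrame(M, index=df.index, columns=df.columns))
    if pairs:
        if asymmetry_policy == "error":
            raise ValueError(f"asymmetric cell pairs: {pairs}; choose a resolution policy")
        for i_lab, j_lab, up, lo in pairs:
            i = df.index.get_loc(i_lab)
            j = df.index.get_loc(j_lab)
            if asymmetry_policy == "keep-upper":
                v = up
            elif asymmetry_policy == "keep-lower":
                v = lo
            elif asymmetry_policy == "mean":
                v = (up + lo) / 2.0
            else:
                raise ValueError(f"unknown asymmetry policy {asymmetry_policy!r}")
            M[i, j] = M[j, i] = v
    M = (M + M.T) / 2.0

    node_ids = tuple(df.index)
    if communities is None:
        communities = default_communities(node_ids)
    return NetworkModel(
        node_ids=node_ids,
        weights=M,
        communities=communities,
        provenance={
            "source": provenance,
            "asymmetry_policy": asymmetry_policy,
            "asymmetric_pairs_resolved": [list(p) for p in pairs],
        },
    )


def load_fixture_network(corrected: bool = True, asymmetry_policy: str = "error") -> NetworkModel:
    """The published 24-node burnout–depression network.

    ``corrected=True`` (default) returns the symmetric matrix with the
    single transcription conflict resolved; ``corrected=False`` returns
    the raw transcription, in which case an ``asymmetry_policy`` other
    than ``"error"`` must be chosen to obtain a symmetric model.
    """
    name = "published_network.csv" if corrected else "published_network_raw.csv"
    with resources.as_file(_data_path(name)) as p:
        net = load_adjacency(p, asymmetry_policy=asymmetry_policy, provenance="published fixture")
    net.provenance["fixture"] = name
    if corrected:
        net.provenance["correction_log"] = list(FIXTURE_CORRECTION_LOG)
    return net


@dataclass
class RunConfig:
    """Validated settings bundle for an end-to-end analysis run."""

    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    pd_floor: float = 1e-6
    n_boot_edges: int = 1000
    n_boot_per_drop: int = 250
    drop_grid: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.751, 0.05), 2))
    cs_threshold_r: float = 0.7
    cs_confidence: float = 0.95
    alpha: float = 0.05
    seed: int = 0
    burnout_cutoff: float = 34
    burnout_cutoff_inclusive: bool = False
    depression_cutoff: float = 5
    depression_cutoff_inclusive: bool = True

    def __post_init__(self):
        if not 0 <= self.gamma:
            raise ValueError("gamma must be nonnegative")
        if self.n_lambda < 1:
            raise ValueError("n_lambda must be >= 1")
        if not 0 < self.lambda_min_ratio <= 1:
            raise ValueError("lambda_min_ratio must be in (0, 1]")
        if self.n_boot_edges < 1 or self.n_boot_per_drop < 1:
            raise ValueError("bootstrap counts must be positive")
        grid = tuple(float(g) for g in self.drop_grid)
        if any(not 0 < g <= 0.8 for g in grid) or any(
            b <= a for a, b in zip(grid, grid[1:])
        ):
            raise ValueError("drop grid must be strictly increasing within (0, 0.8]")
        self.drop_grid = grid
        if not 0 < self.cs_threshold_r <= 1:
            raise ValueError("cs_threshold_r must be in (0, 1]")
        if not 0 < self.cs_confidence < 1:
            raise ValueError("cs_confidence must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = open(path).read()
        payload = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        if "drop_grid" in payload:
            payload["drop_grid"] = tuple(payload["drop_grid"])
        return cls(**payload)

    def to_file(self, path) -> None:
        payload = asdict(self)
        payload["drop_grid"] = list(self.drop_grid)
        with open(path, "w") as fh:
            if str(path).endswith((".yml", ".yaml")):
                yaml.safe_dump(payload, fh)
            else:
                json.dump(payload, fh, indent=2)
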