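"""Nodewise predictability: variance of each node explained by the rest.

Items are treated as continuous (the Gaussian working model of the
network); predictability of node j is the R-squared of an ordinary
least-squares regression of the standardized item on all other
standardized items. For multivariate Gaussian data with covariance
Sigma and precision K the population value is 1 - 1/(Sigma_jj K_jj).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PredictabilityTable", "node_predictability", "summarize_predictability"]

_RIDGE = 1e-8  # stabilizer used only when the design is singular


@dataclass
class PredictabilityTable:
    values: pd.Series  # node -> R^2 in [0, 1]
    method: str
    ridge_nodes: tuple[str, ...] = ()

    def __post_init__(self):
        v = self.values.astype(float)
        if ((v < -1e-9) | (v > 1 + 1e-9)).any():
            raise ValueError("R^2 values must lie in [0, 1]")
        self.values = v.clip(0.0, 1.0)

    def to_csv(self, path) -> None:
        self.values.rename("predictability").to_csv(path, index_label="node")


def node_predictability(responses) -> PredictabilityTable:
    """R^2 of each standardized item regressed on all other items (OLS).

    Singular designs (e.g. duplicated items) fall back to a minimally
    ridge-stabilized solve; affected nodes are flagged.
    """
    df = getattr(responses, "data", responses)
    if df.isna().any().any():
        raise ValueError("responses must be complete")
    n, p = df.shape
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    X = df.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        const = [c for c, s in zip(df.columns, sd) if s == 0]
        raise ValueError(f"constant items cannot be predicted: {const}")
    X = X / sd

    r2 = np.empty(p)
    ridge_nodes = []
    for j in range(p):
        y = X[:, j]
        Z = np.delete(X, j, axis=1)
        G = Z.T @ Z
        b = Z.T @ y
        try:
            coef = np.linalg.solve(G, b)
            if not np.isfinite(coef).all():
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            coef = np.linalg.solve(G + _RIDGE * np.eye(p - 1), b)
            ridge_nodes.append(df.columns[j])
        resid = y - Z @ coef
        r2[j] = 1.0 - resid @ resid / (y @ y)
    method = "nodewise-ols" if not ridge_nodes else "nodewise-ols+ridge"
    return PredictabilityTable(
        values=pd.Series(np.clip(r2, 0.0, 1.0), index=df.columns, name="predictability"),
        method=method,
        ridge_nodes=tuple(ridge_nodes),
    )


def summarize_predictability(table) -> tuple[float, float, float]:
    """(min, max, mean) of the per-node R^2, rounded to 2 decimals."""
    vals = table.values if isinstance(table, PredictabilityTable) else pd.Series(table)
    vals = np.asarray(vals, dtype=float)
    if vals.size == 0:
        raise ValueError("empty predictability table")
    return (
        float(np.round(vals.min(), 2)),
        float(np.round(vals.max(), 2)),
        float(np.round(vals.mean(), 2)),
    )
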