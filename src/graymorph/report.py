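"""Population summaries and feature correlation analysis.

Quartile tables (Q1/median/Q3 with linear-interpolation quantiles) per
group and feature, and Spearman rank-correlation matrices across features
with Bonferroni correction over all tested off-diagonal pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PopulationSummary", "CorrelationMatrix", "summarize", "spearman_matrix"]


@dataclass
class PopulationSummary:
    table: pd.DataFrame  # index (group, feature); columns Q1, median, Q3, n

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path)


@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    n: pd.DataFrame

    def to_csv(self, path_prefix: str) -> None:
        self.rho.to_csv(path_prefix + "_rho.csv")
        self.p_adjusted.to_csv(path_prefix + "_padj.csv")


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r if isinstance(r, dict) else r.to_dict() for r in records])


def summarize(records, grouping: str | None = None) -> PopulationSummary:
    """Per-group, per-feature quartiles.

    ``records`` is a DataFrame or list of record dicts; ``grouping`` names
    a column of group labels (e.g. cell type).  Missing values are excluded
    per feature; ``n`` counts the values actually used.
    """
    df = _as_frame(records)
    groups = (
        df.groupby(grouping) if grouping else [("all", df)]
    )
    rows = []
    for gname, g in groups:
        feats = g.select_dtypes(include=[np.number]).columns
        for feat in feats:
            vals = g[feat].dropna()
            if len(vals) == 0:
                continue
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])  # linear interp
            rows.append(
                {"group": gname, "feature": feat,
                 "Q1": q1, "median": med, "Q3": q3, "n": len(vals)}
            )
    table = pd.DataFrame(rows).set_index(["group", "feature"])
    return PopulationSummary(table=table)


def spearman_matrix(records, features: list[str] | None = None) -> CorrelationMatrix:
    """Spearman rank correlations between features, Bonferroni-adjusted.

    Average ranks are used for ties; the Bonferroni family is all
    off-diagonal feature pairs (m = k(k-1)/2), adjusted p = min(1, p * m).
    """
    df = _as_frame(records)
    if features is None:
        features = list(df.select_dtypes(include=[np.number]).columns)
    k = len(features)
    rho = np.eye(k)
    p_raw = np.zeros((k, k))
    n_mat = np.zeros((k, k), dtype=int)
    m = k * (k - 1) // 2
    for i in range(k):
        n_mat[i, i] = df[features[i]].notna().sum()
        for j in range(i + 1, k):
            pair = df[[features[i], features[j]]].dropna()
            n_mat[i, j] = n_mat[j, i] = len(pair)
            if len(pair) < 3 or pair.iloc[:, 0].nunique() < 2 or pair.iloc[:, 1].nunique() < 2:
                rho[i, j] = rho[j, i] = np.nan
                p_raw[i, j] = p_raw[j, i] = np.nan
                continue
            r, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rho[i, j] = rho[j, i] = r
            p_raw[i, j] = p_raw[j, i] = p
    p_adj = np.minimum(p_raw * m, 1.0)
    np.fill_diagonal(p_adj, 0.0)
    idx = pd.Index(features)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p_raw=pd.DataFrame(p_raw, index=idx, columns=idx),
        p_adjusted=pd.DataFrame(p_adj, index=idx, columns=idx),
        n=pd.DataFrame(n_mat, index=idx, columns=idx),
    )
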