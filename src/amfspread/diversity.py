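"""Plant-community summary metrics from point-intersect cover tables.

Per quadrat: species richness, Shannon diversity H (natural log) and Pielou
evenness J = H / ln(richness).  Evenness is undefined at richness 1 and is
flagged (NaN) rather than forced to 0 or 1, so it never biases group means.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def diversity_metrics(
    cover: pd.DataFrame, species_columns: list[str] | None = None, base: float = np.e
) -> pd.DataFrame:
    """Per-quadrat richness, Shannon H and Pielou evenness.

    ``cover`` holds one row per quadrat; ``species_columns`` (default: all
    numeric columns) are non-negative hit counts.  Empty quadrats get NaN
    metrics with a warning.
    """
    if species_columns is None:
        species_columns = [
            c for c in cover.columns if pd.api.types.is_numeric_dtype(cover[c])
        ]
    hits = cover[species_columns].to_numpy(float)
    if (hits < 0).any():
        raise ValueError("cover table contains negative hit counts")
    totals = hits.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} empty quadrat(s); metrics set to NaN")

    richness = (hits > 0).sum(axis=1).astype(float)
    shannon = np.full(len(hits), np.nan)
    evenness = np.full(len(hits), np.nan)
    for i in range(len(hits)):
        if empty[i]:
            continue
        p = hits[i] / totals[i]
        shannon[i] = stats.entropy(p, base=base)
        if richness[i] >= 2:
            evenness[i] = shannon[i] / (np.log(richness[i]) / np.log(base))
        # richness == 1: evenness undefined, stays NaN
    richness[empty] = np.nan

    out = cover.drop(columns=species_columns).copy()
    out["richness"] = richness
    out["shannon"] = shannon
    out["evenness"] = evenness
    return out


def group_summary(
    metrics: pd.DataFrame,
    by: list[str],
    value_columns: tuple[str, ...] = ("richness", "shannon", "evenness"),
) -> pd.DataFrame:
    """Mean, standard error and n per group for each metric.

    Groups with a single quadrat report an undefined (NaN) standard error;
    empty groups are simply absent from the output.
    """
    rows = []
    for key, grp in metrics.groupby(by):
        if not isinstance(key, tuple):
            key = (key,)
        row = dict(zip(by, key))
        for col in value_columns:
            vals = grp[col].dropna()
            n = len(vals)
            row[f"{col}_mean"] = vals.mean() if n else np.nan
            row[f"{col}_se"] = vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            row[f"{col}_n"] = n
        rows.append(row)
    return pd.DataFrame(rows)
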