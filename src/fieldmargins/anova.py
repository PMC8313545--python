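"""Sums-of-squares ANOVA engine shared by the yield and network stages.

Sequential (Type I) decomposition by default: factors enter the model in
the order given, and each factor's sum of squares is the drop in residual
sum of squares when its dummy block is added. Type II (each factor adjusted
for all others, no interactions) is available for unbalanced designs.
F statistics use the residual mean square of the full model; p-values come
from the F distribution.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("fieldmargins")


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and column rank of the least-squares fit."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _dummies(values: pd.Series) -> np.ndarray:
    d = pd.get_dummies(values.astype(str), drop_first=True, dtype=float)
    return d.to_numpy()


def anova_table(data: pd.DataFrame, response: str,
                factors: Sequence[str], ss_type: str = "I") -> pd.DataFrame:
    """ANOVA of ``response`` on categorical ``factors`` (no interactions).

    Returns a table with one row per factor plus a ``Residual`` row and
    columns ``df``, ``sum_sq``, ``mean_sq``, ``F``, ``p``. Factors with a
    single observed level are dropped with a warning. ``ss_type`` is
    ``"I"`` (sequential, default) or ``"II"``.
    """
    if ss_type not in ("I", "II"):
        raise ValueError("ss_type must be 'I' or 'II'")
    sub = data[[response, *factors]].dropna()
    y = sub[response].to_numpy(dtype=float)
    n = len(y)
    if n == 0:
        raise ValueError("anova_table: no complete observations")

    kept: list[str] = []
    blocks: list[np.ndarray] = []
    for f in factors:
        if sub[f].nunique() < 2:
            logger.warning("factor '%s' has a single level; dropped from "
                           "the ANOVA", f)
            continue
        kept.append(f)
        blocks.append(_dummies(sub[f]))
    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept, *blocks]) if blocks else intercept
    rss_full, rank_full = _rss(X_full, y)
    # snap numerically-zero sums of squares (degenerate, e.g. constant y)
    tss = float(((y - y.mean()) ** 2).sum())
    tol = 1e-10 * max(tss, 1.0)
    if rss_full < tol:
        rss_full = 0.0
    df_resid = n - rank_full
    ms_resid = rss_full / df_resid if df_resid > 0 else np.nan

    rows = []
    if ss_type == "I":
        X = intercept
        rss_prev, rank_prev = _rss(X, y)
        for f, B in zip(kept, blocks):
            X = np.hstack([X, B])
            rss_cur, rank_cur = _rss(X, y)
            ss = rss_prev - rss_cur
            df = rank_cur - rank_prev
            rows.append((f, df, ss))
            rss_prev, rank_prev = rss_cur, rank_cur
    else:
        for i, f in enumerate(kept):
            others = [B for j, B in enumerate(blocks) if j != i]
            X_red = np.hstack([intercept, *others]) if others else intercept
            rss_red, rank_red = _rss(X_red, y)
            rows.append((f, rank_full - rank_red, rss_red - rss_full))

    out = []
    for f, df, ss in rows:
        ss = 0.0 if abs(ss) < tol else max(ss, 0.0)
        ms = ss / df if df > 0 else np.nan
        F = ms / ms_resid if df_resid > 0 and ms_resid > 0 else (
            0.0 if ss <= tol else np.inf)
        p = float(stats.f.sf(F, df, df_resid)) if df_resid > 0 else np.nan
        out.append((f, df, ss, ms, F, p))
    out.append(("Residual", df_resid, rss_full,
                ms_resid, np.nan, np.nan))
    table = pd.DataFrame(out, columns=["term", "df", "sum_sq", "mean_sq",
                                       "F", "p"]).set_index("term")
    table.attrs["ss_type"] = ss_type
    table.attrs["n"] = n
    return table


def oneway(values, groups) -> tuple[float, int, int, float]:
    """One-way ANOVA; returns (F, df_between, df_within, p)."""
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "g": np.asarray(groups)})
    tab = anova_table(df, "y", ["g"])
    if "g" not in tab.index:       # single group: F undefined
        return np.nan, 0, int(tab.loc["Residual", "df"]), np.nan
    row = tab.loc["g"]
    return (float(row["F"]), int(row["df"]),
            int(tab.loc["Residual", "df"]), float(row["p"]))
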