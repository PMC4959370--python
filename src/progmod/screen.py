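"""Genome-wide quartile survival screening.

For every gene, patients are split into the bottom and top expression
quartiles; a log-rank test and hazard ratio (top vs. bottom quartile)
compare the two groups, and the expression separation of the quartiles is
summarized as a fold change.  A gene is called over-expressed in poor
survival (HIGH_POOR) when its hazard ratio exceeds 1, its BH-adjusted
p-value clears the cutoff (default 0.001) and the quartile medians are
separated by at least the fold-change cutoff (default 2); under-expressed
in poor survival (LOW_POOR) is the mirror call with hazard ratio below 1.

Fold change is the ratio of the top-quartile group's median expression to
the bottom-quartile group's on the linear scale (log-scale input is
un-logged base 2 first).  Because quartiles of a gene's own expression
are ordered, this ratio is always >= 1 and encodes separation magnitude;
direction is carried entirely by the hazard ratio.  A strict-literal
variant (requiring the ratio > 2 for HIGH_POOR and the inverse ratio
< 0.5 for LOW_POOR, which the separation reading makes equivalent) is
available via ``fc_mode='literal'``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .survival import adjust_pvalues, hazard_ratio, logrank

__all__ = [
    "ScreenConfig",
    "quartile_groups",
    "screen_gene",
    "screen_all",
    "QuartileSurvivalScreen",
]

HIGH_POOR = "HIGH_POOR"
LOW_POOR = "LOW_POOR"
NONE = "NONE"


@dataclass(frozen=True)
class ScreenConfig:
    """Screening thresholds.

    adj_p_cutoff: BH-adjusted p-value cutoff (default 0.001).
    fc_cutoff: minimum top/bottom quartile median ratio, linear scale.
    fraction: quantile fraction per tail (default 0.25 = quartiles).
    """

    adj_p_cutoff: float = 0.001
    fc_cutoff: float = 2.0
    fraction: float = 0.25
    scale_hint: str = "linear"   # 'linear' | 'log' (log2)
    hr_method: str = "cox"       # 'cox' | 'pike'
    fc_mode: str = "separation"  # 'separation' | 'literal'
    adjust_method: str = "bh"

    def __post_init__(self):
        if not (0 < self.fraction <= 0.5):
            raise ValueError("fraction must be in (0, 0.5]")
        if self.adj_p_cutoff <= 0 or self.fc_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


def quartile_groups(values, fraction: float = 0.25):
    """Index the bottom- and top-``fraction`` samples of one gene.

    Returns (low_idx, high_idx): positions of the floor(n*fraction)
    smallest and largest values.  Ties across the cut are resolved
    deterministically by stable sort order (value, then input position).
    Raises on a constant vector (no split exists).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    k = int(math.floor(n * fraction))
    if k < 1:
        raise ValueError(f"{n} samples with fraction {fraction} leaves an empty tail")
    if np.all(v == v[0]):
        raise ValueError("constant expression: quartile split is degenerate")
    order = np.argsort(v, kind="stable")
    return order[:k], order[n - k:]


def _fold_change(values, low_idx, high_idx, scale_hint: str) -> float:
    """Top/bottom quartile-group median ratio on the linear scale."""
    v = np.asarray(values, dtype=float)
    if scale_hint == "log":
        return float(2.0 ** (np.median(v[high_idx]) - np.median(v[low_idx])))
    lo = float(np.median(v[low_idx]))
    hi = float(np.median(v[high_idx]))
    if lo <= 0:
        return float("nan")
    return hi / lo


def _call_direction(hr, p_adj, fc, cfg: ScreenConfig) -> str:
    if not (np.isfinite(hr) and np.isfinite(p_adj) and np.isfinite(fc)):
        return NONE
    if p_adj >= cfg.adj_p_cutoff:
        return NONE
    if cfg.fc_mode == "literal":
        # ratio is oriented high/low, so the low-direction criterion
        # "(fourth/first) < 0.5" is the same separation bound inverted
        if hr > 1 and fc > cfg.fc_cutoff:
            return HIGH_POOR
        if hr < 1 and (1.0 / fc) < (1.0 / cfg.fc_cutoff):
            return LOW_POOR
        return NONE
    if fc < cfg.fc_cutoff:
        return NONE
    if hr > 1:
        return HIGH_POOR
    if hr < 1:
        return LOW_POOR
    return NONE


def screen_gene(values, times, events, config: ScreenConfig | None = None,
                p_adj: float | None = None) -> dict:
    """Screen a single gene; returns a stats record.

    ``p_adj`` is normally assigned later across the whole screen; when
    given (single-gene use) the direction call uses it directly.
    """
    cfg = config or ScreenConfig()
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    rec = {"hr": np.nan, "p_raw": np.nan, "p_adj": np.nan,
           "fold_change": np.nan, "direction": NONE, "flag": ""}
    try:
        low_idx, high_idx = quartile_groups(v, cfg.fraction)
    except ValueError:
        rec["flag"] = "degenerate_expression"
        return rec
    th, eh = t[high_idx], e[high_idx]
    tl, el = t[low_idx], e[low_idx]
    if eh.sum() == 0 or el.sum() == 0:
        rec["flag"] = "zero_events_in_group"
        return rec
    lr = logrank(th, eh, tl, el)
    hr = hazard_ratio(th, eh, tl, el, method=cfg.hr_method)
    rec["hr"] = hr
    rec["p_raw"] = lr.p_value
    rec["fold_change"] = _fold_change(v, low_idx, high_idx, cfg.scale_hint)
    if lr.degenerate:
        rec["flag"] = "degenerate_logrank"
        return rec
    if p_adj is not None:
        rec["p_adj"] = p_adj
        rec["direction"] = _call_direction(hr, p_adj, rec["fold_change"], cfg)
    return rec


def screen_all(expr: pd.DataFrame, surv: pd.DataFrame,
               config: ScreenConfig | None = None):
    """Screen every gene of a genes-x-samples matrix.

    p-values are BH-adjusted across all testable genes before
    thresholding.  Returns (high_genes, low_genes, stats) where stats is
    a per-gene DataFrame (hr, p_raw, p_adj, fold_change, direction,
    flag) in the input gene order.
    """
    cfg = config or ScreenConfig()
    if list(expr.columns) != list(surv.index):
        raise ValueError("expression and clinical tables are not aligned")
    t = surv["time"].to_numpy(dtype=float)
    e = surv["event"].to_numpy(dtype=int)
    X = expr.to_numpy(dtype=float)
    records = [screen_gene(X[i], t, e, cfg) for i in range(X.shape[0])]
    stats = pd.DataFrame(records, index=expr.index)
    stats.index.name = "gene"
    stats["p_adj"] = adjust_pvalues(stats["p_raw"].to_numpy(), cfg.adjust_method)
    stats["direction"] = [
        _call_direction(h, pa, fc, cfg) if fl == "" else NONE
        for h, pa, fc, fl in zip(stats["hr"], stats["p_adj"],
                                 stats["fold_change"], stats["flag"])
    ]
    high = stats.index[stats["direction"] == HIGH_POOR].tolist()
    low = stats.index[stats["direction"] == LOW_POOR].tolist()
    return high, low, stats


class QuartileSurvivalScreen(BaseEstimator):
    """Per-gene quartile survival screen as a scikit-learn estimator.

    Parameters mirror :class:`ScreenConfig`.  ``fit`` takes ``X`` as a
    samples-x-genes DataFrame (or array) and ``y`` as a survival outcome:
    either a structured array with ``time``/``event`` fields (as used by
    scikit-survival) or a DataFrame/2-column array of (time, event).

    Attributes
    ----------
    stats_ : DataFrame of per-gene hr, p_raw, p_adj, fold_change,
        direction, flag.
    high_genes_, low_genes_ : genes called over-/under-expressed in
        poor survival.
    """

    def __init__(self, adj_p_cutoff=0.001, fc_cutoff=2.0, fraction=0.25,
                 scale_hint="linear", hr_method="cox", fc_mode="separation",
                 adjust_method="bh"):
        self.adj_p_cutoff = adj_p_cutoff
        self.fc_cutoff = fc_cutoff
        self.fraction = fraction
        self.scale_hint = scale_hint
        self.hr_method = hr_method
        self.fc_mode = fc_mode
        self.adjust_method = adjust_method

    def _config(self) -> ScreenConfig:
        return ScreenConfig(
            adj_p_cutoff=self.adj_p_cutoff, fc_cutoff=self.fc_cutoff,
            fraction=self.fraction, scale_hint=self.scale_hint,
            hr_method=self.hr_method, fc_mode=self.fc_mode,
            adjust_method=self.adjust_method,
        )

    def fit(self, X, y):
        expr, surv = _as_expr_surv(X, y)
        self.high_genes_, self.low_genes_, self.stats_ = screen_all(
            expr, surv, self._config())
        self.n_features_in_ = expr.shape[0]
        return self


def _as_expr_surv(X, y) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize sklearn-style (X samples-x-genes, y survival) inputs to
    the genes-x-samples matrix + clinical table convention."""
    if isinstance(X, pd.DataFrame):
        expr = X.T.copy()
    else:
        X = np.asarray(X, dtype=float)
        expr = pd.DataFrame(
            X.T,
            index=[f"g{i}" for i in range(X.shape[1])],
            columns=[f"s{i}" for i in range(X.shape[0])],
        )
    if isinstance(y, pd.DataFrame):
        surv = pd.DataFrame(
            {"time": y["time"].to_numpy(dtype=float),
             "event": y["event"].to_numpy(dtype=int)},
            index=expr.columns,
        )
    elif hasattr(y, "dtype") and getattr(y.dtype, "names", None):
        names = y.dtype.names
        tname = next(n for n in names if n.lower() in ("time", "futime", "t"))
        ename = next(n for n in names if n.lower() in ("event", "status", "e"))
        surv = pd.DataFrame(
            {"time": np.asarray(y[tname], dtype=float),
             "event": np.asarray(y[ename]).astype(int)},
            index=expr.columns,
        )
    else:
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError(
                "y must be a (time, event) structure: structured array, "
                "DataFrame with time/event columns, or (n, 2) array"
            )
        surv = pd.DataFrame({"time": y[:, 0].astype(float),
                             "event": y[:, 1].astype(int)}, index=expr.columns)
    if surv.shape[0] != expr.shape[1]:
        raise ValueError("X and y disagree on the number of samples")
    return expr, surv
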