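"""Per-sample prognostic scores and risk stratification.

A module scores a sample as the ratio of the median expression of its
high-side genes (over-expressed in poor survival) to the median of its
low-side genes — a scalar that rises when the poor-prognosis program
dominates.  On log-scale data the ratio of medians is replaced by their
difference (``mode='difference'``), which is the same quantity in log
units and is well defined for negative values.

Patients are stratified either at the score median (high/low) or into
score quartiles (top 25% = high, middle 50% = medium, bottom 25% = low).
Module genes absent from a matrix — e.g. when scoring a cohort profiled
on a different platform — are dropped with a logged count.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .modules import PrognosticModule

logger = logging.getLogger(__name__)

__all__ = ["module_score", "stratify", "match_genes", "ModuleScorer"]


def match_genes(module: PrognosticModule, gene_index) -> tuple[list, list]:
    """Restrict a module to the genes present in a matrix; logs drops."""
    gene_index = pd.Index(gene_index)
    high = [g for g in module.high_genes if g in gene_index]
    low = [g for g in module.low_genes if g in gene_index]
    n_missing = module.n_genes - len(high) - len(low)
    if n_missing:
        logger.info("%s: %d of %d module genes absent from the matrix",
                    module.label, n_missing, module.n_genes)
    return high, low


def module_score(expr: pd.DataFrame, module: PrognosticModule,
                 mode: str = "ratio") -> pd.Series:
    """Score every sample of a genes-x-samples matrix against a module.

    ratio mode: median(high-side expression) / median(low-side), per
    sample; difference mode (log-scale data): median(high) - median(low).
    Requires at least one matched gene per side.
    """
    high, low = match_genes(module, expr.index)
    if not high or not low:
        raise ValueError(
            f"{module.label}: no matched genes on the "
            f"{'high' if not high else 'low'} side"
        )
    med_hi = expr.loc[high].median(axis=0)
    med_lo = expr.loc[low].median(axis=0)
    if mode == "ratio":
        if (med_lo <= 0).any():
            raise ValueError(
                f"{module.label}: non-positive low-side median expression; "
                "use mode='difference' for log-scale data"
            )
        s = med_hi / med_lo
    elif mode == "difference":
        s = med_hi - med_lo
    else:
        raise ValueError(f"unknown scoring mode: {mode!r}")
    s.name = module.label
    return s


def stratify(scores: pd.Series, scheme: str = "median") -> pd.Series:
    """Assign risk-group labels from scores.

    median scheme: above the median = 'high', else 'low'; quartile
    scheme: top 25% of samples = 'high', middle 50% = 'medium', bottom
    25% = 'low' (requires >= 4 samples).  Group sizes are fixed by rank,
    so labels are invariant under any strictly increasing transform of
    the scores; ties are resolved by stable (score, sample-order) rank.
    Raises when all scores are identical.
    """
    s = pd.Series(scores)
    n = len(s)
    if s.nunique() <= 1:
        raise ValueError("all scores identical: no stratification possible")
    order = np.argsort(s.to_numpy(), kind="stable")
    labels = np.empty(n, dtype=object)
    if scheme == "median":
        k = n // 2  # lower half (incl. median on odd n) = low
        labels[order[: n - k]] = "low"
        labels[order[n - k:]] = "high"
    elif scheme == "quartile":
        if n < 4:
            raise ValueError("quartile stratification needs >= 4 samples")
        q = n // 4
        labels[order[:q]] = "low"
        labels[order[q: n - q]] = "medium"
        labels[order[n - q:]] = "high"
    else:
        raise ValueError(f"unknown stratification scheme: {scheme!r}")
    return pd.Series(labels, index=s.index, name="group")


class ModuleScorer(BaseEstimator, TransformerMixin):
    """Prognostic-module scoring as a scikit-learn transformer.

    ``transform`` maps a samples-x-genes DataFrame to a samples-x-modules
    DataFrame of scores.  Stateless apart from its parameters; ``fit``
    only records the gene universe.

    Parameters
    ----------
    modules : list of PrognosticModule
    mode : 'ratio' (linear-scale data) or 'difference' (log-scale).
    """

    def __init__(self, modules=(), mode="ratio"):
        self.modules = modules
        self.mode = mode

    def fit(self, X, y=None):
        if not len(self.modules):
            raise ValueError("no modules to score")
        self.n_features_in_ = np.asarray(X).shape[1] if not isinstance(
            X, pd.DataFrame) else X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("ModuleScorer needs a DataFrame with gene columns")
        expr = X.T
        cols = {m.label: module_score(expr, m, mode=self.mode)
                for m in self.modules}
        return pd.DataFrame(cols, index=X.index)

    def get_feature_names_out(self, input_features=None):
        return np.asarray([m.label for m in self.modules], dtype=object)
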