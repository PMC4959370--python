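"""Differential expression between TNBC and non-TNBC tumors.

Per-gene Welch (unequal-variance) t-tests on log2-scale expression with
Benjamini-Hochberg FDR control.  A gene is called UP in TNBC when its
mean log2 fold change (TNBC minus non-TNBC) reaches +lfc_cutoff with raw
p < p_cutoff and FDR < fdr_cutoff; DOWN is the mirror call.  Calls from
several cohorts can be intersected, and module gene sets can be overlaid
on the calls to report which module genes are TNBC-regulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .modules import PrognosticModule
from .survival import adjust_pvalues

__all__ = ["deg_screen", "intersect_calls", "overlap_modules",
           "TNBCDifferentialExpression"]

UP = "UP"
DOWN = "DOWN"
NONE = "NONE"


def deg_screen(expr: pd.DataFrame, labels, *, p_cutoff: float = 0.05,
               fdr_cutoff: float = 0.05, lfc_cutoff: float = 0.5) -> pd.DataFrame:
    """Welch t-test DEG screen on a genes-x-samples log2 matrix.

    ``labels`` is a boolean/0-1 vector over samples (True = TNBC).  The
    fold-change gate requires |log2FC| >= lfc_cutoff; genes constant in
    both groups are flagged and not called.  Returns a DataFrame with
    log2fc, p_raw, p_fdr, call, flag per gene.
    """
    lab = np.asarray(labels).astype(bool)
    if lab.size != expr.shape[1]:
        raise ValueError("labels length must equal the number of samples")
    n1, n0 = int(lab.sum()), int((~lab).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    X = expr.to_numpy(dtype=float)
    a, b = X[:, lab], X[:, ~lab]
    logfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tt = sps.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(tt.pvalue, dtype=float)
    const = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    p = np.where(const, np.nan, p)
    fdr = adjust_pvalues(p)
    call = np.full(expr.shape[0], NONE, dtype=object)
    sig = (~np.isnan(p)) & (p < p_cutoff) & (fdr < fdr_cutoff)
    call[sig & (logfc >= lfc_cutoff)] = UP
    call[sig & (logfc <= -lfc_cutoff)] = DOWN
    out = pd.DataFrame({
        "log2fc": logfc, "p_raw": p, "p_fdr": fdr, "call": call,
        "flag": np.where(const, "constant_expression", ""),
    }, index=expr.index)
    out.index.name = "gene"
    return out


def intersect_calls(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Consensus calls across cohorts: a gene is UP (DOWN) only when it
    is called UP (DOWN) in every table it appears in, over the shared
    gene set."""
    if not tables:
        raise ValueError("no DEG tables to intersect")
    genes = tables[0].index
    for t in tables[1:]:
        genes = genes.intersection(t.index)
    calls = pd.DataFrame({i: t.loc[genes, "call"] for i, t in enumerate(tables)})
    consensus = np.where((calls == UP).all(axis=1), UP,
                         np.where((calls == DOWN).all(axis=1), DOWN, NONE))
    return pd.DataFrame({"call": consensus}, index=genes)


def overlap_modules(deg_table: pd.DataFrame,
                    modules: list[PrognosticModule]) -> pd.DataFrame:
    """Per-module counts and identities of TNBC-regulated genes.

    One row per module with, for each side, the genes called UP and DOWN
    and their counts.
    """
    calls = deg_table["call"]
    rows = []
    for m in modules:
        rec = {"module": m.label}
        for side, genes in (("high", m.high_genes), ("low", m.low_genes)):
            up = sorted(g for g in genes if calls.get(g) == UP)
            down = sorted(g for g in genes if calls.get(g) == DOWN)
            rec[f"{side}_up"] = up
            rec[f"{side}_down"] = down
            rec[f"n_{side}_up"] = len(up)
            rec[f"n_{side}_down"] = len(down)
        rec["n_deg_total"] = (rec["n_high_up"] + rec["n_high_down"]
                              + rec["n_low_up"] + rec["n_low_down"])
        rows.append(rec)
    return pd.DataFrame(rows).set_index("module")


class TNBCDifferentialExpression(BaseEstimator):
    """Two-group Welch-t DEG screen as a scikit-learn estimator.

    ``fit(X, y)`` takes a samples-x-genes DataFrame and a binary label
    vector (True = TNBC); fitted attributes expose the per-gene results
    table and the UP/DOWN gene lists.
    """

    def __init__(self, p_cutoff=0.05, fdr_cutoff=0.05, lfc_cutoff=0.5):
        self.p_cutoff = p_cutoff
        self.fdr_cutoff = fdr_cutoff
        self.lfc_cutoff = lfc_cutoff

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"g{i}" for i in range(X.shape[1])]
        self.results_ = deg_screen(
            X.T, np.asarray(y), p_cutoff=self.p_cutoff,
            fdr_cutoff=self.fdr_cutoff, lfc_cutoff=self.lfc_cutoff)
        self.up_genes_ = self.results_.index[self.results_["call"] == UP].tolist()
        self.down_genes_ = self.results_.index[self.results_["call"] == DOWN].tolist()
        self.n_features_in_ = X.shape[1]
        return self
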