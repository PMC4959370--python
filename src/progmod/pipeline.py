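"""End-to-end prognostic-module discovery as one estimator.

``PrognosticModuleDiscovery.fit`` runs the quartile survival screen on a
training cohort and assembles the clique/bi-clique modules; ``transform``
scores any cohort (training or held-out) against the fitted modules, so
the whole method drops into scikit-learn pipelines and model selection.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .modules import ModuleBuildConfig, build_modules
from .scoring import ModuleScorer
from .screen import QuartileSurvivalScreen, _as_expr_surv

__all__ = ["PrognosticModuleDiscovery"]


class PrognosticModuleDiscovery(BaseEstimator, TransformerMixin):
    """Discover paired-gene-set prognostic modules from expression + survival.

    Parameters combine the three stages: the per-gene quartile survival
    screen (adj_p_cutoff, fc_cutoff, fraction, scale_hint), the
    co-expression clique clustering and anticorrelation bi-clique pairing
    (pos_threshold, neg_threshold, min_cluster_size, max_clusters), and
    the scoring mode ('ratio' for linear-scale data, 'difference' for
    log-scale).

    ``fit(X, y)``: X samples-x-genes DataFrame, y survival outcome
    (structured time/event array, DataFrame, or (n, 2) array).
    ``transform(X)``: samples-x-modules score matrix.

    Attributes
    ----------
    screen_ : fitted QuartileSurvivalScreen (per-gene stats, gene lists)
    modules_ : list of PrognosticModule
    scorer_ : fitted ModuleScorer
    """

    def __init__(self, adj_p_cutoff=0.001, fc_cutoff=2.0, fraction=0.25,
                 scale_hint="linear", hr_method="cox",
                 pos_threshold=0.4, neg_threshold=0.4,
                 min_cluster_size=16, max_clusters=2, node_budget=500,
                 score_mode="ratio"):
        self.adj_p_cutoff = adj_p_cutoff
        self.fc_cutoff = fc_cutoff
        self.fraction = fraction
        self.scale_hint = scale_hint
        self.hr_method = hr_method
        self.pos_threshold = pos_threshold
        self.neg_threshold = neg_threshold
        self.min_cluster_size = min_cluster_size
        self.max_clusters = max_clusters
        self.node_budget = node_budget
        self.score_mode = score_mode

    def fit(self, X, y):
        expr, _ = _as_expr_surv(X, y)
        self.screen_ = QuartileSurvivalScreen(
            adj_p_cutoff=self.adj_p_cutoff, fc_cutoff=self.fc_cutoff,
            fraction=self.fraction, scale_hint=self.scale_hint,
            hr_method=self.hr_method,
        ).fit(X, y)
        cfg = ModuleBuildConfig(
            pos_threshold=self.pos_threshold, neg_threshold=self.neg_threshold,
            min_cluster_size=self.min_cluster_size,
            max_clusters=self.max_clusters, node_budget=self.node_budget,
        )
        self.modules_ = build_modules(
            expr, self.screen_.high_genes_, self.screen_.low_genes_, cfg)
        self.scorer_ = None
        if self.modules_:
            self.scorer_ = ModuleScorer(self.modules_, mode=self.score_mode)
            self.scorer_.fit(X)
        self.n_features_in_ = expr.shape[0]
        return self

    def transform(self, X) -> pd.DataFrame:
        if self.scorer_ is None:
            raise RuntimeError("no modules were discovered; nothing to score")
        return self.scorer_.transform(X)
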