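"""Module validation on held-out cohorts and clinical-group association.

Validation scores a cohort with a module (matched genes only), stratifies
the patients, and compares the extreme strata with a log-rank test and
hazard ratio, attaching Kaplan-Meier curves per stratum.  Association
summarizes the score distribution across the levels of a categorical
covariate (subtype, TNBC, ER, grade, TP53 ...) with nonparametric tests:
Kruskal-Wallis omnibus for three or more levels, Mann-Whitney for two,
and BH-adjusted pairwise Mann-Whitney comparisons when the omnibus is
significant.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .modules import PrognosticModule
from .scoring import match_genes, module_score, stratify
from .survival import KMCurve, adjust_pvalues, hazard_ratio, km_curve, logrank

logger = logging.getLogger(__name__)

__all__ = ["ValidationReport", "GroupAssociation", "validate_module",
           "associate_scores", "plot_km"]


@dataclass
class ValidationReport:
    dataset: str
    module: str
    n_matched_high: int
    n_matched_low: int
    scheme: str
    scores: pd.Series
    groups: pd.Series
    km_curves: dict[str, KMCurve]
    logrank_p: float
    logrank_statistic: float
    hazard_ratio: float  # extreme high stratum vs. extreme low stratum

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "module": self.module,
            "n_matched_high": self.n_matched_high,
            "n_matched_low": self.n_matched_low,
            "scheme": self.scheme,
            "logrank_p": self.logrank_p,
            "logrank_statistic": self.logrank_statistic,
            "hazard_ratio": self.hazard_ratio,
            "group_sizes": self.groups.value_counts().to_dict(),
        }


@dataclass
class GroupAssociation:
    covariate: str
    levels: list[str]
    summaries: pd.DataFrame  # per level: n, median, q1, q3
    omnibus_test: str
    omnibus_p: float
    pairwise_p: pd.DataFrame | None = field(default=None)

    def to_dict(self) -> dict:
        d = {
            "covariate": self.covariate,
            "levels": self.levels,
            "summaries": self.summaries.to_dict(orient="index"),
            "omnibus_test": self.omnibus_test,
            "omnibus_p": self.omnibus_p,
        }
        if self.pairwise_p is not None:
            d["pairwise_p"] = self.pairwise_p.to_dict(orient="index")
        return d


def validate_module(
    module: PrognosticModule,
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    scheme: str = "median",
    mode: str = "ratio",
    min_matched: int = 3,
    dataset: str = "",
) -> ValidationReport:
    """Score + stratify a cohort and test the extreme strata.

    ``min_matched`` (default 3 genes per side) guards against scoring a
    cohort on a platform that carries too few of the module's genes.
    """
    if list(expr.columns) != list(surv.index):
        raise ValueError("expression and clinical tables are not aligned")
    high, low = match_genes(module, expr.index)
    if len(high) < min_matched or len(low) < min_matched:
        raise ValueError(
            f"{module.label}: only {len(high)}/{len(low)} high/low genes "
            f"matched; need >= {min_matched} per side"
        )
    matched = PrognosticModule(label=module.label, high_genes=tuple(high),
                               low_genes=tuple(low))
    scores = module_score(expr, matched, mode=mode)
    groups = stratify(scores, scheme=scheme)
    t = surv["time"].to_numpy(dtype=float)
    e = surv["event"].to_numpy(dtype=int)
    curves = {}
    for lab in pd.unique(groups):
        m = (groups == lab).to_numpy()
        curves[lab] = km_curve(t[m], e[m])
    hi = (groups == "high").to_numpy()
    lo = (groups == "low").to_numpy()
    lr = logrank(t[hi], e[hi], t[lo], e[lo])
    hr = hazard_ratio(t[hi], e[hi], t[lo], e[lo])
    return ValidationReport(
        dataset=dataset, module=module.label,
        n_matched_high=len(high), n_matched_low=len(low),
        scheme=scheme, scores=scores, groups=groups, km_curves=curves,
        logrank_p=lr.p_value, logrank_statistic=lr.statistic,
        hazard_ratio=hr,
    )


def associate_scores(scores: pd.Series, covariates: pd.DataFrame,
                     alpha: float = 0.05) -> dict[str, GroupAssociation]:
    """Score distribution across covariate levels, one report per column.

    Covariates with fewer than two non-empty levels are skipped with a
    log entry.  Pairwise Mann-Whitney p-values (BH-adjusted) are attached
    when the omnibus test is significant at ``alpha``.
    """
    out: dict[str, GroupAssociation] = {}
    for cov in covariates.columns:
        col = covariates[cov]
        mask = col.notna() & scores.notna()
        levels = sorted(pd.unique(col[mask]).astype(str))
        by_level = {lv: scores[mask & (col.astype(str) == lv)] for lv in levels}
        by_level = {lv: v for lv, v in by_level.items() if len(v) > 0}
        if len(by_level) < 2:
            logger.info("covariate %r skipped: fewer than two levels", cov)
            continue
        levels = sorted(by_level)
        summ = pd.DataFrame({
            lv: {"n": len(v), "median": float(v.median()),
                 "q1": float(v.quantile(0.25)), "q3": float(v.quantile(0.75))}
            for lv, v in by_level.items()
        }).T
        groups = [by_level[lv].to_numpy() for lv in levels]
        if len(levels) == 2:
            test = "mann-whitney"
            p = float(sps.mannwhitneyu(groups[0], groups[1],
                                       alternative="two-sided").pvalue)
        else:
            test = "kruskal-wallis"
            p = float(sps.kruskal(*groups).pvalue)
        pairwise = None
        if p < alpha and len(levels) > 2:
            pairs = list(itertools.combinations(range(len(levels)), 2))
            raw = [float(sps.mannwhitneyu(groups[i], groups[j],
                                          alternative="two-sided").pvalue)
                   for i, j in pairs]
            adj = adjust_pvalues(raw)
            pairwise = pd.DataFrame(np.nan, index=levels, columns=levels)
            for (i, j), a in zip(pairs, adj):
                pairwise.iloc[i, j] = a
                pairwise.iloc[j, i] = a
        out[cov] = GroupAssociation(covariate=cov, levels=levels,
                                    summaries=summ, omnibus_test=test,
                                    omnibus_p=p, pairwise_p=pairwise)
    return out


def plot_km(report: ValidationReport, path) -> None:
    """Kaplan-Meier plot of the report's strata (step curves with
    censoring ticks), written to ``path`` (format from the extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    order = [g for g in ("high", "medium", "low") if g in report.km_curves]
    for lab in order:
        c = report.km_curves[lab]
        t = np.concatenate([[0.0], c.event_times])
        s = np.concatenate([[1.0], c.survival_prob])
        ax.step(t, s, where="post", label=f"{lab} score")
        if c.censor_times.size:
            ax.plot(c.censor_times, c.survival_at(c.censor_times), "|",
                    color=ax.lines[-1].get_color(), markersize=6)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"{report.module} ({report.dataset or 'cohort'}): "
                 f"log-rank p = {report.logrank_p:.2e}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
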