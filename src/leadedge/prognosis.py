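"""Prognostic signature construction, single-sample enrichment scoring,
and survival stratification.

The S3 fibroblast signature is built in two steps: differential expression
(upregulated, significant genes) proposes candidates, and a small
gradient-boosted tree ensemble (S3 vs other fibroblasts, fixed seed and
budget) ranks them by total-gain importance; the top genes form the
signature.  Each bulk sample is then scored with a single-sample enrichment
statistic — a weighted Kolmogorov-Smirnov random walk down the sample's
expression ranking, in-set steps weighted by rank^alpha (alpha = 0.25) and
the score taken as the integrated difference of the in-set and out-set
cumulative walks.  Cohorts are split at the median score (ties to low) and
compared with the Kaplan-Meier product-limit estimator and the two-group
log-rank test.

The scoring statistic is used only ordinally (high/low split), so any
strictly monotone within-sample transform of expression leaves the
stratification unchanged.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .errors import ValidationError
from .io import GeneSet

logger = logging.getLogger(__name__)

XGB_PARAMS = dict(
    max_depth=3,
    n_estimators=200,
    learning_rate=0.1,
    tree_method="hist",
    n_jobs=1,
)


def select_s3_features(
    adata,
    de: pd.DataFrame,
    n_top: int = 20,
    seed: int = 0,
    target_label: str = "S3",
    groupby: str = "cluster",
) -> GeneSet:
    """Rank DE-candidate genes by gradient-boosted-tree importance.

    Candidates are the significant, upregulated genes of ``de``.  A
    classifier (target subtype vs the rest, in-sample — this is feature
    selection, not generalization) is trained on the candidate columns; genes
    are ranked by total-gain importance with ties broken by gene symbol and
    the top ``n_top`` returned as a GeneSet.
    """
    from xgboost import XGBClassifier

    labels = adata.obs[groupby]
    if labels.nunique() < 2:
        raise ValidationError("need at least two classes to select features")
    candidates = de.loc[de["significant"] & (de["log2fc"] > 0), "gene"]
    candidates = [g for g in candidates if g in set(adata.var_names)]
    if not candidates:
        raise ValidationError("no significant upregulated candidate genes")
    if n_top > len(candidates):
        logger.warning(
            "n_top=%d exceeds %d candidates; returning all candidates",
            n_top, len(candidates),
        )
        n_top = len(candidates)
    X = adata[:, candidates].X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    y = (labels == target_label).to_numpy().astype(int)
    clf = XGBClassifier(random_state=seed, **XGB_PARAMS)
    clf.fit(X, y)
    gain = clf.get_booster().get_score(importance_type="total_gain")
    importance = {
        g: gain.get(f"f{i}", 0.0) for i, g in enumerate(candidates)
    }
    ranked = sorted(importance, key=lambda g: (-importance[g], g))
    return GeneSet(
        name=f"{target_label}_signature",
        members=tuple(ranked[:n_top]),
        description="tree-ensemble-ranked DE genes",
    )


def ssgsea(expr: pd.Series, gs: GeneSet, alpha: float = 0.25) -> float:
    """Single-sample enrichment score of one expression vector.

    Genes are ranked by expression descending (ties broken by gene symbol);
    the top gene has rank weight N^alpha, the bottom 1^alpha.  Walking down
    the ranking, in-set positions add their normalized rank weight, out-set
    positions add 1/(N - |set ∩ genes|); the score is the sum over all
    positions of (cumulative in-set - cumulative out-set).  Depends on the
    expression vector only through its ranks.
    """
    genes = expr.index
    members = set(gs.members) & set(genes)
    if not members:
        raise ValidationError(f"no member of '{gs.name}' present")
    n = len(genes)
    n_out = n - len(members)
    if n_out == 0:
        raise ValidationError("gene set covers every gene; out-set is empty")
    values = expr.to_numpy(dtype=float)
    symbols = np.asarray(genes).astype(str)
    order = np.lexsort((symbols, -values))
    rank_weight = (np.arange(n, 0, -1, dtype=float)) ** alpha
    in_set = np.array([genes[i] in members for i in order])
    inc_in = np.where(in_set, rank_weight, 0.0)
    inc_in /= inc_in.sum()
    inc_out = np.where(in_set, 0.0, 1.0 / n_out)
    return float(np.sum(np.cumsum(inc_in) - np.cumsum(inc_out)))


def score_cohort(
    expr: pd.DataFrame, gs: GeneSet, alpha: float = 0.25
) -> pd.Series:
    """Per-sample enrichment scores, rescaled to [-1, 1] across the cohort.

    ``expr`` is genes x samples (bulk convention).  Scores are divided by
    the cohort's maximum absolute score; a single-sample cohort is returned
    raw with a warning.
    """
    raw = pd.Series(
        {s: ssgsea(expr[s], gs, alpha=alpha) for s in expr.columns},
        name=f"score_{gs.name}",
    )
    if len(raw) < 2:
        logger.warning("single-sample cohort; rescaling skipped")
        return raw
    max_abs = raw.abs().max()
    if max_abs == 0:
        return raw
    logger.info("cohort scores rescaled by max |score| = %.6g", max_abs)
    return raw / max_abs


def stratify(scores: pd.Series, rule: str = "median") -> pd.Series:
    """Split samples into high (> median) and low (<= median) score groups."""
    if rule != "median":
        raise ValidationError(f"unknown stratification rule '{rule}'")
    if len(scores) < 2:
        raise ValidationError("need at least two samples to stratify")
    if scores.nunique() == 1:
        raise ValidationError("all scores identical; cannot stratify")
    med = scores.median()
    return pd.Series(
        np.where(scores > med, "high", "low"), index=scores.index,
        name="group",
    )


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator.

    Returns one row per distinct event time with the at-risk count, number
    of events, and the survival estimate just after that time.  Subjects
    censored at t remain at risk at t.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValidationError("empty cohort")
    if (time <= 0).any():
        raise ValidationError("survival times must be positive")
    event_times = np.unique(time[event == 1])
    rows = []
    s = 1.0
    for t in event_times:
        n_at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_at_risk
        rows.append(
            {"time": float(t), "n_at_risk": n_at_risk, "n_events": d,
             "survival": s}
        )
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, two-sided p), df = 1.

    At each distinct event time the observed events in group 1 are compared
    with their hypergeometric expectation given the at-risk counts; the
    squared summed deviation over the summed variance is chi-square with one
    degree of freedom.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    names = np.unique(group)
    if len(names) != 2:
        raise ValidationError(
            f"log-rank requires exactly two non-empty groups, got {len(names)}"
        )
    g1 = group == names[0]
    observed_minus_expected = 0.0
    variance = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        expected = d * n1 / n
        observed_minus_expected += d1 - expected
        if n > 1:
            variance += d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        return 0.0, 1.0
    chi2 = observed_minus_expected ** 2 / variance
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return float(chi2), p
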