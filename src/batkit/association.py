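"""Biomarker-evaluation statistics.

Nonparametric throughout, matching the small per-group sample sizes of the
assay (2-16 donors): Spearman correlation of expression against the BAT fold
change (exact permutation p at small n), Mann-Whitney and Wilcoxon
matched-pairs comparisons with exact small-sample nulls, ROC analysis with a
DeLong confidence interval and a full threshold table, and a longitudinal
comparison helper for the 0/3/6-month clinical layer. All tests are
two-sided.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import benjamini_hochberg

logger = logging.getLogger(__name__)

_Z975 = stats.norm.ppf(0.975)


class AssociationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def _exact_spearman_p(x: np.ndarray, y: np.ndarray, chunk: int = 100_000) -> float:
    """Exact two-sided permutation p for the Spearman statistic.

    Enumerates all n! orderings of the y-ranks (Pearson on ranks handles
    ties); feasible for the n <= 10 regime where it is used.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    obs = abs(float(rxc @ ryc) / denom)
    n = len(rx)
    total = math.factorial(n)
    hits = 0
    it = itertools.permutations(range(n))
    while True:
        block = np.array(list(itertools.islice(it, chunk)), dtype=np.intp)
        if block.size == 0:
            break
        rho = (ryc[block] @ rxc) / denom
        hits += int((np.abs(rho) >= obs - 1e-12).sum())
    return hits / total


def spearman_test(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 10
) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and two-sided p.

    Exact permutation null for n <= ``exact_max_n``, t-approximation above.
    Returns (NaN, NaN) for degenerate (constant) input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise AssociationError("x and y must have equal length")
    if x.size < 4:
        raise AssociationError("need at least 4 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        logger.warning("spearman_test: constant input, correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    if x.size <= exact_max_n:
        p = _exact_spearman_p(x, y)
    return float(rho), float(p)


def spearman_assoc(
    expr: pd.DataFrame | Mapping[str, Sequence[float]],
    bat_fc: Sequence[float],
    exact_max_n: int = 10,
) -> pd.DataFrame:
    """Per-gene Spearman association of expression with the BAT fold change.

    ``expr`` is genes x samples (rows align with ``bat_fc`` columns).
    BH adjustment runs across the tested gene set; degenerate genes carry
    NaN and are not counted toward the adjustment.
    """
    if not isinstance(expr, pd.DataFrame):
        expr = pd.DataFrame(expr).T
    bat_fc = np.asarray(bat_fc, dtype=float)
    rows = []
    for gene, values in expr.iterrows():
        v = values.to_numpy(dtype=float)
        keep = ~np.isnan(v) & ~np.isnan(bat_fc)
        if keep.sum() < 4:
            rows.append((gene, float("nan"), float("nan"), int(keep.sum())))
            continue
        rho, p = spearman_test(v[keep], bat_fc[keep], exact_max_n=exact_max_n)
        rows.append((gene, rho, p, int(keep.sum())))
    out = pd.DataFrame(rows, columns=["gene", "rho", "p", "n"])
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p: float
    method: str


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 exact_max_n: int = 8) -> RankTestResult:
    """Two-sided Mann-Whitney test; U is the statistic of ``x``.

    Exact null distribution when min(n) <= ``exact_max_n`` and the pooled
    data are tie-free, normal approximation (tie-corrected, continuity-
    corrected) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise AssociationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= exact_max_n and not ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankTestResult(float(res.statistic), float(res.pvalue), method)


def wilcoxon_paired(before: Sequence[float], after: Sequence[float],
                    exact_max_n: int = 15) -> RankTestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped first; with no informative pairs the result
    is flagged undefined (NaN statistic and p). Exact sign-flip null for
    n <= ``exact_max_n`` when the absolute differences are tie-free.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size:
        raise AssociationError("paired samples must have equal length")
    d = after - before
    d = d[d != 0]
    if d.size == 0:
        logger.warning("wilcoxon_paired: no nonzero differences; p undefined")
        return RankTestResult(float("nan"), float("nan"), "undefined")
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= exact_max_n and not ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return RankTestResult(float(res.statistic), float(res.pvalue), method)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    n_positive: int
    n_negative: int
    thresholds: pd.DataFrame  # threshold, sensitivity, specificity


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)


def roc_analysis(score: Sequence[float], labels: Sequence[int],
                 positive: int | str | bool = 1) -> RocResult:
    """ROC analysis: rank-based AUC, DeLong 95% CI, threshold metrics.

    AUC is the Mann-Whitney probability P(score_pos > score_neg) with ties
    counted 1/2 — higher scores must indicate the positive class (flip the
    score sign otherwise). The confidence interval is the DeLong
    placement-variance normal interval truncated to [0, 1]; the threshold
    table enumerates every observed cutoff (predict positive iff
    score >= cutoff) with sensitivity and specificity.
    """
    from sklearn.metrics import roc_curve

    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive
    if is_pos.all() or not is_pos.any():
        raise AssociationError("both classes must be present")
    pos, neg = score[is_pos], score[~is_pos]
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    s10 = float(v10.var(ddof=1)) if pos.size > 1 else 0.0
    s01 = float(v01.var(ddof=1)) if neg.size > 1 else 0.0
    se = math.sqrt(s10 / pos.size + s01 / neg.size)
    ci_low = max(0.0, auc - _Z975 * se)
    ci_high = min(1.0, auc + _Z975 * se)

    fpr, tpr, thr = roc_curve(is_pos.astype(int), score, drop_intermediate=False)
    thresholds = pd.DataFrame({
        "threshold": thr, "sensitivity": tpr, "specificity": 1.0 - fpr,
    })
    return RocResult(auc, ci_low, ci_high, se,
                     int(pos.size), int(neg.size), thresholds)


# ---------------------------------------------------------------------------
# longitudinal clinical comparison
# ---------------------------------------------------------------------------

def longitudinal_compare(
    clinical: pd.DataFrame,
    value_col: str = "rsad2_rel_expr",
    group_col: str = "group",
    subject_col: str = "subject_id",
    time_col: str = "timepoint",
    timepoints: Sequence[int] = (0, 3, 6),
    baseline_outcome: pd.Series | None = None,
) -> dict:
    """Within-group paired and between-group cross-sectional comparisons.

    Wilcoxon matched pairs within each group across consecutive timepoints
    (and first-to-last); Mann-Whitney between groups at each timepoint.
    Subjects missing a timepoint are dropped from the paired tests involving
    it but retained cross-sectionally; dropped subjects are audit-logged.
    When ``baseline_outcome`` (indexed by subject) is given, the Spearman
    correlation of baseline values against it is added.
    """
    timepoints = list(timepoints)
    wide = clinical.pivot_table(index=subject_col, columns=time_col,
                                values=value_col, aggfunc="mean")
    group_of = clinical.groupby(subject_col)[group_col].first()
    groups = sorted(group_of.unique())

    pairs = [(timepoints[i], timepoints[i + 1]) for i in range(len(timepoints) - 1)]
    if len(timepoints) > 2:
        pairs.append((timepoints[0], timepoints[-1]))

    within: dict = {}
    dropped: list[dict] = []
    for g in groups:
        subjects = group_of.index[group_of == g]
        sub = wide.reindex(subjects)
        for t0, t1 in pairs:
            ok = sub[[t0, t1]].dropna()
            for s in sub.index.difference(ok.index):
                dropped.append({"subject_id": s, "pair": (t0, t1), "group": g})
            if len(ok) < 2:
                within[(g, t0, t1)] = {"p": float("nan"), "n": len(ok)}
                continue
            res = wilcoxon_paired(ok[t0], ok[t1])
            within[(g, t0, t1)] = {"p": res.p, "n": len(ok),
                                   "statistic": res.statistic}

    between: dict = {}
    if len(groups) == 2:
        g0, g1 = groups
        for t in timepoints:
            a = wide.loc[group_of == g0, t].dropna()
            b = wide.loc[group_of == g1, t].dropna()
            if len(a) == 0 or len(b) == 0:
                between[t] = {"p": float("nan")}
                continue
            res = mann_whitney(a, b)
            between[t] = {"p": res.p, "U": res.statistic,
                          "n": (len(a), len(b))}

    out = {"within_group": within, "between_group": between,
           "dropped_from_paired": dropped}
    if baseline_outcome is not None:
        base = wide[timepoints[0]].dropna()
        common = base.index.intersection(baseline_outcome.dropna().index)
        if len(common) >= 4:
            rho, p = spearman_test(base.loc[common], baseline_outcome.loc[common])
            out["baseline_vs_outcome"] = {"rho": rho, "p": p, "n": len(common)}
    return out
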