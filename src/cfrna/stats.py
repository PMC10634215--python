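"""Gene-set overlap statistics, concordance counting, group tests, ROC utilities.

Overlap significance follows the hypergeometric/Fisher framing: the universe
is the union of genes tested in the two differential-abundance analyses, the
2x2 table cross-classifies universe membership in each set, the one-sided
enrichment p-value is the upper hypergeometric tail, and the (unconditional
sample) odds ratio measures association strength.  The Jaccard index
|A ∩ B| / |A ∪ B| summarises similarity on a 0-1 scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "OverlapReport",
    "fisher_overlap",
    "jaccard",
    "direction_concordance",
    "circ_linear_concordance",
    "group_compare",
    "holm_adjust",
    "pearson_r",
    "roc_auc",
]


@dataclass
class OverlapReport:
    n_A: int
    n_B: int
    n_intersect: int
    n_universe: int
    table: list  # 2x2: [[a, b], [c, d]]
    fisher_p: float
    odds_ratio: float
    jaccard: float


def fisher_overlap(set_a, set_b, universe, alternative: str = "greater") -> OverlapReport:
    """Hypergeometric enrichment test for the overlap of two gene sets.

    The 2x2 table over the universe is ``[[|A∩B|, |A\\B|], [|B\\A|, rest]]``;
    the default one-sided p-value asks whether the overlap is at least as
    large as observed, and the odds ratio is the sample OR ``ad/bc``
    (``inf`` when ``bc = 0`` and the intersection is non-empty).
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    outside = (set_a | set_b) - universe
    if outside:
        raise ValueError(f"elements outside universe: {sorted(outside)[:5]}")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    if not set_a or not set_b:
        return OverlapReport(len(set_a), len(set_b), a, len(universe),
                             [[a, b], [c, d]], 1.0, float("nan"),
                             jaccard(set_a, set_b))
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    odds = math.inf if b * c == 0 and a > 0 else (
        float("nan") if b * c == 0 else a * d / (b * c)
    )
    return OverlapReport(len(set_a), len(set_b), a, len(universe),
                         [[a, b], [c, d]], float(p), odds, jaccard(set_a, set_b))


def jaccard(set_a, set_b) -> float:
    """Jaccard index |A ∩ B| / |A ∪ B|; 0 for two empty sets (logged)."""
    set_a, set_b = set(set_a), set(set_b)
    union = set_a | set_b
    if not union:
        log.info("jaccard of two empty sets defined as 0")
        return 0.0
    return len(set_a & set_b) / len(union)


def jaccard_from_sizes(n_a: int, n_b: int, n_intersect: int) -> float:
    """Jaccard index from set cardinalities alone."""
    if n_intersect > min(n_a, n_b):
        raise ValueError("intersection larger than a set")
    union = n_a + n_b - n_intersect
    return n_intersect / union if union else 0.0


def direction_concordance(da_a: pd.DataFrame, da_b: pd.DataFrame) -> dict:
    """Direction agreement among genes significant in both contrasts.

    Both inputs are differential-abundance tables (indexed by gene, with
    ``significant`` and ``log2_fold_change`` columns).  Reports the shared
    significant genes, the fraction with matching fold-change sign, and the
    fraction of B's significant genes that are also significant in A.
    """
    sig_a = set(da_a.index[da_a["significant"].astype(bool)])
    sig_b = set(da_b.index[da_b["significant"].astype(bool)])
    shared = sorted(sig_a & sig_b)
    report = {
        "n_significant_a": len(sig_a),
        "n_significant_b": len(sig_b),
        "n_shared": len(shared),
        "shared_genes": shared,
        "fraction_of_b_in_a": (len(shared) / len(sig_b)) if sig_b else float("nan"),
    }
    if not shared:
        log.warning("no shared significant genes; concordance undefined")
        report["same_direction_fraction"] = float("nan")
        return report
    sa = np.sign(da_a.loc[shared, "log2_fold_change"].to_numpy(float))
    sb = np.sign(da_b.loc[shared, "log2_fold_change"].to_numpy(float))
    report["same_direction_fraction"] = float(np.mean(sa == sb))
    return report


def circ_linear_concordance(da: pd.DataFrame, annotation) -> dict:
    """circRNA vs host-gene concordance within one contrast.

    Among significant circRNAs with a host-gene link: the fraction whose
    linear host is also significant, and among such doubly-significant pairs
    the fraction where the fold-change direction matches.
    """
    host_of = annotation.host_of()
    circ_sig = [
        g for g in da.index
        if g in host_of.index and bool(da.loc[g, "significant"])
    ]
    circ_all_sig = da.index[da["significant"].astype(bool)]
    unlinked = [
        g for g in circ_all_sig
        if g in set(annotation.table.index[annotation.table["biotype"] == "circRNA"])
        and g not in host_of.index
    ]
    if unlinked:
        log.warning("%d significant circRNAs without host link excluded", len(unlinked))
    if not circ_sig:
        return {
            "n_circ_significant": 0,
            "host_also_significant_fraction": float("nan"),
            "direction_match_fraction": float("nan"),
        }
    pairs = [(g, host_of[g]) for g in circ_sig if host_of[g] in da.index]
    both = [
        (g, h) for g, h in pairs if bool(da.loc[h, "significant"])
    ]
    host_frac = len(both) / len(pairs) if pairs else float("nan")
    if both:
        match = [
            np.sign(da.loc[g, "log2_fold_change"]) == np.sign(da.loc[h, "log2_fold_change"])
            for g, h in both
        ]
        dir_frac = float(np.mean(match))
    else:
        dir_frac = float("nan")
    return {
        "n_circ_significant": len(circ_sig),
        "n_pairs_tested": len(pairs),
        "n_both_significant": len(both),
        "host_also_significant_fraction": host_frac,
        "direction_match_fraction": dir_frac,
    }


def holm_adjust(pvalues) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def group_compare(values, groups, alpha: float = 0.05) -> dict:
    """Kruskal-Wallis omnibus plus Holm-corrected pairwise rank-sum tests.

    Groups with fewer than two observations are excluded (with a warning).
    Ties are handled by midranks throughout.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep_levels = []
    for lvl in pd.unique(groups):
        n = int(np.sum(groups == lvl))
        if n < 2:
            log.warning("group %r excluded (n=%d < 2)", lvl, n)
        else:
            keep_levels.append(lvl)
    if len(keep_levels) < 2:
        raise ValueError("need at least two groups with n >= 2")
    samples = [values[groups == lvl] for lvl in keep_levels]
    if np.ptp(np.concatenate(samples)) == 0:
        kw_stat, kw_p = 0.0, 1.0  # no rank variation between groups
    else:
        kw_stat, kw_p = sps.kruskal(*samples)
    pair_rows = []
    for (la, xa), (lb, xb) in combinations(zip(keep_levels, samples), 2):
        combined = np.concatenate([xa, xb])
        # exact permutation distribution when tractable and tie-free
        method = (
            "exact"
            if len(np.unique(combined)) == len(combined) and len(combined) <= 40
            else "asymptotic"
        )
        stat, p = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        pair_rows.append({"group_a": la, "group_b": lb, "u": float(stat), "p": float(p)})
    qs = holm_adjust([r["p"] for r in pair_rows])
    for row, q in zip(pair_rows, qs):
        row["q"] = float(q)
        row["significant"] = bool(q < alpha)
    return {
        "groups": [str(g) for g in keep_levels],
        "kruskal_statistic": float(kw_stat),
        "kruskal_p": float(kw_p),
        "pairwise": pair_rows,
    }


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def roc_auc(scores, labels, threshold: float | None = None) -> dict:
    """ROC analysis via the Mann-Whitney identity.

    AUC = P(score_pos > score_neg) + 0.5 P(tie).  Also reports the ROC
    points from a full threshold sweep, the Youden-J optimal threshold, and
    the accuracy at ``threshold`` (Youden optimum when not given).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # threshold sweep (descending unique scores; predict positive when >= t)
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(~sorted_labels)
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], len(scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    cuts = np.r_[np.inf, sorted_scores[distinct]]
    youden = tpr - fpr
    j_best = int(np.argmax(youden))
    youden_threshold = float(cuts[j_best])
    thr = youden_threshold if threshold is None else float(threshold)
    pred = scores >= thr if np.isfinite(thr) else np.zeros_like(labels)
    accuracy = float(np.mean(pred == labels))
    return {
        "auc": float(auc),
        "roc_points": list(zip(fpr.tolist(), tpr.tolist())),
        "thresholds": cuts.tolist(),
        "youden_threshold": youden_threshold,
        "threshold": thr,
        "accuracy": accuracy,
        "n_pos": n_pos,
        "n_neg": n_neg,
    }
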