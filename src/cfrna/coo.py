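"""Cell-of-origin (GCB vs non-GCB) classification from an oriented gene panel.

Two cohort-relative scoring procedures are provided.  The normalized-rank
score ranks each panel gene's normalized abundance across the cohort, maps
ranks to percentiles in [0, 1] (midranks for ties, minimum at 0, maximum at
(n-1)/n), and takes the mean percentile over the class-1 genes minus the
mean over the class-2 genes.  The standardized-abundance score z-scores
log2(normalized count + 1) per gene across the cohort and takes the same
mean difference.  Positive scores are evidence for class 1 (GCB by
convention).  Because both scores are cohort-relative, a sample's score
depends on the cohort it is scored with; a freeze/apply mode stores
per-gene reference distributions so single samples can be scored against a
reference cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin

from .da import size_factors as mor_size_factors
from .io import CountMatrix, GepPanel, ValidationError
from .stats import roc_auc

log = logging.getLogger(__name__)

__all__ = [
    "score_normalized_rank",
    "score_standardized_abundance",
    "classify_and_evaluate",
    "derive_plasma_panel",
    "CooClassifier",
]


def _normalized(counts: CountMatrix) -> pd.DataFrame:
    sf = mor_size_factors(counts)
    return counts.counts.div(sf, axis=1)


def _present_panel_genes(panel: GepPanel, index) -> tuple[list, list]:
    g1 = [g for g in sorted(panel.up_in_class1) if g in index]
    g2 = [g for g in sorted(panel.up_in_class2) if g in index]
    n_missing = len(panel.genes) - len(g1) - len(g2)
    if n_missing:
        log.warning("%d panel genes missing from count matrix", n_missing)
    if not g1 or not g2:
        raise ValidationError("panel genes missing for one or both classes")
    return g1, g2


def score_normalized_rank(counts: CountMatrix, panel: GepPanel) -> pd.Series:
    """Normalized-rank COO score for every sample of the cohort."""
    norm = _normalized(counts)
    if norm.shape[1] < 2:
        raise ValidationError("need at least two cohort samples to rank")
    g1, g2 = _present_panel_genes(panel, norm.index)
    n = norm.shape[1]
    sub = norm.loc[g1 + g2]
    ranks = sub.rank(axis=1, method="average")  # midranks, 1..n
    pct = (ranks - 1.0) / n
    score = pct.loc[g1].mean(axis=0) - pct.loc[g2].mean(axis=0)
    return score.rename("score_rank")


def score_standardized_abundance(counts: CountMatrix, panel: GepPanel) -> pd.Series:
    """Standardized-abundance COO score for every sample of the cohort."""
    norm = _normalized(counts)
    if norm.shape[1] < 2:
        raise ValidationError("need at least two cohort samples")
    g1, g2 = _present_panel_genes(panel, norm.index)
    logx = np.log2(norm.loc[g1 + g2] + 1.0)
    sd = logx.std(axis=1, ddof=0)
    dropped = sd[sd == 0].index
    if len(dropped):
        log.warning("%d zero-variance panel genes dropped", len(dropped))
        g1 = [g for g in g1 if g not in set(dropped)]
        g2 = [g for g in g2 if g not in set(dropped)]
        if not g1 or not g2:
            raise ValidationError("all panel genes of one class have zero variance")
        logx = logx.loc[g1 + g2]
        sd = sd.loc[g1 + g2]
    z = logx.sub(logx.mean(axis=1), axis=0).div(sd, axis=0)
    score = z.loc[g1].mean(axis=0) - z.loc[g2].mean(axis=0)
    return score.rename("score_z")


def classify_and_evaluate(
    scores: pd.Series,
    labels: pd.Series,
    class1_label: str = "GCB",
    class2_label: str = "nonGCB",
    threshold: float | None = None,
) -> dict:
    """ROC/AUC/accuracy of COO scores against reference (Hans) labels.

    The positive class is class 1; predicted class 1 when score exceeds the
    threshold (Youden-J optimum by default).  Returns AUC, accuracy, the
    confusion table, and the ROC points.
    """
    labels = labels.loc[scores.index]
    known = set(labels.dropna())
    if not known <= {class1_label, class2_label}:
        raise ValidationError(f"unexpected labels: {sorted(known - {class1_label, class2_label})}")
    if len(known) < 2:
        raise ValidationError("both classes must be present")
    y = (labels == class1_label).to_numpy()
    rep = roc_auc(scores.to_numpy(float), y, threshold=threshold)
    pred = scores.to_numpy(float) >= rep["threshold"]
    confusion = {
        "tp": int(np.sum(pred & y)),
        "fp": int(np.sum(pred & ~y)),
        "fn": int(np.sum(~pred & y)),
        "tn": int(np.sum(~pred & ~y)),
    }
    rep["confusion"] = confusion
    rep["class1_label"] = class1_label
    rep["class2_label"] = class2_label
    return rep


def derive_plasma_panel(da: pd.DataFrame, name: str = "plasma_panel",
                        class1_label: str = "GCB",
                        class2_label: str = "nonGCB") -> GepPanel:
    """Build a COO panel from a non-GCB-vs-GCB differential abundance table.

    ``da`` must carry fold changes of class 2 (non-GCB) relative to class 1
    (GCB): significant genes with positive log2FC go up-in-class-2, negative
    up-in-class-1.
    """
    sig = da[da["significant"].astype(bool)]
    if sig.empty:
        raise ValidationError("no significant genes to build a panel from")
    up2 = frozenset(sig.index[sig["log2_fold_change"] > 0])
    up1 = frozenset(sig.index[sig["log2_fold_change"] < 0])
    return GepPanel(name, up1, up2, class1_label, class2_label)


class CooClassifier(BaseEstimator, ClassifierMixin):
    """Panel-based GCB vs non-GCB classifier (scikit-learn interface).

    Parameters
    ----------
    panel : GepPanel
        Oriented gene panel; class 1 genes argue for ``panel.class1_label``.
    method : "rank" | "z"
        Normalized-rank or standardized-abundance scoring.
    threshold : float or None
        Decision threshold on the score; None selects the Youden-J optimum
        during ``fit`` (``fit`` without labels, or ``decision_function``
        alone, uses 0).

    ``fit(counts, y)`` scores the cohort, fixes the threshold, and stores
    per-gene reference distributions (``reference_``) so ``predict`` can
    score new samples against the training cohort (freeze/apply mode).
    """

    def __init__(self, panel: GepPanel = None, method: str = "rank",
                 threshold: float | None = None):
        self.panel = panel
        self.method = method
        self.threshold = threshold

    def _score_cohort(self, counts: CountMatrix) -> pd.Series:
        if self.method == "rank":
            return score_normalized_rank(counts, self.panel)
        if self.method == "z":
            return score_standardized_abundance(counts, self.panel)
        raise ValidationError(f"unknown method {self.method!r}")

    def fit(self, counts: CountMatrix, y: pd.Series | None = None):
        if self.panel is None:
            raise ValidationError("a GepPanel is required")
        if self.method not in {"rank", "z"}:
            raise ValidationError(f"unknown method {self.method!r}")
        scores = self._score_cohort(counts)
        self.training_scores_ = scores
        self.classes_ = np.array([self.panel.class2_label, self.panel.class1_label])
        # frozen per-gene reference for single-sample application
        norm = _normalized(counts)
        g1, g2 = _present_panel_genes(self.panel, norm.index)
        logx = np.log2(norm.loc[g1 + g2] + 1.0)
        self.reference_ = {
            "genes_class1": g1,
            "genes_class2": g2,
            "norm_values": norm.loc[g1 + g2],
            "log_mean": logx.mean(axis=1),
            "log_sd": logx.std(axis=1, ddof=0),
            "log_geomean": np.log(norm.loc[g1 + g2] + 0.5).mean(axis=1),
        }
        if y is not None:
            y = pd.Series(y).reindex(scores.index) if not isinstance(y, pd.Series) else y
            self.evaluation_ = classify_and_evaluate(
                scores, y, self.panel.class1_label, self.panel.class2_label,
                threshold=self.threshold,
            )
            self.threshold_ = self.evaluation_["threshold"]
        else:
            self.threshold_ = 0.0 if self.threshold is None else self.threshold
        return self

    def decision_function(self, counts: CountMatrix) -> pd.Series:
        """Cohort-relative scores for a new cohort (not frozen)."""
        return self._score_cohort(counts)

    def score_frozen(self, counts: CountMatrix) -> pd.Series:
        """Score samples one at a time against the stored training reference."""
        if not hasattr(self, "reference_"):
            raise ValidationError("classifier is not fitted")
        ref = self.reference_
        genes = ref["genes_class1"] + ref["genes_class2"]
        missing = [g for g in genes if g not in counts.counts.index]
        if missing:
            raise ValidationError(f"panel genes missing: {missing[:5]}")
        raw = counts.counts.loc[genes].astype(float)
        # per-sample size factor as median ratio against the training reference
        logratio = np.log(raw + 0.5).sub(ref["log_geomean"], axis=0)
        sf = np.exp(logratio.median(axis=0))
        norm = raw.div(sf, axis=1)
        n_ref = ref["norm_values"].shape[1]
        out = {}
        for sample in norm.columns:
            if self.method == "rank":
                pct = {}
                for g in genes:
                    refvals = ref["norm_values"].loc[g].to_numpy()
                    v = norm.loc[g, sample]
                    below = np.sum(refvals < v)
                    ties = np.sum(refvals == v)
                    pct[g] = (below + 0.5 * ties) / n_ref
                pct = pd.Series(pct)
            else:
                z = (np.log2(norm[sample] + 1.0) - ref["log_mean"]) / ref[
                    "log_sd"
                ].replace(0, np.nan)
                pct = z.fillna(0.0)
            out[sample] = (
                pct.loc[ref["genes_class1"]].mean()
                - pct.loc[ref["genes_class2"]].mean()
            )
        return pd.Series(out, name=f"score_{self.method}")

    def predict(self, counts: CountMatrix) -> pd.Series:
        scores = self.decision_function(counts)
        thr = getattr(self, "threshold_", 0.0)
        pred = np.where(
            scores > thr, self.panel.class1_label, self.panel.class2_label
        )
        return pd.Series(pred, index=scores.index, name="predicted_coo")
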