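"""Prognostic gene-signature discovery from survival data.

The pipeline screens genes with univariate Cox proportional-hazards models
(score test reported as the log-rank p-value, the standard generalization of
the two-group log-rank test to a continuous covariate), orients genes as
favorable (beta < 0) or unfavorable (beta > 0), groups the retained genes by
average-linkage hierarchical clustering with an adaptive dendrogram cut,
averages each cluster's expression into a per-sample signature score, tests
the signatures jointly with the NCCN-IPI in a multivariable Cox model,
dichotomizes each signature at the maximally selected rank-statistic
cutpoint, and compares the resulting risk groups with Kaplan-Meier curves
and a log-rank test.

The Cox engine (Newton-Raphson on the partial likelihood with Breslow tie
handling), the Kaplan-Meier estimator, the log-rank test, the maximally
selected rank statistic, and the dendrogram cut are implemented here
directly; only the linkage matrix comes from scipy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from sklearn.base import BaseEstimator

from .da import size_factors as mor_size_factors
from .io import AnalysisConfig, CountMatrix, SampleTable, ValidationError, NCCN_IPI_LEVELS

log = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "SignatureModel",
    "cox_fit",
    "screen_genes",
    "cluster_genes",
    "signature_scores",
    "multivariable_fit",
    "maxstat_cutpoint",
    "kaplan_meier",
    "km_logrank",
    "normalized_log_expression",
    "PrognosticPipeline",
    "run_prognostic_pipeline",
]

_BETA_CAP = 20.0


@dataclass
class CoxFit:
    covariates: list
    beta: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    score_test_p: float
    loglik: float
    converged: bool
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "beta": [float(b) for b in self.beta],
            "se": [float(s) for s in self.se],
            "wald_p": [float(p) for p in self.wald_p],
            "score_test_p": float(self.score_test_p),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "degenerate": bool(self.degenerate),
        }


@dataclass
class SignatureModel:
    """A favorable or unfavorable gene cluster with its per-sample score.

    High-risk samples lie above the cutpoint for an unfavorable signature
    and below it for a favorable one.
    """

    orientation: str  # favorable | unfavorable
    genes: list
    scores: pd.Series
    cutpoint: float
    max_statistic: float
    risk_group: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.orientation not in {"favorable", "unfavorable"}:
            raise ValidationError(f"bad orientation {self.orientation!r}")
        if not self.genes:
            raise ValidationError("signature gene list is empty")
        if self.risk_group is None:
            self.risk_group = self.assign_risk(self.scores)

    def assign_risk(self, scores: pd.Series) -> pd.Series:
        if self.orientation == "unfavorable":
            high = scores > self.cutpoint
        else:
            high = scores < self.cutpoint
        return pd.Series(np.where(high, "high", "low"), index=scores.index)


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------


def _prepare(time, event, X):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    if X.shape[0] != len(time):
        raise ValidationError("covariate rows must match number of subjects")
    if (time < 0).any():
        raise ValidationError("negative survival times")
    if not np.isin(event, [0, 1]).all():
        raise ValidationError("events must be 0/1")
    if event.sum() < 2:
        raise ValidationError("need at least two events")
    order = np.argsort(-time, kind="stable")
    time, event, X = time[order], event[order], X[order]
    # index of the end of each tie block in the descending-time ordering:
    # risk set of an event at t = rows 0..block_end (all with time >= t)
    block_end = np.empty(len(time), dtype=int)
    i = 0
    while i < len(time):
        j = i
        while j + 1 < len(time) and time[j + 1] == time[i]:
            j += 1
        block_end[i : j + 1] = j
        i = j + 1
    return time, event, X, block_end


def _loglik_grad_hess(beta, event, X, block_end):
    """Breslow partial log-likelihood with gradient and Hessian of -ll."""
    eta = X @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    cw = np.cumsum(w)
    cwx = np.cumsum(w[:, None] * X, axis=0)
    cwxx = np.cumsum(w[:, None, None] * (X[:, :, None] * X[:, None, :]), axis=0)
    ev = event == 1
    be = block_end[ev]
    denom = cw[be]
    mean_x = cwx[be] / denom[:, None]
    ll = float(np.sum(eta[ev] - np.log(denom)))
    grad = X[ev].sum(axis=0) - mean_x.sum(axis=0)
    hess = (cwxx[be] / denom[:, None, None]).sum(axis=0) - np.einsum(
        "ij,ik->jk", mean_x, mean_x
    )
    return ll, grad, hess


def cox_fit(
    X,
    time,
    event,
    covariate_names=None,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson (Breslow ties).

    Also reports the score test at beta = 0 (for a single binary covariate
    without ties this is exactly the two-group log-rank test).  Constant
    covariates give a flagged degenerate fit (beta = 0, p = 1); a monotone
    partial likelihood (perfect separation) is flagged non-converged with
    beta capped.
    """
    time, event, X, block_end = _prepare(time, event, X)
    n, p = X.shape
    names = list(covariate_names) if covariate_names is not None else [
        f"x{i}" for i in range(p)
    ]
    if np.any(X.std(axis=0) == 0):
        log.warning("constant covariate; degenerate Cox fit")
        zero = np.zeros(p)
        ll0, _, _ = _loglik_grad_hess(zero, event, X, block_end)
        return CoxFit(names, zero, np.full(p, np.nan), np.ones(p), 1.0,
                      ll0, True, degenerate=True)

    beta = np.zeros(p)
    ll0, grad0, hess0 = _loglik_grad_hess(beta, event, X, block_end)
    # score test at beta = 0
    try:
        score_chi2 = float(grad0 @ np.linalg.solve(hess0, grad0))
        score_p = float(sps.chi2.sf(score_chi2, df=p))
    except np.linalg.LinAlgError:
        score_p = float("nan")

    ll = ll0
    converged = False
    hess = hess0
    grad = grad0
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # damped step with simple halving to keep the likelihood increasing
        factor = 1.0
        for _ in range(30):
            new_beta = np.clip(beta + factor * step, -_BETA_CAP, _BETA_CAP)
            new_ll, new_grad, new_hess = _loglik_grad_hess(
                new_beta, event, X, block_end
            )
            if new_ll >= ll - 1e-12:
                break
            factor /= 2.0
        moved = np.max(np.abs(new_beta - beta))
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if moved < tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
    capped = np.any(np.abs(beta) >= _BETA_CAP - 1e-9)
    if capped:
        log.warning("monotone partial likelihood: beta capped at %s", _BETA_CAP)
        converged = False
    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    wald_p = 2.0 * sps.norm.sf(np.abs(np.where(se > 0, beta / se, 0.0)))
    return CoxFit(names, beta, se, wald_p, score_p, ll, converged)


# ---------------------------------------------------------------------------
# Gene screening
# ---------------------------------------------------------------------------


def screen_genes(
    expr: pd.DataFrame,
    time,
    event,
    p_threshold: float = 0.01,
    beta_threshold: float = 2.0,
) -> tuple[list, list, pd.DataFrame]:
    """Univariate Cox screen over genes (rows of ``expr``).

    A gene is retained when its score-test ("log-rank") p-value is at most
    ``p_threshold`` and |beta| is at least ``beta_threshold``; retained genes
    with beta < 0 are favorable, beta > 0 unfavorable.  Returns the two gene
    lists and the full per-gene table.
    """
    rows = []
    for gene, values in expr.iterrows():
        fit = cox_fit(values.to_numpy()[:, None], time, event)
        rows.append(
            {
                "gene_id": gene,
                "beta": float(fit.beta[0]),
                "se": float(fit.se[0]),
                "score_test_p": fit.score_test_p,
                "wald_p": float(fit.wald_p[0]),
                "converged": fit.converged,
                "degenerate": fit.degenerate,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    retained = (
        (table["score_test_p"] <= p_threshold)
        & (table["beta"].abs() >= beta_threshold)
        & table["converged"]
    )
    table["retained"] = retained
    table["orientation"] = np.where(
        ~retained, "none", np.where(table["beta"] < 0, "favorable", "unfavorable")
    )
    favorable = sorted(table.index[retained & (table["beta"] < 0)])
    unfavorable = sorted(table.index[retained & (table["beta"] > 0)])
    if not favorable and not unfavorable:
        log.warning("gene screen retained no genes")
    return favorable, unfavorable, table


# ---------------------------------------------------------------------------
# Clustering (average linkage + adaptive dendrogram cut)
# ---------------------------------------------------------------------------


def _subtree_leaves(Z, node, n):
    stack, leaves = [node], []
    while stack:
        k = stack.pop()
        if k < n:
            leaves.append(k)
        else:
            stack.extend((int(Z[k - n, 0]), int(Z[k - n, 1])))
    return leaves


def _node_height(Z, node, n):
    return 0.0 if node < n else float(Z[node - n, 2])


def cluster_genes(
    expr: pd.DataFrame,
    min_cluster_size: int = 3,
    min_gap_fraction: float = 0.15,
    cut_height: float | None = None,
) -> list[list]:
    """Average-linkage hierarchical clustering of gene profiles with an
    adaptive dendrogram cut.

    Genes are objects, samples features; each profile is z-scored before
    Euclidean distances are taken.  Branches are split recursively wherever
    the joining height exceeds both children's heights by at least
    ``min_gap_fraction`` of the joining height and both children would hold
    at least ``min_cluster_size`` genes; a dendrogram of identical profiles
    is one cluster.  ``cut_height`` switches to a fixed-height cut.
    """
    genes = list(expr.index)
    n = len(genes)
    if n == 0:
        return []
    if n == 1:
        return [genes]
    mat = expr.to_numpy(float)
    sd = mat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (mat - mat.mean(axis=1, keepdims=True)) / sd
    Z = linkage(z, method="average", metric="euclidean")

    if cut_height is not None:
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(Z, t=cut_height, criterion="distance")
        order = {g: i for i, g in enumerate(genes)}
        groups: dict[int, list] = {}
        for g, lab in zip(genes, labels):
            groups.setdefault(int(lab), []).append(g)
        return [sorted(v, key=order.__getitem__) for _, v in sorted(groups.items())]

    clusters: list[list[int]] = []

    def descend(node: int) -> None:
        if node < n:
            clusters.append([node])
            return
        h = _node_height(Z, node, n)
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        hl, hr = _node_height(Z, left, n), _node_height(Z, right, n)
        leaves_l = _subtree_leaves(Z, left, n)
        leaves_r = _subtree_leaves(Z, right, n)
        gap_ok = h > 0 and (h - max(hl, hr)) >= min_gap_fraction * h
        size_ok = (
            len(leaves_l) >= min_cluster_size and len(leaves_r) >= min_cluster_size
        )
        if gap_ok and size_ok:
            descend(left)
            descend(right)
        else:
            clusters.append(sorted(leaves_l + leaves_r))

    descend(2 * n - 2)
    clusters.sort(key=lambda c: min(c))
    return [[genes[i] for i in c] for c in clusters]


def signature_scores(expr: pd.DataFrame, genes) -> pd.Series:
    """Per-sample signature score: arithmetic mean of the member genes'
    normalized log-scale expression (missing members dropped, logged)."""
    present = [g for g in genes if g in expr.index]
    missing = [g for g in genes if g not in expr.index]
    if missing:
        log.warning("%d signature genes missing from expression", len(missing))
    if not present:
        raise ValidationError("no signature genes present in expression matrix")
    return expr.loc[present].mean(axis=0)


def multivariable_fit(
    signatures: pd.DataFrame, nccn_ipi: pd.Series, time, event
) -> CoxFit:
    """Joint Cox fit of signature scores plus the ordinal NCCN-IPI.

    ``signatures``: samples x signature-score columns; ``nccn_ipi``: per
    sample the category (low / low_int / high_int / high), encoded 0-3.
    """
    ipi = nccn_ipi.map({lvl: i for i, lvl in enumerate(NCCN_IPI_LEVELS)})
    if ipi.isna().any():
        bad = sorted(nccn_ipi[ipi.isna()].index)
        raise ValidationError(f"samples without NCCN-IPI: {bad[:5]}")
    Xdf = signatures.copy()
    Xdf["nccn_ipi"] = ipi.astype(float)
    return cox_fit(Xdf.to_numpy(float), time, event, covariate_names=list(Xdf.columns))


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank / maxstat
# ---------------------------------------------------------------------------


def kaplan_meier(time, event) -> pd.DataFrame:
    """Product-limit survival estimate with at-risk/event tables."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    rows = []
    surv = 1.0
    for t in np.unique(time[event == 1]):
        at_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        surv *= 1.0 - d / at_risk
        rows.append({"time": float(t), "n_at_risk": at_risk, "n_events": d,
                     "survival": surv})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def _logrank_U_V(time, event, in_group1) -> tuple[float, float]:
    """Log-rank score U = sum(O1 - E1) and hypergeometric variance V."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g1 = np.asarray(in_group1, dtype=bool)
    U = 0.0
    V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return U, V


def km_logrank(time, event, groups) -> dict:
    """Kaplan-Meier curves per group plus the two-group log-rank test."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if any(np.sum(groups == lvl) == 0 for lvl in levels):
        raise ValidationError("empty group")
    curves = {
        str(lvl): kaplan_meier(time[groups == lvl], event[groups == lvl])
        for lvl in levels
    }
    report = {"groups": [str(l) for l in levels], "curves": curves}
    if len(levels) == 2:
        U, V = _logrank_U_V(time, event, groups == levels[0])
        chi2 = U**2 / V if V > 0 else 0.0
        report["logrank_statistic"] = float(chi2)
        report["logrank_p"] = float(sps.chi2.sf(chi2, df=1)) if V > 0 else 1.0
    return report


def maxstat_cutpoint(
    scores,
    time,
    event,
    quantile_range: tuple[float, float] = (0.10, 0.90),
    rng: np.random.Generator | None = None,
    n_permutations: int = 0,
) -> dict:
    """Maximally selected rank statistic over candidate score cutpoints.

    Candidates are midpoints between consecutive sorted unique scores whose
    low side lies within the quantile window; each is scored by the
    standardized log-rank statistic |U|/sqrt(V) of the induced split, and
    the maximizing cutpoint is returned.  No selection-bias-adjusted p-value
    is computed; an optional permutation p (``n_permutations`` label
    shuffles of the scores) is available instead.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValidationError("all scores tied: no candidate cutpoints")
    lo, hi = np.quantile(scores, quantile_range)
    candidates = [
        (a + b) / 2.0 for a, b in zip(uniq[:-1], uniq[1:]) if lo <= a <= hi
    ]
    if not candidates:
        candidates = [float((uniq[0] + uniq[-1]) / 2.0)]

    def best_stat(sc):
        best_c, best_s = None, -np.inf
        for c in candidates:
            U, V = _logrank_U_V(time, event, sc > c)
            s = abs(U) / math.sqrt(V) if V > 0 else 0.0
            if s > best_s:
                best_c, best_s = c, s
        return best_c, best_s

    cutpoint, stat = best_stat(scores)
    out = {"cutpoint": float(cutpoint), "max_statistic": float(stat),
           "n_candidates": len(candidates)}
    if n_permutations > 0:
        rng = rng or np.random.default_rng()
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            null[i] = best_stat(rng.permutation(scores))[1]
        out["permutation_p"] = float((1 + np.sum(null >= stat)) / (1 + n_permutations))
    return out


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def normalized_log_expression(counts: CountMatrix) -> pd.DataFrame:
    """log2(normalized count + 1) on median-of-ratios size factors."""
    sf = mor_size_factors(counts)
    return np.log2(counts.counts.div(sf, axis=1) + 1.0)


class PrognosticPipeline(BaseEstimator):
    """Survival gene-signature discovery as a scikit-learn style estimator.

    ``fit(counts, samples)`` runs screen -> orient -> cluster -> score ->
    multivariable Cox (with NCCN-IPI) -> maxstat cutpoint -> KM/log-rank on
    the requested endpoint and stores:

    signatures_ : list of :class:`SignatureModel`
    screen_table_ : per-gene univariate Cox table
    multivariable_ : joint CoxFit of signature scores + NCCN-IPI
    report_ : JSON-serializable summary of every stage
    """

    def __init__(self, endpoint: str = "PFS", config: AnalysisConfig | None = None,
                 timepoint: str | None = "diagnosis"):
        self.endpoint = endpoint
        self.config = config
        self.timepoint = timepoint

    def fit(self, counts: CountMatrix, samples: SampleTable):
        cfg = self.config or AnalysisConfig()
        endpoint = self.endpoint.upper()
        if endpoint not in {"PFS", "OS"}:
            raise ValidationError("endpoint must be PFS or OS")
        tcol, ecol = (
            ("pfs_time", "pfs_event") if endpoint == "PFS" else ("os_time", "os_event")
        )
        meta = samples.table
        mask = meta[tcol].notna() & meta[ecol].notna()
        if self.timepoint is not None:
            mask &= meta["timepoint"] == self.timepoint
        ids = [s for s in counts.sample_ids if s in set(meta.index[mask])]
        if len(ids) < 4:
            raise ValidationError("too few samples with survival data")
        sub = counts.subset_samples(ids)
        time = meta.loc[ids, tcol].to_numpy(float)
        event = meta.loc[ids, ecol].to_numpy(int)

        logexpr = normalized_log_expression(sub)
        sd = logexpr.std(axis=1)
        usable = logexpr.loc[sd > 0]
        zexpr = usable.sub(usable.mean(axis=1), axis=0).div(
            usable.std(axis=1), axis=0
        )
        favorable, unfavorable, screen_table = screen_genes(
            zexpr, time, event,
            p_threshold=cfg.cox_p_threshold,
            beta_threshold=cfg.cox_beta_threshold,
        )
        self.screen_table_ = screen_table
        retained = favorable + unfavorable
        report: dict = {
            "endpoint": endpoint,
            "n_samples": len(ids),
            "n_events": int(event.sum()),
            "n_genes_screened": int(len(zexpr)),
            "favorable_genes": favorable,
            "unfavorable_genes": unfavorable,
        }
        if not retained:
            log.warning("pipeline halted: screen retained no genes")
            self.signatures_ = []
            self.multivariable_ = None
            report["signatures"] = []
            self.report_ = report
            return self

        clusters = cluster_genes(
            zexpr.loc[retained], min_cluster_size=cfg.min_cluster_size
        )
        beta = screen_table["beta"]
        signatures: list[SignatureModel] = []
        for members in clusters:
            orientation = (
                "unfavorable" if beta.loc[members].mean() > 0 else "favorable"
            )
            scores = signature_scores(logexpr, members)
            ms = maxstat_cutpoint(
                scores.to_numpy(), time, event,
                quantile_range=cfg.maxstat_quantile_range,
            )
            signatures.append(
                SignatureModel(
                    orientation, list(members), scores,
                    ms["cutpoint"], ms["max_statistic"],
                )
            )
        self.signatures_ = signatures

        score_df = pd.DataFrame(
            {f"signature_{i}": s.scores for i, s in enumerate(signatures)}
        )
        ipi = meta.loc[ids, "nccn_ipi"]
        if ipi.notna().all():
            self.multivariable_ = multivariable_fit(score_df, ipi, time, event)
        else:
            log.warning("NCCN-IPI missing for some samples; multivariable fit skipped")
            self.multivariable_ = None

        sig_reports = []
        for i, s in enumerate(signatures):
            uni = cox_fit(s.scores.to_numpy()[:, None], time, event)
            km = km_logrank(time, event, s.risk_group.to_numpy())
            sig_reports.append(
                {
                    "name": f"signature_{i}",
                    "orientation": s.orientation,
                    "genes": list(s.genes),
                    "cutpoint": float(s.cutpoint),
                    "max_statistic": float(s.max_statistic),
                    "univariate_beta": float(uni.beta[0]),
                    "univariate_p": float(uni.wald_p[0]),
                    "univariate_score_p": float(uni.score_test_p),
                    "logrank_statistic": km.get("logrank_statistic"),
                    "logrank_p": km.get("logrank_p"),
                    "n_high_risk": int((s.risk_group == "high").sum()),
                    "n_low_risk": int((s.risk_group == "low").sum()),
                }
            )
        report["signatures"] = sig_reports
        if self.multivariable_ is not None:
            report["multivariable"] = self.multivariable_.as_dict()
        self.report_ = report
        return self


def run_prognostic_pipeline(
    counts: CountMatrix,
    samples: SampleTable,
    endpoint: str = "PFS",
    config: AnalysisConfig | None = None,
    timepoint: str | None = "diagnosis",
) -> tuple[list, dict]:
    """Functional wrapper over :class:`PrognosticPipeline`."""
    pipe = PrognosticPipeline(endpoint=endpoint, config=config, timepoint=timepoint)
    pipe.fit(counts, samples)
    return pipe.signatures_, pipe.report_
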