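"""Prefiltering, median-of-ratios normalization, and a negative-binomial
Wald test for two-group differential abundance.

The per-gene test is a deliberately simple stand-in for a full DA framework:
method-of-moments dispersion estimation followed by an NB log-link GLM with a
group indicator, fit by iteratively reweighted least squares, with a Wald
test on the group coefficient and Benjamini-Hochberg correction across
genes.  There is no independent filtering and no fold-change shrinkage; the
result schema is stable so an external engine can be swapped in without
touching downstream modules.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .io import AnalysisConfig, CountMatrix, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "prefilter_genes",
    "size_factors",
    "bh_adjust",
    "NBWaldTest",
    "nb_wald_test",
    "run_contrast",
]


def prefilter_genes(
    counts: CountMatrix,
    group_a,
    group_b,
    min_count: int = 10,
    fraction: float = 0.5,
    min_circ_bsj: int = 4,
) -> list[str]:
    """Expression prefilter: keep a gene iff its count reaches ``min_count``
    in at least ``ceil(fraction * n)`` samples of one of the two groups.

    circRNA genes are filtered on back-splice junction counts with their own
    (lower) threshold ``min_circ_bsj``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    kept: list[str] = []
    mat = counts.counts
    is_circ = counts.biotype == "circRNA"
    for genes, threshold in (
        (counts.counts.index[~is_circ], min_count),
        (counts.counts.index[is_circ], min_circ_bsj),
    ):
        if len(genes) == 0:
            continue
        sub = mat.loc[genes]
        keep = np.zeros(len(genes), dtype=bool)
        for grp in (group_a, group_b):
            need = math.ceil(fraction * len(grp))
            n_pass = (sub[grp] >= threshold).sum(axis=1).to_numpy()
            keep |= n_pass >= need
        kept.extend(np.asarray(genes)[keep])
    order = {g: i for i, g in enumerate(counts.gene_ids)}
    return sorted(kept, key=order.__getitem__)


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Only genes with a nonzero count in every sample contribute; if no such
    gene exists the matrix is too sparse and the caller should prefilter.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else pd.DataFrame(counts)
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValidationError(
            "no gene expressed in every sample; prefilter before normalizing"
        )
    ref = mat.loc[expressed].astype(float)
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref).sub(log_geomean, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values propagate NaN and
    are excluded from the number of tests."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return q
    pv = p[ok]
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


class NBWaldTest(BaseEstimator):
    """Per-gene negative-binomial Wald test for a two-group contrast.

    scikit-learn estimator interface: ``fit(X, y)`` where ``X`` is an
    ``(n_samples, n_genes)`` count array and ``y`` the two-level group
    labels; the positive level (``group_a``, defaulting to the label that
    sorts last) is the numerator of the fold change.  Fitted attributes:

    results_ : DataFrame with base_mean, log2_fold_change, lfc_se, wald_p,
        q, significant, direction per gene
    size_factors_ : per-sample normalization factors
    dispersions_ : per-gene method-of-moments NB dispersion estimates
    """

    def __init__(
        self,
        q_threshold: float = 0.05,
        dispersion_floor: float = 1e-8,
        max_iter: int = 50,
        tol: float = 1e-8,
        group_a=None,
    ):
        self.q_threshold = q_threshold
        self.dispersion_floor = dispersion_floor
        self.max_iter = max_iter
        self.tol = tol
        self.group_a = group_a

    def fit(self, X, y, size_factors=None, gene_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValidationError("X must be (n_samples, n_genes) aligned with y")
        levels = sorted(pd.unique(y).tolist())
        if len(levels) != 2:
            raise ValidationError(f"need exactly two group levels, got {levels}")
        group_a = self.group_a if self.group_a is not None else levels[-1]
        if group_a not in levels:
            raise ValidationError(f"group_a {group_a!r} not among levels {levels}")
        group_b = [l for l in levels if l != group_a][0]
        x = (y == group_a).astype(float)
        if x.sum() < 2 or (1 - x).sum() < 2:
            raise ValidationError("each group needs n >= 2")

        counts = X.T  # genes x samples
        n_genes, n_samples = counts.shape
        if size_factors is None:
            sf = _size_factors_array(counts)
        else:
            sf = np.asarray(size_factors, dtype=float)
        norm = counts / sf[None, :]

        phi = self._mom_dispersion(norm, x)

        beta0, beta1, se1, converged = _irls_two_group(
            counts, x, np.log(sf), phi, self.max_iter, self.tol
        )
        wald_z = np.where(se1 > 0, beta1 / se1, 0.0)
        wald_p = 2.0 * sps.norm.sf(np.abs(wald_z))
        wald_p = np.where(converged, wald_p, np.nan)
        n_failed = int((~converged).sum())
        if n_failed:
            log.warning("%d genes failed to converge; excluded from BH", n_failed)
        q = bh_adjust(wald_p)
        log2fc = beta1 / math.log(2.0)
        res = pd.DataFrame(
            {
                "base_mean": norm.mean(axis=1),
                "log2_fold_change": log2fc,
                "lfc_se": se1 / math.log(2.0),
                "wald_p": wald_p,
                "q": q,
                "significant": (q < self.q_threshold) & converged,
                "direction": np.where(log2fc > 0, "up", "down"),
                "converged": converged,
            },
            index=gene_ids if gene_ids is not None else pd.RangeIndex(n_genes),
        )
        res.index.name = "gene_id"
        self.results_ = res
        self.contrast_ = (group_a, group_b)
        self.size_factors_ = sf
        self.dispersions_ = phi
        return self

    def _mom_dispersion(self, norm: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Pooled within-group method-of-moments dispersion on normalized
        counts: phi = (within-var - mean) / mean^2, floored."""
        phi = np.full(norm.shape[0], self.dispersion_floor)
        masks = [x == 1, x == 0]
        mean_all = norm.mean(axis=1)
        ss = np.zeros(norm.shape[0])
        dof = 0
        for m in masks:
            sub = norm[:, m]
            mu = sub.mean(axis=1, keepdims=True)
            ss += ((sub - mu) ** 2).sum(axis=1)
            dof += sub.shape[1] - 1
        var_within = ss / max(dof, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            est = (var_within - mean_all) / mean_all**2
        ok = (mean_all > 0) & np.isfinite(est)
        phi[ok] = np.maximum(est[ok], self.dispersion_floor)
        return phi


def _size_factors_array(counts: np.ndarray) -> np.ndarray:
    expressed = (counts > 0).all(axis=1)
    if not expressed.any():
        raise ValidationError(
            "no gene expressed in every sample; prefilter before normalizing"
        )
    ref = np.log(counts[expressed])
    log_geo = ref.mean(axis=1, keepdims=True)
    return np.exp(np.median(ref - log_geo, axis=0))


def _irls_two_group(counts, x, log_sf, phi, max_iter, tol):
    """Vectorized IRLS for ``log mu = b0 + b1*x + offset`` per gene.

    The design is shared across genes, so the weighted normal equations are
    a closed-form 2x2 solve per gene.  Returns (b0, b1, se_b1, converged).
    """
    n_genes, n_samples = counts.shape
    offset = log_sf[None, :]
    eps = 1e-8
    m1 = x == 1
    m0 = ~m1
    mean1 = (counts[:, m1] / np.exp(log_sf[m1])[None, :]).mean(axis=1)
    mean0 = (counts[:, m0] / np.exp(log_sf[m0])[None, :]).mean(axis=1)
    b0 = np.log(np.maximum(mean0, eps) + 0.1)
    b1 = np.log(np.maximum(mean1, eps) + 0.1) - b0
    phi_col = phi[:, None]
    converged = np.zeros(n_genes, dtype=bool)
    active = ~converged
    sw = swx = swxx = None
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x[None, :] + offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + phi_col * mu)
        z = (eta - offset) + (counts - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x[None, :]).sum(axis=1)
        swxx = (w * (x**2)[None, :]).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x[None, :] * z).sum(axis=1)
        det = sw * swxx - swx**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        nb0 = (swxx * swz - swx * swxz) / det
        nb1 = (sw * swxz - swx * swz) / det
        step0 = nb0 - b0
        step1 = nb1 - b1
        bad = ~np.isfinite(nb0) | ~np.isfinite(nb1)
        nb0 = np.where(bad, b0, nb0)
        nb1 = np.where(bad, b1, nb1)
        moved = np.maximum(np.abs(step0), np.abs(step1))
        moved = np.where(bad, np.inf, moved)
        newly = moved < tol * (1.0 + np.abs(nb1))
        b0, b1 = nb0, nb1
        converged |= newly
        if converged.all():
            break
    # Wald SE from the converged Fisher information
    eta = np.clip(b0[:, None] + b1[:, None] * x[None, :] + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + phi_col * mu)
    sw = w.sum(axis=1)
    swx = (w * x[None, :]).sum(axis=1)
    swxx = (w * (x**2)[None, :]).sum(axis=1)
    det = sw * swxx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(np.where(det > 0, sw / det, np.nan))
    converged &= np.isfinite(se1) & np.isfinite(b1)
    return b0, b1, se1, converged


def nb_wald_test(
    counts: CountMatrix,
    groups: pd.Series | dict,
    size_factors_=None,
    q_threshold: float = 0.05,
    group_a=None,
) -> pd.DataFrame:
    """Two-group NB Wald differential abundance on a :class:`CountMatrix`.

    ``groups`` maps sample id -> group label (exactly two levels among the
    matrix samples).  Fold changes are ``group_a`` relative to the other
    level.  Returns the per-gene result table indexed by gene id.
    """
    groups = pd.Series(groups)
    samples = [s for s in counts.sample_ids if s in groups.index and pd.notna(groups[s])]
    sub = counts.subset_samples(samples)
    y = groups.loc[samples].to_numpy()
    est = NBWaldTest(q_threshold=q_threshold, group_a=group_a)
    est.fit(
        sub.counts.to_numpy().T,
        y,
        size_factors=size_factors_,
        gene_ids=sub.counts.index,
    )
    res = est.results_
    res.attrs["contrast"] = est.contrast_
    return res


def run_contrast(
    counts: CountMatrix,
    samples,
    groups: pd.Series | dict,
    config: AnalysisConfig | None = None,
    group_a=None,
) -> pd.DataFrame:
    """Prefilter, normalize, and test one two-group contrast end to end."""
    config = config or AnalysisConfig()
    groups = pd.Series(groups)
    groups = groups[groups.notna()]
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise ValidationError(f"need two levels, got {levels}")
    ga = group_a if group_a is not None else levels[-1]
    gb = [l for l in levels if l != ga][0]
    in_matrix = set(counts.sample_ids)
    a_samples = [s for s in groups.index if groups[s] == ga and s in in_matrix]
    b_samples = [s for s in groups.index if groups[s] == gb and s in in_matrix]
    kept = prefilter_genes(
        counts.subset_samples(a_samples + b_samples),
        a_samples,
        b_samples,
        min_count=config.prefilter_min_count,
        fraction=config.prefilter_group_fraction,
        min_circ_bsj=config.prefilter_min_circ_bsj,
    )
    filtered = counts.subset_genes(kept).subset_samples(a_samples + b_samples)
    return nb_wald_test(
        filtered, groups.loc[a_samples + b_samples],
        q_threshold=config.q_threshold, group_a=ga,
    )
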