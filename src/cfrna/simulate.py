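"""Synthetic cfRNA cohort generator.

Generates count matrices, sample metadata, spike-in reads, circRNA rows and
survival outcomes with the statistical structure the downstream analyses
assume: three diagnostic groups plus healthy controls, GCB/non-GCB effect
genes, longitudinal timepoints with responder trajectories, prognostic gene
clusters whose expression drives the hazard, and per-sample sequencing
depth variation.  Counts follow a negative binomial with variance
mu + phi * mu^2 (single global dispersion phi); sequencing depth is
lognormal with a configurable coefficient of variation so normalization has
real work to do.  Survival is generated from expression, not from labels,
so signature discovery can be validated as a discovery procedure.

Every generator is deterministic under the design seed; sub-stage seeds are
derived from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    GeneAnnotation,
    SampleTable,
    ValidationError,
    NCCN_IPI_LEVELS,
)

__all__ = [
    "PrognosticCluster",
    "SpikeDesign",
    "CircDesign",
    "SimulationDesign",
    "default_design",
    "generate_counts",
    "generate_survival",
    "generate_spikes",
    "generate_circ",
    "generate_cohort",
]


@dataclass
class PrognosticCluster:
    """A planted prognostic gene cluster.

    Member genes share a per-sample latent factor (loading in log2 units)
    that both correlates their expression and, scaled by ``beta_sim`` per
    gene, drives the hazard of the target endpoint.
    """

    genes: list
    beta_sim: float
    endpoint: str = "PFS"  # PFS | OS
    orientation: str = "unfavorable"  # sign of beta_sim's effect
    latent_loading: float = 1.0

    def __post_init__(self) -> None:
        if self.endpoint not in {"PFS", "OS"}:
            raise ValidationError("cluster endpoint must be PFS or OS")


@dataclass
class SpikeDesign:
    spike_mass_ng: float = 1.6e-4  # per-sample mass of the top spike
    plasma_volume_ml: float = 0.2
    endo_mass_ng: dict = field(
        default_factory=lambda: {"control": 0.5, "DLBCL": 1.0, "PMBCL": 1.0}
    )
    depth: float = 1e6
    spike_id: str = "ERCC00130"


@dataclass
class CircDesign:
    n_circ: int = 0
    mean_fraction_of_host: float = 0.3
    copy_proportion: float = 1.0  # fraction of circs copying the host effect
    bsj_phi: float = 0.2


@dataclass
class SimulationDesign:
    """Cohort design; the defaults mirror a modest lymphoma plasma study
    (22 controls, 41 DLBCL split 20 GCB / 21 non-GCB, 14 PMBCL)."""

    n_control: int = 22
    n_dlbcl_gcb: int = 20
    n_dlbcl_nongcb: int = 21
    n_pmbcl: int = 14
    n_genes: int = 2000
    baseline_log2_loc: float = 4.0
    baseline_log2_scale: float = 1.5
    phi: float = 0.1
    depth_cv: float = 0.2
    # planted effects, all as gene -> log2 fold change
    dlbcl_effects: dict = field(default_factory=dict)  # DLBCL vs control
    pmbcl_effects: dict = field(default_factory=dict)  # PMBCL vs control
    coo_effects: dict = field(default_factory=dict)  # nonGCB vs GCB (DLBCL only)
    prognostic_clusters: list = field(default_factory=list)
    # longitudinal design: responders' lymphoma signal shrinks over therapy
    longitudinal: bool = False
    attenuation_responder: dict = field(
        default_factory=lambda: {"diagnosis": 1.0, "interim": 0.35, "final": 0.1}
    )
    attenuation_nonresponder: dict = field(
        default_factory=lambda: {"diagnosis": 1.0, "interim": 0.95, "final": 1.0}
    )
    responder_fraction: float = 0.5
    # survival generation
    censoring_window_days: int = 1500
    baseline_hazard: float = 1.0 / 900.0  # events per day
    ipi_gamma: float = 0.3
    spike: SpikeDesign = field(default_factory=SpikeDesign)
    circ: CircDesign = field(default_factory=CircDesign)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_dlbcl_gcb", "n_dlbcl_nongcb", "n_pmbcl", "n_genes"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.phi <= 0:
            raise ValidationError("dispersion phi must be positive")
        for att in (self.attenuation_responder, self.attenuation_nonresponder):
            if any(not (0.0 <= v <= 1.0) for v in att.values()):
                raise ValidationError("attenuation multipliers must lie in [0, 1]")

    @property
    def gene_ids(self) -> list:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def validate_effect_genes(self) -> None:
        known = set(self.gene_ids)
        for label, eff in (
            ("dlbcl_effects", self.dlbcl_effects),
            ("pmbcl_effects", self.pmbcl_effects),
            ("coo_effects", self.coo_effects),
        ):
            unknown = set(eff) - known
            if unknown:
                raise ValidationError(f"{label} reference unknown genes: {sorted(unknown)[:5]}")
        for cl in self.prognostic_clusters:
            unknown = set(cl.genes) - known
            if unknown:
                raise ValidationError(f"cluster genes unknown: {sorted(unknown)[:5]}")


_BIOTYPE_PROBS = {
    "protein_coding": 0.68,
    "lncRNA": 0.12,
    "pseudogene": 0.08,
    "snRNA": 0.03,
    "snoRNA": 0.03,
    "mt_tRNA": 0.01,
    "rRNA": 0.01,
    "other": 0.04,
}


def default_design(seed: int = 0, **overrides) -> SimulationDesign:
    """Design with the standard planted structure: 100 DLBCL and 150 PMBCL
    disease genes at |log2FC| = 2, 64 cell-of-origin genes at |log2FC| = 1.5,
    one unfavorable 9-gene PFS cluster and one unfavorable 5-gene OS cluster."""
    design = SimulationDesign(seed=seed, **overrides)
    rng = np.random.default_rng(_subseed(seed, 99))
    genes = design.gene_ids
    pool = rng.permutation(design.n_genes)
    i = 0

    def take(k):
        nonlocal i
        out = [genes[j] for j in pool[i : i + k]]
        i += k
        return out

    dlbcl = take(100)
    design.dlbcl_effects = {
        g: (2.0 if j < 50 else -2.0) for j, g in enumerate(dlbcl)
    }
    pmbcl = take(150)
    design.pmbcl_effects = {
        g: (2.0 if j < 75 else -2.0) for j, g in enumerate(pmbcl)
    }
    coo = take(64)
    design.coo_effects = {
        g: (1.5 if j < 32 else -1.5) for j, g in enumerate(coo)
    }
    design.prognostic_clusters = [
        PrognosticCluster(take(9), beta_sim=0.5, endpoint="PFS", latent_loading=1.5),
        PrognosticCluster(take(5), beta_sim=0.8, endpoint="OS", latent_loading=1.5),
    ]
    design.validate_effect_genes()
    return design


def _subseed(seed: int, offset: int) -> int:
    return int((seed * 1_000_003 + offset) % (2**31 - 1))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, variance mu + phi mu^2) via gamma-Poisson mixing."""
    mu = np.maximum(mu, 1e-12)
    if phi <= 1e-12:
        return rng.poisson(mu)
    shape = 1.0 / phi
    lam = rng.gamma(shape, mu * phi)
    return rng.poisson(lam)


def _sample_frame(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    timepoints = (
        ["diagnosis", "interim", "final"] if design.longitudinal else ["diagnosis"]
    )
    for i in range(design.n_control):
        rows.append(
            dict(sample_id=f"CTRL{i:03d}", subject_id=f"ctrl{i:03d}",
                 group="control", coo_label=None, timepoint="diagnosis",
                 responder=None)
        )
    ipi_probs = [0.05, 0.40, 0.35, 0.20]
    subj = 0
    for coo, n in (("GCB", design.n_dlbcl_gcb), ("nonGCB", design.n_dlbcl_nongcb)):
        for _ in range(n):
            responder = bool(rng.random() < design.responder_fraction)
            ipi = NCCN_IPI_LEVELS[rng.choice(4, p=ipi_probs)]
            for tp in timepoints:
                rows.append(
                    dict(sample_id=f"DLBCL{subj:03d}_{tp}",
                         subject_id=f"dlbcl{subj:03d}", group="DLBCL",
                         coo_label=coo, timepoint=tp, responder=responder,
                         nccn_ipi=ipi)
                )
            subj += 1
    for j in range(design.n_pmbcl):
        responder = bool(rng.random() < design.responder_fraction)
        for tp in timepoints:
            rows.append(
                dict(sample_id=f"PMBCL{j:03d}_{tp}", subject_id=f"pmbcl{j:03d}",
                     group="PMBCL", coo_label=None, timepoint=tp,
                     responder=responder,
                     nccn_ipi=NCCN_IPI_LEVELS[rng.choice(4, p=[0.2, 0.6, 0.15, 0.05])])
            )
    df = pd.DataFrame(rows)
    df["plasma_volume"] = design.spike.plasma_volume_ml
    return df


def generate_counts(
    design: SimulationDesign,
) -> tuple[CountMatrix, SampleTable, dict]:
    """Draw the gene-by-sample count matrix and the sample metadata.

    log2 mu(g, s) = baseline(g) + group/COO/timepoint effects + depth offset;
    counts ~ NB(mu, phi).  Returns the matrix, the metadata, and a truth
    record (planted effects, latent factors, depth factors).
    """
    design.validate_effect_genes()
    rng = np.random.default_rng(_subseed(design.seed, 0))
    genes = design.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    meta = _sample_frame(design, rng)
    n_genes, n_samples = design.n_genes, len(meta)

    baseline = rng.normal(design.baseline_log2_loc, design.baseline_log2_scale, n_genes)
    biotype = pd.Series(
        rng.choice(list(_BIOTYPE_PROBS), p=list(_BIOTYPE_PROBS.values()), size=n_genes),
        index=genes,
    )
    if design.depth_cv > 0:
        sigma = math.sqrt(math.log(1.0 + design.depth_cv**2))
        depth = rng.lognormal(-0.5 * sigma**2, sigma, n_samples)
    else:
        depth = np.ones(n_samples)

    log2mu = np.tile(baseline[:, None], (1, n_samples))
    latent: dict[str, np.ndarray] = {}
    for ci, cl in enumerate(design.prognostic_clusters):
        latent[f"cluster_{ci}"] = rng.normal(0.0, 1.0, n_samples)

    for s in range(n_samples):
        row = meta.iloc[s]
        group = row["group"]
        if group in ("DLBCL", "PMBCL"):
            att = (
                design.attenuation_responder
                if row["responder"]
                else design.attenuation_nonresponder
            )[row["timepoint"]]
            effects = (
                design.dlbcl_effects if group == "DLBCL" else design.pmbcl_effects
            )
            for g, fc in effects.items():
                log2mu[gene_pos[g], s] += fc * att
            if group == "DLBCL":
                sign = 1.0 if row["coo_label"] == "nonGCB" else 0.0
                for g, fc in design.coo_effects.items():
                    log2mu[gene_pos[g], s] += fc * sign
                for ci, cl in enumerate(design.prognostic_clusters):
                    u = latent[f"cluster_{ci}"][s]
                    for g in cl.genes:
                        log2mu[gene_pos[g], s] += cl.latent_loading * u
    log2mu += np.log2(depth)[None, :]

    counts = _nb_draw(rng, np.exp2(log2mu), design.phi)
    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=meta["sample_id"].tolist()),
        biotype,
    )
    st = SampleTable(meta.copy())
    truth = {
        "dlbcl_effects": dict(design.dlbcl_effects),
        "pmbcl_effects": dict(design.pmbcl_effects),
        "coo_effects": dict(design.coo_effects),
        "prognostic_clusters": [
            {"genes": list(c.genes), "beta_sim": c.beta_sim, "endpoint": c.endpoint}
            for c in design.prognostic_clusters
        ],
        "depth": depth.tolist(),
        "latent": {k: v.tolist() for k, v in latent.items()},
    }
    return cm, st, truth


def generate_survival(
    design: SimulationDesign, samples: SampleTable, counts: CountMatrix
) -> SampleTable:
    """Fill PFS/OS outcomes for DLBCL subjects from planted-gene expression.

    Event times are exponential with hazard
    h0 * exp(sum_g beta_sim * z_g + gamma * ipi_ordinal), using the
    subject's diagnostic-sample z-scored log expression of each planted
    cluster gene; censoring is uniform over the censoring window.
    """
    rng = np.random.default_rng(_subseed(design.seed, 1))
    meta = samples.table.copy()
    mask = (meta["group"] == "DLBCL") & (meta["timepoint"] == "diagnosis")
    ids = [s for s in counts.sample_ids if s in set(meta.index[mask])]
    if not ids:
        return samples
    logexpr = np.log2(counts.counts[ids].to_numpy(float) + 1.0)
    gene_pos = {g: i for i, g in enumerate(counts.gene_ids)}
    ipi_ord = (
        meta.loc[ids, "nccn_ipi"]
        .map({lvl: i for i, lvl in enumerate(NCCN_IPI_LEVELS)})
        .fillna(1)
        .to_numpy(float)
    )
    for endpoint, tcol, ecol in (("PFS", "pfs_time", "pfs_event"),
                                 ("OS", "os_time", "os_event")):
        lin = design.ipi_gamma * (ipi_ord - ipi_ord.mean())
        for cl in design.prognostic_clusters:
            if cl.endpoint != endpoint:
                continue
            for g in cl.genes:
                x = logexpr[gene_pos[g]]
                sd = x.std()
                z = (x - x.mean()) / (sd if sd > 0 else 1.0)
                lin = lin + cl.beta_sim * z
        hazard = design.baseline_hazard * np.exp(lin)
        t_event = rng.exponential(1.0 / hazard)
        if design.censoring_window_days > 0:
            t_cens = rng.uniform(0, design.censoring_window_days, len(ids))
        else:
            t_cens = np.full(len(ids), np.inf)
        observed = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        subj_of = meta.loc[ids, "subject_id"]
        for subject, t, e in zip(subj_of, observed, event):
            sel = meta["subject_id"] == subject
            meta.loc[sel, tcol] = float(t)
            meta.loc[sel, ecol] = int(e)
    return SampleTable(meta.reset_index(drop=True))


def generate_spikes(
    design: SimulationDesign, samples: SampleTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample spike read counts plus the true-concentration table.

    Reads mapping to the spike are Poisson with rate depth * mass fraction;
    endogenous reads make up the remainder of the depth.  The recorded true
    concentration is endogenous mass / plasma volume.
    """
    sp = design.spike
    if sp.spike_mass_ng <= 0:
        raise ValidationError("spike mass must be positive")
    if sp.depth <= 0:
        raise ValidationError("sequencing depth must be positive")
    rng = np.random.default_rng(_subseed(design.seed, 2))
    rows, truth_rows = [], []
    for _, r in samples.table.iterrows():
        endo_mass = sp.endo_mass_ng[r["group"]]
        frac = sp.spike_mass_ng / (sp.spike_mass_ng + endo_mass)
        spike_reads = int(rng.poisson(sp.depth * frac))
        endo_reads = int(sp.depth) - spike_reads
        rows.append(
            dict(sample_id=r["sample_id"], spike_id=sp.spike_id,
                 spike_mass=sp.spike_mass_ng, spike_reads=spike_reads,
                 endogenous_reads=endo_reads, plasma_volume=sp.plasma_volume_ml)
        )
        truth_rows.append(
            dict(sample_id=r["sample_id"],
                 true_concentration=endo_mass / sp.plasma_volume_ml)
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows).set_index("sample_id")


def generate_circ(
    design: SimulationDesign, counts: CountMatrix, samples: SampleTable
) -> tuple[CountMatrix, GeneAnnotation, dict]:
    """Append circRNA rows whose back-splice junction counts track a host gene.

    Each circ's mean is ``mean_fraction_of_host`` times the host's observed
    normalized mean; a ``copy_proportion`` fraction of circs copy the host's
    planted disease direction, the rest stay flat.  Returns the extended
    matrix, the annotation with host links, and a truth record.
    """
    cd = design.circ
    ann_rows = [
        dict(gene_id=g, symbol=g, biotype=str(counts.biotype[g]), host_gene_id=None)
        for g in counts.gene_ids
    ]
    if cd.n_circ == 0:
        ann = GeneAnnotation(pd.DataFrame(ann_rows))
        return counts, ann, {"circ_hosts": {}, "circ_copies_host": {}}
    rng = np.random.default_rng(_subseed(design.seed, 3))
    effect_hosts = [g for g in design.dlbcl_effects if g in counts.counts.index]
    null_hosts = [
        g for g in counts.gene_ids
        if g not in design.dlbcl_effects and counts.biotype[g] != "circRNA"
    ]
    n_eff = min(len(effect_hosts), cd.n_circ)
    hosts = list(rng.choice(effect_hosts, size=n_eff, replace=False)) + list(
        rng.choice(null_hosts, size=cd.n_circ - n_eff, replace=False)
    )
    meta = samples.table.set_index("sample_id").loc[counts.sample_ids]
    is_lymphoma = (meta["group"] != "control").to_numpy()
    new_rows, hosts_of, copies = {}, {}, {}
    for k, host in enumerate(hosts):
        circ_id = f"circ_{host}_{k}"
        hosts_of[circ_id] = host
        copy = bool(rng.random() < cd.copy_proportion)
        copies[circ_id] = copy
        base = counts.counts.loc[host].to_numpy(float)
        host_ctrl_mean = max(base[~is_lymphoma].mean() if (~is_lymphoma).any()
                             else base.mean(), 1.0)
        mu = np.full(len(base), cd.mean_fraction_of_host * host_ctrl_mean)
        if copy and host in design.dlbcl_effects:
            fc = design.dlbcl_effects[host]
            mu = np.where(
                (meta["group"] == "DLBCL").to_numpy(), mu * 2.0**fc, mu
            )
        new_rows[circ_id] = _nb_draw(rng, mu, cd.bsj_phi)
    circ_df = pd.DataFrame(new_rows, index=counts.sample_ids).T
    all_counts = pd.concat([counts.counts, circ_df])
    biotype = pd.concat(
        [counts.biotype, pd.Series("circRNA", index=list(new_rows))]
    )
    cm = CountMatrix(all_counts, biotype)
    ann_rows += [
        dict(gene_id=c, symbol=c, biotype="circRNA", host_gene_id=h)
        for c, h in hosts_of.items()
    ]
    ann = GeneAnnotation(pd.DataFrame(ann_rows))
    return cm, ann, {"circ_hosts": hosts_of, "circ_copies_host": copies}


def generate_cohort(design: SimulationDesign):
    """Full cohort: counts, metadata with survival, spikes, circRNAs, truth."""
    cm, st, truth = generate_counts(design)
    st = generate_survival(design, st, cm)
    spikes, spike_truth = generate_spikes(design, st)
    cm, ann, circ_truth = generate_circ(design, cm, st)
    truth.update(circ_truth)
    truth["true_concentration"] = spike_truth["true_concentration"].to_dict()
    return cm, st, ann, spikes, truth
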