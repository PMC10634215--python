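"""Domain types and TSV readers/writers shared by every analysis stage.

All tabular interchange is tab-separated UTF-8 with a header row and the
string ``NA`` for missing values.  Validation is strict: malformed input
raises :class:`ValidationError` naming the offending gene/sample, never a
silent coercion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "BIOTYPES",
    "GROUPS",
    "TIMEPOINTS",
    "NCCN_IPI_LEVELS",
    "CountMatrix",
    "SampleTable",
    "GepPanel",
    "GeneAnnotation",
    "AnalysisConfig",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_panel",
    "write_panel",
    "read_annotation",
    "write_annotation",
    "validate_cohort",
]

NA = "NA"

BIOTYPES = frozenset(
    {
        "protein_coding",
        "lncRNA",
        "pseudogene",
        "snRNA",
        "snoRNA",
        "mt_tRNA",
        "rRNA",
        "circRNA",
        "spike_in",
        "other",
    }
)
GROUPS = frozenset({"control", "DLBCL", "PMBCL"})
COO_LABELS = frozenset({"GCB", "nonGCB"})
TIMEPOINTS = frozenset({"diagnosis", "interim", "final", "relapse"})
NCCN_IPI_LEVELS = ("low", "low_int", "high_int", "high")

#: upper limit of the serum LDH reference interval (IU/L); values above it
#: flag an elevated LDH, a surrogate marker of tumor burden.
LDH_UPPER_REFERENCE = 250.0


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Non-negative integer gene-by-sample count matrix with gene biotypes.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with sample ids as columns; values are
        non-negative integers (read counts, or back-splice junction counts
        for circRNA rows).
    biotype
        Per-gene biotype, one of :data:`BIOTYPES`, aligned to ``counts.index``.
    """

    counts: pd.DataFrame
    biotype: pd.Series

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dupes}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts must be numeric")
        bad = ~(np.isfinite(vals) & (vals >= 0) & (vals == np.floor(vals)))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"count for gene {idx[g]!r}, sample {cols[s]!r} is "
                f"{vals[g, s]!r}: counts must be non-negative integers"
            )
        self.counts = self.counts.astype(np.int64)
        self.biotype = self.biotype.reindex(idx)
        if self.biotype.isna().any():
            missing = list(idx[self.biotype.isna()])[:5]
            raise ValidationError(f"genes without biotype: {missing}")
        unknown = set(self.biotype.unique()) - BIOTYPES
        if unknown:
            raise ValidationError(f"unknown biotypes: {sorted(unknown)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return CountMatrix(self.counts[list(sample_ids)].copy(), self.biotype.copy())

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        missing = [g for g in gene_ids if g not in self.counts.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing}")
        return CountMatrix(
            self.counts.loc[list(gene_ids)].copy(),
            self.biotype.loc[list(gene_ids)].copy(),
        )

    def biotype_counts(self) -> dict[str, int]:
        return self.biotype.value_counts().to_dict()


def read_count_matrix(path) -> CountMatrix:
    """Read a gene-by-sample count TSV.

    The first column holds gene ids; an optional ``biotype`` column holds
    per-gene biotypes (defaulting to ``other`` when absent); every remaining
    column is a sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_filter=False)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"duplicate gene ids in {path}: {dupes}")
    if "biotype" in df.columns:
        biotype = df["biotype"]
        df = df.drop(columns=["biotype"])
    else:
        biotype = pd.Series("other", index=df.index)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"non-numeric count for gene {gene!r}, sample {col!r}: "
                f"{df.loc[gene, col]!r}"
            )
        frac = converted != np.floor(converted)
        if frac.any():
            gene = df.index[frac.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"non-integer count for gene {gene!r}, sample {col!r}: "
                f"{df.loc[gene, col]!r}"
            )
        numeric[col] = converted
    return CountMatrix(numeric, biotype)


def write_count_matrix(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.insert(0, "biotype", cm.biotype)
    out.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------

_SAMPLE_COLUMNS = [
    "sample_id",
    "subject_id",
    "group",
    "coo_label",
    "timepoint",
    "plasma_volume",
    "ldh",
    "ldh_elevated",
    "nccn_ipi",
    "responder",
    "pfs_time",
    "os_time",
    "pfs_event",
    "os_event",
]


@dataclass
class SampleTable:
    """Per-sample clinical and design metadata.

    Wraps a DataFrame with one row per sample: study group (control / DLBCL /
    PMBCL), cell-of-origin label for DLBCL, longitudinal timepoint, plasma
    volume (mL), LDH (IU/L) with the derived ``ldh_elevated`` flag
    (LDH > 250 IU/L, the upper reference limit), NCCN-IPI category, therapy
    response, and PFS/OS times (days) and event indicators.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if "sample_id" not in df.columns:
            raise ValidationError("sample table needs a sample_id column")
        if df["sample_id"].duplicated().any():
            dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
            raise ValidationError(f"duplicate sample ids: {dupes}")
        for col in _SAMPLE_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        bad_group = set(df["group"].dropna()) - GROUPS
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        bad_coo = set(df["coo_label"].dropna()) - COO_LABELS
        if bad_coo:
            raise ValidationError(f"unknown COO labels: {sorted(bad_coo)}")
        coo_outside = df["coo_label"].notna() & (df["group"] != "DLBCL")
        if coo_outside.any():
            raise ValidationError(
                "coo_label set for non-DLBCL samples: "
                f"{sorted(df.loc[coo_outside, 'sample_id'])}"
            )
        bad_tp = set(df["timepoint"].dropna()) - TIMEPOINTS
        if bad_tp:
            raise ValidationError(f"unknown timepoints: {sorted(bad_tp)}")
        bad_ipi = set(df["nccn_ipi"].dropna()) - set(NCCN_IPI_LEVELS)
        if bad_ipi:
            raise ValidationError(f"unknown NCCN-IPI levels: {sorted(bad_ipi)}")
        for col in ("pfs_time", "os_time", "ldh", "plasma_volume"):
            df[col] = pd.to_numeric(df[col], errors="raise")
            if (df[col].dropna() < 0).any():
                raise ValidationError(f"negative values in {col}")
        for col in ("pfs_event", "os_event"):
            df[col] = pd.to_numeric(df[col], errors="raise")
            bad = ~df[col].dropna().isin([0, 1])
            if bad.any():
                raise ValidationError(f"{col} must be 0/1")
        # ldh_elevated is derived, never trusted from input
        df["ldh_elevated"] = (df["ldh"] > LDH_UPPER_REFERENCE).astype("boolean")
        df.loc[df["ldh"].isna(), "ldh_elevated"] = pd.NA
        self.table = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group_counts(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()

    def select(self, **criteria) -> "SampleTable":
        """Rows matching every ``column=value`` (or ``column=list``) criterion."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in criteria.items():
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= self.table[col].isin(list(val))
            else:
                mask &= self.table[col] == val
        return SampleTable(self.table.loc[mask].reset_index(drop=True).copy())


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA], keep_default_na=False)
    for col in ("plasma_volume", "ldh", "pfs_time", "os_time"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("pfs_event", "os_event"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    if "responder" in df.columns:
        df["responder"] = df["responder"].map(
            {"True": True, "False": False, "true": True, "false": False,
             "1": True, "0": False, None: pd.NA}
        )
    return SampleTable(df)


def write_sample_table(st: SampleTable, path) -> None:
    st.table.to_csv(path, sep="\t", index=False, na_rep=NA)


# ---------------------------------------------------------------------------
# GepPanel / GeneAnnotation
# ---------------------------------------------------------------------------


@dataclass
class GepPanel:
    """Two disjoint oriented gene lists defining a two-class expression classifier."""

    name: str
    up_in_class1: frozenset
    up_in_class2: frozenset
    class1_label: str = "GCB"
    class2_label: str = "nonGCB"

    def __post_init__(self) -> None:
        self.up_in_class1 = frozenset(self.up_in_class1)
        self.up_in_class2 = frozenset(self.up_in_class2)
        if not self.up_in_class1 or not self.up_in_class2:
            raise ValidationError(
                f"panel {self.name!r}: both gene sets must be non-empty "
                f"(got {len(self.up_in_class1)} / {len(self.up_in_class2)})"
            )
        overlap = self.up_in_class1 & self.up_in_class2
        if overlap:
            raise ValidationError(
                f"panel {self.name!r}: gene sets overlap: {sorted(overlap)}"
            )

    def swapped(self) -> "GepPanel":
        """Panel with the two class gene sets (and labels) exchanged."""
        return GepPanel(
            self.name + "_swapped",
            self.up_in_class2,
            self.up_in_class1,
            self.class2_label,
            self.class1_label,
        )

    @property
    def genes(self) -> frozenset:
        return self.up_in_class1 | self.up_in_class2


def read_panel(path, name: str | None = None,
               class1_label: str = "GCB", class2_label: str = "nonGCB") -> GepPanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "class"} <= set(df.columns):
        raise ValidationError("panel file needs gene_id and class columns")
    bad = set(df["class"]) - {"class1", "class2"}
    if bad:
        raise ValidationError(f"panel class must be class1/class2, got {sorted(bad)}")
    return GepPanel(
        name or str(path),
        frozenset(df.loc[df["class"] == "class1", "gene_id"]),
        frozenset(df.loc[df["class"] == "class2", "gene_id"]),
        class1_label,
        class2_label,
    )


def write_panel(panel: GepPanel, path) -> None:
    rows = [(g, "class1") for g in sorted(panel.up_in_class1)] + [
        (g, "class2") for g in sorted(panel.up_in_class2)
    ]
    pd.DataFrame(rows, columns=["gene_id", "class"]).to_csv(path, sep="\t", index=False)


@dataclass
class GeneAnnotation:
    """Gene id / symbol / biotype table with circRNA-to-host-gene links."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        for col in ("gene_id", "symbol", "biotype", "host_gene_id"):
            if col not in df.columns:
                df[col] = pd.NA
        if df["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene ids in annotation")
        linked = df["host_gene_id"].dropna()
        known = set(df["gene_id"])
        dangling = set(linked) - known
        if dangling:
            raise ValidationError(f"host_gene_id not in annotation: {sorted(dangling)}")
        host_biotype = df.set_index("gene_id")["biotype"].reindex(linked)
        circ_hosts = host_biotype == "circRNA"
        if circ_hosts.any():
            raise ValidationError(
                f"circRNA listed as host gene: {sorted(host_biotype[circ_hosts].index)}"
            )
        self.table = df.set_index("gene_id", drop=False)

    def host_of(self) -> pd.Series:
        """circRNA gene id -> host gene id (only rows with a link)."""
        return self.table["host_gene_id"].dropna()


def read_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA], keep_default_na=False)
    return GeneAnnotation(df)


def write_annotation(ann: GeneAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False, na_rep=NA)


# ---------------------------------------------------------------------------
# AnalysisConfig
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Thresholds shared across the pipeline.

    prefilter_min_count : minimum count for the expression prefilter (linear genes)
    prefilter_min_circ_bsj : minimum back-splice junction count (circRNA genes)
    prefilter_group_fraction : fraction of a group that must pass the minimum
    q_threshold : BH q-value significance cutoff for differential abundance
    cox_p_threshold, cox_beta_threshold : univariate Cox gene-screen cutoffs
    maxstat_quantile_range : candidate-cutpoint window for maximally selected
        rank statistics
    """

    prefilter_min_count: int = 10
    prefilter_min_circ_bsj: int = 4
    prefilter_group_fraction: float = 0.5
    q_threshold: float = 0.05
    cox_p_threshold: float = 0.01
    cox_beta_threshold: float = 2.0
    maxstat_quantile_range: tuple[float, float] = (0.10, 0.90)
    min_cluster_size: int = 3
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "prefilter_min_count",
            "prefilter_min_circ_bsj",
            "prefilter_group_fraction",
            "q_threshold",
            "cox_p_threshold",
            "cox_beta_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        lo, hi = self.maxstat_quantile_range
        if not (0 < lo < hi < 1):
            raise ValidationError("maxstat_quantile_range must be ordered within (0,1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "maxstat_quantile_range" in data:
            data["maxstat_quantile_range"] = tuple(data["maxstat_quantile_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maxstat_quantile_range"] = list(self.maxstat_quantile_range)
        return d


# ---------------------------------------------------------------------------
# Cohort validation
# ---------------------------------------------------------------------------


def validate_cohort(counts: CountMatrix, samples: SampleTable) -> dict:
    """Check that counts and metadata describe the same samples.

    Returns a report with per-group sample tallies and per-biotype gene
    tallies; raises :class:`ValidationError` listing any sample-id mismatch.
    """
    in_counts = set(counts.sample_ids)
    in_meta = set(samples.sample_ids)
    if in_counts != in_meta:
        extra = sorted(in_counts - in_meta)
        missing = sorted(in_meta - in_counts)
        raise ValidationError(
            f"sample sets differ: only in counts {extra}; only in metadata {missing}"
        )
    return {
        "n_samples": len(in_counts),
        "n_genes": counts.shape[0],
        "samples_per_group": samples.group_counts(),
        "genes_per_biotype": counts.biotype_counts(),
    }


def cohort_summary(samples: SampleTable, numerators: Mapping[str, int] | None = None,
                   denominator: int | None = None) -> dict:
    """Percentage arithmetic for cohort characteristic tables.

    With explicit ``numerators``/``denominator`` computes ``100*k/n`` per entry
    (two-decimal rounding); otherwise tallies group sizes from the table.
    """
    if numerators is not None:
        if not denominator or denominator <= 0:
            raise ValidationError("denominator must be positive")
        return {k: round(100.0 * v / denominator, 2) for k, v in numerators.items()}
    counts = samples.group_counts()
    total = sum(counts.values())
    return {k: round(100.0 * v / total, 2) for k, v in counts.items()}
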