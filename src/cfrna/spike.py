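"""Spike-in based absolute cfRNA concentration estimation.

A known mass of a synthetic spike-in control is added to each plasma sample
before library preparation.  Because spike and endogenous molecules share
the same capture and sequencing path, the ratio of endogenous to spike reads
estimates the ratio of endogenous to spike mass, so

    concentration (ng/mL) = spike_mass * (endogenous_reads / spike_reads)
                            / plasma_volume

The spike used is the most abundant control in the mix (configurable; by
default the spike with the highest mean read count across samples).
Endogenous read counts are taken as deduplicated uniquely mapped counts
supplied as an input column; this module never touches alignments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SampleTable, ValidationError
from .stats import group_compare

log = logging.getLogger(__name__)

__all__ = [
    "SpikeInput",
    "ConcentrationResult",
    "spike_mass_from_stock",
    "estimate_concentration",
    "estimate_concentrations",
    "select_top_spike",
    "compare_concentration_groups",
]


@dataclass
class SpikeInput:
    sample_id: str
    spike_id: str
    spike_mass: float  # ng added to the sample
    spike_reads: int
    endogenous_reads: int
    plasma_volume: float  # mL

    def __post_init__(self) -> None:
        if self.spike_mass <= 0:
            raise ValidationError("spike_mass must be positive")
        if self.plasma_volume <= 0:
            raise ValidationError("plasma_volume must be positive")
        if self.spike_reads < 0 or self.endogenous_reads < 0:
            raise ValidationError("read counts must be non-negative")


@dataclass
class ConcentrationResult:
    sample_id: str
    concentration: float  # ng RNA / mL plasma; NaN when undefined
    defined: bool


def spike_mass_from_stock(
    stock_conc: float, dilution_factor: float, volume_added: float
) -> float:
    """Mass (ng) of spike added: stock concentration (ng/uL) x volume (uL)
    divided by the dilution factor of the working mix."""
    if stock_conc <= 0 or dilution_factor <= 0 or volume_added <= 0:
        raise ValidationError("stock concentration, dilution and volume must be positive")
    return stock_conc * volume_added / dilution_factor


def estimate_concentration(inp: SpikeInput) -> ConcentrationResult:
    """Single-sample concentration from the spike read ratio.

    A sample with zero spike reads yields a flagged-undefined result (NaN),
    never a silent zero."""
    if inp.spike_reads == 0:
        log.warning("sample %s: spike dropout, concentration undefined", inp.sample_id)
        return ConcentrationResult(inp.sample_id, float("nan"), False)
    conc = inp.spike_mass * (inp.endogenous_reads / inp.spike_reads) / inp.plasma_volume
    return ConcentrationResult(inp.sample_id, conc, True)


def select_top_spike(spike_table: pd.DataFrame, spike_id: str | None = None) -> str:
    """The named spike, or the spike with the highest mean read count."""
    if spike_id is not None:
        if spike_id not in set(spike_table["spike_id"]):
            raise ValidationError(f"spike {spike_id!r} absent from table")
        return spike_id
    means = spike_table.groupby("spike_id")["spike_reads"].mean()
    return str(means.idxmax())


def estimate_concentrations(
    spike_table: pd.DataFrame, spike_id: str | None = None
) -> pd.DataFrame:
    """Per-sample concentrations from a long-format spike read table.

    Columns required: sample_id, spike_id, spike_mass, spike_reads,
    endogenous_reads, plasma_volume.  Only rows for the selected (top
    abundant or named) spike are used.
    """
    required = {
        "sample_id", "spike_id", "spike_mass",
        "spike_reads", "endogenous_reads", "plasma_volume",
    }
    missing = required - set(spike_table.columns)
    if missing:
        raise ValidationError(f"spike table missing columns: {sorted(missing)}")
    chosen = select_top_spike(spike_table, spike_id)
    sub = spike_table[spike_table["spike_id"] == chosen]
    rows = []
    for _, r in sub.iterrows():
        res = estimate_concentration(
            SpikeInput(
                str(r["sample_id"]), chosen, float(r["spike_mass"]),
                int(r["spike_reads"]), int(r["endogenous_reads"]),
                float(r["plasma_volume"]),
            )
        )
        rows.append(
            {"sample_id": res.sample_id, "spike_id": chosen,
             "concentration": res.concentration, "defined": res.defined}
        )
    n_undef = sum(not r["defined"] for r in rows)
    if n_undef:
        log.warning("%d samples with undefined concentration (spike dropout)", n_undef)
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def compare_concentration_groups(
    concentrations: pd.DataFrame,
    samples: SampleTable,
    grouping: str = "group",
    paired_timepoints: tuple[str, str] | None = None,
) -> dict:
    """Compare concentrations across sample groups.

    Kruskal-Wallis omnibus over the levels of ``grouping`` with Holm-adjusted
    pairwise rank-sum tests (undefined concentrations excluded, count
    logged).  When ``paired_timepoints`` is given, additionally runs a
    Wilcoxon signed-rank test on subjects with samples at both timepoints.
    """
    merged = concentrations.join(
        samples.table.drop(columns=["sample_id"]), how="inner"
    )
    defined = merged[merged["defined"].astype(bool) & merged[grouping].notna()]
    dropped = len(merged) - len(defined)
    if dropped:
        log.info("excluded %d samples (undefined concentration or missing label)", dropped)
    report = group_compare(
        defined["concentration"].to_numpy(), defined[grouping].to_numpy()
    )
    report["grouping"] = grouping
    report["n_excluded"] = int(dropped)
    if paired_timepoints is not None:
        from scipy.stats import wilcoxon

        pre, post = paired_timepoints
        wide = defined.pivot_table(
            index="subject_id", columns="timepoint", values="concentration",
            aggfunc="first",
        )
        both = wide.dropna(subset=[pre, post]) if {pre, post} <= set(wide.columns) else wide.iloc[:0]
        if len(both) >= 2 and not np.allclose(both[pre], both[post]):
            stat, p = wilcoxon(both[pre], both[post])
            report["paired"] = {
                "timepoints": [pre, post], "n_subjects": int(len(both)),
                "statistic": float(stat), "p": float(p),
            }
        else:
            report["paired"] = {
                "timepoints": [pre, post], "n_subjects": int(len(both)),
                "statistic": float("nan"), "p": float("nan"),
            }
    return report
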