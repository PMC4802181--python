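"""Expression quantification and the two-control concordant differential call.

FPKM is computed from raw counts, replicates are averaged on the log2
scale, and a gene is called increased/decreased in a knockdown only when
the log2 change relative to BOTH controls (untreated and siControl)
exceeds the threshold in the same direction. Also provides reference-
condition quartile binning and the 2^-ddCt qPCR fold change.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_LOG2_PSEUDOCOUNT = 0.01
DEFAULT_LFC_THRESHOLD = 1.0


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct values (cycles) for target and reference gene in two conditions."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for v in (
            self.ct_target_treated,
            self.ct_reference_treated,
            self.ct_target_control,
            self.ct_reference_control,
        ):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("Ct values must be finite and > 0")


@dataclass(frozen=True)
class DifferentialCall:
    gene_id: str
    direction: str  # increased | decreased | unchanged
    lfc_vs_control_1: float
    lfc_vs_control_2: float


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    mapped_totals: pd.Series,
) -> pd.DataFrame:
    """FPKM = count / ((length/1e3) * (mapped_total/1e6)).

    ``counts`` is genes x samples; ``gene_lengths`` in bp indexed like the
    rows; ``mapped_totals`` in reads indexed like the columns.
    """
    lengths = gene_lengths.reindex(counts.index)
    totals = mapped_totals.reindex(counts.columns)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if (totals <= 0).any():
        raise ValueError("mapped totals must be > 0")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def log2_average_replicates(
    fpkm: pd.DataFrame,
    condition_map: dict[str, list[str]],
    pseudocount: float = DEFAULT_LOG2_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Mean over replicates of log2(FPKM + pseudocount), per condition.

    Averaging on the log scale means the per-condition value is the log of
    the geometric mean of the replicates (up to the pseudocount).
    """
    out = {}
    for condition, samples in condition_map.items():
        if not samples:
            raise ValueError(f"condition {condition!r} has no replicates")
        out[condition] = np.log2(fpkm[samples] + pseudocount).mean(axis=1)
    result = pd.DataFrame(out)
    result.attrs["pseudocount"] = pseudocount
    return result


def concordant_differential_call(
    gene_id: str,
    kd: float,
    control_1: float,
    control_2: float,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> DifferentialCall:
    """Two-control concordance rule on log2-scale expression values.

    decreased iff (control_1 - kd) >= threshold AND (control_2 - kd) >=
    threshold; increased symmetrically; otherwise unchanged.
    """
    d1 = kd - control_1
    d2 = kd - control_2
    if d1 <= -lfc_threshold and d2 <= -lfc_threshold:
        direction = "decreased"
    elif d1 >= lfc_threshold and d2 >= lfc_threshold:
        direction = "increased"
    else:
        direction = "unchanged"
    return DifferentialCall(gene_id, direction, d1, d2)


def call_differential_table(
    log2_table: pd.DataFrame,
    kd: str,
    control_1: str = "control_1",
    control_2: str = "control_2",
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Apply the concordance rule to every gene of a per-condition log2 table."""
    for col in (kd, control_1, control_2):
        if col not in log2_table.columns:
            raise ValueError(f"missing condition column {col!r}")
    calls = [
        concordant_differential_call(
            str(g),
            float(log2_table.at[g, kd]),
            float(log2_table.at[g, control_1]),
            float(log2_table.at[g, control_2]),
            lfc_threshold,
        )
        for g in log2_table.index
    ]
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "direction": [c.direction for c in calls],
            "lfc_vs_control_1": [c.lfc_vs_control_1 for c in calls],
            "lfc_vs_control_2": [c.lfc_vs_control_2 for c in calls],
        }
    ).set_index("gene_id")


def quartile_bins(values: pd.Series | np.ndarray) -> pd.Series:
    """Q1 (lowest 25%) .. Q4 (top 25%) labels by nearest-rank quartile.

    Ties at a boundary are kept in the upper bin (inclusive-tie policy), so
    an all-equal input is labelled entirely Q4.
    """
    s = pd.Series(values)
    if len(s) < 4:
        raise ValueError("need at least 4 values")
    sorted_vals = np.sort(s.to_numpy())
    n = len(sorted_vals)
    cuts = [
        sorted_vals[min(int(np.ceil(q * n)), n - 1)] for q in (0.25, 0.5, 0.75)
    ]
    labels = pd.Series("Q1", index=s.index, dtype=object)
    labels[s >= cuts[0]] = "Q2"
    labels[s >= cuts[1]] = "Q3"
    labels[s >= cuts[2]] = "Q4"
    return labels


def fold_change_ddct(m: QpcrMeasurement) -> float:
    """Relative quantification: 2^-(ddCt) with dCt = Ct_target - Ct_reference
    per condition and ddCt = dCt_treated - dCt_control."""
    dct_treated = m.ct_target_treated - m.ct_reference_treated
    dct_control = m.ct_target_control - m.ct_reference_control
    return 2.0 ** (-(dct_treated - dct_control))
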