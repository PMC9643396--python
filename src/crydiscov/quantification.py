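"""Bespoke quantification rules: 2^-ddCT expression, caspase fold activity,
AP-MS spectral-count retention, and small reporting helpers.

The AP-MS filter mirrors a pull-down triage over three experiments with
three arms each (control, bait, bait+competitor): a protein is retained when
its bait spectral count exceeds ``bait_gt`` while its control count stays
below ``control_lt`` in at least ``min_replicates`` experiments, and a
competitor/bait mean-count ratio is attached as competition evidence (lower
ratio = binding more specifically displaced by free compound).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError

__all__ = [
    "QPCRRecord",
    "SpectralCountMatrix",
    "ddct_fold",
    "caspase_fold",
    "apms_filter",
    "event_proportion",
]


@dataclass(frozen=True)
class QPCRRecord:
    sample: str
    condition: str
    gene: str
    ct: float  # threshold cycle
    replicate: str = "1"

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError("CT must be positive")


@dataclass
class SpectralCountMatrix:
    """Long-format spectral counts: one row per (protein, experiment, arm).

    ``data`` columns: protein, experiment, control, bait, bait_competitor.
    Counts must be non-negative integers with complete arm coverage per
    experiment.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"protein", "experiment", "control", "bait", "bait_competitor"}
        missing = required - set(self.data.columns)
        if missing:
            raise AnalysisError(f"spectral-count table missing columns: {sorted(missing)}")
        counts = self.data[["control", "bait", "bait_competitor"]]
        if (counts.to_numpy() < 0).any():
            raise AnalysisError("spectral counts must be >= 0")

    @classmethod
    def from_rows(
        cls, rows: Mapping[str, Sequence[tuple[int, int, int]]]
    ) -> "SpectralCountMatrix":
        """Build from {protein: [(control, bait, bait_competitor) per experiment]}."""
        records = []
        for protein, triples in rows.items():
            for i, (ctrl, bait, comp) in enumerate(triples, start=1):
                records.append(
                    dict(protein=protein, experiment=i, control=ctrl,
                         bait=bait, bait_competitor=comp)
                )
        return cls(pd.DataFrame.from_records(records))


def ddct_fold(
    records: Sequence[QPCRRecord],
    target_gene: str,
    reference_gene: str,
    calibrator_condition: str,
) -> pd.DataFrame:
    """Relative expression per condition by the 2^-ddCT method.

    dCT = CT_target - CT_reference within each (condition, sample,
    replicate); ddCT subtracts the mean calibrator dCT; fold = 2^-ddCT.
    Returns per-condition mean fold, SEM and replicate count.
    """
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        raise AnalysisError("no qPCR records supplied")
    pivot = df.pivot_table(
        index=["condition", "sample", "replicate"],
        columns="gene", values="ct", aggfunc="mean",
    )
    for gene in (target_gene, reference_gene):
        if gene not in pivot.columns:
            raise AnalysisError(f"gene {gene!r} absent from records")
    missing_ref = pivot[pivot[reference_gene].isna()]
    if not missing_ref.empty:
        sample = missing_ref.index[0][1]
        raise AnalysisError(f"missing reference CT for sample {sample!r}")
    missing_tgt = pivot[pivot[target_gene].isna()]
    if not missing_tgt.empty:
        sample = missing_tgt.index[0][1]
        raise AnalysisError(f"missing target CT for sample {sample!r}")
    dct = pivot[target_gene] - pivot[reference_gene]
    cal = dct.xs(calibrator_condition, level="condition")
    if cal.empty:
        raise AnalysisError(f"no records for calibrator condition {calibrator_condition!r}")
    ddct = dct - cal.mean()
    fold = np.power(2.0, -ddct)
    out = fold.groupby(level="condition").agg(["mean", "sem", "count"])
    out.columns = ["fold_mean", "fold_sem", "n"]
    out["fold_sem"] = out["fold_sem"].fillna(0.0)
    return out


def caspase_fold(
    activity: float, protein: float, baseline_activity: float, baseline_protein: float
) -> float:
    """Protein-normalized caspase activity as fold over the untreated baseline.

    fold = (activity / protein) / (baseline_activity / baseline_protein).
    """
    if protein <= 0 or baseline_protein <= 0:
        raise AnalysisError("protein amounts must be positive")
    baseline_ratio = baseline_activity / baseline_protein
    if baseline_ratio == 0:
        raise AnalysisError("baseline activity ratio is zero")
    return (activity / protein) / baseline_ratio


def apms_filter(
    matrix: SpectralCountMatrix,
    bait_gt: int = 5,
    control_lt: int = 5,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Retain pull-down proteins with bait SC > ``bait_gt`` and control SC <
    ``control_lt`` in at least ``min_replicates`` experiments.

    Returns the retained proteins with the number of qualifying experiments
    and the competitor-reduction ratio mean(bait+competitor SC)/mean(bait SC).
    """
    df = matrix.data
    n_experiments = df.groupby("protein")["experiment"].nunique()
    if min_replicates > int(n_experiments.max()):
        raise AnalysisError(
            f"min_replicates={min_replicates} exceeds the "
            f"{int(n_experiments.max())} available experiments"
        )
    qualifying = (df["bait"] > bait_gt) & (df["control"] < control_lt)
    hits = (
        df.assign(q=qualifying)
        .groupby("protein")
        .agg(
            qualifying_experiments=("q", "sum"),
            bait_mean=("bait", "mean"),
            competitor_mean=("bait_competitor", "mean"),
        )
    )
    retained = hits[hits["qualifying_experiments"] >= min_replicates].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        retained["competitor_ratio"] = np.where(
            retained["bait_mean"] > 0,
            retained["competitor_mean"] / retained["bait_mean"],
            np.nan,
        )
    return retained.sort_values("competitor_ratio")


def event_proportion(events: int, total: int) -> float:
    """Proportion of subjects with an event, as a percentage (e.g. mortality
    of 1 among 6 animals -> 16.67)."""
    if total <= 0:
        raise AnalysisError("total must be positive")
    if not 0 <= events <= total:
        raise AnalysisError("events must lie in [0, total]")
    return 100.0 * events / total
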