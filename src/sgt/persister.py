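"""End-to-end relative-survival workflows for antibiotic-tolerance assays.

A persister assay compares, per sample, an antibiotic-treated culture against
an untreated "normalizer" aliquot of the same culture (both diluted by the
same factor, so the dilution cancels from every SGT difference), then
normalizes each sample's dSGT to a reference strain or condition, the
"calibrator". The reported log2 fold change (-ddSGT) is the relative size of
the surviving, antibiotic-tolerant subpopulation.

Also provided: concordance checks of SGT-derived fold changes against
ground-truth counts, and plate-capacity planning for compound screens
(triplicates of 32 compounds fit a 96-well plate; 128 fit a 384-well plate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .core import (
    DeltaDeltaResult,
    DeltaSGT,
    aggregate_replicates,
    compute_sgt,
    delta_delta_sgt,
    delta_sgt,
    estimate_doubling_time,
)
from .exceptions import DesignError, UsageError, ValidationError
from .plate_io import GrowthCurve, PlateMap

__all__ = [
    "AssayDesign",
    "SurvivalComparison",
    "quantify_survival",
    "compare_with_counts",
    "plate_capacity",
]

RESULT_COLUMNS = [
    "sample_id", "n_treated", "n_normalizer", "delta_sgt", "sd_delta_sgt",
    "ddsgt", "log2_fold", "sd_log2_fold", "fold", "sd_fold", "mode", "censored",
]


@dataclass(frozen=True)
class AssayDesign:
    """Design of a relative-survival assay.

    ``dilution_factor`` is the common post-antibiotic dilution of both arms
    (1:500 conventionally). It cancels from the arithmetic but is recorded,
    and the design refuses unequal treated/normalizer dilutions elsewhere in
    the pipeline because they would bias dSGT by log2(ratio) doublings.
    """

    samples: tuple[str, ...]
    calibrator_id: str
    dilution_factor: float = 500.0
    threshold: float = 0.15
    mode: str = "paper"
    doubling_time_hours: float | None = None
    consecutive: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        if len(set(self.samples)) != len(self.samples):
            raise DesignError("duplicate sample_id in design")
        if self.calibrator_id not in self.samples:
            raise DesignError(
                f"calibrator {self.calibrator_id!r} is not among the design samples"
            )
        if not self.dilution_factor > 0:
            raise DesignError("dilution_factor must be positive")
        if self.mode not in {"paper", "doublings"}:
            raise UsageError(f"unknown mode {self.mode!r}")
        if self.mode == "doublings" and (
            self.doubling_time_hours is None or not self.doubling_time_hours > 0
        ):
            raise UsageError("doublings mode requires doubling_time_hours > 0")


@dataclass(frozen=True)
class SurvivalComparison:
    """Concordance of SGT-derived log2 folds with ground-truth counts."""

    table: pd.DataFrame  # sample_id, log2_fold_sgt, log2_fold_true, difference
    mean_abs_difference: float
    statistic: float
    p_value: float


def _check_design_wells(plate_map: PlateMap, design: AssayDesign) -> None:
    have: dict[tuple[str, str], int] = {}
    for e in plate_map.entries.values():
        have[(e.sample_id, e.role)] = have.get((e.sample_id, e.role), 0) + 1
    for sample in design.samples:
        for role in ("treated", "normalizer"):
            if have.get((sample, role), 0) < 1:
                raise DesignError(
                    f"sample {sample!r} has no {role} wells in the plate map"
                )


def _awakening_check(
    curves_by_sample_role: Mapping[tuple[str, str], list[GrowthCurve]],
    design: AssayDesign,
    warn_factor: float,
) -> None:
    """Warn when a treated arm's post-threshold growth differs from its normalizer's.

    Unequal regrowth kinetics (slow or fast "awakening" of survivors) bias
    dSGT; the bias is surfaced, not corrected.
    """
    window = (design.threshold, 4.0 * design.threshold)
    for sample in design.samples:
        tds = {}
        for role in ("treated", "normalizer"):
            estimates = []
            for c in curves_by_sample_role.get((sample, role), []):
                try:
                    estimates.append(estimate_doubling_time(c, window))
                except Exception:
                    continue
            if estimates:
                tds[role] = float(np.mean(estimates))
        if len(tds) == 2 and tds["normalizer"] > 0:
            ratio = tds["treated"] / tds["normalizer"]
            if ratio > warn_factor or ratio < 1.0 / warn_factor:
                warnings.warn(
                    f"sample {sample!r}: treated/normalizer doubling-time ratio "
                    f"{ratio:.2f} exceeds {warn_factor:g}x; regrowth (awakening) "
                    "kinetics differ and may bias the survival estimate",
                    stacklevel=3,
                )


def quantify_survival(
    curves: Sequence[GrowthCurve],
    plate_map: PlateMap,
    design: AssayDesign,
    awakening_warn_factor: float = 1.5,
) -> pd.DataFrame:
    """Per-sample relative survival: dSGT, ddSGT, log2 fold and fold with sd.

    Pipeline: SGT per well -> replicate aggregation per (sample, arm) ->
    dSGT per sample -> ddSGT against the calibrator. The calibrator's own
    row has log2_fold 0 and fold 1 by construction. Censored wells propagate
    into flagged rows, never silent numbers.
    """
    _check_design_wells(plate_map, design)
    by_key: dict[tuple[str, str], list[GrowthCurve]] = {}
    relevant = []
    for c in curves:
        if c.well_id not in plate_map:
            continue
        e = plate_map[c.well_id]
        if e.sample_id in design.samples and e.role in ("treated", "normalizer"):
            relevant.append(c)
            by_key.setdefault((e.sample_id, e.role), []).append(c)
    for sample in design.samples:
        for role in ("treated", "normalizer"):
            if not by_key.get((sample, role)):
                raise DesignError(
                    f"sample {sample!r}: {role} wells referenced by the design "
                    f"are missing from the kinetic data"
                )

    results = [
        compute_sgt(c, threshold=design.threshold, consecutive=design.consecutive)
        for c in relevant
    ]
    stats = aggregate_replicates(results, plate_map)
    _awakening_check(by_key, design, awakening_warn_factor)

    def arm(sample: str, role: str):
        key = f"{sample}:{role}"
        if key in stats:
            return stats[key]
        # replicate_group labels in the plate map override the default key
        for e in plate_map.entries.values():
            if e.sample_id == sample and e.role == role and e.replicate_group:
                return stats[e.replicate_group]
        raise DesignError(f"no aggregated {role} group for sample {sample!r}")

    dsgts = {
        s: delta_sgt(arm(s, "treated"), arm(s, "normalizer"), s)
        for s in design.samples
    }
    calibrator = dsgts[design.calibrator_id]

    rows = []
    for s in design.samples:
        dd = delta_delta_sgt(
            dsgts[s], calibrator, mode=design.mode,
            doubling_time_hours=design.doubling_time_hours,
        )
        rows.append({
            "sample_id": s,
            "n_treated": dsgts[s].n_treated,
            "n_normalizer": dsgts[s].n_normalizer,
            "delta_sgt": dsgts[s].value,
            "sd_delta_sgt": dsgts[s].sd,
            "ddsgt": dd.ddsgt,
            "log2_fold": dd.log2_fold,
            "sd_log2_fold": dd.sd,
            "fold": dd.fold,
            "sd_fold": dd.sd_fold,
            "mode": dd.mode,
            "censored": dd.censored,
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def compare_with_counts(
    sgt_table: pd.DataFrame,
    true_counts_table: pd.DataFrame,
) -> SurvivalComparison:
    """Compare SGT-derived log2 fold changes with ground-truth-derived ones.

    ``sgt_table`` is the output of :func:`quantify_survival`;
    ``true_counts_table`` needs columns ``sample_id`` and ``log2_fold``
    (e.g. computed from a simulator's true surviving counts, standing in for
    CFU plating). Reports per-sample differences, their mean absolute value
    and a paired two-sided t-test; the p-value is reported, never
    thresholded here.
    """
    for name, df in (("sgt_table", sgt_table), ("true_counts_table", true_counts_table)):
        for col in ("sample_id", "log2_fold"):
            if col not in df.columns:
                raise ValidationError(f"{name} must have a {col!r} column")
    left = sgt_table.set_index("sample_id")["log2_fold"]
    right = true_counts_table.set_index("sample_id")["log2_fold"]
    if set(left.index) != set(right.index):
        missing = set(left.index) ^ set(right.index)
        raise ValidationError(f"sample_ids do not match; unpaired: {sorted(missing)}")
    right = right.reindex(left.index)
    diff = (left - right).astype(float)
    table = pd.DataFrame({
        "sample_id": left.index,
        "log2_fold_sgt": left.to_numpy(float),
        "log2_fold_true": right.to_numpy(float),
        "difference": diff.to_numpy(),
    }).reset_index(drop=True)
    mad = float(np.mean(np.abs(diff)))
    if len(diff) >= 2 and float(np.std(diff, ddof=1)) > 0:
        stat, p = _stats.ttest_rel(left.to_numpy(float), right.to_numpy(float))
        stat, p = float(stat), float(p)
    else:  # identical tables or a single pair: no variance to test against
        stat, p = 0.0 if mad == 0 else float("nan"), 1.0 if mad == 0 else float("nan")
    return SurvivalComparison(table, mad, stat, p)


def plate_capacity(total_wells: int, replicates: int, control_wells: int = 0) -> int:
    """Number of compounds a screening plate accommodates.

    ``floor((total_wells - control_wells) / replicates)``: triplicates of 32
    compounds fit a 96-well plate, triplicates of 128 a 384-well plate.
    """
    if replicates < 1:
        raise UsageError("replicates must be a positive integer")
    if control_wells < 0:
        raise UsageError("control_wells must be non-negative")
    if control_wells >= total_wells:
        raise UsageError("control_wells must be fewer than total_wells")
    return (int(total_wells) - int(control_wells)) // int(replicates)
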