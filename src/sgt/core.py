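"""The Start Growth Time statistic and its relative-quantification calculus.

The SGT of a well is the time its culture takes to reach a preset OD600
threshold (0.15 by default, configurable up to 0.2). Because a growing
culture's time-to-threshold is linear in the log of its starting inoculum,
differences of SGTs encode log2 ratios of viable-cell counts, exactly as Ct
differences do in qPCR:

    dSGT  = SGT_treated - SGT_normalizer          (hours)
    ddSGT = dSGT_sample - dSGT_calibrator         (hours or doublings)
    fold  = 2 ** -ddSGT,  log2 fold = -ddSGT

Two exponentiation modes are offered. ``"paper"`` exponentiates ddSGT in
hours verbatim; ``"doublings"`` first divides by the culture's doubling time,
which makes ``fold`` a true cell-count ratio under exponential growth. The
mode is always recorded in the result.

Censoring: a well that never reaches the threshold within the observation
window carries its last read time as a lower bound and a ``censored`` flag.
Censored values propagate through the calculus as flagged, non-numeric
results — they are never silently dropped or turned into numbers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .exceptions import EstimationError, UsageError, ValidationError
from .plate_io import GrowthCurve, PlateMap

__all__ = [
    "SGTResult",
    "ReplicateStats",
    "DeltaSGT",
    "DeltaDeltaResult",
    "DEFAULT_THRESHOLD",
    "compute_sgt",
    "aggregate_replicates",
    "delta_sgt",
    "delta_delta_sgt",
    "estimate_doubling_time",
]

#: Default OD600 threshold: the low end of the 0.15-0.2 range, slightly above
#: typical plate-reader background at the start of log phase.
DEFAULT_THRESHOLD = 0.15


@dataclass(frozen=True)
class SGTResult:
    """Time-to-threshold for one well.

    When ``censored`` is True the culture never reached the threshold and
    ``sgt_hours`` holds the last observed time — a lower bound, not an SGT.
    """

    well_id: str
    sgt_hours: float
    threshold: float
    censored: bool = False
    interpolated: bool = False


@dataclass(frozen=True)
class ReplicateStats:
    """Aggregate of replicate SGTs within one replicate group."""

    group: str
    mean: float
    sd: float  # NaN when n < 2 (a single well cannot estimate spread)
    n: int
    n_censored: int = 0

    @property
    def censored(self) -> bool:
        return self.n == 0


@dataclass(frozen=True)
class DeltaSGT:
    """SGT_treated - SGT_normalizer for one sample, sd by quadrature."""

    sample_id: str
    value: float
    sd: float
    n_treated: int
    n_normalizer: int
    censored: bool = False


@dataclass(frozen=True)
class DeltaDeltaResult:
    """ddSGT of a sample against the calibrator, with fold change.

    ``ddsgt`` is in hours in ``"paper"`` mode and in doublings in
    ``"doublings"`` mode; ``sd`` is on the same scale. Always
    ``log2_fold == -ddsgt`` and ``fold == 2 ** log2_fold``.
    """

    sample_id: str
    calibrator_id: str
    ddsgt: float
    log2_fold: float
    fold: float
    sd: float
    mode: str
    doubling_time_hours: float | None = None
    censored: bool = False

    @property
    def sd_fold(self) -> float:
        """Delta-method sd of the fold change: fold * ln2 * sd(ddSGT)."""
        return self.fold * math.log(2.0) * self.sd


def _moving_median3(x: np.ndarray) -> np.ndarray:
    out = x.copy()
    if len(x) >= 3:
        out[1:-1] = np.median(np.lib.stride_tricks.sliding_window_view(x, 3), axis=1)
    return out


def compute_sgt(
    curve: GrowthCurve,
    threshold: float = DEFAULT_THRESHOLD,
    consecutive: int = 2,
    smooth: bool = False,
) -> SGTResult:
    """Find the time a curve first reaches the OD threshold.

    The crossing index is the first ``i`` with ``od[i] >= threshold`` whose
    next ``consecutive - 1`` readings are also at or above the threshold
    (a run truncated by the end of the series counts); this resists isolated
    noise spikes. The reported SGT is linearly interpolated between the reads
    bracketing the crossing, so it is finer than the read cadence. If the
    first reading is already at the threshold the SGT is the first read time;
    if the threshold is never reached the result is censored at the last
    read time.

    Parameters
    ----------
    curve : GrowthCurve
    threshold : float
        OD600 threshold, > 0. The 0.15-0.2 range is conventional.
    consecutive : int
        Number of consecutive supra-threshold reads required to confirm a
        crossing, >= 1.
    smooth : bool
        Apply a window-3 moving median to the ODs before thresholding.
    """
    if not threshold > 0:
        raise UsageError(f"threshold must be positive, got {threshold}")
    if consecutive < 1:
        raise UsageError(f"consecutive must be >= 1, got {consecutive}")
    if len(curve) < 2:
        raise ValidationError(f"well {curve.well_id}: need >= 2 points to compute SGT")

    t = curve.times
    od = _moving_median3(curve.ods) if smooth else curve.ods
    above = od >= threshold

    crossing = None
    for i in np.flatnonzero(above):
        run = above[i : i + consecutive]
        if run.all():  # run may be clipped by the series end
            crossing = int(i)
            break
    if crossing is None:
        return SGTResult(curve.well_id, float(t[-1]), threshold, censored=True)
    if crossing == 0:
        return SGTResult(curve.well_id, float(t[0]), threshold)

    t0, t1 = t[crossing - 1], t[crossing]
    od0, od1 = od[crossing - 1], od[crossing]
    if od1 == od0:  # flat segment at the threshold: take the confirming read
        sgt = float(t1)
    else:
        sgt = float(t0 + (threshold - od0) * (t1 - t0) / (od1 - od0))
    return SGTResult(curve.well_id, sgt, threshold, interpolated=True)


def aggregate_replicates(
    results: Sequence[SGTResult], plate_map: PlateMap
) -> dict[str, ReplicateStats]:
    """Aggregate per-well SGTs into replicate-group means.

    The group key is the plate map's ``replicate_group`` when present,
    otherwise ``"<sample_id>:<role>"``. Censored wells are counted and
    excluded from the mean with a warning; a group whose members are all
    censored is reported censored (``n == 0``). The sd uses the n-1
    denominator and is NaN for single-member groups.
    """
    grouped: dict[str, list[SGTResult]] = {}
    for r in results:
        if r.well_id not in plate_map:
            raise ValidationError(f"well {r.well_id} not present in plate map")
        entry = plate_map[r.well_id]
        key = entry.replicate_group or f"{entry.sample_id}:{entry.role}"
        grouped.setdefault(key, []).append(r)

    out: dict[str, ReplicateStats] = {}
    for key, members in grouped.items():
        values = [m.sgt_hours for m in members if not m.censored]
        n_censored = sum(m.censored for m in members)
        if n_censored and values:
            warnings.warn(
                f"group {key}: {n_censored} censored well(s) excluded from the mean",
                stacklevel=2,
            )
        if not values:
            last = max(m.sgt_hours for m in members)
            out[key] = ReplicateStats(key, float(last), float("nan"), 0, n_censored)
            continue
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if len(values) >= 2 else float("nan")
        out[key] = ReplicateStats(key, mean, sd, len(values), n_censored)
    return out


def _combine_sd(a: float, b: float) -> float:
    return math.hypot(a, b)


def delta_sgt(
    treated: ReplicateStats, normalizer: ReplicateStats, sample_id: str
) -> DeltaSGT:
    """SGT difference between a sample's treated and normalizer arms.

    The sd combines the two arms in quadrature (the qPCR ddCt convention).
    If either arm is censored the result is flagged and non-numeric.
    """
    if treated.censored or normalizer.censored:
        return DeltaSGT(
            sample_id, float("nan"), float("nan"), treated.n, normalizer.n, censored=True
        )
    return DeltaSGT(
        sample_id,
        treated.mean - normalizer.mean,
        _combine_sd(treated.sd, normalizer.sd),
        treated.n,
        normalizer.n,
    )


def delta_delta_sgt(
    sample: DeltaSGT,
    calibrator: DeltaSGT,
    mode: str = "paper",
    doubling_time_hours: float | None = None,
) -> DeltaDeltaResult:
    """Relative survival of a sample against the calibrator.

    ``mode="paper"`` exponentiates the hour-valued ddSGT directly
    (``fold = 2 ** -ddSGT``). ``mode="doublings"`` divides ddSGT by the
    doubling time first, so the fold is a genuine cell-count ratio under
    exponential growth; it requires ``doubling_time_hours``.
    """
    if mode not in {"paper", "doublings"}:
        raise UsageError(f"unknown mode {mode!r}; expected 'paper' or 'doublings'")
    td: float | None = None
    if mode == "doublings":
        if doubling_time_hours is None or not doubling_time_hours > 0:
            raise UsageError("doublings mode requires doubling_time_hours > 0")
        td = float(doubling_time_hours)

    if sample.censored or calibrator.censored:
        nan = float("nan")
        return DeltaDeltaResult(
            sample.sample_id, calibrator.sample_id, nan, nan, nan, nan,
            mode, td, censored=True,
        )

    dd = sample.value - calibrator.value
    sd = _combine_sd(sample.sd, calibrator.sd)
    if mode == "doublings":
        dd /= td
        sd /= td
    return DeltaDeltaResult(
        sample.sample_id,
        calibrator.sample_id,
        dd,
        -dd + 0.0,  # avoid IEEE negative zero in reports
        2.0 ** (-dd),
        sd,
        mode,
        td,
    )


def estimate_doubling_time(
    curve: GrowthCurve, window: tuple[float, float] | None = None
) -> float:
    """Doubling time from a log-linear fit over the exponential OD window.

    Ordinary least squares of ln(OD) on time restricted to readings with
    OD inside ``window`` (default ``[0.15, 0.6]``, i.e. threshold to 4x
    threshold, where growth is reliably exponential and well above
    background); returns ``ln 2 / slope`` in hours.
    """
    if window is None:
        window = (DEFAULT_THRESHOLD, 4.0 * DEFAULT_THRESHOLD)
    lo, hi = window
    if not (0 < lo < hi):
        raise UsageError(f"window must satisfy 0 < lo < hi, got {window}")
    mask = (curve.ods >= lo) & (curve.ods <= hi)
    if int(mask.sum()) < 3:
        raise EstimationError(
            f"well {curve.well_id}: fewer than 3 readings with OD in "
            f"[{lo}, {hi}]; cannot estimate doubling time"
        )
    fit = _stats.linregress(curve.times[mask], np.log(curve.ods[mask]))
    if not fit.slope > 0:
        raise EstimationError(
            f"well {curve.well_id}: non-positive growth slope in window"
        )
    return math.log(2.0) / fit.slope
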