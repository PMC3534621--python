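"""Synthetic plate-reader experiments with known ground truth.

Cultures grow logistically from a known inoculum: with rate r = ln2/td and
carrying capacity K,

    N(t) = n0                                   for t < lag
    N(t) = K n0 e^{r t'} / (K + n0 (e^{r t'} - 1)),  t' = t - lag,

which reduces to pure exponential growth in the K -> infinity limit used by
the closed-form oracles. The reader converts cells to absorbance linearly,
OD = od_background + od_per_cell * N, multiplied by lognormal noise of a
given CV and perturbed by additive Gaussian read noise, sampled every
``read_interval_hours`` (15 min by default).

Defaults place OD 2.0 at ~4.07e9 cells/mL, the plate-reader regime where an
OD600 of 0.15-0.2 sits just above background at the start of log phase.

Inoculum realisation: dilution-series wells below 1000 cells/mL draw their
true per-mL count from a Poisson law (the dominant error source at low
inocula); persister wells whose expected surviving count in the well volume
falls below ~1 cell draw a Poisson count in the well and may come up sterile.

Every generator takes its seed from :class:`SimulationParams`; identical
parameters and seed give bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .plate_io import GrowthCurve, PlateMap, PlateMapEntry

__all__ = [
    "SimulationParams",
    "KillParams",
    "SampleSpec",
    "simulate_growth",
    "simulate_dilution_series",
    "simulate_persister_assay",
    "well_names",
]

#: OD600 of 2.0 corresponds to ~4.07e9 cells/mL in the calibrated regime.
DEFAULT_OD_PER_CELL = 2.0 / 4.07e9
#: Per-mL concentration below which inocula are Poisson-realised.
POISSON_CUTOFF = 1000.0
#: Microplate well volume used for sterile-well draws, mL.
WELL_VOLUME_ML = 0.2


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters for one growth condition.

    Attributes
    ----------
    n0 : float
        Initial viable cells/mL, > 0.
    doubling_time_hours : float
        Exponential-phase doubling time td; growth rate is ln2/td.
    carrying_capacity : float
        Logistic ceiling K, cells/mL (stationary phase ~ OD 2 by default).
    od_per_cell : float
        Absorbance per cell/mL; default calibrated so OD 2.0 ~ 4.07e9 cells/mL.
    od_background : float
        Medium/plate absorbance floor added to every read.
    noise_multiplicative_cv : float
        CV of the lognormal factor applied to each read (0 disables).
    noise_additive_sd : float
        SD of additive Gaussian read noise in OD units (0 disables).
    lag_hours : float
        Dormancy before growth resumes; cells persist but do not divide.
    read_interval_hours : float
        Plate-reader cadence; 0.25 h = one read every 15 min.
    duration_hours : float
        Total observation window.
    seed : int
        Mandatory RNG seed; there is no hidden global randomness.
    """

    seed: int
    n0: float = 1e6
    doubling_time_hours: float = 0.5
    carrying_capacity: float = 4.07e9
    od_per_cell: float = DEFAULT_OD_PER_CELL
    od_background: float = 0.05
    noise_multiplicative_cv: float = 0.05
    noise_additive_sd: float = 0.005
    lag_hours: float = 0.0
    read_interval_hours: float = 0.25
    duration_hours: float = 24.0

    def __post_init__(self) -> None:
        if not self.n0 > 0:
            raise ValidationError("n0 must be positive")
        if not self.doubling_time_hours > 0:
            raise ValidationError("doubling_time_hours must be positive")
        if self.n0 > self.carrying_capacity:
            raise ValidationError("n0 cannot exceed carrying_capacity")
        if not self.od_per_cell > 0:
            raise ValidationError("od_per_cell must be positive")
        if self.od_background < 0 or self.noise_multiplicative_cv < 0 \
                or self.noise_additive_sd < 0 or self.lag_hours < 0:
            raise ValidationError("noise, background and lag must be non-negative")
        if not self.read_interval_hours > 0:
            raise ValidationError("read_interval_hours must be positive")
        if self.duration_hours < self.read_interval_hours:
            raise ValidationError("duration_hours must cover at least one interval")


@dataclass(frozen=True)
class KillParams:
    """Outcome of a bactericidal antibiotic exposure.

    ``persister_fraction`` is the surviving fraction f in (0, 1]; surviving
    count before regrowth is n0 * f. ``awakening_delay_hours`` is the extra
    dormancy of survivors before regrowth — a known bias source, since slow
    awakening inflates SGT and mimics fewer survivors.
    """

    persister_fraction: float = 1e-3
    awakening_delay_hours: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.persister_fraction <= 1.0:
            raise ValidationError("persister_fraction must be in (0, 1]")
        if self.awakening_delay_hours < 0:
            raise ValidationError("awakening_delay_hours must be >= 0")


@dataclass(frozen=True)
class SampleSpec:
    """One sample in a persister assay; fraction overrides the assay default."""

    sample_id: str
    persister_fraction: float | None = None


def well_names(n: int, plate: int = 96) -> list[str]:
    """Row-major well coordinates (A1, A2, ...) for a 96- or 384-well plate."""
    cols = 12 if plate == 96 else 24
    rows = "ABCDEFGHIJKLMNOP"
    names = [f"{rows[i // cols]}{i % cols + 1}" for i in range(n)]
    if n > (8 if plate == 96 else 16) * cols:
        raise ValidationError(f"{n} wells exceed a {plate}-well plate")
    return names


def _grid(params: SimulationParams) -> np.ndarray:
    n = int(math.floor(params.duration_hours / params.read_interval_hours)) + 1
    return np.arange(n) * params.read_interval_hours


def _true_counts(params: SimulationParams, n0: float, lag: float,
                 t: np.ndarray) -> np.ndarray:
    """Logistic trajectory; dormant (constant n0) during the lag."""
    if n0 == 0:
        return np.zeros_like(t)
    K = params.carrying_capacity
    r = math.log(2.0) / params.doubling_time_hours
    tp = np.clip(t - lag, 0.0, None)
    with np.errstate(over="ignore"):
        e = np.exp(r * tp)
        n = K * n0 * e / (K + n0 * (e - 1.0))
    return np.where(np.isfinite(n), n, K)


def _read_od(params: SimulationParams, counts: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    od = params.od_background + params.od_per_cell * counts
    cv = params.noise_multiplicative_cv
    if cv > 0:
        sigma = math.sqrt(math.log1p(cv * cv))
        od = od * rng.lognormal(-0.5 * sigma * sigma, sigma, size=od.shape)
    if params.noise_additive_sd > 0:
        od = od + rng.normal(0.0, params.noise_additive_sd, size=od.shape)
    return od


def _realize_per_ml(n0: float, rng: np.random.Generator) -> float:
    """Poisson-sample a per-mL inoculum when it is small enough to be granular."""
    if n0 < POISSON_CUTOFF:
        return float(rng.poisson(n0))
    return n0


def simulate_growth(
    params: SimulationParams,
    well_id: str = "A1",
    poisson_inoculum: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[GrowthCurve, np.ndarray]:
    """Simulate one well; returns the curve and the true cell-count trajectory.

    With ``poisson_inoculum`` the per-mL inoculum is Poisson-realised below
    1000 cells/mL before growth, as in a physical dilution.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t = _grid(params)
    n0 = _realize_per_ml(params.n0, rng) if poisson_inoculum else params.n0
    counts = _true_counts(params, n0, params.lag_hours, t)
    ods = _read_od(params, counts, rng)
    return GrowthCurve(well_id, t, ods), counts


def simulate_dilution_series(
    params: SimulationParams,
    fold: float = 10.0,
    steps: int = 8,
) -> tuple[list[GrowthCurve], pd.DataFrame]:
    """Serial dilution of one culture across a plate row with recorded truth.

    Well k = 0..steps-1 is inoculated at ``n0 / fold**k``; wells below 1000
    cells/mL Poisson-realise their integer per-mL inoculum. Noise draws are
    independent per well. Returns the curves and a truth table with columns
    ``well``, ``nominal_n0``, ``true_n0``.
    """
    if steps < 2:
        raise ValidationError("a dilution series needs >= 2 steps")
    rng = np.random.default_rng(params.seed)
    lowest = params.n0 / fold ** (steps - 1)
    if lowest < 1.0:
        warnings.warn(
            f"lowest dilution at {lowest:.3g} cells/mL is below one cell/mL; "
            "wells in this regime are frequently empty",
            stacklevel=2,
        )
    names = well_names(steps)
    t = _grid(params)
    curves, rows = [], []
    for k, well in enumerate(names):
        nominal = params.n0 / fold ** k
        true_n0 = _realize_per_ml(nominal, rng)
        counts = _true_counts(params, true_n0, params.lag_hours, t)
        curves.append(GrowthCurve(well, t, _read_od(params, counts, rng)))
        rows.append((well, nominal, true_n0))
    truth = pd.DataFrame(rows, columns=["well", "nominal_n0", "true_n0"])
    return curves, truth


def simulate_persister_assay(
    params: SimulationParams,
    kill: KillParams,
    samples: Sequence[SampleSpec | str],
    dilution_factor: float = 500.0,
    replicates: int = 3,
    well_volume_ml: float = WELL_VOLUME_ML,
) -> tuple[list[GrowthCurve], PlateMap, pd.DataFrame]:
    """Simulate an antibiotic-kill experiment with paired normalizers.

    For each sample, ``replicates`` normalizer wells regrow from
    ``n0 / dilution_factor`` (the untreated aliquot) and ``replicates``
    treated wells regrow from ``n0 * f / dilution_factor`` after the
    awakening delay, where f is the sample's persister fraction. Treated
    wells whose expected surviving count in the well volume is granular
    draw a Poisson count and may be sterile (flat at background).

    Returns the curves, a matching :class:`PlateMap` and a truth table with
    per-well true inocula and per-sample true surviving fractions.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    specs = [s if isinstance(s, SampleSpec) else SampleSpec(str(s)) for s in samples]
    if len({s.sample_id for s in specs}) != len(specs):
        raise ValidationError("duplicate sample_id in persister assay")
    rng = np.random.default_rng(params.seed)
    t = _grid(params)

    names = iter(well_names(2 * replicates * len(specs)))
    curves: list[GrowthCurve] = []
    entries: list[PlateMapEntry] = []
    rows = []
    for spec in specs:
        f = spec.persister_fraction if spec.persister_fraction is not None \
            else kill.persister_fraction
        if not 0.0 < f <= 1.0:
            raise ValidationError(f"sample {spec.sample_id}: fraction must be in (0, 1]")
        arms = (
            ("normalizer", params.n0 / dilution_factor, 0.0),
            ("treated", params.n0 * f / dilution_factor, kill.awakening_delay_hours),
        )
        for role, conc, lag in arms:
            for _ in range(replicates):
                well = next(names)
                if conc < POISSON_CUTOFF:
                    count = rng.poisson(conc * well_volume_ml)
                    true_conc = count / well_volume_ml
                else:
                    true_conc = conc
                counts = _true_counts(params, true_conc, lag, t)
                curves.append(GrowthCurve(well, t, _read_od(params, counts, rng)))
                entries.append(PlateMapEntry(well, spec.sample_id, role))
                rows.append(
                    (well, spec.sample_id, role, conc, true_conc, f, true_conc == 0.0)
                )
    truth = pd.DataFrame(
        rows,
        columns=["well", "sample_id", "role", "expected_n0", "true_n0",
                 "persister_fraction", "sterile"],
    )
    return curves, PlateMap.from_entries(entries), truth
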