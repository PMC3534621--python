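"""Reading, validating and writing microplate kinetic data and plate maps.

Kinetic OD600 exports come in two delimited-text dialects:

* ``long`` — columns exactly ``well,time,od``, one row per reading;
* ``wide`` — a leading time column followed by one column per well.

Times are converted to hours internally (the unit every downstream quantity
is reported in). A plate map assigns each well a sample, a role (``treated``,
``normalizer``, ``blank`` or ``calibration_point``) and optionally a replicate
group, a known CFU/mL (calibration points only) and a compound label.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError, UsageError, ValidationError

__all__ = [
    "GrowthCurve",
    "PlateMapEntry",
    "PlateMap",
    "ROLES",
    "read_kinetic_table",
    "write_kinetic_table",
    "read_plate_map",
    "apply_blank_correction",
]

ROLES = frozenset({"treated", "normalizer", "blank", "calibration_point"})

_TIME_FACTORS = {"hours": 1.0, "minutes": 1.0 / 60.0, "seconds": 1.0 / 3600.0}


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 time series.

    Parameters
    ----------
    well_id : str
        Plate coordinate, e.g. ``"A1"`` .. ``"P24"``.
    times : ndarray
        Reading times in hours, strictly increasing, length >= 2.
    ods : ndarray
        OD600 absorbance values, same length as ``times``, all finite.
    blank_corrected : bool
        Whether per-timepoint blank subtraction has been applied.
    """

    well_id: str
    times: np.ndarray
    ods: np.ndarray
    blank_corrected: bool = False

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ods = np.asarray(self.ods, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ods", ods)
        if times.ndim != 1 or ods.ndim != 1 or len(times) != len(ods):
            raise ValidationError(
                f"well {self.well_id}: times and ods must be 1-D and equal length"
            )
        if len(times) < 2:
            raise ValidationError(f"well {self.well_id}: need at least 2 readings")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(ods)):
            raise ValidationError(f"well {self.well_id}: non-finite reading")
        if not np.all(np.diff(times) > 0):
            raise ValidationError(
                f"well {self.well_id}: times must be strictly increasing "
                "(duplicate or out-of-order timepoints)"
            )

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class PlateMapEntry:
    well_id: str
    sample_id: str
    role: str
    replicate_group: str | None = None
    known_cfu_per_ml: float | None = None
    compound: str | None = None

    def __post_init__(self) -> None:
        role = str(self.role).strip().lower()
        object.__setattr__(self, "role", role)
        if role not in ROLES:
            raise ValidationError(
                f"well {self.well_id}: unknown role {role!r}; expected one of {sorted(ROLES)}"
            )
        if role == "calibration_point":
            if self.known_cfu_per_ml is None:
                raise ValidationError(
                    f"well {self.well_id}: calibration_point requires known_cfu_per_ml"
                )
            if not self.known_cfu_per_ml > 0:
                raise ValidationError(
                    f"well {self.well_id}: known_cfu_per_ml must be positive"
                )
        elif self.known_cfu_per_ml is not None:
            raise ValidationError(
                f"well {self.well_id}: known_cfu_per_ml only allowed on "
                f"calibration_point wells, not role {role!r}"
            )


@dataclass
class PlateMap:
    """Mapping of wells to samples and experimental roles."""

    entries: dict[str, PlateMapEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for well_id, entry in self.entries.items():
            if entry.well_id != well_id:
                raise ValidationError(
                    f"plate map key {well_id!r} disagrees with entry well {entry.well_id!r}"
                )

    def __getitem__(self, well_id: str) -> PlateMapEntry:
        return self.entries[well_id]

    def __contains__(self, well_id: str) -> bool:
        return well_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def wells_with_role(self, role: str) -> list[str]:
        role = role.strip().lower()
        return [w for w, e in self.entries.items() if e.role == role]

    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries.values():
            seen.setdefault(e.sample_id)
        return list(seen)

    @classmethod
    def from_entries(cls, entries: Iterable[PlateMapEntry]) -> "PlateMap":
        table: dict[str, PlateMapEntry] = {}
        for e in entries:
            if e.well_id in table:
                raise ValidationError(f"duplicate well {e.well_id} in plate map")
            table[e.well_id] = e
        return cls(table)


def _read_delimited(source, sep: str | None) -> pd.DataFrame:
    """Read a CSV/TSV, autodetecting the delimiter from the extension."""
    if sep is None:
        name = getattr(source, "name", source)
        sep = "\t" if str(name).endswith((".tsv", ".txt")) else ","
    try:
        return pd.read_csv(source, sep=sep, keep_default_na=False, dtype=str,
                           skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed delimited file: {exc}") from exc


def _numeric_column(df: pd.DataFrame, col: str, what: str) -> np.ndarray:
    values = pd.to_numeric(df[col].str.strip(), errors="coerce")
    bad = values.isna()
    if bad.any():
        # +2: one for the header row, one for 1-based numbering
        line = int(bad.idxmax()) + 2
        raise ParseError(
            f"line {line}: cannot parse {what} value {df[col].iloc[bad.idxmax()]!r}"
        )
    # re-parse through float(): correctly-rounded, so written reprs round-trip
    return np.array([float(v) for v in df[col].str.strip()], dtype=float)


def read_kinetic_table(
    source: str | Path | io.TextIOBase,
    layout: str = "long",
    time_unit: str = "hours",
    sep: str | None = None,
) -> list[GrowthCurve]:
    """Read a kinetic plate-reader export into one :class:`GrowthCurve` per well.

    Parameters
    ----------
    source : path or open text stream
    layout : {"long", "wide"}
        ``long`` expects columns exactly ``well,time,od``; ``wide`` expects a
        leading time column followed by one column per well.
    time_unit : {"hours", "minutes", "seconds"}
        Unit of the time column; converted to hours on read.
    sep : str, optional
        Field delimiter; autodetected from the file extension when omitted
        (``.tsv``/``.txt`` -> tab, otherwise comma).
    """
    if time_unit not in _TIME_FACTORS:
        raise UsageError(
            f"unknown time_unit {time_unit!r}; expected hours, minutes or seconds"
        )
    if layout not in {"long", "wide"}:
        raise UsageError(f"unknown layout {layout!r}; expected 'long' or 'wide'")
    factor = _TIME_FACTORS[time_unit]
    df = _read_delimited(source, sep)

    if layout == "long":
        expected = ["well", "time", "od"]
        if list(df.columns) != expected:
            raise ParseError(
                f"long layout requires columns exactly {expected}, got {list(df.columns)}"
            )
        times = _numeric_column(df, "time", "time") * factor
        ods = _numeric_column(df, "od", "od")
        wells = df["well"].str.strip()
        curves = []
        for well, idx in wells.groupby(wells, sort=False).groups.items():
            t = times[idx]
            o = ods[idx]
            order = np.argsort(t, kind="stable")
            t, o = t[order], o[order]
            if np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"well {well}: duplicate or non-increasing timepoints"
                )
            curves.append(GrowthCurve(str(well), t, o))
        return curves

    # wide layout: first column is time, remaining columns are wells
    if df.shape[1] < 2:
        raise ParseError("wide layout requires a time column plus >= 1 well column")
    time_col = df.columns[0]
    times = _numeric_column(df, time_col, "time") * factor
    order = np.argsort(times, kind="stable")
    times = times[order]
    if np.any(np.diff(times) <= 0):
        raise ValidationError("duplicate or non-increasing timepoints in time column")
    curves = []
    for col in df.columns[1:]:
        ods = _numeric_column(df, col, f"od ({col})")[order]
        curves.append(GrowthCurve(str(col).strip(), times, ods))
    return curves


def write_kinetic_table(curves: Sequence[GrowthCurve], path: str | Path) -> None:
    """Write curves as a long-layout CSV (``well,time,od``, hours), full precision."""
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.ods):
            rows.append((c.well_id, repr(float(t)), repr(float(od))))
    pd.DataFrame(rows, columns=["well", "time", "od"]).to_csv(path, index=False)


def read_plate_map(source: str | Path | io.TextIOBase, sep: str | None = None) -> PlateMap:
    """Read and validate a plate-map CSV.

    Required columns: ``well``, ``sample_id``, ``role``. Optional:
    ``replicate_group``, ``known_cfu_per_ml``, ``compound``. Roles are
    normalized case-insensitively.
    """
    df = _read_delimited(source, sep)
    required = {"well", "sample_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"plate map missing required columns: {sorted(missing)}")

    entries = []
    for i, row in df.iterrows():
        line = int(i) + 2
        cfu: float | None = None
        if "known_cfu_per_ml" in df.columns and str(row["known_cfu_per_ml"]).strip():
            raw = str(row["known_cfu_per_ml"]).strip()
            try:
                cfu = float(raw)
            except ValueError:
                raise ParseError(f"line {line}: cannot parse known_cfu_per_ml {raw!r}")
        rep = None
        if "replicate_group" in df.columns and str(row["replicate_group"]).strip():
            rep = str(row["replicate_group"]).strip()
        compound = None
        if "compound" in df.columns and str(row["compound"]).strip():
            compound = str(row["compound"]).strip()
        entries.append(
            PlateMapEntry(
                well_id=str(row["well"]).strip(),
                sample_id=str(row["sample_id"]).strip(),
                role=str(row["role"]),
                replicate_group=rep,
                known_cfu_per_ml=cfu,
                compound=compound,
            )
        )
    return PlateMap.from_entries(entries)


def apply_blank_correction(
    curves: Sequence[GrowthCurve], plate_map: PlateMap
) -> list[GrowthCurve]:
    """Subtract the per-timepoint median of blank wells from every non-blank well.

    If the plate map defines no blank wells the input is returned unchanged.
    Values are not clipped at zero. Blank wells themselves pass through
    untouched. Correcting an already-corrected curve raises, so the operation
    cannot silently be applied twice.
    """
    blanks = [c for c in curves if c.well_id in plate_map
              and plate_map[c.well_id].role == "blank"]
    if not blanks:
        return list(curves)

    ref = blanks[0].times
    for b in blanks[1:]:
        if len(b.times) != len(ref) or not np.allclose(b.times, ref):
            raise ValidationError(
                f"blank wells have mismatched time grids ({blanks[0].well_id} vs {b.well_id})"
            )
    blank_median = np.median(np.vstack([b.ods for b in blanks]), axis=0)

    out = []
    for c in curves:
        if c.well_id in plate_map and plate_map[c.well_id].role == "blank":
            out.append(c)
            continue
        if c.blank_corrected:
            raise ValidationError(
                f"well {c.well_id} is already blank-corrected; refusing to correct twice"
            )
        if len(c.times) != len(ref) or not np.allclose(c.times, ref):
            raise ValidationError(
                f"well {c.well_id}: time grid differs from blank wells; cannot subtract"
            )
        out.append(replace(c, ods=c.ods - blank_median, blank_corrected=True))
    return out
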