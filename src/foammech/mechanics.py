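"""Bioreactor trace I/O and force/displacement -> stress/strain conversion.

Sign convention: compression positive throughout — compressive force,
displacement into the specimen, stress and strain are all reported as
positive numbers.  Strain is engineering strain referenced to the specimen
thickness measured at the preload contact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import ProtocolSpec

__all__ = [
    "TimeSeriesRecord",
    "SpecimenGeometry",
    "StressStrainTrace",
    "read_trace",
    "write_trace",
    "determine_thickness",
    "to_stress_strain",
    "label_segments",
    "write_stress_strain",
    "read_stress_strain",
]

DEFAULT_COLUMNS = {"time": "time_s", "force": "force_N", "displacement": "displacement_mm"}


@dataclass
class TimeSeriesRecord:
    """Raw bioreactor signal: time (s), force (N), displacement (mm)."""

    time: np.ndarray
    force: np.ndarray
    displacement: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        n = self.time.size
        if n < 2 or self.force.size != n or self.displacement.size != n:
            raise ValueError("time/force/displacement must have equal length >= 2")
        for name, arr in (("time", self.time), ("force", self.force),
                          ("displacement", self.displacement)):
            if not np.all(np.isfinite(arr)):
                row = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise ValueError(f"non-finite value in column '{name}' at row {row}")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            row = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise ValueError(f"time not strictly increasing at row {row}")

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass
class SpecimenGeometry:
    """Cylindrical specimen geometry: 10 mm rounds by default."""

    diameter: float = 10.0  # mm
    thickness: float | None = None  # mm

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.thickness is not None and self.thickness <= 0:
            raise ValueError("thickness must be positive")

    @property
    def cross_section_area(self) -> float:
        """Cross-sectional area in mm^2 (pi d^2 / 4)."""
        return math.pi * self.diameter**2 / 4.0


@dataclass
class StressStrainTrace:
    """Time-stamped stress/strain signal with protocol segment labels."""

    time: np.ndarray
    stress: np.ndarray  # Pa, compression positive
    strain: np.ndarray  # engineering strain, compression positive
    segment_labels: np.ndarray  # per-sample string tags

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        self.segment_labels = np.asarray(self.segment_labels, dtype=object)
        n = self.time.size
        if not (self.stress.size == self.strain.size == self.segment_labels.size == n):
            raise ValueError("all trace columns must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.strain < -1e-12):
            raise ValueError("strain must be non-negative (compression positive)")

    def __len__(self) -> int:
        return int(self.time.size)

    def mask(self, label_prefix: str) -> np.ndarray:
        """Boolean mask of samples whose label starts with *label_prefix*."""
        return np.array([str(s).startswith(label_prefix) for s in self.segment_labels])

    def segment(self, label_prefix: str) -> "StressStrainTrace":
        m = self.mask(label_prefix)
        if not m.any():
            raise ValueError(f"no samples labelled '{label_prefix}'")
        return StressStrainTrace(self.time[m], self.stress[m], self.strain[m],
                                 self.segment_labels[m])


# ----------------------------------------------------------------------
# delimited-text I/O
# ----------------------------------------------------------------------

def read_trace(path: str | Path, column_mapping: dict[str, str] | None = None,
               ) -> TimeSeriesRecord:
    """Read a delimited bioreactor trace into a validated record.

    ``column_mapping`` maps the logical names ``time``/``force``/
    ``displacement`` onto header names in the file; by default the
    simulator's own header (``time_s,force_N,displacement_mm``) is used.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_mapping:
        cols.update(column_mapping)
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns {missing} in {path}")
    for logical, name in cols.items():
        series = pd.to_numeric(df[name], errors="coerce")
        if series.isna().any():
            row = int(series.isna().idxmax())
            raise ValueError(f"non-numeric cell in column '{name}' at row {row}")
        df[name] = series
    return TimeSeriesRecord(df[cols["time"]].to_numpy(),
                            df[cols["force"]].to_numpy(),
                            df[cols["displacement"]].to_numpy())


def write_trace(record: TimeSeriesRecord, path: str | Path,
                stress: np.ndarray | None = None,
                strain: np.ndarray | None = None) -> None:
    """Write a record as delimited text (optionally with stress/strain)."""
    data = {"time_s": record.time, "force_N": record.force,
            "displacement_mm": record.displacement}
    if stress is not None:
        data["stress_Pa"] = np.asarray(stress, dtype=float)
    if strain is not None:
        data["strain"] = np.asarray(strain, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def write_stress_strain(trace: StressStrainTrace, path: str | Path) -> None:
    pd.DataFrame({
        "time_s": trace.time, "stress_Pa": trace.stress,
        "strain": trace.strain, "segment": trace.segment_labels,
    }).to_csv(path, index=False, float_format="%.12g")


def read_stress_strain(path: str | Path) -> StressStrainTrace:
    df = pd.read_csv(path)
    return StressStrainTrace(df["time_s"].to_numpy(), df["stress_Pa"].to_numpy(),
                             df["strain"].to_numpy(), df["segment"].to_numpy(dtype=object))


# ----------------------------------------------------------------------
# thickness from the preload contact
# ----------------------------------------------------------------------

def determine_thickness(record: TimeSeriesRecord,
                        initial_gap: float,
                        preload_window: tuple[float, float] = (0.02, 0.03),
                        ) -> tuple[float, float]:
    """Specimen thickness from the first preload-window force crossing.

    The actuator approaches the specimen; the platen gap at the instant the
    force first enters ``preload_window`` (N) is taken as the specimen
    thickness.  ``initial_gap`` is the platen gap (mm) at displacement 0,
    so gap(t) = initial_gap - displacement(t).

    Returns ``(thickness_mm, contact_index)`` where ``contact_index`` is a
    (possibly fractional) sample index: fractional when the force jumps over
    the window between consecutive samples and linear interpolation is used.
    """
    lo, hi = preload_window
    if not (0 < lo <= hi):
        raise ValueError(f"invalid preload window [{lo}, {hi}]")
    f = record.force
    if np.nanmax(f) < lo:
        raise ValueError("no contact: force never reaches the preload window")
    inside = (f >= lo) & (f <= hi)
    first_inside = int(np.argmax(inside)) if inside.any() else None
    first_above = int(np.argmax(f > hi)) if (f > hi).any() else None
    if first_inside is not None and (first_above is None or first_inside < first_above):
        idx = float(first_inside)
        gap = initial_gap - record.displacement[first_inside]
    else:
        # force jumped across the window between two samples: interpolate
        j = first_above
        i = j - 1
        warnings.warn("force jumped over the preload window; interpolating "
                      "the crossing", stacklevel=2)
        frac = (lo - f[i]) / (f[j] - f[i])
        idx = i + float(frac)
        disp = record.displacement[i] + frac * (record.displacement[j] - record.displacement[i])
        gap = initial_gap - disp
    if gap <= 0:
        raise ValueError("non-positive thickness at contact; check initial_gap")
    return float(gap), idx


# ----------------------------------------------------------------------
# stress/strain conversion and segment labelling
# ----------------------------------------------------------------------

def label_segments(time: np.ndarray, protocol: ProtocolSpec,
                   t0: float | None = None) -> np.ndarray:
    """Per-sample protocol labels by aligning the known schedule to time.

    ``t0`` is the protocol start time; defaults to the first sample.  Samples
    past the end of the schedule keep the final (dynamic) label.
    """
    time = np.asarray(time, dtype=float)
    if t0 is None:
        t0 = float(time[0])
    rel = time - t0
    labels = np.empty(time.size, dtype=object)
    sched = protocol.segment_schedule()
    labels[:] = sched[-1][0]
    for name, a, b in sched:
        m = (rel >= a - 1e-12) & (rel < b - 1e-12)
        labels[m] = name
    labels[rel < sched[0][1]] = sched[0][0]
    return labels


def to_stress_strain(record: TimeSeriesRecord, geometry: SpecimenGeometry,
                     protocol: ProtocolSpec | None = None,
                     contact_displacement: float = 0.0,
                     ) -> StressStrainTrace:
    """Engineering stress/strain from force/displacement.

    stress = force / cross-section area (Pa); strain = compressive
    displacement past the contact datum divided by the contact thickness.
    Segments are labelled from the protocol schedule when one is given.
    """
    if geometry.thickness is None or geometry.thickness <= 0:
        raise ValueError("geometry thickness must be set (see determine_thickness)")
    area_m2 = geometry.cross_section_area * 1e-6  # mm^2 -> m^2
    stress = record.force / area_m2
    strain = (record.displacement - contact_displacement) / geometry.thickness
    strain = np.clip(strain, 0.0, None)
    if np.any(strain > 1.0):
        raise ValueError("strain exceeds 1; check thickness/displacement units")
    if protocol is not None:
        labels = label_segments(record.time, protocol)
    else:
        labels = np.full(record.time.size, "unlabelled", dtype=object)
    return StressStrainTrace(record.time, stress, strain, labels)
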