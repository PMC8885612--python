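"""Reading and writing resuscitation case directories.

A *case* is a directory of CSV time series exported from a defibrillator
record, following the layout of the CPRDAT open data set: continuous
channels (``Accelerometer.csv`` at 250 Hz in device-internal units,
``ShockElectrodes.csv`` at 250 Hz in mV, ``Capnography.csv`` at 125 Hz in
mmHg), patient-state annotations (``PhysioStatus.csv`` with Arrest and
ROSC/Termination time points), and start/stop markers of chest-compression
periods, either manually annotated (``Ann_CC-periods.csv``) or produced by
the detector (``Alg_CC-periods.csv``).  All time stamps are seconds elapsed
since the defibrillator was switched on and are carried through unchanged —
nothing is re-based, re-ordered or resampled on the way in or out.

The CSV dialect used when writing is comma-separated, dot-decimal, UTF-8,
one header line.  When reading, the header line is optional and column
*positions* (not names) are authoritative, so externally produced case
files with differing labels parse without a mapping step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ccperiods")

ACCEL_FILE = "Accelerometer.csv"
ECG_FILE = "ShockElectrodes.csv"
CAPNO_FILE = "Capnography.csv"
PHYSIO_FILE = "PhysioStatus.csv"
ANN_FILE = "Ann_CC-periods.csv"
ALG_FILE = "Alg_CC-periods.csv"
DEFIB_FILE = "Defibrillations.csv"

ACCEL_FS = 250.0
ECG_FS = 250.0
CAPNO_FS = 125.0

ARREST = "Arrest"
ROSC_TERMINATION = "ROSC/Termination"

#: Tolerated relative deviation of the inferred sample rate from nominal.
RATE_TOL = 0.01


class CaseFormatError(ValueError):
    """A case file violates the expected layout or an invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniformTrace:
    """One uniformly sampled channel.

    Parameters
    ----------
    t
        Time stamps in seconds since device power-on, strictly increasing.
    v
        Channel values (internal units, mV or mmHg depending on channel).
    fs_nominal
        Nominal sample rate in Hz.  The rate inferred from ``t`` must agree
        within 1 %.
    """

    t: np.ndarray
    v: np.ndarray
    fs_nominal: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise CaseFormatError("time and value arrays must be 1-D and equal length")
        if len(t) < 2:
            raise CaseFormatError("trace needs at least two samples")
        if not np.all(np.isfinite(t)):
            raise CaseFormatError("non-finite timestamps")
        if np.any(np.diff(t) <= 0):
            raise CaseFormatError("non-monotone timestamps")
        if not (self.fs_nominal > 0):
            raise CaseFormatError("fs_nominal must be positive")
        if abs(self.fs * self.fs_nominal**-1 - 1.0) > RATE_TOL:
            raise CaseFormatError(
                f"sample-rate mismatch: inferred {self.fs:.3f} Hz vs "
                f"nominal {self.fs_nominal:g} Hz"
            )

    @property
    def fs(self) -> float:
        """Sample rate inferred from the median time step, in Hz."""
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        """Record span ``t[-1] - t[0]`` in seconds."""
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class Segmentation:
    """Ordered, pairwise-disjoint chest-compression periods.

    Each period is a ``(start, stop)`` pair in seconds since device
    power-on with ``start < stop``; periods are sorted by start time and do
    not overlap.
    """

    periods: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        norm = tuple((float(a), float(b)) for a, b in self.periods)
        object.__setattr__(self, "periods", norm)
        prev_stop = -math.inf
        for start, stop in norm:
            if not (math.isfinite(start) and math.isfinite(stop)):
                raise CaseFormatError("invalid segmentation: non-finite boundary")
            if not start < stop:
                raise CaseFormatError("invalid segmentation: start >= stop")
            if start < prev_stop:
                raise CaseFormatError("invalid segmentation: overlapping or unsorted periods")
            prev_stop = stop

    def __len__(self) -> int:
        return len(self.periods)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(self.periods)

    @property
    def starts(self) -> np.ndarray:
        return np.array([p[0] for p in self.periods])

    @property
    def stops(self) -> np.ndarray:
        return np.array([p[1] for p in self.periods])

    @property
    def total_time(self) -> float:
        """Summed compression time in seconds."""
        return float(sum(b - a for a, b in self.periods))


@dataclass(frozen=True)
class CaseRecord:
    """All channels, side data and annotations of one resuscitation case."""

    accel: UniformTrace
    ecg_pads: Optional[UniformTrace] = None
    capno: Optional[UniformTrace] = None
    #: ``(label, time_s)`` pairs; labels are ``Arrest`` / ``ROSC/Termination``.
    physio: tuple[tuple[str, float], ...] = ()
    ann_periods: Optional[Segmentation] = None
    #: ``(time_s, energy_J, impedance_Ohm)`` per delivered shock.
    defib_events: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        _check_physio_pairing(self.physio)
        if self.ann_periods is not None and len(self.ann_periods):
            t0, t1 = self.accel.t[0], self.accel.t[-1]
            if self.ann_periods.starts[0] < t0 - 1e-9 or self.ann_periods.stops[-1] > t1 + 1e-9:
                raise CaseFormatError("annotated periods outside accelerometer time range")

    def physio_window(self) -> tuple[float, float]:
        """(Arrest, ROSC/Termination) times of the first annotated episode."""
        arrest = next(t for lab, t in self.physio if lab == ARREST)
        end = next(t for lab, t in self.physio if lab == ROSC_TERMINATION)
        return arrest, end


def _check_physio_pairing(physio: Sequence[tuple[str, float]]) -> None:
    """Every Arrest must precede its paired ROSC/Termination time."""
    pending_arrest: float | None = None
    for label, t in physio:
        if label == ARREST:
            pending_arrest = float(t)
        elif label == ROSC_TERMINATION:
            if pending_arrest is not None and not (pending_arrest < float(t)):
                raise CaseFormatError("Arrest time does not precede ROSC/Termination")
            pending_arrest = None
        else:
            raise CaseFormatError(f"unknown physio label {label!r}")


# ---------------------------------------------------------------------------
# Low-level CSV helpers
# ---------------------------------------------------------------------------

def _floatable(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _has_header(path: Path) -> bool:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
    if not first:
        return False
    return not all(_floatable(tok) for tok in first.split(","))


def _read_numeric_csv(path: Path, ncols: int) -> np.ndarray:
    """Read the first ``ncols`` columns of a CSV as floats.

    Raises :class:`CaseFormatError` naming the first offending data row
    (1-based, header excluded) when a cell does not parse as a number.
    """
    header = 0 if _has_header(path) else None
    df = pd.read_csv(path, header=header, dtype=str, skip_blank_lines=True)
    if df.shape[1] < ncols:
        raise CaseFormatError(f"{path.name}: expected at least {ncols} columns")
    if df.empty:
        return np.empty((0, ncols))
    block = df.iloc[:, :ncols].apply(lambda c: pd.to_numeric(c, errors="coerce"))
    arr = block.to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(arr).all(axis=1))[0]
    if bad.size:
        raise CaseFormatError(f"{path.name}: unparseable numeric cell in data row {bad[0] + 1}")
    return arr


def _read_channel(path: Path, fs_nominal: float) -> UniformTrace:
    arr = _read_numeric_csv(path, 2)
    if len(arr) < 2:
        raise CaseFormatError(f"{path.name}: channel needs at least two samples")
    return UniformTrace(arr[:, 0], arr[:, 1], fs_nominal)


# ---------------------------------------------------------------------------
# Segmentation files
# ---------------------------------------------------------------------------

def write_segmentation(seg: Segmentation, path: Path | str) -> None:
    """Write period boundaries as a two-column CSV (``start_s,stop_s``).

    Values carry six decimal places, so a read/write cycle is the identity
    well below the 1 ms level.
    """
    if not isinstance(seg, Segmentation):
        seg = Segmentation(tuple(seg))  # validates; raises "invalid segmentation"
    df = pd.DataFrame(seg.periods, columns=["start_s", "stop_s"])
    df.to_csv(path, index=False, float_format="%.6f")


def read_segmentation(path: Path | str) -> Segmentation:
    """Read a period-boundary CSV written by :func:`write_segmentation`.

    Also accepts header-less two-column files.  Any row with stop ≤ start,
    or rows out of order / overlapping, is rejected.
    """
    arr = _read_numeric_csv(Path(path), 2)
    return Segmentation(tuple((row[0], row[1]) for row in arr))


# ---------------------------------------------------------------------------
# Case directories
# ---------------------------------------------------------------------------

def read_case(case_dir: Path | str) -> CaseRecord:
    """Read one case directory into a validated :class:`CaseRecord`.

    ``Accelerometer.csv`` is mandatory; every other file is optional and,
    when missing, yields an absent field plus a logged warning.  Channels
    whose inferred sample rate deviates more than 1 % from the nominal rate
    of the file are rejected.
    """
    case_dir = Path(case_dir)
    accel_path = case_dir / ACCEL_FILE
    if not accel_path.exists():
        raise CaseFormatError(f"no accelerometer channel in {case_dir}")
    accel = _read_channel(accel_path, ACCEL_FS)

    def optional_channel(name: str, fs: float) -> Optional[UniformTrace]:
        p = case_dir / name
        if not p.exists():
            logger.warning("%s: optional channel %s missing", case_dir.name, name)
            return None
        return _read_channel(p, fs)

    ecg = optional_channel(ECG_FILE, ECG_FS)
    capno = optional_channel(CAPNO_FILE, CAPNO_FS)

    physio: tuple[tuple[str, float], ...] = ()
    physio_path = case_dir / PHYSIO_FILE
    if physio_path.exists():
        header = 0 if _has_header(physio_path) else None
        df = pd.read_csv(physio_path, header=header, dtype=str)
        rows = []
        for i, row in enumerate(df.itertuples(index=False)):
            label = str(row[0]).strip()
            try:
                t = float(row[1])
            except (TypeError, ValueError):
                raise CaseFormatError(
                    f"{PHYSIO_FILE}: unparseable numeric cell in data row {i + 1}"
                ) from None
            rows.append((label, t))
        physio = tuple(rows)
    else:
        logger.warning("%s: %s missing", case_dir.name, PHYSIO_FILE)

    ann = None
    ann_path = case_dir / ANN_FILE
    if ann_path.exists():
        ann = read_segmentation(ann_path)
    else:
        logger.warning("%s: %s missing", case_dir.name, ANN_FILE)

    defib: tuple[tuple[float, float, float], ...] = ()
    defib_path = case_dir / DEFIB_FILE
    if defib_path.exists():
        arr = _read_numeric_csv(defib_path, 3)
        defib = tuple((r[0], r[1], r[2]) for r in arr)

    return CaseRecord(
        accel=accel, ecg_pads=ecg, capno=capno,
        physio=physio, ann_periods=ann, defib_events=defib,
    )


def write_case(record: CaseRecord, case_dir: Path | str) -> Path:
    """Write a :class:`CaseRecord` as a case directory (see module docstring)."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)

    def write_channel(trace: Optional[UniformTrace], name: str) -> None:
        if trace is None:
            return
        df = pd.DataFrame({"time_s": trace.t, "value": trace.v})
        df.to_csv(case_dir / name, index=False, float_format="%.6f")

    write_channel(record.accel, ACCEL_FILE)
    write_channel(record.ecg_pads, ECG_FILE)
    write_channel(record.capno, CAPNO_FILE)

    if record.physio:
        pd.DataFrame(record.physio, columns=["label", "time_s"]).to_csv(
            case_dir / PHYSIO_FILE, index=False, float_format="%.6f"
        )
    if record.ann_periods is not None:
        write_segmentation(record.ann_periods, case_dir / ANN_FILE)
    if record.defib_events:
        pd.DataFrame(
            record.defib_events, columns=["time_s", "energy_j", "impedance_ohm"]
        ).to_csv(case_dir / DEFIB_FILE, index=False, float_format="%.6f")
    return case_dir
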