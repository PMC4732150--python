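"""Acceleration traces, movement records, and the record-extraction pipeline.

A *record* is the unit of analysis for fall detection here: a 3-axis x
51-sample window of acceleration (1 s at 50 Hz), in units of g, centered on
a signal-magnitude peak of at least 1.5 g.  Continuous pocket-worn
smartphone monitoring is reduced to records by resampling the raw trace to
a uniform 50 Hz grid, locating magnitude peaks above the 1.5 g gate with a
6 s separation rule, and cropping a one-second window around each peak.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.signal import find_peaks

ADL = "ADL"
FALL = "FALL"
LABELS = (ADL, FALL)

#: canonical sampling rate after interpolation, Hz
RATE_HZ = 50.0
#: samples per record (both endpoints of the 1 s window included)
RECORD_LEN = 51
#: 0-based index of the magnitude peak within a record
CENTER_INDEX = 25
#: magnitude gate below which peaks are disregarded, g
PEAK_THRESHOLD_G = 1.5
#: minimum separation between retained peaks, s
PEAK_SEPARATION_S = 6.0
#: accelerometer full-scale range of the emulated low-end phone, g
DEVICE_RANGE_G = 2.0


class InvalidTraceError(ValueError):
    """Raised when a trace violates the RawTrace contract."""


class NonUniformTraceError(ValueError):
    """Raised when an operation requires a uniformly sampled trace."""


class WindowOutOfBoundsError(ValueError):
    """Raised when a record window would extend past the trace ends."""


class RecordParseError(ValueError):
    """Raised on malformed record or trace CSV content."""


@dataclass(eq=False)
class RawTrace:
    """Continuous triaxial acceleration signal for one subject.

    times are seconds and must be strictly increasing; accel is an (n, 3)
    array of (x, y, z) in g.  ``device_range`` emulates the sensor's
    full-scale range; clipping to it is applied at resampling.
    """

    subject_id: str
    times: np.ndarray
    accel: np.ndarray
    device_range: float = DEVICE_RANGE_G

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise InvalidTraceError(
                f"trace {self.subject_id!r} needs >= 2 samples, "
                f"got {self.times.size}"
            )
        if self.accel.shape != (self.times.size, 3):
            raise InvalidTraceError(
                f"accel shape {self.accel.shape} does not match "
                f"({self.times.size}, 3)"
            )
        if not np.all(np.diff(self.times) > 0):
            raise InvalidTraceError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        dt = np.diff(self.times)
        return bool(np.allclose(dt, dt[0], rtol=rtol, atol=1e-9))

    @property
    def rate(self) -> float:
        """Sampling rate in Hz; only meaningful for uniform traces."""
        if not self.is_uniform():
            raise NonUniformTraceError(
                "trace is not uniformly sampled; call resample_trace first"
            )
        return 1.0 / float(self.times[1] - self.times[0])


@dataclass(eq=False)
class Record:
    """One labeled movement event: 3 axes x 51 samples centered on the peak."""

    subject_id: str
    label: str
    samples: np.ndarray  # shape (3, RECORD_LEN), g
    center_index: int = CENTER_INDEX
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.samples.shape != (3, RECORD_LEN):
            raise ValueError(
                f"record samples must be (3, {RECORD_LEN}), "
                f"got {self.samples.shape}"
            )

    def magnitude(self) -> np.ndarray:
        return magnitude_series(self)

    def center_magnitude(self) -> float:
        return float(np.linalg.norm(self.samples[:, self.center_index]))

    def flat(self) -> np.ndarray:
        """All 153 values as one vector (axis-major, time within axis)."""
        return self.samples.reshape(-1)


@dataclass
class Dataset:
    """A labeled collection of records with a subject index."""

    records: list[Record]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Record]:
        return iter(self.records)

    @property
    def subject_index(self) -> dict[str, list[int]]:
        index: dict[str, list[int]] = {}
        for pos, rec in enumerate(self.records):
            index.setdefault(rec.subject_id, []).append(pos)
        return index

    def subjects(self) -> list[str]:
        return sorted(self.subject_index)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def select(
        self, subject_id: str | None = None, label: str | None = None,
        exclude_subject: str | None = None,
    ) -> "Dataset":
        kept = [
            r
            for r in self.records
            if (subject_id is None or r.subject_id == subject_id)
            and (label is None or r.label == label)
            and (exclude_subject is None or r.subject_id != exclude_subject)
        ]
        return Dataset(kept)

    def counts(self) -> dict[str, int]:
        out = {ADL: 0, FALL: 0}
        for r in self.records:
            out[r.label] += 1
        return out


def magnitude_series(obj: RawTrace | Record | np.ndarray) -> np.ndarray:
    """Euclidean norm of the (x, y, z) triple at every sample."""
    if isinstance(obj, RawTrace):
        arr = obj.accel  # (n, 3)
        return np.linalg.norm(arr, axis=1)
    if isinstance(obj, Record):
        return np.linalg.norm(obj.samples, axis=0)
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2 or 3 not in arr.shape:
        raise ValueError("expected an (n, 3) or (3, n) array")
    axis = 1 if arr.shape[1] == 3 else 0
    return np.linalg.norm(arr, axis=axis)


def resample_trace(trace: RawTrace, rate: float = RATE_HZ) -> RawTrace:
    """Linearly interpolate each axis onto a uniform grid and clip.

    The grid spans [first, last] input time at the requested rate; values
    are clipped to +/- ``trace.device_range``, emulating the sensor range.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    t0, t1 = float(trace.times[0]), float(trace.times[-1])
    n = int(np.floor((t1 - t0) * rate)) + 1
    grid = t0 + np.arange(n) / rate
    out = np.empty((n, 3))
    for ax in range(3):
        out[:, ax] = np.interp(grid, trace.times, trace.accel[:, ax])
    np.clip(out, -trace.device_range, trace.device_range, out=out)
    return RawTrace(trace.subject_id, grid, out, trace.device_range)


def detect_peaks(
    trace: RawTrace,
    threshold: float = PEAK_THRESHOLD_G,
    min_separation: float = PEAK_SEPARATION_S,
) -> np.ndarray:
    """Indices of magnitude peaks >= threshold, separated by >= min_separation.

    Candidates are local maxima of the magnitude series.  Conflicts within
    the separation window are resolved greedily by descending magnitude, so
    the largest peak in any crowded stretch survives.
    """
    if not trace.is_uniform():
        raise NonUniformTraceError(
            "detect_peaks requires uniform sampling; call resample_trace first"
        )
    mag = magnitude_series(trace)
    candidates, _ = find_peaks(mag, height=threshold)
    if candidates.size == 0:
        return np.array([], dtype=int)
    sep = int(round(min_separation * trace.rate))
    # greedy: biggest magnitude first, index as deterministic tie-break
    order = np.lexsort((candidates, -mag[candidates]))
    kept: list[int] = []
    for idx in candidates[order]:
        if all(abs(int(idx) - k) >= sep for k in kept):
            kept.append(int(idx))
    return np.array(sorted(kept), dtype=int)


def extract_record(
    trace: RawTrace,
    peak_index: int,
    label: str,
    half_window: float = 0.5,
) -> Record:
    """Crop the 1 s window around a peak into a Record.

    Requires a uniformly sampled trace (nominally 50 Hz).  The peak must
    sit at least ``half_window`` seconds from both trace ends.
    """
    if not trace.is_uniform():
        raise NonUniformTraceError("extract_record requires uniform sampling")
    half = int(round(half_window * trace.rate))
    if peak_index < half or peak_index + half >= len(trace):
        raise WindowOutOfBoundsError(
            f"peak at sample {peak_index} is closer than {half} samples "
            f"to a trace edge (trace length {len(trace)})"
        )
    window = trace.accel[peak_index - half : peak_index + half + 1]
    meta = {
        "trace_id": trace.subject_id,
        "peak_time": float(trace.times[peak_index]),
    }
    return Record(trace.subject_id, label, window.T.copy(), half, meta)


def extract_records(
    trace: RawTrace,
    label: str,
    threshold: float = PEAK_THRESHOLD_G,
    min_separation: float = PEAK_SEPARATION_S,
) -> list[Record]:
    """Full extraction pipeline: detect peaks, crop windows, apply the gates.

    Peaks too close to the trace edges are skipped.  A cropped window is
    kept only if its center magnitude is the window maximum and >= the
    threshold, so every returned record satisfies the record invariants.
    """
    out: list[Record] = []
    for idx in detect_peaks(trace, threshold, min_separation):
        try:
            rec = extract_record(trace, int(idx), label)
        except WindowOutOfBoundsError:
            continue
        mag = rec.magnitude()
        center = mag[rec.center_index]
        if center < threshold or center < mag.max() - 1e-12:
            continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# CSV plumbing

_AXES = ("ax", "ay", "az")


def _record_header() -> list[str]:
    cols = ["subject_id", "label"]
    for ax in _AXES:
        cols.extend(f"{ax}_{i:02d}" for i in range(RECORD_LEN))
    return cols


def write_records_csv(dataset: Dataset, path) -> None:
    """Write records with >= 9 significant digits per value."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_record_header())
        for rec in dataset.records:
            row = [rec.subject_id, rec.label]
            row.extend(format(v, ".10g") for v in rec.flat())
            writer.writerow(row)


def read_records_csv(path) -> Dataset:
    """Read a record CSV (header + 153 value columns per row)."""
    expected = _record_header()
    records: list[Record] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RecordParseError(f"{path}: empty file, expected a header")
        if len(header) != len(expected):
            raise RecordParseError(
                f"{path}: header has {len(header)} columns, "
                f"expected {len(expected)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected):
                raise RecordParseError(
                    f"{path}: row {lineno} has {len(row)} columns, "
                    f"expected {len(expected)}"
                )
            subject_id, label = row[0], row[1]
            if label not in LABELS:
                raise RecordParseError(
                    f"{path}: row {lineno} has unknown label {label!r}"
                )
            try:
                values = np.array([float(v) for v in row[2:]])
            except ValueError as exc:
                raise RecordParseError(
                    f"{path}: row {lineno}: non-numeric value ({exc})"
                ) from None
            records.append(
                Record(subject_id, label, values.reshape(3, RECORD_LEN))
            )
    return Dataset(records)


def write_trace_csv(trace: RawTrace, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_s", "ax_g", "ay_g", "az_g"])
        for t, (x, y, z) in zip(trace.times, trace.accel):
            writer.writerow(
                [format(t, ".10g")] + [format(v, ".10g") for v in (x, y, z)]
            )


def read_trace_csv(path, subject_id: str | None = None,
                   device_range: float = DEVICE_RANGE_G) -> RawTrace:
    """Read a `t_s,ax_g,ay_g,az_g` trace; subject id defaults to the stem."""
    import os

    if subject_id is None:
        subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    times: list[float] = []
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip() for c in header] != [
            "t_s", "ax_g", "ay_g", "az_g",
        ]:
            raise RecordParseError(
                f"{path}: expected header t_s,ax_g,ay_g,az_g, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise RecordParseError(
                    f"{path}: row {lineno} has {len(row)} columns, expected 4"
                )
            try:
                vals = [float(v) for v in row]
            except ValueError as exc:
                raise RecordParseError(
                    f"{path}: row {lineno}: non-numeric value ({exc})"
                ) from None
            times.append(vals[0])
            rows.append(vals[1:])
    return RawTrace(subject_id, np.array(times), np.array(rows), device_range)
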