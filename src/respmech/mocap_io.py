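"""Reading, writing and time-alignment of motion-capture trial data.

The pipeline works on four record kinds: labelled 3D marker trajectories,
force-plate force/moment channels, surface-EMG channels, and movement-cycle
event tables.  Markers are stored in millimetres, forces in newtons, moments
in newton-metres, EMG in millivolts and time in seconds everywhere inside the
package; unit conversion happens only at this boundary.

Two marker dialects are supported:

* a tab-separated text dialect (hand-writable; see :func:`read_markers_tsv`),
* a binary C3D subset (Intel byte order, floating-point samples, 3D points
  plus analog channels) read and written natively.

Gaps in marker tracking are represented as NaN and are never silently
interpolated on read.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MarkerTrajectorySet",
    "ForcePlateRecord",
    "EmgRecord",
    "EventTable",
    "TrialBundle",
    "read_markers",
    "write_markers",
    "read_events",
    "write_events",
    "resample",
    "synchronize",
]

#: Axis convention used throughout: X anteroposterior, Y mediolateral,
#: Z superoinferior (vertical, positive up).
AXES = ("X", "Y", "Z")

#: The eight bilateral lower-limb muscles recorded by the protocol.
MUSCLES = ("GMAX", "GMED", "RF", "VM", "VL", "BF", "MG", "TA")


class ParseError(ValueError):
    """Raised when a marker/event file cannot be parsed; names the offender."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass
class MarkerTrajectorySet:
    """Frame-indexed labelled 3D marker positions.

    Parameters
    ----------
    labels
        Unique marker names, one per trajectory.
    positions
        Array of shape ``(n_frames, n_markers, 3)`` in millimetres.  Missing
        samples are NaN.
    rate
        Sampling frequency in Hz.
    """

    labels: list[str]
    positions: np.ndarray
    rate: float
    axes: tuple[str, str, str] = AXES

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_markers, 3)")
        if len(self.labels) != self.positions.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels but {self.positions.shape[1]} trajectories"
            )
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ParseError(f"duplicate marker labels: {dupes}")
        if not self.rate > 0:
            raise ValueError("rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.rate

    def get(self, label: str) -> np.ndarray:
        """Trajectory of one marker, shape ``(n_frames, 3)``."""
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no marker named {label!r}") from None
        return self.positions[:, i, :]

    def subset(self, labels: Sequence[str]) -> "MarkerTrajectorySet":
        idx = [self.labels.index(l) for l in labels]
        return MarkerTrajectorySet(list(labels), self.positions[:, idx, :], self.rate)


@dataclass
class ForcePlateRecord:
    """Force-plate forces (N) and moments about the plate origin (N·m).

    ``origin_offset`` locates the plate origin in the lab frame, in metres,
    so centre-of-pressure output can be expressed in lab coordinates.
    """

    forces: np.ndarray  # (n, 3) Fx, Fy, Fz
    moments: np.ndarray  # (n, 3) Mx, My, Mz
    rate: float
    origin_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    plate_id: str = "FP1"

    def __post_init__(self) -> None:
        self.forces = np.atleast_2d(np.asarray(self.forces, dtype=float))
        self.moments = np.atleast_2d(np.asarray(self.moments, dtype=float))
        if self.forces.shape != self.moments.shape or self.forces.shape[1] != 3:
            raise ValueError("forces and moments must both be (n, 3)")
        if not self.rate > 0:
            raise ValueError("rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.forces.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.rate


@dataclass
class EmgRecord:
    """Muscle-labelled surface-EMG voltage series in millivolts."""

    channels: dict[str, np.ndarray]
    rate: float
    reference_peak: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {v.shape[0] for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError(f"EMG channels have unequal lengths: {sorted(lengths)}")
        if not self.rate > 0:
            raise ValueError("rate must be > 0")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0] if self.channels else 0

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.rate


@dataclass
class EventTable:
    """Point events and movement-cycle windows for one trial.

    ``cycles`` maps a movement name to a list of ``(start_s, end_s)`` windows;
    windows must be ordered and non-overlapping within a movement.
    """

    events: list[tuple[str, float]] = field(default_factory=list)
    cycles: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for movement, windows in self.cycles.items():
            prev_end = -np.inf
            for start, end in windows:
                if not start < end:
                    raise ValueError(
                        f"cycle of {movement!r} has start {start} >= end {end}"
                    )
                if start < prev_end:
                    raise ValueError(f"cycles of {movement!r} overlap at {start} s")
                prev_end = end

    def all_cycles(self) -> list[tuple[str, int, float, float]]:
        """Flat ``(movement, cycle_index, start, end)`` list."""
        out = []
        for movement, windows in sorted(self.cycles.items()):
            for i, (start, end) in enumerate(windows):
                out.append((movement, i, start, end))
        return out


@dataclass
class TrialBundle:
    """One trial's streams trimmed to a common duration.

    Markers are resampled onto the analysis time base (default 100 Hz, the
    kinematic rate).  Plate and EMG records are kept at their native rates —
    centre-of-pressure and iEMG are computed at full kinetic/EMG bandwidth and
    only their derived series are brought onto the analysis base — but
    :meth:`plate_aligned` / :meth:`emg_aligned` provide resampled copies when
    a common time vector is required.
    """

    markers: MarkerTrajectorySet
    plate: ForcePlateRecord | None
    emg: EmgRecord | None
    events: EventTable
    analysis_rate: float

    @property
    def time(self) -> np.ndarray:
        return self.markers.time

    @property
    def duration(self) -> float:
        return self.markers.duration

    def index_of(self, t: float) -> int:
        """Index of time ``t`` on the analysis base (nearest sample)."""
        return int(round(t * self.analysis_rate))

    def plate_aligned(self) -> ForcePlateRecord | None:
        if self.plate is None:
            return None
        return resample(self.plate, self.analysis_rate)

    def emg_aligned(self) -> EmgRecord | None:
        if self.emg is None:
            return None
        return resample(self.emg, self.analysis_rate)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------
#
# Layout (hand-writable, mirrors common Qualisys text exports):
#
#     FREQUENCY<TAB>100            optional KEY<TAB>VALUE metadata lines
#     Chest_0_0<TAB><TAB><TAB>Chest_0_1...   marker names, one per 3 columns
#     mm<TAB>mm<TAB>mm<TAB>...                units row
#     12.0<TAB>3.5<TAB>900.1<TAB>...          data rows; empty field or nan = gap


def read_markers_tsv(path: str | Path, default_rate: float = 100.0) -> MarkerTrajectorySet:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rate = None
    i = 0
    while i < len(lines):
        fields = lines[i].rstrip("\n").split("\t")
        # metadata lines have a value only in column 2
        if len(fields) >= 2 and fields[0].strip().upper() in ("FREQUENCY", "RATE"):
            try:
                rate = float(fields[1])
            except ValueError:
                raise ParseError(f"{path}: bad rate on line {i + 1}: {fields[1]!r}")
            i += 1
        elif len(fields) >= 2 and fields[0].strip().upper() in ("NO_OF_FRAMES", "NO_OF_MARKERS"):
            i += 1  # tolerated Qualisys metadata, unused
        else:
            break
    if i >= len(lines):
        raise ParseError(f"{path}: no marker-name row found")
    name_fields = lines[i].rstrip("\n").split("\t")
    labels = [name_fields[j].strip() for j in range(0, len(name_fields), 3)]
    labels = [l for l in labels if l]
    if not labels:
        raise ParseError(f"{path}: empty marker-name row (line {i + 1})")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"{path}: duplicate marker labels {dupes} (line {i + 1})")
    i += 1  # units row
    if i >= len(lines):
        raise ParseError(f"{path}: missing units row")
    i += 1
    rows = []
    for lineno, line in enumerate(lines[i:], start=i + 1):
        if not line:  # blank line; a row of empty *fields* is a gap frame
            continue
        fields = line.split("\t")
        if len(fields) < 3 * len(labels):
            fields = fields + [""] * (3 * len(labels) - len(fields))
        try:
            rows.append(
                [float(f) if f.strip() not in ("", "NA") else np.nan
                 for f in fields[: 3 * len(labels)]]
            )
        except ValueError as exc:
            raise ParseError(f"{path}: malformed data on line {lineno}: {exc}")
    positions = np.asarray(rows, dtype=float).reshape(len(rows), len(labels), 3)
    return MarkerTrajectorySet(labels, positions, rate if rate is not None else default_rate)


def write_markers_tsv(markers: MarkerTrajectorySet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"FREQUENCY\t{markers.rate:g}\n")
        fh.write("\t\t\t".join(markers.labels) + "\n")
        fh.write("\t".join(["mm"] * (3 * len(markers.labels))) + "\n")
        flat = markers.positions.reshape(markers.n_frames, -1)
        for row in flat:
            fh.write("\t".join("" if np.isnan(v) else f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# C3D subset
# ---------------------------------------------------------------------------
#
# Only the modern common case is handled: Intel (little-endian) byte order,
# floating-point point and analog samples, one parameter section.  That is
# the subset the package itself writes; files from other processor types are
# rejected with a clear message.

_PROC_INTEL = 84


def _c3d_params(buf: bytes, start_block: int) -> dict[str, dict[str, object]]:
    """Parse the parameter section into {GROUP: {PARAM: value}}."""
    off = (start_block - 1) * 512
    n_param_blocks = buf[off + 2]
    proc = buf[off + 3]
    if proc != _PROC_INTEL:
        raise ParseError(f"unsupported C3D processor type {proc} (only Intel/{_PROC_INTEL})")
    pos = off + 4
    end = off + 512 * n_param_blocks
    groups: dict[int, str] = {}
    params: list[tuple[int, str, object]] = []
    while pos < end:
        nname = struct.unpack_from("b", buf, pos)[0]
        gid = struct.unpack_from("b", buf, pos + 1)[0]
        if nname == 0 or gid == 0:
            break
        name = buf[pos + 2 : pos + 2 + abs(nname)].decode("ascii")
        p = pos + 2 + abs(nname)
        offset = struct.unpack_from("<h", buf, p)[0]
        next_pos = p + offset if offset != 0 else end
        p += 2
        if gid < 0:  # group record
            groups[-gid] = name
        else:  # parameter record
            dtype = struct.unpack_from("b", buf, p)[0]
            ndims = buf[p + 1]
            dims = list(buf[p + 2 : p + 2 + ndims])
            p += 2 + ndims
            count = int(np.prod(dims)) if dims else 1
            if dtype == -1:
                raw = buf[p : p + count]
                if len(dims) <= 1:
                    value: object = raw.decode("ascii").rstrip()
                else:  # array of strings, first dim is string length
                    slen = dims[0]
                    n = count // slen
                    value = [
                        raw[i * slen : (i + 1) * slen].decode("ascii").strip()
                        for i in range(n)
                    ]
            elif dtype == 1:
                value = np.frombuffer(buf, np.int8, count, p)
            elif dtype == 2:
                value = np.frombuffer(buf, "<i2", count, p)
            elif dtype == 4:
                value = np.frombuffer(buf, "<f4", count, p)
            else:
                raise ParseError(f"unknown C3D parameter type {dtype} for {name}")
            if isinstance(value, np.ndarray) and value.size == 1:
                value = value.item()
            params.append((gid, name, value))
        if offset == 0:
            break
        pos = next_pos
    out: dict[str, dict[str, object]] = {g: {} for g in groups.values()}
    for gid, name, value in params:
        out.setdefault(groups.get(gid, f"G{gid}"), {})[name] = value
    return out


def read_c3d(path: str | Path) -> tuple[MarkerTrajectorySet, EmgRecord | None]:
    """Read a C3D file (subset): 3D points and optional analog channels."""
    buf = Path(path).read_bytes()
    if len(buf) < 512 or buf[1] != 0x50:
        raise ParseError(f"{path}: not a C3D file")
    param_block = buf[0]
    n_points = struct.unpack_from("<H", buf, 2)[0]
    analog_per_frame = struct.unpack_from("<H", buf, 4)[0]
    first_frame = struct.unpack_from("<H", buf, 6)[0]
    last_frame = struct.unpack_from("<H", buf, 8)[0]
    point_scale = struct.unpack_from("<f", buf, 12)[0]
    data_block = struct.unpack_from("<H", buf, 16)[0]
    analog_sub = struct.unpack_from("<H", buf, 18)[0]
    point_rate = struct.unpack_from("<f", buf, 20)[0]
    if point_scale >= 0:
        raise ParseError(f"{path}: integer C3D data not supported (scale {point_scale})")
    params = _c3d_params(buf, param_block)
    n_frames = last_frame - first_frame + 1
    n_analog = analog_per_frame // analog_sub if analog_sub else 0
    frame_words = 4 * n_points + analog_per_frame
    data = np.frombuffer(
        buf, "<f4", n_frames * frame_words, (data_block - 1) * 512
    ).reshape(n_frames, frame_words)
    pts = data[:, : 4 * n_points].reshape(n_frames, n_points, 4).astype(float)
    positions = pts[:, :, :3].copy()
    positions[pts[:, :, 3] < 0] = np.nan  # negative residual marks missing
    labels = list(params.get("POINT", {}).get("LABELS", []))[:n_points]
    if len(labels) < n_points:
        labels += [f"M{i}" for i in range(len(labels), n_points)]
    markers = MarkerTrajectorySet(labels, positions, float(point_rate))
    emg = None
    if n_analog:
        analog = (
            data[:, 4 * n_points :]
            .reshape(n_frames, analog_sub, n_analog)
            .reshape(n_frames * analog_sub, n_analog)
        )
        alabels = list(params.get("ANALOG", {}).get("LABELS", []))[:n_analog]
        if len(alabels) < n_analog:
            alabels += [f"A{i}" for i in range(len(alabels), n_analog)]
        emg = EmgRecord(
            {lab: analog[:, i].astype(float) for i, lab in enumerate(alabels)},
            rate=float(point_rate) * analog_sub,
        )
    return markers, emg


def _param_record(gid: int, name: str, dtype: int, dims: list[int], payload: bytes) -> bytes:
    body = struct.pack("bb", dtype, len(dims)) + bytes(dims) + payload + b"\x00"
    rec = struct.pack("bb", len(name), gid) + name.encode("ascii")
    return rec + struct.pack("<h", 2 + len(body)) + body


def _group_record(gid: int, name: str) -> bytes:
    rec = struct.pack("bb", len(name), -gid) + name.encode("ascii")
    return rec + struct.pack("<h", 3) + b"\x00"


def _labels_param(gid: int, name: str, labels: Sequence[str]) -> bytes:
    width = max(4, max((len(l) for l in labels), default=4))
    payload = b"".join(l.ljust(width).encode("ascii") for l in labels)
    return _param_record(gid, name, -1, [width, len(labels)], payload)


def write_c3d(
    markers: MarkerTrajectorySet, path: str | Path, emg: EmgRecord | None = None
) -> None:
    """Write a C3D file (Intel, float) with 3D points and optional analog."""
    n_frames, n_points = markers.n_frames, len(markers.labels)
    if emg is not None and emg.channels:
        sub = emg.rate / markers.rate
        if abs(sub - round(sub)) > 1e-9 or round(sub) < 1:
            raise ValueError("EMG rate must be an integer multiple of the marker rate")
        analog_sub = int(round(sub))
        alabels = list(emg.channels)
        analog = np.stack([emg.channels[l] for l in alabels], axis=1)
        if analog.shape[0] != n_frames * analog_sub:
            raise ValueError("EMG length does not match marker frames × subsampling")
        n_analog = len(alabels)
    else:
        analog_sub, n_analog, alabels, analog = 0, 0, [], None

    recs = b"".join(
        [
            _group_record(1, "POINT"),
            _param_record(1, "USED", 2, [], struct.pack("<h", n_points)),
            _param_record(1, "FRAMES", 2, [], struct.pack("<h", n_frames)),
            _param_record(1, "RATE", 4, [], struct.pack("<f", markers.rate)),
            _param_record(1, "SCALE", 4, [], struct.pack("<f", -1.0)),
            _param_record(1, "UNITS", -1, [4], b"mm  "),
            _labels_param(1, "LABELS", markers.labels),
            _group_record(2, "ANALOG"),
            _param_record(2, "USED", 2, [], struct.pack("<h", n_analog)),
            _param_record(2, "RATE", 4, [], struct.pack("<f", emg.rate if n_analog else 0.0)),
            _param_record(2, "GEN_SCALE", 4, [], struct.pack("<f", 1.0)),
            _labels_param(2, "LABELS", alabels),
        ]
    )
    recs += struct.pack("bb", 0, 0)  # terminator
    n_param_blocks = (4 + len(recs) + 511) // 512
    data_block = 2 + n_param_blocks

    header = bytearray(512)
    struct.pack_into("BB", header, 0, 2, 0x50)
    struct.pack_into("<H", header, 2, n_points)
    struct.pack_into("<H", header, 4, n_analog * analog_sub)
    struct.pack_into("<H", header, 6, 1)
    struct.pack_into("<H", header, 8, n_frames)
    struct.pack_into("<f", header, 12, -1.0)
    struct.pack_into("<H", header, 16, data_block)
    struct.pack_into("<H", header, 18, analog_sub)
    struct.pack_into("<f", header, 20, markers.rate)

    pblock = bytearray(512 * n_param_blocks)
    struct.pack_into("BBBB", pblock, 0, 1, 0x50, n_param_blocks, _PROC_INTEL)
    pblock[4 : 4 + len(recs)] = recs

    frame_words = 4 * n_points + n_analog * analog_sub
    data = np.zeros((n_frames, frame_words), dtype="<f4")
    pts = np.zeros((n_frames, n_points, 4), dtype="<f4")
    pts[:, :, :3] = markers.positions
    missing = np.isnan(markers.positions).any(axis=2)
    pts[:, :, 3] = np.where(missing, -1.0, 0.0)
    pts[:, :, :3][missing] = 0.0
    data[:, : 4 * n_points] = pts.reshape(n_frames, -1)
    if n_analog:
        data[:, 4 * n_points :] = analog.reshape(n_frames, analog_sub * n_analog)
    Path(path).write_bytes(bytes(header) + bytes(pblock) + data.tobytes())


# ---------------------------------------------------------------------------
# dispatching readers / writers
# ---------------------------------------------------------------------------


def read_markers(path: str | Path, dialect: str = "tsv") -> MarkerTrajectorySet:
    """Read marker trajectories from ``path`` under the named dialect.

    ``dialect`` is ``"tsv"`` (text) or ``"c3d"`` (binary).  Positions come
    back in millimetres with the rate declared in the file; gaps stay NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return read_markers_tsv(path)
    if dialect == "c3d":
        return read_c3d(path)[0]
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'c3d'")


def write_markers(markers: MarkerTrajectorySet, path: str | Path, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        write_markers_tsv(markers, path)
    elif dialect == "c3d":
        write_c3d(markers, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'c3d'")


def read_events(path: str | Path) -> EventTable:
    """Read a ``label,time_s`` CSV event table.

    Labels of the form ``<movement>_start`` / ``<movement>_end`` are paired in
    order into movement cycles; other labels become point events.
    """
    import csv

    events: list[tuple[str, float]] = []
    starts: dict[str, list[float]] = {}
    cycles: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != ["label", "time_s"]:
            raise ParseError(f"{path}: expected header 'label,time_s'")
        for row in reader:
            label, t = row["label"].strip(), float(row["time_s"])
            if label.endswith("_start"):
                starts.setdefault(label[: -len("_start")], []).append(t)
            elif label.endswith("_end"):
                movement = label[: -len("_end")]
                pending = starts.get(movement, [])
                if not pending:
                    raise ParseError(f"{path}: '{label}' at {t} s has no matching start")
                cycles.setdefault(movement, []).append((pending.pop(0), t))
            else:
                events.append((label, t))
    dangling = {m: s for m, s in starts.items() if s}
    if dangling:
        raise ParseError(f"{path}: unmatched cycle starts: {dangling}")
    return EventTable(events=events, cycles=cycles)


def write_events(table: EventTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("label,time_s\n")
        rows = [(l, t) for l, t in table.events]
        for movement, windows in table.cycles.items():
            for start, end in windows:
                rows.append((f"{movement}_start", start))
                rows.append((f"{movement}_end", end))
        for label, t in sorted(rows, key=lambda r: r[1]):
            fh.write(f"{label},{t:.6f}\n")


# ---------------------------------------------------------------------------
# resampling and synchronization
# ---------------------------------------------------------------------------


def _resample_array(x: np.ndarray, rate: float, target_rate: float) -> np.ndarray:
    """Linear interpolation of columns onto the target time base.

    Output spans the same duration to within one sample period.  NaN gaps
    propagate to any target sample whose bracketing input interval touches
    a NaN — gaps are preserved, never invented away.
    """
    n = x.shape[0]
    t = np.arange(n) / rate
    n_out = int(np.floor((n - 1) / rate * target_rate + 1e-9)) + 1
    t_new = np.arange(n_out) / target_rate
    flat = x.reshape(n, -1)
    out = np.empty((n_out, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(t_new, t, flat[:, j])
    return out.reshape((n_out,) + x.shape[1:])


def resample(record, target_rate: float):
    """Resample a marker / plate / EMG record onto ``target_rate`` (Hz)."""
    if not target_rate > 0:
        raise ValueError("target_rate must be > 0")
    if isinstance(record, MarkerTrajectorySet):
        return replace(
            record, positions=_resample_array(record.positions, record.rate, target_rate),
            rate=target_rate,
        )
    if isinstance(record, ForcePlateRecord):
        return replace(
            record,
            forces=_resample_array(record.forces, record.rate, target_rate),
            moments=_resample_array(record.moments, record.rate, target_rate),
            rate=target_rate,
        )
    if isinstance(record, EmgRecord):
        return replace(
            record,
            channels={
                k: _resample_array(v[:, None], record.rate, target_rate)[:, 0]
                for k, v in record.channels.items()
            },
            rate=target_rate,
        )
    raise TypeError(f"cannot resample {type(record).__name__}")


def _trim(record, duration: float):
    n_keep = int(np.floor(duration * record.rate + 1e-9)) + 1
    if isinstance(record, MarkerTrajectorySet):
        return replace(record, positions=record.positions[:n_keep])
    if isinstance(record, ForcePlateRecord):
        return replace(record, forces=record.forces[:n_keep], moments=record.moments[:n_keep])
    if isinstance(record, EmgRecord):
        return replace(record, channels={k: v[:n_keep] for k, v in record.channels.items()})
    raise TypeError(type(record).__name__)


def synchronize(
    markers: MarkerTrajectorySet,
    plate: ForcePlateRecord | None = None,
    emg: EmgRecord | None = None,
    events: EventTable | None = None,
    analysis_rate: float = 100.0,
    max_duration_mismatch: float = 0.05,
) -> TrialBundle:
    """Trim streams (all sharing t=0) to a common duration and align markers
    onto the analysis time base.

    Streams whose durations disagree by more than ``max_duration_mismatch``
    (fractional) raise, naming the offenders; smaller mismatches are resolved
    by trimming to the shortest stream.  The output never extrapolates: its
    time range is the intersection of the inputs'.
    """
    streams = {"markers": markers}
    if plate is not None:
        streams["plate"] = plate
    if emg is not None:
        streams["emg"] = emg
    durations = {k: v.duration for k, v in streams.items()}
    dmin, dmax = min(durations.values()), max(durations.values())
    if dmin <= 0:
        raise ValueError("streams must span more than one sample")
    if (dmax - dmin) / dmax > max_duration_mismatch:
        detail = ", ".join(f"{k}={v:.3f}s" for k, v in durations.items())
        raise ValueError(f"stream durations disagree by more than "
                         f"{max_duration_mismatch:.0%}: {detail}")
    aligned_markers = _trim(
        resample(markers, analysis_rate) if markers.rate != analysis_rate else markers,
        dmin,
    )
    return TrialBundle(
        markers=aligned_markers,
        plate=_trim(plate, dmin) if plate is not None else None,
        emg=_trim(emg, dmin) if emg is not None else None,
        events=events if events is not None else EventTable(),
        analysis_rate=analysis_rate,
    )
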