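"""Activity-monitor file I/O, concentration protocols, and trace/protocol alignment.

The locomotor data consumed by this package are beam-break counts per fly per
5-minute bin, as produced by Drosophila activity monitors.  Because vendor
formats vary, the package reads and writes one documented tab-separated
dialect::

    <row index> \\t <date: "D Mon YY"> \\t <time: "HH:MM:SS"> \\t <status> \\t <count ch1> \\t <count ch2> ...

One row per time bin, rows in chronological order.  ``status`` is ``1`` for a
valid reading and ``0`` for a dropped reading; a dropped row marks that bin as
missing for every channel in the file.  Counts are non-negative integers.
Timestamps are converted to zeitgeber time (minutes since lights-on, ZT0) via
a lights-on clock time supplied by the caller.

Concentration protocols describe a stepwise anesthetic titration: an
ascending limb of non-decreasing concentrations followed by a descending limb
of non-increasing concentrations, each step held for a dwell time that is a
whole number of bins, preceded by a drug-free pre-window (>= 15 min) and
followed by a drug-free post-window (default 24 h) used for recovery scoring.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ActivityTrace",
    "ProtocolStep",
    "ConcentrationProtocol",
    "AlignedTrace",
    "MonitorParseError",
    "read_monitor_file",
    "write_monitor_file",
    "align_to_protocol",
    "default_protocol",
    "protocol_from_yaml",
    "protocol_to_yaml",
    "PRE_WINDOW",
    "POST_WINDOW",
]

#: Sentinel step labels used in AlignedTrace.step_index_per_bin.
PRE_WINDOW = -1
POST_WINDOW = -2

_DATE_FMT = "%d %b %y"
_TIME_FMT = "%H:%M:%S"
#: Arbitrary calendar anchor used when writing traces back to the dialect.
_EPOCH_DATE = _dt.date(2000, 1, 1)


class MonitorParseError(ValueError):
    """Raised when a monitor file does not conform to the documented dialect."""


@dataclass
class ActivityTrace:
    """One fly's binned locomotor counts.

    Parameters
    ----------
    fly_id : str
        Identifier for the fly (typically monitor + channel).
    counts : array-like of int
        Beam-break counts per bin, all >= 0.
    genotype : str
        Free-text genotype label carried through to results tables.
    bin_minutes : float
        Bin width in minutes (default 5, the standard monitor resolution).
    start_time : float
        Zeitgeber time of the start of the first bin, in minutes (ZT0 =
        lights-on).  Bins are half-open intervals labeled by their start.
    missing : array-like of bool, optional
        Mask of dropped readings.  Missing bins carry a count of 0 but are
        distinguished from genuine immobility unless the caller opts in to
        treating them as such.
    """

    fly_id: str
    counts: np.ndarray
    genotype: str = ""
    bin_minutes: float = 5.0
    start_time: float = 0.0
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.bin_minutes > 0:
            raise ValueError("bin_minutes must be positive")
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.counts.shape:
                raise ValueError("missing mask must match counts in length")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bin_starts(self) -> np.ndarray:
        """Zeitgeber start time of every bin, in minutes."""
        return self.start_time + self.bin_minutes * np.arange(self.n_bins)

    def has_missing(self) -> bool:
        return self.missing is not None and bool(self.missing.any())


@dataclass(frozen=True)
class ProtocolStep:
    concentration: float  # vol% atm
    dwell_minutes: float
    limb: str  # "ascending" | "descending"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not self.dwell_minutes > 0:
            raise ValueError("dwell_minutes must be positive")
        if self.limb not in ("ascending", "descending"):
            raise ValueError("limb must be 'ascending' or 'descending'")


@dataclass(frozen=True)
class ConcentrationProtocol:
    """Stepwise ascending-then-descending anesthetic titration."""

    steps: tuple[ProtocolStep, ...]
    pre_window_minutes: float = 15.0
    post_window_minutes: float = 1440.0

    def __post_init__(self) -> None:
        steps = tuple(self.steps)
        object.__setattr__(self, "steps", steps)
        if self.pre_window_minutes < 15:
            raise ValueError("pre_window_minutes must be >= 15")
        limbs = [s.limb for s in steps]
        if "ascending" not in limbs or "descending" not in limbs:
            raise ValueError("protocol needs at least one step per limb")
        # Ascending block must precede descending block.
        first_desc = limbs.index("descending")
        if any(l == "ascending" for l in limbs[first_desc:]):
            raise ValueError("ascending steps must all precede descending steps")
        asc = [s.concentration for s in steps if s.limb == "ascending"]
        desc = [s.concentration for s in steps if s.limb == "descending"]
        if any(b < a for a, b in zip(asc, asc[1:])):
            raise ValueError("ascending concentrations must be non-decreasing")
        if any(b > a for a, b in zip(desc, desc[1:])):
            raise ValueError("descending concentrations must be non-increasing")

    @property
    def ascending(self) -> tuple[ProtocolStep, ...]:
        return tuple(s for s in self.steps if s.limb == "ascending")

    @property
    def descending(self) -> tuple[ProtocolStep, ...]:
        return tuple(s for s in self.steps if s.limb == "descending")

    def limb_concentrations(self, limb: str) -> np.ndarray:
        return np.array([s.concentration for s in self.steps if s.limb == limb])

    def total_dwell_minutes(self) -> float:
        return float(sum(s.dwell_minutes for s in self.steps))

    def bins_per_step(self, bin_minutes: float) -> list[int]:
        out = []
        for s in self.steps:
            n, rem = divmod(s.dwell_minutes, bin_minutes)
            if abs(rem) > 1e-9 and abs(rem - bin_minutes) > 1e-9:
                raise ValueError(
                    f"dwell of {s.dwell_minutes} min is not a multiple of the "
                    f"{bin_minutes}-min bin width"
                )
            out.append(int(round(s.dwell_minutes / bin_minutes)))
        return out


def default_protocol() -> ConcentrationProtocol:
    """The package's default isoflurane titration.

    Ascending 0.25 to 2.00 vol% in 0.25 vol% increments, then descending
    1.75 down to 0.00, with 10-minute dwells, a 15-minute drug-free
    pre-window and a 24-hour recovery post-window.
    """
    asc = [ProtocolStep(k * 0.25, 10.0, "ascending") for k in range(1, 9)]
    desc = [ProtocolStep(k * 0.25, 10.0, "descending") for k in range(7, -1, -1)]
    return ConcentrationProtocol(tuple(asc + desc))


@dataclass
class AlignedTrace:
    """An activity trace with every bin labeled by its protocol step.

    ``step_index_per_bin[i]`` is the index into ``protocol.steps`` of bin
    ``i``, or :data:`PRE_WINDOW` / :data:`POST_WINDOW`.
    """

    trace: ActivityTrace
    protocol: ConcentrationProtocol
    step_index_per_bin: np.ndarray = field(repr=False)

    def bins_of_step(self, step_index: int) -> np.ndarray:
        return np.flatnonzero(self.step_index_per_bin == step_index)

    def limb_bins(self, limb: str) -> np.ndarray:
        """Bin indices belonging to the given limb, in chronological order."""
        idx = [
            i
            for i, s in enumerate(self.protocol.steps)
            if s.limb == limb
        ]
        mask = np.isin(self.step_index_per_bin, idx)
        return np.flatnonzero(mask)

    @property
    def pre_bins(self) -> np.ndarray:
        return np.flatnonzero(self.step_index_per_bin == PRE_WINDOW)

    @property
    def post_bins(self) -> np.ndarray:
        return np.flatnonzero(self.step_index_per_bin == POST_WINDOW)

    def to_dataframe(self) -> pd.DataFrame:
        """Export as tidy CSV-ready rows."""
        steps = self.protocol.steps
        conc = [
            steps[i].concentration if i >= 0 else np.nan
            for i in self.step_index_per_bin
        ]
        limb = [
            steps[i].limb if i >= 0 else ("pre" if i == PRE_WINDOW else "post")
            for i in self.step_index_per_bin
        ]
        return pd.DataFrame(
            {
                "fly_id": self.trace.fly_id,
                "bin_start_min": self.trace.bin_starts,
                "count": self.trace.counts,
                "step_concentration": conc,
                "limb": limb,
            }
        )


# ---------------------------------------------------------------------------
# File I/O


def _zt_minutes(date: _dt.date, time: _dt.time, lights_on: _dt.time) -> float:
    """Minutes since lights-on of the first calendar day, may exceed 1440."""
    day_offset = (date - _EPOCH_DATE).days
    mins = (
        time.hour * 60
        + time.minute
        + time.second / 60.0
        - (lights_on.hour * 60 + lights_on.minute)
    )
    return day_offset * 1440.0 + mins


def _parse_lights_on(lights_on: str | float) -> _dt.time:
    if isinstance(lights_on, str):
        h, m = lights_on.split(":")
        return _dt.time(int(h), int(m))
    mins = float(lights_on)
    return _dt.time(int(mins // 60), int(mins % 60))


def read_monitor_file(
    path,
    channel_map: Mapping[int, str] | Sequence[str],
    *,
    lights_on: str | float = "08:00",
    bin_minutes: float = 5.0,
    genotype: str = "",
) -> list[ActivityTrace]:
    """Read a monitor channel file in the documented dialect.

    Parameters
    ----------
    path : path-like
        Tab-separated file, one row per bin (see module docstring).
    channel_map : mapping or sequence
        Either a mapping of 1-based count-column number -> fly_id, or a
        sequence of fly_ids covering the count columns left to right.
    lights_on : "HH:MM" or minutes
        Clock time of lights-on used to convert timestamps to zeitgeber
        minutes.
    """
    lights = _parse_lights_on(lights_on)
    rows: list[tuple[float, int, list[int]]] = []
    n_counts = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise MonitorParseError(
                    f"line {lineno}: expected >= 5 tab-separated fields, got {len(parts)}"
                )
            _, date_s, time_s, status_s = parts[:4]
            try:
                date = _dt.datetime.strptime(date_s.strip(), _DATE_FMT).date()
                time = _dt.datetime.strptime(time_s.strip(), _TIME_FMT).time()
            except ValueError as exc:
                raise MonitorParseError(f"line {lineno}: bad timestamp: {exc}") from exc
            try:
                status = int(status_s)
            except ValueError as exc:
                raise MonitorParseError(
                    f"line {lineno}: non-integer status {status_s!r}"
                ) from exc
            try:
                counts = [int(p) for p in parts[4:]]
            except ValueError as exc:
                raise MonitorParseError(
                    f"line {lineno}: non-integer count: {exc}"
                ) from exc
            if any(c < 0 for c in counts):
                raise MonitorParseError(f"line {lineno}: negative count")
            if n_counts is None:
                n_counts = len(counts)
            elif len(counts) != n_counts:
                raise MonitorParseError(
                    f"line {lineno}: expected {n_counts} count columns, got {len(counts)}"
                )
            rows.append((_zt_minutes(date, time, lights), status, counts))
    if not rows:
        raise MonitorParseError("no data rows")

    if isinstance(channel_map, Mapping):
        items = sorted((int(col), fid) for col, fid in channel_map.items())
    else:
        items = list(enumerate(channel_map, start=1))
    for col, fid in items:
        if not 1 <= col <= n_counts:
            raise LookupError(
                f"channel column {col} (fly {fid!r}) not present: file has "
                f"{n_counts} count columns"
            )

    start = rows[0][0]
    missing = np.array([status != 1 for _, status, _ in rows], dtype=bool)
    count_mat = np.array([c for _, _, c in rows], dtype=np.int64)
    count_mat[missing, :] = 0  # dropped readings carry no counts
    traces = []
    for col, fid in items:
        traces.append(
            ActivityTrace(
                fly_id=fid,
                counts=count_mat[:, col - 1],
                genotype=genotype,
                bin_minutes=bin_minutes,
                start_time=start,
                missing=missing.copy() if missing.any() else None,
            )
        )
    return traces


def write_monitor_file(
    traces: Iterable[ActivityTrace],
    path,
    *,
    lights_on: str | float = "08:00",
) -> None:
    """Write traces back to the documented dialect.

    All traces must share bin width, start time and length.  A bin is written
    with status 0 (dropped) if any trace marks it missing; reading the file
    back reproduces counts, timestamps and missing markers bit-exactly.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to write")
    ref = traces[0]
    for t in traces[1:]:
        if (
            t.n_bins != ref.n_bins
            or t.bin_minutes != ref.bin_minutes
            or t.start_time != ref.start_time
        ):
            raise ValueError("all traces must share the same bin grid")
    lights = _parse_lights_on(lights_on)
    lights_min = lights.hour * 60 + lights.minute

    missing = np.zeros(ref.n_bins, dtype=bool)
    for t in traces:
        if t.missing is not None:
            missing |= t.missing

    with open(path, "w", encoding="utf-8") as fh:
        for i in range(ref.n_bins):
            zt = ref.start_time + i * ref.bin_minutes
            abs_min = zt + lights_min
            day, rem = divmod(abs_min, 1440.0)
            date = _EPOCH_DATE + _dt.timedelta(days=int(day))
            secs = int(round(rem * 60))
            time = _dt.time(secs // 3600, (secs % 3600) // 60, secs % 60)
            fields = [
                str(i + 1),
                date.strftime(_DATE_FMT).lstrip("0"),
                time.strftime(_TIME_FMT),
                "0" if missing[i] else "1",
            ]
            fields += [str(int(t.counts[i])) for t in traces]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Alignment


def align_to_protocol(
    trace: ActivityTrace, protocol: ConcentrationProtocol
) -> AlignedTrace:
    """Label every bin of *trace* with its protocol step.

    The first ``pre_window_minutes`` of the trace are the pre-window, followed
    by the protocol steps in order; every remaining bin is the post-window.
    Raises if the trace is too short to cover pre-window plus all dwells, or
    if a dwell or window is not a whole number of bins.
    """
    bw = trace.bin_minutes
    n_pre, rem = divmod(protocol.pre_window_minutes, bw)
    if rem > 1e-9:
        raise ValueError("pre-window is not a multiple of the bin width")
    n_pre = int(n_pre)
    per_step = protocol.bins_per_step(bw)
    needed = n_pre + sum(per_step)
    if trace.n_bins < needed:
        raise ValueError(
            f"trace has {trace.n_bins} bins but the protocol requires at "
            f"least {needed} (pre-window + dwells)"
        )
    labels = np.full(trace.n_bins, POST_WINDOW, dtype=np.int64)
    labels[:n_pre] = PRE_WINDOW
    pos = n_pre
    for step_idx, nb in enumerate(per_step):
        labels[pos : pos + nb] = step_idx
        pos += nb
    return AlignedTrace(trace=trace, protocol=protocol, step_index_per_bin=labels)


# ---------------------------------------------------------------------------
# YAML config


def protocol_to_yaml(protocol: ConcentrationProtocol, path) -> None:
    doc = {
        "protocol": {
            "pre_window_minutes": protocol.pre_window_minutes,
            "post_window_minutes": protocol.post_window_minutes,
            "steps": [
                {
                    "concentration": float(s.concentration),
                    "dwell_minutes": float(s.dwell_minutes),
                    "limb": str(s.limb),
                }
                for s in protocol.steps
            ],
        }
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def protocol_from_yaml(path) -> ConcentrationProtocol:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    spec = doc["protocol"] if "protocol" in doc else doc
    steps = tuple(
        ProtocolStep(
            concentration=float(s["concentration"]),
            dwell_minutes=float(s["dwell_minutes"]),
            limb=str(s["limb"]),
        )
        for s in spec["steps"]
    )
    return ConcentrationProtocol(
        steps=steps,
        pre_window_minutes=float(spec.get("pre_window_minutes", 15.0)),
        post_window_minutes=float(spec.get("post_window_minutes", 1440.0)),
    )
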