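"""Parsers for the three profiling sources and measurement-table I/O.

Profiling a BLAST run happens at three levels that cross-check each other:

* shell level — the Unix ``time`` command (real / user / sys seconds);
* code level — stopwatch logs emitted by BLAST+'s built-in profiling module
  (label + elapsed seconds per instrumented section);
* system level — ``gprof`` flat profiles (per-function self time, cumulative
  time, call counts).

All parsers are pure text -> records. Measurement tables are TSV/CSV files
with the fixed header ``node_type, database_size, query_size, threads,
component, runtime_seconds, replicate``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .perf_model import Component, MeasurementRecord

__all__ = [
    "TimeResult",
    "GprofFlatEntry",
    "StopwatchEntry",
    "ProfilingParseError",
    "parse_time_output",
    "parse_gprof_flat",
    "parse_blastprof_log",
    "read_measurements",
    "write_measurements",
    "DEFAULT_STOPWATCH_PATTERN",
    "MEASUREMENT_COLUMNS",
]

MEASUREMENT_COLUMNS = (
    "node_type",
    "database_size",
    "query_size",
    "threads",
    "component",
    "runtime_seconds",
    "replicate",
)


class ProfilingParseError(ValueError):
    pass


@dataclass(frozen=True)
class TimeResult:
    """The three measures of ``time(1)``.

    No ``real == user + sys`` constraint is imposed: multithreading makes
    user time exceed real, while I/O waits make real exceed user + sys.
    """

    real_seconds: float
    user_seconds: float
    sys_seconds: float

    def __post_init__(self) -> None:
        for v in (self.real_seconds, self.user_seconds, self.sys_seconds):
            if v < 0:
                raise ValueError("time measures must be non-negative")


@dataclass(frozen=True)
class GprofFlatEntry:
    percent_time: float
    cumulative_seconds: float
    self_seconds: float
    calls: int | None
    function_name: str

    def __post_init__(self) -> None:
        if not 0 <= self.percent_time <= 100:
            raise ValueError("percent_time must be in [0, 100]")


@dataclass(frozen=True)
class StopwatchEntry:
    label: str
    seconds: float

    def __post_init__(self) -> None:
        if self.seconds < 0:
            raise ValueError("seconds must be non-negative")


_MINSEC = re.compile(r"^(\d+)m([\d.]+)s$")


def _parse_duration(token: str, dialect: str) -> float:
    if dialect == "posix_p":
        return float(token)
    m = _MINSEC.match(token)
    if not m:
        raise ProfilingParseError(
            f"cannot parse bash time value {token!r} (expected e.g. '2m15.720s')"
        )
    return int(m.group(1)) * 60 + float(m.group(2))


def parse_time_output(text: str, dialect: str = "posix_p") -> TimeResult:
    """Parse Unix ``time`` output.

    ``posix_p`` expects ``real 135.72`` lines (``time -p``); ``bash_builtin``
    expects ``real\\t2m15.720s`` lines. All three keys must be present.
    """
    if dialect not in ("posix_p", "bash_builtin"):
        raise ProfilingParseError(f"unknown time dialect {dialect!r}")
    values: dict[str, float] = {}
    for line in text.splitlines():
        parts = line.split()
        if len(parts) == 2 and parts[0] in ("real", "user", "sys"):
            values[parts[0]] = _parse_duration(parts[1], dialect)
    for key in ("real", "user", "sys"):
        if key not in values:
            raise ProfilingParseError(f"time output is missing the '{key}' line")
    return TimeResult(values["real"], values["user"], values["sys"])


_GPROF_HEADER = re.compile(r"^\s*%\s+cumulative\s+self", re.IGNORECASE)
# columns: % time, cumulative s, self s, [calls, self/call, total/call,] name
_GPROF_ROW = re.compile(
    r"^\s*([\d.]+)\s+([\d.]+)\s+([\d.]+)\s+(?:(\d+)\s+[\d.]+\s+[\d.]+\s+)?(\S.*?)\s*$"
)


def parse_gprof_flat(text: str) -> list[GprofFlatEntry]:
    """Parse a gprof flat profile into ordered entries.

    Rows without call counts (gprof omits them for functions it could not
    count) are accepted with ``calls=None``. Parsing stops at the first
    blank line after the data rows begin.
    """
    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if _GPROF_HEADER.match(line):
            start = i
            break
    if start is None:
        raise ProfilingParseError("no gprof flat-profile section found")
    entries: list[GprofFlatEntry] = []
    in_rows = False
    for line in lines[start + 1:]:
        if not line.strip():
            if in_rows:
                break
            continue
        if re.match(r"^\s*time\s+seconds", line, re.IGNORECASE):
            continue  # second header line
        m = _GPROF_ROW.match(line)
        if m:
            in_rows = True
            entries.append(
                GprofFlatEntry(
                    percent_time=float(m.group(1)),
                    cumulative_seconds=float(m.group(2)),
                    self_seconds=float(m.group(3)),
                    calls=int(m.group(4)) if m.group(4) else None,
                    function_name=m.group(5),
                )
            )
        elif in_rows:
            break
    return entries


#: Stopwatch logs are label<TAB>seconds by default; real logs from other
#: builds can be matched by overriding the pattern (it must expose groups
#: named ``label`` and ``seconds``).
DEFAULT_STOPWATCH_PATTERN = r"^(?P<label>[^\t]+)\t(?P<seconds>[\d.eE+-]+)\s*$"


def parse_blastprof_log(
    text: str, pattern: str = DEFAULT_STOPWATCH_PATTERN
) -> list[StopwatchEntry]:
    """Parse a stopwatch log into ordered entries (duplicates preserved)."""
    rx = re.compile(pattern)
    entries: list[StopwatchEntry] = []
    for line in text.splitlines():
        m = rx.match(line)
        if m:
            entries.append(StopwatchEntry(m.group("label"), float(m.group("seconds"))))
    if not entries and text.strip():
        warnings.warn("no stopwatch lines matched the configured pattern")
    return entries


def _detect_sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def write_measurements(records: Iterable[MeasurementRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "node_type": r.node_type,
                "database_size": r.database_size,
                "query_size": r.query_size,
                "threads": r.threads,
                "component": r.component.value,
                "runtime_seconds": r.runtime_seconds,
                "replicate": r.replicate,
            }
            for r in records
        ],
        columns=list(MEASUREMENT_COLUMNS),
    )
    # %.17g guarantees exact binary round trips for the runtime column
    df.to_csv(path, sep=_detect_sep(path), index=False, float_format="%.17g")


def read_measurements(path) -> list[MeasurementRecord]:
    df = pd.read_csv(path, sep=_detect_sep(path), float_precision="round_trip")
    unknown = set(df.columns) - set(MEASUREMENT_COLUMNS)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if unknown or missing:
        raise ProfilingParseError(
            f"{path}: bad measurement header; unknown columns {sorted(unknown)}, "
            f"missing columns {sorted(missing)}"
        )
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                MeasurementRecord(
                    node_type=str(row["node_type"]),
                    database_size=int(row["database_size"]),
                    query_size=int(row["query_size"]),
                    threads=int(row["threads"]),
                    component=Component(row["component"]),
                    runtime_seconds=float(row["runtime_seconds"]),
                    replicate=int(row["replicate"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ProfilingParseError(f"{path}: row {idx + 2}: {exc}") from exc
    return records
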