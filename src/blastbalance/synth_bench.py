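"""Synthetic benchmark inputs: measurement grids, FASTA files, profiler logs.

Everything the package consumes can be generated here deterministically from
a seed, so fitting, planning and splitting are testable end to end with no
external data. The default grid geometry mirrors the study conditions this
tool is built around: six truncated nucleotide databases crossed with
fifteen truncated metagenomic short-read queries, with runtimes drawn from a
known surface plus multiplicative Gaussian noise averaged over replicate
trials (three in the underlying experiments). Sequence content is
uniform-random over the alphabet — content realism is irrelevant because the
package never aligns sequences, it only counts and splits them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .perf_model import (
    Component,
    MeasurementRecord,
    PerformanceModel,
    QuadraticSurface,
    predict_runtime,
)

__all__ = [
    "DEFAULT_DATABASE_SIZES",
    "DEFAULT_QUERY_SIZES",
    "ProfilerFixtureSpec",
    "DEFAULT_PROFILER_SPEC",
    "gen_measurements",
    "gen_fasta",
    "gen_profiler_fixtures",
]

#: Six database truncation sizes (sequence counts) of the reference study.
DEFAULT_DATABASE_SIZES = (8179, 16358, 32716, 65432, 130862, 261725)

#: Fifteen query truncation sizes (sequence counts) of the reference study.
DEFAULT_QUERY_SIZES = (
    17848, 35695, 53555, 71389, 89258, 107188, 124961, 142778,
    285555, 393022, 480935, 571110, 696210, 821372, 1142220,
)


def gen_measurements(
    surface_or_model: QuadraticSurface | PerformanceModel,
    database_sizes: Sequence[int] = DEFAULT_DATABASE_SIZES,
    query_sizes: Sequence[int] = DEFAULT_QUERY_SIZES,
    noise_sigma_fraction: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    node_type: str = "V",
    component: Component | str = Component.OVERALL,
    threads: int = 1,
) -> list[MeasurementRecord]:
    """Generate a full Cartesian measurement grid from a known predictor.

    Each observation is ``value * (1 + N(0, sigma))`` with sigma the given
    fraction of the point's value, floored at 0 (runtimes are physical).
    For parameter-recovery studies the grid must lie inside the surface's
    positive region, otherwise the floor destroys information the fit would
    need. Deterministic under ``seed``.
    """
    if noise_sigma_fraction < 0:
        raise ValueError("noise_sigma_fraction must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    component = Component(component)
    rng = np.random.default_rng(seed)
    records: list[MeasurementRecord] = []
    for d in database_sizes:
        for q in query_sizes:
            if isinstance(surface_or_model, QuadraticSurface):
                value = surface_or_model(d, q)
            else:
                value = predict_runtime(surface_or_model, d, q, threads=threads)
            for rep in range(replicates):
                noisy = value * (1.0 + rng.normal(0.0, noise_sigma_fraction)) \
                    if noise_sigma_fraction > 0 else value
                noisy = max(noisy, 0.0)
                records.append(
                    MeasurementRecord(
                        node_type=node_type,
                        database_size=int(d),
                        query_size=int(q),
                        threads=threads,
                        component=component,
                        runtime_seconds=float(noisy),
                        replicate=rep,
                    )
                )
    return records


def gen_fasta(
    num_records: int,
    length_range: tuple[int, int] = (90, 150),
    alphabet: str = "ACGT",
    seed: int = 0,
    out_path=None,
    line_width: int = 70,
) -> str:
    """Write (or return) a deterministic synthetic FASTA file.

    Default lengths mirror metagenomic short reads (90-150 bp). Headers
    carry ordinal indices so fragment contents are checkable by eye.
    """
    if num_records < 0:
        raise ValueError("num_records must be >= 0")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length_range")
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    chunks: list[str] = []
    for i in range(num_records):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(letters[rng.integers(0, len(letters), length)])
        chunks.append(f">seq_{i:08d} synthetic len={length}\n")
        for start in range(0, length, line_width):
            chunks.append(seq[start:start + line_width] + "\n")
    text = "".join(chunks)
    if out_path is not None:
        Path(out_path).write_text(text)
    return text


@dataclass(frozen=True)
class ProfilerFixtureSpec:
    """Design of a mutually consistent trio of profiler outputs.

    ``stage_fractions`` are the five stopwatch sections of the main search
    routine as fractions of the total; ``function_fractions`` are the five
    hot functions (a..e) as fractions of the total. Both may sum to less
    than 1 (unattributed time) but not more.
    """

    total_seconds: float = 135.72
    code_total_seconds: float = 135.60
    user_seconds: float = 130.10
    sys_seconds: float = 2.02
    stage_fractions: tuple[float, ...] = (0.0002, 0.1091, 0.3804, 0.4813, 0.0001)
    function_fractions: tuple[float, ...] = (0.3066, 0.2928, 0.1700, 0.0972, 0.0546)
    function_names: tuple[str, ...] = (
        "PrintOneResultSet",
        "CLocalBlast::CLocalBlast",
        "CLocalBlast::Run",
        "GetNextSeqBatch",
        "PreFetchSequenceData",
    )
    function_calls: tuple[int, ...] = (53555, 4, 4, 4, 4)
    stage_labels: tuple[str, ...] = (
        "stage1_preloop",
        "stage2_prepare",
        "stage3_blast",
        "stage4_format",
        "stage5_postloop",
    )

    def __post_init__(self) -> None:
        for fracs in (self.stage_fractions, self.function_fractions):
            if any(f < 0 or f > 1 for f in fracs):
                raise ValueError("fractions must be within [0, 1]")
            if sum(fracs) > 1 + 1e-9:
                raise ValueError("fractions must not sum above 1")


#: The default fixture reproduces the percentage structure of the reference
#: profiling run (a 16k-database x 54k-query BLASTN job).
DEFAULT_PROFILER_SPEC = ProfilerFixtureSpec()


def gen_profiler_fixtures(
    spec: ProfilerFixtureSpec = DEFAULT_PROFILER_SPEC,
) -> tuple[str, str, str]:
    """Render (time text, gprof text, stopwatch text) from one spec.

    The three texts are mutually consistent: parsing each recovers the
    seconds/percentages implied by the spec's total and fractions.
    """
    time_text = (
        f"real {spec.total_seconds:.2f}\n"
        f"user {spec.user_seconds:.2f}\n"
        f"sys {spec.sys_seconds:.2f}\n"
    )

    lines = [
        "Flat profile:",
        "",
        "Each sample counts as 0.01 seconds.",
        "  %   cumulative   self              self     total",
        " time   seconds   seconds    calls  s/call   s/call  name",
    ]
    cumulative = 0.0
    for frac, name, calls in zip(
        spec.function_fractions, spec.function_names, spec.function_calls
    ):
        self_s = frac * spec.total_seconds
        cumulative += self_s
        per_call = self_s / calls if calls else 0.0
        lines.append(
            f"{frac * 100:6.2f} {cumulative:10.2f} {self_s:9.2f} "
            f"{calls:8d} {per_call:8.2f} {per_call:8.2f}  {name}"
        )
    gprof_text = "\n".join(lines) + "\n"

    sw_lines = [f"RunMTBySplitDB\t{spec.code_total_seconds:.2f}"]
    for label, frac in zip(spec.stage_labels, spec.stage_fractions):
        sw_lines.append(f"{label}\t{frac * spec.total_seconds:.4f}")
    stopwatch_text = "\n".join(sw_lines) + "\n"

    return time_text, gprof_text, stopwatch_text
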