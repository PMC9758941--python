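"""FASTA fragmentation and sub-job manifest emission.

Splitting is by sequence count only (the one property of an input a user is
assumed to know ahead of time); record text is streamed through verbatim —
no re-wrapping, no header normalisation — so concatenating the fragments
reproduces the source records byte for byte.

Every emitted BLAST command carries ``-dbseqnum <D>`` with D the sequence
count of the ORIGINAL database, never of the fragment: E-values depend on
the effective database size, and without this correction each sub-job would
compute statistics against its fragment only.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .partitioner import PartitionPlan, fragment_sizes

__all__ = [
    "FastaRecord",
    "FastaFormatError",
    "ManifestEntry",
    "Manifest",
    "iter_fasta_records",
    "count_sequences",
    "split_fasta",
    "make_manifest",
    "write_manifest_shell",
    "write_manifest_sge",
    "write_manifest_json",
]

DEFAULT_COMMAND_TEMPLATE = (
    "blastn -db {database} -query {query} -out {output} "
    "-dbseqnum {dbseqnum} -num_threads {threads}"
)


@dataclass(frozen=True)
class FastaRecord:
    """One FASTA record, preserved verbatim (lines keep their endings)."""

    header: str
    sequence_lines: tuple[str, ...]

    @property
    def text(self) -> str:
        return self.header + "".join(self.sequence_lines)


class FastaFormatError(ValueError):
    pass


def iter_fasta_records(path) -> Iterator[FastaRecord]:
    """Stream records from a FASTA file one at a time (constant memory).

    Content before the first ``>`` header is rejected with its line number.
    """
    header: str | None = None
    seq_lines: list[str] = []
    with open(path, "r", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                if header is not None:
                    yield FastaRecord(header, tuple(seq_lines))
                header = line
                seq_lines = []
            else:
                if header is None:
                    if line.strip() == "":
                        continue  # leading blank lines tolerated
                    raise FastaFormatError(
                        f"{path}: line {lineno}: sequence data before first '>' header"
                    )
                seq_lines.append(line)
    if header is not None:
        yield FastaRecord(header, tuple(seq_lines))


def count_sequences(path) -> int:
    """Number of records in a FASTA file, streaming."""
    n = 0
    for _ in iter_fasta_records(path):
        n += 1
    return n


def split_fasta(
    fasta_path,
    parts: int,
    out_dir,
    name_template: str = "{stem}.part{index:04d}.fasta",
) -> list[Path]:
    """Split a FASTA file into ``parts`` fragments by the ceiling rule.

    Fragment record counts follow :func:`fragment_sizes` exactly; record
    order and bytes are preserved. When ``parts`` exceeds the record count
    the surplus fragments are written as empty files and a warning is
    issued, keeping file arithmetic aligned with the plan.
    """
    if parts < 1:
        raise ValueError("parts must be >= 1")
    fasta_path = Path(fasta_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    total = count_sequences(fasta_path)

    if total == 0:
        sizes = [0] * parts
    else:
        sizes = fragment_sizes(total, parts)
    if any(s == 0 for s in sizes):
        warnings.warn(
            f"{fasta_path}: {parts} fragments requested for {total} records; "
            f"{sum(1 for s in sizes if s == 0)} fragment(s) will be empty"
        )

    records = iter_fasta_records(fasta_path)
    paths: list[Path] = []
    stem = fasta_path.stem
    for index, size in enumerate(sizes):
        frag_path = out_dir / name_template.format(stem=stem, index=index)
        with open(frag_path, "w", newline="") as out:
            for _ in range(size):
                out.write(next(records).text)
        paths.append(frag_path)
    return paths


@dataclass(frozen=True)
class ManifestEntry:
    database_fragment: str
    query_fragment: str
    node_type: str
    command_line: str


@dataclass(frozen=True)
class Manifest:
    entries: tuple[ManifestEntry, ...]
    dbseqnum: int
    threads: int


def _per_type_fragments(
    plan: PartitionPlan,
    db_fragments,
    query_fragments,
) -> dict[str, tuple[Sequence, Sequence]]:
    """Normalise fragment arguments to node_type -> (db paths, query paths)."""
    if isinstance(db_fragments, Mapping) or isinstance(query_fragments, Mapping):
        if not (isinstance(db_fragments, Mapping) and isinstance(query_fragments, Mapping)):
            raise ValueError("db_fragments and query_fragments must both be mappings")
        return {
            t: (list(db_fragments[t]), list(query_fragments[t]))
            for t in db_fragments
        }
    if len(plan.entries) != 1:
        raise ValueError(
            "plain fragment lists only apply to single-type plans; pass "
            "mappings keyed by node_type for a heterogeneous plan"
        )
    return {plan.entries[0].node_type: (list(db_fragments), list(query_fragments))}


def make_manifest(
    plan: PartitionPlan,
    db_fragments,
    query_fragments,
    dbseqnum: int,
    threads: int = 1,
    command_template: str = DEFAULT_COMMAND_TEMPLATE,
    output_template: str = "out.{node_type}.d{i:04d}.q{j:04d}.txt",
) -> Manifest:
    """Expand a plan into one BLAST command per (database, query) pair.

    For each node type the commands cover the full Cartesian product of its
    m_k database fragments and n_k query fragments. ``dbseqnum`` must be the
    pre-split database sequence count and is injected into every command.
    """
    per_type = _per_type_fragments(plan, db_fragments, query_fragments)
    entries: list[ManifestEntry] = []
    for entry in plan.entries:
        if entry.node_type not in per_type:
            raise ValueError(f"no fragments given for node type {entry.node_type!r}")
        dbs, queries = per_type[entry.node_type]
        if len(dbs) != entry.split.m:
            raise ValueError(
                f"node type {entry.node_type!r}: expected {entry.split.m} database "
                f"fragments, got {len(dbs)}"
            )
        if len(queries) != entry.split.n:
            raise ValueError(
                f"node type {entry.node_type!r}: expected {entry.split.n} query "
                f"fragments, got {len(queries)}"
            )
        for i, db in enumerate(dbs):
            for j, q in enumerate(queries):
                cmd = command_template.format(
                    database=db,
                    query=q,
                    output=output_template.format(node_type=entry.node_type, i=i, j=j),
                    dbseqnum=dbseqnum,
                    threads=threads,
                )
                entries.append(ManifestEntry(str(db), str(q), entry.node_type, cmd))
    return Manifest(tuple(entries), dbseqnum=dbseqnum, threads=threads)


def write_manifest_shell(manifest: Manifest, path) -> None:
    with open(path, "w") as fh:
        fh.write("#!/bin/sh\n")
        fh.write(f"# {len(manifest.entries)} sub-jobs, dbseqnum={manifest.dbseqnum}\n")
        for entry in manifest.entries:
            fh.write(entry.command_line + "\n")
    os.chmod(path, 0o755)


def write_manifest_sge(manifest: Manifest, path, job_name: str = "blastbalance") -> None:
    """Emit the manifest as an SGE array-job script (one task per sub-job)."""
    with open(path, "w") as fh:
        fh.write("#!/bin/sh\n")
        fh.write(f"#$ -N {job_name}\n")
        fh.write(f"#$ -t 1-{len(manifest.entries)}\n")
        fh.write("#$ -cwd\n")
        fh.write('case "$SGE_TASK_ID" in\n')
        for i, entry in enumerate(manifest.entries, start=1):
            fh.write(f"{i}) {entry.command_line} ;;\n")
        fh.write("esac\n")
    os.chmod(path, 0o755)


def write_manifest_json(manifest: Manifest, path) -> None:
    doc = {
        "dbseqnum": manifest.dbseqnum,
        "threads": manifest.threads,
        "entries": [
            {
                "database_fragment": e.database_fragment,
                "query_fragment": e.query_fragment,
                "node_type": e.node_type,
                "command_line": e.command_line,
            }
            for e in manifest.entries
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
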