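"""Static partitioning of a database x query BLAST job across cluster nodes.

A job of D database sequences and Q query sequences run on P nodes is split
into m database fragments and n query fragments with m*n <= P; each node
runs one sub-job of size (ceil(D/m), ceil(Q/n)) and the job finishes when
the slowest sub-job does, so the cost of a plan is the maximum predicted
sub-job runtime. On a homogeneous cluster the optimizer simply evaluates the
performance model at every candidate (m, n) and keeps the minimum. On a
heterogeneous cluster the query is first apportioned between node types in
proportion to their accumulated computing power W_k = s_k * P_k, after which
each type is solved as its own homogeneous sub-problem; only the query is
divided between types because shrinking the query fragment is consistently
the more effective lever.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .perf_model import NodeTypeProfile, PerformanceModel, predict_runtime

__all__ = [
    "JobSpec",
    "SplitCandidate",
    "PlanEntry",
    "PartitionPlan",
    "fragment_size",
    "fragment_sizes",
    "enumerate_splits",
    "solve_homogeneous",
    "compute_power",
    "split_query_by_power",
    "solve_heterogeneous",
    "plan_cost",
    "load_cluster",
    "save_plan",
    "format_plan_table",
]


@dataclass(frozen=True)
class JobSpec:
    """Total problem size: D database and Q query sequences."""

    database_total: int
    query_total: int

    def __post_init__(self) -> None:
        if self.database_total < 1 or self.query_total < 1:
            raise ValueError("database_total and query_total must be >= 1")


@dataclass(frozen=True)
class SplitCandidate:
    """One (m, n) fragmentation with its ceiling fragment sizes."""

    m: int
    n: int
    database_fragment: int
    query_fragment: int
    predicted_seconds: float = math.nan

    @property
    def nodes_used(self) -> int:
        return self.m * self.n


@dataclass(frozen=True)
class PlanEntry:
    """The chosen fragmentation for one node type of a plan."""

    node_type: str
    node_count: int
    power: float
    query_quota: int
    per_node_quota: int
    split: SplitCandidate
    predicted_seconds: float
    idle_nodes: int


@dataclass(frozen=True)
class PartitionPlan:
    job: JobSpec
    entries: tuple[PlanEntry, ...]

    @property
    def cost_seconds(self) -> float:
        return plan_cost(self)


def fragment_size(total: int, parts: int) -> int:
    """Ceiling fragment size ceil(total/parts); never below 1."""
    if total < 1 or parts < 1:
        raise ValueError("total and parts must be >= 1")
    return -(-total // parts)


def fragment_sizes(total: int, parts: int) -> list[int]:
    """Materialize the ceiling rule into exact per-fragment counts.

    The first parts-1 fragments hold ceil(total/parts) sequences and the
    last absorbs the remainder; entries sum exactly to total. When parts
    exceeds total the trailing fragments are zero-sized (reported, not
    dropped, so downstream manifest arithmetic stays aligned).
    """
    size = fragment_size(total, parts)
    sizes = []
    remaining = total
    for _ in range(parts - 1):
        take = min(size, remaining)
        sizes.append(take)
        remaining -= take
    sizes.append(remaining)
    assert sum(sizes) == total
    return sizes


def enumerate_splits(P: int) -> list[tuple[int, int]]:
    """Candidate (m, n) fragmentations for P nodes.

    For every m in 1..P the pair (m, floor(P/m)) is emitted (deduplicated,
    sorted by m). This includes all exact divisor pairs and also near-misses
    such as (3, floor(4096/3)) = (3, 1365) that leave a few nodes idle but
    can still be optimal.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    seen: dict[int, int] = {}
    for m in range(1, P + 1):
        n = P // m
        if n >= 1 and m not in seen:
            seen[m] = n
    return sorted(seen.items())


def solve_homogeneous(
    job: JobSpec, P: int, model: PerformanceModel, threads: int = 1
) -> SplitCandidate:
    """Pick the (m, n) with minimum predicted sub-job runtime.

    Ties are broken by larger n (smaller query fragments), then smaller m:
    shrinking the query is the more performance-effective direction.
    """
    best: SplitCandidate | None = None
    for m, n in enumerate_splits(P):
        d_i = fragment_size(job.database_total, m)
        q_j = fragment_size(job.query_total, n)
        try:
            t = predict_runtime(model, d_i, q_j, threads=threads)
        except Exception as exc:
            raise RuntimeError(
                f"model evaluation failed for candidate (m={m}, n={n}, "
                f"D_i={d_i}, Q_j={q_j}): {exc}"
            ) from exc
        cand = SplitCandidate(m, n, d_i, q_j, t)
        if best is None or (t, -n, m) < (best.predicted_seconds, -best.n, best.m):
            best = cand
    assert best is not None
    return best


def compute_power(cluster: Sequence[NodeTypeProfile]) -> dict[str, float]:
    """Accumulated computing power W_k = s_k * P_k per node type."""
    if not cluster:
        raise ValueError("empty cluster")
    return {p.node_type: p.performance_factor * p.count for p in cluster}


def split_query_by_power(
    Q: int, cluster: Sequence[NodeTypeProfile]
) -> dict[str, tuple[int, int]]:
    """Apportion Q query sequences between node types by computing power.

    Each type receives a share W_k / sum(W); its per-node quota is
    q_k = ceil(share * Q / P_k) and its type quota Q_k = q_k * P_k, so the
    quotas always cover Q with at most one extra sequence per node.
    Returns node_type -> (Q_k, q_k); types with zero nodes are excluded.
    """
    power = compute_power(cluster)
    active = [p for p in cluster if p.count > 0]
    total_power = sum(power[p.node_type] for p in active)
    if total_power <= 0:
        raise ValueError("total computing power must be > 0")
    quotas: dict[str, tuple[int, int]] = {}
    for p in active:
        share = power[p.node_type] / total_power
        per_node = math.ceil(share * Q / p.count)
        quotas[p.node_type] = (per_node * p.count, per_node)
    return quotas


def solve_heterogeneous(
    job: JobSpec,
    cluster: Sequence[NodeTypeProfile],
    models: Mapping[str, PerformanceModel],
    threads: int = 1,
) -> PartitionPlan:
    """Algorithm for a mixed-hardware cluster.

    The query is divided between node types by computing power; each type is
    then solved as a homogeneous cluster over (D, Q_k). The full database
    goes to every type (only the query is divided at the top level). The
    plan's cost is the max predicted sub-job time across types.
    """
    quotas = split_query_by_power(job.query_total, cluster)
    power = compute_power(cluster)
    entries = []
    for profile in cluster:
        if profile.count == 0:
            continue
        if profile.node_type not in models:
            raise ValueError(f"no performance model for node type {profile.node_type!r}")
        q_k, per_node = quotas[profile.node_type]
        sub_job = JobSpec(job.database_total, q_k)
        split = solve_homogeneous(sub_job, profile.count, models[profile.node_type], threads)
        entries.append(
            PlanEntry(
                node_type=profile.node_type,
                node_count=profile.count,
                power=power[profile.node_type],
                query_quota=q_k,
                per_node_quota=per_node,
                split=split,
                predicted_seconds=split.predicted_seconds,
                idle_nodes=profile.count - split.nodes_used,
            )
        )
    if not entries:
        raise ValueError("cluster has no usable nodes")
    return PartitionPlan(job=job, entries=tuple(entries))


def plan_cost(plan: PartitionPlan) -> float:
    """Overall predicted runtime: the slowest sub-job determines the job."""
    if not plan.entries:
        raise ValueError("empty plan")
    return max(e.predicted_seconds for e in plan.entries)


# ---------------------------------------------------------------------------
# cluster description / plan I/O


def load_cluster(path) -> list[NodeTypeProfile]:
    """Read a cluster description JSON.

    Schema: {"node_types": [{"node_type": ..., "count": ...,
    "performance_factor": ..., "function_scale_factors": {...},
    "thread_speedup": {"2": 1.25, ...}}, ...]}
    """
    with open(path) as fh:
        doc = json.load(fh)
    profiles = []
    for entry in doc["node_types"]:
        profiles.append(
            NodeTypeProfile(
                node_type=entry["node_type"],
                count=entry["count"],
                performance_factor=entry.get("performance_factor", 1.0),
                function_scale_factors=entry.get("function_scale_factors"),
                thread_speedup=(
                    {int(k): v for k, v in entry["thread_speedup"].items()}
                    if "thread_speedup" in entry
                    else None
                ),
            )
        )
    return profiles


def plan_to_dict(plan: PartitionPlan) -> dict:
    return {
        "database_total": plan.job.database_total,
        "query_total": plan.job.query_total,
        "cost_seconds": plan.cost_seconds,
        "entries": [
            {
                "node_type": e.node_type,
                "node_count": e.node_count,
                "power": e.power,
                "query_quota": e.query_quota,
                "per_node_quota": e.per_node_quota,
                "m": e.split.m,
                "n": e.split.n,
                "database_fragment": e.split.database_fragment,
                "query_fragment": e.split.query_fragment,
                "predicted_seconds": e.predicted_seconds,
                "idle_nodes": e.idle_nodes,
            }
            for e in plan.entries
        ],
    }


def save_plan(plan: PartitionPlan, path) -> None:
    with open(path, "w") as fh:
        json.dump(plan_to_dict(plan), fh, indent=2)
        fh.write("\n")


def load_plan(path) -> PartitionPlan:
    with open(path) as fh:
        doc = json.load(fh)
    entries = tuple(
        PlanEntry(
            node_type=e["node_type"],
            node_count=e["node_count"],
            power=e["power"],
            query_quota=e["query_quota"],
            per_node_quota=e["per_node_quota"],
            split=SplitCandidate(
                e["m"], e["n"], e["database_fragment"], e["query_fragment"],
                e["predicted_seconds"],
            ),
            predicted_seconds=e["predicted_seconds"],
            idle_nodes=e["idle_nodes"],
        )
        for e in doc["entries"]
    )
    return PartitionPlan(JobSpec(doc["database_total"], doc["query_total"]), entries)


def format_plan_table(plan: PartitionPlan) -> str:
    """Human-readable summary table of a partition plan."""
    header = (
        f"{'type':>6} {'nodes':>6} {'m':>5} {'n':>6} {'D_i':>10} {'Q_j':>10} "
        f"{'quota':>12} {'pred(s)':>10} {'idle':>5}"
    )
    lines = [header, "-" * len(header)]
    for e in plan.entries:
        lines.append(
            f"{e.node_type:>6} {e.node_count:>6} {e.split.m:>5} {e.split.n:>6} "
            f"{e.split.database_fragment:>10} {e.split.query_fragment:>10} "
            f"{e.query_quota:>12} {e.predicted_seconds:>10.2f} {e.idle_nodes:>5}"
        )
    lines.append(f"overall predicted cost: {plan.cost_seconds:.2f} s")
    return "\n".join(lines)
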