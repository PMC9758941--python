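"""Runtime performance models for segmented BLAST jobs.

A BLAST sub-job of (database fragment, query fragment) size ``(D_i, Q_j)``
is modelled per node type *k* by one of three predictor kinds:

* **cpm** — constant performance model: ``T = D_i / s`` with a fixed speed
  *s* in sequences/second.
* **fpm** — functional performance model: the speed itself depends on the
  problem size, ``T = D_i / s(D_i)``, with *s* given as a piecewise table.
* **quadratic_sum** — a sum of bivariate quadratic surfaces, one per
  profiled component (e.g. the five hot functions of the BLASTN main loop):

  .. math::

     T(D, Q) = c_1 x^2 + c_2 x y + c_3 y^2 + c_4 x + c_5 y + c_6

  where ``y = Q_m`` (query sequences in millions) and ``x`` is either
  ``D_m`` (database sequences in millions) or ``log(D_m)`` — the log axis
  fits the I/O-heavy formatting/prefetch components markedly better.

Surfaces are fitted by ordinary least squares from measurement grids and can
be rescaled between node types with per-component relative-runtime factors
("abstract processor" scaling: a node type is characterised by its runtime
ratios against a reference type).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Component",
    "MeasurementRecord",
    "QuadraticSurface",
    "SurfaceEvaluation",
    "PerformanceModel",
    "NodeTypeProfile",
    "FitReport",
    "FitError",
    "fit_surface",
    "evaluate_surface",
    "predict_runtime",
    "derive_scale_factors",
    "scale_model",
    "check_monotonic",
    "default_performance_factor",
    "save_model",
    "load_model",
    "load_reference_surfaces",
    "load_reference_scale_factors",
]

#: Sequence counts are expressed in millions before entering a surface.
SEQUENCES_PER_UNIT = 1_000_000

#: Default floor (seconds) substituted when a surface predicts <= 0.
DEFAULT_CLAMP_FLOOR = 0.001


class Component(str, Enum):
    """Profiled runtime components of a BLASTN run.

    ``overall`` is the shell-level wall clock; ``stage*`` are the five
    stopwatch sections of the main search routine; ``func_a``..``func_e``
    are its five most expensive functions (a = result formatting,
    b = object construction, c = the core search, d = batch input,
    e = sequence prefetch); ``time_*`` are the raw ``time(1)`` measures.
    """

    OVERALL = "overall"
    STAGE1_PRELOOP = "stage1_preloop"
    STAGE2_PREPARE = "stage2_prepare"
    STAGE3_BLAST = "stage3_blast"
    STAGE4_FORMAT = "stage4_format"
    STAGE5_POSTLOOP = "stage5_postloop"
    FUNC_A = "func_a"
    FUNC_B = "func_b"
    FUNC_C = "func_c"
    FUNC_D = "func_d"
    FUNC_E = "func_e"
    TIME_REAL = "time_real"
    TIME_USER = "time_user"
    TIME_SYS = "time_sys"


@dataclass(frozen=True)
class MeasurementRecord:
    """One profiled runtime observation."""

    node_type: str
    database_size: int
    query_size: int
    threads: int
    component: Component
    runtime_seconds: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.database_size < 1 or self.query_size < 1:
            raise ValueError("database_size and query_size must be >= 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.runtime_seconds < 0:
            raise ValueError("runtime_seconds must be non-negative")
        if not isinstance(self.component, Component):
            object.__setattr__(self, "component", Component(self.component))


@dataclass(frozen=True)
class QuadraticSurface:
    """Bivariate quadratic runtime surface.

    Evaluation order is fixed: ``c1*x^2 + c2*x*y + c3*y^2 + c4*x + c5*y + c6``
    with ``x = transform(D_m)`` and ``y = Q_m`` (both in millions of
    sequences). ``x_transform`` is ``"identity"`` or ``"log"``; the log base
    defaults to *e* and must be recorded because published coefficients are
    only meaningful under the base they were fitted with.
    """

    c1: float
    c2: float
    c3: float
    c4: float
    c5: float
    c6: float
    x_transform: str = "identity"
    log_base: float = math.e

    def __post_init__(self) -> None:
        if self.x_transform not in ("identity", "log"):
            raise ValueError(f"unknown x_transform {self.x_transform!r}")
        if self.x_transform == "log" and self.log_base <= 0:
            raise ValueError("log_base must be positive")

    @property
    def coefficients(self) -> tuple[float, float, float, float, float, float]:
        return (self.c1, self.c2, self.c3, self.c4, self.c5, self.c6)

    @property
    def is_plane(self) -> bool:
        return self.c1 == self.c2 == self.c3 == 0

    def _x(self, database_size: float) -> float:
        d_m = database_size / SEQUENCES_PER_UNIT
        if self.x_transform == "log":
            if d_m <= 0:
                raise ValueError("log transform requires database_size > 0")
            return math.log(d_m) / math.log(self.log_base)
        return d_m

    def __call__(self, database_size: float, query_size: float) -> float:
        """Raw (unclamped) prediction in seconds."""
        x = self._x(database_size)
        y = query_size / SEQUENCES_PER_UNIT
        return (
            self.c1 * x * x
            + self.c2 * x * y
            + self.c3 * y * y
            + self.c4 * x
            + self.c5 * y
            + self.c6
        )


@dataclass(frozen=True)
class SurfaceEvaluation:
    """Raw and floor-clamped value of one surface evaluation."""

    raw_seconds: float
    clamped_seconds: float
    clamped: bool


@dataclass(frozen=True)
class FitReport:
    residual_sum_of_squares: float
    r_squared: float
    n_points: int
    condition_warning: bool
    per_point_residuals: tuple[float, ...]


class FitError(ValueError):
    """Raised when a surface cannot be fitted from the given grid."""


@dataclass(frozen=True)
class NodeTypeProfile:
    """Inventory entry for one node type of a cluster.

    ``performance_factor`` is the relative speed s_k (higher = faster) used
    to apportion query quotas; ``function_scale_factors`` are per-component
    runtime ratios relative to a reference type (all 1.0 on the reference);
    ``thread_speedup`` maps thread count to a runtime divisor.
    """

    node_type: str
    count: int
    performance_factor: float = 1.0
    function_scale_factors: Mapping[str, float] | None = None
    thread_speedup: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("node count must be >= 0")
        if self.performance_factor <= 0:
            raise ValueError("performance_factor must be > 0")
        if self.function_scale_factors is not None:
            if any(f <= 0 for f in self.function_scale_factors.values()):
                raise ValueError("scale factors must be > 0")


_TERM_NAMES = ("x^2", "x*y", "y^2", "x", "y", "1")


def _design_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])


def fit_surface(
    records: Iterable[MeasurementRecord],
    x_transform: str = "identity",
    log_base: float = math.e,
) -> tuple[QuadraticSurface, FitReport]:
    """Fit a quadratic surface to a measurement grid by OLS.

    Replicates at the same (database_size, query_size) are averaged before
    fitting. Requires at least 6 distinct grid points and a full-rank design;
    a rank-deficient design raises :class:`FitError` naming the dependent
    term (e.g. a single database size makes every x-term collinear).
    """
    records = list(records)
    if not records:
        raise FitError("no measurement records given")
    node_types = {r.node_type for r in records}
    components = {r.component for r in records}
    if len(node_types) > 1 or len(components) > 1:
        raise FitError(
            "fit_surface expects a grid for one node type and one component, "
            f"got node types {sorted(node_types)} and components "
            f"{sorted(c.value for c in components)}"
        )

    # replicate averaging per (D, Q)
    sums: dict[tuple[int, int], list[float]] = {}
    for r in records:
        sums.setdefault((r.database_size, r.query_size), []).append(
            r.runtime_seconds
        )
    points = sorted(sums)
    if len(points) < 6:
        raise FitError(
            f"need >= 6 distinct (database_size, query_size) points, got {len(points)}"
        )
    probe = QuadraticSurface(0, 0, 0, 0, 0, 0, x_transform=x_transform, log_base=log_base)
    x = np.array([probe._x(d) for d, _ in points])
    y = np.array([q / SEQUENCES_PER_UNIT for _, q in points])
    t = np.array([float(np.mean(sums[p])) for p in points])

    A = _design_matrix(x, y)
    rank = np.linalg.matrix_rank(A)
    if rank < 6:
        # name the first column explainable by the preceding ones
        for j in range(1, 6):
            sub = A[:, :j]
            resid = A[:, j] - sub @ np.linalg.lstsq(sub, A[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(A[:, j])):
                raise FitError(
                    f"design matrix is rank-deficient: term '{_TERM_NAMES[j]}' is "
                    "collinear with lower-order terms; vary both database and "
                    "query sizes across the grid"
                )
        raise FitError("design matrix is rank-deficient")

    coef, _, _, sv = np.linalg.lstsq(A, t, rcond=None)
    cond = sv[0] / sv[-1] if sv[-1] > 0 else math.inf
    fitted = A @ coef
    residuals = t - fitted
    rss = float(residuals @ residuals)
    tss = float(np.sum((t - t.mean()) ** 2))
    r_squared = 1.0 - rss / tss if tss > 0 else 1.0
    surface = QuadraticSurface(
        *(float(c) for c in coef), x_transform=x_transform, log_base=log_base
    )
    report = FitReport(
        residual_sum_of_squares=rss,
        r_squared=r_squared,
        n_points=len(points),
        condition_warning=cond > 1e8,
        per_point_residuals=tuple(float(r) for r in residuals),
    )
    return surface, report


def evaluate_surface(
    surface: QuadraticSurface,
    database_size: float,
    query_size: float,
    clamp_floor: float = DEFAULT_CLAMP_FLOOR,
) -> SurfaceEvaluation:
    """Evaluate a surface, reporting both raw and floor-clamped values.

    Quadratics fitted to positive runtimes can dip below zero near the edge
    of the fitted domain; the optimizer needs a usable total order there, so
    non-positive raw values are clamped to ``clamp_floor`` and flagged.
    """
    if database_size < 1 or query_size < 1:
        raise ValueError("sizes must be >= 1")
    raw = surface(database_size, query_size)
    if raw <= 0:
        return SurfaceEvaluation(raw, clamp_floor, True)
    return SurfaceEvaluation(raw, raw, False)


@dataclass(frozen=True)
class PerformanceModel:
    """Per-node-type runtime predictor T_k(D_i, Q_j).

    ``kind`` selects the prediction rule:

    * ``"quadratic_sum"`` — sum of the clamped evaluations of ``components``.
    * ``"cpm"`` — ``D_i / speed_constant``.
    * ``"fpm"`` — ``D_i / s(D_i)`` with ``speed_table`` a sorted sequence of
      ``(max_database_size, speed)`` bins; sizes beyond the last bin are out
      of the model's domain.

    Predictions at ``threads > 1`` are divided by the node type's measured
    thread speed-up factor; threading is deliberately not modelled inside
    the surfaces because the surface shape is stable across thread counts.
    """

    node_type: str
    kind: str
    components: Mapping[str, QuadraticSurface] | None = None
    speed_constant: float | None = None
    speed_table: Sequence[tuple[float, float]] | None = None
    clamp_floor: float = DEFAULT_CLAMP_FLOOR
    thread_speedup: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.kind == "quadratic_sum":
            if not self.components:
                raise ValueError("quadratic_sum model needs components")
        elif self.kind == "cpm":
            if not self.speed_constant or self.speed_constant <= 0:
                raise ValueError("cpm model needs a positive speed_constant")
        elif self.kind == "fpm":
            if not self.speed_table:
                raise ValueError("fpm model needs a speed_table")
            sizes = [s for s, _ in self.speed_table]
            if sizes != sorted(sizes) or any(v <= 0 for _, v in self.speed_table):
                raise ValueError("speed_table must be sorted with positive speeds")
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")


def predict_runtime(
    model: PerformanceModel,
    database_size: float,
    query_size: float,
    threads: int = 1,
) -> float:
    """Predicted sub-job runtime in seconds for one node of this type."""
    if model.kind == "quadratic_sum":
        assert model.components is not None
        total = sum(
            evaluate_surface(s, database_size, query_size, model.clamp_floor).clamped_seconds
            for s in model.components.values()
        )
    elif model.kind == "cpm":
        total = database_size / model.speed_constant  # type: ignore[operator]
    else:  # fpm
        assert model.speed_table is not None
        for max_size, speed in model.speed_table:
            if database_size <= max_size:
                total = database_size / speed
                break
        else:
            raise ValueError(
                f"database_size {database_size} outside fpm speed_table domain "
                f"(max {model.speed_table[-1][0]})"
            )
    if threads != 1:
        if not model.thread_speedup or threads not in model.thread_speedup:
            raise ValueError(
                f"no thread speed-up factor for threads={threads} on node type "
                f"{model.node_type!r}"
            )
        total /= model.thread_speedup[threads]
    return total


def derive_scale_factors(
    records_ref: Iterable[MeasurementRecord],
    records_other: Iterable[MeasurementRecord],
) -> dict[str, float]:
    """Per-component runtime ratios of another node type against a reference.

    The factor for a component is the mean, over matched
    (database_size, query_size, component) keys, of
    ``runtime_other / runtime_ref``. Matched grids measured on two node types
    reduce the second type to an "abstract processor": the reference model
    times these factors.
    """
    def keyed(records: Iterable[MeasurementRecord]):
        table: dict[tuple[int, int, Component], list[float]] = {}
        for r in records:
            table.setdefault(
                (r.database_size, r.query_size, r.component), []
            ).append(r.runtime_seconds)
        return {k: float(np.mean(v)) for k, v in table.items()}

    ref = keyed(records_ref)
    other = keyed(records_other)
    shared = sorted(set(ref) & set(other))
    if not shared:
        raise ValueError("no overlapping (database, query, component) keys")
    ratios: dict[str, list[float]] = {}
    for key in shared:
        if ref[key] == 0:
            continue
        ratios.setdefault(key[2].value, []).append(other[key] / ref[key])
    if not ratios:
        raise ValueError("all reference runtimes are zero on shared keys")
    return {comp: float(np.mean(vals)) for comp, vals in sorted(ratios.items())}


def scale_model(
    model: PerformanceModel, factors: Mapping[str, float]
) -> PerformanceModel:
    """Rescale a quadratic_sum model to another node type.

    Each component surface's six coefficients are multiplied by that
    component's factor; because the surface is linear in its coefficients,
    predictions scale exactly by the factor at every input.
    """
    if model.kind != "quadratic_sum":
        raise ValueError("scale_model applies to quadratic_sum models")
    assert model.components is not None
    missing = set(model.components) - set(factors)
    if missing:
        raise ValueError(f"missing scale factors for components: {sorted(missing)}")
    scaled = {
        name: replace(
            surf,
            c1=surf.c1 * factors[name],
            c2=surf.c2 * factors[name],
            c3=surf.c3 * factors[name],
            c4=surf.c4 * factors[name],
            c5=surf.c5 * factors[name],
            c6=surf.c6 * factors[name],
        )
        for name, surf in model.components.items()
    }
    return replace(model, components=scaled)


def check_monotonic(
    model: PerformanceModel,
    d_range: tuple[float, float],
    q_range: tuple[float, float],
    grid_step: int = 10,
) -> list[tuple[float, float]]:
    """Scan a grid for points where predicted runtime decreases as a size grows.

    Physical runtimes increase with both database and query size; violations
    indicate the model is being evaluated outside its trustworthy domain.
    Returns the violating (database_size, query_size) points; empty = monotone
    on the grid.
    """
    ds = np.linspace(d_range[0], d_range[1], grid_step)
    qs = np.linspace(q_range[0], q_range[1], grid_step)
    pred = np.array(
        [[predict_runtime(model, d, q) for q in qs] for d in ds]
    )
    bad: list[tuple[float, float]] = []
    for i in range(len(ds)):
        for j in range(len(qs)):
            if i + 1 < len(ds) and pred[i + 1, j] < pred[i, j]:
                bad.append((float(ds[i + 1]), float(qs[j])))
            if j + 1 < len(qs) and pred[i, j + 1] < pred[i, j]:
                bad.append((float(ds[i]), float(qs[j + 1])))
    return sorted(set(bad))


def default_performance_factor(function_scale_factors: Mapping[str, float]) -> float:
    """Relative speed implied by per-component runtime factors.

    A type whose functions take, on average, f times as long as the
    reference's runs 1/f as fast.
    """
    vals = list(function_scale_factors.values())
    if not vals:
        raise ValueError("empty factor map")
    return 1.0 / (sum(vals) / len(vals))


# ---------------------------------------------------------------------------
# model (de)serialization and packaged reference data


def _surface_to_dict(s: QuadraticSurface) -> dict:
    return {
        "coefficients": list(s.coefficients),
        "x_transform": s.x_transform,
        "log_base": s.log_base,
    }


def _surface_from_dict(d: Mapping) -> QuadraticSurface:
    return QuadraticSurface(
        *d["coefficients"],
        x_transform=d.get("x_transform", "identity"),
        log_base=d.get("log_base", math.e),
    )


def save_model(model: PerformanceModel, path) -> None:
    doc: dict = {
        "node_type": model.node_type,
        "kind": model.kind,
        "clamp_floor": model.clamp_floor,
    }
    if model.components is not None:
        doc["components"] = {
            name: _surface_to_dict(s) for name, s in model.components.items()
        }
    if model.speed_constant is not None:
        doc["speed_constant"] = model.speed_constant
    if model.speed_table is not None:
        doc["speed_table"] = [list(row) for row in model.speed_table]
    if model.thread_speedup is not None:
        doc["thread_speedup"] = {str(k): v for k, v in model.thread_speedup.items()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_model(path) -> PerformanceModel:
    with open(path) as fh:
        doc = json.load(fh)
    return PerformanceModel(
        node_type=doc["node_type"],
        kind=doc["kind"],
        components=(
            {n: _surface_from_dict(d) for n, d in doc["components"].items()}
            if "components" in doc
            else None
        ),
        speed_constant=doc.get("speed_constant"),
        speed_table=(
            [tuple(row) for row in doc["speed_table"]]
            if "speed_table" in doc
            else None
        ),
        clamp_floor=doc.get("clamp_floor", DEFAULT_CLAMP_FLOOR),
        thread_speedup=(
            {int(k): v for k, v in doc["thread_speedup"].items()}
            if "thread_speedup" in doc
            else None
        ),
    )


def _load_data(name: str) -> dict:
    with resources.files("blastbalance.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_reference_surfaces() -> dict[str, QuadraticSurface]:
    """Published per-function surfaces for the reference node type.

    Keys are the hot-function components ``func_a``..``func_e``. The two
    saddle-shaped functions (a, e) use a log-transformed database axis; the
    log base is recorded in the data file (assumed natural, the common
    regression default; the published source does not state it).
    """
    doc = _load_data("reference_surfaces.json")
    return {
        name: _surface_from_dict(entry) for name, entry in doc["surfaces"].items()
    }


def load_reference_scale_factors() -> dict[str, dict[str, float]]:
    """Published per-function runtime factors of six node types vs. the reference."""
    doc = _load_data("node_type_scale_factors.json")
    return {k: dict(v) for k, v in doc["factors"].items()}
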