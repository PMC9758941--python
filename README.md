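# blastbalance

Static load balancing for segmented BLAST jobs, driven by fitted runtime
models.

A BLAST search of a query against a database parallelizes naturally by
splitting the database into *m* fragments and the query into *n* fragments
and running one sub-job per (fragment, fragment) pair on *m* × *n* cluster
nodes. The job finishes when the slowest sub-job does, so the choice of
(*m*, *n*) — for a fixed node budget *P* — can change the wall clock by
multiples. `blastbalance` is for bioinformaticians and HPC support staff who
run large BLASTN jobs on shared clusters and want that choice made from
measurements instead of folklore.

## The model

Profiled runtimes of a BLASTN sub-job on a fixed node type are modelled per
component (the five hot functions of the main search loop, or the overall
wall clock) by a bivariate quadratic surface

    T(D, Q) = c1·x² + c2·x·y + c3·y² + c4·x + c5·y + c6

with *y* = Q_m the query size in millions of sequences and *x* either D_m,
the database size in millions, or log(D_m) — the logarithmic axis fits the
I/O-heavy formatting and prefetch components markedly better. Coefficients
are estimated by ordinary least squares on a measurement grid. Simpler
predictors are also supported: a constant-speed model T = D/s and a
functional model T = D/s(D) with piecewise speed.

Given a model T_k per node type *k*:

* **Homogeneous cluster** (one type, *P* nodes): evaluate
  T(⌈D/m⌉, ⌈Q/n⌉) over all candidate pairs (m, n = ⌊P/m⌋) and keep the
  minimizer; ties prefer larger *n* because shrinking the query fragment is
  consistently the more effective lever.
* **Heterogeneous cluster** (types *k* with counts P_k and relative speeds
  s_k): apportion the query in proportion to accumulated computing power
  W_k = s_k·P_k (per-node quota q_k = ⌈share_k·Q/P_k⌉), then solve each
  type as its own homogeneous sub-problem; the plan's cost is
  max_k T_k(D_i, Q_j).

Node types can be rescaled from a single reference model by per-component
runtime ratios ("abstract processor" factors); published reference
coefficients and factor tables ship with the package. The plan is
materialized by a byte-faithful FASTA splitter (ceiling-rule fragment
sizes) and a manifest writer that emits one `blastn` command per sub-job,
each carrying `-dbseqnum <D>` with the *original* database sequence count
so E-values stay correct after segmentation.

## Worked example

Plan a 523,449-sequence database × 73,102,023-sequence query job, first on
4,096 identical reference-type nodes, then on a mixed inventory of 2,048
slower nodes (Type II) and 2,048 reference nodes (Type V):

```python
from blastbalance import (
    JobSpec, NodeTypeProfile, PerformanceModel,
    load_reference_surfaces, load_reference_scale_factors,
    default_performance_factor, scale_model,
    solve_homogeneous, solve_heterogeneous,
)
from blastbalance.partitioner import format_plan_table

model_v = PerformanceModel("V", "quadratic_sum",
                           components=load_reference_surfaces())
job = JobSpec(523_449, 73_102_023)

best = solve_homogeneous(job, 4096, model_v)
print(best.m, best.n, best.database_fragment, best.query_fragment,
      round(best.predicted_seconds, 2))
# 3 1365 174483 53555 91.23

factors = load_reference_scale_factors()["II"]
model_ii = scale_model(model_v, factors)
cluster = [
    NodeTypeProfile("II", 2048, default_performance_factor(factors), factors),
    NodeTypeProfile("V", 2048, 1.0),
]
plan = solve_heterogeneous(job, cluster, {"II": model_ii, "V": model_v})
print(format_plan_table(plan))
```

which prints

```
  type  nodes     m      n        D_i        Q_j        quota    pred(s)  idle
------------------------------------------------------------------------------
    II   2048     3    682     174483      44075     30058496     106.68     2
     V   2048     3    682     174483      63116     43044864     108.95     2
overall predicted cost: 108.95 s
```

Reading the output: on the homogeneous cluster the optimizer picks 3
database fragments × 1,365 query fragments (sub-jobs of 174,483 × 53,555
sequences, predicted 91.23 s each). On the mixed cluster the slower type
receives a 30,058,496-sequence query quota (about 41%) against 43,044,864
for the faster type, each type then splits its quota 3 × 682, and the
predicted wall clock is the slower of the two sides, 108.95 s. Two nodes
per type sit idle because 3 × 682 = 2,046 < 2,048; the planner reports
rather than hides them.

The same pipeline is available from the shell:

```sh
blastbalance synth --kind measurements --out grid.tsv
blastbalance fit grid.tsv --component func_c --out model.json
blastbalance plan -D 523449 -Q 73102023 -P 4096 --model V model.json
blastbalance split db.fasta --parts 3 --out-dir frags/
blastbalance manifest plan.json --db-fragments dbs.json \
    --query-fragments qs.json --dbseqnum 523449 --out run.sh
```

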