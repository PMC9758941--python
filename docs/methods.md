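# Methods

## Problem and model

A BLAST job is characterized by two integers: D database sequences and Q
query sequences. Splitting the inputs into m database and n query fragments
yields m·n independent sub-jobs of size (⌈D/m⌉, ⌈Q/n⌉); because all
sub-jobs start together and the result is ready when the last one ends, the
cost of a fragmentation is the maximum predicted sub-job runtime. The
planner therefore needs a per-node-type runtime predictor T_k(D_i, Q_j),
and everything else is search.

Three predictor kinds are implemented:

* **Constant performance model (cpm)** — T = D_i/s with a constant speed s
  in sequences/second. Appropriate when per-function runtime ratios between
  node types are stable across problem sizes, which is what the shipped
  factor table shows.
* **Functional performance model (fpm)** — T = D_i/s(D_i), with s a
  piecewise-constant function of the database size given as a sorted
  `(max_size, speed)` table. Sizes beyond the last bin are a hard error
  rather than an extrapolation.
* **Quadratic surface sum** — the package's main model. Each profiled
  component (overall wall clock, or the five hot functions of the search
  loop) gets a bivariate quadratic
  T(D, Q) = c1·x² + c2·x·y + c3·y² + c4·x + c5·y + c6, with y = Q_m (query
  sequences in millions) and x = D_m or log(D_m). The model prediction is
  the sum of the component surfaces.

### Conventions that matter

* **Input scale.** Sizes enter the surfaces in millions of sequences. This
  is fixed, not configurable: the shipped reference coefficients are only
  meaningful under it.
* **Log base.** The log-axis option defaults to the natural log and the
  base is stored with every surface. Fitting is invariant to base (the
  choice is absorbed by c1, c2, c4), but *evaluating published
  coefficients* is not, so serialized models record the base explicitly.
  The shipped reference surfaces assume natural log; their source does not
  state the base, and this assumption is recorded in the data file.
* **Clamping.** A quadratic fitted to positive runtimes can dip below zero
  near the domain edge; the shipped prefetch surface (func_e), for
  instance, is negative at mid-size inputs. Rather than crash the
  optimizer, evaluations at or below zero return a configurable floor
  (default 0.001 s) plus a flag. The floor keeps the candidate ordering
  total; it is deliberately tiny so it never wins a comparison it should
  not.
* **Replicates.** Repeated measurements at the same (D, Q) are averaged
  arithmetically before fitting, matching how profiling campaigns average
  their trials.
* **Threads.** Multithreading is handled by a user-supplied divisor table
  (thread count → measured speed-up), not modelled inside the surfaces:
  measured surfaces keep their shape across thread counts, so folding
  threads into the quadratic would add parameters without information.
  A missing divisor is an error, never an implicit 1.0.
* **Overall vs. component models.** Both a single `overall` surface and a
  sum of per-function surfaces are supported; which to use is the caller's
  choice when assembling the `PerformanceModel`. The two views are not
  numerically reconciled against each other.

### Fitting

`fit_surface` builds the six-column design matrix [x², xy, y², x, y, 1] and
solves ordinary least squares via `numpy.linalg.lstsq`. Preconditions: at
least six distinct (D, Q) points and a full-rank design; a rank-deficient
design (e.g. a single database size, which makes every x-column collinear
with the intercept) raises an error naming the offending term. The report
carries RSS, R², residuals and an ill-conditioning flag (condition number
above 1e8).

### Node-type scaling

A node type is reduced to its per-component runtime ratios against a
reference type. `scale_model` multiplies each component surface's six
coefficients by the component's factor; since the surface is linear in its
coefficients, predictions scale exactly. The scalar speed s_k used for
quota apportionment defaults to the reciprocal of the mean of a type's
function factors (a type whose functions take 1.4× as long runs ~0.7× as
fast) and is overridable, because a site may prefer a benchmark-derived
speed.

## The planning algorithms

**Candidate set.** For P nodes, the candidates are (m, ⌊P/m⌋) for every
m in 1..P, deduplicated. This includes all exact divisor pairs plus
near-miss pairs such as (3, 1365) at P = 4096 that idle a few nodes but can
still minimize the cost; idle counts are reported in the plan.

**Fragment sizes.** Ceiling division: the first parts−1 fragments hold
⌈total/parts⌉ sequences, the last absorbs the remainder; sizes sum exactly
to the total. Requesting more fragments than sequences yields trailing
empty fragments with a warning — deliberately not an error, so file
arithmetic stays aligned with plans.

**Homogeneous solve.** Exhaustive evaluation over the candidate set (at
most P candidates; microseconds at P = 4096). Ties prefer larger n, then
smaller m: reducing the query fragment is the consistently more effective
direction, and tie-breaking should not contradict that.

**Heterogeneous solve.** Only the query is divided between types: the full
database goes to every type, each type k receives a quota
Q_k = q_k·P_k with q_k = ⌈(W_k/ΣW)·Q/P_k⌉ and W_k = s_k·P_k, then each type
is solved as a homogeneous cluster over (D, Q_k). Rounding is per-node and
upward, so quotas always cover Q with an overshoot below one sequence per
node; that overshoot is the price of integer per-node work assignments.
Plan cost is the maximum per-type predicted time.

## FASTA handling and manifests

Splitting is by record count only — the one property of an input a user
can be assumed to know — never by residue count or content. The reader is
a minimal streaming parser holding one record in memory; records pass
through verbatim (line endings, wrapping, header whitespace untouched), so
concatenating the fragments reproduces the source bytes exactly. This
byte-fidelity is the module's contract and the reason a re-formatting
FASTA library is not used here.

Manifests expand a plan into one `blastn` command per (database fragment,
query fragment) pair per node type, as a flat shell script, an SGE array
job, or JSON. Every command carries `-dbseqnum <D>` with D the pre-split
database sequence count: E-values scale with the effective database size,
and a sub-job left to default to its fragment's size would report wrong
statistics. Output merging across sub-jobs is out of scope.

## Synthetic data

The generator module defines the test conditions:

* **Measurement grids** default to the study geometry this package is
  benchmarked against: database sizes {8,179 … 261,725} (six points) ×
  query sizes {17,848 … 1,142,220} (fifteen points), with observations
  value·(1 + N(0, σ)) floored at zero and σ defaulting to 0 (noise studies
  use σ = 0.05 with three replicates, mirroring triple-trial averaging).
* **FASTA files** use uniform-random sequences of 90–150 bp over ACGT
  (metagenomic short-read lengths). Content realism is irrelevant: the
  package counts and splits records, it never aligns them, so passing
  tests say nothing about BLAST runtimes on real sequence content.
* **Profiler fixtures** render one consistent specification (total
  seconds, five stage fractions, five function fractions) into the three
  text formats the parsers consume.

Because the two shipped log-axis surfaces are negative over the
small-database corner of the study grid (physically impossible runtimes
the generator floors at 0), parameter-recovery checks probe them on a 6×15
grid inside their positive region (databases 523k–4M sequences, same query
sizes). The identity-axis surfaces are positive on the study grid and use
it unchanged.

## Known limitations

* **Noisy coefficient identifiability.** With 5% multiplicative response
  noise, OLS on the 6×15 grid pins down only the strongly contributing
  coefficients (the x·y and y terms recover within 10% essentially
  always). Weakly contributing terms — e.g. a y² term peaking near 0.5% of
  the surface value — sit below the noise floor and cannot be recovered to
  10% from this design, no matter the estimator; the corresponding
  acceptance check is stated at its nominal threshold and fails, by
  design honestly rather than by a loosened bound. Predictions, as opposed
  to coefficients, are well-conditioned (see the prediction-accuracy
  test).
* **Static only.** Plans are computed once, ahead of execution; there is no
  re-balancing, migration or monitoring of running sub-jobs.
* **Count-based partitioning.** Fragments equalize sequence counts, not
  residue counts or content difficulty; skewed sequence lengths will skew
  sub-job runtimes.
* **No scheduler integration.** Manifests are written, never submitted;
  compiling or running BLAST itself is outside the package.
* **Idle nodes.** When m·n < P the surplus nodes are reported idle; no
  work-stealing or fractional assignment is attempted.
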