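# Methods

## Model

The niche is treated as a mean field: the combined structural, biochemical
and biophysical cues acting on a stem cell are summarised as sustained
activation or inhibition of signalling pathways, not as individual
time-resolved ligand events. Under that premise, the question "which
intracellular nodes mediate the niche's influence?" becomes a question about
long-run flux through the signalling interactome.

### Expression-weighted Markov chain

The interactome is a signed directed graph with nodes labelled by layer
(receptor / intermediate / TF). For each sample (a bulk replicate or a
single cell) a finite, discrete-time, time-homogeneous Markov chain is built
over the network nodes. The unnormalised weight of edge *i → j* is
*w<sub>ij</sub>* = *E<sub>i</sub>E<sub>j</sub>* (expression of both
endpoints), and rows are normalised to give the transition matrix *P*. The
product form has two consequences we rely on:

* flux vanishes through unexpressed nodes in either direction, and
* for an expressed source the row reduces to the out-neighbour expression
  share *E<sub>j</sub> / Σ<sub>k</sub> E<sub>k</sub>* — so *P*, and hence
  everything downstream, is invariant to global rescaling of the expression
  matrix (normalisation units do not matter).

The weight function is pluggable (`product`, `target` = *E<sub>j</sub>*
alone, `min`); `product` is the default.

Two conventions make the chain well-behaved:

* **Dangling / zero-weight rows.** Nodes with no out-edges (terminal TFs)
  or whose out-neighbours are all unexpressed get a uniform jump row,
  the standard dangling-node treatment in PageRank-style chains. We
  initially evaluated a self-loop convention and rejected it: under
  single-cell dropout a self-loop makes every transiently unexpressed node
  absorbing, so the per-cell stationary distribution mostly encodes *which
  nodes trapped the walker in that cell* — a function of the dropout mask,
  not of signalling flux — and averaging across cells then ranks
  low-out-degree baseline nodes above genuinely high-flux nodes. The
  uniform jump is rank-neutral: it returns the trapped mass to the chain
  without favouring any node.
* **Teleportation.** *P′* = (1 − β)*P* + β/n with β = 0.01 guarantees a
  unique stationary distribution on reducible or periodic graphs. β is
  configurable; 0.01 is small enough that π is dominated by the
  expression-weighted structure.

The stationary distribution π (πP′ = π, Σπ = 1) is computed by one of three
interchangeable solvers: direct linear solve (default; exact at the sizes
involved), power iteration from a uniform start (tolerance on the L1 step
change), or a seeded Monte Carlo walk whose visit frequencies estimate π.
The three agree on ergodic chains (power vs direct < 1e−8 L1; Monte Carlo
≈ 1e−3–1e−2 L1 at 10⁶ steps) and the cross-check is part of the test suite.

Per-sample π vectors are aggregated to a condition-level π by element-wise
mean (median available) and renormalised; the per-node standard deviation
across cells is retained for the heterogeneity report. **Hotspots** are the
intermediate-layer nodes whose condition π reaches the chosen percentile
(default 90) of the intermediate π distribution; ties at the threshold are
all included, and ordering is deterministic by (−π, node id). Receptors and
TFs are excluded from hotspot candidacy — receptors are inputs and TFs are
the read-out layer — but appear in the full π tables so that, e.g., a
receptor-level ranking can still be inspected.

### Compatibility scoring

High π says a node *could* carry flux; it cannot say whether the node's
activity is consistent with the observed phenotype, because signalling
activity is post-translational. The signature of differentially expressed
TFs (direction only, condition A relative to B) supplies that constraint.

For a (node, TF) pair, all minimum-hop directed paths from the node to the
TF are enumerated (BFS distance labelling, then backward enumeration over
the shortest-path DAG; enumeration is capped at `max_paths` = 10 000 with a
warning, since shortest-path counts can grow combinatorially on dense
graphs). Each path gets:

* a **sign**: the product of its edge signs (+1 activation, −1 inhibition);
* a **relative contribution Ω**: the geometric mean of π over its interior
  nodes (direct edges weigh 1), normalised to sum 1 over the pair's path
  set. The geometric mean was chosen over the plain product because all
  shortest paths for a pair have equal length and the product would merely
  shrink with length elsewhere; both, plus an arithmetic-mean variant, are
  exposed via configuration. If every interior weight is zero, Ω falls
  back to uniform with a warning.

A path is *compatible* when its sign matches the TF's direction (+1 with
up, −1 with down). The pair score is the Ω mass of compatible paths. The
two sign classes partition the path set, so score(up) + score(down) = 1
exactly — the implementation computes the down-score as the complement of
the activating mass, which makes the identity hold to the last bit.

Signature TFs absent from the interactome are scored through interactome
TFs that regulate them via exactly one GRN edge; the GRN edge sign
multiplies the path sign. With several such regulators, Ω is normalised
within each (node, regulator) route and the per-route scores are averaged.
Longer GRN chains are out of scope.

The node-level score is the unweighted mean of its defined pair scores.
Unreachable TFs are *excluded* from the mean rather than scored 0: no path
is absence of evidence, not contradiction. Calls: active above 0.5,
inactive below, indeterminate at exactly 0.5, unreachable when no signature
TF has a path. The 0.5 threshold mirrors how compatibility scores of
≈ 0.3 are read as inactive and ≈ 0.7 as active in practice.

### Two-condition comparison

`compare_conditions` runs the full pipeline per condition. The signature is
A-relative, so directions are flipped for condition B. The hotspot sets of
the two conditions are pooled and every pooled node is scored under **each
condition's own π** (the natural choice, since Ω is meant to reflect that
condition's flux), producing per-condition pair and node tables plus a
joint score-difference table. With identical expression in both conditions
the construction forces score_B = 1 − score_A for every fully scored node.

## Synthetic scenarios

The generator emulates the study design the pipeline targets: two
conditions whose difference is a sustained pathway activation.

* **Topology.** A strictly layered DAG (default 60 nodes, 4 layers:
  receptors, two intermediate tiers, TFs; every node on at least one
  receptor→TF route; extra forward edges with probability 0.3, giving mean
  total degree ≈ 6, comparable to curated signed signalling interactomes).
  Signs are random ±1 except where cascades are planted.
* **Planted truth.** One all-activating cascade receptor→…→TF (the last
  intermediate is the *driver*; its TF is up in the signature) and one
  *decoy* cascade, equally highly expressed, whose final edge is inhibitory
  while its TF is also up — every decoy path contradicts the signature by
  construction. The two cross edges that would blur the planted truth
  (driver→decoy-TF, decoy→planted-TF) are excluded during generation. One
  GRN-only TF regulated by the planted TF exercises the GRN scoring route.
* **Expression.** Condition A expresses both cascades at 10× a baseline
  mean of 5 (a typical normalised-count scale); condition B is all
  baseline. Bulk mode draws mean-preserving log-normal values with the
  requested coefficient of variation. Single-cell mode draws Poisson
  counts with log-normal rate heterogeneity, then applies Bernoulli
  dropout (default 0.3) per entry. Everything derives from one numpy
  PCG64 generator, so scenarios are byte-reproducible from the seed.

What the generator does **not** emulate: real transcriptome-wide gene
counts (only network genes are simulated), correlated dropout or
library-size variation, feedback loops and crosstalk cycles, post-
translational regulation that decouples activity from expression, or any
particular tissue's interactome. Passing the planted-truth tests therefore
demonstrates that the inference machinery is sound under the stated
generative model — not that predictions on a real interactome and RNA-seq
data set are biologically correct.

## Numerical choices and problem sizes

* Row-stochasticity is enforced to 1e−10; the stationary fixed point to
  ‖πP′ − π‖₁ ≤ 1e−8 (the direct solve typically reaches ~1e−15).
* Power iteration defaults: tol 1e−10 on the L1 step, max 100 000
  iterations; non-convergence raises an error carrying the last residual.
* Monte Carlo requires an explicit seed (default 0), recorded in the run
  manifest along with the RNG algorithm.
* Ties in hotspot selection are kept; ties in the activity call are
  reported as indeterminate rather than forced to a side.
* Degenerate inputs: an all-zero expression column is a hard error; an
  empty hotspot set produces empty reports with a warning and exit code 0;
  contradictory duplicate interactome edges keep the inhibitory sign
  (conservative for compatibility) with a warning.
* Test and acceptance workloads use networks of ≤ 200 nodes, 100-replicate
  scenario batches and 10⁶-step Monte Carlo runs — sizes at which the
  direct solver is exact and the whole suite completes in well under a
  minute, while still exercising every code path at realistic scale.

## Known limitations

* Compatibility considers only minimum-hop paths; slightly longer paths
  carry no weight even when their π support is strong.
* The GRN extension is one edge deep by design.
* Aggregating π across cells before hotspot selection (the default) can
  mask bimodal subpopulations; the per-cell heterogeneity report (π and
  score dispersion, per-cell hotspot frequency) is the intended diagnostic,
  and median aggregation is available.
* Whether receptors may themselves be hotspots is a modelling choice; here
  they are excluded and reported separately via the π tables.
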