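# Methods

This note documents the models behind temponet, the parameters that matter,
the synthetic data the tests run on, and the numerical choices made where
the design was genuinely open.

## Study design emulated

The pipeline targets longitudinal two-omics designs: miRNA and mRNA
expression from the same subjects at T post-insult time-points (default
labels 24h, 72h, 10d, DOFS, Chronic) with R biological replicates each
(default 3, so 15 non-control samples), plus a single control group
(default 3 samples) used only for differential-expression calling. Control
samples never enter the network models; the model input at each time-point
is the 15 non-control samples.

## Synthetic data generator

`simulate.generate_scenario` plants a directed regulatory network over
miRNA and mRNA nodes and `simulate_expression` samples from the implied
linear-Gaussian structural equation model (SEM): evaluating nodes in
topological order,

    x_v = baseline(v, t) + Σ_{u ∈ parents_t(v)} β_uv · x_u + ε_v,
    ε_v ~ N(0, σ_v²).

Design choices and defaults:

* **Linear-Gaussian family** — chosen for self-consistency with the
  Gaussian-BIC learner, so structure-recovery tests have a well-defined
  target. The implied per-time-point covariance `(I−A)⁻ᵀ D (I−A)⁻¹` is
  exposed (`implied_covariance`) and verified against sample covariances.
* **Acyclicity by construction** — edges are sampled respecting a random
  topological order over all nodes, so every per-time-point active edge set
  is a DAG.
* **Edge coefficients** — magnitudes uniform in [0.5, 1]; miRNA→mRNA edges
  negative (repressive) with probability `frac_repressive` (default 0.8),
  other edge types random sign.
* **Time-point specificity** — each edge is active everywhere or, with
  probability `frac_timepoint_specific` (default 0.5), at a random proper
  non-empty subset of time-points.
* **Differential expression** — each (node, time-point) receives a ±5 σ
  baseline shift with probability 0.4. Five noise-sd units is the effect
  size at which a 3-vs-3 Welch test retains power after BH correction;
  smaller planted shifts would make the stand-in DE engine, not the network
  method, the bottleneck of every downstream test.
* **Controls** — a separate condition with zero baselines and all planted
  edges inactive.

What the generator does **not** emulate: count noise (no negative-binomial
read model), library-size or depth effects, batch structure, and the
correlated biological replicate structure of real animals. Passing tests on
this generator therefore demonstrate that the inference machinery recovers
the structures it is designed for under its own model assumptions — not
that those assumptions hold for any particular sequencing dataset.

## Differential expression

The stand-in DE engine is a Welch two-sample t-test (time-point replicates
vs control replicates) with Benjamini–Hochberg correction applied
separately within miRNAs and within mRNAs (the two families are measured by
different assays and analysed separately throughout). The pipeline treats
DE tables as an interface: tables produced by count-based engines can be
supplied instead via `preprocess.read_de_table`.

## Bi-clustering

DE mRNAs × time-points form a bipartite response graph: gene g is linked to
condition c when the replicate-averaged standardised response |z̄_gc|
exceeds `response_threshold` (default 1.0). A module (G, C) is scored by the
log-likelihood-ratio weight with module edge probability `p_module = 0.9`
against a null `p_0` clipped to [0.02, 0.5] at the observed graph density.
Because the weight is separable, the search alternates optimal-gene-set and
optimal-condition-set updates from single-condition and condition-pair
seeds until a fixed point; this monotonically increases the weight.

Choices:

* **Modules span ≥ 2 conditions** (`min_conditions = 2`). A single-condition
  "module" is only that condition's responder list; with a log-likelihood
  weight it can outscore genuine cross-condition blocks, so it is excluded
  by default.
* **Overlap filter** — greedy acceptance by descending weight; overlap
  fraction is |intersection| / |smaller gene set|, threshold 0.10. The
  convention (relative to the smaller set) is stated because upstream tools
  leave it undocumented.
* **Condition granularity** is the time-point (replicate-averaged response),
  giving 5 condition columns in the default design.

## Bayesian network structure learning

Per time-point, the model input is the z-scored (population 1/n sd) matrix
of DE miRNAs ∪ bi-clustered mRNAs over the 15 non-control samples.
Z-scoring is performed after subsetting to those samples.

**Scoring.** Gaussian BIC in bnlearn's convention: for child v with parent
set P, an OLS fit with intercept gives the ML residual variance σ̂², and

    family(v|P) = −(n/2)(log 2πσ̂² + 1) − ((|P|+2)/2)·log n.

The network score is the sum of family scores (decomposability). Scores are
computed from the centred cross-product matrix, making each candidate move
a small linear solve independent of n. Collinear parent sets score −∞.

**Search.** Greedy hill climbing over single-arc additions, deletions and
reversals from the empty graph, ties broken by move kind then lexicographic
(parent, child). Because single-arc moves cannot reorient a collider
(v-structure) in one step, the search restarts from `restarts = 20` sparse
random DAGs (arc probability ~2/p along a random topological order, drawn
from a generator seeded by the learn config) and keeps the best local
optimum. On 3-variable Gaussian data this attains the exhaustive-search
optimum (25 DAGs) in all seeded tests; on 4 variables (543 DAGs) in ≥ 90% —
hill climbing can still hit deep local optima, which is recorded rather
than hidden.

**Degrees-of-freedom guard.** A family needs at least one residual degree
of freedom; `hill_climb` therefore never allows more than n − 3 parents.
Without this, at n = 15 the ML variance collapses as |P| → n − 2 and the
score diverges, producing saturated, meaningless fits. The pipeline
additionally defaults to `max_parents = 3` for the 15-sample design
(≥ 10 residual df per family); at n = 200 recovery tests this cap is
inactive.

**Bootstrap arc strength.** Samples (columns) are resampled with
replacement B times (default 1000, the analysis default; tests and examples
scale B down to 25–200 to keep runtimes in seconds-to-minutes); each
resample is re-learned (without restarts — averaging over B resamples
already smooths local-optimum noise, and restarts would multiply the cost).
Degenerate resamples in which a variable becomes constant are re-drawn and
logged.

* **Strength definition** (default `"undirected"`): the frequency of the
  skeleton edge across the B structures, reported on its majority
  orientation. Rationale: the orientation of a covered edge is arbitrary
  within a Markov equivalence class, so directed frequencies split between
  the two orientations bootstrap-by-bootstrap and true edges get diluted;
  the skeleton frequency is the stable quantity. `"directed"` (frequency of
  the exact directed arc) is available.
* **Edge set** (default `"consensus"`): the returned network's edges are
  those of the structure learned from the full, un-resampled data, each
  annotated with its bootstrap strength. The full table of every arc ever
  observed in the bootstrap (`"observed"`) is available, but its strength
  distribution is dominated by hundreds of one-off arcs, which makes a
  quartile-based cut uninformative.

**Quartile filter.** The threshold is the 0.75 sample quantile (linear
interpolation, numpy's default definition) of the positive strengths at
that time-point; arcs with strength ≥ threshold are retained and the
threshold is recorded. Under the recovery conditions used in the acceptance
suite (10 miRNA + 30 mRNA, 30 planted arcs, |β| ∈ [0.5, 1], n = 200,
B = 100) this yields mean skeleton precision ≈ 0.99 and recall ≈ 0.87 over
10 seeds. At the study's real sample size (n = 15) recovery is reported by
the acceptance script but not gated: precision drops to ≈ 0.2–0.3,
documenting the small-sample regime honestly.

## Network statistics

Degree is in + out degree over retained arcs. Betweenness is unweighted
shortest-path betweenness on the directed graph, unnormalised, all shortest
paths counted (networkx implementation; an exhaustive all-pairs path
enumeration serves as the oracle in tests); an undirected option exists
because published analyses often do not state the choice. The β-index is
#edges/#nodes with isolated entities excluded from the node count. Overlap
reports give both exclusive-intersection (upset) counts — which sum to the
union — and plain pairwise intersections, since prose "shared" counts in the
literature usually mean the latter. Top-k% labelling uses a rank cutoff
with ties included.

## Prioritisation

"Inferred mRNA targets" of a miRNA are its direct retained miRNA→mRNA arcs
(two-hop effects excluded). The cascade: (1) drop miRNAs with no inferred
target at any time-point; (2) drop those without a human orthologue (the
orthology map is an input, not computed); (3) keep those with targets at
≥ 2 time-points ("multiple" = at least two); (4) keep those whose seed (nt
2–8, 1-based inclusive, U/T-unified, case-insensitive) is identical between
the rat and human mature sequences. Gene-symbol cleanup drops symbols
containing "." or prefixed LOC/RGD and applies a rat→human synonym map
(shipping defaults: Cecr6→TMEM121B, Pnmal2→PNMA8B, Oasl2→OASL). Resource
annotation joins on (human miRNA id, gene symbol) and only ever adds
columns. The degree heat map z-scores per-miRNA target counts across the
time-points where the miRNA has targets (zero-target cells are missing;
rows with < 2 defined cells or constant counts are flagged
non-normalisable).

`resources.generate_resources` fabricates internally consistent synthetic
orthology maps, mature sequences, prediction tables (planted miRNA→mRNA
edges enriched and up-weighted in confidence), validation/iCLIP lists and
human-DE lists so the cascade and joins run end to end on simulated data.
The mature-sequence FASTA under `tests/data/` is likewise a constructed
fixture, not a database export.

## Reproducibility

Every source of randomness is seeded. The pipeline derives one independent
stream per stage from the master seed (`numpy.random.SeedSequence.spawn`),
so each stage is reproducible regardless of execution order; re-running with
the same seed is bit-identical. A run manifest records the package version,
configuration (with hash) and the derived stage seeds.

## Known limitations

* Hill climbing is a local search; the restart mechanism makes small-p
  optima reliable but gives no global guarantee at realistic sizes.
* At n = 15 the networks are exploratory: bootstrap strengths and the
  quartile filter control, but do not eliminate, instability.
* The bi-clustering search is a greedy maximiser of the stated weight, not
  a reimplementation of any specific published tool; its module lists will
  differ from theirs.
* The stand-in DE engine ignores count structure; for real sequencing data,
  use a count-based engine and import its table.
* Orthology and biotype information are inputs; the package performs no
  sequence-based target prediction.
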