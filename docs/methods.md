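# Methods

This note documents the models and procedures implemented in `volvoloss`, the
defaults that matter, the numerical conventions, and what the synthetic-data
generators do and do not emulate.

## Threshold-network model of gene deletion and duplication

### Model

`N` genes carry expression states `S_i ∈ {−1, +1}` (0 is reserved for deleted
genes). Dynamics are synchronous:

    S_i(t+1) = σ( Σ_j w_ij S_j(t) ),

with `w` an `N×N` real matrix of interaction weights and `σ` the sign
function. Nonzero weights are drawn i.i.d. N(0, 1); the connectivity `c` is
the probability that an entry is nonzero (independent Bernoulli mask; an
exact-count mask is available via `exact_count=True`). A *viable network set*
`(S(0), w, S_eq)` consists of uniformly drawn initial and target states and a
matrix `w` accepted by rejection sampling when the trajectory from `S(0)`
reaches a fixed point exactly equal to `S_eq` within `max_iters = 100`
updates. Trajectories that fail to fix within the budget (limit cycles) are
non-viable.

Perturbations:

- **deletion** of `k` genes zeroes their rows and columns of `w` and pins
  their state to 0 from `t = 0` (they cannot influence anything — their
  columns are zero — so the pinned value only affects Hamming bookkeeping;
  `deleted_state=-1` switches to the off-state convention).
- **duplication** of `k` distinct genes appends indistinguishable copies:
  `w'[a, b] = w[src(a), src(b)]` under the index map
  `src = (1..N, duplicated indices)`, and `S_{i'}(0) = S_i(0)`. A copy and
  its original then have identical states at all times.

A perturbed trial is **novel-stable** when it converges and the new
equilibrium differs from `S_eq` in more than the forced positions: `d_h > k`
for deletion (the `k` zeroed genes always differ from their old `±1` values),
`d_h > 0` over the original `N` genes for duplication.

### Conventions and choices

- `σ(0) = +1`. Ties have probability zero under dense Gaussian weights but do
  occur after deletions and under sparse masks; a fixed convention keeps runs
  deterministic.
- Non-converged perturbed trials stay in the denominator of
  `proportion_novel_stable` and are reported via `n_nonconverged`, so either
  normalization is recoverable from the outputs. **The directional
  comparison** between deletion and duplication in the tests and the
  acceptance script uses the proportion of novel stable states *among
  converged trials* — "novel stable states among stable outcomes" — because
  deletion both produces more novelty among stable outcomes and destabilizes
  more trials outright, and the all-trials ratio conflates the two effects
  (at `k ≤ 3` they cancel almost exactly; see Limitations).
- Random streams: one master seed; per-(mode, k, connectivity) substreams
  derived by `SeedSequence` spawn keys, so a `k`-sweep reproduces any of its
  members run alone.

### Vectorized viability sampling (exact)

Sequential rejection toward a pre-drawn target is expensive (`≈ 2^N` draws
per acceptance). Two symmetries make an exact batched scheme possible: the
weight law is invariant under gauge conjugation `w → GwG`, `G = diag(g)`,
`g ∈ {−1,+1}^N` (which maps trajectories of `(S0, w)` to `(gS0, GwG)` with
states `g·S(t)`) and under simultaneous row/column permutation. Hence the
probability that a random `w` carries `S(0)` to a prescribed `S_eq` depends
only on `m = d_h(S(0), S_eq)`. The sequential sampler is therefore exactly
emulated by drawing each trial's `m ~ Binomial(N, 1/2)` and filling the
`m`-strata from batched free-running draws `(S0, w) → eq(S0, w)` conditioned
on convergence. Strata that stay unfilled past the per-trial rejection budget
(`max_rejection_attempts`, default 10⁴) have their `(S(0), S_eq)` pair
redrawn — the same stall rule the sequential sampler needs for unreachable
targets (e.g. `N = 1`, `S(0) = +1`, `S_eq = −1`).

The public `sample_viable_network` implements the literal sequential
contract; `run_ensemble` uses the batched engine. Both are covered by the
fixed-point contract test, and `N ≤ 3` dynamics are verified against
exhaustive enumeration of the full state space.

### Modular topology

`sample_modular_adjacency` is a stand-in generator for topologies that mimic
empirical gene networks: near-equal contiguous modules (default
`p_in = 0.8`, `p_out = 0.05`, optional overlapping membership), scaled
entrywise by N(0,1) weights. It reproduces the qualitative feature that
matters here — dense within-module, sparse between-module interaction — not
any specific empirical degree sequence.

## Copy-number trend detection

Per group, ordinary least squares of copy number on tip-to-LCA distance over
**all** species (zero counts are data; sparsity is handled by eligibility,
not by dropping points). Eligibility: nonzero count in ≥ 2 species and
non-identical counts. Outlier calling: type-7 quartiles, Tukey fences at
`1.5·IQR` (multiplier configurable). No per-group p-value is attached:
"significant" contraction/expansion *means* outlier status. Distances come
from summing branch lengths root-ward of each tip up to the in-group MRCA of
a user-supplied rooted Newick tree.

## Synteny-anchored loss classification

- **Anchor selection**: anchor-species genes of contracting groups; loci on
  unplaced scaffolds are excluded (with a recorded reason).
- **Neighborhood**: up to `window = 5` genes per side (the window is
  config-exposed and recorded in outputs; results at toy scale are
  insensitive to it between 3 and 10).
- **Interval mapping**: requires ≥ 1 upstream and ≥ 1 downstream neighborhood
  ortholog on one target scaffold with the two flank groups separable along
  it (all upstream orthologs on one side of all downstream ones). Strand and
  within-flank order are ignored — local inversions are tolerated. The
  weakest rule that still bounds a search interval; anything less leaves the
  search unanchored. The interval runs between the innermost flanking
  orthologs, intergenic sequence included.
- **Calls**: `retained` is decided from the ortholog table alone (no sequence
  check). Otherwise: unmappable neighborhood → `non_informative`; translated
  hit with `E < 1e−5` → `decayed`; else `deleted`. Multi-copy anchors are
  called independently per anchor gene.
- **Patterns**: the bin is the species subset with losses; `cryptic` means
  the subset is not a single clade of the species tree (one loss event does
  not explain it). Cluster labels: `retained_all` (no losses),
  `decayed_cluster` (≥ 1 decay call), `deleted_cluster` (all losses are
  deletions).
- **χ² goodness of fit**: uniform expectation, no continuity correction,
  `df = cells − 1`. The operation is generic; the pipeline applies it to
  decay-vs-deletion counts.
- Coordinates are 1-based closed (GFF3 convention) in all tables.

## Translated search engine

Six-frame translation of query and subject (standard code, `N`-codons → `X`,
trailing partial codons dropped), BLOSUM62 Smith–Waterman local alignment
with affine gaps (NCBI convention: a gap of length `L` costs
`gap_open + L·gap_extend`, defaults 11/1), statistics
`bits = (λS − ln K)/ln 2`, `E = K·m·n·e^{−λS}` with ungapped BLOSUM62
parameters `λ = 0.3176` nats, `K = 0.134`, and `m, n` the translated lengths.

Approximations, deliberate and documented:

- Ungapped `λ, K` applied to gapped scores, raw lengths without edge-effect
  correction. The engine's contract is **internal consistency** — the decay
  fixtures are calibrated against this engine — not score parity with any
  external BLAST implementation.
- Alignments never cross stop codons: each frame is split at stops and the
  segments aligned independently. Decayed remnants are expected to carry
  premature stops, and this mimics translated-search behavior without
  stop-penalized extension logic.
- No seeding heuristics: subjects are single syntenic intervals, so full
  dynamic programming at `O(mn)` per frame pair is affordable. Segment pairs
  too short to reach the threshold score at the maximal diagonal score are
  skipped (an exact bound, not a heuristic).
- Background calibration: on random 300-nt pairs at threshold `e = 0.1`, the
  mean hit count per pair stays below the 36-frame-pair multiplicity of the
  single-comparison expectation (`36·e`); the per-comparison expectation is
  approximate because all frames of one sequence share composition.

## Synthetic data

### Count matrices

`count[g, s] ~ Poisson(max(0.01, baseline_mean + β_g · d_s))`. Defaults: 6
species with equally spaced tip-to-LCA distances 0.02–0.42 substitutions/site
(a ladder phylogeny from a unicellular anchor to the most derived tip), 2% of
groups contracting and 2% expanding at
`|β|·range(d) = 5·√baseline_mean`, `baseline_mean = 25`. The baseline is the
unique scale at which such a contraction runs from `baseline` to ≈ 0 copies
across the range without truncation by the mean floor — i.e. the planted
contraction is "a large multi-copy family (histone-like) going extinct". The
floor (ε = 0.01) keeps the Poisson mean valid where the linear predictor goes
negative.

Power note: the planted slope sits ≈ 4.2 neutral-slope-SDs from zero while
Tukey fences sit at ≈ 2.7, so contracting groups (whose Poisson noise shrinks
along the trend) are recovered at ~96%, but expanding groups (noise grows
with the mean, slope-SD inflated ~1.25×) only at ~80–90%. This asymmetry is a
property of Poisson noise at this effect size, not of the estimator.

### Toy genomes

An anchor genome of random ORFs (ATG + stop-free body + stop; default 300
codons) separated by 150-nt random spacers, 2 chromosomes × 30 genes. Each
derived species copies the anchor gene order (synteny is exact), applies
i.i.d. per-site neutral substitutions at `neutral_rate`, then applies planted
events: **retain** (keep gene + annotation + ortholog-table row), **decay**
(truncate to `remnant_fraction = 0.6`, inject 2 frameshifts and 2 premature
stops, leave the remnant in the DNA but *remove it from the GFF3 and ortholog
table* — exactly the evidence state the classifier confronts), **delete**
(excise the locus, splice the flanking spacers). The default event table
retains even-indexed and chromosome-end genes in every species and draws
retain/decay/delete at 0.5/0.25/0.25 for the interior odd-indexed genes:
every tested locus is thereby guaranteed mappable retained flanks, so on
noise-free fixtures planted truth is recoverable exactly and classifier
errors measure the caller, not the fixture.

What the generator does **not** emulate: indels and rearrangements in neutral
evolution (substitution only, so decay signatures stay unambiguous at toy
scale), repeat content, gene structure (no introns/UTRs), realistic genome
sizes, or lineage-correlated loss events (events are i.i.d. per species, so
most multi-species loss patterns are cryptic by construction). Passing tests
therefore demonstrate correctness of the calling logic under clean synteny,
not performance on real assemblies with fragmented scaffolds or annotation
error.

### Trees

Ladder (caterpillar) topologies realizing requested tip-to-LCA distances:
species sorted by distance, internal edges `min(d)/(2n)`, tip branches making
each root-to-tip path exact. `distances_from_tree(make_tree(d)) = d` to
1e−6 (Newick text carries 10 significant digits).

## Pipeline

Stages (`synthetic → trends → classify_loss → simulate`) are sequenced by
`run_full_pipeline` from a validated YAML config (unknown keys are rejected
by name before anything runs). All artifacts are plain text; the manifest
records the config hash, seed, and a SHA-256 checksum per output. Reruns
under a fixed seed are byte-identical.

## Problem sizes used by the test suite and acceptance script

Network contrasts run at `N = 10`, `c = 1`, 1000 trials per `k` in the test
suite and 300 in the acceptance script (the deletion-floor check uses ~10⁴
converged trials); trend recovery uses 5000 groups × 6 species; the loss
caller runs the default 60-anchor toy fixture at neutral rates 0 and 0.05;
oracle checks use 100–200 random instances. These sizes give stable
statistics at seconds-to-a-minute cost per check.

## Known limitations

- At small `k` (≤ 3) the deletion-vs-duplication contrast on the *all-trials*
  normalization is null: deletion's extra novelty among stable outcomes is
  offset by its extra non-convergence. The effect the model supports is the
  converged-conditional one, and it emerges clearly only for `k ≥ 3–4`.
- Karlin–Altschul parameters are not re-estimated for the gapped, stop-split
  regime; E-values are internally consistent, not portable.
- The trend classifier attaches no uncertainty to individual rates; fence
  outliers at small species counts (n = 6 points per fit) are sensitive to
  single-species count fluctuations, as the ~80–90% expansion recovery shows.
- The loss caller trusts the ortholog table for retention; a mis-assigned
  ortholog masks a real loss (no sequence re-check by design).
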