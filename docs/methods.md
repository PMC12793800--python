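# Methods

## Scope and design

npbench evaluates the standard analysis stack of herbal network
pharmacology — multi-database network assembly, consistency scoring,
key-target identification, and network-based efficacy prediction — as a
library of tested operations. The live source databases (TCMSP, TCM-mesh,
BATMAN-TCM, SymMap, HERB and the like) are not scraped or redistributed;
a synthetic-data generator produces pseudo-database ensembles with the
statistical structure those analyses assume, so every claim the package
makes is a property of the *methods*, demonstrated under controlled
conditions, not a reproduction of any particular database snapshot.

Entities are keyed by `(namespace, value)` pairs: compounds as PubChem
CIDs, protein targets as Entrez Gene IDs (both positive-integer strings),
herbs/diseases/functions as opaque accessions. Only ID-mapped data enter
any analysis; unmapped rows are dropped with an enumerated report, never
silently or fuzzily matched. Edge multiplicity carries no meaning anywhere
in the formulas, so duplicate rows collapse at load time with a logged
count. Database intersection is computed at the association level (exact
edge match), matching how target information is actually intersected when
databases are combined.

## Synthetic study conditions

`SyntheticConfig` defaults define the study conditions; they were fixed
once, before any experiment, and are not tuned per test.

| parameter | default | rationale |
|---|---|---|
| n_herbs / n_compounds / n_targets | 30 / 120 / 200 | desk-scale tripartite network; every analysis runs in seconds |
| mean_compounds_per_herb | 8 | per herb, 1 + Poisson(7) compounds: right-skewed ingredient counts with no empty herbs |
| mean_targets_per_compound | 5 | same scheme on the CT layer |
| hub_exponent | 1.0 | linear preferential attachment; a few promiscuous hub compounds/targets, many specific ones |
| n_databases | 5 | matches the number of major sources an integration study would use |
| dropout_rate | 0.15 | per-database independent edge loss; chosen so databases disagree visibly but remain recognizable |
| spurious_rate | 0.1 (HC) | spurious edges per database relative to latent layer size |
| ct_noise_factor | 3.0 | CT-layer spurious rate = 0.3: target information in real sources is largely model-predicted and diverges far more across databases than ingredient lists do |
| known_ct_density / known_ht_density | 0.013 / 0.038 | the sparsity of curated compound-target and herb-target labels observed for real herbal data |
| disease_module_size / disease_locality | 12 / 0.8 | disease proteins cluster in PPI neighborhoods; locality 1 forces a connected module, 0 a random set |
| treatment_set_size | 8 | typical size of a curated target set for one preparation |
| ppi_attachment (BA m) | 3 | scale-free-like PPI with heavy-tailed degrees |
| α (diffusion restart) | 0.85 | standard restart probability for random-walk-with-restart methods; configurable |
| ε (diffusion tolerance) | 1e-6 | L1 convergence tolerance of the power iteration |
| n_perm (proximity null) | 1000 | permutation count for the degree-matched null |

All randomness flows from one root seed through named child streams
(crc32 of the stage name spawns an independent `numpy` SeedSequence
child), so inserting a generator stage never perturbs another stage's
draws, and identical config + seed reproduces byte-identical fixtures.

### Signal modes

Four modes place a planted signal where exactly one analysis should find
it, converting the methodological claims into parameter-recovery tests:

- **hub_noise** — spurious CT edges attach preferentially to hub
  compounds and high-degree targets, while known associations are planted
  with probability proportional to inverse metaedge-degree products
  (specific, low-degree routes). This is the regime where degree damping
  should beat the raw path count.
- **proximal** — treatment target sets are sampled from the disease
  module and its PPI neighborhood; network proximity should recover them.
- **function_mediated** — each disease gets a dedicated leaf function
  annotated to both its module proteins and its treatment's targets, and
  the treatment targets are chosen among the PPI-most-distant proteins.
  Diffusion over the function hierarchy sees the link; PPI distance does
  not (and is actively misled — proximity AUROC falls below 0.5).
- **null** — uniform labels and random treatment sets; every scorer must
  sit at AUROC 0.5 within Monte-Carlo error. This calibration is asserted
  by the acceptance suite.

### What the generator does not emulate

No attempt is made to fit real degree distributions, database sizes, or
literature-curation biases; the Bernoulli dropout/spurious model is the
simplest ensemble reproducing the qualitative pattern of high herb-level
but lower compound-level cross-database consistency. Passing tests
therefore show that each method recovers the mechanism it assumes *when
that mechanism is present*, and nothing when it is absent — they do not
show how strongly those mechanisms operate in the real databases.

## Consistency scoring

Profiles are one-hot vectors over the union of the relevant entity sets
across the two databases under comparison (any database-specific universe
would make profiles incomparable). The recall percentile counts reference
values *strictly* below the observed similarity (midrank tie handling is
available as an option); the reference pool ranges over the entities of
the database in which similarity is measured, excluding the query entity
itself, restricted to entities with nonzero-variance profiles. Pearson
correlation of a zero-variance profile is undefined: such entities are
skipped and reported, never coerced to 0. Identical databases therefore
give recall exactly 1.0 (modulo exact ties), and independent databases
give recall uniform on [0,1] — both properties are asserted as tests.

## Centralities

Degree, betweenness, and closeness follow the bare unnormalized formulas
(betweenness over unordered pairs, closeness = 1/Σ distances). For
disconnected graphs, closeness is computed within the node's connected
component, since the distance sum is undefined across components; isolated
nodes get closeness 0 and the component count is logged. Betweenness is
delegated to networkx (`normalized=False`, which sums over unordered pairs
on undirected graphs); closeness is computed directly by BFS because
networkx applies a component-size rescaling that the bare formula lacks.
Per-herb subnetworks (induced PPI on the herb's targets) are the default
evaluation unit; a pooled mode exists.

## Path count and DWPC

Degrees are metaedge-specific: a compound's HC-degree counts the herbs
containing it across the whole database, its CT-degree counts its
targets — computed once per network, not per query. The implementation
accumulates per-path degree factors with vectorized exponentiation and a
bincount per herb; tests compare it against an explicit path-enumeration
oracle (independent code path) on hundreds of random networks to 1e-12,
and the identities DWPC(0,0) ≡ PC and DWPC ≤ PC (every degree ≥ 1) are
asserted exactly. Percentile thresholding uses midrank ranks within the
herb's reachable-target list, keeping herbs of different sizes comparable;
the damping grid search averages per-herb AUROC (pooled mode optional) and
reports *all* argmax ties.

## Network proximity

d_c(S,T) averages, over drug targets t, the shortest-path distance to the
nearest disease protein; targets absent from the PPI or unreachable from
every disease protein are excluded with a logged count (assigning ∞ would
make the average undefined). The null randomizes *both* S and T:
1000 sets matching each template's size and degree profile, drawn from
log2 degree bins merged upward until each bin holds ≥ 10 nodes
(configurable), without replacement within a set. σ = 0 or an empty null
is reported as a degenerate-null signal, never scored. All-pairs distances
come from scipy's sparse BFS (`csgraph.shortest_path`, unweighted) and are
computed once per graph, making 10⁵ null evaluations cheap.

## Multiscale-interactome diffusion

The interactome is a directed, type-weighted graph: PPI edges in both
directions, protein↔function annotation edges, and hierarchy edges up and
down a rooted function tree. Per-type scalar weights (default 1.0,
configurable — no weight learning) scale out-edges before row
normalization into the transition matrix M; rows with zero out-weight form
the dangling set J, whose mass is redistributed through the restart vector
s — the only reading of the recurrence under which total probability is
conserved, and the package asserts Σr = 1 ± 1e-9 at convergence and
agreement with the direct linear solve of the stationarity equation
r = (1−α)·s·(I − α(M + 1_J sᵀ))⁻¹ to within 10·ε on fixtures up to 200
nodes. Entities and diseases are embedded as virtual nodes with directed
edges to their targets (s = indicator of the virtual node), so all
profiles share one node ordering; a restart-over-targets mode without
virtual nodes is available as a flag. Profiles are compared by correlation
distance (1 − centered cosine), which is symmetric and shift-invariant; a
constant profile is an undefined-distance signal.

## Evaluation conventions

- MCC with any empty marginal is reported as 0 and flagged
  (`mcc_zero_denominator`) — the formula is undefined there.
- The printed formulas for coverage and recall coincide; the package
  reports association-level recall TP/(TP+FN) and, separately, an
  entity-level coverage (share of entities with ≥ 1 recovered known
  association), labeled distinctly, with the convention recorded in every
  report's notes.
- Negatives are the scored-but-unknown pairs of the explicit candidate
  universe (unknown associations may contain true positives; the universe
  definition travels with each report).
- AUROC is the midrank Mann–Whitney statistic; AUPR integrates the
  precision-recall step curve in descending score order with tie groups
  processed as blocks. Both match independent oracles (exhaustive pair
  counting; scikit-learn) in the tests.
- Prioritization sorts by (score desc, entity id, disease id) so ties are
  deterministic; undefined scores rank last and stay explicitly missing.

## Numerical and degenerate-input choices

Parse errors name file and line; empty edge files are valid (empty
networks); unknown herbs raise lookup errors rather than returning empty
scores; thresholds outside [0,1], empty grids, empty universes, and
nonpositive type weights are usage errors. Diffusion failing to reach ε
within 10⁴ iterations raises a convergence error carrying the last
residual (CLI exit code 4).

## Problem sizes of the shipped experiments

The acceptance experiments use: 200 random networks (≤ 60 nodes) for DWPC
oracle equivalence; interactome fixtures ≤ 200 nodes for the linear-solve
comparison; a 300-protein PPI with 100 null replicates and 20 planted
replicates (n_perm = 1000) for proximity calibration; 60-herb network
pairs for null-recall uniformity; and 20-seed ensembles at the default
configuration for the damping-recovery and regime-separation win
fractions. These sizes give stable Monte-Carlo estimates while keeping
the full suite in the minutes range on one CPU.

## Known limitations

- Herb-level target sets default to the union over the herb's compounds;
  weighted aggregation schemes are not modeled (the aggregation point is
  a flag).
- Oral-bioavailability/drug-likeness filtering is available only as an
  optional pre-filter on pre-supplied compound attributes; the scores are
  never computed.
- Only the length-2 herb→compound→target metapath is scored; longer
  metapaths and eigenvector-style centralities are out of scope.
- Per-edge-type diffusion weights are configuration, not learned.
- The proximity null excludes template members from nothing: a sampled
  set may overlap the original, which is the standard construction but
  slightly shrinks |z| for very large templates on small graphs.
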