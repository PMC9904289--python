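# Methods

## Scoring model

A functional association between two proteins is summarized by a combined
confidence score in [0, 1], aggregated from per-channel scores under a
shared prior *p* — the probability that a random protein pair is
associated. Each channel score is first corrected for the prior,

    s' = max(0, (s − p) / (1 − p)),

the corrected scores are combined with a noisy-OR (channels treated as
independent witnesses), and the prior is re-added:

    S = p + (1 − p) · (1 − ∏ᵢ (1 − s'ᵢ)).

The default prior is **p = 0.041**, the convention used by large
protein-association databases; it is configurable everywhere because
published descriptions of the aggregation cite it only by reference.
Useful consequences of the formula: a single-channel vector combines to
exactly that channel's score (for s ≥ p), the combined score is monotone
non-decreasing in every channel, and empty evidence combines to p.

Direct and orthology-transferred evidence for the same pair are merged
*within* each channel by the same noisy-OR of prior-corrected scores,
before the cross-channel combination. One edge case is handled explicitly:
when no source in a channel exceeds the prior, there is nothing to combine
(every corrected contribution is zero) and the merge returns the maximum of
the sources rather than re-adding the prior. This keeps a lone sub-prior
score a fixed point of aggregation and keeps the merge continuous and
monotone at s = p.

## Score store

Scores are persisted as sorted TSV tables, one row per protein pair, with
integer scores in 0–1000 (thousandths). Channel scores are snapped to that
grid when a pair is inserted, and capped at 999: the value 1000 would
denote certainty, which the store never asserts. The combined score is
always recomputed from the stored channels, so the "combined equals the
combination of the evidence" invariant holds exactly and round-trips are
lossless. Each row also retains its *direct* evidence vector separately
from the merged (direct + transferred) vector; this is what makes
re-running orthology transfer on an already-transferred store a no-op (see
below). Alias resolution normalizes identifiers by Unicode casefold and
whitespace trimming and is species-scoped; an alias resolving to more than
one protein is an error carrying the candidate list, never a silent pick.

## Orthology transfer

Orthologs between two proteomes are detected by reciprocal best hits of
Smith–Waterman local alignments. Alignment defaults are BLOSUM62 with
affine gaps (open −11, extend −1; a gap of length L costs
open + (L−1)·extend); the wildcard X scores 0 against everything.
Similarity is self-normalized by the geometric mean of the self-scores,

    σ(a, b) = SW(a, b) / √(SW(a, a) · SW(b, b)),

which is symmetric and equals 1 on identical sequences. Exact best-score
ties disqualify the tied query — a deterministic one-to-one map is worth
more than an arbitrary tie-break. Pairs below a minimum similarity
(default σ ≥ 0.3) are discarded as likely spurious.

Evidence transfer from a source host–parasite pair to a target pair is
admissible only within taxonomic scope: the parasites must share the taxon
at the parasite scope (default **genus**) and the hosts at the host scope
(default **class**). Each channel score is penalized multiplicatively,

    s_transferred = s · (σ_host · σ_parasite)^α,

with α = 1 by default; the penalty function is an approximation chosen for
monotonicity and for never increasing a score. Transferred evidence is
flagged and only the direct portion of any row ever acts as a transfer
source, so transfer cannot daisy-chain and the operation is idempotent on
its own output.

## Queries and network manipulation

All queries share the store machinery. The cross-species query takes every
interspecies edge at the cutoff, then adds intraspecies edges among those
same proteins; every node in the result touches at least one cross-species
edge, and the absence of any such edge at the cutoff is an error, not an
empty network. Expansion ranks candidate proteins by (number of selected
neighbors at the cutoff, then the sum of those scores, then id); the
ranking criterion of the original server is unpublished, so determinism was
chosen over fidelity. All score ties anywhere resolve lexicographically by
node id.

Raising the confidence cutoff only deletes edges (nodes are kept, possibly
isolated); lowering it re-queries the store for the current node set.
Changing the network type deletes all store-backed association edges and
re-fetches from the target store at the current cutoff, preserving user and
enrichment edges and the node set — so full → physical → full restores the
original edge set exactly.

STRINGify maps a user network onto store identifiers via the alias table,
lifts every original edge (typed `user`, source `lifted`), copies all node
and edge attributes, keeps unmappable nodes by default, and sets the cutoff
to 1.0 so that no store edge is present until the user lowers it. Two user
nodes mapping to the same store protein are merged, concatenating
conflicting attribute values with `|` and recording the merge in the
report.

## Enrichment

Each term's over-representation in the query is tested with the one-sided
hypergeometric tail P[X ≥ k] for X ~ Hypergeometric(N, K, n), where k/K
are the query/background proteins the term annotates and n/N the query and
background sizes. The background defaults to all annotated proteins of the
species and is overridable. Terms annotating no query protein are not
tested — they cannot be enriched and would only inflate the
Benjamini–Hochberg divisor. BH correction is applied within each category
(the scope of the correction in public servers is not documented; per
category is the conservative reading that keeps categories independently
interpretable). Results with FDR below the cutoff (default 0.05) are
returned sorted by FDR then term id; a cutoff of 1.0 is a no-op filter.

Group-wise enrichment partitions the network by a node attribute and runs
the identical analysis per group; by construction each group's table equals
a plain enrichment call on its members. Publication enrichment reuses the
same code path with each document's text-mined gene set as one term,
attaching title and year to the results. Redundancy filtering greedily
scans results in FDR order and drops any term whose annotated-query-gene
set has Jaccard similarity at or above the cutoff (default 0.5) with an
already-retained term. An enriched term can be injected into the network
as a node of type `enriched_term` with one `enrichment` edge per annotated
query protein; the operation is idempotent.

## Markov clustering

MCL iterates expansion (matrix power, default 2) and inflation
(elementwise power, default 4, suited to dense confidence-weighted
networks) on the column-stochastic transition matrix of the weighted
adjacency. Numerical choices, all configurable: self-loops with weight
equal to each node's maximum incident weight (1 for isolated nodes) damp
oscillation and guarantee every column an attractor; entries below 1e-5
are pruned after inflation; iteration stops when the matrix changes by
less than 1e-8 in max-norm, with a hard cap of 100 iterations (exceeding
it raises a convergence error reporting the residual). Column
stochasticity is asserted to 1e-9 at every step. Clusters are read off the
converged matrix via its attractors (nodes with non-negligible return
flow); attractors sharing a column form one attractor system, and a node
in overlapping systems joins the lowest-index cluster. Cluster indices are
1-based, ordered by decreasing size with ties broken by smallest member
id. Because flow never crosses a disconnected component boundary, clusters
are always confined to connected components — this is used as a test
oracle.

## Localization filters

Subcellular-compartment and tissue confidences use the 0–5 star scale of
the COMPARTMENTS/TISSUES resources, stored as node attributes under
`compartment::<name>` / `tissue::<name>`. Node filtering keeps proteins at
or above a threshold for a named location, keeps unannotated nodes only on
request, always keeps non-protein nodes, and induces edges on the
survivors. Edge filtering thresholds one evidence channel (absent ≡ 0) and
never touches user or enrichment edges. Both filters are monotone in their
threshold and commute.

## Synthetic worlds

The generator emulates the data shapes a functional-association backend
serves, with planted ground truth recorded alongside:

* **Species**: two mammalian hosts (*Homo sapiens*, *Mus musculus*), two
  congeneric apicomplexan parasites (*Plasmodium falciparum*,
  *P. vivax*), one insect vector (*Anopheles gambiae*), each with a
  genus/family/order/class lineage — so the transfer scope rules have both
  admissible and inadmissible pairs to act on.
* **Intraspecies networks**: 30 proteins per species; three planted
  modules of six proteins with within-module combined scores ~N(0.9,
  0.03²) and a sparse background (15 % of remaining pairs at ~N(0.15,
  0.05²), single-channel so background scores cannot drift above the 0.4
  default cutoff). A single evidence channel makes the combined score
  equal the planted score exactly; a fraction of module edges carry a
  second channel for realism.
* **Cross-species edges**: 25 per interacting species pair (host–parasite,
  parasite–vector, host–vector), scores uniform on [0.45, 0.95], evidence
  on the experiments and textmining channels only, concentrated on the
  proteins that also have planted orthologs so that transfer has material
  to act on.
* **Physical store**: a 50 % subset of the full store's edge rows.
* **Proteomes**: length-60 sequences; eight ortholog pairs per host pair
  and per parasite pair are planted by mutating a shared ancestor at a
  rate chosen to hit target similarities spanning [0.6, 0.95]; the truth
  table records the *realized* alignment similarity, not the target. All
  other sequences are independent random strings.
* **Annotations / documents / entities / localization**: one planted term
  per module (plus two background proteins), random distractor terms, one
  planted publication covering a module, random documents, ranked
  entity–protein association lists, and 0–5 localization scores with the
  first host module biased toward high liver expression.

A single integer seed drives one generator; identical seeds give
byte-identical world directories. These worlds are small and clean by
design: scores are exactly on the storage grid, modules are well separated,
orthologs are unambiguous. Passing tests therefore demonstrate correctness
of the algorithms and their contracts — not performance or robustness on
genome-scale, noisy, redundantly annotated real data, where module
boundaries blur and paralogy confounds RBH.

## Problem sizes

The default world has 5 × 30 proteins and ≈ 600 score rows; statistical
claims (planted-term recovery, planted-partition recovery, ortholog
recovery) are measured over 100 seeded replicates of focused
mini-fixtures (500-protein enrichment backgrounds, 18-node planted
partitions, 12-protein proteomes), sizes chosen so the full suite and the
acceptance script each complete in well under a minute of compute while
keeping the statistical assertions meaningful.

## Known limitations

* Raw Smith–Waterman scores stand in for database-provided bit scores; the
  published self-normalization formula is not public, and the geometric-mean
  normalization used here is the standard interolog-literature choice.
* Channel-specific raw-score calibration (benchmarking against pathway
  gold standards) is out of scope; channel scores are taken as given.
* Whether orthology transfer should cross the full/physical store boundary
  is unspecified upstream; here each store is transferred independently.
* The CLI covers the analysis chain but not any service/API deployment;
  concurrency is out of scope.
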