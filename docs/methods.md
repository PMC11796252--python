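# Methods

## Scoring and the SRV metric

Pairwise similarity is computed by an in-house Smith–Waterman aligner with
affine gaps (Gotoh recurrence). A gap of length L costs
`gap_open + L·gap_extend`; the defaults are BLOSUM62 with 11/1, and raw
scores are converted to bits with the Karlin–Altschul formula
`bits = (λ·S − ln K)/ln 2` using the published gapped-BLOSUM62/11/1
constants λ = 0.267, K = 0.041. The aligner is deliberately deterministic:
the optimal cell is the highest score at the lexicographically smallest
(end_query, end_subject), traceback prefers diagonal over up over left, and
gaps are closed as early as possible. Outputs are therefore bit-reproducible
across runs and platforms. An exact reproduction of BLAST's bit scores
(composition-based statistics, SEG masking) is out of scope.

The SRV of a directed hit is its bit score divided by the *query's*
self-alignment bit score. Which side's self score to use is ambiguous on its
face; the choice is harmless because reciprocal hits are averaged into a
symmetric weight immediately afterwards. SRVs read from external hit tables
may exceed 1 by rounding; they are clamped at 1 up to a 1e-6 excess and
rejected as inconsistent beyond that.

The E-value proxy is `K·m·n·exp(−λS)` with m, n the two sequence lengths —
a pairwise search space rather than a database-size correction. This keeps
the gate deterministic and self-contained; at ≤ 50 aa the 1e-5 ceiling it
feeds is generous. The ceiling is applied to all hit generation, including
hits ingested from tables.

`all_vs_all` aligns each unordered pair once and mirrors the result for the
reverse direction (the local score is symmetric; coordinates and coverages
swap). Each ordered pair still yields at most one hit with its own SRV.

## Graph construction and pruning

A directed hit enters the graph iff SRV ≥ 0.3 and both coverages
(aligned span / sequence length) are ≥ 0.70 — "mutual" coverage reads as
both-sided, which blocks domain-sized matches between very unequal lengths.
Surviving reciprocal pairs are averaged; a surviving one-directional hit
contributes its own SRV (dropping unpaired hits is the stronger assumption
and is available via `require_reciprocal`).

Singleton (degree-0) and pendant (degree-1) nodes are removed in one
simultaneous pass on the input degrees, not iteratively — iterative peeling
would shrink the graph further than intended. A node that loses its last
edge in this pass (the interior of a two-edge path) is moved to the
singleton report before k-selection, whose contract requires minimum degree
one.

k-best pruning uses **mutual** (intersection) semantics: an edge survives
only if it ranks in the top-k lists of both endpoints, ties broken by
ascending neighbour id. Under union semantics every node would keep its best
edge and the minimal-k criterion ("smallest k creating no singletons") would
be vacuous at k = 1; intersection makes it meaningful. k is found by
scanning k = 1 … max-degree, which always terminates because pruning at the
maximum degree keeps every edge.

Per-component weak-edge pruning picks, among the component's distinct edge
weights, the **largest threshold whose application isolates no node**, then
deletes all lighter edges. The component may split — that is the point: the
deleted edges are the weak bridges that would otherwise glue unrelated
clusters. This rule is a deterministic, testable stand-in for
edge-weight-distribution heuristics from the graph-clustering literature and
sits behind a small strategy surface (`component_threshold_prune`) so an
alternative can be slotted in.

Components are then batched on a quantile grid (quartiles by default) over
mean node degree and mean edge weight, so that inflation selection happens
among structurally similar components. The number of bins is a free choice;
quartiles are scale-free and keep batches populated at desk scale.

## Markov clustering and inflation selection

Classic MCL on the column-stochastic matrix of each component with
self-loops set to the per-column maximum weight (scale-free across SRV
magnitudes, and the common MCL default; configurable). Iteration: expansion
(matrix squaring), inflation (elementwise power r), column renormalisation,
then zeroing of entries below 1e-6. Convergence is declared when the largest
absolute entry change drops below 1e-8, with a 200-iteration cap (a warning,
not an error, on hitting the cap); a final renormalisation precedes cluster
extraction. Components above 500 nodes iterate in scipy.sparse CSR so cost
scales with nonzeros. Clusters are read off the limit matrix via attractors
(positive diagonal): attractors connected by nonzero flow form a system, and
every node joins the system receiving the most of its column mass, ties to
the system containing the lowest attractor index.

The inflation r is swept over 1.2–4.0 in steps of 0.2 (15 points; the
interval is the method's, the step is ours) and selected per batch by the
quality score

```
Q = W_intra / W_total − Σ_c n_c(n_c−1) / (n(n−1))
```

— intra-cluster edge-mass coverage minus its expectation under the cluster
sizes, in [−1, 1], zero for both trivial partitions. The batch score is the
edge-mass-weighted mean of per-component Q; ties go to the smallest r. This
efficiency-style criterion is a documented stand-in for van Dongen's
node-wise efficiency and is isolated behind `clustering_efficiency` so the
original can replace it without touching the sweep.

## Families, profiles, gathering cutoffs

Clusters with **at least five** members are families (the size threshold is
applied uniformly; sub-threshold clusters and singletons are reported with
counts). The member MSA is a deterministic center-star: the center maximises
the summed pairwise bit score (ties to the smallest id), every other member
is globally aligned to the center with the same scoring scheme, and
alignments are merged under "once a gap, always a gap". Removing gaps from
any row reproduces that member's sequence exactly — this round-trip is
asserted on every fixture. An external aligner can be substituted as long as
its output satisfies the same invariant.

The profile model is intentionally lightweight rather than a full
HMMER-compatible HMM: columns with gap fraction < 0.5 become match states;
emissions mix counts with background pseudocounts
(`(counts + w·bg)/(n + w)`, w = 1) and are reported as log-odds in bits
against the BLOSUM62 background frequencies; transitions are pooled
(position-independent) over the seven labels M→M/I/D, I→M/I, D→M/D with
add-one smoothing (observed I→D events, which the reduced state machine
lacks, are ignored). Scoring is Viterbi, global in the profile and local in
the query: flanking query residues are free, insert emissions score zero,
entry at M₁/D₁ and exit from M_K/D_K are free. The scorer is verified
against exhaustive path enumeration on small profiles.

The gathering cutoff is the minimum member score — the weakest threshold
that still recovers every member when the profile is scanned. Stricter
variants (noise/trusted cutoffs) are not modelled. Product assignment is a
strict plurality vote after normalising labels (trim, collapse whitespace,
casefold) and discarding uninformative ones ("hypothetical protein",
"uncharacterized protein", empty; the set is configurable); ties yield no
assignment, and the winner is reported in its first-seen casing.

## Synthetic data

The generator emulates the statistical structure the clustering assumes:
each family descends from a root peptide (length 20–50, drawn from the
BLOSUM62 background) by i.i.d. per-site substitutions (default rate 0.15 per
member; the replacement is drawn from the background excluding the original
residue, so substitution counts are Binomial(length, rate)) and single-residue
indels (default 0.02/site, insert/delete equiprobable, lengths clamped to
[5, 50]). Decoys and singletons are independent background peptides; a
label-noise fraction (default 0.2) of family members is marked
"hypothetical protein". Defaults (family sizes 5–20 in general use; the
benchmark uses 20 families of 5–15 with 50 decoys and 20 singletons) are
chosen as a realistic desk-scale regime: ~70% pairwise identity within
families is comfortably above the SRV 0.3 floor while random 20–50-mers
essentially never pass the E-value gate.

What the generator does **not** emulate: phylogenetic correlation between
members (a star tree, not a real genealogy), multi-residue indels,
compositional bias, shared domains between distinct families, and redundant
identical sequences. Passing the benchmark therefore shows the pipeline
recovers well-separated families under i.i.d. noise; it does not certify
behaviour on real proteomes where families overlap and composition drifts.

Recovery is scored by an internally implemented pair-counting adjusted Rand
index (cross-checked against scikit-learn in the tests) plus pairwise
precision/recall; decoys and singletons count as their own truth classes, so
absorbing them into families is penalised. A planted family counts as
recovered when some called family matches it at Jaccard ≥ 0.5.

## Problem sizes and determinism

The shipped benchmark (≈ 270–290 proteins: 20 families of 5–15 members,
50 decoys, 20 singletons) runs the full pipeline in a few seconds on one
CPU and is the size used throughout the test suite and
`scripts/acceptance.py`; it is comfortably past the regime where every stage
(reciprocal averaging, pendant removal, k-selection, batching, inflation
selection) is exercised. Every ordering in the pipeline is explicitly
sorted, all randomness flows from a single integer seed, and two runs with
the same seed produce byte-identical cluster and family tables. The CLI
accepts `--threads` for interface stability but executes sequentially.

## Known limitations

- Bit scores approximate, not reproduce, BLAST's (no composition-based
  statistics); SRVs from external BLAST tables mix cleanly only if the
  self-hits come from the same program.
- The component-prune and efficiency criteria are documented stand-ins
  behind strategy seams, not ports of the originally cited procedures.
- The profile model is not HMMER-compatible and has pooled, not
  per-position, transitions; gathering cutoffs are min-member only.
- Center-star alignment is within a factor of two of optimal SP score in
  theory and adequate for tight families; divergent families would benefit
  from a progressive aligner.
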