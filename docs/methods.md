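# Methods

`taxoplace` assigns taxonomy to marker-gene amplicons (16S rRNA and
similar) from a *primer-specific* reference phylogeny, preserving
one-to-many taxonomic ambiguity where the sequenced region genuinely
cannot separate taxa. This note documents the model, the numerical
choices, and what the synthetic fixtures do and do not demonstrate.

## The model

**Region-specific reference.** An aligned full-length reference
database is trimmed to the amplicon defined by a primer pair. Primer
sites are located by in-silico PCR: each sequence's ungapped text is
scanned for an IUPAC-compatible match (0 mismatches by default,
configurable), hit coordinates are mapped back to alignment columns,
and the modal column interval across sequences is used. Trimming is a
pure column slice, so the trimmed sequences remain aligned. By default
primer-binding columns are removed (`keep_primers` retains them).
Sequences containing N, or shorter than a configurable ungapped length,
are removed with logged counts.

**Region tree.** The production route is to import a maximum-likelihood
tree built externally on the trimmed alignment (e.g. FastTree under
GTR), via Newick. For self-contained work at desk scale the package
also builds a tree internally: Jukes–Cantor distances with pairwise
deletion of gap/N columns, neighbor joining, negative branch lengths
clamped to zero, midpoint rooting. The JC/NJ combination is a
simplification of the GTR/ML route and is a documented substitute, not
an equivalent; all distance semantics downstream (thresholds,
placement) are cophenetic path lengths on whichever tree is supplied.
Negative NJ estimates are clamped rather than redistributed onto
sibling branches because redistribution systematically inflates short
within-taxon paths, which the threshold optimizer is sensitive to.

**Per-rank distance thresholds.** For each taxonomic rank
(Domain → Species) the optimizer cuts the tree at candidate thresholds
*t* into the maximal clades whose *tip diameter* (largest cophenetic
distance among descendant tips) is strictly below *t*; tips qualifying
only as singletons form singleton groups, so every partition covers all
tips. Each group is named for its plurality taxon (lexicographic
tie-break). Errors are counted as:

* **over-merging** — per group, one for each ground-truth taxon beyond
  the majority taxon;
* **over-splitting** — per majority name, one for each group beyond the
  first carrying it.

The total is normalized to [0, 1] by the number of tips labeled at the
rank (the normalizer is a reporting choice only; it does not move the
arg-min). The grid is a hybrid geometric + linear set of 200 points on
(0, tree diameter], plus one point just above the diameter so the
single-group partition is reachable under the strict inequality. Ties
are broken toward the smallest threshold (the most conservative
grouping). Tips unlabeled at the scored rank are excluded from both
error terms. Cutting is clade-based: paraphyletic distance-only groups
are not formed.

**Node labeling (binomial dominance).** A node resolves at a rank when
its tip diameter is within that rank's effective threshold. Its label
set is chosen by a binomial error model: assuming a 5% rate of
mis-annotation among reference sequences, a label observed on *k* of
*n* tips is retained when the upper tail P(X ≥ k) under
Binomial(n, 0.05) is ≤ 0.20 — that is, the label is too frequent to be
plausible annotation error. All labels that pass are retained (a
one-to-many label); if none passes, all observed labels are retained.
The "≤ 0.20" reading of the error gate is the pivotal interpretive
choice; the opposite reading is available behind `tail_rule="ge"` and
is exercised in tests. Once an assignment is ambiguous at a rank,
finer ranks are labeled hierarchically: tips are partitioned by each
retained coarser label and the model runs within each partition, with
results unioned (`hierarchical="pooled"` selects the single-pool
alternative). Ranks are visited coarse → fine and the descent stops at
the first rank whose threshold the node does not meet.

**Species multiplier.** The optimizer's species threshold tends to be
too permissive when false positives are costly, so the effective
species threshold is the optimized value times a multiplier: 0.1 in
**specific** mode (the default, precision-first — in effect only
near-exact matches speciate) and 1.0 in **sensitive** mode (recall-
first). The multiplier applies wherever the species threshold is used
(node labeling and query assignment alike) and is freely overridable,
e.g. for precision–recall sweeps over 0–1.95.

**Query classification.** Queries are aligned into the fixed reference
coordinate frame mothur-style: a k-mer search (k = 8) picks the most
similar template (queries are re-scored reverse-complemented when the
forward strand finds fewer shared k-mers), Needleman–Wunsch with free
end gaps aligns query to the degapped template, and the pairwise
alignment is projected through the template's gap pattern NAST-style:
query insertions are placed into adjacent free columns, rotated
rightward through equal bases when the aligner reported the leftmost
equivalent indel placement, and otherwise trimmed with a logged count,
so alignment width is always preserved. Queries covering < 80% of
their template's ungapped span are dropped (boundary inclusive on
0.80).

Placement is either parsed from standard jplace v3 JSON (pplacer,
EPA-ng — the fidelity route; edge numbers are resolved to tree nodes by
descendant-tip-set identity) or computed internally: the query is
attached above each of the top-5 most k-mer-similar reference tips,
candidate edges are scored by JC-corrected distance over shared
columns, and scores are softmax-converted to a likelihood-weight-ratio
analogue (an exact sequence match collapses to the zero-distance
placements with uniform weight). Placements with LWR within 50% of the
best are retained (inclusive).

Per placement, the *index node* is the child node of the placement
edge. The query-to-tip distance is pendant length + distal offset +
tree path from the index node; the distal offset is measured from the
child node toward the parent and is included by default
(`include_distal=False` gives the alternative). The *proposed level*
is the finest rank whose effective threshold exceeds the query's
distance to every tip under the index node, clamped to the node's
resolved rank; if no rank qualifies the walk continues toward the
root, and an exhausted walk leaves the query unassigned. Across
retained placements, the modal proposed level wins (ties to the
coarser level) and label sets are unioned per rank down to that level.

**Evaluation.** A one-to-many assignment is judged correct when at
least one member equals the truth; a non-assignment is judged correct
(and counted as a true positive) when the truth taxon is absent from
the reference database. With TP = correct assignments + correct
non-assignments, FP = incorrect assignments, FN = incorrect
non-assignments: precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R), accuracy = correct/total. The TP convention follows
the method's intended accounting and is deliberately non-standard;
`unassigned_as_tp=False` selects the textbook definition (correct
non-assignments become true negatives outside P/R). Holdout schemes:
per-genus sampling at 1% or at least five sequences (all available if
fewer), uniform random n, one representative per genus, and
whole-genera removal (where correct behaviour is genus/species
non-assignment).

## Synthetic fixtures

The generator emulates the structure the method assumes: a
rank-nested tree whose taxa are clades by construction, sequences
evolved along it under Jukes–Cantor, conserved primer motifs written
into fixed columns so in-silico PCR has real binding sites, optional
gap decoration, and optional post-truth label swaps emulating
mis-annotation. Everything derives from one seed; equal seeds give
byte-identical outputs.

Default conditions (chosen once, as the fixture's study conditions):
sequences of 600 bases with a ~480-column region; mean branch lengths
per depth (Domain → Species, then tip pendants) of
0.03/0.07/0.04/0.035/0.07/0.09/0.025/0.006 substitutions/site with
±15% jitter. Two deliberate design points:

* **Depth.** Scales keep the deepest pairwise distances near ~0.6
  subs/site. Far deeper trees push observed mismatch fractions toward
  the Jukes–Cantor saturation point, where distance variance explodes
  and any distance-based reconstruction scrambles clades — the fixture
  would then violate the separation-margin premise it is meant to
  instantiate (and would be unrealistic for 16S, where even
  cross-phylum distances stay well below saturation).
* **Within-species genealogy.** Tips descend from a caterpillar
  genealogy with real internal branches rather than a star. A star
  multifurcation has no defensible binary resolution, so a
  reconstructed (binary) tree may interleave the outgoing edge among
  the tips, making the species non-contiguous for clade-based cutting
  even with perfect distances.
* **Genus separation.** Genus stem edges (0.09) are large relative to
  within-genus depth (~0.05), so the between-genus distance clears the
  *global* maximum within-genus diameter — which the smallest-tie-break
  threshold hugs — with room for reconstruction noise.

What passing on these fixtures shows: the optimizer recovers
separating thresholds when they exist; propagation and placement are
internally consistent; novel-genus queries are correctly refused at
genus/species. What it does not show: performance under real 16S
rate heterogeneity, region-specific entropy differences between
hypervariable regions, chimeras, or taxonomies that genuinely conflict
with phylogeny — the generator emulates none of these (label swaps are
a crude stand-in for the last).

## Numerical and procedural choices

* Rank frame: seven ranks, Domain/Kingdom → Species, indexed 0–6;
  algorithms use indices, the rank-0 display name is cosmetic.
* Species tokens are collapsed to their first two whitespace-separated
  words; tokens of fewer words are kept verbatim. This handles
  strain/subspecies suffixes but will also truncate multi-word names
  such as "Candidatus X y" — a known limitation.
* Missing-label vocabulary (case-insensitive, matched on whole token
  and first word): unclassified, uncultured, metagenome, unidentified,
  empty — overridable per call.
* Coordinates are 0-based half-open alignment columns; U→T and
  '.'→'-' on ingest.
* JC distances cap at 5.0 substitutions/site as the observed mismatch
  fraction approaches 3/4.
* In-silico PCR requires a primer hit in ≥ 50% of sequences
  (configurable) and errors out otherwise, reporting the hit rate.
* All boundary comparisons on published percentages are inclusive
  (coverage ≥ 0.80 keeps; LWR ≥ 0.5 × best keeps); diameter-vs-
  threshold comparisons are strict (<), so a threshold of 0 yields
  singletons.
* Leave-one-out species recall is a *sensitive*-mode property: the
  specific mode's 10× smaller species threshold refuses species labels
  for any query that is not a near-exact database match, by design.
* Problem sizes in the shipped tests and acceptance script (64–80-tip
  fixtures, 20–40-query holdouts, 200-point grids) were chosen as the
  smallest at which the margins above are comfortably resolved.

## Known limitations

* The internal NJ tree and the internal distance-based placement are
  stand-ins for ML tree building and ML placement; both are honest
  about being so, and both have external ingestion routes (Newick,
  jplace) that should be preferred when fidelity matters.
* Thresholds are global per rank; clade-specific rate variation is not
  modeled (no per-clade adaptive thresholds).
* The NAST projection trims insertions it cannot rotate into free
  columns; heavily gapped templates near indel-rich queries can lose
  bases (always counted and logged).
* `per-genus-rate` holdouts may remove a species entirely from the
  reference; evaluation then scores those queries under the
  non-assignment convention rather than containment.
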