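# Methods

This note documents the models, rules and numerical choices behind each
module, the conditions the simulator emulates, and what the tests do and do
not establish about real data.

## Co-occurrence classification

A genome inventory counts non-pseudogene *gltX* copies and records GlnRS
(*glnS*) and gatCAB presence; gatCAB requires all three of
*gatA*/*gatB*/*gatC* simultaneously as non-pseudogenes. Pseudogene status is
consumed as an input flag and counts as absence everywhere — a genome whose
only *glnS* is a pseudogene classifies with the GlnRS-lacking groups. The
five legal groups are `1|-|+`, `2|-|+`, `2|+|+`, `1|+|+` and `1|+|-`;
genomes with 0 or >2 GluRS copies, or with neither GlnRS nor gatCAB (no
route to Gln-tRNA^Gln^ at all), return the `UNCLASSIFIED` sentinel with a
logged warning rather than an exception, so batch runs survive odd genomes.

Functional typing follows directly from the group for single-copy genomes:
no GlnRS forces a non-discriminating GluRS (ND); GlnRS without gatCAB
forces a discriminating one (D⁻); GlnRS with gatCAB is only nominally
discriminating (D⁺). Two-copy genomes need sequence evidence:
`label_copies` assigns GluRS1/GluRS2 by nearest annotated reference isoform
under global pairwise alignment (BLOSUM62, gap open −11 / extend −1, via
Biopython), identity measured as matches over aligned columns. Ties are
refused, never guessed. Queries shorter than `min_length` (default 280
residues) are rejected as likely catalytic-domain-only fragments; raise the
threshold to ~330 to reject the full reported fragment-length range.

The packaged fixture stores the survey's phylum × group occurrence counts
(20 phylum/class codes, 366 genomes) and expands every cell into that many
synthetic genome row sets on demand, so the classification chain is
exercised end to end without any download. The phylum vocabulary is
user-extensible via the `phyla` argument.

## Domain splitting and motifs

The N/C boundary is an alignment projection: the split column is the column
holding reference residue `boundary_residue` (default 322, i.e. domains
1–322 and 323–468 on a 468-residue reference), and every row's non-gap
characters partition around it, guaranteeing |N| + |C| equals the ungapped
length for every sequence. Degenerate rows (all-gap on one side) are
flagged, not dropped.

The HIGH motif is matched as `H[IVL]G[GNSTLM]` with the search restricted
to matches starting within the first `window` residues of the catalytic
domain (default 60 — generous for a Rossmann-fold start; set the window to
the domain length to search everywhere, since how far the motif should be
sought is a genuinely open choice). The first (most N-terminal) hit wins;
all windowed hits are retained for inspection. The matcher is
property-tested against a brute-force 4-mer scan over the explicit 18-variant
set.

Yqey detection projects two references onto the GlnRS alignment: a
Yqey-lacking core (canonical end at residue 673) and a Yqey-containing
sequence (appendix spanning residues 710–852). A query is called
Yqey-appended when it has ≥ `min_extension` residues beyond the projected
core end **and** ≥ `min_identity` fractional identity to the reference over
the appendix projection. The thresholds (60 residues, 0.25 identity) are
this package's own operating points — chosen so that an appendix at ~30%
per-site divergence is detected while unrelated C-terminal extensions are
not — and are surfaced as parameters and echoed in reports.

## Distances, neighbor joining, bootstrap, rooting

Distances use pairwise deletion (each pair compared over columns where both
rows are non-gap; zero shared columns is a hard error naming the pair).
`p` is the mismatch fraction; `poisson` is −ln(1 − p) with p capped at 0.95
to keep distances finite (capped pairs are logged). Pairwise deletion is
preferred over complete deletion because domain-split alignments have very
uneven coverage and complete deletion would discard most columns.

Neighbor joining is the classic Q-criterion agglomeration, made fully
deterministic: ties in the Q matrix resolve to the lowest index pair, and
negative pair branch lengths are clamped to zero with the deficit moved to
the sister branch (final three-branch lengths are clamped at zero). On
additive matrices this recovers the generating topology — verified against
100 random 5–8-leaf trees, against scikit-bio's NJ, and against an
exhaustive ordinary-least-squares topology search at n = 8 (all 10,395
unrooted topologies, OLS branch fits, minimum residual).

Bootstrap supports resample alignment columns with replacement; support for
an internal edge is the fraction of replicate NJ trees containing its
bipartition. Rows are canonically sorted by id before any random draw, so
supports are invariant to input order for a fixed seed. The conventional
0.7 flagging level is exported as `WEAK_SUPPORT`. Replicates in which some
pair loses all shared columns are skipped (support denominators keep
`n_reps`, making reported supports mildly conservative in that rare case).

Rooting places the root on the edge whose bipartition separates the
outgroup exactly; when the outgroup is not a clade in the unrooted tree
(which genuinely happens when transferred genes nest inside the donor
clade), the edge maximising Jaccard similarity between one side and the
outgroup is used, with a warning. Because trees are plain scikit-bio
`TreeNode`s with standard Newick I/O, externally built maximum-likelihood
trees can replace NJ trees anywhere downstream; the concordance logic is
estimator-agnostic.

## Concordance verdicts

"Sister clade" is formalised as the pooled leaf set of all sibling subtrees
at the query's attachment node (pooling makes multifurcations conservative).
The donor group is the majority group among sister leaves with margin =
majority fraction; exact ties, or margins below `min_margin` (default 0.6),
yield `ambiguous` rather than a call — mirroring cases that would otherwise
be adjudicated by eye. With gN/gC the donor groups in the N- and C-domain
trees and s the query's own group: gN = gC = s is `concordant_native`,
gN = gC ≠ s is `full_length_hgt`, gN ≠ gC is `chimera`. Note a single-domain
replacement is already a chimera under this definition (one domain native,
one foreign). The duplication test accepts a cherry of the two copies,
copy1 inside copy2's sister clade, or a smallest containing clade pure for
the host group; a foreign-majority sister clade instead returns `hgt`.
Verdicts are per-query; group-level claims should be made by aggregating
counts, never asserted automatically.

Robinson–Foulds counts bipartitions present in exactly one tree, with a
`shear_to_shared` helper for unequal leaf sets; it is validated against
combinatorial bipartition enumeration on every 4- and 5-leaf topology pair
and against dendropy on random trees.

## The simulator and what it emulates

The species tree is a backbone Yule process over clade ancestors (rate
`birth_rate`, default 1.0) carrying one Yule subtree per clade at a faster
rate (`within_birth_rate`, default 10.0 — tight radiations within
phylum-like clades), with every clade stem lengthened by
`clade_separation`/2 so any inter-clade leaf path is at least
`clade_separation` (default 1.2) expected substitutions per site. That
default keeps the recovery experiments in the regime where donor and host
are well separated (≥ 1.0 subs/site), the condition under which sister-clade
reading is meaningful at all.

Protein evolution is the 20-state Jukes–Cantor analogue — uniform
exchangeabilities, independent sites, no indels — chosen because it is the
simplest model with a closed form for the expected p-distance,
p(t) = (19/20)(1 − e^(−20t/19)), which the tests verify by simulation at
10,000 sites. Indel-freedom means simulated alignments are exact, isolating
the concordance logic from aligner noise; real data are expected to arrive
pre-aligned.

Events edit extant leaves: duplication copies a genome's *gltX* and
diverges the new copy by an extra branch (default 0.3); HGT replaces one or
both domains with a donor-clade leaf's sequence plus a short branch
(default 0.1); losses edit the gene table; a Yqey graft appends a
reference-derived segment at a configurable expected p-distance (default
0.3). Each gene copy's truth record stores per-domain donor clades, from
which the expected verdict follows mechanically (mismatched donors →
chimera; foreign matched donors → full-length HGT; duplicate flag →
duplication; otherwise native). tRNA records are drawn per genome from
per-clade probabilities (signature U32-U38/A37 vs the C32-A38/G37
alternative; canonical acceptor determinants with probability
`trna_acceptor_prob`) on a synthetic 72-nt template — a deliberately
tree-free process that is sufficient for the identity-profiling contracts.

What passing these simulations does **not** show: robustness to alignment
error, indels, rate heterogeneity across sites or lineages, compositional
bias, or incomplete lineage sorting. Real GluRS histories also involve far
larger taxon samples and ML-scale inference; the package's role there is to
consume externally built trees, not to replace them.

## Problem sizes and determinism

The recovery experiments use 4 clades × 6 leaves, 468-residue proteins and
20 replicates per scenario; the exhaustive least-squares oracle runs at 8
leaves; the tRNA experiment uses 200 records per clade. These sizes give
exact or near-exact expectations while keeping any single experiment within
seconds. Every stochastic routine takes an explicit seed or
`numpy.random.Generator`; pipeline and dataset emission are byte-identical
across re-runs of the same configuration.

## Known limitations

- NJ is a distance method; on strongly non-additive real data its
  topologies are rougher than ML — import ML trees for real analyses.
- The minimal-sister formalisation reads one level of the tree; histories
  the literature describes as "separated by multiple branching" may need
  the margin threshold loosened or nested-clade inspection.
- Yqey detection assumes the query is already in the reference alignment
  frame; it does not align.
- The co-occurrence scheme has no group for >2 GluRS copies; such genomes
  are surfaced as UNCLASSIFIED for manual review.
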