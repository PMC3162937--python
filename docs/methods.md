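# Methods

## Coordinate system and scope

Every alignment column carries a Ballesteros–Weinstein (BW) label `H.NN`
(helix 1–7, index anchored on the most conserved residue `x.50`). The model
covers only the membrane-spanning helix windows — 1.33–1.56, 2.40–2.65,
3.25–3.51, 4.43–4.64, 5.38–5.63, 6.37–6.59, 7.34–7.56, i.e. segment lengths
24, 26, 27, 22, 26, 23, 23 and 171 columns in total. Loops, termini and
proline-kink geometry are deliberately outside the model: the TM windows are
the structurally alignable part of the receptor and can be aligned without
gaps. A 28-position subset of these columns (the *pocket*) marks the residues
facing the intramembrane cavity in solved class A structures.

## Gap-free per-helix alignment

Because the alignment is gap-free by construction, each helix is modelled as
a position-specific log-odds profile rather than a full profile HMM — with no
insertions or deletions admissible, insert/delete states could never be
exercised, and an exhaustive scan over all window offsets is exact. Column
weights are `log(((count_a + k·bg_a)/(N + k))/bg_a)` with pseudocount mass
`k = 1` distributed proportionally to the background `bg`, which is estimated
once from all seed columns so the seven helix scores share a scale. Ties in
the offset search break toward the smallest offset.

Candidate sequences are scanned independently by all seven profiles. If the
best placements are not strictly increasing and non-overlapping in helix
order, the highest-total-score consistent subset of hits is kept as anchors
(a weighted longest-increasing-subsequence, with the additional constraint
that the gaps around anchors leave room to place every excluded helix), and
each remaining helix is realigned constrained to the interval between its
nearest placed neighbors, reserving space for helices still to be placed.
The output invariant — placements strictly increasing and non-overlapping —
holds for every record the pipeline emits, including pure noise.

**Threshold calibration.** Per helix, `n` artificial sequences (default
10,000; tests use a few hundred, which is enough for a stable 95th
percentile) are drawn i.i.d. from the helix's seed amino-acid composition and
scored with the same max-over-windows search as real sequences. The cutoff is
the empirical 95% quantile under the lower-interpolation convention (exactly
⌈0.95·n⌉ artificial scores fall at or below it); passing requires a score
strictly above the cutoff, so 95% of artificial sequences fail. Artificial
sequences are 350 residues long — a typical class A GPCR length — so the
maximum-over-windows statistic being thresholded matches the one computed on
real sequences; calibrating on single windows would ignore the multiplicity
of the scan and make the cutoff too lenient.

**Filters.** Records failing more than 4 of 7 helix thresholds are dropped
(some genuine families show weak patterns for up to 4 helices, which fixes
the threshold). Within each species, records differing at fewer than 10
aligned TM positions are grouped transitively and only the lexicographically
smallest id survives; the distance is Hamming over the 171 aligned columns,
the natural metric once sequences are embedded in the fixed coordinate
system. Finally, species contributing fewer than 100 sequences are removed to
avoid sampling bias from incompletely sequenced genomes.

## Subfamily tree

Pairwise distances are p-distances: the fraction of mismatching TM columns
(ambiguity codes match only themselves). The tree is Saitou–Nei neighbor
joining (via scikit-bio), midpoint-rooted — NJ is unrooted and the method
needs "the branches containing the receptor" to be well defined; midpoint
rooting is the assumption-free choice. Branch bootstrap support is not
computed: it would annotate confidence but plays no role in scoring. A
*subfamily* is the leaf set of one node; scoring uses every ancestor of the
query receptor whose size lies in [50, 300] — large enough that neutral
positions have visibly diverged, small enough that members plausibly share a
ligand — excluding any clade that covers the whole alignment so the out-set
is never empty.

## The two-entropy score

Per column and subfamily, `E_in` and `E_out` are Shannon entropies (natural
log) over the 20 standard amino acids, computed on the subfamily members and
on their complement respectively; ambiguity codes are excluded from counts,
and a column with no countable symbol is an error (the alignment stage
guarantees gap-free columns). The log base is irrelevant after normalization
by ln 20. Normalized entropies place each column in the unit square; the
branch score is the Euclidean distance to the corner (E_in = 0,
E_out = ln 20). A configuration switch replaces the theoretical corner by the
empirical one (minimum observed E_in, maximum observed E_out within the
branch), which rescales but rarely reorders the top ranks.

Branch aggregation defaults to the **minimum** over eligible branches: a
residue is binding-like if *any* well-sized subfamily conserves it, and the
minimum is invariant to how finely the tree happens to subdivide the
neighborhood of the query. A size-weighted mean (Σ j·s / Σ j, j the branch
size) is provided as the smoother alternative; the choice is recorded in the
output metadata. Ranks ascend in the final score with ties broken by BW
position order, so tables are reproducible bit-for-bit.

## Performance measure

pROC AUC = (1/n) Σᵢ log₁₀(1/βᵢ), with βᵢ the fraction of false positives
ranked above the i-th true residue. βᵢ is clamped below at 1/n_false: the
measure otherwise diverges when a true residue outranks every false one, and
the clamp reproduces the canonical calibration — a perfect ordering among 100
false positives scores exactly log₁₀ 100 = 2.0. True positives above a true
positive do not count as false. The random-ranking expectation is 1/ln 10 ≈
0.4343 asymptotically; at finite size (5 true among 166 false) the exact
expectation is ≈ 0.4365, which the Monte-Carlo acceptance check approaches
within sampling error.

The *theoretically optimal* generic baseline orders the reference positions
by how many receptors use them for ligand binding, ties broken by BW position
order, followed by all remaining positions in BW order. Equal-usage ties are
genuinely arbitrary and shift per-receptor values by a few tenths; the
recomputed 10-receptor mean (≈ 1.77 under BW-order ties) is therefore
reported as context, not asserted against any particular published rounding.
The *top-ranked* transform stably promotes a given position set (the 22
reference positions) ahead of all others, mirroring how pocket knowledge can
be injected into any ranking. External rankings (e.g. Multi-RELIEF) are read
from a two-column TSV and evaluated by the identical code path, never
recomputed.

The packaged reference fixture (10 receptors, 47 residue memberships, 22
distinct positions) reproduces the literature-curated table verbatim,
including one known oddity: the PI2R set contains 7.40, which lies outside
the 28-position pocket definition. The fixture preserves the published
content rather than resolving the inconsistency.

## Synthetic data

The generator emulates exactly the structure the score assumes: *binding*
columns draw a subfamily-specific letter with probability `c` (default 0.95)
inside their subfamily and the background distribution outside; *structural*
columns draw one letter conserved across all records (default probability
0.95, at the `x.50`-style anchor positions); *background* columns are i.i.d.
background (default uniform over 20 letters; a Swissprot-like preset is
included). The canonical conditions are 10 subfamilies of 60 (600 records),
the focal subfamily carrying 5 binding columns at known pocket positions, 10
structural columns, 156 background columns. Everything is deterministic per
seed.

Two caveats delimit what passing tests show. First, with i.i.d. background
columns the planted subfamily is invisible to p-distance except through its
5 binding columns, so under the canonical conditions the tree cannot recover
it; scorer-recovery checks therefore use the planted subfamily directly,
while tree-route integration uses the optional `relatedness` parameter (a
per-subfamily ancestral letter mixed into background columns, off by
default), which gives subfamilies the overall similarity real ortholog
clusters have. Second, real alignments violate the generator's independence
assumptions (columns co-evolve, subfamilies are nested and unevenly sized,
conservation varies by position), so synthetic recovery rates bound the
method's behavior under its own model, not its accuracy on real receptors.

The helix-sequence generator plants the seven profile consensus windows (per
column: consensus letter with probability 0.9, else uniform) in order, joined
by uniform-random linkers of 5–30 residues, and emits per-record
frequency-matched shuffles as decoys — ground truth for placement, order
repair, calibration and the 4-of-7 quality rule.

## Problem sizes and numerical conventions

Tests and the acceptance script run on desk-scale inputs chosen to make the
statistics stable: 600-sequence alignments, 100 generator seeds for recovery
rates, 10,000 random rankings for the pROC baseline, calibration samples of a
few hundred artificial sequences. Entropies use natural logs throughout;
quantiles use lower interpolation; all RNGs are NumPy `default_rng` seeded
explicitly, and every pipeline output is deterministic given its inputs and
seed.

## Known limitations

- Scope is the 171 TM columns of class A non-olfactory receptors; nothing is
  predicted for loops, termini, or other GPCR classes.
- The method needs deep, multi-species alignments: receptors whose subfamily
  window [50, 300] is empty cannot be scored without relaxing the window.
- Sequence retrieval (database BLAST searches) is out of scope; the pipeline
  starts from user-supplied FASTA.
- The score treats columns independently; correlated substitutions and
  allosteric sites conserved for non-binding reasons can rank high.
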