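# Methods

## The locus and the data model

The PRDM9 zinc-finger array is a tandem repeat of 84-bp units, each
encoding one 28-residue C2H2 finger. An *allele* here is the DNA sequence
of the whole array; because units recur, an allele is stored both as DNA
and as an ordered string of two-character unit codes. Unit codes, `M#`
allele names and five-part variant names (`type:complexity:number:donor:
parental-genotype`) follow the published nomenclature; the novel-unit code
space `!A`–`!Z` is extended with lowercase letters and digits so that
simulations cannot exhaust it. Allele equality is defined on the DNA
string, not the name: registering a second name for an identical sequence
is rejected at catalog load.

## Read processing

**Demultiplexing.** Amplicons carry an outer (second-round) and an inner
(primer) barcode at each end, the inner's reverse complement at the far
end. A read is assigned when exactly one (outer, inner) pair matches
within edit-distance budgets (outer ≤ 2, inner ≤ 1) in the front window of
either orientation; ties and orientation conflicts go to the unassigned
bin, so `reads_in = assigned + unassigned` always holds. The eight 12-nt
inner barcodes are the published primer barcodes; the 96 outer barcodes in
the production protocol are a vendor kit, so the package ships 96
deterministic **synthetic** 24-nt stand-ins with minimum pairwise Hamming
distance 8 — capacity arithmetic (8 × 96 = 768) and the matching logic are
unaffected by the actual sequences.

**Flank anchoring.** The array is delimited by two fixed 252-nt genomic
flanks (packaged verbatim). Each flank is located by infix alignment
(edlib, edit distance), on both strands; a hit counts when identity over
the anchor is ≥ 0.75. The original pipeline used Smith–Waterman scores
here; an edit-distance identity floor is an equivalent, parameter-light
criterion for anchors this long, and the floor is config-exposed. Reads
missing either flank, or with flanks out of order, are rejected — this is
the filter that removes PCR slippage ladders with *incomplete* arrays.
Wrong-length but complete arrays pass on purpose; the genotyper's length
rules absorb them.

**Unit tiling.** The inter-flank interval is decomposed 5'→3' by aligning
every catalog unit as a prefix of the remaining sequence (edlib SHW) and
taking the best; a unit is accepted at identity ≥ 0.75 if it consumes at
least half of 84 read bases. The alignment CIGAR projects the read segment
onto unit coordinates: read gaps become `N`, read insertions are dropped,
so every tiled unit is exactly 84 characters and reads of the same unit
count are position-aligned without a multiple alignment step. Gap
tolerance between units is 0 (strict contiguity); any uncovered interior
sequence fails the read. The original used BLASTN (word size 7) for this
step; in-process alignment removes the external dependency and its
sensitivity knobs are re-expressed as the identity and coverage floors.

## Genotyping

Individuals with fewer than 100 retained reads are not called. The two
haplotype lengths come from a five-rule table over the frequencies of the
most, second and third most frequent unit counts (*f_i, f_j, f_k*; count
ties order toward the smaller length):

| # | condition | call |
|---|-----------|------|
| 1 | single observed length | (i, i) |
| 2 | f_i+f_j ≥ 0.7 and f_i/f_j < 2 | (i, j) |
| 3 | f_i+f_j ≥ 0.7 and f_i/f_j < 3 and f_j/f_k > 2 | (i, j) |
| 4 | f_i+f_j ≥ 0.7 and f_i/f_j > 3 | (i, i) |
| 5 | f_i ≥ 0.7 | (i, i) |

Rules fire consecutively; the boundary ratios are strict as printed, so
f_i/f_j exactly 3 escapes rules 3 and 4 and can only be called by rule 5.
With fewer than three lengths f_k is 0 and f_j/f_k is +∞. No rule firing
is a no-call.

Reads at the called lengths are kept. For unequal-length calls each length
group gets a per-position majority consensus; consensus frequency *f_c*
excludes Ns and gaps from the denominator, and an allele is discarded if
any position has *f_c* < 0.6. For equal-length calls, if every position
has *f_c* ≥ 0.7 the individual is homozygous; otherwise reads are reduced
to the positions with *f_c* < 0.7, pairwise mismatch distances (N excluded
pairwise) feed complete-linkage hierarchical clustering, and the cluster
count n ∈ [1, 19] minimizing the pooled mean within-cluster pairwise
distance is chosen. The minimum is degenerate toward large n (singletons
contribute no pairs), so ties break toward the smallest n and only the two
largest clusters are taken as haplotypes — our reading of the published
procedure, flagged as an interpretation. Each cluster consensus is
re-checked against the 0.7 floor; a failing cluster fails that allele but
the partner allele is retained with a qc flag (the alternative — dropping
the individual — is not what we chose, since partial information is still
usable downstream when flagged). Consensus ambiguities (all-N positions)
fail the allele rather than minting fingers containing N.

The pipeline is deterministic: reads are sorted by id before consensus,
base ties break alphabetically, and no step draws random numbers.

## Allele typing and cohort statistics

Contact residues sit at helix positions −1, 3 and 6 of each finger,
located by anchoring on the conserved C-terminal His pair (first His =
helix position 7, so the contacts are 8, 4 and 1 residues before it);
offsets are overridable for non-canonical scaffolds. An allele's profile
is one 3-residue token per finger. Similarity to the A and C references is
a global token alignment (match 1, mismatch 0, gap −0.5) normalized by the
reference token count; the label is the larger similarity when it reaches
0.5, and exact ties or sub-threshold maxima are untyped. The full
reference token list is scored, not only fingers known to contact DNA —
the alternative weighting was considered and rejected for want of a
principled subset. Length comparison between types uses the two-sided
Wilcoxon rank-sum test in its tie-corrected normal approximation. Allele
frequencies count two chromosomes per qc-passing individual, with
Clopper–Pearson intervals at 99%. Trio consistency asks whether the
child's allele pair can be split one-from-each-parent (DNA identity);
cross-platform concordance compares unordered allele-DNA pairs per
individual, reported per zygosity category and overall.

## Template switching

A child allele is derivable from parents (P1, P2) if it can be written as
alternating exact fragments, the first anchored at a parent's 5' end, the
last ending at a parent's 3' end, every fragment strictly longer than 15
nt. The greedy solver repeatedly takes the longest match of the child's
current 5' remainder in the other parent (leftmost on ties), runs from
both starting parents and keeps the cheaper path. The published step 3
says "longest common subsequence"; this is implemented as the longest
exact common *substring* anchored at the remainder's 5' end, since only
substring semantics can satisfy the requirement that concatenated
fragments rebuild the child byte-exactly. Switch counts are unbounded in
principle; a safety cap (default 50) bounds runtime. Self-pairs model
uni-parental derivation, including derivations with switches within one
allele (a one-finger deletion is one switch; a displaced block duplication
is two — a tandem duplication, by contrast, is a single back-jump).

The exact solver is a dynamic program over (child position, active
parent): feasible next-segment lengths at a position form the interval
(15, max longest-common-extension], computed from LCE tables, and the
recursion minimizes switch count with the same anchoring constraints. It
is the oracle for the greedy solver in tests (greedy ≥ exact everywhere;
equality whenever junction contexts are unique). Catalog scans classify
each child as uni, bi, uni-or-bi or unreachable according to whether
single-parent and/or genuinely two-parent derivations achieve the minimal
count; cohort summaries group parental pairs by type class (A×A, A×C,
C×C) and report per-child minima and class averages.

## The simulator

Synthetic fingers share a fixed C2H2-like scaffold (conserved Cys and His
codons, contact residues at the canonical offsets, two silent wobble
sites), so units are homologous — pairwise identity ≥ 85%, comfortably
inside the real minisatellite regime — and translations are stop-free.
`simulate_typed_catalog` builds two allele families from disjoint
contact-residue alphabets: 50 A-like alleles around 13 fingers and 21
C-like around 15, the composition and medians of the published human
catalog, with variants produced by single-finger substitution, duplication
and deletion. Reads are full amplicons (outer+inner barcode, 5' flank,
array, 3' flank, reverse-complemented barcodes), half emitted
reverse-complemented. The default error model — 1% substitutions, 0.5%
insertions, 0.5% deletions per base, 10% whole-unit slippage per read
(shifts ±1 weighted 0.8, ±2 weighted 0.2), 2% 3' truncation — was chosen
to stress the 0.6/0.7 consensus floors without overwhelming them, in the
regime of CCS/corrected long reads the genotyper targets. Slippage is
whole-unit gain/loss only; partial-unit chimeras and signal-level noise
are not modeled, so passing tests demonstrate the pipeline's logic under
the stated artifact classes, not platform-specific base-caller behavior
(e.g. context-dependent CpG errors are upstream of this tool's scope).
All outputs are functions of (parameters, seed).

## Problem sizes and numerical choices

The end-to-end evaluation uses 200 simulated diploid individuals at 150×
coverage through the full demultiplex→extract→genotype chain, the rule
tracer 10⁴ random tables, and the path-identity fuzz 10³ instances —
sizes at which the whole suite completes in minutes on one CPU while
estimating recovery rates to within a few tenths of a percent. Edit
thresholds: flank and unit identity floors 0.75, unit coverage floor 0.5
(42 of 84 bases), barcode budgets 2/1 edits. Consensus tie-breaks are
alphabetical; cluster-count ties take the smallest n; equal-cost greedy
paths prefer the start-with-P1 solution; frequency ties among lengths
prefer the smaller unit count. All thresholds default to the published
values where one exists and are exposed as function parameters.

## Known limitations

- The published human allele catalog is not bundled, so catalog-specific
  numbers (e.g. the exact derivability fractions and the 9-vs-2 switch
  averages for cross-type derivations) are reproduced
  structurally on synthetic two-family catalogs rather than verbatim.
- The A/C similarity scoring realizes a criterion the original describes
  only qualitatively; the concrete match/mismatch/gap scheme and the 0.5
  floor are this package's frozen choices, exposed as parameters.
- Demultiplexing is a generic fuzzy matcher, not a re-implementation of
  vendor tools; score cutoffs do not map one-to-one onto vendor scores.
- Genotypes are called per individual; no joint calling, base-quality
  weighting, or chimeric-read splitting.
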