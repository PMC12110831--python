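# Methods

This note documents the models and procedures implemented in
`mitochar`, the parameter choices that matter, what the synthetic-data
generators do and do not emulate, and the package's known limitations.

## Coordinate model

Features live on a circular genome with 1-based, fully inclusive
coordinates on the deposited heavy (H) strand, so length =
end − start + 1 and a published gene table is reproducible cell by
cell. A feature wrapping the origin is encoded as start > end; no
negative coordinates exist. Strand `L` means the annotated gene is read
from the reverse complement. The two rRNA labels found in some deposits
("18S"/"12S") are normalized by length to the mitochondrial `rrnL`
(≈1.4 kb) and `rrnS` (≈0.8 kb), keeping the original labels available.
Ambiguity codes are preserved in sequence but excluded from every
composition denominator (tallied separately), since the statistics
assume pure A/C/G/T.

## Composition and skew

AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C), computed equivalently
from counts or percentages. Whole-genome values use the H strand as
deposited; per-gene values use the coding strand obtained by extraction
— this is what makes the GC skew of L-strand genes (ND1/ND4/ND4L/ND5 in
the lepidopteran arrangement) come out positive while the genome-wide
GC skew is negative. Codon-position composition pools positions 1/2/3
of every *retained* codon (see below) across all PCGs. Reports round
percentages to 2 decimals and skews to 4; tests compare at ±1 in the
last printed digit, and all arithmetic is full precision internally.

## Codon usage

Codons are read in frame from the first position of the coding strand.
The trailing 1–2 nt remainder of a CDS whose length is not a multiple
of 3 is an incomplete stop (`T`/`TA`, completed to UAA on the
transcript); a terminal complete stop (TAA/TAG) is dropped from usage
counts; the start codon is retained. This convention makes the retained
total over the 13-PCG layout exactly 3696 codons, matching the
published count identity Σ⌊len/3⌋ − #complete stops. Internal stop
codons (possible in mutated or synthetic input) are excluded from
counts and reported with a warning instead of aborting. RSCU is
n_c · k / Σ_family n with family sizes from NCBI translation table 5
(Ser 8, Leu 6, Trp 2); empty families report RSCU 0 for all members and
are flagged. Tables render in the RNA alphabet; everything is DNA
internally.

One source-table cell is internally inconsistent: the ACC (Thr) RSCU
recomputes to 0.376 from the printed counts, which rounds to 0.38, not
the printed 0.37. Cell-level checks therefore allow ±0.011 (±1 in the
last printed digit); the headline values are exact.

## Architecture accounting

Features sorted by linearized start form a single circular successor
relation, mixing strands in one ledger (the convention of printed
mitogenome gene tables). For consecutive features the signed gap is
next.start − prev.end − 1: positive = spacer, negative = overlap,
zero = abutting. The junction across the origin is included (in the
reference layout the D-loop ends at position 15,380 and tRNA-Met starts
at 1, contributing gap 0), which yields the conservation law
Σ feature lengths − Σ overlaps + Σ spacers = genome length, checked
exactly on every valid annotation. A feature nested inside its
predecessor is flagged but still related only to its circular
successor.

Gene orders are compared rotation-invariantly, anchored at tRNA-Met
(fallback: lexicographically smallest label, flagged). Breakpoints
count adjacencies of one order absent from the other, with the circle
treated as unoriented (both reading directions of the second order are
admitted), so a two-gene inversion in an otherwise identical circle
scores 2.

The tandem-repeat scanner does an exhaustive period × start search:
the first window is the template and successive (possibly partial)
copies extend the repeat while each copy's identity to the template is
at least `min_identity`; spans contained in an already-kept repeat are
suppressed. Defaults (period 2–50, ≥2.0 copies, identity ≥0.8) emulate
a common Tandem Repeats Finder operating point and are config-exposed;
they are a screening heuristic, not a reimplementation of TRF's
alignment-scoring model.

## tRNA cloverleaf folding

Folding is an exhaustive search over an anchored four-arm template, not
free-energy minimization. The annotated anticodon must sit centered in
the anticodon loop; arms are bounded by canonical ranges (acceptor 6–8
bp with an optional 1 nt 3' tail, DHU stem 0–4 bp with 3–10 nt loop,
anticodon stem 3–6 bp with 5/7/9 nt loop, TψC stem 0–5 bp with 3–9 nt
loop, connector sizes 1–3 / 0–2 / 0–9 nt). Stems admit Watson–Crick
plus G–T wobble pairs and must pair at every position; the fold
maximizing total paired bases wins, with ties broken by more
Watson–Crick pairs, then longer acceptor stem, then the 5'-most DHU
arm, making the result deterministic. Template ranges are deliberately
wider than the arm sizes observed in any one genome so the method is
not overfit to a single dataset; observed ranges are report outputs,
not constraints. A stem of length 0 reports the arm as missing
(mitochondrial serine tRNAs commonly lack the DHU arm); a sequence
admitting no feasible template is returned as an unfoldable diagnostic,
not an exception. The left (DHU) and right (TψC) segments are optimized
independently given the anchored anticodon and acceptor stems, which is
exact because their scores are additive; tests verify equivalence with
a naive full-grid enumeration. Wobble ("mismatched") pairs are G–T
pairs inside stems — counted, never forbidden.

## Phylogeny stage

This stage is an explicit desk-scale surrogate for full Bayesian/ML
inference, which is out of scope: its validation surface is exact
recovery on additive matrices and topology recovery on simulated data,
not the support values of any published tree. Per-gene alignments are
concatenated in configured (default: sorted-name) order — never input
order — with missing taxa gap-padded and a partition table emitted.
Distances are p or Kimura two-parameter,
d = −½ ln((1−2P−Q)√(1−2Q)), with pairwise deletion of gap/ambiguity
sites; a saturated pair (log argument ≤ 0) raises in the scalar API and
is replaced by a flagged finite fallback (5 substitutions/site) in the
matrix builder. Neighbor joining follows Saitou–Nei with deterministic
tie-breaking by taxon-label order (internal nodes inherit the smallest
label beneath them) and negative branch lengths clamped to zero and
counted. Bootstrap resamples supermatrix columns with replacement under
a single integer seed; support is the percentage of replicates
containing each internal bipartition of the full-data tree, invariant
to taxon input order because taxa are sorted before any computation.
Outgroup rooting splits the chosen edge at its midpoint; a
non-monophyletic outgroup is flagged and the root is placed
deterministically on the split containing all outgroup taxa with the
fewest extras.

## Synthetic data

`generate_mitogenome` realizes the published *A. lactinea* layout by
default: the exact coordinates, strands, anticodons and start/stop
codons of the 38-feature gene table, codon-profile weights from the
published usage counts, and the published A+T targets for the noncoding
classes (rRNA 85.28%, control region 74.25%, spacers 81%). Start/stop
codons are pinned first, tRNAs are built by the cloverleaf constructor
(default planted arms 7/4/5/4 bp, loops sized to each gene's length;
positions already pinned by overlapping genes are honored with stem
partners kept complementary), PCG bodies are then drawn codon-by-codon
from the profile (sense codons only, consistent with pinned positions),
and remaining positions are sampled i.i.d. at their class targets. The
manifest records the realized codon counts, the planted folds and the
geometric ground truth, all of which the pipeline recovers exactly;
composition targets hold in expectation only, so recovery tests use
3σ binomial tolerances.

Two generator choices exist purely to make planted folds uniquely
recoverable: loop and spacer positions draw from {A, C} (which cannot
pair with each other), boundary bases are adjusted so no stem can be
extended by chance, the outermost anticodon stem pair is pinned A–T,
and planted wobble pairs go in the acceptor stem, whose pair positions
are anchored at the sequence ends and cannot be re-paired by a rival
template. Real tRNAs are of course not so cooperative; what passing
recovery tests show is that the folder finds a planted maximum
exactly, not that it reproduces experimentally determined structures.

The generators do not emulate context-dependent mutation, indels,
heteroplasmy, or sequencing error; alignments are simulated
site-independently under Jukes–Cantor (child base kept with probability
e^(−4t/3), else uniform), so the expected p-distance over a path of
length t is ¾(1 − e^(−4t/3)). Conclusions about real data should rest
on the exact table recomputation, not on generator recovery.

## Problem sizes and determinism

The test suite runs study-scale problems: one 15,380 bp synthetic
genome (session fixture), 100 four-taxon Jukes–Cantor replicates at
10 kb for topology recovery, 100 kb pairs for distance consistency, and
brute-force fold enumeration on ≤70 nt sequences. Every stochastic
component draws from a single `numpy` Generator seeded with one
integer; fixed seeds make all fixtures and reports byte-reproducible.

## Known limitations

- The GenBank reader handles the common single-record flat-file layout
  (CDS/tRNA/rRNA/D-loop, `complement()`, origin-spanning `join()`); it
  is not a general-purpose GenBank round-tripper.
- The cloverleaf template assumes the canonical arm order and cannot
  represent pseudoknots, modified bases, or arms rearranged beyond the
  0-length-stem convention.
- Breakpoint counts are adjacency-based; no rearrangement-distance
  model (inversions, DCJ) is implemented.
- The phylogeny stage is distance-based by design; it does not attempt
  model selection, ML search, or Bayesian inference, and bootstrap
  supports from NJ are not comparable to posterior probabilities.
- Cross-species comparison tables require external accessions and are
  out of scope.
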