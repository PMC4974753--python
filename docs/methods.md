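# Methods

## SSR detection

A locus is a maximal run of a primitive motif (2–8 bp; a motif that is
itself a repetition of a shorter unit, like ATAT, is never used — the run
is reported once under the shortest generating unit). Detection compares
each base with the base one period ahead (vectorized over the sequence),
so a maximal period-*k* stretch of length *L* holds ⌊L/k⌋ complete copies;
the locus spans complete copies only, anchored at the leftmost position of
the stretch, and coordinates are 1-based inclusive everywhere.

Class thresholds are minimum total array lengths — di/tri/tetra 18 bp,
penta 20, hexa 24, hepta 21, octo 24 — converted to complete-copy counts
by ceiling (tetra: ⌈18/4⌉ = 5 copies = 20 bp, the only integer reading of
an 18 bp minimum). Mononucleotides are excluded. IUPAC ambiguity codes are
tolerated in input but terminate runs: a repeat spanning an N is not a
bona fide tandem array. Compound SSRs merge adjacent loci separated by at
most `max_interruption` bp (default 100, the conventional mining default;
configurable).

Overlapping runs of *different* motif families are all reported; perfect
loci of one family never overlap (they would be one maximal run).

## Primer design

The picker enumerates every candidate primer in a window (default 150 bp)
on each flank, filters on length 18–24 (optimum 20), Tm 50–60 °C (optimum
55), GC fraction 0.20–0.80, and absence of a perfect self-complementary
stretch ≥ 8 bp, then scores pairs lexicographically by summed |Tm − 55|,
then summed |length − 20|, then leftmost position, subject to a 100–300 bp
product containing the whole array. The search is exhaustive over the top
80 candidates per flank, so results are deterministic across platforms.

Tm is the nearest-neighbor duplex model with the SantaLucia & Hicks (2004)
unified parameter table as shipped in Biopython (`Tm_NN`, `DNA_NN4`),
50 mM monovalent salt with the entropic salt correction, 25 nM for both
strands. Only the 50–60 °C window is contractual; the model and
concentrations are fixed package defaults chosen for reproducibility, and
the test suite pins them against an independent reimplementation of the
same table to 0.1 °C.

## Electronic PCR

The binding rule is asymmetric: mismatches are allowed only inside the
5′-most `five_prime_window` positions (default 5 — the smallest window
consistent with allowing "up to 5" mismatches at the 5′ end), capped at
`max_5prime_mismatches` (5) and by the overall identity floor (0.90)
jointly; every position outside the window, including the 3′ terminus,
must match exactly, and no indels are allowed (primer extension tolerates
none at the 3′ end). For a 20-mer the identity floor is the binding
constraint (⌊20 × 0.10⌋ = 2 mismatches); the 5-mismatch cap only becomes
reachable for primers of ≥ 50 nt — both are enforced together.

Sites are found by seed-and-verify: the exact 3′ portion is the seed
(string search over the target and its reverse complement), the 5′ window
is verified at each hit. Because any legal site must match the seed
exactly, this provably equals a brute-force scan over all offsets and
strands, which the tests and acceptance script check directly on planted
genomes with decoy sites at the 2-vs-3-mismatch identity boundary and at
the 3′ terminus.

Amplicons pair a + strand site of one primer with a downstream − strand
site of the other, in both primer arrangements, so results are invariant
under reverse-complementing the target. Product bounds for e-PCR default
to [50, 3000] bp (the study conditions do not bound them; configurable).
Transferability: exactly one amplicon = single-copy (transferable),
≥ 2 = multi-copy, 0 = absent. Genic annotation is interval overlap
(≥ 1 bp) against GFF3/BED features — a deliberate surrogate for
database-search annotation of product sequences.

## Synteny blocks

Shared markers (single-copy on both genomes, positioned at locus/amplicon
midpoints) are sorted per source chromosome; each gets its positional rank
among the markers of its target chromosome. Blocks are maximal runs in
which the target chromosome is constant and successive target ranks differ
by exactly ±1 in a constant direction ("continuous physical positions on
both genomes"). Requiring consecutive ranks rather than mere monotonicity
is what makes block calling symmetric under swapping the genomes: a
translocated segment leaves a rank gap in its donor flanks that pure
monotonicity would ignore in one direction but split in the other. A
`max_rank_gap` parameter (default 0) relaxes this to skipping ≤ g
interleaved markers. Runs shorter than `min_block_markers` (default 3) are
dropped. Orientation is collinear for increasing ranks, inverted for
decreasing. Spans are reported first-to-last marker, not extended to
breakpoint midpoints. Conserved three-genome blocks are pairwise member
intersections (≥ 3 shared members) of blocks over a common source genome.

Because the block-delimiting rule of comparable published analyses is
under-specified (gap tolerance, handling of stray markers), genome-scale
block counts are not comparable across tools; validation here is entirely
against planted rearrangements.

## Diversity statistics

Frequencies use pairwise deletion: per locus, missing genotypes leave the
denominator (2 × scored genotypes); missing data are never imputed. The
statistics are direct sums over the frequency vector (Na, Ne = 1/Σp²,
He = 1 − Σp², I = −Σp ln p, Ho = heterozygote fraction). PIC defaults to
the Botstein form 1 − Σp² − Σᵢ<ⱼ 2pᵢ²pⱼ²; an "he" variant (1 − Σp²) and a
"legacy" Σp² form (expected homozygosity, occasionally printed as "PIC" in
the SSR literature) are selectable because source formulas in this
literature are often ambiguous — the Botstein form is the one consistent
with PIC as a polymorphism measure.

The accession distance is the allele-sharing distance, d = 1 − mean over
jointly scored loci of (shared alleles / 2), chosen as the standard
codominant metric where the original tool's metric is not documented.
UPGMA uses size-weighted arithmetic-mean updates; the pair with minimal
distance is joined, ties broken by the lexicographically smallest cluster
leaf sets, so output is fully deterministic; node height is half the
joining distance and the tree is ultrametric by construction (verified to
1e-9 in tests, cross-checked against scipy average linkage).

ΔK uses second differences of per-K replicate means
L″(K) = L̄(K+1) − 2L̄(K) + L̄(K−1) over the replicate standard deviation at
K (ddof = 1): replicates are not paired across K, so per-replicate second
differences are not defined. sd = 0 with non-zero curvature yields a +inf
sentinel with a warning; with zero curvature, ΔK = 0. Endpoints of the K
range have no ΔK.

## Synthetic data

Generators are deterministic given (parameters, seed) and write a JSON
planting record that fully determines the fixture; oracle tests read truth
only from the record.

* `make_ssr_genome` — uniform A/C/G/T background, rejection-sampled until
  no incidental array reaches any class threshold (real genomes are *not*
  SSR-free outside annotated loci; this property is what makes precision
  exactly measurable). Planted loci get ≥ 400 bp margins and bases breaking
  the array at both ends; a verification pass re-randomizes any junction
  artifact. Defaults: 100 kb, 50 loci, uniform class mix, copy numbers
  from min_repeats to min_repeats + 5.
* `derive_partner_genome` — inverts/translocates segments of
  `segment_markers` consecutive loci cut at inter-marker midpoints, with
  ≥ 3 undisturbed context loci around each segment; translocations move to
  another chromosome (an intra-chromosomal move can be rank-consistent and
  hence undetectable by any order-based rule). Point mutations are
  Bernoulli per base, sparing the planted arrays and any caller-supplied
  protected intervals (e.g. primer footprints, which are unknowable at
  generation time). The record stores the piece layout — the planted
  synteny truth — and each marker's new midpoint.
* `simulate_genotypes` — per population and locus, allele frequencies ~
  Dirichlet(divergence / A · **1**); diploid calls under Hardy–Weinberg.
  Defaults (K = 2, 25 accessions per population, 32 loci, 5 alleles,
  divergence 0.5) emulate a two-population germplasam panel genotyped at a
  few dozen informative SSRs; no linkage, admixture or mutation model.
* `simulate_lnpd` — piecewise-linear mean LnP(D) over K = 1…10 with the
  only slope break at the planted K (slopes +500 then +20 per K), Gaussian
  replicate noise (sd 30, 20 replicates), matching the usual scale of
  replicate scatter relative to the improvement at the true K.

Passing tests on these fixtures demonstrates algorithmic correctness under
the planted model — exact coordinates, exact block recovery — not
performance on real assemblies, whose repeat landscape, assembly gaps and
paralogy the generators deliberately omit.

## Problem sizes

The test suite and acceptance script run: planted-scan validation on
100 kb / 50 loci; brute-force scanner agreement on 50 (tests) / 20
(script) random 2 kb sequences; e-PCR brute-force agreement on 20 planted
100 kb genomes × 50 markers with decoy sites (tests; the script uses 5
genomes × 25 markers); 20 (tests) / 10 (script) seeded rearrangement
simulations of 60 markers on 3 chromosomes with 3 inversions + 2
translocations; 20-seed clustering-purity and 100-seed ΔK-recovery
batteries; and one end-to-end three-genome pipeline run (240 kb source,
two partners at 0.5 % divergence). These sizes keep the whole suite
around a minute or two while exercising every code path at planted-truth
resolution.

## Known limitations

* Imperfect (mismatch-containing) single arrays are not modeled; only
  perfect and compound SSRs are reported.
* The primer picker is a simplified deterministic stand-in for full
  thermodynamic design: no hairpin/heterodimer screening, no positional
  penalties beyond the documented score.
* e-PCR has no thermodynamic binding model and no degenerate-primer
  support; identity and window thresholds are the whole rule.
* Block calling operates on marker orders, not sequence alignment;
  breakpoints are resolved only to inter-marker gaps.
* Structure inference itself (MCMC admixture) is out of scope; only the
  ΔK post-processing of externally produced LnP(D) tables is implemented.
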