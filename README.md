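# ssrkit

Toolkit for genome-wide characterization of microsatellites (simple
sequence repeats, SSRs) in plant genome assemblies, and for the comparative
and population-genetic analyses built on SSR markers. It targets the
workflow used in cucurbit genomics — mine SSRs from a draft assembly,
design flanking primer pairs, test cross-species transferability by
electronic PCR against related genomes (e.g. watermelon markers against
cucumber and melon), call syntenic blocks from the shared markers, and
summarize germplasm diversity and population structure from codominant
genotypes — but every stage is generic.

## What it computes

**SSR mining.** Perfect tandem arrays of 2–8 bp motifs are reported when
they reach their class's minimum length: 18 bp for di-/tri-/tetra-,
20 bp for penta-, 24 bp for hexa-, 21 bp for hepta- and 24 bp for
octonucleotides (9/6/5/4/4/3/3 complete copies; mononucleotide runs are
excluded as indistinguishable from sequencing error). Adjacent arrays
separated by ≤ 100 bp merge into compound loci. Motifs are grouped into
canonical families under cyclic rotation and reverse complement
(AG ≡ GA ≡ CT ≡ TC).

**Marker design.** A deterministic primer picker over the locus flanks:
products 100–300 bp, primer length 18–20–24 nt, Tm 50–55–60 °C
(nearest-neighbor model), GC 20–80 %, no perfect self-dimer ≥ 8 bp.

**Electronic PCR.** A primer binds a site when all mismatches fall in the
5′-most 5 nt, with at most 5 mismatches, overall identity ≥ 90 %, and the
entire 3′ portion — including the extension terminus — matching exactly;
no indels. Convergent site pairs within the product bounds become
amplicons; a marker with exactly one amplicon on a related genome is
cross-species transferable, multi-product markers are flagged.

**Synteny.** Shared single-copy markers placed on both genomes are split
into maximal runs whose within-chromosome ranks are consecutive on both
genomes; runs of ≥ 3 markers are blocks, collinear when order agrees and
inverted when reversed. Block sets against two partners intersect into
three-genome conserved blocks; Circos link files are emitted.

**Diversity.** Per locus over allele frequencies *pᵢ*: Na, Ne = 1/Σpᵢ²,
He = 1 − Σpᵢ², Ho, Shannon's I = −Σpᵢ ln pᵢ, and PIC (Botstein:
1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ²). Accessions are clustered by allele-sharing
distance with UPGMA into an ultrametric Newick tree. The Evanno statistic
ΔK(K) = |mean L″(K)| / sd(L(K)) post-processes replicate LnP(D) tables
from a structure analysis; its argmax estimates the number of populations.

**Synthetic data.** Every analysis has a paired generator with a planted
ground-truth record: SSR-free backgrounds with planted loci, diverged
partner genomes built by segment inversions/translocations plus point
mutations, K-population Hardy–Weinberg genotype panels, and LnP(D) tables
with a planted elbow.

## Worked example

```python
import ssrkit as sk

seqs, record = sk.make_ssr_genome(length=80_000, n_loci=25, n_chromosomes=2, seed=2)
markers = sk.design_all(seqs, sk.planted_loci(record))
partner, _ = sk.derive_partner_genome(seqs, record, n_inversions=0,
                                      n_translocations=0, mutation_rate=0.01, seed=3)
table, amps = sk.classify_transferability(markers, partner)
print(len(markers), len(table.single_copy), len(table.absent))
```

prints `25 21 4`: all 25 planted loci admit a primer pair, and on a
relative diverged by 1 % point mutations 21 markers still amplify a single
product (transferable) while 4 lost a primer site. The
`examples/` directory has one narrative script per capability — scanning
and summaries, design + e-PCR, synteny blocks, diversity + ΔK — each
printing its numbers with a note on what they mean. A thin CLI mirrors the
library (`ssrkit scan|design|epcr|transfer|synteny|diversity|deltak|simulate|pipeline`).

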