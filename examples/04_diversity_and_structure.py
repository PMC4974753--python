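"""Diversity statistics, UPGMA dendrogram and Evanno ΔK on a simulated panel.

Simulates 50 accessions from two diverged populations genotyped at 32 SSR
loci (Hardy-Weinberg within populations), computes per-locus Na/Ne/Ho/He/
Shannon I/PIC, clusters accessions by allele-sharing distance, and picks
the number of populations from a replicate LnP(D) table via ΔK.
"""

import ssrkit as sk
from ssrkit.diversity import top_split

gm, labels, _ = sk.simulate_genotypes(K=2, n_per_pop=25, n_loci=32, seed=6)
freqs = sk.allele_frequencies(gm)
stats = sk.locus_stats(freqs, gm)  # Botstein PIC by default

print("per-locus statistics (first 5):")
print(stats.head().round(3).to_string(index=False))
print(f"\nmeans: Na {stats['Na'].mean():.2f}, He {stats['He'].mean():.3f}, "
      f"PIC {stats['PIC'].mean():.3f}")

# allele-sharing UPGMA dendrogram; the top split should separate the
# two simulated populations
newick = sk.upgma(sk.distance_matrix(gm))
left, right = top_split(newick)
by_acc = dict(zip(gm.accessions, labels))
purity = max(
    sum(by_acc[a] == 0 for a in left), sum(by_acc[a] == 1 for a in left)
) / len(left)
print(f"\nUPGMA top-split purity vs simulated populations: {purity:.2f}")

# Evanno ΔK from a replicate log-probability table with an elbow at K=2
runs, _ = sk.simulate_lnpd(elbow_k=2, replicates=20, seed=7)
res = sk.evanno_delta_k(runs)
print("\nΔK table:")
print(res.table.round(2).to_string(index=False))
print(f"best K = {res.best_k}  (ΔK peaks where LnP(D) stops improving)")
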