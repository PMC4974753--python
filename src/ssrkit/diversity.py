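"""Codominant-marker diversity statistics, UPGMA clustering and Evanno ΔK.

Per-locus statistics over allele frequencies p_i (estimated from the
non-missing diploid calls at that locus):

* Na — observed number of alleles
* Ne — effective number of alleles, 1 / Σ p_i²
* He — expected heterozygosity (gene diversity), 1 − Σ p_i²
* Ho — observed heterozygosity, fraction of heterozygous genotypes
* I  — Shannon's information index, −Σ p_i ln p_i
* PIC — polymorphic information content.  The default is the Botstein
  form 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²; the "he" variant (1 − Σ p_i²)
  and the "legacy" expected-homozygosity form (Σ p_i², occasionally
  printed as "PIC" in the SSR literature) are selectable.

Accession relatedness uses the allele-sharing distance
d(a,b) = 1 − mean over jointly scored loci of (shared alleles / 2),
clustered by UPGMA (arithmetic-mean linkage, ultrametric output,
deterministic lexicographic tie-breaking).

ΔK post-processing of population-structure replicate log-likelihood
tables: ΔK(K) = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K));
its argmax over interior K estimates the number of populations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = "-9"


@dataclass
class GenotypeMatrix:
    """Accession x locus diploid calls; each call an unordered allele pair
    of string labels (product sizes, typically) or None for missing."""

    accessions: list[str]
    loci: list[str]
    calls: dict[tuple[str, str], tuple[str, str] | None]

    def call(self, accession: str, locus: str) -> tuple[str, str] | None:
        return self.calls.get((accession, locus))

    def to_frame(self) -> pd.DataFrame:
        """STRUCTURE-style layout: two columns per locus, -9 = missing."""
        cols: dict[str, list[str]] = {}
        for loc in self.loci:
            a1, a2 = [], []
            for acc in self.accessions:
                c = self.call(acc, loc)
                a1.append(c[0] if c else MISSING)
                a2.append(c[1] if c else MISSING)
            cols[f"{loc}.1"] = a1
            cols[f"{loc}.2"] = a2
        return pd.DataFrame(cols, index=pd.Index(self.accessions, name="accession"))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        loci = []
        for c in df.columns[::2]:
            if not c.endswith(".1"):
                raise ValueError(f"expected paired allele columns, got {c!r}")
            loci.append(c[:-2])
        calls = {}
        for acc, row in df.iterrows():
            for loc in loci:
                a1, a2 = str(row[f"{loc}.1"]), str(row[f"{loc}.2"])
                missing = a1 in (MISSING, "", "nan") or a2 in (MISSING, "", "nan")
                calls[(str(acc), loc)] = None if missing else (a1, a2)
        return cls(accessions=[str(a) for a in df.index], loci=loci, calls=calls)


def allele_frequencies(gm: GenotypeMatrix) -> dict[str, dict[str, float]]:
    """Per-locus allele frequencies over non-missing calls (pairwise deletion)."""
    freqs: dict[str, dict[str, float]] = {}
    for loc in gm.loci:
        counts: dict[str, int] = {}
        n = 0
        for acc in gm.accessions:
            c = gm.call(acc, loc)
            if c is None:
                continue
            n += 1
            for allele in c:
                counts[allele] = counts.get(allele, 0) + 1
        if n == 0:
            raise ValueError(f"locus {loc!r} has no scored genotypes")
        freqs[loc] = {a: k / (2 * n) for a, k in sorted(counts.items())}
    return freqs


def pic_botstein(p: np.ndarray) -> float:
    s2 = float(np.sum(p**2))
    cross = float(np.sum(np.outer(p**2, p**2)) - np.sum(p**4)) / 2.0
    return 1.0 - s2 - 2.0 * cross


def locus_stats(
    freqs: dict[str, dict[str, float]],
    gm: GenotypeMatrix,
    pic_variant: str = "botstein",
) -> pd.DataFrame:
    """Na, Ne, Ho, He, I and PIC per locus (one row each)."""
    if pic_variant not in {"botstein", "he", "legacy"}:
        raise ValueError("pic_variant must be botstein, he or legacy")
    rows = []
    for loc in gm.loci:
        p = np.array(list(freqs[loc].values()), dtype=float)
        s2 = float(np.sum(p**2))
        he = 1.0 - s2
        shannon = float(-np.sum(p * np.log(p, where=p > 0, out=np.zeros_like(p))))
        n = het = 0
        for acc in gm.accessions:
            c = gm.call(acc, loc)
            if c is None:
                continue
            n += 1
            het += c[0] != c[1]
        if pic_variant == "botstein":
            pic = pic_botstein(p)
        elif pic_variant == "he":
            pic = he
        else:
            pic = s2
        rows.append(
            {"locus": loc, "Na": len(p), "Ne": 1.0 / s2, "Ho": het / n,
             "He": he, "I": shannon, "PIC": pic}
        )
    return pd.DataFrame(rows, columns=["locus", "Na", "Ne", "Ho", "He", "I", "PIC"])


def distance_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Allele-sharing distance between accessions.

    d(a,b) = 1 − mean over jointly non-missing loci of shared-alleles/2,
    where shared alleles counts the size of the multiset intersection of
    the two diploid calls (0, 1 or 2).  Raises if a pair shares no loci.
    """
    accs = gm.accessions
    if len(accs) < 2:
        raise ValueError("need at least two accessions")
    n = len(accs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tot = joint = 0.0
            for loc in gm.loci:
                a = gm.call(accs[i], loc)
                b = gm.call(accs[j], loc)
                if a is None or b is None:
                    continue
                joint += 1
                bl = list(b)
                shared = 0
                for allele in a:
                    if allele in bl:
                        bl.remove(allele)
                        shared += 1
                tot += shared / 2.0
            if joint == 0:
                raise ValueError(f"accessions {accs[i]!r}/{accs[j]!r} share no scored loci")
            d[i, j] = d[j, i] = 1.0 - tot / joint
    return pd.DataFrame(d, index=accs, columns=accs)


@dataclass
class _Node:
    leaves: tuple[str, ...]
    height: float
    newick: str


def upgma(dist: pd.DataFrame) -> str:
    """UPGMA dendrogram as a rooted ultrametric Newick string.

    Arithmetic-mean (size-weighted) cluster updates; each child branch
    length equals half the joining distance minus the child's own height.
    Ties are broken on the lexicographically smallest pair of cluster
    leaf-name tuples, so the output is fully deterministic.
    """
    labels = list(dist.index)
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    nodes = {i: _Node((lab,), 0.0, lab) for i, lab in enumerate(labels)}
    sizes = {i: 1 for i in nodes}
    dd = {(i, j): d[i, j] for i in nodes for j in nodes if i < j}
    nxt = len(labels)
    while len(nodes) > 1:
        best = min(
            dd,
            key=lambda ij: (dd[ij], min(nodes[ij[0]].leaves, nodes[ij[1]].leaves),
                            max(nodes[ij[0]].leaves, nodes[ij[1]].leaves)),
        )
        i, j = best
        h = dd[best] / 2.0
        a, b = nodes.pop(i), nodes.pop(j)
        children = sorted([a, b], key=lambda n: n.leaves)
        nw = "(" + ",".join(
            f"{c.newick}:{h - c.height:.10g}" for c in children
        ) + ")"
        new = _Node(tuple(sorted(a.leaves + b.leaves)), h, nw)
        si, sj = sizes.pop(i), sizes.pop(j)
        for k in list(nodes):
            if k == nxt:
                continue
            dik = dd.pop((min(i, k), max(i, k)))
            djk = dd.pop((min(j, k), max(j, k)))
            dd[(min(k, nxt), max(k, nxt))] = (si * dik + sj * djk) / (si + sj)
        dd.pop((i, j))
        nodes[nxt] = new
        sizes[nxt] = si + sj
        nxt += 1
    root = next(iter(nodes.values()))
    return root.newick + ";"


def newick_leaf_depths(newick: str) -> dict[str, float]:
    """Root-to-leaf path lengths of a Newick tree (used for ultrametric checks)."""
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(newick), "newick")
    return {t.name: tree.distance(tree.root, t) for t in tree.get_terminals()}


def top_split(newick: str) -> tuple[set[str], set[str]]:
    """Leaf sets of the two children of the root."""
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(newick), "newick")
    kids = tree.root.clades
    if len(kids) != 2:
        raise ValueError("root is not bifurcating")
    return (
        {t.name for t in kids[0].get_terminals()},
        {t.name for t in kids[1].get_terminals()},
    )


@dataclass
class DeltaKResult:
    table: pd.DataFrame  # columns K, mean_lnpd, sd_lnpd, abs_second_diff, delta_k
    best_k: int


def evanno_delta_k(runs: pd.DataFrame) -> DeltaKResult:
    """Evanno ΔK from a replicate log-probability table.

    ``runs`` needs columns (K, run, LnPD) with >= 2 replicates for each of
    >= 3 consecutive K values.  Second differences are taken on per-K
    replicate means; the denominator is the replicate standard deviation
    (ddof=1) at K.  A zero standard deviation yields an infinite ΔK
    sentinel.  ΔK is undefined at the endpoints of the K range.
    """
    required = {"K", "run", "LnPD"}
    if not required <= set(runs.columns):
        raise ValueError(f"runs table needs columns {sorted(required)}")
    g = runs.groupby("K")["LnPD"]
    ks = sorted(g.groups)
    if len(ks) < 3:
        raise ValueError("need at least three consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K range must be contiguous")
    counts = g.count()
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates per K")
    means = g.mean()
    sds = g.std(ddof=1)
    rows = []
    for k in ks[1:-1]:
        curv = abs(means[k + 1] - 2 * means[k] + means[k - 1])
        sd = sds[k]
        if sd == 0:
            if curv > 1e-12:
                warnings.warn(f"sd(LnPD) is zero at K={k}; ΔK reported as +inf")
                dk = math.inf
            else:
                dk = 0.0
        else:
            dk = curv / sd
        rows.append({"K": k, "mean_lnpd": means[k], "sd_lnpd": sd,
                     "abs_second_diff": curv, "delta_k": dk})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["delta_k"].idxmax(), "K"])
    return DeltaKResult(table=table, best_k=best)
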