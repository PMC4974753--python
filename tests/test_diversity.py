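"""Diversity statistics, allele-sharing distances, UPGMA and Evanno ΔK."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

import ssrkit as sk
from ssrkit.diversity import newick_leaf_depths, pic_botstein, top_split


def make_gm(calls_per_locus):
    """calls_per_locus: {locus: [ (a1,a2) or None per accession ]}."""
    loci = list(calls_per_locus)
    n = len(next(iter(calls_per_locus.values())))
    accs = [f"acc{i}" for i in range(n)]
    calls = {}
    for loc, col in calls_per_locus.items():
        for acc, c in zip(accs, col):
            calls[(acc, loc)] = c
    return sk.GenotypeMatrix(accessions=accs, loci=loci, calls=calls)


class TestAlleleFrequencies:
    def test_simple_counting(self):
        gm = make_gm({"L1": [("A", "A"), ("A", "B")]})
        freqs = sk.allele_frequencies(gm)
        assert freqs["L1"] == {"A": 0.75, "B": 0.25}

    def test_all_homozygous(self):
        gm = make_gm({"L1": [("A", "A"), ("A", "A")]})
        assert sk.allele_frequencies(gm)["L1"] == {"A": 1.0}

    def test_missing_excluded_from_denominator(self):
        gm = make_gm({"L1": [("A", "B"), None, ("B", "B")]})
        assert sk.allele_frequencies(gm)["L1"] == {"A": 0.25, "B": 0.75}

    def test_all_missing_locus_raises_naming_locus(self):
        gm = make_gm({"BAD": [None, None]})
        with pytest.raises(ValueError, match="BAD"):
            sk.allele_frequencies(gm)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_tally(self, seed):
        gm, _, _ = sk.simulate_genotypes(K=2, n_per_pop=10, n_loci=5, seed=seed)
        freqs = sk.allele_frequencies(gm)
        for loc in gm.loci:
            tally = {}
            n = 0
            for acc in gm.accessions:
                c = gm.call(acc, loc)
                if c is None:
                    continue
                n += 1
                for a in c:
                    tally[a] = tally.get(a, 0) + 1
            for a, k in tally.items():
                assert freqs[loc][a] == pytest.approx(k / (2 * n))


class TestLocusStats:
    def test_monomorphic_locus(self):
        gm = make_gm({"L1": [("A", "A"), ("A", "A")]})
        stats = sk.locus_stats(sk.allele_frequencies(gm), gm).iloc[0]
        assert (stats["Na"], stats["Ne"], stats["He"], stats["I"], stats["Ho"],
                stats["PIC"]) == (1, 1.0, 0.0, 0.0, 0.0, 0.0)

    def test_two_alleles_at_half(self):
        gm = make_gm({"L1": [("A", "B"), ("B", "A"), ("A", "A"), ("B", "B")]})
        stats = sk.locus_stats(sk.allele_frequencies(gm), gm).iloc[0]
        assert stats["Ne"] == pytest.approx(2.0)
        assert stats["He"] == pytest.approx(0.5)
        assert stats["I"] == pytest.approx(math.log(2))
        assert stats["PIC"] == pytest.approx(0.375)  # Botstein closed form
        assert stats["Ho"] == pytest.approx(0.5)

    def test_pic_variants(self):
        gm = make_gm({"L1": [("A", "B"), ("A", "B")]})
        freqs = sk.allele_frequencies(gm)
        assert sk.locus_stats(freqs, gm, pic_variant="he")["PIC"][0] == pytest.approx(0.5)
        assert sk.locus_stats(freqs, gm, pic_variant="legacy")["PIC"][0] == pytest.approx(0.5)
        with pytest.raises(ValueError):
            sk.locus_stats(freqs, gm, pic_variant="nope")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(6))
        s2 = sum(x**2 for x in p)
        he = 1 - s2
        shannon = -sum(x * math.log(x) for x in p)
        pic = 1 - s2 - sum(
            2 * p[i] ** 2 * p[j] ** 2 for i in range(6) for j in range(i + 1, 6)
        )
        assert pic_botstein(np.asarray(p)) == pytest.approx(pic, abs=1e-12)
        assert 1 / s2 <= 6 and he == pytest.approx(1 - s2)
        assert shannon >= 0

    def test_maximal_at_uniform_frequencies(self):
        rng = np.random.default_rng(0)
        uniform = np.full(4, 0.25)
        for _ in range(50):
            p = rng.dirichlet(np.ones(4))
            assert pic_botstein(uniform) >= pic_botstein(p) - 1e-12
            assert 1 - np.sum(uniform**2) >= 1 - np.sum(p**2) - 1e-12

    def test_invariance_under_relabeling_and_reordering(self):
        gm1 = make_gm({"L1": [("A", "B"), ("B", "C"), ("A", "A")]})
        gm2 = make_gm({"L1": [("x", "x"), ("z", "y"), ("y", "x")][::-1]})
        s1 = sk.locus_stats(sk.allele_frequencies(gm1), gm1).iloc[0]
        s2 = sk.locus_stats(sk.allele_frequencies(gm2), gm2).iloc[0]
        for col in ("Na", "Ne", "Ho", "He", "I", "PIC"):
            assert s1[col] == pytest.approx(s2[col])


class TestDistanceMatrix:
    def test_identical_accessions_distance_zero(self):
        gm = make_gm({"L1": [("A", "B"), ("A", "B")], "L2": [("C", "C"), ("C", "C")]})
        d = sk.distance_matrix(gm)
        assert d.iloc[0, 1] == 0.0 and d.iloc[0, 0] == 0.0

    def test_disjoint_alleles_distance_one(self):
        gm = make_gm({"L1": [("A", "A"), ("B", "B")], "L2": [("C", "D"), ("E", "F")]})
        assert sk.distance_matrix(gm).iloc[0, 1] == 1.0

    def test_one_shared_allele_is_half(self):
        gm = make_gm({"L1": [("A", "B"), ("A", "C")]})
        assert sk.distance_matrix(gm).iloc[0, 1] == 0.5

    def test_no_jointly_scored_loci_raises(self):
        gm = make_gm({"L1": [("A", "A"), None], "L2": [None, ("B", "B")]})
        with pytest.raises(ValueError):
            sk.distance_matrix(gm)


class TestUPGMA:
    def test_textbook_three_taxon_case(self):
        d = pd.DataFrame(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        assert sk.upgma(d) == "((A:1,B:1):2,C:3);"

    def test_equal_distances_resolved_deterministically_and_ultrametric(self):
        d = pd.DataFrame(1.0 - np.eye(4), index=list("ABCD"), columns=list("ABCD"))
        nw1, nw2 = sk.upgma(d), sk.upgma(d)
        assert nw1 == nw2
        depths = newick_leaf_depths(nw1)
        assert max(depths.values()) - min(depths.values()) < 1e-9

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], index=list("AB"), columns=list("AB"), dtype=float)
        with pytest.raises(ValueError):
            sk.upgma(d)

    def test_recovers_ultrametric_input_exactly(self):
        nw = sk.upgma(pd.DataFrame(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        ))
        depths = newick_leaf_depths(nw)
        assert all(abs(v - 4.0) < 1e-9 for v in depths.values())

    @pytest.mark.parametrize("seed", range(3))
    def test_cophenetic_agrees_with_scipy_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(8)]
        df = pd.DataFrame(d, index=labels, columns=labels)
        nw = sk.upgma(df)
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nw), "newick")
        Z = linkage(squareform(d), method="average")
        coph = squareform(cophenet(Z))
        terms = {t.name: t for t in tree.get_terminals()}
        for i in range(8):
            for j in range(i + 1, 8):
                got = tree.distance(terms[labels[i]], terms[labels[j]])
                assert got == pytest.approx(coph[i, j], abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_two_population_top_split_purity(self, seed):
        gm, labels, _ = sk.simulate_genotypes(K=2, seed=2000 + seed)
        nw = sk.upgma(sk.distance_matrix(gm))
        left, right = top_split(nw)
        by_acc = dict(zip(gm.accessions, labels))
        purities = []
        for clade in (left, right):
            votes = [by_acc[a] for a in clade]
            purities.append(max(votes.count(0), votes.count(1)) / len(votes))
        assert min(purities) >= 0.95


class TestEvannoDeltaK:
    def test_linear_lnpd_gives_zero_deltak(self):
        rows = [
            {"K": k, "run": r, "LnPD": -1000 + 50 * k + 0.01 * r}
            for k in range(1, 8) for r in range(3)
        ]
        res = sk.evanno_delta_k(pd.DataFrame(rows))
        assert (res.table["delta_k"] < 0.2).all()

    def test_noise_free_elbow_gives_infinite_sentinel_at_elbow_only(self):
        df, rec = sk.simulate_lnpd(elbow_k=3, noise_sd=0.0, seed=0)
        with pytest.warns(UserWarning):
            res = sk.evanno_delta_k(df)
        t = res.table.set_index("K")["delta_k"]
        assert res.best_k == 3 and math.isinf(t[3])
        assert all(t[k] == 0.0 for k in t.index if k != 3)

    def test_planted_elbow_recovered(self):
        df, _ = sk.simulate_lnpd(elbow_k=2, seed=5)
        assert sk.evanno_delta_k(df).best_k == 2

    def test_doubling_noise_halves_deltak_in_expectation(self):
        vals = {}
        for sd in (20.0, 40.0):
            dks = []
            for seed in range(40):
                df, _ = sk.simulate_lnpd(elbow_k=2, noise_sd=sd, seed=3000 + seed)
                t = sk.evanno_delta_k(df).table.set_index("K")["delta_k"]
                dks.append(t[2])
            vals[sd] = np.mean(dks)
        assert vals[20.0] / vals[40.0] == pytest.approx(2.0, rel=0.25)

    def test_input_validation(self):
        base = pd.DataFrame({"K": [1, 1, 2, 2], "run": [1, 2, 1, 2],
                             "LnPD": [0.0, 1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            sk.evanno_delta_k(base)  # only two K values
        gap = pd.DataFrame({"K": [1, 1, 2, 2, 4, 4], "run": [1, 2] * 3,
                            "LnPD": range(6)})
        with pytest.raises(ValueError):
            sk.evanno_delta_k(gap)
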