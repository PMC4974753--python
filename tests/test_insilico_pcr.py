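"""e-PCR: mismatch rule boundaries, brute-force agreement, transferability."""

import numpy as np
import pandas as pd
import pytest

import ssrkit as sk
from ssrkit.insilico_pcr import BindingSite
from ssrkit.ssr_scan import reverse_complement

from conftest import random_dna


def brute_force_sites(primer, target, rule=sk.MatchRule()):
    """All-offsets/all-strands scanner, no seeding tricks."""
    out = []
    n, w = len(primer), rule.five_prime_window
    cap = min(rule.max_5prime_mismatches, int(n * (1 - rule.min_identity) + 1e-9))
    for strand in "+-":
        p = primer if strand == "+" else reverse_complement(primer)
        # on '-', the primer's 5' window sits at the right end of the + strand site
        window = range(w) if strand == "+" else range(n - w, n)
        for i in range(len(target) - n + 1):
            site = target[i : i + n]
            mm_positions = [j for j in range(n) if site[j] != p[j]]
            if all(j in window for j in mm_positions) and len(mm_positions) <= cap:
                out.append(BindingSite(i + 1, strand, len(mm_positions)))
    return sorted(out, key=lambda s: (s.position, s.strand))


def brute_force_amplicons(marker, sequences, rule=sk.MatchRule(), bounds=(50, 3000)):
    """Pair every + site with every downstream - site of the other primer."""
    lo, hi = bounds
    out = set()
    for seq_id, seq in sequences.items():
        f = brute_force_sites(marker.fwd_seq, seq, rule)
        r = brute_force_sites(marker.rev_seq, seq, rule)
        for left, right, rlen in (
            (f, r, len(marker.rev_seq)),
            (r, f, len(marker.fwd_seq)),
        ):
            for p in (s for s in left if s.strand == "+"):
                for m in (s for s in right if s.strand == "-"):
                    end = m.position + rlen - 1
                    if p.position <= m.position and lo <= end - p.position + 1 <= hi:
                        out.add((seq_id, p.position, end))
    return sorted(out)


class TestMatchRule:
    PRIMER = "AGCTTACGGAACCTGTCGAT"  # 20-mer, no internal repeat structure

    def embed(self, site, flank=60, seed=0):
        rng = np.random.default_rng(seed)
        return random_dna(rng, flank) + site + random_dna(rng, flank), flank + 1

    def test_exact_substring_is_single_zero_mismatch_site(self):
        target, pos = self.embed(self.PRIMER)
        sites = sk.find_binding_sites(self.PRIMER, target)
        assert sites == [BindingSite(pos, "+", 0)]

    def test_three_prime_terminal_mismatch_rejected(self):
        site = self.PRIMER[:-1] + ("C" if self.PRIMER[-1] != "C" else "G")
        target, _ = self.embed(site)
        assert sk.find_binding_sites(self.PRIMER, target) == []

    def test_mismatch_outside_window_rejected(self):
        # a single mismatch at position 6 (just past the 5-nt window)
        site = list(self.PRIMER)
        site[5] = "C" if site[5] != "C" else "G"
        target, _ = self.embed("".join(site))
        assert sk.find_binding_sites(self.PRIMER, target) == []

    def test_identity_boundary_two_vs_three_mismatches_on_20mer(self):
        # 2 mismatches at primer positions 1-2: identity 18/20 = 0.90 -> kept
        site2 = list(self.PRIMER)
        for j in range(2):
            site2[j] = "C" if site2[j] != "C" else "G"
        target, pos = self.embed("".join(site2))
        assert sk.find_binding_sites(self.PRIMER, target) == [BindingSite(pos, "+", 2)]
        # 3 mismatches at positions 1-3: identity 0.85 < 0.90 -> rejected
        site3 = list(self.PRIMER)
        for j in range(3):
            site3[j] = "C" if site3[j] != "C" else "G"
        target, _ = self.embed("".join(site3))
        assert sk.find_binding_sites(self.PRIMER, target) == []

    def test_minus_strand_site_found(self):
        target, pos = self.embed(reverse_complement(self.PRIMER))
        assert sk.find_binding_sites(self.PRIMER, target) == [BindingSite(pos, "-", 0)]

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            sk.find_binding_sites("ACGTACG", "ACGTACGT" * 10)

    def test_bad_identity_rejected(self):
        with pytest.raises(ValueError):
            sk.MatchRule(min_identity=1.5)


@pytest.mark.parametrize("seed", range(6))
def test_sites_match_brute_force_with_planted_mutated_copies(seed):
    rng = np.random.default_rng(4000 + seed)
    primer = random_dna(rng, 20)
    target = random_dna(rng, 3000)
    inserts = []
    for nmm, at in [(0, 200), (1, 800), (2, 1400), (3, 2000)]:
        site = list(primer)
        for j in range(nmm):
            site[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[j]]
        inserts.append(("".join(site), at))
    rc_site, at = reverse_complement(primer), 2600
    inserts.append((rc_site, at))
    for s, at in inserts:
        target = target[:at] + s + target[at + len(s) :]
    got = sk.find_binding_sites(primer, target)
    want = brute_force_sites(primer, target)
    assert got == want
    assert len(got) >= 4  # 0,1,2-mismatch copies and the rc copy


class TestAmplify:
    def test_self_amplification(self, planted_genome, planted_markers):
        seqs, _ = planted_genome
        m = planted_markers[0]
        amps = sk.amplify(m, seqs)
        assert len(amps) == 1 and amps[0].length == m.expected_product_bp

    def test_duplicated_forward_site_gives_two_products(self, planted_markers):
        m = planted_markers[0]
        rng = np.random.default_rng(9)
        rc_rev = reverse_complement(m.rev_seq)
        target = (
            random_dna(rng, 100) + m.fwd_seq + random_dna(rng, 120)
            + m.fwd_seq + random_dna(rng, 120) + rc_rev + random_dna(rng, 100)
        )
        amps = sk.amplify(m, {"t": target})
        assert len(amps) == 2
        assert brute_force_amplicons(m, {"t": target}) == [
            ("t", a.start, a.end) for a in amps
        ]

    def test_divergent_orientation_gives_nothing(self, planted_markers):
        m = planted_markers[0]
        rng = np.random.default_rng(10)
        # reverse site upstream of the forward site only
        target = (
            random_dna(rng, 100) + reverse_complement(m.rev_seq)
            + random_dna(rng, 150) + m.fwd_seq + random_dna(rng, 100)
        )
        assert sk.amplify(m, {"t": target}) == []

    def test_strand_invariance_of_product_counts(self, planted_genome, planted_markers):
        seqs, _ = planted_genome
        flipped = {n: reverse_complement(s) for n, s in seqs.items()}
        for m in planted_markers[:10]:
            assert len(sk.amplify(m, seqs)) == len(sk.amplify(m, flipped))


class TestTransferability:
    def test_planted_copy_counts(self, planted_markers):
        rng = np.random.default_rng(77)
        once, twice = planted_markers[:10], planted_markers[10:12]
        parts = []
        for m in once:
            parts += [random_dna(rng, 80), m.fwd_seq,
                      random_dna(rng, 100), reverse_complement(m.rev_seq)]
        for m in twice:
            for _ in range(2):
                parts += [random_dna(rng, 80), m.fwd_seq,
                          random_dna(rng, 100), reverse_complement(m.rev_seq)]
        target = {"t": "".join(parts) + random_dna(rng, 80)}
        table, _ = sk.classify_transferability(once + twice + planted_markers[12:15], target)
        assert table.single_copy == {m.marker_id for m in once}
        assert table.multi_copy == {m.marker_id for m in twice}
        assert table.absent == {m.marker_id for m in planted_markers[12:15]}

    def test_empty_marker_list_rejected(self):
        with pytest.raises(ValueError):
            sk.classify_transferability([], {"t": "ACGT" * 100})

    def test_intersection_is_set_algebra(self):
        t1 = sk.TransferTable({"A": 1, "B": 1, "C": 1, "D": 2})
        t2 = sk.TransferTable({"A": 0, "B": 1, "C": 1, "D": 1})
        assert sk.intersect_transfer_sets([t1, t2]) == {"B", "C"}
        t3 = sk.TransferTable({"A": 0, "B": 0, "C": 0, "D": 0})
        assert sk.intersect_transfer_sets([t1, t2, t3]) == set()
        with pytest.raises(ValueError):
            sk.intersect_transfer_sets([t1])


class TestAnnotate:
    def make_amplicon(self, start, end):
        return sk.Amplicon("m", "c1", start, end, 0, 0)

    def test_inside_feature_is_genic(self):
        feats = pd.DataFrame(
            [{"seq_id": "c1", "start": 100, "end": 500, "feature_type": "CDS"}]
        )
        out = sk.annotate_markers([self.make_amplicon(200, 300)], feats)
        assert out["genic"].tolist() == [True]
        assert out["feature_types"].tolist() == ["CDS"]

    def test_adjacent_but_non_overlapping_is_not_genic(self):
        feats = pd.DataFrame(
            [{"seq_id": "c1", "start": 301, "end": 500, "feature_type": "CDS"}]
        )
        out = sk.annotate_markers([self.make_amplicon(200, 300)], feats)
        assert out["genic"].tolist() == [False]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_overlap(self, seed):
        rng = np.random.default_rng(seed)
        amps = [
            self.make_amplicon(int(s), int(s) + int(rng.integers(50, 300)))
            for s in rng.integers(1, 10_000, size=40)
        ]
        feats = pd.DataFrame(
            [
                {"seq_id": "c1", "start": int(s), "end": int(s) + int(rng.integers(50, 500)),
                 "feature_type": "CDS"}
                for s in rng.integers(1, 10_000, size=30)
            ]
        )
        out = sk.annotate_markers(amps, feats)
        for a, genic in zip(amps, out["genic"]):
            want = any(
                f["start"] <= a.end and f["end"] >= a.start for _, f in feats.iterrows()
            )
            assert genic == want


@pytest.mark.parametrize("seed", range(3))
def test_divergence_monotonicity_in_expectation(seed):
    """Single-copy transfer count never rises with the mutation rate (mean over seeds)."""
    seqs, rec = sk.make_ssr_genome(length=60_000, n_loci=20, n_chromosomes=2, seed=300 + seed)
    markers = sk.design_all(seqs, sk.planted_loci(rec))
    counts = []
    for rate in (0.0, 0.03, 0.10):
        partner, _ = sk.derive_partner_genome(
            seqs, rec, n_inversions=0, n_translocations=0,
            mutation_rate=rate, seed=900 + seed,
        )
        table, _ = sk.classify_transferability(markers, partner)
        counts.append(len(table.single_copy))
    assert counts[0] >= counts[1] >= counts[2] or counts[0] > counts[2]
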