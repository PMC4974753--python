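"""Electronic (in silico) PCR under an asymmetric primer mismatch rule.

A primer binds a site when every mismatch falls inside a short 5' window
(default 5 nt), the mismatch count stays within a cap (default 5), the
overall ungapped identity is at least 90 %, and every position outside the
window — the whole 3' portion, including the terminus that the polymerase
extends — matches exactly.  Indels are never allowed.

Sites are located with a seed-and-verify scan: the exact 3' portion of the
primer is the seed, and the 5' window is verified at each seed hit.  This
is guaranteed to produce the same result as a brute-force scan over every
offset on both strands.

Convergent forward/reverse site pairs whose outer span falls inside the
product-size bounds become amplicons; a marker with exactly one amplicon
on a related genome is called cross-species transferable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .marker_design import MarkerPair
from .ssr_scan import reverse_complement


@dataclass(frozen=True)
class MatchRule:
    """Asymmetric primer-binding rule (mismatches tolerated only at the 5' end)."""

    max_5prime_mismatches: int = 5
    five_prime_window: int = 5
    min_identity: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")

    def max_mismatches(self, primer_len: int) -> int:
        """Joint cap: window cap and identity floor enforced together."""
        by_identity = int(primer_len * (1.0 - self.min_identity) + 1e-9)
        return min(self.max_5prime_mismatches, by_identity)


@dataclass(frozen=True)
class BindingSite:
    """Primer alignment on a target: 1-based + strand start, strand, mismatches."""

    position: int
    strand: str  # '+' : primer as given matches the + strand; '-' : its revcomp does
    mismatches: int


@dataclass
class Amplicon:
    """One predicted PCR product (outer span, 1-based inclusive)."""

    marker_id: str
    target_seq_id: str
    start: int
    end: int
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _count_window_mismatches(site: str, head: str) -> int:
    return sum(a != b for a, b in zip(site, head))


def find_binding_sites(primer: str, target: str, rule: MatchRule = MatchRule()) -> list[BindingSite]:
    """Every ungapped alignment of ``primer`` on either strand of ``target``
    satisfying the mismatch rule, in 1-based + strand coordinates.

    The returned position is always the leftmost + strand base of the
    aligned site, whichever strand the primer matches.
    """
    primer = primer.upper()
    n = len(primer)
    if n < rule.five_prime_window + 5:
        raise ValueError("primer too short for the 5' window plus a usable seed")
    if set(primer) - set("ACGT"):
        raise ValueError("primer must be unambiguous A/C/G/T")
    target = target.upper()
    w = rule.five_prime_window
    cap = rule.max_mismatches(n)

    sites: list[BindingSite] = []
    # + strand: primer 5'->3' left-to-right; seed = exact 3' part primer[w:]
    seed = primer[w:]
    head = primer[:w]
    start = target.find(seed, w)
    while start != -1:
        site_head = target[start - w : start]
        if len(site_head) == w:
            mm = _count_window_mismatches(site_head, head)
            if mm <= cap:
                sites.append(BindingSite(position=start - w + 1, strand="+", mismatches=mm))
        start = target.find(seed, start + 1)
    # - strand: the primer's reverse complement lies on the + strand with its
    # 5' window at the right; seed = revcomp of the 3' part at the left.
    rc = reverse_complement(primer)
    seed_rc = rc[: n - w]
    tail = rc[n - w :]
    start = target.find(seed_rc)
    while start != -1:
        site_tail = target[start + n - w : start + n]
        if len(site_tail) == w:
            mm = _count_window_mismatches(site_tail, tail)
            if mm <= cap:
                sites.append(BindingSite(position=start + 1, strand="-", mismatches=mm))
        start = target.find(seed_rc, start + 1)
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def amplify(
    marker: MarkerPair,
    target_sequences: dict[str, str],
    rule: MatchRule = MatchRule(),
    product_bounds: tuple[int, int] = (50, 3000),
) -> list[Amplicon]:
    """All predicted products of a marker on a target genome.

    A product needs one primer bound on the + strand and the other on the
    - strand, pointing toward each other, with the outer span inside
    ``product_bounds``.  Both primer arrangements (forward on +, reverse
    on -, and vice versa) are considered, so the result is invariant under
    reverse-complementing the target.
    """
    lo, hi = product_bounds
    flen, rlen = len(marker.fwd_seq), len(marker.rev_seq)
    if lo < 1:
        raise ValueError("product bounds must be positive")
    out: list[Amplicon] = []
    seen: set[tuple[str, int, int]] = set()
    for seq_id, seq in target_sequences.items():
        fwd_sites = find_binding_sites(marker.fwd_seq, seq, rule)
        rev_sites = find_binding_sites(marker.rev_seq, seq, rule)
        pairings = (
            # (left primer sites on +, right primer sites on -, left len, right len)
            ([s for s in fwd_sites if s.strand == "+"],
             [s for s in rev_sites if s.strand == "-"], rlen, True),
            ([s for s in rev_sites if s.strand == "+"],
             [s for s in fwd_sites if s.strand == "-"], flen, False),
        )
        for plus_sites, minus_sites, right_len, fwd_is_plus in pairings:
            for p in plus_sites:
                for m in minus_sites:
                    end = m.position + right_len - 1
                    length = end - p.position + 1
                    if p.position <= m.position and lo <= length <= hi:
                        key = (seq_id, p.position, end)
                        if key in seen:
                            continue
                        seen.add(key)
                        fmm, rmm = (p.mismatches, m.mismatches) if fwd_is_plus else (m.mismatches, p.mismatches)
                        out.append(
                            Amplicon(
                                marker_id=marker.marker_id,
                                target_seq_id=seq_id,
                                start=p.position,
                                end=end,
                                fwd_mismatches=fmm,
                                rev_mismatches=rmm,
                            )
                        )
    out.sort(key=lambda a: (a.target_seq_id, a.start, a.end))
    return out


@dataclass
class TransferTable:
    """Per-marker amplicon counts on one target genome."""

    counts: dict[str, int]

    @property
    def single_copy(self) -> set[str]:
        return {m for m, c in self.counts.items() if c == 1}

    @property
    def multi_copy(self) -> set[str]:
        return {m for m, c in self.counts.items() if c >= 2}

    @property
    def absent(self) -> set[str]:
        return {m for m, c in self.counts.items() if c == 0}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"marker_id": m, "n_products": c,
             "category": "single" if c == 1 else ("multi" if c >= 2 else "none")}
            for m, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["marker_id", "n_products", "category"])


def classify_transferability(
    markers: list[MarkerPair],
    target_sequences: dict[str, str],
    rule: MatchRule = MatchRule(),
    product_bounds: tuple[int, int] = (50, 3000),
) -> tuple[TransferTable, dict[str, list[Amplicon]]]:
    """Amplify every marker on the target and classify by product count."""
    if not markers:
        raise ValueError("marker list must be nonempty")
    counts: dict[str, int] = {}
    amps: dict[str, list[Amplicon]] = {}
    for m in markers:
        a = amplify(m, target_sequences, rule, product_bounds)
        counts[m.marker_id] = len(a)
        amps[m.marker_id] = a
    return TransferTable(counts), amps


def intersect_transfer_sets(tables: list[TransferTable]) -> set[str]:
    """Markers single-copy in every table (cross-all-targets transferable)."""
    if len(tables) < 2:
        raise ValueError("need at least two transfer tables")
    universes = [set(t.counts) for t in tables]
    common = set.intersection(*universes)
    if not common:
        raise ValueError("transfer tables share no markers")
    shared = set.intersection(*(t.single_copy for t in tables))
    return shared & common


def annotate_markers(
    amplicons: list[Amplicon],
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Label each amplicon genic/intergenic by >= 1 bp overlap with features.

    ``features`` needs columns (seq_id, start, end, feature_type), 1-based
    inclusive on the same assembly as the amplicons.  Returns one row per
    amplicon with the overlapped feature types (empty string when none).
    """
    by_seq: dict[str, pd.DataFrame] = {s: g for s, g in features.groupby("seq_id")}
    rows = []
    for a in amplicons:
        feats = by_seq.get(a.target_seq_id)
        types: list[str] = []
        if feats is not None:
            hit = feats[(feats["start"] <= a.end) & (feats["end"] >= a.start)]
            types = sorted(set(hit["feature_type"]))
        rows.append(
            {"marker_id": a.marker_id, "target_seq_id": a.target_seq_id,
             "start": a.start, "end": a.end,
             "genic": bool(types), "feature_types": ",".join(types)}
        )
    return pd.DataFrame(
        rows, columns=["marker_id", "target_seq_id", "start", "end", "genic", "feature_types"]
    )
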