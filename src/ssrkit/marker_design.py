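"""Primer-pair design for SSR loci from flanking genomic sequence.

A simplified deterministic picker: candidate primers are enumerated in the
flanks of each locus, filtered on length, melting temperature, GC content
and self-complementarity, and the best pair under a fixed lexicographic
score (Tm closeness, then length closeness, then leftmost position) is
returned.  Constraints follow the common SSR-marker design recipe:
amplicons of 100-300 bp, primer length 18-20-24 nt (min-opt-max) and
Tm 50-55-60 degC.

Melting temperatures come from the nearest-neighbor model (SantaLucia &
Hicks 2004 parameter table as shipped with Biopython, 50 mM Na+, 25 nM
primer) — the model choice is a documented package default, fixed so that
designs are reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

from .ssr_scan import SSRLocus, reverse_complement


@dataclass(frozen=True)
class PrimerConstraints:
    product_size_range: tuple[int, int] = (100, 300)
    primer_length: tuple[int, int, int] = (18, 20, 24)  # min, opt, max
    tm_range: tuple[float, float, float] = (50.0, 55.0, 60.0)  # min, opt, max
    gc_range: tuple[float, float] = (0.20, 0.80)
    max_self_dimer: int = 7  # reject perfect self-complementary stretches > this

    def __post_init__(self) -> None:
        for lo, opt, hi in (self.primer_length, self.tm_range):
            if not lo <= opt <= hi:
                raise ValueError("min <= optimum <= max violated in constraints")


@dataclass
class MarkerPair:
    """A named SSR marker: primer pair plus the expected product size.

    ``rev_seq`` is given 5'->3' on the minus strand, as synthesized.
    """

    marker_id: str
    locus: SSRLocus
    fwd_seq: str
    rev_seq: str
    expected_product_bp: int
    fwd_tm: float
    rev_tm: float


def melting_temperature(primer: str) -> float:
    """Nearest-neighbor Tm (degC) of a primer under the package's fixed
    thermodynamic defaults.  Deterministic; raises on ambiguous bases."""
    primer = primer.upper()
    if not 10 <= len(primer) <= 40:
        raise ValueError("primer length must be 10-40 nt")
    if set(primer) - set("ACGT"):
        raise ValueError(f"ambiguous base in primer {primer!r}")
    return float(_mt.Tm_NN(primer, nn_table=_mt.DNA_NN4, Na=50, dnac1=25, dnac2=25))


def _gc_fraction(s: str) -> float:
    return (s.count("G") + s.count("C")) / len(s)


def _has_self_dimer(primer: str, max_len: int) -> bool:
    """Perfect self-complementary stretch longer than max_len?"""
    rc = reverse_complement(primer)
    k = max_len + 1
    if k > len(primer):
        return False
    subs = {primer[i : i + k] for i in range(len(primer) - k + 1)}
    return any(rc[i : i + k] in subs for i in range(len(rc) - k + 1))


def _candidates(flank: str, offset0: int, constraints: PrimerConstraints):
    """Enumerate acceptable primers anywhere in ``flank``.

    Yields (score, genomic_start_0based, seq, tm); flank coordinates start
    at genome offset ``offset0`` (0-based).  Primers read left-to-right in
    flank orientation.
    """
    lmin, lopt, lmax = constraints.primer_length
    tmin, topt, tmax = constraints.tm_range
    gmin, gmax = constraints.gc_range
    out = []
    for start in range(0, len(flank) - lmin + 1):
        for plen in range(lmin, min(lmax, len(flank) - start) + 1):
            s = flank[start : start + plen]
            if set(s) - set("ACGT"):
                continue
            if not gmin <= _gc_fraction(s) <= gmax:
                continue
            tm = melting_temperature(s)
            if not tmin <= tm <= tmax:
                continue
            if _has_self_dimer(s, constraints.max_self_dimer):
                continue
            score = (abs(tm - topt), abs(plen - lopt), start)
            out.append((score, offset0 + start, s, tm))
    out.sort(key=lambda c: c[0])
    return out


def design_marker(
    sequences: dict[str, str],
    locus: SSRLocus,
    constraints: PrimerConstraints = PrimerConstraints(),
    marker_id: str = "SSR00001",
    max_flank: int = 150,
) -> MarkerPair | None:
    """Pick the best primer pair flanking ``locus``, or None if no pair
    satisfies every constraint.

    Both primers lie wholly outside the SSR array and the amplicon contains
    the full array.  The returned pair is deterministic: candidates are
    scored by summed |Tm - optimum|, then summed |length - optimum|, then
    leftmost forward position.
    """
    seq = sequences[locus.seq_id].upper()
    pmin, pmax = constraints.product_size_range
    lmin = constraints.primer_length[0]

    left_lo = max(0, locus.start - 1 - max_flank)
    left = seq[left_lo : locus.start - 1]
    right_hi = min(len(seq), locus.end + max_flank)
    right = seq[locus.end : right_hi]
    if len(left) < lmin or len(right) < lmin:
        return None

    fwd = _candidates(left, left_lo, constraints)
    # reverse primers anneal to the + strand; enumerate on the minus strand
    rev = _candidates(reverse_complement(right), locus.end, constraints)
    if not fwd or not rev:
        return None

    best = None
    for fs, fstart, fseq, ftm in fwd[:80]:
        for rs, roff, rseq, rtm in rev[:80]:
            # roff counts from locus.end in minus-strand orientation:
            # the site's rightmost + strand base is at right_hi - (roff - locus.end)
            rev_end = right_hi - (roff - locus.end)  # 1-based inclusive end
            product = rev_end - fstart  # fstart is 0-based -> length
            if not pmin <= product <= pmax:
                continue
            score = (fs[0] + rs[0], fs[1] + rs[1], fstart, roff)
            if best is None or score < best[0]:
                best = (score, fstart, fseq, ftm, rseq, rtm, product)
    if best is None:
        return None
    _, fstart, fseq, ftm, rseq, rtm, product = best
    return MarkerPair(
        marker_id=marker_id,
        locus=locus,
        fwd_seq=fseq,
        rev_seq=rseq,
        expected_product_bp=product,
        fwd_tm=round(ftm, 2),
        rev_tm=round(rtm, 2),
    )


def design_all(
    sequences: dict[str, str],
    loci: list[SSRLocus],
    constraints: PrimerConstraints = PrimerConstraints(),
    prefix: str = "ClSSR",
) -> list[MarkerPair]:
    """Design a marker for every locus that admits one; IDs are the prefix
    plus a zero-padded ordinal in genome order."""
    pairs = []
    for i, locus in enumerate(loci):
        mp = design_marker(sequences, locus, constraints, marker_id=f"{prefix}{i + 1:05d}")
        if mp is not None:
            pairs.append(mp)
    return pairs
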