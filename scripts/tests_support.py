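"""Brute-force oracles used by the acceptance script.

Independent of the package's seeded/vectorized search paths: these scan
every offset directly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

import ssrkit as sk
from ssrkit.ssr_scan import MIN_TOTAL_LENGTH, _is_primitive, reverse_complement


def brute_force_scan(seq: str, seq_id: str = "seq"):
    """Enumerate every (start, unit, count) triple and keep threshold passers."""
    seq = seq.upper()
    n = len(seq)
    out = []
    for k in range(2, 9):
        min_r = -(-MIN_TOTAL_LENGTH[k] // k)
        for i in range(n - k + 1):
            motif = seq[i : i + k]
            if set(motif) - set("ACGT") or not _is_primitive(motif):
                continue
            if i >= 1 and i - 1 + k < n and seq[i - 1] == seq[i - 1 + k] and seq[i - 1] in "ACGT":
                continue
            c = 1
            while seq[i + c * k : i + (c + 1) * k] == motif:
                c += 1
            if c >= min_r:
                out.append((seq_id, i + 1, i + c * k, motif, k, c))
    return sorted(out)


def np_brute_sites(primer: str, target: str, rule: sk.MatchRule = sk.MatchRule()):
    """Vectorized all-offsets primer-site scanner on both strands."""
    n, w = len(primer), rule.five_prime_window
    cap = rule.max_mismatches(n)
    t = np.frombuffer(target.encode(), np.uint8)
    if len(t) < n:
        return []
    win = sliding_window_view(t, n)
    out = []
    for strand in "+-":
        p = primer if strand == "+" else reverse_complement(primer)
        pa = np.frombuffer(p.encode(), np.uint8)
        mm = win != pa
        window_cols = np.arange(w) if strand == "+" else np.arange(n - w, n)
        exact_cols = np.setdiff1d(np.arange(n), window_cols)
        keep = ~mm[:, exact_cols].any(axis=1) & (mm[:, window_cols].sum(axis=1) <= cap)
        for pos in np.flatnonzero(keep):
            out.append((int(pos) + 1, strand, int(mm[pos, window_cols].sum())))
    return sorted(out)


def np_brute_amplicons(marker, sequences, rule=sk.MatchRule(), bounds=(50, 3000)):
    """Pair every convergent site pair within the product bounds."""
    lo, hi = bounds
    out = set()
    for seq_id, seq in sequences.items():
        f = np_brute_sites(marker.fwd_seq, seq, rule)
        r = np_brute_sites(marker.rev_seq, seq, rule)
        for left, right, rlen in ((f, r, len(marker.rev_seq)),
                                  (r, f, len(marker.fwd_seq))):
            for pos_l, s_l, _ in left:
                if s_l != "+":
                    continue
                for pos_r, s_r, _ in right:
                    if s_r != "-":
                        continue
                    end = pos_r + rlen - 1
                    if pos_l <= pos_r and lo <= end - pos_l + 1 <= hi:
                        out.add((seq_id, pos_l, end))
    return sorted(out)
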