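"""Synthetic fixtures with planted ground truth.

Every generator is deterministic given (parameters, seed) and returns a
:class:`PlantingRecord` documenting exactly what was planted, so tests can
score recall/precision, block recovery, clustering purity and ΔK recovery
against truth that never came from the code under test.

Generated fixtures:

* SSR genomes — random A/C/G/T background, rejection-sampled so that no
  incidental tandem array reaches any class threshold, with non-overlapping
  SSR loci of known motif/copy-number planted at known coordinates.
* Partner genomes — a diverged relative built by inverting and
  translocating marker-bearing segments and sprinkling point mutations
  (optionally suppressed inside protected intervals such as primer
  footprints).  Segment boundaries sit at midpoints between markers so
  flanking regions travel with their locus.
* Genotype matrices — K populations with locus-wise allele frequencies
  drawn from a Dirichlet; diploid genotypes sampled under Hardy–Weinberg
  within each population.
* LnP(D) replicate tables — piecewise-linear mean with a slope break only
  at the planted K, plus i.i.d. Gaussian replicate noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import GenotypeMatrix
from .ssr_scan import (
    MotifClass,
    SSRLocus,
    _is_primitive,
    default_classes,
    reverse_complement,
    scan_sequence,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PlantingRecord:
    """Serializable ground truth for one synthetic fixture."""

    seed: int
    kind: str
    data: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "kind": self.kind, "data": self.data},
                          indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantingRecord":
        obj = json.loads(text)
        return cls(seed=obj["seed"], kind=obj["kind"], data=obj["data"])


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _clean_background(rng: np.random.Generator, n: int,
                      classes: tuple[MotifClass, ...]) -> str:
    """Random sequence with every threshold-passing tandem array scrubbed."""
    arr = _random_dna(rng, n)
    for _ in range(100):
        seq = arr.tobytes().decode()
        hits = scan_sequence(seq, "bg", classes)
        if not hits:
            return seq
        for h in hits:
            arr[h.start - 1 : h.end] = _random_dna(rng, h.end - h.start + 1)
    raise RuntimeError("background rejection sampling did not converge")


def _random_motif(rng: np.random.Generator, unit_length: int) -> str:
    while True:
        m = _random_dna(rng, unit_length).tobytes().decode()
        if _is_primitive(m) and len(set(m)) >= 2:
            return m


def make_ssr_genome(
    length: int = 100_000,
    n_loci: int = 50,
    n_chromosomes: int = 1,
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
    extra_repeats: int = 5,
    margin: int = 400,
    chrom_prefix: str = "chr",
) -> tuple[dict[str, str], PlantingRecord]:
    """Genome with ``n_loci`` planted SSR loci and an SSR-free background.

    ``class_mix`` weights the seven motif classes (keys di..octo); default
    uniform.  Planted loci keep >= ``margin`` bp of clean flank on each
    side and at least ``margin`` bp between loci, so primer design and
    segment surgery have room to work.  Raises if the loci cannot be packed.
    """
    rng = np.random.default_rng(seed)
    classes = default_classes()
    by_name = {c.class_name: c for c in classes}
    if class_mix is None:
        class_mix = {c.class_name: 1.0 for c in classes}
    names = sorted(class_mix)
    weights = np.array([class_mix[n] for n in names], dtype=float)
    weights = weights / weights.sum()

    chrom_len = length // n_chromosomes
    per_chrom = [n_loci // n_chromosomes] * n_chromosomes
    for i in range(n_loci % n_chromosomes):
        per_chrom[i] += 1
    max_locus = max(c.min_repeats * c.unit_length for c in classes) + 8 * extra_repeats
    sequences: dict[str, str] = {}
    planted: list[dict] = []
    for ci in range(n_chromosomes):
        name = f"{chrom_prefix}{ci + 1}"
        k = per_chrom[ci]
        slot = (chrom_len - 2 * margin) / max(k, 1)
        if k and slot < max_locus + margin:
            raise ValueError("cannot pack planted loci: increase length or reduce n_loci")
        arr = np.frombuffer(
            _clean_background(rng, chrom_len, classes).encode(), dtype=np.uint8
        ).copy()
        for li in range(k):
            cls = by_name[str(rng.choice(names, p=weights))]
            motif = _random_motif(rng, cls.unit_length)
            copies = cls.min_repeats + int(rng.integers(0, extra_repeats + 1))
            pos = margin + int(li * slot) + int(rng.integers(0, max(1, int(slot) - max_locus - margin)))
            unit = np.frombuffer(motif.encode(), dtype=np.uint8)
            tract = np.tile(unit, copies)
            arr[pos : pos + len(tract)] = tract
            # break the array at both ends so the run cannot extend
            prev_choices = BASES[BASES != unit[-1]]
            arr[pos - 1] = prev_choices[rng.integers(0, len(prev_choices))]
            nxt_choices = BASES[BASES != unit[0]]
            arr[pos + len(tract)] = nxt_choices[rng.integers(0, len(nxt_choices))]
            planted.append(
                {"seq_id": name, "start": pos + 1, "end": pos + len(tract),
                 "motif": motif, "unit_length": cls.unit_length,
                 "repeat_count": copies}
            )
        sequences[name] = arr.tobytes().decode()

    # final verification: scrub any incidental locus introduced by planting
    for _ in range(50):
        ok = True
        for name in sequences:
            found = {
                (l.start, l.end, l.motif)
                for l in scan_sequence(sequences[name], name)
            }
            want = {
                (p["start"], p["end"], p["motif"])
                for p in planted
                if p["seq_id"] == name
            }
            extra = found - want
            if extra or (want - found):
                ok = False
                arr = np.frombuffer(sequences[name].encode(), dtype=np.uint8).copy()
                protected = np.zeros(len(arr), dtype=bool)
                for p in planted:
                    if p["seq_id"] == name:
                        protected[p["start"] - 1 : p["end"]] = True
                for s, e, _m in extra:
                    sl = slice(s - 1, e)
                    repl = _random_dna(rng, e - s + 1)
                    keep = protected[sl]
                    seg = arr[sl]
                    seg[~keep] = repl[~keep]
                    arr[sl] = seg
                sequences[name] = arr.tobytes().decode()
        if ok:
            break
    else:
        raise RuntimeError("planting verification did not converge")

    record = PlantingRecord(
        seed=seed,
        kind="ssr_genome",
        data={
            "chromosomes": {n: len(s) for n, s in sequences.items()},
            "ssrs": planted,
        },
    )
    return sequences, record


def derive_partner_genome(
    sequences: dict[str, str],
    record: PlantingRecord,
    n_inversions: int = 3,
    n_translocations: int = 2,
    mutation_rate: float = 0.0,
    seed: int = 0,
    segment_markers: int = 5,
    context_markers: int = 3,
    protected: list[tuple[str, int, int]] | None = None,
) -> tuple[dict[str, str], PlantingRecord]:
    """Diverged partner genome built by segment surgery plus point mutations.

    Segments are runs of ``segment_markers`` consecutive planted loci (with
    their flanks, cut at inter-marker midpoints); chosen segments never
    touch and keep >= ``context_markers`` undisturbed loci between and
    around them.  Inverted segments are reverse-complemented in place;
    translocated segments move to the end of another chromosome.  Point
    mutations are Bernoulli(``mutation_rate``) per base, never inside
    planted SSR arrays nor inside ``protected`` intervals (source
    coordinates, 1-based inclusive).

    The returned record lists, per target chromosome, the ordered source
    pieces (chromosome, marker ids, orientation) — the planted synteny
    truth — and the target-coordinate midpoint of every planted marker.
    """
    rng = np.random.default_rng(seed)
    ssrs = record.data["ssrs"]
    by_chrom: dict[str, list[dict]] = {}
    for i, s in enumerate(ssrs):
        entry = dict(s)
        entry["index"] = i
        by_chrom.setdefault(s["seq_id"], []).append(entry)
    for ms in by_chrom.values():
        ms.sort(key=lambda m: m["start"])

    # candidate segments: disjoint marker windows with context on both sides
    candidates: list[tuple[str, int]] = []  # (chrom, first marker ordinal)
    for chrom, ms in sorted(by_chrom.items()):
        first = context_markers
        last = len(ms) - context_markers - segment_markers
        step = segment_markers + context_markers
        for start in range(first, last + 1, step):
            candidates.append((chrom, start))
    n_ops = n_inversions + n_translocations
    if len(candidates) < n_ops:
        raise ValueError("not enough marker-bearing segments for the requested operations")
    chosen = [candidates[i] for i in sorted(rng.choice(len(candidates), n_ops, replace=False))]
    ops = ["inversion"] * n_inversions + ["translocation"] * n_translocations
    rng.shuffle(ops)

    # split each chromosome into pieces at inter-marker midpoints
    def midpoint(chrom: str, a: dict, b: dict) -> int:
        return (a["end"] + b["start"]) // 2

    pieces_by_chrom: dict[str, list[dict]] = {}
    rearrangements = []
    for chrom, ms in sorted(by_chrom.items()):
        L = len(sequences[chrom])
        cuts = [0]
        seg_ops: list[tuple[int, int, str]] = []  # (first, last marker ordinal, op)
        for (c, start), op in zip(chosen, ops):
            if c == chrom:
                seg_ops.append((start, start + segment_markers - 1, op))
        seg_ops.sort()
        boundaries = []
        for first, last, op in seg_ops:
            b0 = midpoint(chrom, ms[first - 1], ms[first])
            b1 = midpoint(chrom, ms[last], ms[last + 1])
            boundaries.append((b0, b1, op, first, last))
        pieces = []
        prev = 0
        for b0, b1, op, first, last in boundaries:
            if b0 > prev:
                pieces.append({"src": chrom, "start": prev, "end": b0, "orient": "+",
                               "op": "kept"})
            pieces.append({"src": chrom, "start": b0, "end": b1,
                           "orient": "-" if op == "inversion" else "+", "op": op,
                           "marker_ordinals": list(range(first, last + 1))})
            rearrangements.append({"seq_id": chrom, "start": b0 + 1, "end": b1,
                                   "operation": op,
                                   "marker_indices": [ms[i]["index"] for i in range(first, last + 1)]})
            prev = b1
        if prev < L:
            pieces.append({"src": chrom, "start": prev, "end": L, "orient": "+", "op": "kept"})
        pieces_by_chrom[chrom] = pieces

    # translocated pieces move to the end of the next chromosome (cyclic)
    chroms = sorted(sequences)
    target_layout: dict[str, list[dict]] = {c: [] for c in chroms}
    moved: dict[str, list[dict]] = {c: [] for c in chroms}
    for chrom in chroms:
        for p in pieces_by_chrom[chrom]:
            if p["op"] == "translocation":
                if len(chroms) > 1:
                    dest = chroms[(chroms.index(chrom) + 1) % len(chroms)]
                else:
                    dest = chrom
                q = dict(p)
                q["op"] = "translocated"
                moved[dest].append(q)
            else:
                target_layout[chrom].append(p)
    for c in chroms:
        target_layout[c].extend(moved[c])

    # assemble target sequences and map marker midpoints
    out_sequences: dict[str, str] = {}
    marker_map: dict[int, dict] = {}
    layout_record: dict[str, list[dict]] = {}
    for chrom in chroms:
        parts: list[str] = []
        offset = 0
        layout_record[chrom] = []
        for p in target_layout[chrom]:
            src_seq = sequences[p["src"]][p["start"] : p["end"]]
            plen = len(src_seq)
            if p["orient"] == "-":
                src_seq = reverse_complement(src_seq)
            parts.append(src_seq)
            member_ids = []
            for m in by_chrom.get(p["src"], []):
                center = (m["start"] + m["end"]) // 2  # 1-based
                if p["start"] < center <= p["end"]:
                    if p["orient"] == "+":
                        tpos = offset + (center - p["start"])
                    else:
                        new_s = offset + (p["end"] - m["end"]) + 1
                        new_e = offset + (p["end"] - m["start"] + 1)
                        tpos = (new_s + new_e) // 2
                    marker_map[m["index"]] = {
                        "target_seq_id": chrom, "target_pos": tpos,
                        "orient": p["orient"],
                    }
                    member_ids.append(m["index"])
            layout_record[chrom].append(
                {"src": p["src"], "src_start": p["start"] + 1, "src_end": p["end"],
                 "orient": p["orient"], "op": p["op"],
                 "marker_indices": sorted(member_ids)}
            )
            offset += plen
        out_sequences[chrom] = "".join(parts)

    # point mutations (target coordinates), sparing SSR arrays + protected spans
    n_mut = 0
    if mutation_rate > 0:
        protected = protected or []
        forbidden: dict[str, np.ndarray] = {
            c: np.zeros(len(s), dtype=bool) for c, s in out_sequences.items()
        }
        src_spans = [(s["seq_id"], s["start"], s["end"]) for s in ssrs]
        for chrom in chroms:
            offset = 0
            for p in target_layout[chrom]:
                for sc, s1, e1 in src_spans + list(protected):
                    if sc != p["src"]:
                        continue
                    lo = max(s1 - 1, p["start"])
                    hi = min(e1, p["end"])
                    if lo >= hi:
                        continue
                    if p["orient"] == "+":
                        t0 = offset + (lo - p["start"])
                        t1 = offset + (hi - p["start"])
                    else:
                        t0 = offset + (p["end"] - hi)
                        t1 = offset + (p["end"] - lo)
                    forbidden[chrom][t0:t1] = True
                offset += p["end"] - p["start"]
        for chrom in chroms:
            arr = np.frombuffer(out_sequences[chrom].encode(), dtype=np.uint8).copy()
            hit = rng.random(len(arr)) < mutation_rate
            hit &= ~forbidden[chrom]
            idx = np.flatnonzero(hit)
            for i in idx:
                alt = BASES[BASES != arr[i]]
                arr[i] = alt[rng.integers(0, 3)]
            n_mut += len(idx)
            out_sequences[chrom] = arr.tobytes().decode()

    new_record = PlantingRecord(
        seed=seed,
        kind="partner_genome",
        data={
            "source_record": record.data,
            "layout": layout_record,
            "rearrangements": rearrangements,
            "marker_map": {str(k): v for k, v in marker_map.items()},
            "n_mutations": n_mut,
            "mutation_rate": mutation_rate,
        },
    )
    return out_sequences, new_record


def expected_blocks(partner_record: PlantingRecord) -> list[dict]:
    """Planted synteny truth: merge adjacent kept pieces, keep runs >= 3.

    Returns, in target order, dicts of (source chromosome, target
    chromosome, ordered marker indices, orientation).  Adjacent '+' pieces
    that are consecutive in source coordinates merge into one collinear
    run; every rearranged piece stands alone.
    """
    out = []
    for tchrom, pieces in sorted(partner_record.data["layout"].items()):
        run: list[int] = []
        run_src = None
        prev_end = None
        prev_orient = "+"

        def flush():
            if len(run) >= 3:
                out.append({"source_seq_id": run_src, "target_seq_id": tchrom,
                            "marker_indices": list(run),
                            "orientation": "collinear" if prev_orient == "+" else "inverted"})

        for p in pieces:
            ids = p["marker_indices"]
            if not ids:
                prev_end = p["src_end"] if p["src"] == run_src else prev_end
                continue
            contiguous = (
                run
                and p["src"] == run_src
                and p["orient"] == "+"
                and prev_orient == "+"
                and p["src_start"] == (prev_end or 0) + 1
            )
            if contiguous:
                run.extend(ids)
            else:
                flush()
                run = list(ids)
                run_src = p["src"]
                prev_orient = p["orient"]
            prev_end = p["src_end"]
        flush()
    return out


def simulate_genotypes(
    K: int = 2,
    n_per_pop: int = 25,
    n_loci: int = 32,
    alleles_per_locus: int = 5,
    divergence: float = 0.5,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[int], PlantingRecord]:
    """K populations, Dirichlet-divergent allele frequencies, HWE genotypes.

    Per population and locus, allele frequencies ~ Dirichlet(divergence /
    alleles_per_locus * 1); smaller ``divergence`` means stronger drift
    apart.  Returns the matrix, the per-accession population labels, and
    the planting record (which stores the drawn frequencies).
    """
    if K < 1 or alleles_per_locus < 2:
        raise ValueError("K >= 1 and alleles_per_locus >= 2 required")
    rng = np.random.default_rng(seed)
    alpha = np.full(alleles_per_locus, divergence / alleles_per_locus)
    freqs = rng.dirichlet(alpha, size=(K, n_loci))  # (K, loci, alleles)
    loci = [f"L{j + 1:03d}" for j in range(n_loci)]
    allele_labels = [str(100 + 2 * a) for a in range(alleles_per_locus)]
    accessions, labels = [], []
    calls: dict[tuple[str, str], tuple[str, str] | None] = {}
    for k in range(K):
        for i in range(n_per_pop):
            acc = f"P{k + 1}_{i + 1:02d}"
            accessions.append(acc)
            labels.append(k)
            for j, loc in enumerate(loci):
                pair = rng.choice(alleles_per_locus, size=2, p=freqs[k, j])
                calls[(acc, loc)] = (allele_labels[pair[0]], allele_labels[pair[1]])
    gm = GenotypeMatrix(accessions=accessions, loci=loci, calls=calls)
    record = PlantingRecord(
        seed=seed,
        kind="genotypes",
        data={"K": K, "n_per_pop": n_per_pop, "divergence": divergence,
              "labels": labels, "frequencies": freqs.tolist(),
              "allele_labels": allele_labels},
    )
    return gm, labels, record


def simulate_lnpd(
    k_range: tuple[int, int] = (1, 10),
    elbow_k: int = 2,
    replicates: int = 20,
    noise_sd: float = 30.0,
    seed: int = 0,
    slope_before: float = 500.0,
    slope_after: float = 20.0,
    base: float = -15_000.0,
) -> tuple[pd.DataFrame, PlantingRecord]:
    """Replicate LnP(D) table with a single slope break at ``elbow_k``.

    Mean curve: base + slope_before*(K-1) up to the elbow, then
    slope_after per additional K; Gaussian replicate noise on top.
    """
    k_lo, k_hi = k_range
    if not k_lo < elbow_k < k_hi:
        raise ValueError("elbow_k must be interior to k_range")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(k_lo, k_hi + 1):
        mean = base + slope_before * (min(k, elbow_k) - k_lo) + slope_after * max(0, k - elbow_k)
        for r in range(replicates):
            rows.append({"K": k, "run": r + 1,
                         "LnPD": mean + rng.normal(0.0, noise_sd)})
    df = pd.DataFrame(rows)
    record = PlantingRecord(
        seed=seed, kind="lnpd",
        data={"elbow_k": elbow_k, "noise_sd": noise_sd, "replicates": replicates,
              "k_range": [k_lo, k_hi]},
    )
    return df, record


def planted_loci(record: PlantingRecord) -> list[SSRLocus]:
    """The planted SSRs of an ssr_genome record as SSRLocus objects."""
    return [
        SSRLocus(seq_id=p["seq_id"], start=p["start"], end=p["end"],
                 motif=p["motif"], unit_length=p["unit_length"],
                 repeat_count=p["repeat_count"])
        for p in record.data["ssrs"]
    ]
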