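"""Detection and summarization of perfect and compound microsatellites (SSRs).

An SSR is a tandem array of a short motif (here 2-8 bp; mononucleotide runs
are deliberately excluded because they are hard to distinguish from
sequencing/assembly error).  Each motif-length class carries its own minimum
total array length, the convention used for conservative genome-wide SSR
mining in cucurbits:

    di/tri/tetra >= 18 bp, penta >= 20 bp, hexa >= 24 bp,
    hepta >= 21 bp, octo >= 24 bp

which translates into minimum complete-copy counts of 9/6/5/4/4/3/3.
Loci are reported with 1-based inclusive coordinates spanning complete
motif copies only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CLASS_NAMES = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa", 7: "hepta", 8: "octo"}

#: minimum total array length (bp) per motif unit length
MIN_TOTAL_LENGTH = {2: 18, 3: 18, 4: 18, 5: 20, 6: 24, 7: 21, 8: 24}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class MotifClass:
    """One motif-length class with its minimum array length rule."""

    unit_length: int
    min_total_length: int

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.unit_length]

    @property
    def min_repeats(self) -> int:
        # smallest integer r with r * unit_length >= min_total_length
        return -(-self.min_total_length // self.unit_length)


def default_classes() -> tuple[MotifClass, ...]:
    """The seven standard classes (di- through octonucleotide)."""
    return tuple(MotifClass(k, MIN_TOTAL_LENGTH[k]) for k in range(2, 9))


@dataclass
class SSRLocus:
    """One detected microsatellite locus (1-based inclusive coordinates)."""

    seq_id: str
    start: int
    end: int
    motif: str
    unit_length: int
    repeat_count: int
    kind: str = "perfect"  # "perfect" | "compound"
    member_motifs: tuple[str, ...] = ()

    @property
    def canonical_motif(self) -> str:
        return canonical_motif(self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def class_name(self) -> str:
        return CLASS_NAMES.get(self.unit_length, str(self.unit_length))


@dataclass
class SSRCatalog:
    """An ordered collection of SSR loci over one genome."""

    loci: list[SSRLocus]
    genome_length: int
    marker_prefix: str = "ClSSR"

    def __post_init__(self) -> None:
        self.loci = sorted(self.loci, key=lambda l: (l.seq_id, l.start))

    @property
    def density(self) -> float:
        """SSRs per Mb of scanned sequence."""
        return 1e6 * len(self.loci) / self.genome_length

    def marker_id(self, i: int) -> str:
        return f"{self.marker_prefix}{i + 1:05d}"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "marker_id": self.marker_id(i),
                "seq_id": l.seq_id,
                "start": l.start,
                "end": l.end,
                "motif": l.motif if l.kind == "perfect" else "-".join(l.member_motifs),
                "canonical_motif": l.canonical_motif if l.kind == "perfect" else "",
                "unit_length": l.unit_length,
                "repeat_count": l.repeat_count,
                "kind": l.kind,
            }
            for i, l in enumerate(self.loci)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "marker_id", "seq_id", "start", "end", "motif", "canonical_motif",
                "unit_length", "repeat_count", "kind",
            ],
        )


def _is_primitive(motif: str) -> bool:
    """True if the motif is not itself a tandem repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(motif: str) -> str:
    """Family representative: lexicographic minimum over all cyclic rotations
    of the motif and of its reverse complement (so AG ≡ GA ≡ CT ≡ TC → "AG")."""
    rc = reverse_complement(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def scan_sequence(
    seq: str,
    seq_id: str = "seq",
    classes: tuple[MotifClass, ...] | None = None,
) -> list[SSRLocus]:
    """Find every maximal perfect tandem array meeting its class threshold.

    Each maximal run is reported once, under the shortest generating unit
    (e.g. (AT)x10 is a dinucleotide locus, never an ATAT tetranucleotide).
    Ambiguity codes (N etc.) terminate runs; loci never span them.
    Coordinates are 1-based inclusive and cover complete motif copies only.

    Raises ``ValueError`` naming the offset on non-IUPAC characters.
    """
    if classes is None:
        classes = default_classes()
    if not classes:
        raise ValueError("classes must be nonempty")
    seq = seq.upper().replace("\n", "")
    n = len(seq)
    if n == 0:
        return []

    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    acgt = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    if not acgt.all():
        bad = np.flatnonzero(~acgt)
        for off in bad:
            if seq[off] not in _VALID_IUPAC:
                raise ValueError(f"non-IUPAC character {seq[off]!r} at offset {int(off)}")

    loci: list[SSRLocus] = []
    for cls in sorted(classes, key=lambda c: c.unit_length):
        k = cls.unit_length
        if n < cls.min_total_length:
            continue
        # eq[i] True when position i matches position i+k and both are unambiguous
        eq = (arr[:-k] == arr[k:]) & acgt[:-k] & acgt[k:]
        # run-length encode maximal stretches of True
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for s, e in zip(idx[::2], idx[1::2]):
            run = int(e - s)  # length of True stretch: period-k region is run+k bp
            copies = (run + k) // k
            if copies < cls.min_repeats:
                continue
            motif = seq[s : s + k]
            if not _is_primitive(motif):
                continue  # reported under the shorter unit's class
            loci.append(
                SSRLocus(
                    seq_id=seq_id,
                    start=int(s) + 1,
                    end=int(s) + copies * k,
                    motif=motif,
                    unit_length=k,
                    repeat_count=copies,
                )
            )
    loci.sort(key=lambda l: (l.start, l.unit_length))
    return loci


def merge_compound(loci: list[SSRLocus], max_interruption: int = 100) -> list[SSRLocus]:
    """Merge adjacent loci separated by <= ``max_interruption`` bp into
    compound loci; everything else passes through unchanged.

    Input must be sorted by position on a single sequence.  The compound
    locus spans from the first member's start to the last member's end and
    records the ordered member motifs; its ``unit_length``/``repeat_count``
    are those of the first member (the array is no longer a single unit).
    """
    if max_interruption < 0:
        raise ValueError("max_interruption must be non-negative")
    if not loci:
        return []
    out: list[SSRLocus] = []
    group = [loci[0]]
    for loc in loci[1:]:
        gap = loc.start - group[-1].end - 1
        if loc.seq_id == group[-1].seq_id and gap <= max_interruption:
            group.append(loc)
        else:
            out.append(_collapse(group))
            group = [loc]
    out.append(_collapse(group))
    return out


def _collapse(group: list[SSRLocus]) -> SSRLocus:
    if len(group) == 1:
        return group[0]
    first, last = group[0], group[-1]
    members = tuple(m for l in group for m in (l.member_motifs or (l.motif,)))
    return SSRLocus(
        seq_id=first.seq_id,
        start=first.start,
        end=last.end,
        motif=first.motif,
        unit_length=first.unit_length,
        repeat_count=first.repeat_count,
        kind="compound",
        member_motifs=members,
    )


def class_frequencies(per_class_counts: dict[str, int]) -> pd.DataFrame:
    """Per-class counts and frequency percentages (count / total x 100)."""
    total = sum(per_class_counts.values())
    rows = [
        {"class": c, "count": n, "frequency_pct": 100.0 * n / total if total else float("nan")}
        for c, n in per_class_counts.items()
    ]
    return pd.DataFrame(rows)


def summarize_catalog(catalog: SSRCatalog, chrom_sizes: dict[str, int] | None = None) -> dict:
    """Summary tables for an SSR catalog.

    Returns a dict with:

    ``per_class``
        count, frequency %, and mean repeat number per motif class.
    ``per_chromosome``
        per-sequence count and density (SSRs/Mb; requires ``chrom_sizes``).
    ``per_motif``
        counts per canonical motif within each class (perfect loci).
    ``density``
        overall SSRs/Mb.

    An empty catalog yields empty tables rather than an error.
    """
    if not catalog.loci:
        empty = pd.DataFrame()
        return {"per_class": empty, "per_chromosome": empty, "per_motif": empty,
                "density": 0.0, "total": 0}

    df = catalog.to_frame()
    df["class"] = [l.class_name for l in catalog.loci]
    per_class_counts = df.groupby("class", sort=False)["marker_id"].count().to_dict()
    per_class = class_frequencies(per_class_counts)
    mean_rep = df.groupby("class", sort=False)["repeat_count"].mean().rename("mean_repeat_number")
    per_class = per_class.merge(mean_rep, left_on="class", right_index=True)

    per_chrom = df.groupby("seq_id")["marker_id"].count().rename("count").reset_index()
    if chrom_sizes:
        per_chrom["density_per_mb"] = [
            1e6 * c / chrom_sizes[s] if s in chrom_sizes else float("nan")
            for s, c in zip(per_chrom["seq_id"], per_chrom["count"])
        ]

    perfect = df[df["kind"] == "perfect"]
    per_motif = (
        perfect.groupby(["class", "canonical_motif"])["marker_id"]
        .count()
        .rename("count")
        .reset_index()
    )
    return {
        "per_class": per_class,
        "per_chromosome": per_chrom,
        "per_motif": per_motif,
        "density": catalog.density,
        "total": len(catalog.loci),
    }
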