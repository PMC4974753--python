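"""Readers and writers for the standard formats the toolkit touches.

All tables are plain TSV with a header line; lines starting with ``#`` are
comments.  Coordinates are 1-based inclusive everywhere (GFF3 convention),
including BED output headers' companion columns — BED itself is written
half-open 0-based as its standard requires.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ssr_scan import SSRCatalog, SSRLocus


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered {record id: uppercase sequence}; tolerates wrapping, CRLF
    and lowercase input."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    _ = width


def read_tsv(path: str | Path) -> pd.DataFrame:
    head = Path(path).read_bytes()[:4096]
    if b"\x00" in head:
        raise ValueError(f"{path}: malformed TSV (binary content)")
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except Exception as e:  # re-raise with file context
        raise ValueError(f"{path}: malformed TSV ({e})") from e


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_gff3(catalog: SSRCatalog, path: str | Path, source: str = "ssrkit") -> None:
    """SSR loci as a GFF3 track (1-based inclusive, microsatellite features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, l in enumerate(catalog.loci):
            attrs = (
                f"ID={catalog.marker_id(i)};motif={l.motif};"
                f"repeat_count={l.repeat_count};kind={l.kind}"
            )
            fh.write(
                f"{l.seq_id}\t{source}\tmicrosatellite\t{l.start}\t{l.end}"
                f"\t.\t+\t.\t{attrs}\n"
            )


def write_bed(catalog: SSRCatalog, path: str | Path) -> None:
    """SSR loci as BED (0-based half-open, per the BED standard)."""
    with open(path, "w") as fh:
        for i, l in enumerate(catalog.loci):
            fh.write(f"{l.seq_id}\t{l.start - 1}\t{l.end}\t{catalog.marker_id(i)}\n")


def read_gff3_intervals(path: str | Path, feature_type: str | None = None) -> pd.DataFrame:
    """Feature intervals from GFF3 as (seq_id, start, end, feature_type),
    1-based inclusive, optionally filtered to one feature type."""
    cols = ["seq_id", "source", "feature_type", "start", "end",
            "score", "strand", "frame", "attributes"]
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols,
                         dtype={"seq_id": str})
    except Exception as e:
        raise ValueError(f"{path}: malformed GFF3 ({e})") from e
    if feature_type is not None:
        df = df[df["feature_type"] == feature_type]
    return df[["seq_id", "start", "end", "feature_type"]].reset_index(drop=True)


def catalog_from_frame(df: pd.DataFrame, genome_length: int,
                       marker_prefix: str = "ClSSR") -> SSRCatalog:
    """Rebuild an SSRCatalog from its TSV representation."""
    loci = []
    for _, r in df.iterrows():
        kind = str(r["kind"])
        motif = str(r["motif"])
        members = tuple(motif.split("-")) if kind == "compound" else ()
        loci.append(
            SSRLocus(
                seq_id=str(r["seq_id"]), start=int(r["start"]), end=int(r["end"]),
                motif=members[0] if members else motif,
                unit_length=int(r["unit_length"]),
                repeat_count=int(r["repeat_count"]),
                kind=kind, member_motifs=members,
            )
        )
    return SSRCatalog(loci=loci, genome_length=genome_length, marker_prefix=marker_prefix)


def markers_to_frame(markers) -> pd.DataFrame:
    rows = [
        {
            "marker_id": m.marker_id, "seq_id": m.locus.seq_id,
            "ssr_start": m.locus.start, "ssr_end": m.locus.end,
            "motif": m.locus.motif, "fwd_seq": m.fwd_seq, "rev_seq": m.rev_seq,
            "expected_product_bp": m.expected_product_bp,
            "fwd_tm": m.fwd_tm, "rev_tm": m.rev_tm,
        }
        for m in markers
    ]
    return pd.DataFrame(
        rows, columns=["marker_id", "seq_id", "ssr_start", "ssr_end", "motif",
                       "fwd_seq", "rev_seq", "expected_product_bp", "fwd_tm", "rev_tm"],
    )


def markers_from_frame(df: pd.DataFrame):
    from .marker_design import MarkerPair
    from .ssr_scan import SSRLocus

    out = []
    for _, r in df.iterrows():
        locus = SSRLocus(
            seq_id=str(r["seq_id"]), start=int(r["ssr_start"]), end=int(r["ssr_end"]),
            motif=str(r["motif"]).split("-")[0],
            unit_length=len(str(r["motif"]).split("-")[0]),
            repeat_count=1,
        )
        out.append(
            MarkerPair(
                marker_id=str(r["marker_id"]), locus=locus,
                fwd_seq=str(r["fwd_seq"]), rev_seq=str(r["rev_seq"]),
                expected_product_bp=int(r["expected_product_bp"]),
                fwd_tm=float(r.get("fwd_tm", 0.0)), rev_tm=float(r.get("rev_tm", 0.0)),
            )
        )
    return out


def amplicons_to_frame(amplicons) -> pd.DataFrame:
    rows = [
        {"marker_id": a.marker_id, "target_seq_id": a.target_seq_id,
         "start": a.start, "end": a.end, "length": a.length,
         "fwd_mm": a.fwd_mismatches, "rev_mm": a.rev_mismatches}
        for a in amplicons
    ]
    return pd.DataFrame(
        rows, columns=["marker_id", "target_seq_id", "start", "end", "length",
                       "fwd_mm", "rev_mm"],
    )


def shared_markers_to_frame(shared) -> pd.DataFrame:
    rows = [
        {"marker_id": m.marker_id, "src_chr": m.source_seq_id, "src_pos": m.source_pos,
         "tgt_chr": m.target_seq_id, "tgt_pos": m.target_pos}
        for m in shared
    ]
    return pd.DataFrame(rows, columns=["marker_id", "src_chr", "src_pos", "tgt_chr", "tgt_pos"])


def shared_markers_from_frame(df: pd.DataFrame):
    from .synteny import SharedMarker

    return [
        SharedMarker(
            marker_id=str(r["marker_id"]),
            source_seq_id=str(r["src_chr"]), source_pos=int(r["src_pos"]),
            target_seq_id=str(r["tgt_chr"]), target_pos=int(r["tgt_pos"]),
        )
        for _, r in df.iterrows()
    ]


def write_newick(newick: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip() + "\n")
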