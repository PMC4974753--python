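"""End-to-end orchestration: scan → design → e-PCR → transfer → synteny.

The pipeline takes a source genome plus one or more partner genomes,
mines SSRs on the source, designs markers, classifies each marker's
transferability on every partner, builds shared-marker placements from
the single-copy amplicons, calls syntenic blocks per partner, and — when
there are two or more partners — intersects block sets into conserved
blocks.  All primary outputs are deterministic TSV/text files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import insilico_pcr, io, marker_design, ssr_scan, synteny


@dataclass
class PipelineConfig:
    """Resolved parameters for an end-to-end run (documented defaults)."""

    source_fasta: str = ""
    target_fastas: dict[str, str] = field(default_factory=dict)
    out_dir: str = "ssrkit_out"
    marker_prefix: str = "ClSSR"
    max_interruption: int = 100
    product_size_range: tuple[int, int] = (100, 300)
    epcr_product_bounds: tuple[int, int] = (50, 3000)
    max_5prime_mismatches: int = 5
    five_prime_window: int = 5
    min_identity: float = 0.90
    min_block_markers: int = 3
    max_rank_gap: int = 0
    exclude_chr0: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("product_size_range", "epcr_product_bounds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    catalog: ssr_scan.SSRCatalog
    markers: list
    transfer: dict[str, insilico_pcr.TransferTable]
    amplicons: dict[str, dict[str, list]]
    blocks: dict[str, list]
    conserved: list


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    source = io.read_fasta(config.source_fasta)
    loci: list[ssr_scan.SSRLocus] = []
    for name, seq in source.items():
        loci.extend(ssr_scan.scan_sequence(seq, name))
    merged: list[ssr_scan.SSRLocus] = []
    by_chrom: dict[str, list] = {}
    for l in sorted(loci, key=lambda x: (x.seq_id, x.start)):
        by_chrom.setdefault(l.seq_id, []).append(l)
    for name in sorted(by_chrom):
        merged.extend(ssr_scan.merge_compound(by_chrom[name], config.max_interruption))
    catalog = ssr_scan.SSRCatalog(
        loci=merged, genome_length=sum(len(s) for s in source.values()),
        marker_prefix=config.marker_prefix,
    )
    constraints = marker_design.PrimerConstraints(product_size_range=config.product_size_range)
    markers = marker_design.design_all(source, catalog.loci, constraints,
                                       prefix=config.marker_prefix)
    rule = insilico_pcr.MatchRule(
        max_5prime_mismatches=config.max_5prime_mismatches,
        five_prime_window=config.five_prime_window,
        min_identity=config.min_identity,
    )

    transfer: dict[str, insilico_pcr.TransferTable] = {}
    amplicons: dict[str, dict[str, list]] = {}
    blocks: dict[str, list] = {}
    locus_mid = {
        m.marker_id: (m.locus.seq_id, (m.locus.start + m.locus.end) // 2) for m in markers
    }
    for tname, fasta in config.target_fastas.items():
        target = io.read_fasta(fasta)
        table, amps = insilico_pcr.classify_transferability(
            markers, target, rule, config.epcr_product_bounds
        )
        transfer[tname] = table
        amplicons[tname] = amps
        shared = []
        for mid in sorted(table.single_copy):
            schrom, spos = locus_mid[mid]
            if config.exclude_chr0 and schrom.endswith("chr0"):
                continue
            a = amps[mid][0]
            shared.append(
                synteny.SharedMarker(
                    marker_id=mid, source_seq_id=schrom, source_pos=spos,
                    target_seq_id=a.target_seq_id,
                    target_pos=(a.start + a.end) // 2,
                )
            )
        blocks[tname] = synteny.call_blocks(
            shared, config.min_block_markers, prefix=f"{tname[:1].upper()}B",
            max_rank_gap=config.max_rank_gap,
        )
        if write:
            io.write_tsv(io.amplicons_to_frame(
                [a for mid in sorted(amps) for a in amps[mid]]),
                out / f"amplicons_{tname}.tsv")
            io.write_tsv(table.to_frame(), out / f"transfer_{tname}.tsv")
            io.write_tsv(io.shared_markers_to_frame(shared), out / f"shared_{tname}.tsv")
            io.write_tsv(synteny.blocks_to_frame(blocks[tname]), out / f"blocks_{tname}.tsv")
            (out / f"links_{tname}.txt").write_text(
                synteny.export_links(blocks[tname], mode="block"))

    conserved = []
    tnames = sorted(config.target_fastas)
    if len(tnames) >= 2:
        conserved = synteny.intersect_blocks(
            blocks[tnames[0]], blocks[tnames[1]], config.min_block_markers
        )
    if write:
        io.write_tsv(catalog.to_frame(), out / "catalog.tsv")
        io.write_gff3(catalog, out / "catalog.gff3")
        io.write_tsv(io.markers_to_frame(markers), out / "markers.tsv")
        if len(tnames) >= 2:
            rows = [
                {"src_chr": c.source_seq_id, "src_start": c.source_start,
                 "src_end": c.source_end, "n_markers": len(c.marker_ids),
                 "block_a": c.block_a, "block_b": c.block_b,
                 "marker_ids": ",".join(c.marker_ids)}
                for c in conserved
            ]
            import pandas as pd

            io.write_tsv(pd.DataFrame(rows), out / "conserved_blocks.tsv")
    return PipelineResult(
        catalog=catalog, markers=markers, transfer=transfer,
        amplicons=amplicons, blocks=blocks, conserved=conserved,
    )
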