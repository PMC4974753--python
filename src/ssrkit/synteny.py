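"""Syntenic block calling from markers shared between two genomes.

A shared marker is a single-copy marker with one position in each genome.
Per source chromosome, markers are ordered by source position and each is
given its rank among the markers mapping to the same target chromosome.
Maximal runs of markers whose target ranks are strictly monotonic — and
whose target chromosome does not change — are syntenic blocks; increasing
ranks mean a collinear block, decreasing ranks an inverted one.  Runs
shorter than ``min_block_markers`` (default 3) are dropped.

Block sets from two different partner genomes over the same source genome
can be intersected to find segments conserved across all three genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class SharedMarker:
    """One marker placed on both genomes (positions are locus/amplicon midpoints)."""

    marker_id: str
    source_seq_id: str
    source_pos: int
    target_seq_id: str
    target_pos: int


@dataclass
class SyntenyBlock:
    block_id: str
    source_seq_id: str
    source_start: int
    source_end: int
    target_seq_id: str
    target_start: int
    target_end: int
    marker_ids: tuple[str, ...]
    orientation: str  # "collinear" | "inverted"
    source_positions: tuple[int, ...] = ()

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class ConservedBlock:
    """Source-genome segment covered by a block against each of two partners."""

    source_seq_id: str
    source_start: int
    source_end: int
    marker_ids: tuple[str, ...]
    block_a: str
    block_b: str


def call_blocks(
    shared: list[SharedMarker],
    min_block_markers: int = 3,
    prefix: str = "SB",
    max_rank_gap: int = 0,
) -> list[SyntenyBlock]:
    """Call maximal monotone syntenic blocks of >= ``min_block_markers``.

    Splits occur at every target-chromosome change, at every direction
    flip of the target rank, and whenever more than ``max_rank_gap``
    interleaved markers are skipped (default 0: target ranks must be
    consecutive, the operational reading of markers sharing continuous
    physical positions on both genomes; this also makes block calling
    symmetric under swapping the two genomes).  Each retained marker
    belongs to exactly one block.  Raises on duplicate marker ids.
    """
    if not shared:
        return []
    ids = [m.marker_id for m in shared]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate marker_id in shared marker list")

    # rank of each marker among the markers of its target chromosome
    by_target: dict[str, list[SharedMarker]] = {}
    for m in shared:
        by_target.setdefault(m.target_seq_id, []).append(m)
    rank: dict[str, int] = {}
    for tchrom, ms in by_target.items():
        for r, m in enumerate(sorted(ms, key=lambda x: (x.target_pos, x.marker_id))):
            rank[m.marker_id] = r

    blocks: list[SyntenyBlock] = []
    by_source: dict[str, list[SharedMarker]] = {}
    for m in shared:
        by_source.setdefault(m.source_seq_id, []).append(m)

    runs: list[list[SharedMarker]] = []
    for schrom in sorted(by_source):
        ms = sorted(by_source[schrom], key=lambda x: (x.source_pos, x.marker_id))
        run = [ms[0]]
        direction = 0  # 0 unknown, +1 increasing, -1 decreasing
        for m in ms[1:]:
            prev = run[-1]
            if m.target_seq_id != prev.target_seq_id:
                runs.append(run)
                run, direction = [m], 0
                continue
            step = rank[m.marker_id] - rank[prev.marker_id]
            d = 1 if step > 0 else -1
            if abs(step) > 1 + max_rank_gap or (direction and d != direction):
                runs.append(run)
                # the breaking marker starts a fresh run
                run, direction = [m], 0
            else:
                run.append(m)
                direction = d
        runs.append(run)

    ordinal = 0
    for run in runs:
        if len(run) < min_block_markers:
            continue
        ordinal += 1
        r0, r1 = rank[run[0].marker_id], rank[run[-1].marker_id]
        orient = "collinear" if r1 > r0 else "inverted"
        tpos = [m.target_pos for m in run]
        blocks.append(
            SyntenyBlock(
                block_id=f"{prefix}{ordinal}",
                source_seq_id=run[0].source_seq_id,
                source_start=run[0].source_pos,
                source_end=run[-1].source_pos,
                target_seq_id=run[0].target_seq_id,
                target_start=min(tpos),
                target_end=max(tpos),
                marker_ids=tuple(m.marker_id for m in run),
                orientation=orient,
                source_positions=tuple(m.source_pos for m in run),
            )
        )
    return blocks


def chromosome_correspondence(
    blocks: list[SyntenyBlock], min_markers: int = 3
) -> pd.DataFrame:
    """Per source chromosome, the target chromosomes sharing >= ``min_markers``
    markers (summed over blocks), with counts, sorted descending."""
    tally: dict[tuple[str, str], int] = {}
    for b in blocks:
        key = (b.source_seq_id, b.target_seq_id)
        tally[key] = tally.get(key, 0) + b.n_markers
    rows = [
        {"source_seq_id": s, "target_seq_id": t, "n_markers": n}
        for (s, t), n in tally.items()
        if n >= min_markers
    ]
    df = pd.DataFrame(rows, columns=["source_seq_id", "target_seq_id", "n_markers"])
    return df.sort_values(
        ["source_seq_id", "n_markers", "target_seq_id"], ascending=[True, False, True]
    ).reset_index(drop=True)


def intersect_blocks(
    blocks_a: list[SyntenyBlock],
    blocks_b: list[SyntenyBlock],
    min_members: int = 3,
) -> list[ConservedBlock]:
    """Blocks conserved across three genomes: for each pair of blocks on the
    same source chromosome, the markers present in both form a conserved
    block when >= ``min_members`` remain."""
    out: list[ConservedBlock] = []
    for a in blocks_a:
        pos_a = dict(zip(a.marker_ids, a.source_positions))
        for b in blocks_b:
            if b.source_seq_id != a.source_seq_id:
                continue
            members = set(b.marker_ids)
            common = [m for m in a.marker_ids if m in members]
            if len(common) < min_members:
                continue
            spans = [pos_a[m] for m in common]
            out.append(
                ConservedBlock(
                    source_seq_id=a.source_seq_id,
                    source_start=min(spans),
                    source_end=max(spans),
                    marker_ids=tuple(common),
                    block_a=a.block_id,
                    block_b=b.block_id,
                )
            )
    return out


def blocks_to_frame(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    rows = [
        {
            "block_id": b.block_id,
            "src_chr": b.source_seq_id,
            "src_start": b.source_start,
            "src_end": b.source_end,
            "tgt_chr": b.target_seq_id,
            "tgt_start": b.target_start,
            "tgt_end": b.target_end,
            "n_markers": b.n_markers,
            "orientation": b.orientation,
        }
        for b in blocks
    ]
    return pd.DataFrame(
        rows,
        columns=["block_id", "src_chr", "src_start", "src_end", "tgt_chr",
                 "tgt_start", "tgt_end", "n_markers", "orientation"],
    )


def export_links(
    items: list[SyntenyBlock] | list[SharedMarker],
    mode: str = "block",
) -> str:
    """Circos-style link records, one per block ribbon or one per marker.

    Format per line: ``src_chr src_start src_end tgt_chr tgt_start tgt_end``
    with an ``inverted`` option flag on inverted block ribbons.
    """
    lines = ["# circos links"]
    if mode == "block":
        for b in items:  # type: ignore[assignment]
            opt = " orientation=inverted" if b.orientation == "inverted" else ""
            lines.append(
                f"{b.source_seq_id} {b.source_start} {b.source_end} "
                f"{b.target_seq_id} {b.target_start} {b.target_end}{opt}"
            )
    elif mode == "marker":
        for m in items:  # type: ignore[assignment]
            lines.append(
                f"{m.source_seq_id} {m.source_pos} {m.source_pos} "
                f"{m.target_seq_id} {m.target_pos} {m.target_pos}"
            )
    else:
        raise ValueError("mode must be 'block' or 'marker'")
    return "\n".join(lines) + "\n"
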