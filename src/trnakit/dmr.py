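"""Differentially methylated regions versus tRNA genes: proximity windows,
gene-body overlap, and identical-sequence ambiguity counts.

Distances are gaps between closest interval ends (0 on overlap); the
proximity window is inclusive, so "within 5 kb" admits a gap of exactly
5,000 bp.  Because many tRNA loci share a byte-identical sequence, each
reported DMR-gene pair carries the number of loci sharing the gene's exact
sequence — when that count exceeds 1, locus-level expression attribution for
the methylated gene is masked.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from trnakit.annotation import SequenceGroup, TRNAGene

log = logging.getLogger(__name__)


@dataclass
class GenomicInterval:
    """Stored 1-based inclusive regardless of source format."""

    chrom: str
    start: int
    end: int
    name: str = "."
    direction: str | None = None      # "gain" | "loss" of methylation

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.name}: end < start")


def read_bed(source) -> list[GenomicInterval]:
    """Read BED3+ (0-based half-open) into 1-based inclusive intervals.

    A BED end <= start is a hard error reporting the offending line number.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and source and "\n" not in source
        and Path(source).is_file()
    ):
        text = Path(source).read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    out = []
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"BED line {lineno}: fewer than 3 columns")
        chrom, bed_start, bed_end = fields[0], int(fields[1]), int(fields[2])
        if bed_end <= bed_start:
            raise ValueError(f"BED line {lineno}: end {bed_end} <= start {bed_start}")
        name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
        direction = None
        if len(fields) > 4 and fields[4] in ("gain", "loss"):
            direction = fields[4]
        out.append(GenomicInterval(chrom=chrom, start=bed_start + 1, end=bed_end,
                                   name=name, direction=direction))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals back to BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            extra = f"\t{iv.direction}" if iv.direction else ""
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}{extra}\n")


def interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap between two 1-based inclusive intervals; 0 when they intersect."""
    if a_end < b_start:
        return b_start - a_end
    if b_end < a_start:
        return a_start - b_end
    return 0


def genes_near_dmrs(
    genes: Iterable[TRNAGene],
    dmrs: Iterable[GenomicInterval],
    window: int = 5000,
) -> pd.DataFrame:
    """All (gene, DMR) pairs on the same contig within ``window`` bp
    (inclusive boundary); strand is ignored.

    ``relation`` is ``overlap_gene_body`` when the DMR intersects the gene
    span (distance 0), otherwise ``flanking``.
    """
    rows = []
    for g in genes:
        for d in dmrs:
            if g.chrom != d.chrom:
                continue
            dist = interval_distance(g.start, g.end, d.start, d.end)
            if dist <= window:
                relation = "overlap_gene_body" if dist == 0 else "flanking"
                rows.append((g.gene_id, g.anticodon_key, d.name, dist, relation))
    return pd.DataFrame(
        rows, columns=["gene_id", "anticodon", "dmr_name", "distance", "relation"]
    ).sort_values(["gene_id", "dmr_name"], ignore_index=True)


def ambiguity_annotation(gene_id: str, groups: Iterable[SequenceGroup]) -> int:
    """Number of loci (including the gene itself) sharing the gene's exact
    mature sequence; >1 means locus-level attribution is masked."""
    for g in groups:
        if gene_id in g.member_gene_ids:
            return g.size
    raise ValueError(f"gene {gene_id!r} is not a member of any sequence group")


def annotate_dmr_pairs(pairs: pd.DataFrame, groups: Iterable[SequenceGroup]) -> pd.DataFrame:
    """Attach the identical-locus count to each DMR-gene pair."""
    group_list = list(groups)
    out = pairs.copy()
    out["identical_locus_count"] = [
        ambiguity_annotation(gid, group_list) for gid in out["gene_id"]
    ]
    return out
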