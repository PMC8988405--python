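"""Count-matrix handling: ingestion, CPM normalization, expression filtering,
aggregation to sequence-group / anticodon level, and read assignment by exact
sequence match.

The expression filter mirrors a simple presence rule: a feature is expressed
in a tissue when it has a nonzero raw count in at least two distinct
individuals of that tissue.  Individuals are identified by the sample sheet's
``individual`` column, so technical replicates of one animal never satisfy
the rule on their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from trnakit.annotation import SequenceGroup, TRNAGene

log = logging.getLogger(__name__)

_SCALES = ("raw", "cpm", "log2cpm")
_META_COLUMNS = ("tissue", "treatment", "individual")


@dataclass
class CountMatrix:
    """Features x samples matrix with an explicit scale tag."""

    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "raw":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise ValueError("raw counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("raw counts must be integers")

    @property
    def features(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)


def validate_sample_sheet(meta: pd.DataFrame) -> pd.DataFrame:
    """Normalize a sample sheet to a frame indexed by unique sample_id with
    tissue / treatment / individual columns."""
    df = meta.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids: {dup}")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if df[list(_META_COLUMNS)].isna().any().any():
        raise ValueError("sample sheet has missing tissue/treatment/individual labels")
    return df


def read_counts(counts_tsv, sample_sheet_tsv) -> tuple[CountMatrix, pd.DataFrame]:
    """Read a features-x-samples TSV and its sample sheet.

    Sample order is taken from the sheet; samples present in only one of the
    two files are a hard error.
    """
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    counts.columns = counts.columns.astype(str)
    meta = validate_sample_sheet(pd.read_csv(sample_sheet_tsv, sep="\t", dtype=str))

    sheet_only = [s for s in meta.index if s not in counts.columns]
    matrix_only = [s for s in counts.columns if s not in meta.index]
    if sheet_only or matrix_only:
        raise ValueError(
            f"sample sheet / count matrix mismatch: missing from matrix "
            f"{sheet_only}, missing from sheet {matrix_only}"
        )
    counts = counts[list(meta.index)]
    return CountMatrix(values=counts, scale="raw"), meta


def assign_reads(
    reads: Iterable[str],
    groups: Iterable[SequenceGroup],
    min_len: int = 50,
    sample_id: str = "sample",
) -> tuple[CountMatrix, int]:
    """Assign reads to sequence groups by exact full-length match.

    A terminal 3' CCA (the post-transcriptional tail) is stripped before
    matching.  A read counts for a group iff, after stripping, it equals the
    group sequence exactly and is at least ``min_len`` long.  Because group
    sequences are unique, no read can be assigned twice — collapsing identical
    loci is what resolves the multi-mapping problem.  Returns the per-group
    one-sample matrix and the number of unassigned reads.
    """
    group_list = list(groups)
    by_seq = {g.sequence: g.group_id for g in group_list}
    counts = {g.group_id: 0 for g in group_list}
    unassigned = 0
    for read in reads:
        r = read.upper().replace("T", "U")
        if r.endswith("CCA"):
            r = r[:-3]
        gid = by_seq.get(r)
        if gid is None or len(r) < min_len:
            unassigned += 1
        else:
            counts[gid] += 1
    frame = pd.DataFrame({sample_id: pd.Series(counts)}).loc[
        [g.group_id for g in group_list]
    ]
    return CountMatrix(values=frame, scale="raw"), unassigned


def cpm(matrix: CountMatrix) -> CountMatrix:
    """Counts per million; zero-library columns become all zeros with a warning."""
    if matrix.scale != "raw":
        raise ValueError("cpm() expects a raw matrix")
    lib = matrix.library_sizes()
    zero = lib[lib == 0].index.tolist()
    if zero:
        log.warning("zero library size for samples %s; CPM set to 0", zero)
    safe = lib.replace(0, 1)
    vals = matrix.values.div(safe, axis=1) * 1e6
    vals[zero] = 0.0
    return CountMatrix(values=vals, scale="cpm")


def log2cpm(matrix: CountMatrix, pseudocount: float = 1.0) -> CountMatrix:
    """log2(CPM + pseudocount); pseudocount 1 preserves zeros at 0."""
    m = cpm(matrix) if matrix.scale == "raw" else matrix
    if m.scale != "cpm":
        raise ValueError("log2cpm() expects a raw or cpm matrix")
    return CountMatrix(values=np.log2(m.values + pseudocount), scale="log2cpm")


def filter_expressed(
    matrix: CountMatrix,
    meta: pd.DataFrame,
    min_individuals: int = 2,
    group_cols: tuple = ("tissue",),
) -> pd.DataFrame:
    """Boolean expressed flags per (feature, group).

    A feature is expressed in a group (default grouping: tissue) iff its raw
    count is > 0 in at least ``min_individuals`` distinct individuals of that
    group.  Returns features x groups booleans; multi-column groupings use a
    '/'-joined column label.
    """
    if matrix.scale != "raw":
        raise ValueError("filter_expressed() expects raw counts")
    meta = validate_sample_sheet(meta)
    flags = {}
    for key, sub in meta.groupby(list(group_cols), sort=True):
        label = key if isinstance(key, str) else "/".join(map(str, key))
        if len(sub) < min_individuals:
            log.warning(
                "group %s has %d samples < min_individuals=%d",
                label, len(sub), min_individuals,
            )
        nonzero = matrix.values[list(sub.index)] > 0
        # count distinct individuals with >=1 nonzero sample
        by_ind = nonzero.T.groupby(sub["individual"].values).any()
        flags[label] = by_ind.sum(axis=0) >= min_individuals
    return pd.DataFrame(flags)


def aggregate(matrix: CountMatrix, mapping: Mapping[str, str]) -> CountMatrix:
    """Sum features sharing a mapped key (e.g. gene -> group, group -> anticodon).

    Every feature must be mapped; column totals are conserved.
    """
    unmapped = [f for f in matrix.features if f not in mapping]
    if unmapped:
        raise ValueError(f"unmapped features: {unmapped}")
    keys = pd.Series({f: mapping[f] for f in matrix.features})
    out = matrix.values.groupby(keys).sum().sort_index()
    return CountMatrix(values=out, scale=matrix.scale)


def gene_flags_from_groups(
    group_flags: pd.DataFrame,
    groups: Iterable[SequenceGroup],
) -> pd.DataFrame:
    """Propagate group-level expressed flags to every member locus.

    Identical-sequence loci cannot be individually resolved, so a locus is
    called expressed iff its sequence group is.
    """
    rows = {}
    for g in groups:
        for gid in g.member_gene_ids:
            rows[gid] = group_flags.loc[g.group_id]
    return pd.DataFrame(rows).T.sort_index()


def isodecoder_expressed_proportion(
    gene_flags: pd.DataFrame,
    genes: Iterable[TRNAGene],
) -> pd.DataFrame:
    """Fraction of annotated gene copies per anticodon flagged expressed,
    per tissue column of ``gene_flags``.

    Returns long-format rows (anticodon, tissue, expressed_copies,
    total_copies, fraction); anticodons with zero annotated copies are
    omitted by construction.
    """
    gene_list = list(genes)
    rows = []
    keys = sorted({g.anticodon_key for g in gene_list})
    for key in keys:
        members = [g.gene_id for g in gene_list if g.anticodon_key == key]
        present = [m for m in members if m in gene_flags.index]
        for tissue in gene_flags.columns:
            expressed = int(gene_flags.loc[present, tissue].sum()) if present else 0
            rows.append((key, tissue, expressed, len(members), expressed / len(members)))
    return pd.DataFrame(
        rows,
        columns=["anticodon", "tissue", "expressed_copies", "total_copies", "fraction"],
    )
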