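"""tRNA gene annotation: parsing, sequence-group collapsing, copy-number tables.

Multicopy tRNA genes are frequently exact duplicates of one another, which
makes locus-level read attribution impossible.  The central object here is
therefore the *sequence group*: the equivalence class of annotated tRNA loci
whose mature (intron-spliced, CCA-less) sequences are byte-identical.
Downstream expression analysis operates on sequence groups, not loci.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio.Seq import Seq

log = logging.getLogger(__name__)

# GtRNAdb / tRNAscan-SE gene-name token, e.g. "tRNA-Ile-AAT-1-1" or "tRNA-SeC-TCA-1-1".
_NAME_RE = re.compile(r"tRNA-([A-Za-z]{3,4})-([ACGTUacgtu]{3})(?:-(\d+)-(\d+))?")

_CONFIDENCE_LEVELS = ("high", "pseudo", "secondary_filtered")


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class TRNAGene:
    """One annotated tRNA locus (coordinates 1-based inclusive, GFF3 convention)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    amino_acid: str          # 3-letter code; "SeC" and "iMet" allowed
    anticodon: str           # RNA alphabet, written 5'->3'
    compartment: str         # "nuclear" | "mito"
    mature_sequence: str     # RNA alphabet, introns removed, no 3' CCA
    confidence: str = "high"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.confidence not in _CONFIDENCE_LEVELS:
            raise ValueError(f"{self.gene_id}: bad confidence {self.confidence!r}")
        self.anticodon = _rna(self.anticodon)
        self.mature_sequence = _rna(self.mature_sequence)

    @property
    def anticodon_key(self) -> str:
        """Field-standard 'AminoAcid-Anticodon' key, e.g. 'Ile-AAU'."""
        return f"{self.amino_acid}-{self.anticodon}"


@dataclass
class SequenceGroup:
    """Equivalence class of loci with identical mature sequence."""

    group_id: str
    sequence: str
    member_gene_ids: frozenset
    anticodon: str
    amino_acid: str

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)

    @property
    def anticodon_key(self) -> str:
        return f"{self.amino_acid}-{self.anticodon}"


@dataclass
class CopyNumberTable:
    """Gene copy counts keyed either by 'AA-Anticodon' or by group sequence."""

    level: str                      # "anticodon" | "sequence"
    counts: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, dtype=int).sort_index()


class _SequenceSource:
    """Uniform 1-based-inclusive access to a genome FASTA, a dict, or a
    per-gene tRNA FASTA (record ids matching gene ids)."""

    def __init__(self, source):
        if isinstance(source, (str, Path)):
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source))
            self._dict = None
        elif isinstance(source, Mapping):
            self._fasta = None
            self._dict = {k: str(v) for k, v in source.items()}
        else:  # assume a pyfaidx.Fasta-like object
            self._fasta = source
            self._dict = None

    def __contains__(self, name: str) -> bool:
        if self._dict is not None:
            return name in self._dict
        return name in self._fasta

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self:
            raise ValueError(f"contig {chrom!r} not present in sequence source")
        if self._dict is not None:
            return self._dict[chrom][start - 1 : end]
        return str(self._fasta[chrom][start - 1 : end])


def _parse_identity(feature) -> tuple[str, str] | None:
    """(amino_acid, anticodon-RNA) from explicit attributes or the name token."""
    attrs = feature.attributes
    aa = attrs.get("amino_acid", [None])[0]
    ac = attrs.get("anticodon", [None])[0]
    if aa and ac and re.fullmatch(r"[ACGTUacgtu]{3}", ac):
        return aa, _rna(ac)
    for key in ("ID", "Name", "gene_id", "gene_name", "transcript_id"):
        for token in attrs.get(key, []):
            m = _NAME_RE.search(token)
            if m:
                return m.group(1), _rna(m.group(2))
    return None


def _parse_confidence(feature) -> str:
    attrs = feature.attributes
    explicit = attrs.get("confidence", [None])[0]
    if explicit in _CONFIDENCE_LEVELS:
        return explicit
    blob = " ".join(v for vals in attrs.values() for v in vals).lower()
    if "secondary_filtered" in blob or "secondary filtered" in blob:
        return "secondary_filtered"
    if "pseudo" in blob:
        return "pseudo"
    return "high"


def parse_trna_annotation(
    gff,
    sequence_source=None,
    mito_contig: str = "MT",
    high_confidence_only: bool = False,
) -> list[TRNAGene]:
    """Parse a tRNAscan-SE / GtRNAdb-dialect GFF3 into :class:`TRNAGene` records.

    Parameters
    ----------
    gff : path or GFF3 text
        Annotation with ``tRNA`` features; intron-containing genes carry child
        ``exon`` features whose concatenation (reverse-complemented on the
        minus strand) gives the mature body.
    sequence_source : path, mapping or pyfaidx.Fasta, optional
        Genome FASTA covering all referenced contigs, or a per-gene tRNA FASTA
        keyed by gene id.  When omitted, mature sequences are left empty.
    mito_contig : str
        Contig name defining ``compartment="mito"``.
    high_confidence_only : bool
        Drop pseudogene / secondary-filtered records.

    Mature sequences are returned in the RNA alphabet and never include the
    post-transcriptionally added 3' CCA.
    """
    text = gff
    if isinstance(gff, Path) or (
        isinstance(gff, str) and "\n" not in gff and Path(gff).exists()
    ):
        text = Path(gff).read_text()
    elif hasattr(gff, "read"):
        text = gff.read()
    try:
        db = gffutils.create_db(
            text, dbfn=":memory:", from_string=True, force=True,
            keep_order=True, merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    source = _SequenceSource(sequence_source) if sequence_source is not None else None

    genes: list[TRNAGene] = []
    n_skipped = 0
    for feat in db.features_of_type("tRNA", order_by=("seqid", "start")):
        identity = _parse_identity(feat)
        if identity is None:
            n_skipped += 1
            log.warning("skipping %s: unparsable amino-acid/anticodon attributes", feat.id)
            continue
        amino_acid, anticodon = identity
        confidence = _parse_confidence(feat)
        if high_confidence_only and confidence != "high":
            continue

        mature = ""
        if source is not None:
            if feat.seqid in source:
                exons = sorted(
                    db.children(feat, featuretype="exon"), key=lambda e: e.start
                )
                spans = [(e.start, e.end) for e in exons] or [(feat.start, feat.end)]
                dna = "".join(source.fetch(feat.seqid, s, e) for s, e in spans)
                if feat.strand == "-":
                    dna = str(Seq(dna).reverse_complement())
                mature = _rna(dna)
            elif feat.id in source:
                mature = _rna(source.fetch(feat.id, 1, 10**9))
            else:
                raise ValueError(f"contig {feat.seqid!r} not present in sequence source")

        genes.append(
            TRNAGene(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                amino_acid=amino_acid,
                anticodon=anticodon,
                compartment="mito" if feat.seqid == mito_contig else "nuclear",
                mature_sequence=mature,
                confidence=confidence,
            )
        )
    if n_skipped:
        log.warning("skipped %d unparsable tRNA records", n_skipped)
    return genes


def collapse_identical_sequences(genes: Iterable[TRNAGene]) -> list[SequenceGroup]:
    """Partition loci into groups of byte-identical mature sequence.

    Groups are ordered lexicographically by sequence; group ids are stable
    content hashes.  Identical sequences annotated with conflicting anticodons
    indicate a corrupt annotation and raise.
    """
    by_seq: dict[str, list[TRNAGene]] = {}
    for g in genes:
        if not g.mature_sequence:
            raise ValueError(f"{g.gene_id}: empty mature sequence; cannot collapse")
        by_seq.setdefault(g.mature_sequence, []).append(g)

    groups = []
    for seq in sorted(by_seq):
        members = by_seq[seq]
        anticodons = {m.anticodon for m in members}
        aminos = {m.amino_acid for m in members}
        if len(anticodons) > 1 or len(aminos) > 1:
            ids = ",".join(sorted(m.gene_id for m in members))
            raise ValueError(
                f"annotation inconsistency: identical sequence with conflicting "
                f"anticodon/amino-acid labels among {ids}"
            )
        digest = hashlib.sha1(seq.encode()).hexdigest()[:10]
        groups.append(
            SequenceGroup(
                group_id=f"SG-{digest}",
                sequence=seq,
                member_gene_ids=frozenset(m.gene_id for m in members),
                anticodon=members[0].anticodon,
                amino_acid=members[0].amino_acid,
            )
        )
    return groups


def copy_number(
    genes: Iterable[TRNAGene],
    level: str = "anticodon",
    universe: Iterable[str] | None = None,
) -> CopyNumberTable:
    """Count annotated gene copies per anticodon key or per unique sequence.

    With ``universe`` supplied, keys absent from the annotation are reported
    as explicit zeros.
    """
    if level not in ("anticodon", "sequence"):
        raise ValueError(f"unknown level {level!r}")
    counts: dict[str, int] = {}
    if universe is not None:
        counts.update({k: 0 for k in universe})
    for g in genes:
        key = g.anticodon_key if level == "anticodon" else g.mature_sequence
        counts[key] = counts.get(key, 0) + 1
    return CopyNumberTable(level=level, counts=counts)


# The 61 anticodons complementary to the sense codons of the standard code
# (RNA alphabet, 5'->3').  Anticodons pairing the three stops are excluded.
def sense_anticodon_universe() -> list[str]:
    from trnakit.codonusage import anticodon_to_codon, build_codon_table

    table = build_codon_table()
    bases = "ACGU"
    universe = [
        a + b + c
        for a in bases
        for b in bases
        for c in bases
        if anticodon_to_codon(a + b + c) not in table.stop_codons
    ]
    return sorted(universe)


def missing_anticodons(
    table: CopyNumberTable, universe: Iterable[str] | None = None
) -> list[str]:
    """Anticodons from ``universe`` with zero annotated high-confidence copies.

    ``table`` must be anticodon-level and should be built from high-confidence
    genes only (pseudogene / secondary-filtered loci are not copies).
    """
    if table.level != "anticodon":
        raise ValueError("missing_anticodons requires an anticodon-level table")
    if universe is None:
        universe = sense_anticodon_universe()
    present = {
        key.split("-")[-1]
        for key, n in table.counts.items()
        if n > 0
    }
    return sorted(_rna(a) for a in universe if _rna(a) not in present)


# ---------------------------------------------------------------------------
# Tabular I/O

_GENE_COLUMNS = [
    "gene_id", "chrom", "start", "end", "strand",
    "amino_acid", "anticodon", "compartment", "sequence", "confidence",
]


def genes_to_frame(genes: Iterable[TRNAGene]) -> pd.DataFrame:
    rows = [
        (g.gene_id, g.chrom, g.start, g.end, g.strand, g.amino_acid,
         g.anticodon, g.compartment, g.mature_sequence, g.confidence)
        for g in genes
    ]
    return pd.DataFrame(rows, columns=_GENE_COLUMNS)


def write_gene_table(genes: Iterable[TRNAGene], path) -> None:
    genes_to_frame(genes).to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> list[TRNAGene]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        TRNAGene(
            gene_id=r.gene_id, chrom=r.chrom, start=int(r.start), end=int(r.end),
            strand=r.strand, amino_acid=r.amino_acid, anticodon=r.anticodon,
            compartment=r.compartment, mature_sequence=r.sequence,
            confidence=r.confidence,
        )
        for r in df.itertuples()
    ]


def write_group_table(groups: Iterable[SequenceGroup], path) -> None:
    df = pd.DataFrame(
        [
            (g.group_id, g.sequence, g.anticodon, g.amino_acid,
             ",".join(sorted(g.member_gene_ids)))
            for g in groups
        ],
        columns=["group_id", "sequence", "anticodon", "amino_acid", "member_gene_ids"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_group_table(path) -> list[SequenceGroup]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        SequenceGroup(
            group_id=r.group_id, sequence=r.sequence, anticodon=r.anticodon,
            amino_acid=r.amino_acid,
            member_gene_ids=frozenset(r.member_gene_ids.split(",")),
        )
        for r in df.itertuples()
    ]
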