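"""Codon usage: frequencies, RSCU, RAC, wobble decoding and anticodon-codon
concordance.

RSCU (relative synonymous codon usage) is the observed count of a codon
divided by the count expected if all synonymous codons in its amino-acid
family were used uniformly; 1 means no bias and family RSCUs sum to the
family size.  RAC (relative adaptiveness of a codon) rescales frequencies so
the most-used codon of each family scores 1.

Codons are handled in the DNA alphabet, anticodons in RNA; the two meet only
at the reverse-complement pairing boundary.  The wobble position is the first
base of the 5'->3' anticodon (position 34), which pairs the third codon base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

log = logging.getLogger(__name__)


@dataclass
class CodonTable:
    """Standard genetic code: 61 sense codons over 20 amino-acid families."""

    forward: dict                           # DNA codon -> 3-letter amino acid
    stop_codons: frozenset
    families: dict = field(default_factory=dict)   # amino acid -> sorted codons

    @property
    def sense_codons(self) -> list:
        return sorted(self.forward)

    def family_of(self, codon: str) -> str:
        return self.forward[codon]


def build_codon_table() -> CodonTable:
    std = _BioCodonTable.unambiguous_dna_by_id[1]
    forward = {codon: seq3(aa) for codon, aa in std.forward_table.items()}
    families: dict[str, list] = {}
    for codon, aa in forward.items():
        families.setdefault(aa, []).append(codon)
    for aa in families:
        families[aa].sort()
    return CodonTable(
        forward=forward,
        stop_codons=frozenset(std.stop_codons),
        families=families,
    )


def expressed_gene_set(
    tpm: pd.DataFrame,
    meta: pd.DataFrame,
    min_tpm: float = 1.0,
    min_reps: int = 2,
) -> dict:
    """Per (tissue, treatment) sets of genes with TPM >= ``min_tpm`` in at
    least ``min_reps`` replicates (thresholds inclusive)."""
    out: dict = {}
    for (tissue, treatment), sub in meta.groupby(["tissue", "treatment"], sort=True):
        samples = list(sub.index)
        if len(samples) < min_reps:
            log.warning(
                "group (%s, %s) has %d < %d replicates; expressed set is empty",
                tissue, treatment, len(samples), min_reps,
            )
            out[(tissue, treatment)] = set()
            continue
        hits = (tpm[samples] >= min_tpm).sum(axis=1)
        out[(tissue, treatment)] = set(tpm.index[hits >= min_reps])
    return out


def codon_frequencies(
    cds_records: Iterable,
    table: CodonTable | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene codon counts from CDS sequences.

    ``cds_records`` yields ``(gene_id, sequence)`` pairs or Biopython
    SeqRecords.  The terminal stop codon is excluded; codons containing
    ambiguity codes are skipped individually; a length not divisible by 3
    skips the whole gene; internal stops are counted but reported in the QC
    dict (keys ``skipped`` and ``internal_stop``).
    """
    table = table or build_codon_table()
    codons = table.sense_codons + sorted(table.stop_codons)
    rows: dict[str, np.ndarray] = {}
    qc = {"skipped": [], "internal_stop": []}
    idx = {c: i for i, c in enumerate(codons)}
    for rec in cds_records:
        if hasattr(rec, "seq"):
            gene_id, seq = rec.id, str(rec.seq)
        else:
            gene_id, seq = rec
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3 != 0:
            qc["skipped"].append(gene_id)
            log.warning("skipping %s: CDS length %d not divisible by 3", gene_id, len(seq))
            continue
        triplets = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if triplets and triplets[-1] in table.stop_codons:
            triplets = triplets[:-1]
        counts = np.zeros(len(codons), dtype=int)
        internal_stop = False
        for t in triplets:
            i = idx.get(t)
            if i is None:          # ambiguity code somewhere in the triplet
                continue
            counts[i] += 1
            if t in table.stop_codons:
                internal_stop = True
        if internal_stop:
            qc["internal_stop"].append(gene_id)
        rows[gene_id] = counts
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=codons)
    if frame.empty:
        frame = pd.DataFrame(columns=codons, dtype=int)
    return frame, qc


def _family_blocks(columns, table: CodonTable):
    for aa, fam in sorted(table.families.items()):
        cols = [c for c in fam if c in columns]
        if cols:
            yield aa, cols


def rscu(counts, table: CodonTable | None = None):
    """RSCU per sense codon: count / (family total / family size).

    Accepts a per-gene DataFrame (genes x codons) or a single Series; families
    with zero total yield NaN.  Stop codons are dropped.
    """
    table = table or build_codon_table()
    series_in = isinstance(counts, pd.Series)
    df = counts.to_frame().T if series_in else counts
    out = pd.DataFrame(index=df.index, columns=table.sense_codons, dtype=float)
    for aa, cols in _family_blocks(df.columns, table):
        block = df[cols].astype(float)
        total = block.sum(axis=1)
        expected = total / len(cols)
        vals = block.div(expected, axis=0)
        vals[expected == 0] = np.nan
        out.loc[:, cols] = vals
    return out.iloc[0] if series_in else out


def rac(counts, table: CodonTable | None = None):
    """Relative adaptiveness: count / max count within the synonymous family."""
    table = table or build_codon_table()
    series_in = isinstance(counts, pd.Series)
    df = counts.to_frame().T if series_in else counts
    out = pd.DataFrame(index=df.index, columns=table.sense_codons, dtype=float)
    for aa, cols in _family_blocks(df.columns, table):
        block = df[cols].astype(float)
        top = block.max(axis=1)
        vals = block.div(top, axis=0)
        vals[top == 0] = np.nan
        out.loc[:, cols] = vals
    return out.iloc[0] if series_in else out


def average_per_gene(per_gene: pd.DataFrame) -> pd.Series:
    """Unweighted mean of per-gene RSCU/RAC values; genes where a family is
    absent (NaN) are excluded from that family's average, not counted as 0."""
    if per_gene.empty:
        return pd.Series(dtype=float, index=per_gene.columns)
    return per_gene.mean(axis=0, skipna=True)


_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def anticodon_to_codon(anticodon: str) -> str:
    """Watson-Crick codon (DNA) read by an anticodon (RNA, 5'->3')."""
    ac = anticodon.upper().replace("T", "U")
    if len(ac) != 3 or any(b not in "ACGU" for b in ac):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    return ac.translate(_RNA_COMPLEMENT)[::-1].replace("U", "T")


def codon_to_anticodon(codon: str) -> str:
    """Inverse of :func:`anticodon_to_codon` (RNA anticodon for a DNA codon)."""
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in "ACGT" for b in c):
        raise ValueError(f"invalid codon {codon!r}")
    return str(Seq(c).reverse_complement()).replace("T", "U")


# Wobble rules at anticodon position 34 (first base 5'->3') against codon
# position 3: G34 reads C/U, U34 reads A/G, C34 reads G only, A34 reads U --
# or U/C/A when A34 is assumed deaminated to inosine.
_WOBBLE_34 = {"G": "CT", "U": "AG", "C": "G", "A": "T"}
_INOSINE_34 = "TCA"


def wobble_decodes(anticodon: str, inosine_at_A34: bool = True) -> set:
    """Set of DNA codons decodable by an anticodon under wobble pairing."""
    ac = anticodon.upper().replace("T", "U")
    if len(ac) != 3 or any(b not in "ACGU" for b in ac):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    wc = anticodon_to_codon(ac)
    third = _INOSINE_34 if (ac[0] == "A" and inosine_at_A34) else _WOBBLE_34[ac[0]]
    return {wc[:2] + b for b in third}


def preferred_codons(profile: pd.Series, table: CodonTable | None = None) -> dict:
    """Per-family codon with the highest frequency (lexicographic tie-break).

    ``profile`` holds per-codon counts or frequencies; zero families are
    omitted.
    """
    table = table or build_codon_table()
    out = {}
    for aa, cols in _family_blocks(profile.index, table):
        vals = profile[cols].astype(float)
        if vals.fillna(0).sum() <= 0:
            continue
        out[aa] = vals.fillna(0).idxmax()   # idxmax takes the first = lexicographic
    return out


@dataclass
class ConcordanceReport:
    table: pd.DataFrame          # family, top_anticodon, top_codon, wc_codon, concordant
    excluded_families: list      # families with no expressed anticodon

    @property
    def n_concordant(self) -> int:
        return int(self.table["concordant"].sum())

    @property
    def n_families(self) -> int:
        return len(self.table)


def concordance(
    anticodon_expression: Mapping[str, float] | pd.Series,
    profile: pd.Series,
    table: CodonTable | None = None,
) -> ConcordanceReport:
    """Does the top-expressed anticodon of each family Watson-Crick pair the
    family's most frequent codon?

    ``anticodon_expression`` is keyed 'AA-Anticodon' (RNA anticodon);
    ``profile`` holds per-codon usage for the matching tissue/treatment group.
    Families with no expressed anticodon are excluded from the denominator
    and listed separately.
    """
    table = table or build_codon_table()
    expr = pd.Series(dict(anticodon_expression), dtype=float)
    top_codon = preferred_codons(profile, table)

    rows, excluded = [], []
    for aa in sorted(table.families):
        fam_keys = [k for k in expr.index if k.rsplit("-", 1)[0] == aa]
        fam_expr = expr[fam_keys]
        fam_expr = fam_expr[fam_expr > 0]
        if fam_expr.empty or aa not in top_codon:
            excluded.append(aa)
            continue
        top_ac = sorted(fam_expr.index[fam_expr == fam_expr.max()])[0].rsplit("-", 1)[1]
        wc = anticodon_to_codon(top_ac)
        rows.append((aa, top_ac, top_codon[aa], wc, wc == top_codon[aa]))
    frame = pd.DataFrame(
        rows, columns=["family", "top_anticodon", "top_codon", "wc_codon", "concordant"]
    )
    return ConcordanceReport(table=frame, excluded_families=excluded)
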