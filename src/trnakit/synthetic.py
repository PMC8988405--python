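"""Seeded synthetic-data generators with recorded ground truth.

Every generator is a pure function of its parameters and seed, and returns a
:class:`SimulationTruth` alongside the data so each pipeline stage can be
checked against what was actually planted: the gene-to-group map, per-group
expected rates, silenced groups, spiked fold changes, the imposed
copy-number/expression relation, CDS codon-draw tallies, and DMR placement
distances.

The default count design mirrors a two-tissue (muscle, liver), three-
treatment study with 13 animals per tissue (5 control, 4 + 4 treated) —
small-n bulk tRNA-seq with log-uniform library sizes and negative-binomial
counts.  What it deliberately does not emulate: reverse-transcription stalls
at modified bases, adapter artefacts, or alignment ambiguity beyond exact
sequence identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from trnakit.annotation import (
    SequenceGroup,
    TRNAGene,
    collapse_identical_sequences,
    sense_anticodon_universe,
)
from trnakit.quantify import CountMatrix

# YAMAT-seq adapter constants, used only to decorate synthetic reads.
ADAPTER_3P = "GTATCCAGTTGGAATTCTCGGGTGCCAAGG"
ADAPTER_5P = "GTTCAGAGTTCTACAGTCCGACGATCACTGGATACTGGN"

_AA_BY_ANTICODON = None


def _amino_acid_of(anticodon: str) -> str:
    global _AA_BY_ANTICODON
    if _AA_BY_ANTICODON is None:
        from trnakit.codonusage import anticodon_to_codon, build_codon_table

        table = build_codon_table()
        _AA_BY_ANTICODON = {
            ac: table.forward[anticodon_to_codon(ac)]
            for ac in sense_anticodon_universe()
        }
    return _AA_BY_ANTICODON[anticodon]


@dataclass
class SimulationTruth:
    """Everything the generators planted, serializable to JSON."""

    seed: int
    gene_to_group: dict = field(default_factory=dict)
    group_rates: dict = field(default_factory=dict)       # group -> {sample: rate}
    silenced_groups: list = field(default_factory=list)
    spiked_groups: dict = field(default_factory=dict)     # group -> {treatment, fold}
    copy_relation: str = "independent"
    cds_bias: dict = field(default_factory=dict)
    cds_codon_tallies: dict = field(default_factory=dict)
    dmr_distances: dict = field(default_factory=dict)     # dmr name -> (gene_id, distance)
    read_tallies: dict = field(default_factory=dict)      # group -> reads drawn

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SimulationTruth":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    data = json.load(fh)
        return cls(**data)


@dataclass
class SyntheticAnnotation:
    genes: list
    gff_text: str
    genome: dict                  # contig -> DNA sequence
    truth: SimulationTruth

    @property
    def groups(self) -> list:
        return collapse_identical_sequences(self.genes)

    def genome_fasta(self) -> str:
        return "".join(f">{c}\n{s}\n" for c, s in self.genome.items())


def _random_body(rng: np.random.Generator, anticodon: str, length: int) -> str:
    """Random tRNA-like RNA body carrying the anticodon at positions 34-36."""
    bases = np.array(list("ACGU"))
    seq = rng.choice(bases, size=length)
    seq[33:36] = list(anticodon)
    return "".join(seq)


def make_annotation(
    n_anticodons: int = 20,
    copies_per_anticodon: tuple = (2, 8),
    dup_fraction: float = 0.3,
    seed: int = 0,
    mito_contig: str = "MT",
    intron_fraction: float = 0.0,
    minus_strand_fraction: float = 0.4,
) -> SyntheticAnnotation:
    """Generate a multicopy tRNA annotation with controlled duplication.

    For each of ``n_anticodons`` anticodons (drawn deterministically from the
    sense universe) the copy count is uniform over ``copies_per_anticodon``
    inclusive; ``round(dup_fraction * (copies - 1))`` of the extra copies are
    exact duplicates of the first copy's 72-90 nt sequence, the rest are
    distinct.  The truth records the intended gene-to-group partition.
    """
    if not 0 <= dup_fraction <= 1:
        raise ValueError("dup_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = sense_anticodon_universe()
    if n_anticodons > len(universe):
        raise ValueError(f"at most {len(universe)} anticodons available")
    anticodons = list(rng.choice(universe, size=n_anticodons, replace=False))

    truth = SimulationTruth(seed=seed)
    genes: list[TRNAGene] = []
    gff_lines = ["##gff-version 3"]
    chrom = "chr1"
    cursor = 1000
    genome_parts: list[str] = []
    genome_len = 0
    seen_sequences: set = set()

    def reverse_complement_dna(s: str) -> str:
        return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]

    for anticodon in anticodons:
        aa = _amino_acid_of(anticodon)
        copies = int(rng.integers(copies_per_anticodon[0], copies_per_anticodon[1] + 1))
        n_dup = int(round(dup_fraction * (copies - 1)))
        sequences = []
        base = None
        for i in range(copies):
            if i > 0 and i <= n_dup and base is not None:
                sequences.append(base)
                continue
            while True:
                length = int(rng.integers(72, 91))
                s = _random_body(rng, anticodon, length)
                if s not in seen_sequences:
                    seen_sequences.add(s)
                    break
            if i == 0:
                base = s
            sequences.append(s)

        ac_dna = anticodon.replace("U", "T")
        for i, seq in enumerate(sequences, start=1):
            gene_id = f"tRNA-{aa}-{ac_dna}-{anticodons.index(anticodon) + 1}-{i}"
            dna = seq.replace("U", "T")
            strand = "-" if rng.random() < minus_strand_fraction else "+"
            has_intron = rng.random() < intron_fraction
            intron = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 25)))) \
                if has_intron else ""
            # split the body after base 37 when an intron is inserted
            genomic = dna[:37] + intron + dna[37:] if has_intron else dna
            plus_slice = reverse_complement_dna(genomic) if strand == "-" else genomic

            start = cursor
            end = cursor + len(plus_slice) - 1
            pad = int(rng.integers(200, 600))
            genome_parts.append("".join(rng.choice(list("ACGT"), size=start - 1 - genome_len)))
            genome_parts.append(plus_slice)
            genome_len = end
            cursor = end + pad

            attrs = f"ID={gene_id};Name={gene_id}"
            gff_lines.append(
                f"{chrom}\ttrnascan-se\ttRNA\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"
            )
            if has_intron:
                if strand == "+":
                    e1 = (start, start + 36)
                    e2 = (start + 37 + len(intron), end)
                else:
                    e2 = (start, start + len(dna) - 37 - 1)
                    e1 = (end - 36, end)
                for j, (es, ee) in enumerate(sorted([e1, e2]), start=1):
                    gff_lines.append(
                        f"{chrom}\ttrnascan-se\texon\t{es}\t{ee}\t.\t{strand}\t.\t"
                        f"ID={gene_id}.exon{j};Parent={gene_id}"
                    )
            genes.append(
                TRNAGene(
                    gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand,
                    amino_acid=aa, anticodon=anticodon, compartment="nuclear",
                    mature_sequence=seq, confidence="high",
                )
            )

    genome_parts.append("".join(rng.choice(list("ACGT"), size=500)))
    genome = {chrom: "".join(genome_parts)}

    for group in collapse_identical_sequences(genes):
        for gid in group.member_gene_ids:
            truth.gene_to_group[gid] = group.group_id
    return SyntheticAnnotation(
        genes=genes, gff_text="\n".join(gff_lines) + "\n", genome=genome, truth=truth
    )


DEFAULT_TREATMENTS = {"Control-AI": 5, "ART-Normal": 4, "ART-LOS": 4}


def make_design(
    tissues: Sequence[str] = ("muscle", "liver"),
    treatments: Mapping[str, int] = None,
) -> pd.DataFrame:
    """Sample sheet for a tissues x treatments design; individuals are shared
    across tissues (the same animals sampled in both)."""
    treatments = dict(treatments or DEFAULT_TREATMENTS)
    rows = []
    for tissue in tissues:
        for treatment, n in treatments.items():
            for rep in range(1, n + 1):
                individual = f"{treatment}-{rep}"
                rows.append((f"{tissue}.{treatment}.{rep}", tissue, treatment, individual))
    return pd.DataFrame(
        rows, columns=["sample_id", "tissue", "treatment", "individual"]
    ).set_index("sample_id")


def make_counts(
    groups: Iterable[SequenceGroup],
    meta: pd.DataFrame | None = None,
    lib_size_range: tuple = (0.5e6, 2.0e6),
    phi: float = 0.1,
    spike_spec: Mapping[str, tuple] | None = None,
    silence_spec: Iterable[str] | None = None,
    copy_relation: str = "independent",
    base_rate_sigma: float = 1.0,
    proportional_noise_sigma: float = 0.1,
    seed: int = 0,
    truth: SimulationTruth | None = None,
) -> tuple[CountMatrix, pd.DataFrame, SimulationTruth]:
    """NB-distributed gene-level counts over a study design.

    Per-gene base rates follow the imposed copy-number relation:
    ``proportional`` gives every locus the same base rate (so a group's total
    scales with its copy number), ``independent`` draws a group-level rate
    unrelated to copy number and splits it across loci.  Spikes multiply a
    group's rate by ``fold`` in one treatment (both tissues); silenced groups
    have rate 0 everywhere.  Library sizes are log-uniform over
    ``lib_size_range``; counts are NB with variance mu + phi * mu^2
    (Poisson when phi = 0).
    """
    if copy_relation not in ("proportional", "independent"):
        raise ValueError(f"unknown copy_relation {copy_relation!r}")
    rng = np.random.default_rng(seed)
    group_list = list(groups)
    meta = make_design() if meta is None else meta
    spike_spec = dict(spike_spec or {})
    silenced = set(silence_spec or [])
    truth = truth or SimulationTruth(seed=seed)
    truth.copy_relation = copy_relation
    truth.silenced_groups = sorted(silenced)
    truth.spiked_groups = {
        g: {"treatment": t, "fold": f} for g, (t, f) in spike_spec.items()
    }

    gene_rates: dict[str, float] = {}
    for g in group_list:
        if g.group_id in silenced:
            for gid in g.member_gene_ids:
                gene_rates[gid] = 0.0
            continue
        if copy_relation == "proportional":
            for gid in sorted(g.member_gene_ids):
                gene_rates[gid] = float(
                    np.exp(rng.normal(0.0, proportional_noise_sigma))
                )
        else:
            group_rate = float(np.exp(rng.normal(0.0, base_rate_sigma)))
            for gid in sorted(g.member_gene_ids):
                gene_rates[gid] = group_rate / g.size

    gene_ids = sorted(gene_rates)
    base = np.array([gene_rates[g] for g in gene_ids])
    gene_group = {gid: g.group_id for g in group_list for gid in g.member_gene_ids}

    values = {}
    for sid, row in meta.iterrows():
        rates = base.copy()
        for gid_idx, gid in enumerate(gene_ids):
            spike = spike_spec.get(gene_group[gid])
            if spike and row["treatment"] == spike[0]:
                rates[gid_idx] *= spike[1]
        lib = float(np.exp(rng.uniform(np.log(lib_size_range[0]),
                                       np.log(lib_size_range[1]))))
        total = rates.sum()
        mu = rates / total * lib if total > 0 else np.zeros_like(rates)
        if phi <= 0:
            draws = rng.poisson(mu)
        else:
            r = 1.0 / phi
            draws = np.where(
                mu > 0, rng.negative_binomial(r, r / (r + np.where(mu > 0, mu, 1.0))), 0
            )
        values[sid] = draws
        truth.group_rates.setdefault(sid, {})
        for gid, m in zip(gene_ids, mu):
            key = gene_group[gid]
            truth.group_rates[sid][key] = truth.group_rates[sid].get(key, 0.0) + float(m)

    matrix = CountMatrix(
        values=pd.DataFrame(values, index=gene_ids)[list(meta.index)], scale="raw"
    )
    return matrix, meta, truth


def make_reads(
    groups: Sequence[SequenceGroup],
    weights: Sequence[float],
    n_reads: int = 1000,
    add_cca: bool = True,
    seed: int = 0,
) -> tuple[list, dict]:
    """Sample reads from group sequences with the given weights; returns the
    reads and the generator's own per-group draw tally."""
    rng = np.random.default_rng(seed)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    picks = rng.choice(len(groups), size=n_reads, p=w)
    tally = {g.group_id: 0 for g in groups}
    reads = []
    for i in picks:
        g = groups[int(i)]
        tally[g.group_id] += 1
        reads.append(g.sequence + ("CCA" if add_cca else ""))
    return reads, tally


def make_cds(
    n_genes: int = 100,
    family_bias: Mapping[str, Mapping[str, float]] | None = None,
    length_range: tuple = (300, 900),
    seed: int = 0,
    n_samples_per_group: int = 3,
    meta: pd.DataFrame | None = None,
) -> tuple[list, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """CDS sequences with controllable codon bias plus a TPM matrix.

    Each CDS is ATG + weighted sense-codon draws + TAA, with length divisible
    by 3 inside ``length_range``.  ``family_bias`` maps amino-acid family ->
    {codon: weight}; unlisted families draw uniformly.  The TPM matrix marks
    every gene expressed (TPM 10) in every sample of a minimal design unless
    ``meta`` is supplied.  Returns (records, tpm, meta, truth) where truth
    carries the per-codon draw tallies.
    """
    from trnakit.codonusage import build_codon_table

    rng = np.random.default_rng(seed)
    table = build_codon_table()
    bias = {aa: dict(w) for aa, w in (family_bias or {}).items()}
    truth = SimulationTruth(seed=seed)
    truth.cds_bias = {aa: dict(w) for aa, w in bias.items()}

    aa_list = sorted(table.families)
    tallies: dict[str, int] = {}
    records = []
    for i in range(1, n_genes + 1):
        n_codons = int(rng.integers(length_range[0] // 3, length_range[1] // 3 + 1)) - 2
        body = []
        for _ in range(n_codons):
            aa = aa_list[int(rng.integers(len(aa_list)))]
            fam = table.families[aa]
            w = np.array([bias.get(aa, {}).get(c, 1.0) for c in fam], dtype=float)
            if w.sum() <= 0:
                raise ValueError(f"family {aa}: all weights zero")
            codon = fam[int(rng.choice(len(fam), p=w / w.sum()))]
            body.append(codon)
            tallies[codon] = tallies.get(codon, 0) + 1
        gene_id = f"cds{i:04d}"
        records.append((gene_id, "ATG" + "".join(body) + "TAA"))
        tallies["ATG"] = tallies.get("ATG", 0) + 1
    truth.cds_codon_tallies = tallies

    if meta is None:
        rows = []
        for treatment in DEFAULT_TREATMENTS:
            for rep in range(1, n_samples_per_group + 1):
                rows.append((f"rna.{treatment}.{rep}", "muscle", treatment,
                             f"{treatment}-{rep}"))
        meta = pd.DataFrame(
            rows, columns=["sample_id", "tissue", "treatment", "individual"]
        ).set_index("sample_id")
    tpm = pd.DataFrame(
        10.0, index=[r[0] for r in records], columns=list(meta.index)
    )
    return records, tpm, meta, truth


def make_correlated_usage_expression(
    r0: float,
    n_pairs: int = 50,
    seed: int = 0,
    mean: float = 20.0,
    sd: float = 5.0,
) -> tuple[pd.Series, pd.Series]:
    """Paired codon-usage and anticodon-expression scores with an imposed
    population correlation ``r0``.

    Returns (usage keyed by DNA codon, expression keyed by 'AA-Anticodon')
    over ``n_pairs`` anticodons drawn from the sense universe, linked by
    Watson-Crick pairing.  Values are positive percentage-scale scores built
    by a linear Gaussian construction, so the sample correlation fluctuates
    around ``r0`` with the usual sqrt(1/n) error.
    """
    if not -1 <= r0 <= 1:
        raise ValueError("r0 must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    universe = sense_anticodon_universe()
    anticodons = list(rng.choice(universe, size=n_pairs, replace=False))
    z = rng.standard_normal(n_pairs)
    e = rng.standard_normal(n_pairs)
    x = mean + sd * z
    y = mean + sd * (r0 * z + np.sqrt(1 - r0**2) * e)
    x = np.clip(x, 0.1, None)
    y = np.clip(y, 0.1, None)

    from trnakit.codonusage import anticodon_to_codon

    usage = pd.Series(x, index=[anticodon_to_codon(a) for a in anticodons])
    expr = pd.Series(y, index=[f"{_amino_acid_of(a)}-{a}" for a in anticodons])
    return usage, expr


def make_dmrs(
    genes: Sequence[TRNAGene],
    planted_distances: Sequence[int],
    seed: int = 0,
    max_retries: int = 100,
) -> tuple[list, SimulationTruth]:
    """Place one DMR at exactly each requested distance from a randomly
    chosen gene (0 means overlapping the gene body).

    The truth guarantees the distance between each DMR and its planted gene;
    other genes may also fall within a query window.  Placements that land on
    top of a different gene (which would blur the planted relation) are
    re-drawn; persistent failure raises.  Returns (intervals, truth).
    """
    from trnakit.dmr import GenomicInterval, interval_distance

    rng = np.random.default_rng(seed)
    gene_list = list(genes)
    intervals = []
    truth = SimulationTruth(seed=seed)
    for i, d in enumerate(planted_distances, start=1):
        if d < 0:
            raise ValueError("planted distances must be >= 0")
        for _ in range(max_retries):
            g = gene_list[int(rng.integers(len(gene_list)))]
            width = int(rng.integers(100, 400))
            if d == 0:
                start = g.start + max(0, (g.end - g.start) // 2 - width // 2)
                end = start + width - 1
            else:
                start = g.end + d
                end = start + width - 1
            ok = all(
                interval_distance(o.start, o.end, start, end) > 0
                for o in gene_list
                if o.chrom == g.chrom and o.gene_id != g.gene_id
            )
            if ok:
                name = f"dmr{i}"
                direction = "gain" if rng.random() < 0.5 else "loss"
                intervals.append(GenomicInterval(
                    chrom=g.chrom, start=start, end=end, name=name, direction=direction
                ))
                truth.dmr_distances[name] = (g.gene_id, int(d))
                break
        else:
            raise RuntimeError(f"could not place DMR at distance {d} after retries")
    return intervals, truth
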