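import numpy as np
import pandas as pd
import pytest

from trnakit.annotation import SequenceGroup, TRNAGene
from trnakit.synthetic import make_annotation, make_counts, make_design


def build_gene(
    gene_id,
    sequence,
    anticodon="GCC",
    amino_acid="Gly",
    chrom="chr1",
    start=1000,
    strand="+",
    compartment="nuclear",
    confidence="high",
):
    return TRNAGene(
        gene_id=gene_id,
        chrom=chrom,
        start=start,
        end=start + len(sequence) - 1,
        strand=strand,
        amino_acid=amino_acid,
        anticodon=anticodon,
        compartment=compartment,
        mature_sequence=sequence,
        confidence=confidence,
    )


def random_rna(rng, length=76):
    return "".join(rng.choice(list("ACGU"), size=length))


@pytest.fixture(scope="session")
def toy_groups():
    rng = np.random.default_rng(7)
    seqs = [random_rna(rng) for _ in range(3)]
    return [
        SequenceGroup(
            group_id=f"G{i}",
            sequence=s,
            member_gene_ids=frozenset({f"g{i}"}),
            anticodon="GCC",
            amino_acid="Gly",
        )
        for i, s in enumerate(seqs)
    ]


@pytest.fixture(scope="session")
def synthetic_study():
    """Small annotated study: genes, groups, gene-level counts, sample sheet."""
    anno = make_annotation(n_anticodons=12, copies_per_anticodon=(2, 6),
                           dup_fraction=0.4, seed=42)
    groups = anno.groups
    matrix, meta, truth = make_counts(groups, phi=0.1, seed=43, truth=anno.truth)
    return anno, groups, matrix, meta, truth


@pytest.fixture
def role_map():
    return {"Control-AI": "control", "ART-Normal": "normal", "ART-LOS": "los"}


@pytest.fixture
def small_meta():
    return make_design(tissues=("muscle",), treatments={"Control-AI": 3, "ART-LOS": 3})
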