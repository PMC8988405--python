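"""Count ingestion, CPM, expression filtering, aggregation, read assignment."""

import numpy as np
import pandas as pd
import pytest

from trnakit.quantify import (
    CountMatrix,
    aggregate,
    assign_reads,
    cpm,
    filter_expressed,
    gene_flags_from_groups,
    isodecoder_expressed_proportion,
    log2cpm,
    read_counts,
)
from trnakit.synthetic import make_counts, make_design, make_reads
from conftest import build_gene


def _write_counts(tmp_path, frame, meta_frame):
    cpath, spath = tmp_path / "c.tsv", tmp_path / "s.tsv"
    frame.to_csv(cpath, sep="\t")
    meta_frame.to_csv(spath, sep="\t")
    return cpath, spath


def _toy_meta(samples, tissue="muscle"):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "tissue": tissue,
            "treatment": "Control-AI",
            "individual": [f"ind{i}" for i in range(len(samples))],
        }
    ).set_index("sample_id")


class TestReadCounts:
    def test_toy_values_round_trip(self, tmp_path):
        frame = pd.DataFrame({"s1": [1, 2], "s2": [3, 4]}, index=["f1", "f2"])
        cpath, spath = _write_counts(tmp_path, frame, _toy_meta(["s1", "s2"]))
        matrix, meta = read_counts(cpath, spath)
        assert matrix.scale == "raw"
        pd.testing.assert_frame_equal(matrix.values, frame)

    def test_sample_order_taken_from_sheet(self, tmp_path):
        frame = pd.DataFrame({"s2": [3, 4], "s1": [1, 2]}, index=["f1", "f2"])
        cpath, spath = _write_counts(tmp_path, frame, _toy_meta(["s1", "s2"]))
        matrix, _ = read_counts(cpath, spath)
        assert matrix.samples == ["s1", "s2"]
        assert matrix.values.loc["f1", "s1"] == 1

    def test_sheet_sample_missing_from_matrix_is_error(self, tmp_path):
        frame = pd.DataFrame({"s1": [1]}, index=["f1"])
        cpath, spath = _write_counts(tmp_path, frame, _toy_meta(["s1", "S9"]))
        with pytest.raises(ValueError, match="S9"):
            read_counts(cpath, spath)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            CountMatrix(values=pd.DataFrame({"s": [-1]}), scale="raw")


class TestCpm:
    def test_single_feature_full_library(self):
        m = CountMatrix(values=pd.DataFrame({"s": [10]}, index=["f"]), scale="raw")
        assert cpm(m).values.loc["f", "s"] == 1_000_000

    def test_hand_arithmetic(self):
        m = CountMatrix(values=pd.DataFrame({"s": [1, 3]}, index=["a", "b"]))
        out = cpm(m).values["s"]
        assert out.tolist() == [250_000.0, 750_000.0]

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.poisson(50, size=(40, 6)),
                            columns=[f"s{i}" for i in range(6)])
        out = cpm(CountMatrix(values=vals)).values
        assert np.allclose(out.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_library_column_becomes_zero(self):
        m = CountMatrix(values=pd.DataFrame({"s1": [5], "s2": [0]}, index=["f"]))
        out = cpm(m).values
        assert out.loc["f", "s2"] == 0.0

    def test_log2cpm_preserves_zero(self):
        m = CountMatrix(values=pd.DataFrame({"s": [0, 10]}, index=["a", "b"]))
        assert log2cpm(m).values.loc["a", "s"] == 0.0


class TestFilterExpressed:
    def test_two_nonzero_individuals_is_expressed(self):
        counts = np.zeros((1, 13), dtype=int)
        counts[0, 0], counts[0, 12] = 3, 2
        samples = [f"m{i}" for i in range(13)]
        m = CountMatrix(values=pd.DataFrame(counts, index=["f"], columns=samples))
        flags = filter_expressed(m, _toy_meta(samples))
        assert bool(flags.loc["f", "muscle"])

    def test_single_nonzero_individual_is_not_expressed(self):
        samples = [f"m{i}" for i in range(13)]
        counts = np.zeros((1, 13), dtype=int)
        counts[0, 4] = 100
        m = CountMatrix(values=pd.DataFrame(counts, index=["f"], columns=samples))
        assert not filter_expressed(m, _toy_meta(samples)).loc["f", "muscle"]

    def test_technical_replicates_of_one_individual_do_not_count_twice(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "tissue": "muscle",
                "treatment": "Control-AI",
                "individual": ["A", "A", "B"],       # s1, s2 are the same animal
            }
        ).set_index("sample_id")
        m = CountMatrix(values=pd.DataFrame({"s1": [5], "s2": [9], "s3": [0]},
                                            index=["f"]))
        assert not filter_expressed(m, meta).loc["f", "muscle"]

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(1)
        meta = make_design()
        for _ in range(20):
            counts = rng.poisson(0.5, size=(20, len(meta)))
            m = CountMatrix(values=pd.DataFrame(
                counts, index=[f"f{i}" for i in range(20)], columns=meta.index))
            flags = filter_expressed(m, meta)
            for tissue in meta["tissue"].unique():
                sub = meta[meta["tissue"] == tissue]
                for f in m.features:
                    inds = {
                        sub.loc[s, "individual"]
                        for s in sub.index
                        if m.values.loc[f, s] > 0
                    }
                    assert flags.loc[f, tissue] == (len(inds) >= 2)

    def test_monotone_in_counts(self):
        rng = np.random.default_rng(2)
        meta = make_design(tissues=("muscle",))
        counts = rng.poisson(0.3, size=(30, len(meta)))
        m1 = CountMatrix(values=pd.DataFrame(
            counts, index=[f"f{i}" for i in range(30)], columns=meta.index))
        m2 = CountMatrix(values=m1.values + rng.poisson(0.3, size=counts.shape))
        f1 = filter_expressed(m1, meta)
        f2 = filter_expressed(m2, meta)
        assert (f2 | ~f1).all().all()          # expressed never flips off


class TestAggregate:
    def test_identity_mapping_is_noop(self):
        m = CountMatrix(values=pd.DataFrame({"s": [1, 2]}, index=["a", "b"]))
        out = aggregate(m, {"a": "a", "b": "b"})
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_manual_sum(self):
        m = CountMatrix(values=pd.DataFrame({"s": [1, 2, 3, 4]},
                                            index=["g1", "g2", "g3", "g4"]))
        out = aggregate(m, {"g1": "K1", "g2": "K1", "g3": "K2", "g4": "K2"})
        assert out.values["s"].to_dict() == {"K1": 3, "K2": 7}

    def test_column_sums_conserved(self):
        rng = np.random.default_rng(3)
        m = CountMatrix(values=pd.DataFrame(
            rng.poisson(10, size=(12, 4)), index=[f"g{i}" for i in range(12)],
            columns=list("wxyz")))
        mapping = {f"g{i}": f"k{i % 3}" for i in range(12)}
        out = aggregate(m, mapping)
        assert (out.values.sum(axis=0) == m.values.sum(axis=0)).all()

    def test_unmapped_feature_is_hard_error(self):
        m = CountMatrix(values=pd.DataFrame({"s": [1, 2]}, index=["a", "b"]))
        with pytest.raises(ValueError, match="b"):
            aggregate(m, {"a": "k"})


class TestAssignReads:
    def test_cca_suffix_is_stripped_before_matching(self, toy_groups):
        g = toy_groups[0]
        matrix, unassigned = assign_reads([g.sequence + "CCA"], toy_groups)
        assert matrix.values.loc[g.group_id].iloc[0] == 1 and unassigned == 0

    def test_short_reads_unassigned_regardless_of_match(self, toy_groups):
        g = toy_groups[0]
        matrix, unassigned = assign_reads([g.sequence], toy_groups, min_len=200)
        assert matrix.values.to_numpy().sum() == 0 and unassigned == 1

    def test_counts_equal_generator_tally(self, toy_groups):
        reads, tally = make_reads(toy_groups, weights=[0.5, 0.3, 0.2],
                                  n_reads=1000, seed=5)
        matrix, unassigned = assign_reads(reads, toy_groups)
        assert unassigned == 0
        for g in toy_groups:
            assert matrix.values.loc[g.group_id].iloc[0] == tally[g.group_id]

    def test_assigned_plus_unassigned_equals_input(self, toy_groups):
        reads, _ = make_reads(toy_groups, [1, 1, 1], n_reads=200, seed=6)
        reads += ["ACGU" * 20]                     # matches nothing
        matrix, unassigned = assign_reads(reads, toy_groups)
        assert matrix.values.to_numpy().sum() + unassigned == len(reads)


class TestIsodecoderProportion:
    def test_ratio_arithmetic(self):
        genes = [build_gene(f"g{i}", "A" * (60 + i), "GCC", "Gly") for i in range(5)]
        flags = pd.DataFrame({"muscle": [True, True, True, True, False]},
                             index=[f"g{i}" for i in range(5)])
        out = isodecoder_expressed_proportion(flags, genes)
        row = out[(out.anticodon == "Gly-GCC") & (out.tissue == "muscle")].iloc[0]
        assert row.fraction == 0.8

    def test_all_unexpressed_gives_zero(self):
        genes = [build_gene("g0", "A" * 60, "GCC", "Gly")]
        flags = pd.DataFrame({"liver": [False]}, index=["g0"])
        out = isodecoder_expressed_proportion(flags, genes)
        assert out.iloc[0].fraction == 0.0

    def test_silenced_groups_match_generator_truth(self, synthetic_study):
        anno, groups, matrix, meta, _ = synthetic_study
        silenced = sorted(g.group_id for g in groups)[:3]
        matrix2, meta2, truth = make_counts(groups, phi=0.1,
                                            silence_spec=silenced, seed=9)
        g2g = {gid: g.group_id for g in groups for gid in g.member_gene_ids}
        gmx = aggregate(matrix2, g2g)
        group_flags = filter_expressed(gmx, meta2)
        gene_flags = gene_flags_from_groups(group_flags, groups)
        for g in groups:
            if g.group_id in silenced:
                assert not group_flags.loc[g.group_id].any()
                for gid in g.member_gene_ids:
                    assert not gene_flags.loc[gid].any()
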