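import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from csrscope.alignments import BreakRealignment, Insert, ReadAlignment, AlignmentBlock
from csrscope.annotation import SwitchAnnotation
from csrscope.cluster import ClusterSet
from csrscope.features import (BreakpointMatrix, build_breakpoint_matrix,
                               breakpoint_statistics, compute_cluster_stats,
                               context_scores, isotype_composition,
                               load_manifest, longest_common_substring,
                               summarize_sample)
from csrscope.msa import MSAMatrix


@pytest.fixture
def annot():
    # two regions at 50 nt-aligned offsets: SM [0,2000), SA1 [2000,3000)
    return SwitchAnnotation([("SM", "c", 100, 2100), ("SA1", "c", 3000, 4000)])


def _msa_rows(rows, n_bases=3000):
    mat = sp.csr_matrix(np.asarray(rows, dtype=np.int32))
    mat.resize((len(rows), n_bases))
    return MSAMatrix(mat, [f"r{i}" for i in range(len(rows))], n_bases)


def _cs(labels, n_clusters=None):
    labels = np.asarray(labels)
    k = n_clusters or labels.max() + 1
    return ClusterSet(labels, np.zeros(k, bool), 0.01, np.bincount(labels,
                                                                   minlength=k),
                      np.zeros(k))


def _dummy_reads(msa, isotype="SA1"):
    out = {}
    for rid in msa.read_ids:
        ra = ReadAlignment(rid, [AlignmentBlock(0, 10, "c", 100, 110, "+"),
                                 AlignmentBlock(10, 20, "c", 3000, 3010, "+")],
                           20)
        ra.isotype = isotype
        out[rid] = ra
    return out


class TestClusterStats:
    def test_identical_reads_consensus_and_spread(self, annot):
        row = np.zeros(3000, dtype=np.int32)
        row[0:500] = 10 + 1  # A over SM start
        row[2000:2400] = 10 + 3  # G over SA1
        msa = _msa_rows([row] * 10)
        cs = _cs([0] * 10)
        stats = compute_cluster_stats(msa, cs, _dummy_reads(msa),
                                      pd.DataFrame(), annot)
        assert len(stats) == 1
        s = stats.iloc[0]
        assert s["consensus_len"] == 900
        assert s["spread"] == 0
        assert s["gc"] == pytest.approx(400 / 900)  # G block over A block

    def test_half_extended_reads_spread(self, annot):
        short = np.zeros(3000, dtype=np.int32)
        short[0:400] = 11
        long = np.zeros(3000, dtype=np.int32)
        long[0:500] = 11
        msa = _msa_rows([short] * 5 + [long] * 5)
        cs = _cs([0] * 10)
        stats = compute_cluster_stats(msa, cs, _dummy_reads(msa),
                                      pd.DataFrame(), annot)
        assert stats.iloc[0]["spread"] == 100

    def test_isotype_most_frequent(self, annot):
        row = np.zeros(3000, dtype=np.int32)
        row[0:100] = 11
        msa = _msa_rows([row] * 3)
        reads = _dummy_reads(msa)
        for i, iso in enumerate(["SA1", "SA1", "SG1"]):
            reads[f"r{i}"].isotype = iso
        stats = compute_cluster_stats(msa, _cs([0, 0, 0]), reads,
                                      pd.DataFrame(), annot)
        assert stats.iloc[0]["isotype"] == "SA1"

    def test_junction_statistics_cluster_first(self, annot):
        row = np.zeros(3000, dtype=np.int32)
        row[0:100] = 11
        msa = _msa_rows([row] * 4)
        reads = _dummy_reads(msa)
        for i, h in enumerate([2, 2, 8, 0]):
            reads[f"r{i}"].realignments = [
                BreakRealignment(f"r{i}", 0, 50, 2100, h, 0)]
        stats = compute_cluster_stats(msa, _cs([0] * 4), reads,
                                      pd.DataFrame(), annot)
        s = stats.iloc[0]
        assert s["homology"] == pytest.approx(3.0)
        assert s["homology_1_3"] == pytest.approx(0.5)
        assert s["homology_gt6"] == pytest.approx(0.25)
        assert s["blunt_fraction"] == pytest.approx(0.25)


class TestBreakpointMatrix:
    def _gaps(self, entries):
        return pd.DataFrame(entries,
                            columns=["read_idx", "left", "right", "size"])

    def test_cluster_equal_weighting(self, annot):
        # clusters of 10 and 1000 reads, one identical break per read
        labels = [0] * 10 + [1] * 1000
        gaps = self._gaps([(i, 500, 2200, 1700) for i in range(1010)])
        bm = build_breakpoint_matrix(gaps, _cs(labels), pd.DataFrame(), annot)
        t = bm.table
        assert t.groupby("cluster")["weight"].sum().tolist() == \
            pytest.approx([1.0, 1.0])

    def test_hand_fixture_accumulation(self, annot):
        # 5 gaps in 3 clusters; spreadsheet-style expected weights
        labels = [0, 0, 1, 1, 2]
        gaps = self._gaps([(0, 100, 2100, 2000), (1, 100, 2100, 2000),
                           (2, 300, 2200, 1900), (3, 350, 2600, 2250),
                           (4, 900, 2900, 2000)])
        bm = build_breakpoint_matrix(gaps, _cs(labels), pd.DataFrame(), annot)
        # cluster sizes 2,2,1 -> weights 0.5,0.5,0.5,0.5,1.0
        expected = np.zeros((60, 60))
        expected[99 // 50, 2100 // 50] += 1.0  # two gaps at same bins
        expected[299 // 50, 2200 // 50] += 0.5
        expected[349 // 50, 2600 // 50] += 0.5
        expected[899 // 50, 2900 // 50] += 1.0
        assert np.allclose(bm.matrix, expected)
        # total matrix weight = sum over clusters (breaks / cluster size)
        assert bm.matrix.sum() == pytest.approx(2 / 2 + 2 / 2 + 1 / 1)

    def test_read_equal_weighting(self, annot):
        labels = [0] * 10 + [1] * 20
        gaps = self._gaps([(i, 500, 2200, 1700) for i in range(30)])
        bm = build_breakpoint_matrix(gaps, _cs(labels), pd.DataFrame(), annot,
                                     weighting="read-equal")
        assert bm.matrix.sum() == pytest.approx(30.0)

    def test_short_gaps_excluded(self, annot):
        gaps = self._gaps([(0, 500, 560, 60), (0, 700, 2500, 1800)])
        bm = build_breakpoint_matrix(gaps, _cs([0]), pd.DataFrame(), annot)
        assert len(bm.table) == 1


class TestBreakpointStatistics:
    def _bm(self, gaps, annot, labels=None, rearr=None):
        labels = labels if labels is not None else [0] * (max(g[0] for g in gaps) + 1)
        df = pd.DataFrame(gaps, columns=["read_idx", "left", "right", "size"])
        return build_breakpoint_matrix(df, _cs(labels),
                                       rearr if rearr is not None
                                       else pd.DataFrame(), annot)

    def test_all_direct_switch(self, annot):
        bm = self._bm([(0, 500, 2200, 1700), (1, 700, 2600, 1900)], annot)
        out = breakpoint_statistics(bm, annot, pd.DataFrame())
        assert out["pct_direct_switch"] == pytest.approx(100.0)
        assert out["pct_sequential_switch"] == pytest.approx(0.0)

    def test_half_direct_half_sequential(self):
        annot3 = SwitchAnnotation([("SM", "c", 0, 2000), ("SG1", "c", 3000, 4000),
                                   ("SA1", "c", 5000, 6000)])
        # constructed gap table (reduced coords: SM [0,2000), SG1 [2000,3000),
        # SA1 [3000,4000)): SM->SG1 and SG1->SA1
        gaps = [(0, 500, 2500, 2000), (1, 2500, 3500, 1000)]
        bm = self._bm(gaps, annot3, labels=[0, 0])
        out = breakpoint_statistics(bm, annot3, pd.DataFrame())
        assert out["pct_direct_switch"] == pytest.approx(50.0)
        assert out["pct_sequential_switch"] == pytest.approx(50.0)
        assert out["pct_breaks_SM_SG"] == pytest.approx(50.0)
        assert out["pct_breaks_SG_SA"] == pytest.approx(50.0)

    def test_zero_dispersion_single_position(self, annot):
        bm = self._bm([(0, 500, 2200, 1700), (1, 500, 2200, 1700)], annot,
                      labels=[0, 1])
        out = breakpoint_statistics(bm, annot, pd.DataFrame())
        assert out["break_dispersion_SA1"] == pytest.approx(0.0)

    def test_categories_sum_to_100(self, annot):
        rng = np.random.default_rng(0)
        gaps = [(i, int(rng.integers(100, 1900)),
                 int(rng.integers(2000, 2950)), 500) for i in range(50)]
        rearr = pd.DataFrame({"read_idx": [0, 1], "kind": ["inversion",
                                                           "duplication"],
                              "left": [gaps[0][2], gaps[1][2]],
                              "right": [2950, 2950], "size": [100, 100]})
        bm = self._bm(gaps, annot, labels=[0] * 50, rearr=rearr)
        out = breakpoint_statistics(bm, annot, pd.DataFrame())
        total = (out["pct_direct_switch"] + out["pct_sequential_switch"]
                 + out["pct_intraswitch_deletion"] + out["pct_inversions"]
                 + out["pct_duplications"])
        assert total == pytest.approx(100.0, abs=1e-9)
        assert out["pct_inversions"] > 0 and out["pct_duplications"] > 0


class TestContextScores:
    def test_no_shared_substring_zero_homology(self, annot):
        ref = "A" * 1000 + "C" * 1000 + "G" * 500 + "T" * 500
        gaps = pd.DataFrame([(0, 500, 2200, 1700)],
                            columns=["read_idx", "left", "right", "size"])
        bm = build_breakpoint_matrix(gaps, _cs([0]), pd.DataFrame(), annot)
        out = context_scores(bm, pd.DataFrame(), ref, annot)
        # donor bin is all A, acceptor bin all G: no common substring
        assert out["homology_score_fw"] == 0.0

    def test_planted_shared_8mer(self, annot):
        rng = np.random.default_rng(1)
        ref = list("".join(rng.choice(list("ACGT"), size=3000)))
        donor_pos, acc_pos = 499, 2200
        motif = "GGATCCTA"
        # plant the 8-mer in both the donor bin and the acceptor bin
        ref[460:468] = motif
        ref[2210:2218] = motif
        ref = "".join(ref)
        d_bin, a_bin = donor_pos // 50, acc_pos // 50
        gaps = pd.DataFrame([(0, donor_pos + 1, acc_pos, acc_pos - donor_pos - 1)],
                            columns=["read_idx", "left", "right", "size"])
        bm = build_breakpoint_matrix(gaps, _cs([0]), pd.DataFrame(), annot)
        out = context_scores(bm, pd.DataFrame(), ref, annot)
        # exhaustive bin-pair oracle: single occupied bin pair
        expected = longest_common_substring(ref[d_bin * 50:(d_bin + 1) * 50],
                                            ref[a_bin * 50:(a_bin + 1) * 50]) / 50
        assert expected >= 8 / 50
        assert out["homology_score_fw"] == pytest.approx(expected)

    def test_lcs_basics(self):
        assert longest_common_substring("AAAA", "CCCC") == 0
        assert longest_common_substring("ACGTACGT", "GGACGTGG") == 4
        assert longest_common_substring("", "ACGT") == 0


class TestIsotypeComposition:
    annot = SwitchAnnotation([("SM", "c", 0, 1000), ("SG1", "c", 2000, 3000),
                              ("SA1", "c", 4000, 5000)])

    def test_all_one_isotype(self):
        stats = pd.DataFrame({"isotype": ["SA1"] * 4})
        out = isotype_composition(stats, self.annot)
        assert out["pct_clusters_SA1"] == 100.0
        assert out["pct_clusters_SG1"] == 0.0

    def test_three_one_split(self):
        stats = pd.DataFrame({"isotype": ["SG1"] * 3 + ["SA1"]})
        out = isotype_composition(stats, self.annot)
        assert out["pct_clusters_SG1"] == 75.0
        assert out["pct_clusters_SA1"] == 25.0
        assert out["pct_clusters_SG"] == 75.0

    def test_invariant_to_cluster_sizes(self):
        # composition is cluster-level: duplicating reads in one cluster
        # does not change it (sizes never enter)
        a = isotype_composition(pd.DataFrame({"isotype": ["SG1", "SA1"],
                                              "size": [10, 10]}), self.annot)
        b = isotype_composition(pd.DataFrame({"isotype": ["SG1", "SA1"],
                                              "size": [1000, 10]}), self.annot)
        assert a == b


class TestManifest:
    def test_category_counts(self):
        m = load_manifest()
        counts = m["category"].value_counts().to_dict()
        assert len(m) == 68
        assert counts == {"structural": 5, "context": 17,
                          "breakpoint_matrix": 28, "diversity": 9,
                          "isotype": 9}
        assert m["feature"].is_unique


class TestSummarize:
    def test_full_vector_from_pipeline(self, noisy_result):
        result, _ = noisy_result
        vec = result.features
        manifest = load_manifest()
        assert list(vec.index) == list(manifest["feature"])
        assert len(vec) == 68

    def test_determinism(self, locus, primers):
        from csrscope import simulate_sample
        from csrscope.pipeline import run_sample
        vecs = []
        for _ in range(2):
            records, truth, _ = simulate_sample(locus, 8, 150,
                                                "nanopore-like", seed=33)
            res = run_sample(records, None, locus.genome, locus.annotation,
                             truth=truth, primers=primers, seed=33)
            vecs.append(res.features)
        pd.testing.assert_series_equal(vecs[0], vecs[1])

    def test_single_clone_closed_forms(self, locus, primers):
        from csrscope import simulate_sample
        from csrscope.pipeline import run_sample
        from csrscope.simulate import make_clone_table
        rng = np.random.default_rng(44)
        table = make_clone_table(locus, 1, rng)
        records, truth, _ = simulate_sample(locus, 1, 200, "nanopore-like",
                                            seed=44, clone_table=table)
        res = run_sample(records, None, locus.genome, locus.annotation,
                         truth=truth, primers=primers, seed=44)
        assert res.features["clusters"] == pytest.approx(1.0)
        assert res.features["occupancy_top_clone"] == pytest.approx(1.0)
        assert res.features["cluster_entropy"] == pytest.approx(0.0)
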