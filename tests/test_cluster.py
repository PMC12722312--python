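import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from csrscope.cluster import (ClusterSet, clean_coverage, cluster_curve,
                              cosine_distance_matrix, cut_dendrogram,
                              diversity_measures, downsample_diversity,
                              filter_clusters, find_cutoff, gini,
                              inverse_simpson, linkage_dense, linkage_sparse,
                              shannon_entropy)
from csrscope.config import ClusterConfig
from csrscope.msa import MSAMatrix


def _msa_from_rows(rows, n_bases):
    mats = sp.csr_matrix(np.asarray(rows, dtype=np.int32))
    return MSAMatrix(mats, [f"r{i}" for i in range(len(rows))], n_bases)


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------

class TestCleanCoverage:
    def _row_with_gaps(self, gap_sizes, n_bases=1000):
        row = np.zeros(n_bases, dtype=np.int32)
        pos = 0
        for g in gap_sizes:
            row[pos:pos + 50] = 11
            pos += 50 + g
        row[pos:pos + 50] = 11
        return row

    @pytest.mark.parametrize("gap,filled", [(74, True), (75, False)])
    def test_strict_cutoff_boundary(self, gap, filled):
        msa = _msa_from_rows([self._row_with_gaps([gap])], 1000)
        cleaned = clean_coverage(msa, 75)
        cols = cleaned[0].indices
        has_gap = np.any(np.diff(np.sort(cols)) > 1)
        assert has_gap != filled

    def test_no_gaps_unchanged(self):
        row = np.zeros(500, dtype=np.int32)
        row[100:400] = 11
        msa = _msa_from_rows([row], 500)
        cleaned = clean_coverage(msa, 75)
        assert (cleaned.toarray() != (msa.coverage()).toarray()).sum() == 0

    def test_mixed_gaps_run_length_oracle(self):
        # gaps of 10, 74, 76 nt -> exactly one gap remains (the 76 nt one)
        msa = _msa_from_rows([self._row_with_gaps([10, 74, 76])], 1000)
        cleaned = clean_coverage(msa, 75)
        cols = np.sort(cleaned[0].indices)
        jumps = np.diff(cols) - 1
        remaining = jumps[jumps > 0]
        assert list(remaining) == [76]


# ---------------------------------------------------------------------------
# UPGMA linkage
# ---------------------------------------------------------------------------

def naive_upgma(dist):
    """O(n^3) average-linkage oracle with lowest-index tie-breaking."""
    n = dist.shape[0]
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    heights = []
    next_id = n
    while len(active) > 1:
        best = min(d[tuple(sorted((a, b)))] for i, a in enumerate(active)
                   for b in active[i + 1:])
        pair = min((tuple(sorted((a, b))) for i, a in enumerate(active)
                    for b in active[i + 1:]
                    if d[tuple(sorted((a, b)))] == best))
        a, b = pair
        heights.append(best)
        new = next_id
        next_id += 1
        sizes[new] = sizes[a] + sizes[b]
        for c in active:
            if c in (a, b):
                continue
            da = d[tuple(sorted((a, c)))]
            db = d[tuple(sorted((b, c)))]
            d[tuple(sorted((new, c)))] = \
                (sizes[a] * da + sizes[b] * db) / sizes[new]
        active = [c for c in active if c not in (a, b)] + [new]
    return np.array(heights)


class TestLinkageDense:
    def test_identical_rows_merge_at_zero(self):
        X = sp.csr_matrix(np.array([[1, 1, 0, 0], [1, 1, 0, 0]], dtype=float))
        link = linkage_dense(X)
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_rows_merge_at_one(self):
        X = sp.csr_matrix(np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=float))
        link = linkage_dense(X)
        assert link[0, 2] == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(2)
        X = sp.csr_matrix((rng.random((20, 40)) < 0.3).astype(float))
        link = linkage_dense(X)
        expected = naive_upgma(cosine_distance_matrix(X))
        assert np.allclose(np.sort(link[:, 2]), np.sort(expected), atol=1e-12)

    def test_zero_rows_do_not_crash(self):
        X = sp.csr_matrix(np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0]],
                                   dtype=float))
        d = cosine_distance_matrix(X)
        assert d[0, 1] == 0.0 and d[0, 2] == 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = (rng.random((30, 60)) < 0.3).astype(float)
        perm = rng.permutation(30)
        la = cut_dendrogram(linkage_dense(sp.csr_matrix(X)), 0.3)
        lb = cut_dendrogram(linkage_dense(sp.csr_matrix(X[perm])), 0.3)
        assert adjusted_rand_score(la[perm], lb) == pytest.approx(1.0)


def _two_group_coverage(n_per_group=20, jitter=0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, (start, end) in enumerate([(0, 400), (600, 1000)]):
        for _ in range(n_per_group):
            j = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            row = np.zeros(1000)
            row[start + max(j, 0):end + min(j, 0)] = 1
            rows.append(row)
    return sp.csr_matrix(np.array(rows))


class TestCutAndCutoff:
    def test_cut_below_smallest_height_all_singletons(self):
        X = _two_group_coverage(5, jitter=30)
        link = linkage_dense(X)
        positive = link[link[:, 2] > 0, 2]
        labels = cut_dendrogram(link, positive.min() / 2)
        # reads with strictly identical coverage still collapse
        assert len(np.unique(labels)) == len(np.unique(X.toarray(), axis=0))

    def test_cut_above_largest_height_single_cluster(self):
        X = _two_group_coverage(5)
        link = linkage_dense(X)
        assert len(np.unique(cut_dendrogram(link, 1.5))) == 1

    def test_two_group_fixture_cutoff_two_clusters(self):
        X = _two_group_coverage(20, jitter=5, seed=4)
        link = linkage_dense(X)
        labels = cut_dendrogram(link, 0.01)
        assert len(np.unique(labels)) == 2

    def test_chord_method_matches_grid_oracle(self):
        # construct a linkage whose cluster curve is ~ 100 exp(-50 c) + 5
        n = 105
        heights = [-np.log(1 - j / 100) / 50 for j in range(1, 100)]
        heights += [0.95, 0.96, 0.97, 0.98, 0.99]
        heights = np.sort(heights)
        link = np.zeros((n - 1, 4))
        link[:, 0] = np.arange(n - 1)          # chain merges (shape unused)
        link[:, 1] = np.arange(n, 2 * n - 1)
        link[:, 2] = heights
        link[:, 3] = np.arange(2, n + 1)
        got = find_cutoff(link, (0.0, 0.2), n_scan=400, method="chord")
        # dense-grid oracle on the same curve
        grid = np.linspace(0, 0.2, 10_000)
        counts = cluster_curve(link, grid).astype(float)
        p0, p1 = np.array([0, counts[0]]), np.array([0.2, counts[-1]])
        u = (p1 - p0) / np.linalg.norm(p1 - p0)
        rel = np.stack([grid, counts], 1) - p0
        oracle = grid[np.argmax(np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0]))]
        assert abs(got - oracle) < 0.2 / 400 * 2

    def test_flat_curve_returns_midpoint_with_warning(self, caplog):
        link = np.array([[0, 1, 0.5, 2]])
        with caplog.at_level("WARNING"):
            got = find_cutoff(link, (0.0, 0.2))
        assert got == pytest.approx(0.1)
        assert "flat" in caplog.text

    def test_two_group_fixture_found_cutoff_gives_two_clusters(self):
        X = _two_group_coverage(20, jitter=5, seed=5)
        link = linkage_dense(X)
        cutoff = find_cutoff(link, (0.0, 0.5))
        assert len(np.unique(cut_dendrogram(link, cutoff))) == 2


# ---------------------------------------------------------------------------
# sparse linkage
# ---------------------------------------------------------------------------

class TestLinkageSparse:
    def test_well_separated_groups_match_dense(self):
        X = _two_group_coverage(25)
        dense_labels = cut_dendrogram(linkage_dense(X), 0.01)
        sparse_labels = cut_dendrogram(linkage_sparse(X, 5), 0.01)
        assert adjusted_rand_score(dense_labels, sparse_labels) == 1.0

    def test_identical_reads_single_cluster(self):
        X = sp.csr_matrix(np.tile(np.r_[np.ones(100), np.zeros(100)], (30, 1)))
        labels = cut_dendrogram(linkage_sparse(X, 5), 0.01)
        assert len(np.unique(labels)) == 1

    def test_disconnected_graph_still_full_dendrogram(self):
        X = _two_group_coverage(10)  # disjoint support -> distance 1
        link = linkage_sparse(X, 3)
        assert link.shape == (19, 3 + 1)
        assert len(np.unique(cut_dendrogram(link, 2.0))) == 1


# ---------------------------------------------------------------------------
# cluster filtering
# ---------------------------------------------------------------------------

def _labels_from_sizes(sizes):
    return np.repeat(np.arange(len(sizes)), sizes)


class TestFilterClusters:
    empty_link = np.zeros((0, 4))

    def test_single_cluster_nothing_flagged(self):
        cs = filter_clusters(_labels_from_sizes([100]), self.empty_link)
        assert not cs.filtered.any()
        assert cs.retained_fraction == 1.0

    def test_greedy_flagging_of_singletons(self):
        cs = filter_clusters(_labels_from_sizes([96, 1, 1, 1, 1]),
                             self.empty_link)
        assert cs.filtered.sum() == 4
        assert not cs.filtered[0]
        assert cs.retained_fraction == pytest.approx(0.96)

    def test_removal_stopping_rule(self):
        # removing the 6-read cluster would drop retention below 95%
        cs = filter_clusters(_labels_from_sizes([94, 6]), self.empty_link)
        assert not cs.filtered.any()

    def test_retention_guarantee_on_random_size_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = int(rng.integers(1, 30))
            sizes = rng.integers(1, 50, size=k)
            cs = filter_clusters(_labels_from_sizes(sizes), self.empty_link)
            assert cs.retained_fraction >= 0.95

    def test_tie_broken_by_root_height(self):
        # two singleton-sized clusters, only one removable: the isolated
        # one (larger root height) goes first
        labels = np.array([0] * 38 + [1, 1] + [2, 2])
        link = np.zeros((len(labels) - 1, 4))
        # merge leaves 38,39 (cluster 1) at height 0.002, leaves 40,41
        # (cluster 2) at height 0.008; remaining merges above cutoff
        link[0] = [38, 39, 0.002, 2]
        link[1] = [40, 41, 0.008, 2]
        # chain-merge everything else above the cutoff
        nodes = list(range(38)) + [42, 43]
        row, h, current = 2, 0.5, nodes[0]
        for b in nodes[1:]:
            link[row] = [current, b, h, 0]
            current = 42 + row
            row += 1
            h += 0.01
        cs = filter_clusters(labels, link, min_retained=0.95)
        assert cs.filtered[2] and not cs.filtered[1]


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def _cs(sizes):
    labels = _labels_from_sizes(sizes)
    return ClusterSet(labels, np.zeros(len(sizes), bool), 0.01,
                      np.asarray(sizes), np.zeros(len(sizes)))


class TestDiversity:
    def test_single_cluster_closed_forms(self):
        d = diversity_measures(_cs([50]))
        assert d["clusters"] == 1
        assert d["cluster_entropy"] == 0.0
        assert d["cluster_inverse_simpson"] == pytest.approx(1.0)
        assert d["cluster_gini"] == pytest.approx(0.0)
        assert d["occupancy_top_clone"] == 1.0

    def test_uniform_clusters_closed_forms(self):
        d = diversity_measures(_cs([25, 25, 25, 25]))
        assert d["cluster_entropy"] == pytest.approx(np.log(4))
        assert d["cluster_inverse_simpson"] == pytest.approx(4.0)
        assert d["clusters_eff"] == pytest.approx(4.0)

    def test_5_3_2_formula_oracle(self):
        d = diversity_measures(_cs([5, 3, 2]))
        assert d["cluster_inverse_simpson"] == \
            pytest.approx(1 / (0.25 + 0.09 + 0.04))
        assert d["cluster_gini"] == pytest.approx(0.2)

    def test_diversity_inequalities(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            sizes = rng.integers(1, 100, size=int(rng.integers(1, 20)))
            inv = inverse_simpson(sizes)
            ent = shannon_entropy(sizes)
            assert 1.0 - 1e-9 <= inv <= np.exp(ent) + 1e-9 <= len(sizes) + 1e-9
            assert 0.0 <= gini(sizes) < 1.0

    def test_downsample_with_few_reads_flags(self):
        X = _two_group_coverage(10, jitter=3)
        cfg = ClusterConfig(downsample_reps=3)
        out = downsample_diversity(X, cfg, seed=0)
        assert out["downsampled"] is False
        assert out["clusters"] == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.integers(min_value=1, max_value=500), min_size=1,
                max_size=25))
def test_diversity_bounds_hold_for_any_size_vector(sizes):
    sizes = np.array(sizes)
    inv = inverse_simpson(sizes)
    ent = shannon_entropy(sizes)
    assert 1.0 - 1e-9 <= inv <= np.exp(ent) + 1e-9
    assert np.exp(ent) <= len(sizes) + 1e-9
    assert 0.0 <= gini(sizes) < 1.0


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.integers(min_value=1, max_value=200), min_size=1,
                max_size=20))
def test_filtering_retention_guarantee_property(sizes):
    cs = filter_clusters(_labels_from_sizes(sizes), np.zeros((0, 4)))
    assert cs.retained_fraction >= 0.95
    assert (~cs.filtered).sum() >= 1
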