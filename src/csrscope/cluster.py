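"""Hierarchical clustering of reads on cleaned coverage patterns.

Reads sharing a CSR junction produce near-identical coverage patterns over
the reduced coordinate system, so clones are recovered by UPGMA (average
linkage) on cosine distances between coverage rows.  Before clustering,
gaps strictly smaller than a cutoff (default 75 nt) are filled in — small
indel artefacts of sequencing/mapping would otherwise fragment clones.
Clusters come from cutting the dendrogram at a fixed height (default 0.01)
or at an automatically detected inflection point; small and isolated
clusters are then flagged so that the remaining clusters retain at least
95% of the reads.  Diversity measures are estimated on repeated downsampled
subsets for robustness to read depth.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.optimize import curve_fit
from scipy.spatial.distance import squareform

from .config import ClusterConfig
from .msa import MSAMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# coverage cleaning
# ---------------------------------------------------------------------------

def clean_coverage(msa: MSAMatrix, gap_fill_cutoff: int = 75) -> sp.csr_matrix:
    """Coverage values with internal gaps strictly smaller than the cutoff
    filled with coverage 1 (noise suppression); gaps >= cutoff are kept."""
    cov = msa.coverage()
    if cov.nnz == 0:
        return cov
    cols = cov.indices.astype(np.int64)
    row_of = np.repeat(np.arange(cov.shape[0], dtype=np.int32),
                       np.diff(cov.indptr))
    # gaps: consecutive entries of the same row with a column jump
    same_row = row_of[1:] == row_of[:-1]
    jump = np.diff(cols)
    fillable = np.where(same_row & (jump > 1) & (jump - 1 < gap_fill_cutoff))[0]
    if len(fillable):
        starts = cols[fillable] + 1
        lens = (jump[fillable] - 1).astype(np.int64)
        total = int(lens.sum())
        # concatenated ranges [start_i, start_i + len_i)
        offs = np.repeat(np.cumsum(lens) - lens, lens)
        fill_cols = np.repeat(starts, lens) + np.arange(total) - offs
        fill_rows = np.repeat(row_of[fillable], lens)
        rows = np.concatenate([row_of, fill_rows])
        out_cols = np.concatenate([cols, fill_cols])
        vals = np.concatenate([cov.data.astype(np.int32),
                               np.ones(total, dtype=np.int32)])
    else:
        rows, out_cols, vals = row_of, cols, cov.data.astype(np.int32)
    return sp.coo_matrix((vals, (rows, out_cols)), shape=cov.shape,
                         dtype=np.int32).tocsr()


# ---------------------------------------------------------------------------
# distances and linkage
# ---------------------------------------------------------------------------

def _normalize_rows(X: sp.csr_matrix) -> tuple[sp.csr_matrix, np.ndarray]:
    X = X.astype(np.float64).tocsr()
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    zero = norms == 0
    inv = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, norms))
    D = sp.diags(inv)
    return (D @ X).tocsr(), zero


def cosine_distance_matrix(X: sp.csr_matrix) -> np.ndarray:
    """Dense pairwise cosine distances; two all-zero rows are at distance 0,
    a zero row is at distance 1 from any non-zero row."""
    Xn, zero = _normalize_rows(X)
    if Xn.shape[0] * Xn.shape[1] <= 2e8:  # dense BLAS beats sparse product here
        Xd = Xn.toarray()
        sim = Xd @ Xd.T
    else:
        sim = np.asarray((Xn @ Xn.T).todense())
    dist = np.clip(1.0 - sim, 0.0, 2.0)
    if zero.any():
        dist[np.ix_(zero, zero)] = 0.0
    np.fill_diagonal(dist, 0.0)
    return dist


def linkage_dense(coverage: sp.csr_matrix | np.ndarray) -> np.ndarray:
    """UPGMA merge table (scipy linkage format) on cosine distances."""
    X = sp.csr_matrix(coverage)
    dist = cosine_distance_matrix(X)
    condensed = squareform(dist, checks=False)
    return scipy_linkage(condensed, method="average")


def _bin_columns(X: sp.csr_matrix, factor: int) -> sp.csr_matrix:
    """Sum coverage within column bins of ``factor`` nt (for candidate search)."""
    n, m = X.shape
    cols = X.indices // factor
    rows = np.repeat(np.arange(n, dtype=np.int64), np.diff(X.indptr))
    return sp.coo_matrix((X.data, (rows, cols)),
                         shape=(n, -(-m // factor))).tocsr()


def _exact_pair_distances(Xn: sp.csr_matrix, a: np.ndarray, b: np.ndarray,
                          batch: int = 5000) -> np.ndarray:
    """Cosine distances for an explicit list of row pairs (batched)."""
    out = np.empty(len(a))
    for s in range(0, len(a), batch):
        e = min(s + batch, len(a))
        prod = Xn[a[s:e]].multiply(Xn[b[s:e]]).sum(axis=1)
        out[s:e] = 1.0 - np.asarray(prod).ravel()
    return np.clip(out, 0.0, 2.0)


def linkage_sparse(coverage: sp.csr_matrix, k_neighbors: int = 20,
                   chunk: int = 1000, candidate_bin: int = 25) -> np.ndarray:
    """Approximate average-linkage dendrogram on a k-nearest-neighbor graph.

    Pairwise cosine similarities are computed blockwise as sparse products;
    only each read's ``k_neighbors`` nearest neighbors enter the merge graph.
    Merging follows UPGMA's weighted-average update restricted to existing
    graph edges, so the result is approximate for distant pairs; exactness
    is claimed only at the partition level (dense-oracle agreement is part
    of the test contract).  Disconnected components are merged at maximal
    height.
    """
    n = coverage.shape[0]
    if n < 2:
        return np.zeros((0, 4))
    X = sp.csr_matrix(coverage)
    Xn, _ = _normalize_rows(X)
    # neighbor candidates from a column-binned matrix (much cheaper product),
    # exact full-resolution cosine distances computed for candidate pairs only
    Xb, _ = _normalize_rows(_bin_columns(X, candidate_bin))
    cand_a, cand_b = [], []
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        sim = (Xb[start:stop] @ Xb.T).tocsr()
        indptr, indices, data = sim.indptr, sim.indices, sim.data
        for i in range(stop - start):
            cols = indices[indptr[i]:indptr[i + 1]]
            vals = data[indptr[i]:indptr[i + 1]]
            mask = cols != (start + i)
            cols, vals = cols[mask], vals[mask]
            if len(cols) > k_neighbors:
                top = np.argpartition(-vals, k_neighbors)[:k_neighbors]
                cols = cols[top]
            cand_a.append(np.full(len(cols), start + i, dtype=np.int64))
            cand_b.append(cols.astype(np.int64))
    a = np.concatenate(cand_a) if cand_a else np.zeros(0, dtype=np.int64)
    b = np.concatenate(cand_b) if cand_b else np.zeros(0, dtype=np.int64)
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    uniq = np.unique(np.stack([lo, hi], axis=1), axis=0)
    dists = _exact_pair_distances(Xn, uniq[:, 0], uniq[:, 1])
    neighbor: list[dict[int, float]] = [dict() for _ in range(n)]
    for (i, j), d in zip(uniq, dists):
        neighbor[int(i)][int(j)] = float(d)
        neighbor[int(j)][int(i)] = float(d)

    size = {i: 1 for i in range(n)}
    height = {i: 0.0 for i in range(n)}
    heap = [(d, i, j) for i in range(n) for j, d in neighbor[i].items() if i < j]
    heapq.heapify(heap)
    merges = []
    next_id = n
    nbrs: dict[int, dict[int, float]] = {i: dict(neighbor[i]) for i in range(n)}
    active = set(range(n))
    while len(active) > 1 and heap:
        d, a, b = heapq.heappop(heap)
        if a not in active or b not in active:
            continue
        if nbrs[a].get(b) != d:
            continue  # stale entry
        new = next_id
        next_id += 1
        h = max(d, height[a], height[b])
        merges.append((a, b, h, size[a] + size[b]))
        size[new] = size[a] + size[b]
        height[new] = h
        da, db = nbrs.pop(a), nbrs.pop(b)
        merged: dict[int, float] = {}
        for c in set(da) | set(db):
            if c in (a, b):
                continue
            if c in da and c in db:
                # both parts know c: exact UPGMA weighted average
                merged[c] = (size[a] * da[c] + size[b] * db[c]) / size[new]
            else:
                merged[c] = da.get(c, db.get(c))
        active.discard(a)
        active.discard(b)
        active.add(new)
        nbrs[new] = {}
        for c, dc in merged.items():
            if c not in active:
                continue
            nbrs[new][c] = dc
            nbrs[c].pop(a, None)
            nbrs[c].pop(b, None)
            nbrs[c][new] = dc
            heapq.heappush(heap, (dc, min(new, c), max(new, c)))
    if len(active) > 1:
        log.info("kNN graph disconnected: merging %d components at max height",
                 len(active))
        top = max(max(height.values()), 1.0)
        rest = sorted(active)
        while len(rest) > 1:
            a, b = rest[0], rest[1]
            merges.append((a, b, top, size[a] + size[b]))
            size[next_id] = size[a] + size[b]
            height[next_id] = top
            rest = [next_id] + rest[2:]
            next_id += 1
    return np.array(merges, dtype=float)


def cut_dendrogram(link: np.ndarray, cutoff: float = 0.01) -> np.ndarray:
    """Flat 0-based cluster labels from cutting the dendrogram at a height."""
    if len(link) == 0:
        return np.zeros(1, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign non-monotonicity in sparse mode
        return fcluster(link, t=cutoff, criterion="distance") - 1


def cluster_curve(link: np.ndarray, cutoffs: np.ndarray) -> np.ndarray:
    """Number of flat clusters as a function of the cut height."""
    n = len(link) + 1
    heights = np.sort(link[:, 2]) if len(link) else np.zeros(0)
    return n - np.searchsorted(heights, cutoffs, side="right")


def find_cutoff(link: np.ndarray, scan_range: tuple[float, float] = (0.0, 0.2),
                n_scan: int = 200, method: str = "chord") -> float:
    """Inflection point of the clusters-vs-cutoff curve.

    ``chord`` (default): the scan point farthest from the straight line
    connecting the curve extremes.  ``doubleexp``: fit
    ``a exp(-b c) + d exp(-e c)`` and return the crossing of the two
    exponential components.  A flat curve degenerates to the scan midpoint.
    """
    lo, hi = scan_range
    grid = np.linspace(lo, hi, n_scan)
    counts = cluster_curve(link, grid).astype(float)
    if counts[0] == counts[-1]:
        log.warning("cluster curve is flat over the scan range; using midpoint")
        return float((lo + hi) / 2)
    if method == "chord":
        p0 = np.array([grid[0], counts[0]])
        p1 = np.array([grid[-1], counts[-1]])
        span = p1 - p0
        span = span / np.linalg.norm(span)
        rel = np.stack([grid, counts], axis=1) - p0
        dist = np.abs(rel[:, 0] * span[1] - rel[:, 1] * span[0])
        return float(grid[int(np.argmax(dist))])
    if method == "doubleexp":
        def model(c, a, b, d, e):
            return a * np.exp(-b * c) + d * np.exp(-e * c)
        p, _ = curve_fit(model, grid, counts,
                         p0=[counts[0], 50.0, max(counts[-1], 1.0), 1.0],
                         maxfev=20000)
        a, b, d, e = p
        if a <= 0 or d <= 0 or b == e:
            return float((lo + hi) / 2)
        c_star = np.log(a / d) / (b - e)
        return float(np.clip(c_star, lo, hi))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# cluster filtering
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    labels: np.ndarray  # per-read flat cluster ids (0..k-1)
    filtered: np.ndarray  # per-cluster flag: True = removed
    cutoff: float
    sizes: np.ndarray  # per-cluster read counts
    root_heights: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def kept(self) -> np.ndarray:
        """Indices of retained clusters."""
        return np.where(~self.filtered)[0]

    @property
    def read_kept(self) -> np.ndarray:
        """Boolean per-read mask of reads in retained clusters."""
        return ~self.filtered[self.labels]

    @property
    def retained_fraction(self) -> float:
        return float(self.sizes[~self.filtered].sum() / self.sizes.sum())

    def to_frame(self, read_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame({"read_id": read_ids, "cluster": self.labels,
                             "filtered": self.filtered[self.labels]})


def _root_heights(labels: np.ndarray, link: np.ndarray) -> np.ndarray:
    """Height of the root node of each flat cluster (0 for singletons)."""
    n = len(labels)
    k = labels.max() + 1
    node_label: dict[int, int] = {i: int(labels[i]) for i in range(n)}
    heights = np.zeros(k)
    for t, (a, b, h, _s) in enumerate(link):
        la, lb = node_label.get(int(a), -1), node_label.get(int(b), -1)
        if la >= 0 and la == lb:
            node_label[n + t] = la
            heights[la] = max(heights[la], h)
    return heights


def filter_clusters(labels: np.ndarray, link: np.ndarray, cutoff: float = 0.01,
                    min_retained: float = 0.95) -> ClusterSet:
    """Flag small/isolated clusters while retaining >= ``min_retained`` reads.

    Clusters are flagged in order of increasing size (ties: larger root
    height first, i.e. more isolated), stopping before the retained read
    fraction would drop below the threshold.
    """
    labels = np.asarray(labels)
    sizes = np.bincount(labels)
    heights = _root_heights(labels, link)
    order = sorted(range(len(sizes)), key=lambda c: (sizes[c], -heights[c], c))
    total = sizes.sum()
    budget = total - int(np.ceil(min_retained * total))
    filtered = np.zeros(len(sizes), dtype=bool)
    removed = 0
    for c in order:
        if removed + sizes[c] <= budget:
            filtered[c] = True
            removed += sizes[c]
        else:
            break
    return ClusterSet(labels, filtered, cutoff, sizes, heights)


def cluster_reads(cleaned: sp.csr_matrix, cfg: ClusterConfig | None = None,
                  sparse: bool | None = None) -> tuple[ClusterSet, np.ndarray]:
    """Linkage + cut + filter in one call; returns (ClusterSet, linkage).

    ``sparse=None`` picks the kNN-graph linkage above 3000 reads.
    """
    cfg = cfg or ClusterConfig()
    n = cleaned.shape[0]
    if sparse is None:
        sparse = n > 3000
    link = (linkage_sparse(cleaned, cfg.k_neighbors) if sparse
            else linkage_dense(cleaned))
    labels = cut_dendrogram(link, cfg.cutoff)
    return filter_clusters(labels, link, cfg.cutoff, cfg.min_retained), link


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def gini(sizes: np.ndarray) -> float:
    x = np.sort(np.asarray(sizes, dtype=float))
    n = len(x)
    if n == 0 or x.sum() == 0:
        return 0.0
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)


def shannon_entropy(sizes: np.ndarray) -> float:
    p = np.asarray(sizes, dtype=float)
    p = p[p > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def inverse_simpson(sizes: np.ndarray) -> float:
    p = np.asarray(sizes, dtype=float)
    p = p[p > 0]
    p = p / p.sum()
    return float(1.0 / (p ** 2).sum())


def diversity_measures(cs: ClusterSet, big_clone_fraction: float = 0.01) -> dict:
    """The nine diversity statistics of one clustering."""
    all_sizes = cs.sizes
    kept_sizes = cs.sizes[~cs.filtered]
    total = all_sizes.sum()
    frac = kept_sizes / kept_sizes.sum()
    return {
        "cluster_size_mean": float(frac.mean()),
        "cluster_size_std": float(frac.std()),
        "clusters": int(len(kept_sizes)),
        "clusters_eff": float(np.exp(shannon_entropy(all_sizes))),
        "cluster_gini": gini(kept_sizes),
        "cluster_entropy": shannon_entropy(kept_sizes),
        "cluster_inverse_simpson": inverse_simpson(kept_sizes),
        "occupancy_top_clone": float(frac.max()),
        "occupancy_big_clones": float(frac[frac > big_clone_fraction].sum()),
    }


def downsample_diversity(cleaned: sp.csr_matrix, cfg: ClusterConfig | None = None,
                         seed: int = 0) -> dict:
    """Diversity averaged over repeated subsamples (default 10 x 1000 reads).

    Each replicate is clustered independently (dense UPGMA, same cutoff);
    replicate r uses seed ``seed + r``.  With fewer reads than the subsample
    size, all reads are used and the result flagged.
    """
    cfg = cfg or ClusterConfig()
    n = cleaned.shape[0]
    n_sub = min(cfg.downsample_n, n)
    reps = []
    for r in range(cfg.downsample_reps):
        rng = np.random.default_rng(seed + r)
        idx = (np.arange(n) if n_sub == n
               else np.sort(rng.choice(n, size=n_sub, replace=False)))
        cs, _ = cluster_reads(cleaned[idx], cfg, sparse=False)
        reps.append(diversity_measures(cs, cfg.big_clone_fraction))
    out = {k: float(np.mean([r[k] for r in reps])) for k in reps[0]}
    out["downsampled"] = n > cfg.downsample_n
    return out
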