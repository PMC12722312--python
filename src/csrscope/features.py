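"""Per-cluster statistics, the 2D breakpoint matrix and the 68-feature
per-sample summary vector.

Five feature categories condense one sample: structural aberrations (5),
sequence context around junctions (17), the donor x acceptor breakpoint
matrix and statistics derived from it (28), diversity of the clone size
distribution (9), and isotype composition (9).  The canonical feature list
ships as ``data/feature_manifest.csv``.

Breakpoints are binned at 50 nt along the reduced coordinate system; by
default each gap is weighted by the inverse of its cluster's size so that
all clusters contribute equally regardless of clonal expansion.
Cluster-specific quantities are averaged within clusters first and then
over the sample, which decouples the estimates from cluster sizes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .alignments import ReadAlignment
from .annotation import SwitchAnnotation, REGION_CLASS
from .cluster import ClusterSet
from .msa import MSAMatrix
from .simulate import revcomp

BIN_SIZE = 50

#: default motif set: weak/strong single-base classes and the AID hotspot
#: WRCY (deaminated strand) / its reverse complement RGYW
MOTIFS = {
    "W": re.compile("[AT]"),
    "S": re.compile("[GC]"),
    "WRCY": re.compile("(?=[AT][AG]C[CT])"),
    "RGYW": re.compile("(?=[AG]G[CT][AT])"),
}


def load_manifest() -> pd.DataFrame:
    with resources.files("csrscope.data").joinpath("feature_manifest.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# per-cluster statistics
# ---------------------------------------------------------------------------

def _most_frequent_isotype(isotypes: list[str], annot: SwitchAnnotation) -> str | None:
    counts: dict[str, int] = {}
    for iso in isotypes:
        if iso:
            counts[iso] = counts.get(iso, 0) + 1
    if not counts:
        return None
    order = {name: i for i, name in enumerate(annot.names)}
    # ties broken toward the downstream (locus-later) region
    return max(counts, key=lambda k: (counts[k], order.get(k, -1)))


def compute_cluster_stats(
    msa: MSAMatrix,
    cs: ClusterSet,
    reads_by_id: dict[str, ReadAlignment],
    rearrangements: pd.DataFrame,
    annot: SwitchAnnotation,
) -> pd.DataFrame:
    """One row of summary statistics per retained cluster.

    The consensus base at a position is the majority base over cluster
    reads; consensus positions are those covered by at least half the
    cluster.  Breakpoint spread counts positions with coverage strictly
    between 5% and 95% of the cluster size (fuzzy cluster boundaries).
    """
    bases = msa.bases()
    cover = msa.coverage()
    cover_bool = cover.copy()
    cover_bool.data = np.ones_like(cover_bool.data)
    rows = []
    rearr_by_read = (rearrangements.groupby("read_idx")
                     if len(rearrangements) else None)
    for c in cs.kept:
        idx = np.where(cs.labels == c)[0]
        size = len(idx)
        sub_cov = cover_bool[idx]
        colcover = np.asarray(sub_cov.sum(axis=0)).ravel()
        base_counts = np.zeros((4, msa.n_bases))
        sub_bases = bases[idx]
        for code in range(1, 5):
            m = sub_bases.copy()
            m.data = (m.data == code).astype(np.int32)
            base_counts[code - 1] = np.asarray(m.sum(axis=0)).ravel()
        cons_mask = colcover >= size / 2.0
        cons_cols = np.where(cons_mask)[0]
        cons_base = base_counts[:, cons_cols].argmax(axis=0) + 1
        consensus_len = len(cons_cols)
        gc = float(np.isin(cons_base, (2, 3)).mean()) if consensus_len else np.nan
        spread = int(((colcover > 0.05 * size) & (colcover < 0.95 * size)).sum())

        region_cov = {f"covered_{r.name}":
                      int(cons_mask[r.offset:r.reduced_end].sum()) for r in annot}

        ras = [reads_by_id[msa.read_ids[i]] for i in idx]
        isotype = _most_frequent_isotype([ra.isotype for ra in ras], annot)

        inv_sizes, dup_sizes, inv_reads, dup_reads = [], [], 0, 0
        if rearr_by_read is not None:
            for i in idx:
                if i not in rearr_by_read.groups:
                    continue
                g = rearr_by_read.get_group(i)
                inv = g[g["kind"] == "inversion"]["size"]
                dup = g[g["kind"] == "duplication"]["size"]
                inv_sizes.extend(inv)
                dup_sizes.extend(dup)
                inv_reads += int(len(inv) > 0)
                dup_reads += int(len(dup) > 0)

        inserts = [ins for ra in ras for ins in ra.inserts]
        insert_reads = sum(1 for ra in ras if ra.inserts)
        insert_overlap = np.nan
        if len(inserts) >= 2:
            lo = max(i.genome_start for i in inserts)
            hi = min(i.genome_end for i in inserts)
            union = (max(i.genome_end for i in inserts)
                     - min(i.genome_start for i in inserts))
            same_chrom = len({i.chrom for i in inserts}) == 1
            insert_overlap = max(0, hi - lo) / union if same_chrom and union else 0.0

        sw = [br for ra in ras for br in ra.realignments
              if br.defined and not br.is_insert]
        ib = [br for ra in ras for br in ra.realignments
              if br.defined and br.is_insert]
        rows.append({
            "cluster": int(c), "size": size, "isotype": isotype,
            "consensus_len": consensus_len, "gc": gc, "spread": spread,
            "pct_reads_inverted": 100.0 * inv_reads / size,
            "pct_reads_duplicated": 100.0 * dup_reads / size,
            "inversion_size": float(np.mean(inv_sizes)) if inv_sizes else np.nan,
            "duplication_size": float(np.mean(dup_sizes)) if dup_sizes else np.nan,
            "insert_frequency": insert_reads / size,
            "insert_length": (float(np.mean([i.read_end - i.read_start
                                             for i in inserts]))
                              if inserts else np.nan),
            "insert_gap": (float(np.mean([i.left_gap + i.right_gap
                                          for i in inserts])) if inserts else np.nan),
            "insert_overlap": insert_overlap,
            "homology": float(np.mean([b.n_homology for b in sw])) if sw else np.nan,
            "untemplated": (float(np.mean([b.n_untemplated for b in sw]))
                            if sw else np.nan),
            "homology_1_3": (float(np.mean([1 <= b.n_homology <= 3 for b in sw]))
                             if sw else np.nan),
            "homology_gt6": (float(np.mean([b.n_homology > 6 for b in sw]))
                             if sw else np.nan),
            "blunt_fraction": (float(np.mean([b.n_homology == 0 and
                                              b.n_untemplated == 0 for b in sw]))
                               if sw else np.nan),
            "homology_inserts": (float(np.mean([b.n_homology for b in ib]))
                                 if ib else np.nan),
            "untemplated_inserts": (float(np.mean([b.n_untemplated for b in ib]))
                                    if ib else np.nan),
            **region_cov,
        })
    stats = pd.DataFrame(rows)
    if len(stats) > 1:
        # size adjusted for amplification length/GC bias: residual of
        # log(size) regressed on consensus length and GC, re-exponentiated
        ok = stats[["consensus_len", "gc"]].notna().all(axis=1)
        X = np.column_stack([np.ones(ok.sum()), stats.loc[ok, "consensus_len"],
                             stats.loc[ok, "gc"]])
        y = np.log(stats.loc[ok, "size"].to_numpy(dtype=float))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        stats.loc[ok, "adjusted_size"] = np.exp(y - X @ beta + np.mean(y))
    else:
        stats["adjusted_size"] = stats["size"] if len(stats) else []
    return stats


# ---------------------------------------------------------------------------
# breakpoint matrix
# ---------------------------------------------------------------------------

@dataclass
class BreakpointMatrix:
    matrix: np.ndarray  # n_bins x n_bins, donor x acceptor, weights
    table: pd.DataFrame  # per-gap: donor, acceptor, weight, linkage flags
    bin_size: int
    n_clusters: int


def build_breakpoint_matrix(
    gaps: pd.DataFrame,
    cs: ClusterSet,
    rearrangements: pd.DataFrame,
    annot: SwitchAnnotation,
    min_gap: int = 75,
    weighting: str = "cluster-equal",
) -> BreakpointMatrix:
    """2D histogram of (donor, acceptor) breakpoint positions in 50 nt bins.

    Only gaps >= ``min_gap`` nt from reads in retained clusters enter.  With
    ``cluster-equal`` weighting each gap carries weight 1/cluster_size so a
    cluster's breaks sum to its per-read break count; ``read-equal`` gives
    every gap weight 1.  Each gap is annotated with whether an inversion or
    duplication event of the same read abuts it (within 25 nt).
    """
    if weighting not in ("cluster-equal", "read-equal"):
        raise ValueError(f"unknown weighting {weighting!r}")
    keep_mask = cs.read_kept
    gaps = gaps[(gaps["size"] >= min_gap)
                & gaps["read_idx"].map(lambda i: bool(keep_mask[i]))].copy()
    if len(gaps):
        gaps["cluster"] = cs.labels[gaps["read_idx"]]
        sizes = cs.sizes
        gaps["weight"] = (1.0 / sizes[gaps["cluster"]]
                          if weighting == "cluster-equal" else 1.0)
        # breakpoint positions guaranteed inside regions
        gaps["donor"] = gaps["left"] - 1
        gaps["acceptor"] = gaps["right"]
        gaps["inv_linked"] = False
        gaps["dup_linked"] = False
        if len(rearrangements):
            by_read = {k: v for k, v in rearrangements.groupby("read_idx")}
            for gi, g in gaps.iterrows():
                ev = by_read.get(g["read_idx"])
                if ev is None:
                    continue
                near = ((ev["left"] - g["right"]).abs() <= 25) | \
                       ((ev["right"] - g["left"]).abs() <= 25)
                kinds = set(ev.loc[near, "kind"])
                gaps.at[gi, "inv_linked"] = "inversion" in kinds
                gaps.at[gi, "dup_linked"] = "duplication" in kinds
    n_bins = annot.n_bins(BIN_SIZE)
    mat = np.zeros((n_bins, n_bins))
    if len(gaps):
        np.add.at(mat, (gaps["donor"] // BIN_SIZE, gaps["acceptor"] // BIN_SIZE),
                  gaps["weight"])
    return BreakpointMatrix(mat, gaps.reset_index(drop=True), BIN_SIZE,
                            int(len(cs.kept)))


def breakpoint_statistics(bm: BreakpointMatrix, annot: SwitchAnnotation,
                          cluster_stats: pd.DataFrame) -> dict:
    """Aggregate statistics of the breakpoint matrix.

    Each break falls in exactly one of five categories (direct switch,
    sequential switch, intra-switch deletion, inversion-linked,
    duplication-linked), so those percentages sum to 100.
    """
    out: dict[str, float] = {}
    t = bm.table
    total = t["weight"].sum() if len(t) else 0.0
    out["breaks_normalized"] = total / bm.n_clusters if bm.n_clusters else np.nan

    pair_names = ["SM_SG", "SM_SA", "SM_SE", "SG_SG", "SG_SA", "SG_SE",
                  "SA_SA", "SA_SE"]
    for name in pair_names:
        out[f"pct_breaks_{name}"] = 0.0 if total else np.nan
    cats = {k: 0.0 for k in ("direct", "sequential", "intra_del", "inv", "dup",
                             "intra_inv", "intra_dup")}
    disp_points: dict[str, list[tuple[float, float]]] = {r.name: [] for r in annot}
    class_order = ["SM", "SG", "SA", "SE"]
    for g in t.itertuples():
        dreg = annot.region_of_reduced(int(g.donor))
        areg = annot.region_of_reduced(int(g.acceptor))
        if dreg is None or areg is None:
            continue
        w = g.weight
        same = dreg.name == areg.name
        if g.inv_linked:
            cats["inv"] += w
            if same:
                cats["intra_inv"] += w
        elif g.dup_linked:
            cats["dup"] += w
            if same:
                cats["intra_dup"] += w
        elif same:
            cats["intra_del"] += w
        elif dreg.name == "SM":
            cats["direct"] += w
        else:
            cats["sequential"] += w
        dc, ac = REGION_CLASS[dreg.name], REGION_CLASS[areg.name]
        pair = "_".join(sorted((dc, ac), key=class_order.index))
        key = f"pct_breaks_{pair}"
        if key in out:
            out[key] += 100.0 * w / total
        disp_points[dreg.name].append((g.donor, w))
        disp_points[areg.name].append((g.acceptor, w))

    scale = 100.0 / total if total else np.nan
    out["pct_direct_switch"] = cats["direct"] * scale
    out["pct_sequential_switch"] = cats["sequential"] * scale
    out["pct_intraswitch_deletion"] = cats["intra_del"] * scale
    out["pct_inversions"] = cats["inv"] * scale
    out["pct_duplications"] = cats["dup"] * scale
    out["pct_intraswitch_inversion"] = cats["intra_inv"] * scale
    out["pct_intraswitch_duplication"] = cats["intra_dup"] * scale

    for name, pts in disp_points.items():
        if len(pts) >= 2:
            pos = np.array([p for p, _ in pts], dtype=float)
            w = np.array([wt for _, wt in pts])
            mean = np.average(pos, weights=w)
            out[f"break_dispersion_{name}"] = float(
                np.sqrt(np.average((pos - mean) ** 2, weights=w)))
        else:
            out[f"break_dispersion_{name}"] = np.nan

    out["breakpoint_spread"] = (float(cluster_stats["spread"].mean())
                                if len(cluster_stats) else np.nan)
    out["frag_length_mean"] = (float(cluster_stats["consensus_len"].mean())
                               if len(cluster_stats) else np.nan)
    out["frag_length_std"] = (float(cluster_stats["consensus_len"].std(ddof=0))
                              if len(cluster_stats) else np.nan)
    out["frag_gc"] = (float(cluster_stats["gc"].mean())
                      if len(cluster_stats) else np.nan)
    return out


# ---------------------------------------------------------------------------
# sequence context scores
# ---------------------------------------------------------------------------

def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest exact common substring (classic DP)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def _bin_seq(reduced_ref: str, b: int, bin_size: int) -> str:
    return reduced_ref[b * bin_size:(b + 1) * bin_size]


def _three_mer_entropy(seq: str) -> float:
    counts: dict[str, int] = {}
    for i in range(len(seq) - 2):
        k = seq[i:i + 3]
        counts[k] = counts.get(k, 0) + 1
    if not counts:
        return 0.0
    p = np.array(list(counts.values()), dtype=float)
    p /= p.sum()
    return float(-(p * np.log(p)).sum())


def context_scores(bm: BreakpointMatrix, cluster_stats: pd.DataFrame,
                   reduced_ref: str, annot: SwitchAnnotation) -> dict:
    """Homology, motif and complexity scores of breakpoint surroundings.

    Bin homology is the longest exact common substring between the 50 nt
    bin sequences (forward) or between donor bin and reverse-complemented
    acceptor bin (reverse), normalized by bin length; scores are the
    breakpoint-frequency-weighted means over occupied bins.  Motif scores
    weight the 1D donor/acceptor breakpoint frequencies by per-base motif
    occurrence; complexity is the Shannon entropy of bin 3-mer frequencies.
    """
    out: dict[str, float] = {}
    bs = bm.bin_size
    di, ai = np.nonzero(bm.matrix)
    w = bm.matrix[di, ai]
    total = w.sum()
    if total == 0:
        for k in ("homology_score_fw", "homology_score_rv", "donor_complexity",
                  "acceptor_complexity"):
            out[k] = np.nan
        for side in ("donor", "acceptor"):
            for m in ("W", "S", "WRCY", "RGYW"):
                out[f"{side}_score_{m}"] = np.nan
    else:
        hom_fw = np.array([longest_common_substring(_bin_seq(reduced_ref, d, bs),
                                                    _bin_seq(reduced_ref, a, bs))
                           for d, a in zip(di, ai)]) / bs
        hom_rv = np.array([longest_common_substring(
            _bin_seq(reduced_ref, d, bs), revcomp(_bin_seq(reduced_ref, a, bs)))
            for d, a in zip(di, ai)]) / bs
        out["homology_score_fw"] = float((w * hom_fw).sum() / total)
        out["homology_score_rv"] = float((w * hom_rv).sum() / total)

        donor_freq = bm.matrix.sum(axis=1)
        acc_freq = bm.matrix.sum(axis=0)
        for side, freq in (("donor", donor_freq), ("acceptor", acc_freq)):
            bins = np.nonzero(freq)[0]
            fw = freq[bins]
            seqs = [_bin_seq(reduced_ref, b, bs) for b in bins]
            for m in ("W", "S", "WRCY", "RGYW"):
                occ = np.array([len(MOTIFS[m].findall(s)) / max(len(s), 1)
                                for s in seqs])
                out[f"{side}_score_{m}"] = float((fw * occ).sum() / fw.sum())
            ent = np.array([_three_mer_entropy(s) for s in seqs])
            out[f"{side}_complexity"] = float((fw * ent).sum() / fw.sum())
    # spec keeps one motif per side in the manifest for the hotspot classes
    out.pop("donor_score_RGYW", None)
    out.pop("acceptor_score_WRCY", None)

    # read-level junction statistics, averaged cluster-first
    for col in ("homology", "homology_1_3", "homology_gt6", "untemplated",
                "blunt_fraction", "homology_inserts", "untemplated_inserts"):
        vals = cluster_stats[col] if col in cluster_stats else pd.Series(dtype=float)
        vals = vals.dropna()
        out[col] = float(vals.mean()) if len(vals) else np.nan
    return out


# ---------------------------------------------------------------------------
# isotype composition and assembly
# ---------------------------------------------------------------------------

def isotype_composition(cluster_stats: pd.DataFrame,
                        annot: SwitchAnnotation) -> dict:
    """Fraction of retained clusters per isotype (cluster level, in %)."""
    out = {}
    n = len(cluster_stats)
    counts = cluster_stats["isotype"].value_counts() if n else pd.Series(dtype=int)
    for r in annot:
        if r.name == "SM":
            continue
        out[f"pct_clusters_{r.name}"] = (100.0 * counts.get(r.name, 0) / n
                                         if n else np.nan)
    for cls in ("SG", "SA"):
        members = [r.name for r in annot if REGION_CLASS[r.name] == cls]
        out[f"pct_clusters_{cls}"] = (float(sum(out[f"pct_clusters_{m}"]
                                                for m in members)) if n else np.nan)
    return out


def summarize_sample(
    cluster_stats: pd.DataFrame,
    bm: BreakpointMatrix,
    diversity: dict,
    reduced_ref: str,
    annot: SwitchAnnotation,
) -> pd.Series:
    """Assemble the 68-feature vector (manifest order); undefined -> NaN."""
    values: dict[str, float] = {}
    n = len(cluster_stats)
    for col in ("pct_reads_inverted", "pct_reads_duplicated", "insert_frequency",
                "inversion_size", "duplication_size"):
        vals = cluster_stats[col].dropna() if n else pd.Series(dtype=float)
        values[col] = float(vals.mean()) if len(vals) else np.nan
    values.update(context_scores(bm, cluster_stats, reduced_ref, annot))
    values.update(breakpoint_statistics(bm, annot, cluster_stats))
    values.update({k: v for k, v in diversity.items() if k != "downsampled"})
    values.update(isotype_composition(cluster_stats, annot))
    manifest = load_manifest()
    vec = pd.Series({f: values.get(f, np.nan) for f in manifest["feature"]},
                    name="value")
    vec.index.name = "feature"
    return vec


def feature_frame(vec: pd.Series) -> pd.DataFrame:
    """Long-format (feature, category, value) table for one sample."""
    manifest = load_manifest()
    return manifest.assign(value=vec.reindex(manifest["feature"]).to_numpy())
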