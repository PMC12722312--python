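"""Single-nucleotide variant calling from the pseudo-MSA and rank-2
weighted-NMF haplotyping.

Candidate positions are found by a chi-square goodness-of-fit test of the
observed base counts against the expectation from the reference base plus
the platform error rate.  Candidates are filtered for gap proximity, for a
minor allele frequency compatible with sequencing error (Poisson model),
for strand bias, and for lack of cluster support.  Surviving variants are
used to group read clusters into two putative haplotypes (alleles) via
weighted non-negative matrix factorization of cluster-wise alternate-allele
counts (weights = per-position cluster coverage); a variant with allele
frequency > 0.6 in both components is a homozygous germline variant, in
exactly one component heterozygous germline, otherwise likely somatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
import scipy.sparse as sp
from scipy import stats

from .annotation import SwitchAnnotation
from .cluster import ClusterSet
from .config import VariantConfig
from .msa import MSAMatrix

BASES = "NACGT"  # code -> base (code 0 = gap)
PURINES = {"A", "G"}


@dataclass
class VariantCall:
    pos: int  # reduced coordinate
    ref: str
    alt: str
    counts: np.ndarray  # per base A,C,G,T
    alt_plus: int
    alt_minus: int
    depth_plus: int
    depth_minus: int
    af: float
    p_value: float
    flags: list[str] = field(default_factory=list)
    known: bool = False
    classification: str = "unclassified"

    @property
    def passed(self) -> bool:
        return not self.flags

    @property
    def is_transition(self) -> bool:
        return (self.ref in PURINES) == (self.alt in PURINES)


def _base_counts(msa: MSAMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position base counts (4 x n_bases) overall and split by strand."""
    mat = msa.matrix
    cov = mat.copy()
    cov.data = cov.data // 10
    base = mat.copy()
    base.data = np.where(cov.data != 0, mat.data % 10, 0)
    counts = np.zeros((4, msa.n_bases))
    plus = np.zeros((4, msa.n_bases))
    for code in range(1, 5):
        m = base.copy()
        m.data = (m.data == code).astype(np.int32)
        counts[code - 1] = np.asarray(m.sum(axis=0)).ravel()
        p = base.copy()
        p.data = ((p.data == code) & (cov.data > 0)).astype(np.int32)
        plus[code - 1] = np.asarray(p.sum(axis=0)).ravel()
    return counts, plus, counts - plus


def call_candidates(msa: MSAMatrix, reduced_ref: str, error_rate: float = 0.03,
                    cfg: VariantConfig | None = None) -> list[VariantCall]:
    """Chi-square test of observed base counts vs reference + error model.

    The candidate threshold is Bonferroni-corrected over the number of
    tested positions; a candidate needs a non-reference base in excess of
    its expectation.  Zero-depth positions are skipped.
    """
    cfg = cfg or VariantConfig()
    counts, plus, minus = _base_counts(msa)
    depth = counts.sum(axis=0)
    testable = [i for i in np.nonzero(depth)[0] if reduced_ref[i] in "ACGT"]
    threshold = cfg.alpha / max(len(testable), 1)
    out = []
    for i in testable:
        ref = reduced_ref[i]
        ref_code = BASES.index(ref) - 1
        expected = np.full(4, error_rate / 3) * depth[i]
        expected[ref_code] = (1 - error_rate) * depth[i]
        stat = ((counts[:, i] - expected) ** 2 / np.maximum(expected, 1e-12)).sum()
        p = float(stats.chi2.sf(stat, df=3))
        if p >= threshold:
            continue
        excess = counts[:, i] - expected
        excess[ref_code] = -np.inf
        alt_code = int(np.argmax(excess))
        if counts[alt_code, i] <= expected[alt_code]:
            continue
        out.append(VariantCall(
            pos=int(i), ref=ref, alt=BASES[alt_code + 1],
            counts=counts[:, i].copy(),
            alt_plus=int(plus[alt_code, i]), alt_minus=int(minus[alt_code, i]),
            depth_plus=int(plus[:, i].sum()), depth_minus=int(minus[:, i].sum()),
            af=float(counts[alt_code, i] / depth[i]), p_value=p))
    return out


def _gap_fraction(msa: MSAMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-position counts of reads spanning and reads gapped (zero coverage
    inside their covered span)."""
    cov = msa.coverage()
    span = np.zeros(msa.n_bases + 1)
    covered = np.zeros(msa.n_bases)
    indptr, indices = cov.indptr, cov.indices
    for i in range(cov.shape[0]):
        cols = indices[indptr[i]:indptr[i + 1]]
        if len(cols) == 0:
            continue
        span[cols[0]] += 1
        span[cols[-1] + 1] -= 1
        covered[cols] += 1
    span = np.cumsum(span)[:-1]
    return span, span - covered


def filter_variants(cands: list[VariantCall], msa: MSAMatrix, cs: ClusterSet,
                    error_rate: float = 0.03,
                    cfg: VariantConfig | None = None) -> list[VariantCall]:
    """Apply the exclusion rules; all triggered flags are recorded.

    A variant passes only with an empty flag list.  Cluster support uses
    retained clusters with >= ``cfg.min_cluster_reads`` reads.
    """
    cfg = cfg or VariantConfig()
    span, gapped = _gap_fraction(msa)
    cov = msa.coverage()
    half = cfg.gap_window // 2
    # per-cluster alt/coverage counts at candidate positions
    for v in cands:
        lo, hi = max(0, v.pos - half), min(msa.n_bases, v.pos + half + 1)
        span_w, gap_w = span[lo:hi].sum(), gapped[lo:hi].sum()
        if span_w > 0 and gap_w / span_w > cfg.gap_frequency:
            v.flags.append("gap_proximity")
        depth = v.counts.sum()
        lam = error_rate * depth
        alt_count = v.counts[BASES.index(v.alt) - 1]
        if alt_count <= stats.poisson.ppf(cfg.poisson_quantile, max(lam, 1e-9)):
            v.flags.append("low_minor_af")
        n_plus, n_minus = v.alt_plus, v.alt_minus
        if n_plus + n_minus > 0 and v.depth_plus > 0 and v.depth_minus > 0:
            table = np.array([[n_plus, n_minus],
                              [v.depth_plus - n_plus, v.depth_minus - n_minus]])
            if table.min() >= 0 and table.sum(axis=1).min() > 0:
                _, p, *_ = stats.chi2_contingency(table + 1e-9)
                rel = abs(n_plus - n_minus) / (n_plus + n_minus)
                if p < cfg.strand_bias_p and rel > cfg.strand_bias_diff:
                    v.flags.append("strand_bias")
        # cluster support
        col = msa.matrix[:, v.pos].toarray().ravel()
        covered = (col // 10) != 0
        is_alt = covered & ((col % 10) == BASES.index(v.alt))
        supported = False
        for c in cs.kept:
            if cs.sizes[c] < cfg.min_cluster_reads:
                continue
            in_c = cs.labels == c
            depth_c = (covered & in_c).sum()
            if depth_c and (is_alt & in_c).sum() / depth_c > cfg.min_cluster_af:
                supported = True
                break
        if not supported and v.af < cfg.min_total_af:
            v.flags.append("no_cluster_support")
    return [v for v in cands if v.passed]


def annotate_known(variants: list[VariantCall], catalogue_vcf: str,
                   annot: SwitchAnnotation) -> list[VariantCall]:
    """Mark variants present in a VCF catalogue (position + alleles match).

    The catalogue is in genomic coordinates; reduced positions are mapped
    back through the annotation.
    """
    known: set[tuple[str, int, str, str]] = set()
    with pysam.VariantFile(catalogue_vcf) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                known.add((rec.chrom, rec.pos, rec.ref.upper(), alt.upper()))
    for v in variants:
        try:
            chrom, gpos = annot.from_reduced(v.pos)
        except ValueError:
            v.known = False
            continue
        v.known = (chrom, gpos + 1, v.ref, v.alt) in known
    return variants


# ---------------------------------------------------------------------------
# weighted NMF haplotyping
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeResult:
    assignment: np.ndarray  # per eligible cluster: component 0/1
    cluster_ids: np.ndarray
    component_af: np.ndarray  # 2 x n_variants
    consistency: float
    classifications: list[str]


def _wnmf(V: np.ndarray, W: np.ndarray, rank: int, rng: np.random.Generator,
          max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, float]:
    n, m = V.shape
    A = rng.uniform(0.1, 1.0, size=(n, rank)) * max(V.max(), 1e-6)
    B = rng.uniform(0.1, 1.0, size=(rank, m))
    eps = 1e-12
    prev = np.inf
    for _ in range(max_iter):
        AB = A @ B
        A *= ((W * V) @ B.T) / (((W * AB) @ B.T) + eps)
        AB = A @ B
        B *= (A.T @ (W * V)) / ((A.T @ (W * AB)) + eps)
        loss = float((W * (V - A @ B) ** 2).sum())
        if prev - loss < tol * max(prev, 1e-12):
            break
        prev = loss
    return A, B, loss


def haplotype_wnmf(alt_counts: np.ndarray, coverage: np.ndarray,
                   cluster_sizes: np.ndarray, cluster_ids: np.ndarray,
                   cfg: VariantConfig | None = None) -> HaplotypeResult:
    """Split clusters into two putative alleles and classify variants.

    ``alt_counts``/``coverage``: clusters x variants matrices restricted to
    eligible clusters (retained, >= 10 reads).  The factorization is run
    ``cfg.nmf_restarts`` times; the consistency score is the fraction of
    run pairs producing the identical cluster partition, and the best-loss
    run provides the reported assignment.
    """
    cfg = cfg or VariantConfig()
    n, m = alt_counts.shape
    if n == 0 or m == 0:
        return HaplotypeResult(np.zeros(0, dtype=int), cluster_ids,
                               np.zeros((2, m)), 1.0,
                               _default_classification(alt_counts, coverage, cfg))
    V = alt_counts / np.maximum(coverage, 1)
    W = coverage.astype(float)

    def _comp_af(assign):
        af = np.zeros((2, m))
        for k in (0, 1):
            members = assign == k
            if members.any():
                af[k] = (alt_counts[members].sum(axis=0)
                         / np.maximum(coverage[members].sum(axis=0), 1))
        return af

    partitions, losses, assignments = [], [], []
    for r in range(cfg.nmf_restarts):
        rng = np.random.default_rng(cfg.seed + r)
        A, _B, loss = _wnmf(V, W, 2, rng, cfg.nmf_max_iter, cfg.nmf_tol)
        assign = (A[:, 1] > A[:, 0]).astype(int)
        # canonical form: component of cluster 0 is 0; a degenerate split
        # (both components with the same AF profile) collapses to one group
        if assign[0] == 1:
            assign = 1 - assign
        af = _comp_af(assign)
        if (assign == 1).any() and (assign == 0).any() and \
                np.allclose(af[0], af[1], atol=0.05):
            assign = np.zeros_like(assign)
        partitions.append(tuple(assign))
        losses.append(loss)
        assignments.append(assign)
    counts = pd.Series(partitions).value_counts()
    n_runs = len(partitions)
    same_pairs = sum(c * (c - 1) // 2 for c in counts)
    consistency = (same_pairs / (n_runs * (n_runs - 1) / 2)) if n_runs > 1 else 1.0
    best = assignments[int(np.argmin(losses))]
    comp_af = _comp_af(best)
    classifications = []
    for j in range(m):
        if not (best == 0).any() or not (best == 1).any():
            total_af = alt_counts[:, j].sum() / max(coverage[:, j].sum(), 1)
            classifications.append("hom_germline" if total_af > cfg.germline_af
                                   else "likely_somatic")
            continue
        hi = comp_af[:, j] > cfg.germline_af
        if hi.all():
            classifications.append("hom_germline")
        elif hi.any():
            classifications.append("het_germline")
        else:
            classifications.append("likely_somatic")
    return HaplotypeResult(best, cluster_ids, comp_af, consistency, classifications)


def _default_classification(alt_counts, coverage, cfg) -> list[str]:
    out = []
    for j in range(alt_counts.shape[1]):
        total = coverage[:, j].sum() if coverage.size else 0
        af = alt_counts[:, j].sum() / total if total else 0.0
        out.append("hom_germline" if af > cfg.germline_af else "likely_somatic")
    return out


# ---------------------------------------------------------------------------
# driver + IO
# ---------------------------------------------------------------------------

def call_variants(msa: MSAMatrix, cs: ClusterSet, reduced_ref: str,
                  error_rate: float = 0.03, cfg: VariantConfig | None = None
                  ) -> tuple[list[VariantCall], HaplotypeResult]:
    """Candidates -> filters -> wNMF haplotyping, on one sample."""
    cfg = cfg or VariantConfig()
    cands = call_candidates(msa, reduced_ref, error_rate, cfg)
    passed = filter_variants(cands, msa, cs, error_rate, cfg)
    eligible = [c for c in cs.kept if cs.sizes[c] >= cfg.min_cluster_reads]
    positions = [v.pos for v in passed]
    alt = np.zeros((len(eligible), len(passed)))
    covm = np.zeros((len(eligible), len(passed)))
    for j, v in enumerate(passed):
        col = msa.matrix[:, v.pos].toarray().ravel()
        covered = (col // 10) != 0
        is_alt = covered & ((col % 10) == BASES.index(v.alt))
        for ci, c in enumerate(eligible):
            in_c = cs.labels == c
            alt[ci, j] = (is_alt & in_c).sum()
            covm[ci, j] = (covered & in_c).sum()
    hap = haplotype_wnmf(alt, covm, cs.sizes[eligible] if eligible else np.zeros(0),
                         np.array(eligible), cfg)
    for v, cls in zip(passed, hap.classifications):
        v.classification = cls
    return passed, hap


def variant_summary(variants: list[VariantCall]) -> dict:
    """Sample-level variant statistics (reported alongside the 68 features)."""
    passed = [v for v in variants if v.passed]
    return {
        "n_variants": len(passed),
        "germline_variants": sum(v.classification.endswith("germline")
                                 for v in passed),
        "somatic_variants": sum(v.classification == "likely_somatic"
                                for v in passed),
        "known_variants": sum(v.known for v in passed),
        "transitions": sum(v.is_transition for v in passed),
        "transversions": sum(not v.is_transition for v in passed),
    }


def write_vcf(variants: list[VariantCall], path: str,
              annot: SwitchAnnotation) -> None:
    """Minimal VCF with genomic coordinates and reduced position in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=RPOS,Number=1,Type=Integer,'
                 'Description="Reduced coordinate">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele freq">\n')
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,'
                 'Description="Variant classification">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            try:
                chrom, gpos = annot.from_reduced(v.pos)
            except ValueError:
                continue
            filt = "PASS" if v.passed else ";".join(v.flags)
            fh.write(f"{chrom}\t{gpos + 1}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\t"
                     f"RPOS={v.pos};AF={v.af:.4f};CLASS={v.classification}\n")
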