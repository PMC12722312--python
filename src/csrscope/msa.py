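"""Sparse pseudo-MSA over concatenated switch regions.

Reads are projected onto the reduced coordinate system as rows of a sparse
``n_reads x n_bases`` integer matrix.  Each cell value ``m`` encodes the
consensus nucleotide and a signed per-read coverage:

* ``m % 10``  — nucleotide identity (A=1, C=2, G=3, T=4; gap = 0/absent)
* ``m // 10`` — coverage (+1 normal, >=2 tandem duplication, negative
  inversion), using *floored* division so negative coverage decodes
  consistently (e.g. -8 -> coverage -1, base C).

Gaps in a read's covered span mark junction breaks; stretches of coverage
>1 or <0 are called as duplications / inversions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .alignments import ReadAlignment
from .annotation import SwitchAnnotation
from .simulate import revcomp

BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}
_BASE_LUT = np.zeros(256, dtype=np.int8)
for _b, _c in BASE_CODE.items():
    _BASE_LUT[ord(_b)] = _c
    _BASE_LUT[ord(_b.lower())] = _c


def encode(coverage, base):
    """Cell encoding 10*coverage + base (floored-division semantics)."""
    return 10 * np.asarray(coverage) + np.asarray(base)


def decode(m):
    """Inverse of :func:`encode`: returns (coverage, base)."""
    m = np.asarray(m)
    return m // 10, m % 10


@dataclass
class MSAMatrix:
    matrix: sp.csr_matrix  # int32, n_reads x n_bases
    read_ids: list[str]
    n_bases: int
    annot_checksum: str = ""

    @property
    def n_reads(self) -> int:
        return self.matrix.shape[0]

    def coverage(self) -> sp.csr_matrix:
        """Signed coverage values m // 10 (explicit zeros eliminated)."""
        cov = self.matrix.copy()
        cov.data = cov.data // 10
        cov.eliminate_zeros()
        return cov

    def bases(self) -> sp.csr_matrix:
        """Nucleotide codes m % 10."""
        b = self.matrix.copy()
        b.data = b.data % 10
        return b

    # -- IO: coordinate triplets + JSON sidecar --------------------------

    def save(self, prefix: str) -> None:
        coo = self.matrix.tocoo()
        pd.DataFrame({"row": coo.row, "col": coo.col, "value": coo.data}).to_csv(
            f"{prefix}.triplets.tsv", sep="\t", index=False)
        with open(f"{prefix}.json", "w") as fh:
            json.dump({"read_ids": self.read_ids, "n_bases": self.n_bases,
                       "annot_checksum": self.annot_checksum}, fh)

    @classmethod
    def load(cls, prefix: str) -> "MSAMatrix":
        trip = pd.read_csv(f"{prefix}.triplets.tsv", sep="\t")
        with open(f"{prefix}.json") as fh:
            side = json.load(fh)
        mat = sp.coo_matrix(
            (trip["value"], (trip["row"], trip["col"])),
            shape=(len(side["read_ids"]), side["n_bases"]), dtype=np.int32).tocsr()
        return cls(mat, side["read_ids"], side["n_bases"], side["annot_checksum"])


def annot_checksum(annot: SwitchAnnotation) -> str:
    blob = ";".join(f"{r.name}:{r.chrom}:{r.start}-{r.end}@{r.offset}" for r in annot)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# per-block gapped fill
# ---------------------------------------------------------------------------

def _walk_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def block_fill(read_seq: str, block, genome: dict[str, str]
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-genome-position base codes for one alignment block.

    The read segment is globally re-aligned to its genomic segment (edlib)
    and the alignment path walked; genome positions deleted in the read get
    no entry (they surface as micro-gaps).  Returns (genomic positions,
    base codes) on the + strand.
    """
    seg = read_seq[block.read_start:block.read_end]
    if block.orientation == "-":
        seg = revcomp(seg)
    ref = genome[block.chrom][block.genome_start:block.genome_end]
    res = edlib.align(seg, ref, mode="NW", task="path")
    gpos_list, base_list = [], []
    g = block.genome_start
    r = 0
    seg_codes = _BASE_LUT[np.frombuffer(seg.encode(), dtype=np.uint8)]
    for n, op in _walk_cigar(res["cigar"]):
        if op in "=XM":
            gpos_list.append(np.arange(g, g + n))
            base_list.append(seg_codes[r:r + n])
            g += n
            r += n
        elif op == "I":  # extra read bases, no genome position
            r += n
        elif op == "D":  # genome bases absent from the read
            g += n
    if not gpos_list:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int8)
    return np.concatenate(gpos_list), np.concatenate(base_list)


def build_msa(
    reads: list[ReadAlignment],
    sequences: dict[str, str],
    genome: dict[str, str],
    annot: SwitchAnnotation,
    max_reads: int = 50_000,
    subsample_seed: int = 1,
) -> tuple[MSAMatrix, np.ndarray]:
    """Build the sparse coverage matrix from filtered reads.

    If more than ``max_reads`` reads are given, a deterministic seeded
    subsample is used.  Returns (msa, per-row fraction of aligned bases
    falling outside the annotated regions).
    """
    if len(reads) > max_reads:
        rng = np.random.default_rng(subsample_seed)
        keep = np.sort(rng.choice(len(reads), size=max_reads, replace=False))
        reads = [reads[i] for i in keep]

    rows, cols, vals = [], [], []
    outside_frac = np.zeros(len(reads))
    for row_i, ra in enumerate(reads):
        gpos_all, base_all, cov_all = [], [], []
        for block in ra.blocks:  # read order = left-most block first
            gpos, bases = block_fill(sequences[ra.read_id], block, genome)
            gpos_all.append(gpos)
            base_all.append(bases)
            cov_all.append(np.full(len(gpos), -1 if block.orientation == "-" else 1,
                                   dtype=np.int32))
        gpos = np.concatenate(gpos_all)
        bases = np.concatenate(base_all)
        covs = np.concatenate(cov_all)
        # genomic -> reduced, dropping bases outside the annotation
        rcols = np.full(len(gpos), -1, dtype=np.int64)
        chrom = ra.blocks[0].chrom
        for r in annot:
            if r.chrom != chrom:
                continue
            mask = (gpos >= r.start) & (gpos < r.end)
            rcols[mask] = r.offset + gpos[mask] - r.start
        inside = rcols >= 0
        outside_frac[row_i] = 1.0 - inside.mean() if len(gpos) else 1.0
        rcols, bases, covs = rcols[inside], bases[inside], covs[inside]
        # combine duplicate positions: coverage adds, base from left-most block
        uniq, first_idx = np.unique(rcols, return_index=True)
        cov_sum = np.zeros(len(uniq), dtype=np.int32)
        np.add.at(cov_sum, np.searchsorted(uniq, rcols), covs)
        base_first = bases[first_idx].astype(np.int32)
        rows.append(np.full(len(uniq), row_i, dtype=np.int32))
        cols.append(uniq)
        vals.append(10 * cov_sum + base_first)
    if rows:
        mat = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(reads), annot.n_bases), dtype=np.int32).tocsr()
    else:
        mat = sp.csr_matrix((0, annot.n_bases), dtype=np.int32)
    return MSAMatrix(mat, [ra.read_id for ra in reads], annot.n_bases,
                     annot_checksum(annot)), outside_frac


# ---------------------------------------------------------------------------
# gaps and rearrangements
# ---------------------------------------------------------------------------

def detect_gaps(msa: MSAMatrix) -> pd.DataFrame:
    """Maximal zero-coverage runs strictly inside each read's covered span.

    Returns columns (read_idx, left, right, size) with ``left`` the first
    uncovered and ``right`` the next covered reduced position.
    """
    cov = msa.coverage()
    rows = []
    indptr, indices = cov.indptr, cov.indices
    for i in range(cov.shape[0]):
        cols = indices[indptr[i]:indptr[i + 1]]
        if len(cols) < 2:
            continue
        jumps = np.where(np.diff(cols) > 1)[0]
        for j in jumps:
            left, right = int(cols[j]) + 1, int(cols[j + 1])
            rows.append((i, left, right, right - left))
    return pd.DataFrame(rows, columns=["read_idx", "left", "right", "size"])


def call_rearrangements(msa: MSAMatrix, max_internal_gap: int = 25) -> pd.DataFrame:
    """Duplications (coverage > 1) and inversions (coverage < 0) per read.

    Qualifying positions are merged into one event as long as interruptions
    do not exceed ``max_internal_gap`` nt.  Returns columns
    (read_idx, kind, left, right, size).
    """
    cov = msa.coverage()
    rows = []
    indptr, indices, data = cov.indptr, cov.indices, cov.data
    for i in range(cov.shape[0]):
        cols = indices[indptr[i]:indptr[i + 1]]
        vals = data[indptr[i]:indptr[i + 1]]
        for kind, mask in (("duplication", vals > 1), ("inversion", vals < 0)):
            qcols = cols[mask]
            if len(qcols) == 0:
                continue
            breaks = np.where(np.diff(qcols) > max_internal_gap + 1)[0]
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [len(qcols) - 1]])
            for s, e in zip(starts, ends):
                left, right = int(qcols[s]), int(qcols[e]) + 1
                rows.append((i, kind, left, right, right - left))
    return pd.DataFrame(rows, columns=["read_idx", "kind", "left", "right", "size"])
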