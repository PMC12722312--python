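"""Alignment ingestion, isotype assignment, read filtering, inserts and
breakpoint realignment.

A read aligned across a CSR junction decomposes into ordered alignment
blocks (read interval ↔ genome interval, orientation).  Blocks come either
from a SAM/BAM file (primary + supplementary alignments of one read) or
from the simulator's truth tables.  The isotype is the switch region
overlapped by the right-most block; reads failing any quality rule are
dropped with a reason code.  Around every junction between adjacent blocks,
donor- and acceptor-side sequence is compared with the read to count
microhomologies (bases aligning to both sides) and untemplated nucleotides
(bases aligning to neither) — the repair-pathway signature of the junction.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .annotation import SwitchAnnotation
from .config import FilterConfig
from .simulate import SimTruth

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class AlignmentBlock:
    read_start: int  # 0-based half-open, original read orientation
    read_end: int
    chrom: str
    genome_start: int  # always + strand coordinates
    genome_end: int
    orientation: str  # "+" or "-"

    def __post_init__(self):
        if self.read_start >= self.read_end or self.genome_start >= self.genome_end:
            raise ValueError(f"degenerate block {self}")


@dataclass
class Insert:
    """A templated insert: non-S blocks captured between two S-region blocks."""

    chrom: str
    genome_start: int
    genome_end: int
    orientation: str
    read_start: int
    read_end: int
    left_gap: int  # read-coordinate gap to the flanking S blocks
    right_gap: int
    isotype_context: str | None = None


@dataclass
class BreakRealignment:
    read_id: str
    junction_index: int
    donor_pos: int | None  # reduced coordinates, None if outside annotation
    acceptor_pos: int | None
    n_homology: int
    n_untemplated: int
    is_insert: bool = False  # junction touches an insert block
    inverted: bool = False  # either side maps in reverse orientation
    defined: bool = True


@dataclass
class ReadAlignment:
    read_id: str
    blocks: list[AlignmentBlock]
    read_length: int
    isotype: str | None = None
    inserts: list[Insert] = field(default_factory=list)
    filtered_inserts: list[Insert] = field(default_factory=list)
    realignments: list[BreakRealignment] = field(default_factory=list)
    filter_status: str = "unfiltered"

    def __post_init__(self):
        self.blocks = sorted(self.blocks, key=lambda b: b.read_start)

    @property
    def frac_read_mapped(self) -> float:
        if self.read_length == 0:
            return 0.0
        covered = 0
        prev_end = 0
        for b in self.blocks:
            covered += max(0, b.read_end - max(b.read_start, prev_end))
            prev_end = max(prev_end, b.read_end)
        return covered / self.read_length

    def switch_blocks(self, annot: SwitchAnnotation) -> list[AlignmentBlock]:
        return [b for b in self.blocks
                if annot.overlap_genomic(b.chrom, b.genome_start, b.genome_end)]


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def from_truth(truth: SimTruth, read_lengths: dict[str, int] | None = None
               ) -> list[ReadAlignment]:
    """Turn simulator truth blocks into ReadAlignments (round-trip exact)."""
    out = []
    for read_id, grp in truth.blocks.groupby("read_id", sort=False):
        blocks = [AlignmentBlock(r.read_start, r.read_end, r.chrom,
                                 r.genome_start, r.genome_end, r.orientation)
                  for r in grp.sort_values("read_start").itertuples()]
        length = (read_lengths[read_id] if read_lengths
                  else int(grp["read_end"].max()))
        out.append(ReadAlignment(read_id, blocks, length))
    return out


def parse_sam(path: str) -> list[ReadAlignment]:
    """Collect primary + supplementary alignments per read into ordered blocks.

    Read coordinates are reported in the original read orientation (reverse
    alignments are flipped back); hard clips are honoured so supplementary
    records line up.  Malformed records are skipped with a warning.
    """
    per_read: dict[str, list[AlignmentBlock]] = {}
    lengths: dict[str, int] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            try:
                cigar = rec.cigartuples
                length = rec.infer_read_length()
                # leading/trailing clip lengths (ops 4=S, 5=H)
                lead = 0
                for op, n in cigar:
                    if op in (4, 5):
                        lead += n
                    else:
                        break
                trail = 0
                for op, n in reversed(cigar):
                    if op in (4, 5):
                        trail += n
                    else:
                        break
                qstart, qend = lead, length - trail
                if rec.is_reverse:
                    qstart, qend = length - qend, length - qstart
                block = AlignmentBlock(qstart, qend, rec.reference_name,
                                       rec.reference_start, rec.reference_end,
                                       "-" if rec.is_reverse else "+")
            except (TypeError, ValueError) as exc:
                log.warning("skipping malformed record %s: %s", rec.query_name, exc)
                continue
            per_read.setdefault(rec.query_name, []).append(block)
            lengths[rec.query_name] = max(lengths.get(rec.query_name, 0), length or 0)
    return [ReadAlignment(rid, blocks, lengths[rid])
            for rid, blocks in per_read.items()]


def run_aligner(command_template: str, fastq: str, reference: str, out_sam: str) -> None:
    """Shell out to a user-supplied aligner command.

    ``command_template`` uses ``{fastq}``, ``{reference}`` and ``{out}``
    placeholders, e.g. ``minimap2 -a -x map-ont {reference} {fastq} -o {out}``.
    """
    cmd = command_template.format(fastq=fastq, reference=reference, out=out_sam)
    subprocess.run(shlex.split(cmd), check=True)


# ---------------------------------------------------------------------------
# isotype and filtering
# ---------------------------------------------------------------------------

def assign_isotype(ra: ReadAlignment, annot: SwitchAnnotation) -> str | None:
    """Label of the acceptor S region overlapped by the right-most block.

    Sμ is the donor and never an isotype; ties in overlap go to the
    downstream (locus-later) region.
    """
    if not ra.blocks:
        raise ValueError("read has no alignment blocks")
    rightmost = max(ra.blocks, key=lambda b: b.read_end)
    overlaps = annot.overlap_genomic(rightmost.chrom, rightmost.genome_start,
                                     rightmost.genome_end)
    overlaps = [(r, ov) for r, ov in overlaps if r.name != "SM"]
    if not overlaps:
        return None
    best = max(range(len(overlaps)),
               key=lambda i: (overlaps[i][1], i))  # tie -> later = downstream
    return overlaps[best][0].name


def filter_read(ra: ReadAlignment, meta, cfg: FilterConfig,
                annot: SwitchAnnotation) -> tuple[bool, str]:
    """Apply the read-quality rules in fixed order; first failure wins.

    ``meta`` needs ``has_fw_primer``, ``has_rv_primer`` and
    ``internal_primer`` attributes (or be None to skip primer rules).
    """
    if ra.read_length < cfg.min_read_length:
        return False, "too_short"
    if cfg.require_primers and meta is not None:
        if not (meta.has_fw_primer and meta.has_rv_primer):
            return False, "missing_primer"
        if meta.internal_primer:
            return False, "internal_primer"
    sblocks = ra.switch_blocks(annot)
    if len(sblocks) < 2:
        return False, "few_switch_blocks"
    read_span = sum(b.read_end - b.read_start for b in ra.blocks)
    genome_span = sum(b.genome_end - b.genome_start for b in ra.blocks)
    if genome_span < cfg.genome_span_factor * read_span:
        return False, "genome_span"
    for i, a in enumerate(ra.blocks):
        for b in ra.blocks[i + 1:]:
            if min(a.read_end, b.read_end) - max(a.read_start, b.read_start) \
                    > cfg.max_block_overlap:
                return False, "block_overlap"
    if ra.frac_read_mapped < cfg.min_mapped_fraction:
        return False, "low_mapped_fraction"
    fwd = [b for b in sblocks if b.orientation == "+"]
    for a, b in zip(fwd, fwd[1:]):
        if b.genome_start < a.genome_start:
            return False, "block_order"
    if assign_isotype(ra, annot) is None:
        return False, "no_isotype"
    return True, "pass"


def detect_inserts(ra: ReadAlignment, annot: SwitchAnnotation,
                   min_insert_len: int = 20) -> tuple[list[Insert], list[Insert]]:
    """Maximal runs of non-S blocks flanked by S blocks become inserts.

    Returns (kept, dropped-below-threshold); both are recorded on the read.
    """
    is_switch = [bool(annot.overlap_genomic(b.chrom, b.genome_start, b.genome_end))
                 for b in ra.blocks]
    kept, dropped = [], []
    i = 0
    n = len(ra.blocks)
    while i < n:
        if is_switch[i]:
            i += 1
            continue
        j = i
        while j < n and not is_switch[j]:
            j += 1
        if i > 0 and j < n:  # flanked on both sides
            run = ra.blocks[i:j]
            read_start, read_end = run[0].read_start, run[-1].read_end
            ins = Insert(run[0].chrom, min(b.genome_start for b in run),
                         max(b.genome_end for b in run), run[0].orientation,
                         read_start, read_end,
                         left_gap=read_start - ra.blocks[i - 1].read_end,
                         right_gap=ra.blocks[j].read_start - read_end,
                         isotype_context=ra.isotype)
            (kept if read_end - read_start >= min_insert_len else dropped).append(ins)
        i = j
    return kept, dropped


# ---------------------------------------------------------------------------
# breakpoint realignment
# ---------------------------------------------------------------------------

def _donor_continuation(genome: dict[str, str], block: AlignmentBlock, i: int) -> str | None:
    """i-th genomic base continuing past the donor block in read direction."""
    seq = genome[block.chrom]
    if block.orientation == "+":
        pos = block.genome_end + i
        return seq[pos] if pos < len(seq) else None
    pos = block.genome_start - 1 - i
    return seq[pos].translate(COMPLEMENT) if pos >= 0 else None


def _acceptor_upstream(genome: dict[str, str], block: AlignmentBlock, i: int) -> str | None:
    """i-th genomic base preceding the acceptor block in read direction."""
    seq = genome[block.chrom]
    if block.orientation == "+":
        pos = block.genome_start - 1 - i
        return seq[pos] if pos >= 0 else None
    pos = block.genome_end + i
    return seq[pos].translate(COMPLEMENT) if pos < len(seq) else None


def realign_breakpoint(
    read_seq: str,
    donor: AlignmentBlock,
    acceptor: AlignmentBlock,
    genome: dict[str, str],
    annot: SwitchAnnotation | None = None,
    context: int = 20,
    read_id: str = "",
    junction_index: int = 0,
) -> BreakRealignment:
    """Count homologous and untemplated nucleotides at one junction.

    The donor match is extended rightward past its block end and the
    acceptor match leftward past its block start, gapless, stopping at the
    first mismatch (up to ``context`` bases).  With the unaligned junction
    gap ``g = acceptor.read_start - donor.read_end``, the slack
    ``d_ext + a_ext - g`` is reported as microhomology when positive; when
    negative, the uncovered junction bases are untemplated.  The two are
    mutually exclusive by construction.
    """
    p, q = donor.read_end, acceptor.read_start
    if p <= 0 or q >= len(read_seq) or q < p:
        return BreakRealignment(read_id, junction_index, None, None, 0, 0,
                                defined=False)
    read = read_seq.upper()
    d_ext = 0
    while d_ext < context and p + d_ext < len(read):
        base = _donor_continuation(genome, donor, d_ext)
        if base is None or read[p + d_ext] != base.upper():
            break
        d_ext += 1
    a_ext = 0
    while a_ext < context and q - 1 - a_ext >= 0:
        base = _acceptor_upstream(genome, acceptor, a_ext)
        if base is None or read[q - 1 - a_ext] != base.upper():
            break
        a_ext += 1
    slack = d_ext + a_ext - (q - p)
    n_hom, n_unt = (slack, 0) if slack >= 0 else (0, -slack)

    donor_gpos = donor.genome_end if donor.orientation == "+" else donor.genome_start
    acc_gpos = acceptor.genome_start if acceptor.orientation == "+" else acceptor.genome_end
    donor_pos = acc_pos = None
    if annot is not None:
        try:
            donor_pos = annot.to_reduced(donor.chrom, min(donor_gpos, donor.genome_end - 1))
        except ValueError:
            donor_pos = None
        try:
            acc_pos = annot.to_reduced(acceptor.chrom, min(acc_gpos, acceptor.genome_end - 1))
        except ValueError:
            acc_pos = None
    return BreakRealignment(read_id, junction_index, donor_pos, acc_pos,
                            n_hom, n_unt,
                            inverted="-" in (donor.orientation, acceptor.orientation))


def realign_read(ra: ReadAlignment, read_seq: str, genome: dict[str, str],
                 annot: SwitchAnnotation) -> list[BreakRealignment]:
    """Realign every junction between adjacent blocks of one read."""
    is_switch = [bool(annot.overlap_genomic(b.chrom, b.genome_start, b.genome_end))
                 for b in ra.blocks]
    out = []
    for i, (a, b) in enumerate(zip(ra.blocks, ra.blocks[1:])):
        br = realign_breakpoint(read_seq, a, b, genome, annot,
                                read_id=ra.read_id, junction_index=i)
        br.is_insert = not (is_switch[i] and is_switch[i + 1])
        out.append(br)
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def process_reads(
    alignments: list[ReadAlignment],
    reads: dict[str, str],
    metas: dict[str, object] | None,
    genome: dict[str, str],
    annot: SwitchAnnotation,
    cfg: FilterConfig | None = None,
) -> tuple[list[ReadAlignment], pd.DataFrame]:
    """Assign isotypes, filter, detect inserts and realign breakpoints.

    Returns (passing reads fully annotated, per-read status table).
    """
    cfg = cfg or FilterConfig()
    passed, rows = [], []
    for ra in alignments:
        ra.isotype = assign_isotype(ra, annot)
        meta = metas.get(ra.read_id) if metas else None
        ok, reason = filter_read(ra, meta, cfg, annot)
        ra.filter_status = reason
        if ok:
            ra.inserts, ra.filtered_inserts = detect_inserts(ra, annot,
                                                             cfg.min_insert_len)
            ra.realignments = realign_read(ra, reads[ra.read_id], genome, annot)
            passed.append(ra)
        rows.append({
            "read_id": ra.read_id, "length": ra.read_length,
            "n_blocks": len(ra.blocks), "isotype": ra.isotype,
            "frac_mapped": round(ra.frac_read_mapped, 4),
            "status": reason, "n_inserts": len(ra.inserts),
            "n_junctions": len(ra.realignments),
        })
    return passed, pd.DataFrame(rows)
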