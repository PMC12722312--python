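"""Synthetic class-switch-recombination junction reads with known truth.

A clone is a junction between a donor breakpoint in Sμ and an acceptor
breakpoint in a downstream switch region; its amplicon runs from the forward
primer site upstream of Sμ, through the donor breakpoint, and continues at
the acceptor breakpoint down to the reverse primer site of the acceptor
region.  The simulator samples clones from a junction coordinate table,
emits an average of *k* copies per clone (Poisson by default), applies a
per-base substitution/insertion/deletion error model, and writes FASTQ
records together with truth tables (clone assignment and true alignment
blocks per read) so that every downstream stage can be validated.

Structural aberrations (inversions, tandem duplications, templated inserts)
are expressed as extra template segments, e.g. a reverse-orientation segment
inside a switch region, and propagate into the truth tables.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import SwitchAnnotation, HUMAN_REGION_ORDER
from .config import NoiseModel, NOISE_PRESETS

BASES = np.array(list("ACGT"))
BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(BASE_BYTES):
    _CODE_LUT[_b] = _i


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# synthetic locus
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLocus:
    """A compact synthetic IGH-like locus with primer sites and a decoy contig."""

    genome: dict[str, str]
    annotation: SwitchAnnotation
    fw_primer: str
    fw_start: int  # genomic start of the amplicon (FW primer site)
    rv_primers: dict[str, str]  # acceptor region -> RV primer (read 3' end, revcomp)
    rv_site_end: dict[str, int]  # acceptor region -> genomic end of the amplicon


def synthetic_locus(
    seed: int = 20240917,
    sm_length: int = 3000,
    region_length: int = 1500,
    spacer: int = 400,
    primer_length: int = 24,
    gc_switch: float = 0.65,
    gc_background: float = 0.45,
) -> SyntheticLocus:
    """Build a random GC-rich switch locus on one contig plus a decoy contig.

    Region lengths default to multiples of 500 so the reduced coordinate
    system needs no extra padding.  The forward primer sits 600 nt upstream
    of Sμ; each acceptor region has a reverse primer site 150 nt downstream,
    mirroring a multiplexed junction PCR.
    """
    rng = np.random.default_rng(seed)

    def rand_seq(n: int, gc: float) -> str:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return "".join(rng.choice(BASES, size=n, p=p))

    chrom = "chr14s"
    parts = [rand_seq(800, gc_background)]
    pos = 800
    regions = []
    for name in HUMAN_REGION_ORDER:
        length = sm_length if name == "SM" else region_length
        regions.append((name, chrom, pos, pos + length))
        parts.append(rand_seq(length, gc_switch))
        pos += length
        parts.append(rand_seq(spacer, gc_background))
        pos += spacer
    genome = {chrom: "".join(parts), "decoy": rand_seq(3000, 0.5)}
    annot = SwitchAnnotation(regions)

    fw_start = annot["SM"].start - 600
    fw_primer = genome[chrom][fw_start:fw_start + primer_length]
    rv_primers, rv_site_end = {}, {}
    for r in annot:
        if r.name == "SM":
            continue
        site_end = r.end + 150
        rv_primers[r.name] = revcomp(genome[chrom][site_end - primer_length:site_end])
        rv_site_end[r.name] = site_end
    return SyntheticLocus(genome, annot, fw_primer, fw_start, rv_primers, rv_site_end)


# ---------------------------------------------------------------------------
# clone templates
# ---------------------------------------------------------------------------

@dataclass
class CloneTemplate:
    """An amplifiable junction clone: ordered genomic segments of one read."""

    clone_id: str
    segments: list[tuple[str, int, int, str]]  # (chrom, start, end, orientation)
    isotype: str  # switch-region label of the last segment

    def __post_init__(self):
        if len(self.segments) < 2:
            raise ValueError("a clone template needs at least 2 segments")
        for chrom, start, end, orient in self.segments:
            if start >= end or orient not in "+-":
                raise ValueError(f"bad segment {(chrom, start, end, orient)}")

    def sequence(self, genome: dict[str, str]) -> str:
        out = []
        for chrom, start, end, orient in self.segments:
            if chrom not in genome or start < 0 or end > len(genome[chrom]):
                raise ValueError(f"segment {chrom}:{start}-{end} outside genome bounds")
            seg = genome[chrom][start:end]
            out.append(revcomp(seg) if orient == "-" else seg)
        return "".join(out)


def format_segments(segments: list[tuple[str, int, int, str]]) -> str:
    return ";".join(f"{c}:{s}-{e}:{o}" for c, s, e, o in segments)


def parse_segments(text: str) -> list[tuple[str, int, int, str]]:
    out = []
    for part in text.split(";"):
        chrom, interval, orient = part.rsplit(":", 2)
        start, end = interval.split("-")
        out.append((chrom, int(start), int(end), orient))
    return out


def make_clone_table(
    locus: SyntheticLocus,
    n: int,
    rng: np.random.Generator,
    min_margin: int = 100,
    min_separation: int = 0,
) -> pd.DataFrame:
    """Random junction coordinate table: one row per clone.

    Donor breakpoints are uniform inside Sμ, acceptor breakpoints uniform
    inside a randomly chosen downstream region.  ``min_separation`` enforces
    a minimum pairwise distance between donor breakpoints of different
    clones (useful for constructing well-separated fixtures).
    """
    annot = locus.annotation
    sm = annot["SM"]
    acceptors = [r for r in annot if r.name != "SM"]
    rows, used_donors = [], []
    attempts = 0
    while len(rows) < n:
        attempts += 1
        if attempts > 100 * n + 100:
            raise RuntimeError("cannot place clones with requested separation")
        donor_bp = int(rng.integers(sm.start + min_margin, sm.end - min_margin))
        if min_separation and any(abs(donor_bp - d) < min_separation for d in used_donors):
            continue
        acc = acceptors[int(rng.integers(len(acceptors)))]
        acc_bp = int(rng.integers(acc.start + min_margin, acc.end - min_margin))
        segments = [
            (sm.chrom, locus.fw_start, donor_bp, "+"),
            (acc.chrom, acc_bp, locus.rv_site_end[acc.name], "+"),
        ]
        used_donors.append(donor_bp)
        rows.append({
            "clone_id": f"clone{len(rows):04d}",
            "isotype": acc.name,
            "segments": format_segments(segments),
        })
    return pd.DataFrame(rows)


def make_structural_template(
    locus: SyntheticLocus,
    kind: str,
    rng: np.random.Generator,
    size: int = 300,
    clone_id: str = "sv0",
) -> CloneTemplate:
    """A clone carrying one planted structural event for testing.

    ``kind``: ``inversion`` (a reverse-orientation stretch inside the
    acceptor region), ``duplication`` (a tandemly repeated stretch), or
    ``insert`` (a decoy-contig segment captured between Sμ and acceptor).
    """
    annot = locus.annotation
    sm = annot["SM"]
    acc = annot["SA1"]
    donor_bp = int(rng.integers(sm.start + 100, sm.end - 100))
    acc_bp = int(rng.integers(acc.start + 100, acc.end - 100 - 2 * size))
    head = (sm.chrom, locus.fw_start, donor_bp, "+")
    tail_end = locus.rv_site_end[acc.name]
    if kind == "inversion":
        segments = [
            head,
            (acc.chrom, acc_bp, acc_bp + size, "-"),
            (acc.chrom, acc_bp + size, tail_end, "+"),
        ]
    elif kind == "duplication":
        segments = [
            head,
            (acc.chrom, acc_bp, acc_bp + size, "+"),
            (acc.chrom, acc_bp, tail_end, "+"),
        ]
    elif kind == "insert":
        ins_start = int(rng.integers(100, len(locus.genome["decoy"]) - 100 - size))
        segments = [
            head,
            ("decoy", ins_start, ins_start + size, "+"),
            (acc.chrom, acc_bp, tail_end, "+"),
        ]
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return CloneTemplate(clone_id, segments, acc.name)


def sample_clones(clone_table: pd.DataFrame, n_clones: int, seed: int) -> list[CloneTemplate]:
    """Sample ``n_clones`` rows without replacement, reproducibly."""
    if n_clones > len(clone_table):
        raise ValueError(
            f"requested {n_clones} clones from a table of {len(clone_table)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(clone_table), size=n_clones, replace=False)
    out = []
    for i in idx:
        row = clone_table.iloc[int(i)]
        out.append(CloneTemplate(row["clone_id"], parse_segments(row["segments"]),
                                 row["isotype"]))
    return out


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def _capped_geometric(rng: np.random.Generator, n: int, mean: float, cap: int) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=int)
    return np.minimum(rng.geometric(1.0 / mean, size=n), cap)


def apply_noise(seq: str, noise: NoiseModel, rng: np.random.Generator) -> tuple[str, int, int, int]:
    """Apply the error model; returns (noisy sequence, n_sub, n_ins, n_del).

    Indel rates are per *base*: events start at rate rate/mean_length and
    extend geometrically, so the expected fraction of inserted/deleted bases
    matches the configured rate.
    """
    if noise.substitution_rate == noise.insertion_rate == noise.deletion_rate == 0:
        return seq, 0, 0, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    L = len(arr)

    sub_mask = rng.random(L) < noise.substitution_rate
    n_sub = int(sub_mask.sum())
    if n_sub:
        shifts = rng.integers(1, 4, size=n_sub)
        codes = _CODE_LUT[arr[sub_mask]]
        arr[sub_mask] = BASE_BYTES[(codes + shifts) % 4]

    event_rate_del = noise.deletion_rate / noise.indel_mean_length
    keep = np.ones(L, dtype=bool)
    if event_rate_del > 0:
        starts = np.where(rng.random(L) < event_rate_del)[0]
        lens = _capped_geometric(rng, len(starts), noise.indel_mean_length,
                                 noise.indel_max_length)
        for s, l in zip(starts, lens):
            keep[s:s + l] = False
    n_del = int(L - keep.sum())

    event_rate_ins = noise.insertion_rate / noise.indel_mean_length
    pieces, n_ins = [], 0
    if event_rate_ins > 0:
        starts = np.where(rng.random(L) < event_rate_ins)[0]
        lens = _capped_geometric(rng, len(starts), noise.indel_mean_length,
                                 noise.indel_max_length)
        prev = 0
        for s, l in zip(starts, lens):
            pieces.append(arr[prev:s][keep[prev:s]])
            pieces.append(BASE_BYTES[rng.integers(0, 4, size=l)])
            n_ins += int(l)
            prev = s
        pieces.append(arr[prev:][keep[prev:]])
        out = np.concatenate(pieces)
    else:
        out = arr[keep]
    return out.tobytes().decode(), n_sub, n_ins, n_del


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth for a simulated read set.

    ``reads``: one row per emitted read (read_id, clone_id, isotype, edit
    counts); ``blocks``: one row per true alignment block in noisy-read
    coordinates (read interval, genomic interval, orientation).
    """

    reads: pd.DataFrame
    blocks: pd.DataFrame

    READ_COLUMNS = ["read_id", "clone_id", "isotype", "n_sub", "n_ins", "n_del"]
    BLOCK_COLUMNS = ["read_id", "seg", "read_start", "read_end",
                     "chrom", "genome_start", "genome_end", "orientation"]

    def to_tsv(self, reads_path: str, blocks_path: str) -> None:
        self.reads.to_csv(reads_path, sep="\t", index=False)
        self.blocks.to_csv(blocks_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, reads_path: str, blocks_path: str) -> "SimTruth":
        return cls(pd.read_csv(reads_path, sep="\t"),
                   pd.read_csv(blocks_path, sep="\t"))


def simulate_reads(
    templates: list[CloneTemplate],
    k_mean: float,
    distribution: str = "poisson",
    noise: NoiseModel | str | None = None,
    genome: dict[str, str] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[SeqRecord], SimTruth]:
    """Emit noisy reads for each template with ~``k_mean`` copies per clone.

    Noise is applied independently per template segment so that the truth
    blocks carry exact noisy-read coordinates.
    """
    if k_mean <= 0:
        raise ValueError("k_mean must be positive")
    if distribution not in ("poisson", "fixed"):
        raise ValueError(f"unknown copy-number distribution {distribution!r}")
    if isinstance(noise, str):
        noise = NOISE_PRESETS[noise]
    if noise is None:
        noise = NOISE_PRESETS["clean"]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if distribution == "poisson":
        copies = rng.poisson(k_mean, size=len(templates))
    else:
        copies = np.full(len(templates), int(round(k_mean)))

    qual = ord(noise.quality_char) - 33
    records, read_rows, block_rows = [], [], []
    for template, n_copies in zip(templates, copies):
        seg_seqs = []
        for chrom, start, end, orient in template.segments:
            if chrom not in genome or start < 0 or end > len(genome[chrom]):
                raise ValueError(f"segment {chrom}:{start}-{end} outside genome bounds")
            seg = genome[chrom][start:end]
            seg_seqs.append(revcomp(seg) if orient == "-" else seg)
        for copy_i in range(n_copies):
            read_id = f"{template.clone_id}_copy{copy_i:04d}"
            cursor, pieces = 0, []
            tot = [0, 0, 0]
            for seg_idx, (clean, seg) in enumerate(zip(seg_seqs, template.segments)):
                noisy, n_sub, n_ins, n_del = apply_noise(clean, noise, rng)
                pieces.append(noisy)
                block_rows.append((read_id, seg_idx, cursor, cursor + len(noisy),
                                   seg[0], seg[1], seg[2], seg[3]))
                cursor += len(noisy)
                tot[0] += n_sub; tot[1] += n_ins; tot[2] += n_del
            seq = "".join(pieces)
            rec = SeqRecord(Seq(seq), id=read_id, description="")
            rec.letter_annotations["phred_quality"] = [qual] * len(seq)
            records.append(rec)
            read_rows.append((read_id, template.clone_id, template.isotype, *tot))
    truth = SimTruth(
        pd.DataFrame(read_rows, columns=SimTruth.READ_COLUMNS),
        pd.DataFrame(block_rows, columns=SimTruth.BLOCK_COLUMNS),
    )
    return records, truth


def attach_adapters(
    records: list[SeqRecord],
    barcode: str = "",
    fw_primer: str = "",
    rv_primer: str = "",
    truth: SimTruth | None = None,
    concatemer: bool = False,
) -> tuple[list[SeqRecord], SimTruth | None]:
    """Decorate reads with barcode/primer adapters for demultiplexing tests.

    Each read becomes ``barcode + fw_primer + read + revcomp(rv_primer)``.
    With ``concatemer=True``, consecutive pairs of decorated reads are joined
    into single records (truth blocks are not adjusted for concatemers).
    With all adapter sequences empty this is a no-op.
    """
    prefix = barcode + fw_primer
    suffix = revcomp(rv_primer) if rv_primer else ""
    if not prefix and not suffix and not concatemer:
        return records, truth
    out = []
    for rec in records:
        seq = prefix + str(rec.seq) + suffix
        new = SeqRecord(Seq(seq), id=rec.id, description=rec.description)
        q = rec.letter_annotations.get("phred_quality")
        fill = q[0] if q else 30
        new.letter_annotations["phred_quality"] = (
            [fill] * len(prefix) + list(q or [fill] * (len(seq) - len(prefix) - len(suffix)))
            + [fill] * len(suffix))
        out.append(new)
    if truth is not None and prefix:
        truth = SimTruth(truth.reads.copy(), truth.blocks.copy())
        truth.blocks["read_start"] += len(prefix)
        truth.blocks["read_end"] += len(prefix)
    if concatemer:
        joined = []
        for i in range(0, len(out) - 1, 2):
            a, b = out[i], out[i + 1]
            rec = SeqRecord(a.seq + b.seq, id=f"{a.id}__{b.id}", description="")
            rec.letter_annotations["phred_quality"] = (
                a.letter_annotations["phred_quality"]
                + b.letter_annotations["phred_quality"])
            joined.append(rec)
        if len(out) % 2:
            joined.append(out[-1])
        out = joined
    return out, truth


def write_fastq(records: list[SeqRecord], path: str) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path: str) -> list[SeqRecord]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return list(SeqIO.parse(fh, "fastq"))
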