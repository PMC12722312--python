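"""Barcode/primer detection, sample assignment and concatemer splitting.

Raw long reads are scanned for short motifs (sample barcodes, forward and
reverse amplification primers) with a banded edit-distance search in both
orientations.  Reads are assigned to samples from barcodes found near the
read ends; motif hits wholly more than ``end_distance`` (100 nt) from both
ends count as internal.  Chimeric reads produced by ligation of two library
molecules show up as clusters of motif hits in close proximity inside the
read and can be split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from .config import DemuxConfig
from .simulate import revcomp


@dataclass
class MotifHit:
    motif_id: str
    read_start: int  # 0-based half-open read coordinates
    read_end: int
    orientation: str  # "+" or "-"
    identity: float

    def overlaps(self, other: "MotifHit") -> bool:
        return self.read_start < other.read_end and other.read_start < self.read_end


@dataclass
class ReadMeta:
    read_id: str
    length: int
    mean_quality: float
    sample: str | None = None
    end_barcodes: list[str] = field(default_factory=list)
    internal_barcode: bool = False
    has_fw_primer: bool = False
    has_rv_primer: bool = False
    internal_primer: bool = False
    split: bool = False


def _search_motif(seq: str, motif_id: str, motif: str, orientation: str,
                  max_edits: int) -> list[MotifHit]:
    """All non-overlapping matches of one motif in one orientation.

    edlib reports only best-scoring locations per call, so found intervals
    are masked out and the search repeats until nothing under the edit
    threshold remains.
    """
    query = motif if orientation == "+" else revcomp(motif)
    target = list(seq)
    hits = []
    for _ in range(50):  # safety bound
        res = edlib.align(query, "".join(target), mode="HW", task="locations",
                          k=max_edits)
        if res["editDistance"] < 0 or not res["locations"]:
            break
        identity = 1.0 - res["editDistance"] / len(motif)
        for start, end in res["locations"]:
            end = end + 1  # edlib locations are inclusive
            hits.append(MotifHit(motif_id, start, end, orientation, identity))
            target[start:end] = "#" * (end - start)
    return hits


def _merge_overlapping(hits: list[MotifHit]) -> list[MotifHit]:
    """Merge overlapping hits of the same motif, keeping the best identity."""
    merged: list[MotifHit] = []
    for hit in sorted(hits, key=lambda h: (h.motif_id, h.read_start)):
        if merged and merged[-1].motif_id == hit.motif_id and merged[-1].overlaps(hit):
            if hit.identity > merged[-1].identity:
                hit.read_start = min(hit.read_start, merged[-1].read_start)
                hit.read_end = max(hit.read_end, merged[-1].read_end)
                merged[-1] = hit
            else:
                merged[-1].read_end = max(merged[-1].read_end, hit.read_end)
        else:
            merged.append(hit)
    return sorted(merged, key=lambda h: (h.read_start, h.read_end, h.motif_id))


def scan_motifs(seq: str, motifs: dict[str, str], min_identity: float = 0.75,
                min_length_fraction: float = 0.7) -> list[MotifHit]:
    """Locate all motif occurrences (either orientation) above identity cutoff.

    The edit-distance band is ``len(motif) * (1 - min_identity)``; matches
    are full-motif infix alignments, so motifs truncated below
    ``min_length_fraction`` of their length at read ends are not reported.
    """
    if not motifs:
        raise ValueError("motif set must not be empty")
    if not seq:
        return []
    hits = []
    for motif_id, motif in motifs.items():
        max_edits = int(len(motif) * (1.0 - min_identity))
        for orientation in "+-":
            hits.extend(_search_motif(seq, motif_id, motif, orientation, max_edits))
    return _merge_overlapping(hits)


def _is_internal(hit: MotifHit, read_len: int, end_distance: int) -> bool:
    # strictly more than end_distance away from both ends
    return hit.read_start > end_distance and hit.read_end < read_len - end_distance


def assign_sample(hits: list[MotifHit], sample_sheet: dict[str, str], read_len: int,
                  end_distance: int = 100) -> tuple[str | None, list[str], bool]:
    """Pick the sample from end-located barcode hits.

    Returns (sample or None, end-barcode ids, internal-barcode flag).
    Distinct barcodes at the two ends conflict and leave the read unassigned.
    """
    if not sample_sheet:
        raise ValueError("sample sheet must not be empty")
    bc_hits = [h for h in hits if h.motif_id in sample_sheet]
    end_ids = sorted({h.motif_id for h in bc_hits
                      if not _is_internal(h, read_len, end_distance)})
    internal = any(_is_internal(h, read_len, end_distance) for h in bc_hits)
    samples = {sample_sheet[b] for b in end_ids}
    sample = samples.pop() if len(samples) == 1 else None
    return sample, end_ids, internal


def split_concatemers(seq: str, hits: list[MotifHit], cfg: DemuxConfig | None = None
                      ) -> list[tuple[int, int]]:
    """Split points for presumably concatenated reads.

    Motif hits are grouped into clusters of close proximity; an internal
    cluster with at least two hits marks a ligation junction.  The split
    point is the midpoint of the gap between a reverse-oriented hit and the
    following forward-oriented hit (the inward-facing adapter boundary), or
    the widest gap inside the cluster if no such transition exists.

    Returns half-open subread intervals covering the read; subreads shorter
    than ``cfg.min_subread_length`` are dropped.
    """
    cfg = cfg or DemuxConfig()
    read_len = len(seq)
    ordered = sorted(hits, key=lambda h: h.read_start)
    clusters: list[list[MotifHit]] = []
    for hit in ordered:
        if clusters and hit.read_start - clusters[-1][-1].read_end <= cfg.cluster_distance:
            clusters[-1].append(hit)
        else:
            clusters.append([hit])
    split_points = []
    for cluster in clusters:
        if len(cluster) < 2:
            continue
        span_start, span_end = cluster[0].read_start, cluster[-1].read_end
        if span_start <= cfg.end_distance or span_end >= read_len - cfg.end_distance:
            continue  # end cluster, not a junction
        point = None
        widest, widest_gap = None, -1
        for a, b in zip(cluster, cluster[1:]):
            gap = b.read_start - a.read_end
            if gap > widest_gap:
                widest_gap, widest = gap, (a.read_end + max(b.read_start, a.read_end)) // 2
            if a.orientation == "-" and b.orientation == "+" and point is None:
                point = (a.read_end + max(b.read_start, a.read_end)) // 2
        split_points.append(point if point is not None else widest)
    bounds = [0] + sorted(split_points) + [read_len]
    intervals = [(s, e) for s, e in zip(bounds, bounds[1:])
                 if e - s >= cfg.min_subread_length]
    return intervals or [(0, read_len)]


def demux_reads(
    records: list[SeqRecord],
    sample_sheet: pd.DataFrame,
    primers: dict[str, str],
    cfg: DemuxConfig | None = None,
    split: bool = False,
) -> tuple[dict[str, list[SeqRecord]], pd.DataFrame, list[ReadMeta]]:
    """Distribute reads into per-sample bins and collect per-read metadata.

    ``sample_sheet`` needs columns ``sample`` and ``barcode_seq``; ``primers``
    maps primer names (forward names starting with ``FW``) to sequences.
    Returns (sample -> records incl. "unassigned", metadata table, metas).
    """
    cfg = cfg or DemuxConfig()
    barcodes = {f"bc_{row.sample}": row.barcode_seq for row in sample_sheet.itertuples()}
    bc_to_sample = {f"bc_{row.sample}": row.sample for row in sample_sheet.itertuples()}
    motifs = {**barcodes, **primers}
    fw_names = {p for p in primers if p.upper().startswith("FW")}

    buckets: dict[str, list[SeqRecord]] = {}
    metas: list[ReadMeta] = []
    for rec in records:
        seq = str(rec.seq)
        hits = scan_motifs(seq, motifs, cfg.min_identity, cfg.min_length_fraction)
        if split:
            intervals = split_concatemers(seq, hits, cfg)
        else:
            intervals = [(0, len(seq))]
        was_split = len(intervals) > 1
        for part_i, (s, e) in enumerate(intervals):
            sub_id = f"{rec.id}_part{part_i}" if was_split else rec.id
            sub_hits = [MotifHit(h.motif_id, max(h.read_start, s) - s,
                                 min(h.read_end, e) - s, h.orientation, h.identity)
                        for h in hits if h.read_start < e and h.read_end > s]
            sub_len = e - s
            sample, end_bcs, internal_bc = assign_sample(
                sub_hits, bc_to_sample, sub_len, cfg.end_distance)
            primer_hits = [h for h in sub_hits if h.motif_id in primers]
            end_primers = [h for h in primer_hits
                           if not _is_internal(h, sub_len, cfg.end_distance)]
            has_fw = any(h.motif_id in fw_names for h in end_primers)
            has_rv = any(h.motif_id not in fw_names for h in end_primers)
            internal_primer = any(_is_internal(h, sub_len, cfg.end_distance)
                                  and h.identity >= cfg.internal_min_identity
                                  for h in primer_hits)
            quals = rec.letter_annotations.get("phred_quality")
            mean_q = float(np.mean(quals[s:e])) if quals else float("nan")
            meta = ReadMeta(sub_id, sub_len, mean_q, sample, end_bcs, internal_bc,
                            has_fw, has_rv, internal_primer, was_split)
            metas.append(meta)
            sub = rec[s:e]
            sub.id, sub.description = sub_id, ""
            buckets.setdefault(sample or "unassigned", []).append(sub)
    table = pd.DataFrame([vars(m) | {"end_barcodes": ",".join(m.end_barcodes)}
                          for m in metas])
    return buckets, table, metas
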