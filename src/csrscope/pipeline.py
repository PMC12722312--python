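"""End-to-end per-sample pipeline: reads -> clusters -> feature vector."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import alignments as aln
from . import cluster as clu
from . import features as feat
from . import msa as msamod
from . import variants as var
from .annotation import SwitchAnnotation, reduced_reference
from .config import PipelineConfig, NOISE_PRESETS
from .demux import ReadMeta, scan_motifs, _is_internal
from .simulate import (SimTruth, SyntheticLocus, make_clone_table,
                       sample_clones, simulate_reads)

log = logging.getLogger(__name__)


@dataclass
class SampleResult:
    """Everything the pipeline derives from one sample."""

    features: pd.Series  # the 68-feature vector
    msa: msamod.MSAMatrix
    cluster_set: clu.ClusterSet
    linkage: np.ndarray
    gaps: pd.DataFrame
    rearrangements: pd.DataFrame
    cluster_stats: pd.DataFrame
    breakpoints: feat.BreakpointMatrix
    diversity: dict
    read_table: pd.DataFrame
    variant_stats: dict = field(default_factory=dict)
    variants: list = field(default_factory=list)


def primer_metas(records, primers: dict[str, str], cfg: PipelineConfig
                 ) -> dict[str, ReadMeta]:
    """Scan each read for primer motifs and fill the primer-related flags."""
    fw_names = {p for p in primers if p.upper().startswith("FW")}
    metas = {}
    for rec in records:
        seq = str(rec.seq)
        hits = scan_motifs(seq, primers, cfg.demux.min_identity,
                           cfg.demux.min_length_fraction)
        end_hits = [h for h in hits
                    if not _is_internal(h, len(seq), cfg.demux.end_distance)]
        meta = ReadMeta(rec.id, len(seq), float("nan"))
        meta.has_fw_primer = any(h.motif_id in fw_names for h in end_hits)
        meta.has_rv_primer = any(h.motif_id not in fw_names for h in end_hits)
        meta.internal_primer = any(
            _is_internal(h, len(seq), cfg.demux.end_distance)
            and h.identity >= cfg.demux.internal_min_identity for h in hits)
        metas[rec.id] = meta
    return metas


def run_sample(
    records,
    read_alignments: list[aln.ReadAlignment] | None,
    genome: dict[str, str],
    annot: SwitchAnnotation,
    cfg: PipelineConfig | None = None,
    truth: SimTruth | None = None,
    primers: dict[str, str] | None = None,
    metas: dict[str, ReadMeta] | None = None,
    call_variants: bool = False,
    sparse: bool | None = None,
    seed: int = 0,
) -> SampleResult:
    """Process one sample end to end.

    ``read_alignments`` may be given directly (e.g. from a SAM file);
    otherwise they are taken from simulator ``truth`` blocks.  ``primers``
    enables primer-presence filtering via a motif scan when ``metas`` is
    not supplied.
    """
    cfg = cfg or PipelineConfig()
    sequences = {rec.id: str(rec.seq) for rec in records}
    if read_alignments is None:
        if truth is None:
            raise ValueError("need read_alignments or truth")
        read_alignments = aln.from_truth(
            truth, {rid: len(s) for rid, s in sequences.items()})
    if metas is None and primers:
        metas = primer_metas(records, primers, cfg)
    elif metas is None:
        cfg.filters.require_primers = False

    passed, read_table = aln.process_reads(read_alignments, sequences, metas,
                                           genome, annot, cfg.filters)
    if not passed:
        raise ValueError("no reads passed filtering")
    msa, outside = msamod.build_msa(passed, sequences, genome, annot,
                                    cfg.cluster.max_reads,
                                    cfg.cluster.subsample_seed)
    cleaned = clu.clean_coverage(msa, cfg.cluster.gap_fill_cutoff)
    cs, link = clu.cluster_reads(cleaned, cfg.cluster, sparse=sparse)
    gaps = msamod.detect_gaps(msa)
    rearr = msamod.call_rearrangements(msa)
    reads_by_id = {ra.read_id: ra for ra in passed}
    cluster_stats = feat.compute_cluster_stats(msa, cs, reads_by_id, rearr, annot)
    bm = feat.build_breakpoint_matrix(gaps, cs, rearr, annot,
                                      min_gap=cfg.cluster.gap_fill_cutoff)
    diversity = clu.downsample_diversity(cleaned, cfg.cluster, seed=seed)
    reduced_ref = reduced_reference(annot, genome)
    vec = feat.summarize_sample(cluster_stats, bm, diversity, reduced_ref, annot)

    result = SampleResult(vec, msa, cs, link, gaps, rearr, cluster_stats, bm,
                          diversity, read_table)
    if call_variants:
        noise = NOISE_PRESETS[cfg.noise_preset]
        calls, _hap = var.call_variants(msa, cs, reduced_ref,
                                        error_rate=max(noise.substitution_rate,
                                                       1e-4),
                                        cfg=cfg.variants)
        result.variants = calls
        result.variant_stats = var.variant_summary(calls)
    return result


def simulate_sample(
    locus: SyntheticLocus,
    n_clones: int,
    n_reads: int,
    noise_preset: str = "nanopore-like",
    seed: int = 0,
    clone_table: pd.DataFrame | None = None,
    min_separation: int = 0,
):
    """Simulate one sample: ``n_reads`` reads over ``n_clones`` clones.

    Per-clone copy numbers are Poisson with mean ``n_reads / n_clones``.
    Returns (records, truth, templates).
    """
    rng = np.random.default_rng(seed)
    if clone_table is None:
        clone_table = make_clone_table(locus, n_clones, rng,
                                       min_separation=min_separation)
    templates = sample_clones(clone_table, n_clones, seed)
    records, truth = simulate_reads(templates, n_reads / n_clones, "poisson",
                                    noise_preset, locus.genome, rng)
    return records, truth, templates
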