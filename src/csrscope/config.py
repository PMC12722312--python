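"""Configuration objects and platform presets.

Every numeric threshold used by the pipeline lives here so that presets can be
expressed as plain YAML.  Two platform presets ship with the package:

* ``nanopore-like`` — error rates typical of MinION amplicon reads
  (3% substitutions, 2% insertions, 3% deletions)
* ``hifi-like`` — circular-consensus style rates (0.2% each)

The original error rates were trained on a non-PCR plasmid control; the
presets approximate that regime and are configuration, not constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class NoiseModel:
    """Per-base read error model.

    ``substitution_rate``, ``insertion_rate`` and ``deletion_rate`` are the
    expected per-base fractions of substituted, inserted and deleted bases.
    Indel events have geometric lengths with mean ``indel_mean_length``,
    capped at ``indel_max_length``; the per-base rates are converted to event
    rates internally so the *base-level* rates come out as specified.
    """

    substitution_rate: float = 0.03
    insertion_rate: float = 0.02
    deletion_rate: float = 0.03
    indel_mean_length: float = 1.5
    indel_max_length: int = 20
    quality_char: str = "+"  # constant Q score written to FASTQ (Q10)

    def __post_init__(self):
        rates = (self.substitution_rate, self.insertion_rate, self.deletion_rate)
        if any(r < 0 or r >= 1 for r in rates):
            raise ValueError("noise rates must lie in [0, 1)")
        if sum(rates) >= 1:
            raise ValueError("joint noise rate must be < 1")


NOISE_PRESETS = {
    "nanopore-like": NoiseModel(0.03, 0.02, 0.03, quality_char="+"),
    "hifi-like": NoiseModel(0.002, 0.002, 0.002, quality_char="I"),
    "clean": NoiseModel(0.0, 0.0, 0.0, quality_char="I"),
}

#: gap-affine scores used when a breakpoint needs re-anchoring (match,
#: mismatch, gap open, gap extend); modeled on common long-read mapping
#: defaults for each platform
REALIGN_SCORES = {
    "nanopore-like": (2, -4, -4, -2),
    "hifi-like": (2, -6, -26, -2),
    "clean": (2, -4, -4, -2),
}


@dataclass
class FilterConfig:
    """Read-level filtering thresholds (pipeline processing step)."""

    min_read_length: int = 500
    min_mapped_fraction: float = 0.9
    # genome span < genome_span_factor * read span fails ("much shorter")
    genome_span_factor: float = 0.5
    max_block_overlap: int = 25  # nt, on read or genome
    min_insert_len: int = 20
    require_primers: bool = True


@dataclass
class ClusterConfig:
    gap_fill_cutoff: int = 75  # gaps strictly smaller than this are filled
    cutoff: float = 0.01  # dendrogram cut height (cosine distance)
    min_retained: float = 0.95  # cluster filtering keeps >= this read fraction
    k_neighbors: int = 20  # sparse linkage graph degree
    max_reads: int = 50_000  # MSA row cap; excess subsampled deterministically
    subsample_seed: int = 1
    downsample_n: int = 1000
    downsample_reps: int = 10
    big_clone_fraction: float = 0.01  # "big clones" hold more than this


@dataclass
class VariantConfig:
    alpha: float = 0.05  # candidate threshold, Bonferroni-corrected over n_bases
    gap_window: int = 10
    gap_frequency: float = 0.7
    poisson_quantile: float = 0.999
    strand_bias_p: float = 0.05
    strand_bias_diff: float = 0.125
    min_cluster_reads: int = 10
    min_cluster_af: float = 0.4
    min_total_af: float = 0.4
    germline_af: float = 0.6
    nmf_restarts: int = 100
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-6
    seed: int = 0


@dataclass
class DemuxConfig:
    min_identity: float = 0.75
    min_length_fraction: float = 0.7  # of motif length (short-match scan)
    # internal hits must clear a stricter identity: an unexpected motif deep
    # inside a read needs more evidence than an expected one at the ends
    internal_min_identity: float = 0.85
    end_distance: int = 100  # hits wholly > this from both ends are internal
    cluster_distance: int = 250  # concatemer hit-cluster proximity
    min_subread_length: int = 200


@dataclass
class PipelineConfig:
    noise_preset: str = "nanopore-like"
    demux: DemuxConfig = field(default_factory=DemuxConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    variants: VariantConfig = field(default_factory=VariantConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for section, klass in (("demux", DemuxConfig), ("filters", FilterConfig),
                               ("cluster", ClusterConfig), ("variants", VariantConfig)):
            if section in raw:
                setattr(cfg, section, klass(**raw[section]))
        if "noise_preset" in raw:
            cfg.noise_preset = raw["noise_preset"]
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)
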