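"""Switch-region annotation and the reduced coordinate system.

The immunoglobulin heavy-chain locus carries an ordered series of switch (S)
regions (Sμ, Sγ3, Sγ1, Sα1, Sγ2, Sγ4, Sε, Sα2 in human).  All per-read
bookkeeping downstream of alignment happens in a *reduced* coordinate system
in which the annotated S regions are concatenated and everything between them
is dropped.  Each region is placed at an offset rounded up to the nearest
multiple of 500 so that 50 nt bins never straddle a region boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical human locus order, 5' to 3'
HUMAN_REGION_ORDER = ("SM", "SG3", "SG1", "SA1", "SG2", "SG4", "SE", "SA2")

#: coarse region classes used for break-pair statistics
REGION_CLASS = {
    "SM": "SM",
    "SG3": "SG",
    "SG1": "SG",
    "SG2": "SG",
    "SG4": "SG",
    "SA1": "SA",
    "SA2": "SA",
    "SE": "SE",
}

PAD = 500  # reduced offsets are padded to multiples of this


@dataclass(frozen=True)
class SwitchRegion:
    name: str
    chrom: str
    start: int  # 0-based half-open genomic interval
    end: int
    offset: int = 0  # start position in reduced coordinates

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def reduced_end(self) -> int:
        return self.offset + len(self)


class SwitchAnnotation:
    """Ordered, non-overlapping switch regions with reduced-coordinate offsets."""

    def __init__(self, regions: list[tuple[str, str, int, int]]):
        """``regions``: list of (name, chrom, start, end) in locus order."""
        placed = []
        offset = 0
        prev = None
        for name, chrom, start, end in regions:
            if start >= end:
                raise ValueError(f"empty region {name}")
            if prev is not None and prev.chrom == chrom and start < prev.end:
                raise ValueError(f"regions overlap or are out of order at {name}")
            offset = -(-offset // PAD) * PAD  # round up to multiple of PAD
            region = SwitchRegion(name, chrom, start, end, offset)
            placed.append(region)
            offset = region.reduced_end
            prev = region
        self.regions: list[SwitchRegion] = placed
        self.n_bases: int = -(-offset // PAD) * PAD
        self._by_name = {r.name: r for r in placed}

    # -- lookups ---------------------------------------------------------

    def __getitem__(self, name: str) -> SwitchRegion:
        return self._by_name[name]

    def __iter__(self):
        return iter(self.regions)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def region_of_genomic(self, chrom: str, pos: int) -> SwitchRegion | None:
        for r in self.regions:
            if r.chrom == chrom and r.start <= pos < r.end:
                return r
        return None

    def region_of_reduced(self, rpos: int) -> SwitchRegion | None:
        for r in self.regions:
            if r.offset <= rpos < r.reduced_end:
                return r
        return None

    # -- coordinate mapping ---------------------------------------------

    def to_reduced(self, chrom: str, pos: int) -> int:
        """Map a genomic position inside an annotated region to reduced space."""
        r = self.region_of_genomic(chrom, pos)
        if r is None:
            raise ValueError(f"{chrom}:{pos} is outside all annotated regions")
        return r.offset + (pos - r.start)

    def from_reduced(self, rpos: int) -> tuple[str, int]:
        r = self.region_of_reduced(rpos)
        if r is None:
            raise ValueError(f"reduced position {rpos} falls in inter-region padding")
        return r.chrom, r.start + (rpos - r.offset)

    def overlap_genomic(self, chrom: str, start: int, end: int) -> list[tuple[SwitchRegion, int]]:
        """Regions overlapping a genomic interval, with overlap lengths."""
        out = []
        for r in self.regions:
            if r.chrom != chrom:
                continue
            ov = min(end, r.end) - max(start, r.start)
            if ov > 0:
                out.append((r, ov))
        return out

    # -- IO ---------------------------------------------------------------

    @classmethod
    def from_bed(cls, path: str) -> "SwitchAnnotation":
        """Read a 4-column BED (chrom, start, end, name), 0-based half-open.

        Rows must appear in locus order; the name column gives the region label.
        """
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, name = line.split("\t")[:4]
                rows.append((name, chrom, int(start), int(end)))
        return cls(rows)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for r in self.regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")

    # -- binning -----------------------------------------------------------

    def bin_of(self, rpos: int, bin_size: int = 50) -> int:
        return rpos // bin_size

    def n_bins(self, bin_size: int = 50) -> int:
        return self.n_bases // bin_size


def reduced_reference(annot: SwitchAnnotation, genome: dict[str, str]) -> str:
    """Concatenated reference sequence in reduced coordinates (padding = N)."""
    out = np.full(annot.n_bases, "N", dtype="U1")
    for r in annot:
        seq = genome[r.chrom][r.start:r.end]
        out[r.offset:r.offset + len(r)] = list(seq.upper())
    return "".join(out)
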