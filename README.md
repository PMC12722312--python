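# csrscope

Profiling of class-switch-recombination (CSR) junctions from long-read
amplicon sequencing.

During CSR, B cells rearrange the immunoglobulin heavy-chain locus: a donor
breakpoint in the Sμ switch region is joined to an acceptor breakpoint in a
downstream switch region (Sγ3, Sγ1, Sα1, Sγ2, Sγ4, Sε or Sα2), changing the
antibody isotype. Each junction is a repaired double-strand break, so the
*repertoire* of junctions in a blood sample carries two signals at once:
the clonal diversity of the switched B-cell compartment, and the footprint
of the DNA-repair pathways that formed the joins (blunt ends and short
microhomologies for NHEJ, long microhomologies for MMEJ, untemplated
nucleotides, resections, inversions, duplications, templated inserts).
`csrscope` turns a FASTQ of junction amplicon reads into clone clusters,
breakpoint and repair statistics, and a 68-feature per-sample summary
vector usable for immunodeficiency / DNA-repair classification — and ships
a synthetic read simulator with full ground truth so that every stage is
testable without patient data.

## Method

1. **Demultiplexing** — barcodes and primers are located by banded
   edit-distance search in both orientations; reads are assigned to samples
   from end barcodes, and clusters of internal adapter hits mark
   concatenated reads that can be split.
2. **Alignment processing** — per-read alignment blocks (from SAM/BAM or
   simulator truth) are ordered along the read; the isotype is the switch
   region overlapped by the right-most block. Reads failing quality rules
   (missing/internal primers, <2 switch-region alignments, <90% of the read
   mapped, inconsistent block order, …) are dropped with a reason code.
3. **Pseudo-MSA** — reads are projected into a reduced coordinate system of
   concatenated switch regions as a sparse `n_reads × n_bases` matrix whose
   cell value `m` encodes base identity (`m % 10`: A=1, C=2, G=3, T=4) and
   signed coverage (`m // 10`, floored: +1 normal, ≥2 duplication, negative
   inversion). Gaps in a row are junction breaks; coverage >1 / <0 calls
   duplications / inversions.
4. **Clustering** — UPGMA (average linkage) on cosine distances between
   gap-filled coverage rows, exact (`scipy`) or via an approximate
   k-nearest-neighbour-graph agglomeration for large samples; the
   dendrogram is cut at 0.01 (or at an automatically detected inflection),
   and small/isolated clusters are flagged while keeping ≥95% of reads.
   Clusters are the clones ("switched alleles").
5. **Junction realignment** — around every break, the donor match is
   extended rightward and the acceptor match leftward into the read;
   the overlap is the microhomology, the uncovered junction bases are
   untemplated nucleotides (mutually exclusive by construction).
6. **Variants & haplotypes** — per-position chi-square tests against the
   platform error model call SNVs; filters remove gap-proximal,
   Poisson-compatible, strand-biased and unsupported candidates; rank-2
   weighted NMF of cluster × variant allele counts splits clusters into two
   alleles and classifies variants as hom/het germline or likely somatic.
7. **Features** — 68 named features in 5 categories: structural aberrations
   (5), sequence context (17), breakpoint matrix (28), diversity (9),
   isotype composition (9); the manifest ships as
   `src/csrscope/data/feature_manifest.csv`. Downstream analysis (z-scoring,
   PCA projection of held-out samples, cross-validated ridge classification)
   lives in `csrscope.classify`.

## Worked example

```python
import csrscope

locus = csrscope.synthetic_locus()                     # synthetic IGH-like locus
records, truth, templates = csrscope.simulate_sample(
    locus, n_clones=8, n_reads=200, noise_preset="nanopore-like", seed=2)
primers = {"FW": locus.fw_primer,
           **{f"RV_{k}": v for k, v in locus.rv_primers.items()}}
result = csrscope.run_sample(records, None, locus.genome, locus.annotation,
                             truth=truth, primers=primers, seed=2)
print(result.features[["clusters", "occupancy_top_clone", "cluster_entropy",
                       "pct_direct_switch", "homology", "blunt_fraction"]])
```

prints

```
clusters                 8.000
occupancy_top_clone      0.167
cluster_entropy          2.067
pct_direct_switch      100.000
homology                 1.050
blunt_fraction           0.508
```

All 8 simulated clones are recovered as clusters; the largest clone holds
~1/6 of the reads and the size-distribution entropy (2.07 ≈ ln 8) confirms
an even repertoire. Every break joins Sμ directly to an acceptor region
(100% direct switching — the simulator plants no sequential switches), and
junctions show ~1 nt mean microhomology with half of them blunt, as
expected for random joins in this synthetic locus.

The same pipeline is available from the shell:

```bash
csrscope simulate --n-clones 50 --k-mean 100 --seed 1 --out sim/sample
csrscope demux sim/reads.fastq sample_sheet.csv --split-reads
csrscope run --n-clones 50 --n-reads 2000 --seed 1 --out results/sample
```

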