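# rloopshift

Tools for differential R-loop landscape analysis on strand-specific binned
coverage: HMM peak calling with a high-sensitivity decoding mode,
negative-binomial differential signal testing with gain/loss gene
classification, matched-control Monte-Carlo chromatin enrichment, strand-aware
metagene profiling, replication-fork-directionality (RFD) segmentation, and a
deterministic synthetic-data generator that plants all of the ground truth the
test suite verifies.

## Modules

| module | what it does |
|---|---|
| `rloopshift.core_io` | interval/gene/track data model; BED, BED12, GTF, bedGraph, chrom.sizes I/O; blacklist masking; depth normalization |
| `rloopshift.synthetic_data` | toy genome with planted gaining/losing/mixed/invariant genes, NB coverage noise, chromatin features, Repli-seq, RNAP ChIP and OK-seq tracks |
| `rloopshift.peakcall_hmm` | 2-state NB-emission Baum-Welch fit, Viterbi and posterior decoding, standard + high-sensitivity peak calling, cross-sample union peaks |
| `rloopshift.diff_rloop` | counting in peaks, median-of-ratios size factors, trend-shrunk dispersion, NB GLM Wald test, BH adjustment, gain/loss calls (padj < 0.1, FC > 1.25x or < 0.8x), 5:1 RLG/RLL gene classification |
| `rloopshift.matched_enrichment` | expression/length/compartment-matched control peaks, observed/expected overlap with Monte-Carlo p, nearest-feature distances, Mann-Whitney comparisons, equal-occupancy fold-change bins, Repli-seq phase assignment |
| `rloopshift.profiles` | 40-bin scaled-gene metagenes, TSS/PAS strand-resolved metaplots, LAD-boundary promoter density by orientation, pausing index, TSS ratio profiles |
| `rloopshift.rfd_hmm` | RFD = (C-W)/(C+W) computation and 3-state drift HMM segmentation into ascending (initiation-zone) / descending / flat runs |

## CLI

```sh
rloopshift simulate --dump-defaults           # print the simulation config
rloopshift simulate --out sim/ --seed 7       # write a full synthetic dataset
rloopshift io-validate --format BED6 peaks.bed
rloopshift callpeaks --bedgraph cov.bedgraph --chrom-sizes genome.chrom.sizes \
    --strand + --mode high_sensitivity --out peaks.bed
rloopshift diff --counts counts.tsv \
    --conditions '{"c1":"control","c2":"control","d1":"depleted","d2":"depleted"}' \
    --out results.tsv
rloopshift rfd --crick crick.bedgraph --watson watson.bedgraph \
    --chrom-sizes genome.chrom.sizes --out zones.bed
```

## Conventions

Coordinates are 0-based half-open everywhere (GTF converted on ingestion).
Template strand means the DRIPc signal strand equals the gene's annotated
strand. Masked (blacklisted) bins break HMM chains and are excluded from all
counting. All randomness flows through integer-keyed NumPy generator streams:
a fixed seed reproduces every output byte-for-byte.
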