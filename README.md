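# txciatac

A toolkit for droplet single-cell ATAC-seq data that carries three barcode
levels per read: an 8 bp Tn5 pre-index attached during plate-well
tagmentation, a 16 bp droplet (GEM) bead barcode, and an 8 bp i7 sample
index. Pre-indexing lets multiple nuclei share a droplet and still be
demultiplexed, which is the basis of the loading simulator included here.

## What's inside

| Module | Purpose |
| --- | --- |
| `txciatac.fixtures` | Synthetic, fully ground-truthed inputs at toy scale: whitelists, FASTQ runs, hybrid-genome fragment files, binary matrices with planted doublets, motif/SNV datasets. Deterministic per seed. |
| `txciatac.barcodes` | Tn5/GEM/i7 extraction, Hamming (optionally Levenshtein) error correction against whitelists, combined-barcode construction, sample demultiplexing. |
| `txciatac.fragments` | Proper-pair/MAPQ/nuclear-contig filtering of aligned reads, fragment deduplication by (barcode, chrom, start, end), per-species read counting on a hybrid genome. |
| `txciatac.cells_barnyard` | Cell calling (fixed threshold or 1-D k-means on log10 counts), 90%-purity species classification, cryptic-collision correction (`observed / 2pq`), bead-multiplet barcode merging. |
| `txciatac.qc_metrics` | Fraction of reads in reference regions, TSS enrichment (flanking-window background), Picard-style library-complexity inversion, saturation, QC cell filters. |
| `txciatac.loading_sim` | Poisson droplet-loading model: duplicate-barcode probability, occupancy caps, analytic and Monte Carlo usable-cell counts, loading optimization for molecular vs. cellular hashing. |
| `txciatac.doublets` | Simulated-doublet detection: matrix filtering, log(TF×IDF), doublet simulation, PCA projection + L2 normalization, k-nearest-neighbor scoring, Gaussian-mixture thresholding. |
| `txciatac.snv_motif` | SNV filtering (QUAL/DP/replicate concordance), hotspot assignment, Jaccard set comparison, SNV substitution into peak sequences, PWM scanning with an exact DP score threshold, motif gain/loss association tests, explained-peak counting. |

## CLI

The console script is `txci`:

```bash
# generate a synthetic run and demultiplex it
txci fixtures --kind run --seed 1 --out run/ --n-cells 200
txci demux --r1 run/R1.fastq --r2 run/R2.fastq --i1 run/I1.fastq \
    --i2 run/I2.fastq --whitelist-dir run/ --samplesheet sheet.tsv --out demux/

# fragments from an aligned BAM/SAM with CB tags (or :barcode name suffixes)
txci fragments --bam aligned.bam --out fragments.bed --seed 0

# barnyard collision analysis
txci barnyard --fragments fragments.bed --mix 0.5,0.5 --threshold kmeans \
    --out collision.json

# per-cell QC
txci qc --fragments fragments.bed --dhs peaks.bed --tss tss.tsv --out qc.tsv

# droplet-loading optimization (molecular vs cellular hashing)
txci simulate --strategy molecular --barcodes 96 --grid 1000:1500000:1000

# doublet detection on a MatrixMarket binary matrix
txci doublets --matrix matrix.mtx --barcodes barcodes.tsv --seed 0 --out scores.tsv

# SNV-driven motif gain/loss analysis
txci snvmotif --vcf snvs.vcf --peaks-fasta peaks.fasta --pfms motifs.jaspar \
    --diff-table diff_peaks.tsv --out motif_out/
```

## Conventions

- Coordinates are BED-style 0-based half-open throughout; a fragment spans
  the outermost mate coordinates of a proper pair. No Tn5 +4/-5 shift is
  applied.
- Hybrid-genome contigs are species-prefixed (`hg_...`, `mm_...`); the
  species is the text before the first underscore.
- Barcode correction uses Hamming distance ≤ 2 by default and never breaks
  ties: any observation matching more than one whitelist entry within the
  radius is discarded as ambiguous.
- VCF positions are 1-based; motif hotspot intervals are accepted as 1-based
  closed and converted internally.
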