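# regscreen

A toolkit for the computational stages of multi-condition regulatory-element
screens in T cells (and similar settings):

- **STARR-seq activity calling** (`regscreen.starr`) — fragment length
  filtering (150–800 bp), 50 bp sliding windows at a 25 bp step restricted to
  a union peak set, TMM composition correction on 2,500 bp bins, per-window
  negative-binomial tests of each RNA condition against input DNA, window
  merging (tolerance 0 bp, max merged width 3,000 bp), region-level p-value
  combination via a summit-weighted Holm order statistic (≥3 significant
  windows), and BH classification into active / repressive /
  not-significant at FDR ≤ 0.05.
- **Subset-specificity projection** (`regscreen.specificity`) — per-subset
  weighted effect scores (|log2FC| × −log10 FDR, FDR < 0.01 filter),
  normalization to proportional shares, star-coordinate projection onto
  equally spaced spokes, radial classification (subset-preferred at
  r > 0.85, shared at r < 0.10, with per-class caps), and Fisher-exact
  motif-family enrichment with BH correction.
- **CRISPR tiling library design** (`regscreen.guides`) — NGG PAM scanning,
  specificity filtering (score ≥ 0.2, no GGGGG/TTTT), ATAC-accessibility
  scoring of 20 bp footprints (max over subset means of replicate CPM sums),
  greedy non-overlapping selection (≤10 bp overlap, 10 or 15 guides per
  region), and GC-matched non-targeting controls (5% of the final library,
  no exact or 1-mismatch genome match).
- **Sorted-bin screen analysis** (`regscreen.screen`) — protospacer
  extraction (CROP:20), exact or 1-mismatch counting against the library,
  median-of-ratios size factors, per-guide NB tests of hi-vs-lo bins with
  moderated dispersion, and element-level aggregation (significant when ≥1
  guide passes padj < 0.05; NTCs summarized as the empirical null).
- **Contact-matrix tools** (`regscreen.contacts`) — ICE balancing
  (min-count masking, marginal CV < 1e-6), per-diagonal observed/expected
  normalization, aggregate peak analysis in ±2-bin anchor windows, APA
  ratios between conditions, differential log2 maps, and coarsening.
- **Synthetic data** (`regscreen.simulate`) — generators for genomes,
  peaks, STARR fragment libraries (with a planted short-fragment
  contaminant mode), guide candidates, negative-binomial screen counts and
  distance-decay contact maps with planted loops; every generator is
  seeded and emits its ground truth.

## CLI

Each stage has a console script; all write TSV/BED outputs plus a JSON
manifest echoing every parameter:

```bash
# synthetic dataset with planted truth
regscreen-simulate --seed 1 --genome-length 200000 --n-peaks 50 --depth 100000 --out sim/

# window pipeline: fragments (one BED per sample) + peaks + design TSV (sample, group)
starr-activity --fragments 'sim/*_rep*.bed' --peaks sim/peaks.bed \
    --design design.tsv --window 50 --step 25 --min-len 150 --max-len 800 \
    --merge-tol 0 --max-width 3000 --min-sig-n 3 --fdr 0.05 --out starr/

# star projection from the region-level activity table
specificity --activity starr/activity.tsv --r-specific 0.85 --r-shared 0.10 \
    --cap-specific 2000 --cap-shared 5000 --out spec/

# guide library design
design-guides --genome sim/genome.fa --regions sim/peaks.bed \
    --cap 10 --max-overlap 10 --ntc-fraction 0.05 --seed 7 --out lib/

# sorted-bin screen: reads per sample + library + design (sample, replicate, bin)
screen-test --reads-dir reads/ --library lib/library.tsv \
    --design screen_design.tsv --policy exact --fdr 0.05 --out screen/

# contact matrices (text COO + JSON sidecar), optional perturbed partner and anchors
contact-tools --matrix ctl.coo --perturbed prt.coo --anchors anchors.tsv \
    --flank 2 --out contacts/
```

## Conventions

All genomic coordinates are 0-based half-open (BED). Abutting intervals
overlap by 0 bp. Window tilings are anchored at multiples of the step from
coordinate 0 per chromosome. The NB window/guide tests are contract-level
reimplementations (calibration + recovery), not bit-compatible ports of
edgeR/DESeq2.
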