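# mirpull

Analysis pipeline for **biotin-miRNA pull-down** experiments: identify the
direct target transcripts of a microRNA from four-arm microarray data, and
characterize them by down-regulation, seed-sequence content and pathway
membership.

In a pull-down experiment, cells are transfected with a 3′-biotinylated
miRNA mimic (or a biotinylated control miRNA such as cel-miR-67), and mRNAs
bound to the miRNA are captured on streptavidin beads.  Expression is
measured in four arms — pull-down (PD) and input (whole-lysate) RNA, each
under test- and control-miRNA transfection — with biological replicates,
typically in more than one cell line.  `mirpull` implements the downstream
statistics:

* **Enrichment-ratio hit calling.**  Per probe and replicate the
  enrichment ratio is

  ```
  E = (PD_test / PD_control) / (input_test / input_control)
  ```

  Replicate ratios are averaged, probes are collapsed to genes by their
  mean ratio, and unexpressed genes (no probe above background in any
  sample) are dropped.  Dividing by the input ratio cancels nonspecific
  bead capture of abundant mRNAs and folds target knockdown into the
  denominator.  A log-normal background is fitted to the log2 ratios of
  all expressed genes; genes with `E ≥ 2^(μ + n·σ)` (default n = 1 SD)
  are hits.  Hit sets from different cell lines can be intersected.
* **Down-regulation calling.**  Input-arm fold change
  `FC = input_test / input_control` per gene; genes with mean FC ≤ 0.8
  (a 20% drop, ≈1 SD) are called down-regulated.  Fold-change
  distributions of gene sets are compared via empirical CDFs and the
  two-sample Kolmogorov–Smirnov test.
* **Positional seed-hexamer enrichment.**  Every 6-nt window of the
  mature miRNA (positions 1…L−5) defines a DNA target site (its reverse
  complement); the window at nt 2–7 is the canonical seed.  For each
  window × transcript region (5′UTR/CDS/3′UTR) × gene set, the pooled
  match frequency per kb is compared with a Monte-Carlo null of equally
  sized random gene sets drawn without replacement from the background,
  giving an empirical two-tailed p-value; a Gaussian fit to the null
  extrapolates p beyond the resampling floor.
* **Pathway over-representation.**  Hypergeometric upper-tail
  `P(X ≥ k)` of a query's overlap with each pathway in a GMT collection,
  and a pathway-overlap network (nodes = enriched pathways at p < 0.001,
  edges = shared query genes) exported as SIF + node attributes.
* **Synthetic-data generator.**  Produces probe matrices with planted
  targets (multiplicative pull-down enrichment, input knockdown,
  abundance-coupled bead background, log-normal noise), region sequences
  with planted seed sites, pathway collections with planted
  over-representation, and ground-truth labels — so the entire pipeline
  runs and is testable with no external data.

## Worked example

Simulate a two-cell-line study (2000 genes, 10% true targets with 4-fold
pull-down enrichment and 2-fold knockdown) and run every stage:

```sh
mirpull simulate --outdir demo --n-genes 2000 --seed 42
mirpull run-all --config demo/config.yaml
```

with `demo/config.yaml`:

```yaml
output_dir: demo/out
sequences_fasta: demo/regions.fasta
pathways_gmt: demo/pathways.gmt
cell_lines:
  simA: {matrix: demo/simA.matrix.tsv, design: demo/simA.design.tsv, probe_map: demo/simA.probe_map.tsv}
  simB: {matrix: demo/simB.matrix.tsv, design: demo/simB.design.tsv, probe_map: demo/simB.probe_map.tsv}
hexamer: {n_sims: 2000, rng_seed: 7, regions: [utr3, cds, utr5]}
```

This prints:

```
simA: 204 hits (threshold 2.03-fold), 314 down-regulated
simB: 213 hits (threshold 2.03-fold), 303 down-regulated
hit overlap (both cell lines): 197
```

The 1 SD threshold lands at ≈2-fold and recovers essentially all 200
planted targets in each cell line; 197 genes are hits in both.  The
hexamer grid (`demo/out/hexamer_grid.tsv`) for the overlap set's 3′UTRs
shows the seed window (miRNA nt 2, site `ACTGCC` for hsa-miR-34a-5p) as
the top-enriched window:

```
hexamer_start   site    set_freq_per_kb  bg_freq_per_kb  fold   p_empirical  p_tail
2               ACTGCC  5.39             1.63            3.30   0.001        1.1e-178
1               CTGCCA  1.64             0.59            2.79   0.001        4.4e-64
3               CACTGC  1.45             0.60            2.39   0.001        5.4e-40
```

(windows 1 and 3 overlap planted seed sites by five bases and inherit
partial enrichment, as seed-adjacent windows do in real data).  KS
comparisons confirm that hits are strongly shifted toward low fold
changes (`D = 0.85`, p ≈ 1e-152 vs all expressed genes), and 12–13
pathways per hit set are significant at p < 0.001 — the planted
target-enriched pathways.  `demo/out/manifest.json` records versions,
seeds and thresholds for reproduction.

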