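# Methods

## The measurement model

A biotin-miRNA pull-down experiment measures, for each transcript, four
quantities per biological replicate: pull-down (PD) and input abundance
under test-miRNA and control-miRNA transfection.  The per-probe,
per-replicate enrichment ratio

    E = (PD_test / PD_control) / (input_test / input_control)

is designed so that two nuisance effects cancel: (i) nonspecific
streptavidin-bead capture, which scales with cellular abundance and is
common to both PD arms, and (ii) overall abundance differences between
transfections.  It also folds knockdown of the target mRNA into the
denominator, boosting E for genes whose input level drops under the test
miRNA.  Under a multiplicative (log-normal) noise model, log2 E is
approximately Gaussian for non-target genes; target genes are shifted by
log2 of their true binding enrichment.

## Order of operations and hit calling

The pipeline computes ratios per probe per replicate, averages replicate
ratios arithmetically, and then averages a gene's probes (single-probe
genes pass through).  The alternative order (probes first) is not
distinguished by the ratio definition itself; this order is fixed and a
geometric-mean collapse is available via `collapse="gmean"`.  One
consequence of arithmetic replicate averaging is that rescaling a single
sample multiplies different genes' mean ratios by slightly different
factors (a mixture of scaled and unscaled replicate ratios); with one
replicate, or with geometric averaging, the rescaling is exactly uniform.

Genes are *expressed* when at least one of their probes exceeds a
background intensity in at least one sample.  Arrays' native
present/absent calls are platform-specific, so the background is either a
user-supplied absolute intensity or a quantile of the whole matrix
(default: 5th percentile).  Unexpressed genes are removed before any
statistic is computed.  Genes with a zero or negative intensity in any
ratio term are excluded outright (ratios are undefined, and normalized
array output should be strictly positive, so this indicates corrupt
input); the count is logged.

The hit threshold is fitted on the **full** distribution of log2 mean
ratios over expressed genes — the threshold is defined from the
distribution, so hits are necessarily included in the fit.  μ and σ are
the sample mean and sample SD (n−1).  Hits satisfy
`mean_ratio ≥ 2^(μ + n_sd·σ)` with an inclusive boundary, n_sd = 1 by
default.  Under a pure null this calls the upper normal tail,
≈15.9% of genes.  Thresholds for different cell lines are fitted
independently, so the same 1 SD rule can correspond to different fold
values per line.

## Down-regulation and distribution comparison

Input-arm fold changes (test/control) use the same machinery restricted
to the input arms.  The default call is mean FC ≤ 0.8 (inclusive), i.e. a
drop of at least 20%, which is about one SD of the log-normal fold-change
distribution at typical noise levels.  Gene-set fold-change distributions
are compared on log2 values via the two-sample Kolmogorov–Smirnov
statistic D = sup|F_a − F_b| evaluated at all pooled data points, with the
asymptotic p-value (`scipy.stats.ks_2samp(method="asymp")`); exact
small-sample p-values are not used because the intended comparisons
involve hundreds to thousands of genes.  D is invariant under any strictly
monotone transform, so log2 vs linear fold changes give identical D.  KS
p-values are discrete; calibration tests therefore check tail fractions
against nominal α rather than strict uniformity.

## Positional hexamer enrichment

Each 6-nt window of the mature miRNA (1-based positions 1…L−5 from the 5′
end) is converted to its DNA target site by reverse complement with U→A
pairing; the nt 2–7 window is the canonical seed (site `ACTGCC` for
hsa-miR-34a-5p, `UGGCAGUGUCUUAGCUGGUUGU`, embedded as `MIR34A`).  Matches
are counted as **overlapping** exact occurrences, case-insensitive, with
`N` never matching; overlapping counting is the conservative superset
where the convention is ambiguous.  The per-set frequency is pooled —
total matches over total kb of the set's region sequence — rather than a
mean of per-gene frequencies, because "matches per kb of sequence"
describes pooled sequence; genes lacking sequence for a region are
excluded and counted in a coverage report.

When a FASTA contains several transcripts per gene
(`gene|transcript|region` headers), the transcript with the longest 3′UTR
is kept, ties broken lexicographically by transcript id.

Significance uses a Monte-Carlo null: n_sims random subsets of the
background of size |set|, drawn without replacement (implemented by
random-key partial sorting, chunked for memory).  The empirical
two-tailed p doubles the smaller one-sided rank probability with a +1
pseudocount, capped at 1:

    p = min(1, 2·min(P_ge, P_le)),  P_ge = (1 + #{null ≥ obs})/(n_sims + 1)

The background includes the test set's genes (the background is "all
expressed genes", not the complement).  When p reaches the nominal 1e-4
threshold or the observed frequency lies beyond every null value (the
empirical floor 2/(n_sims+1)), a Gaussian is fitted to the null sample
and the two-tailed normal tail probability is reported as `p_tail`
alongside — never replacing — `p_empirical`.  A gamma-tail alternative
was considered and rejected for the default because the pooled frequency
of a moderately large random set is close to Gaussian by the CLT, and a
two-parameter fit is the most stable at the sample sizes used; degenerate
nulls (SD = 0) yield `p_tail = NaN` with the empirical value retained.

A full scan evaluates the grid (hexamer start × region × gene set); child
RNG seeds per cell are derived from one root seed via `SeedSequence`, so
the grid is reproducible and cells can be recomputed in isolation.

## Pathway over-representation

For a query of size n from a universe of N genes (default: expressed
genes; configurable), a pathway with K members in the universe and k in
the query scores the hypergeometric upper tail P(X ≥ k), inclusive
(`scipy.stats.hypergeom.sf`).  No multiple-testing correction is applied
to the significance flag — filtering is at raw p < 0.001 — but a
Benjamini–Hochberg column is emitted for information.  The overlap
network connects enriched pathways with edge weight equal to the number
of shared **query** genes (the genes driving the enrichment); a
full-membership option exists.  Zero-weight edges are omitted.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* Gene abundance: log2 A ~ N(8, 2); probe affinities log2 ~ N(0, 0.25)
  (they cancel in ratios).
* Arm expectations: input_control = A; input_test = A·kd for targets
  (kd = `knockdown_effect`, default 0.5); both PD arms share the
  nonspecific capture factor A^β (β = `background_affinity`, default
  0.5) computed from the control abundance, with PD_test additionally
  multiplied by kd·e (e = `enrichment_effect`, default 4).  The shared
  capture factor makes the expected enrichment ratio exactly e for
  targets and 1 otherwise, for any β — the input normalization cancels
  abundance-coupled background by construction, which is the property
  the ratio is designed to have.
* Noise: each observed value is its expectation times 2^N(0, noise_sd),
  independent per probe and sample.  noise_sd defaults to 0.35; the
  null hit fraction at the 1 SD rule is ≈15.7–15.9% for noise_sd
  anywhere in 0.25–0.5, so the calibration is insensitive to this
  choice.  Replicates default to 2 and probes per gene to 2 (a fixed
  count or a range).
* Sequences: uniform-composition DNA per region with lengths
  median·exp(N(0, log_sd)) (defaults: 5′UTR 150 bp, CDS 1200 bp, 3′UTR
  800 bp).  Seed sites are planted in the 3′UTR as a Poisson process at
  5/kb (targets) vs 1/kb (background), by non-overlapping overwrite
  (rejection sampling), so planted counts are exact and recorded in the
  truth labels.  Chance matches (≈0.24/kb for a random hexamer) occur
  on top of planted ones.  Note that windows adjacent to the seed
  inherit ≈25% of planted-site matches through one random flanking
  base — the same seed-adjacent enrichment shoulder seen in real data —
  so seed-vs-neighbor discrimination requires enough aggregate sequence
  for Poisson noise to be small relative to that gap (hundreds of kb in
  the recovery tests).
* Pathways: a stated fraction of pathways oversample target genes
  (weight 8 by default, weighted sampling without replacement via
  exponential keys); the rest sample uniformly, and their overlap
  p-values follow the (super-uniform, discrete) hypergeometric null.
* Determinism: a two-cell-line study shares one planted target set with
  independent expression noise per line; all streams spawn from one
  `SeedSequence`, and identical config + seed reproduces byte-identical
  TSV/FASTA/GMT outputs.

What the generator does **not** emulate: probe-level cross-hybridization
and saturation, correlated (batch) noise across arrays, sequence
composition bias and conservation structure, G:U wobble seed matches,
3′UTR isoform heterogeneity, and translation-only repression (targets
whose mRNA does not decay).  Passing tests on synthetic data therefore
demonstrate correctness of the statistics under the stated model, not
biological completeness on real arrays.

## Independent oracles used in testing

* Enrichment/fold-change stages: plain-loop hand recomputation on small
  fixtures (1e-12 relative tolerance).
* Null σ of gene-level log2 ratios: Fenton–Wilkinson moment matching —
  a gene value is the mean of k iid log-normals with
  σ_ln = 2·noise_sd·ln 2, matched by σ_z² = ln(1 + (e^{σ_ln²} − 1)/k)
  (within 5% of simulation at the noise levels used).
* Planted-target sensitivity/specificity: closed-form normal tails on
  the two-component mixture, with the threshold at mixture mean + 1
  mixture SD.
* Hypergeometric p: exhaustive enumeration over binomial coefficients
  for every margin with N ≤ 12.
* KS statistic: brute-force sup-distance over all pooled points.
* Gaussian tail extrapolation: 2·Φ(−z) at 6 and 10 SD of simulated
  Gaussian nulls (agreement within a factor of two).

## Problem sizes and budgets

Test and acceptance simulations are sized for tight Monte-Carlo error at
interactive runtimes: 10,000-gene null studies (×20) for threshold
calibration, 2,000-gene studies for recovery, 1,000 resampled sets for
empirical-p calibration, and 100 seeded sequence runs of ≈300 kb target
sequence each for seed-window detection.  The complete suite runs in
about half a minute; the acceptance script in well under a minute.

## Known limitations

* The expressed-gene background is a quantile surrogate for platform
  present/absent calls; with real arrays, supply the platform's absolute
  background intensity instead.
* The asymptotic KS p-value is inaccurate below ~20 genes per set; such
  sets are skipped with a warning rather than switched to exact mode.
* Gaussian tail extrapolation underestimates very extreme significance
  if the true null is right-skewed; for small sets or short sequence,
  inspect the null sample before trusting p_tail far below the
  empirical floor.
* The pathway-overlap network is an export (SIF + node table), not a
  rendering; thresholding is on raw p by design.
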