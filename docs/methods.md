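# Methods

`seedshift` implements the computational core of a 5'isomiR expression and
function analysis: classifying small-RNA reads into 5'-end variants of a
miRNA, testing their tumor/normal differential expression, predicting
targets of the shifted seed, scoring gene-set activity per patient, and
running gene set enrichment analysis on correlation- or fold-change-ranked
lists. This note records the models, the defaults and why, the numerical
choices, and what the synthetic data does and does not establish.

## 5'isomiR model and read classification

A mature miRNA is located on its precursor hairpin by the canonical arm
interval `[start, end)` (0-based half-open). A read is classified by exact
substring search in the hairpin: an occurrence beginning `k` bases after
the canonical start and ending `d` bases after the canonical end is the
5'isomiR `name|k` with 3' offset `d`. Because the 5' end fixes the seed
(nucleotides 2–8) and hence the target spectrum, `k` is the identity
coordinate; reads differing only in `d` (tolerance ±3 nt, `tol3`) are
summed during aggregation. Defaults and rationale:

* **Templated 3' ends only.** A read must occur verbatim in the hairpin.
  Non-templated 3' additions (e.g. uridylation) are unassigned by default;
  `trim_nontemplated ≤ 2` opts into trimming terminal bases before
  retrying. The 3' end does not affect the seed, so this only changes the
  assigned/unassigned split, never an isomiR's identity.
* **Multi-occurrence reads** resolve to the occurrence with minimal
  `|offset5|` (tie → smaller signed offset): deterministic and biased
  toward the canonical annotation.
* **Offsets beyond ±5** are assigned but logged as implausible —
  Drosha/Dicer cleavage heterogeneity is local.
* A shifted mature sequence must retain ≥8 nt so a complete seed exists.
* T/U and case are normalised on input (FASTQ is DNA-alphabet).

RPM is `count / library_size × 1e6` with the library size being total
sequenced reads (assigned + unassigned). The expressed-isomiR filter keeps
features whose per-feature **median** RPM is strictly greater than 15
(mean available as an option); median is the default because it is robust
to a few extreme libraries.

## Differential expression and proteome statistics

Per feature: log2 of the ratio of group means with a 0.5-RPM pseudocount
(avoids ±∞ on zero groups; configurable), a two-sided unpaired t-test
(Welch by default — equal variances are not assumed; Student optional),
Benjamini–Hochberg adjustment (statsmodels), and volcano classes with
strict inequalities: significant iff `|log2FC| > 2` **and** `p_adj <
0.05`. Degenerate variances are handled explicitly: identical constant
groups give (t=0, p=1); constant groups with different means give an
infinite t and the smallest positive double as p.

Proteins are classed up/down/unchanged by sign of log2FC with `p < 0.05`
(strict; fc exactly 0 is unchanged). Gene-set over-representation among
regulated proteins uses the one-sided (greater) Fisher's exact test with
all detected proteins as the background universe; the odds ratio is
`(a·d)/(b·c)` with ∞ allowed.

Missing log-intensities are imputed by downshifted-Gaussian draws per
sample: `Normal(mean_s − 1.8·sd_s, (0.3·sd_s)²)` from the sample's
observed moments — the standard proteomics model of detection-limit
censoring. Observed cells are returned bit-identical; the draw is
deterministic under a fixed seed.

Ranked lists for preranked GSEA are per-feature treatment-vs-reference
fold changes — difference of means on the log scale (default for
log-intensity matrices) or log2 ratio of means on a linear scale — sorted
descending with lexicographic tie-breaking for cross-platform
determinism.

## Target prediction

Expressed 3'UTR regions are the per-UTR union of read alignments clipped
to the annotated UTR, merged where overlapping or book-ended; separate
merged runs of the same UTR stay separate regions.

The seed scanner reports every match of the four canonical site types for
the *shifted* seed — 8mer (pairing 2–8 plus A opposite position 1),
7mer-m8 (2–8), 7mer-A1 (2–7 plus A), 6mer (2–7) — anchored on the 6mer
core so each location is reported once with its highest-priority type.
Site coordinates are 0-based half-open on the mRNA 5'→3'.

The duplex scorer is a deliberately simple miRanda-style local aligner:
affine-gap Smith–Waterman of the miRNA (5'→3') against the reversed UTR
window, pair scores +5 (Watson–Crick), +1 (G:U wobble), −3 (mismatch),
gaps −8/−2, and pair scores at seed positions 2–8 multiplied by 2. The
local floor keeps scores ≥0; the default acceptance threshold is 80
(roughly a perfect seed duplex plus half the 3' region paired). No free
energy is computed; the score threshold plays that role.

A transcript is a **consensus target** only if both independent predictors
fire: at least one site of type ≥7mer (configurable down to 6mer, the
7mer default following the conserved-site convention of seed-based
predictors) *and* duplex score ≥ threshold over windows (~30 nt, clipped
to [15, 40]) centred on those sites. The point faithfully reproduced is
the intersection logic of two complementary algorithms over
transcript/miRNA pairs, not any specific third-party tool's output.
Venn-partition counts over per-isomiR target sets label each region by the
sets it belongs to and always sum to the union size.

## Activity score and GSEA

The single-sample activity score z-scales each gene over all patients
(sample sd, n−1; zero-variance genes become missing and are logged) and
takes the per-patient **median** over the gene set. Because z-scaling
removes per-gene location and scale, the score is invariant under
per-gene affine transforms of the raw matrix — asserted to 1e-12 in
tests (bit-exactness is not attainable in floating point).

The GSEA engine implements the weighted KS statistic: walking the ranked
list, hits add `|score|^p / Σ_hits |score|^p` (p = 1, the "weighted"
default; p = 0 reduces to the classic KS), misses subtract `1/(N−N_h)`;
ES is the running-sum value of maximal absolute deviation. Significance:

* **preranked mode** — null ES from random same-size gene-set draws
  (shared across sets of equal size within a call);
* **phenotype mode** — the phenotype vector is permuted and the
  Spearman-correlation ranking recomputed per permutation. Expression is
  converted to ranks once and the phenotype permuted against those ranks.

NES divides ES by the mean |null ES| of matching sign; the permutation p
uses the +1 correction (never exactly zero); the FDR q follows the
standard sign-stratified pooled-NES procedure, clipped to [0, 1], with a
degenerate (no same-sign null) q reported as missing with a warning.
Gene sets are intersected with the measured universe first; sets below 5
members are skipped with a warning. All tie-breaking is lexicographic and
every permutation stream is seeded, so results are reproducible.

A practical note on the FDR estimate: with very few sets the pooled q of
a single set is approximately uniform under the null; only with a
realistically sized collection (tens of sets, e.g. the 50-set Hallmark
collection) does the estimate concentrate near 1 for null sets. The
calibration checks therefore use 50-set collections.

## Synthetic data: what it emulates and what it does not

All generators are seeded and emit truth tables.

* **Reads**: i.i.d. draws from a user-specified joint (offset5, offset3)
  distribution over a hairpin; error-free, no adapters or quality model.
  Classification recovering 100% of these reads shows the coordinate
  arithmetic is exact, not that the classifier tolerates sequencing
  error (by design it does not — mismatched reads are unassigned).
* **Cohorts**: negative-binomial counts (`var = m + φm²`, φ = 0.1; φ = 0
  gives Poisson) around log-normal baselines (median ≈ 50 RPM, log-sd
  1.5), 20 tumor vs 20 normal, 500 isomiRs, library 2e6. Planted features
  have tumor means scaled by `2^log2FC`, with baselines resampled above
  30 RPM so planted effects sit in the stratum the >15 RPM filter keeps —
  a power statement about expressed isomiRs is the scientifically
  relevant one. No batch effects or library-composition artifacts.
* **Activity cohorts**: latent activity `A ~ N(0,1)` per patient; set
  genes get `loading·A` plus N(0, 1) gene-level noise (noise comparable
  to signal, as in real expression data); the miRNA couples to A through
  a Gaussian copula with Pearson `ρ_p = 2·sin(π·ρ_s/6)` so the population
  Spearman equals the target exactly, then a monotone transform puts it
  on an expression-like scale. At n = 300 the Spearman estimator's SE is
  ≈0.05, so a ±0.1 recovery band is a ≈2-SD (≈95% coverage) statement —
  replicate fractions just below 95% are sampling noise, not bias.
* **Proteomes**: Gaussian log2 intensities (mean 25, sd 2, sample noise
  0.25) for 1000 proteins, 4 vs 4; one 50-protein set shifted down in the
  treated group; missingness via a logistic curve in true intensity
  anchored at the 15% quantile (left-censoring). No peptide-level or
  shared-peptide structure.
* **UTRs**: random-background sequences rejection-sampled (bounded at
  10⁴ attempts) to carry no accidental site for the queried isomiRs, then
  planted site strings written in with guard bases so a site cannot
  silently upgrade type, and verified by re-scanning — the truth table is
  exhaustive by construction.

## Problem sizes in the checks

The acceptance script and end-to-end tests use: 10⁴ reads; 200 null
cohorts of 500 × (20+20) plus 5 planted cohorts; exhaustive 2×2 tables to
universe 14 plus 300 random tables to universe 50; all subsets of ranked
lists to length 12; one planted and 50 null proteome runs at 1000
permutations with 50-set collections; 100 activity replicates at n = 300;
1000 random UTRs to length 500. These sizes give Monte-Carlo error well
inside each check's tolerance.

## Known limitations

* No genome alignment, adapter trimming, quality filtering, or
  sequencing-error tolerance in classification.
* The duplex scorer is a transparent stand-in for energy-based duplex
  tools; absolute consensus set sizes are therefore not comparable to
  published miRanda/TargetScan runs — only the consensus logic is.
* No count-model DE (negative binomial GLM), batch correction, paired
  survival statistics, conservation scoring or context features.
* The GSEA FDR is the classic pooled estimate; it is conservative for
  strongly correlated sets and undefined when a sign stratum is empty.
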