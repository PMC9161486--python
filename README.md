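# seedshift

5'isomiR quantification, shifted-seed target prediction and gene-set
activity analysis for small-RNA and expression cohorts.

## The problem

High-throughput small-RNA sequencing shows that a single miRNA locus
produces several 5'-end variants, called **5'isomiRs**. Because the seed —
nucleotides 2–8 from the 5' end — is the primary determinant of target
recognition, a 5' shift of even one or two bases changes the seed and
therefore the target spectrum: isomiRs from the same hairpin can have
different, even opposing, functions. A well-studied example is
miR-183-5p in breast cancer, where the canonical miRNA and its |+1 and
|+2 variants are co-expressed but only the |+2 variant (seed `GGCACUG`
instead of `AUGGCAC`) represses the E2F cell-cycle program.

`seedshift` is for computational biologists who want to take 5'isomiRs
seriously in such analyses. It provides, as a tested library plus a thin
CLI:

* **isomiR classification** — exact-substring assignment of reads to a
  pre-miRNA arm with 5'/3' offsets, aggregation over 3' variation
  (`name|offset` labels, e.g. `miR-183-5p|+2`), RPM normalisation and the
  median > 15 RPM expressed filter;
* **cohort statistics** — log2 group fold changes, unpaired (Welch)
  t-tests, Benjamini–Hochberg adjustment and volcano classes
  (|log2FC| > 2 ∧ q < 0.05); protein regulation classes, one-sided
  Fisher's exact gene-set enrichment, and downshifted-Gaussian imputation
  of left-censored proteomics intensities;
* **target prediction** — expressed-3'UTR extraction by interval algebra,
  a shifted-seed site scanner (8mer / 7mer-m8 / 7mer-A1 / 6mer), a
  miRanda-style local duplex scorer, and consensus calls requiring both
  predictors;
* **enrichment** — the per-patient gene-set activity score (median of
  z-scaled expression, e.g. an "E2F activity score"), Spearman-correlation
  ranking metrics, and a self-contained GSEA engine (weighted KS
  statistic, NES, permutation p, pooled FDR q) in preranked and
  phenotype-permutation modes;
* **synthetic data** — seeded generators with truth tables for every
  input the pipeline consumes.

The statistic at the core of the enrichment engine is the weighted
Kolmogorov–Smirnov running sum: for a ranked list r₁ ≥ … ≥ r_N and a set
S with N_h members, hits add |r_i|ᵖ / Σ_{j∈S} |r_j|ᵖ (p = 1) and misses
subtract 1/(N − N_h); ES(S) is the extremum of the walk, normalised to
NES by the mean same-sign null ES from permutations.

## Worked example

Simulate an error-free 10,000-read library over a hairpin carrying the
canonical miR-183-5p sequence with 5' offsets drawn as 50% |0, 30% |+1,
20% |+2 (and ±1 nt of 3' heterogeneity), then classify and quantify:

```python
from seedshift import (MatureArm, PremirnaReference, classify_read,
                       collapse_5p, rpm_normalize)
from seedshift.simulate import ReadSimSpec, simulate_reads

mature = "UAUGGCACUGGUAGAAUUCACU"                  # canonical miR-183-5p
hairpin = "CCGCAGAG" + mature + "GUGCCUUACCGAAGGG"  # synthetic hairpin context
ref = PremirnaReference("synthetic-mir183", hairpin,
                        (MatureArm("miR-183-5p", 8, 30),))

spec = ReadSimSpec(ref, "miR-183-5p",
                   offset5_probs={0: 0.5, 1: 0.3, 2: 0.2},
                   offset3_probs={-1: 0.2, 0: 0.6, 1: 0.2},
                   n_reads=10_000, seed=1)
records, truth = simulate_reads(spec)
assignments = [(classify_read(seq, ref, "miR-183-5p"), 1) for _, seq in records]
counts, summary = collapse_5p(assignments, sample_id="library")
print(counts.data)
print(rpm_normalize(counts, {"library": len(records)}).data)
print(summary)
```

This prints:

```
               library
miR-183-5p|+1     3025
miR-183-5p|+2     2022
miR-183-5p|0      4953

                library
miR-183-5p|+1  302500.0
miR-183-5p|+2  202200.0
miR-183-5p|0   495300.0

{'assigned': 10000, 'unassigned': 0}
```

Reads with different 3' ends but the same 5' end were summed into one
isomiR each; the recovered proportions (0.495/0.303/0.202) match the
simulated 0.5/0.3/0.2 to binomial noise, and every read was assigned
because the library is error-free. The same flow is available from the
shell:

```bash
seedshift simulate --outdir sim --seed 7
seedshift quantify --config quantify.yaml --outdir quant
```

where `quantify.yaml` points `inputs.reads_fastq`, `inputs.premirna_fasta`,
`inputs.arm_table` at the simulated files and sets `inputs.arm_id:
miR-183-5p`. Every stage writes a manifest (config hash, seed, input
checksums) and identical reruns are byte-identical.

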