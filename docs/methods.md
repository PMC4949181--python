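# Methods

## Statistical model of the synthetic data

All generators derive from one additive Gaussian model on the Ct scale:

    Ct[g, s, r] = mu_g + lambda_s + beta_g * x_s + eps[g, s, r]

| term | meaning | default |
|---|---|---|
| `mu_g` | gene baseline Ct (cycles) or baseline log2 intensity | U(18, 28) cycles; U(6, 12) log2 units for expression |
| `lambda_s` | per-sample loading offset (RNA input, RT efficiency), shared by all genes of a sample | N(0, 1) cycles |
| `x_s` | centered condition contrast: −0.5 well-watered, +0.5 drought | balanced design |
| `beta_g` | gene condition sensitivity; 0 for a true reference gene | see layouts below |
| `eps` | per-well noise (technical scatter plus condition-independent biological variability) | gene-specific, see layouts |

Expression intensities use the same linear predictor without the loading
term, exponentiated base 2 (`2**(mu + beta*x + eps)`), making expression
multiplicative-lognormal while Ct stays additive — the standard
correspondence of one PCR cycle per doubling.

Since `lambda_s` enters every gene of a sample identically, it cancels
exactly in any ΔCt.  This is deliberate: it makes the central property of
pairwise stability statistics (immunity to per-sample mRNA content) hold
*exactly* in the simulation, so invariance can be asserted to 1e−10 rather
than approximately.

Samples cycle deterministically through the cartesian product of the
annotation levels (genotype × stage × tissue × water status) with water
status flipping fastest, keeping conditions balanced for any sample count.

### Generator layouts

*Planted-reference benchmark* (`ct_benchmark_config`): 10 genes, 12
samples, 3 technical replicates.  `REF01` is a true reference (beta 0,
eps SD 0.05 cycles — pure replicate scatter).  The other nine genes draw a
condition sensitivity of magnitude U(0.5, 1.5) cycles with **random sign**
and per-well noise U(1.0, 1.5) cycles.  Two choices matter here:

- *Random sign.*  Drought-responsive transcripts are induced and repressed
  in comparable numbers.  Statistically the sign mix is load-bearing: if
  every unstable gene responded in the same direction, the condition
  effect would be a common mode that pairwise differencing removes, and a
  gene sitting at the centre of the beta distribution would score *better*
  than the true reference — with one-signed betas the planted gene is
  recovered in only about a third of runs, which says something real about
  the blind spot of pairwise statistics when all candidates co-respond.
- *Noise magnitude.*  The 1–1.5-cycle noise of unstable genes lumps
  technical with condition-independent biological variability, placing
  them in the 1–2 cycle ΔCt-SD regime typical of poor reference genes,
  against ~0.9 cycles for the stable gene (its score is dominated by its
  noisy partners, not its own scatter).

*Independent-noise panel* (`heterogeneous_noise_config`): 10 genes, all
beta 0, per-gene noise U(0.4, 0.8) cycles.  With no condition axis,
stability differences come purely from independent noise, and averaging
genes into combinations reduces the pseudo-reference's variance — the
regime in which growing the reference from 1 to 4 genes is expected to
help monotonically.  The range is deliberately narrow: combinations can
only beat the best single gene when the second-quietest gene's variance is
within a factor ~3 of the quietest (else the lone quiet gene is genuinely
the optimum), and a wide noise spread would make non-monotonicity the
*correct* answer rather than an error.

*Family screen* (`screen_config`): 74 genes in the four classic reference
families (7 GAPDH, 13 actin, 31 ubiquitin, 23 cyclophilin isogenes), one
quiet isogene per family, used for the CV/WRS pre-screen across several
datasets.

*Validation scenario* (`simulate_validation_scenario`): array log2 fold
changes x ~ N(0, 2); concordant qPCR values y = x + N(0, sd); planted
outliers receive an extra ±shift on y.

### What the simulation does not emulate

No amplification-efficiency variation (the ΔΔCt fold change assumes a
clean doubling), no probe cross-hybridization, no plate or batch effects
beyond the per-sample offset, no heavy-tailed or Ct-dependent noise, and
the condition structure is a single two-level contrast.  Passing tests
therefore demonstrate correctness of the statistics and the expected
behaviour *under the model's assumptions*; they do not certify performance
on real data where efficiency differences and correlated biological noise
blur these properties.

## Pipeline statistics and numerical choices

**CV and ranking.**  CV = sample SD (n−1 denominator) / mean, computed on
linear intensities; log2-stored matrices are exponentiated first, since CV
on log data conflates additive and multiplicative variation.  Genes with
fewer than 2 finite values or non-positive mean are excluded with a log
notice.  Within-family ranks average ties.

**WRS.**  Rank r in a family of N maps to the percentile score
s = 1 − (r−1)/(N−1) (s = 1 for a singleton family); scores are summed over
datasets with weights equal to each dataset's count of distinct annotation
tuples (overridable), then normalized to 100 % of the family maximum.  A
gene absent from a dataset contributes 0 there — missing evidence never
raises a score.  Candidate quotas are filled by descending WRS with
lexicographic tie-break (logged).

**Mean ΔCt SD.**  Technical replicates are collapsed by arithmetic mean
first.  A combination's pseudo-Ct is the arithmetic mean of member Cts
(geometric mean of expression, the standard multi-reference convention);
a sample missing any member is missing for the combination.  Partners
exclude the set's own members — a member compared against itself would
deflate the SD.  Pairs are evaluated pairwise-complete with a floor of 3
shared samples (error below that).  Enumeration covers all subsets of
size 1..max_size (guard at 50 000 sets), ranks are ascending tie-averaged,
and equal-score rows order lexicographically so output files are
reproducible.

**geNorm comparator.**  Single-pass M: for gene j, the mean over partners
k of the SD across samples of (Ct_k − Ct_j) — the Ct-scale equivalent of
the SD of the pairwise log2 expression ratio at efficiency 2.  No stepwise
worst-gene elimination is performed; the comparator is used for top-gene
agreement only.  Note the single-*gene* mean ΔCt SD and M differ only in
partner bookkeeping, so their agreement on the most stable gene is near
structural; the two are nevertheless computed by independent code paths.

**ΔΔCt.**  Efficiency fixed at 2 (no Pfaffl correction).  The calibrator
may be a sample id, an explicit sample list, or an annotation level (all
samples carrying it); ΔΔCt subtracts the mean calibrator ΔCt, so a
single-sample calibrator has ΔΔCt = 0 exactly and a condition calibrator
has zero mean ΔΔCt.  Condition-level fold changes are means of per-sample
log2 fold changes with standard errors.  Targets with entirely missing
calibrator wells are skipped with a notice.

**Residual variance.**  RV is measured against the *fixed* line y = x —
zero fitted parameters — with an n−1 denominator, over at least 3 retained
points.  Outlier policies: `residual-sd` (single pass, default 2 SD of
residuals), `fixed-count` (remove the k largest |y−x|, stable tie-break),
`explicit` ids, or `none`; one policy is applied uniformly to all
reference sets being compared so their RVs stay comparable.

## Problem sizes

The test suite and the reproduction script run the stochastic benchmarks
at 100 seeded replicates of the 10-gene × 12-sample × 3-replicate panels,
RV calibration at 1000 points, and generator moment checks at 10 000
samples; full enumeration is exercised at its natural size (385 sets from
10 candidates).  Planted-ordering recovery of four disagreement levels
(SD 0.2/0.3/0.4/0.5) is checked at 60 shared targets, where the RV
estimate has enough degrees of freedom for the full 4-way ordering to be
identifiable; with 8 targets only the extreme pair separates reliably.

## Known limitations

- The WRS weight (annotation-tuple count) treats all annotation axes as
  equally informative; a dataset with many technical conditions but one
  tissue is weighted as "broad".
- Exhaustive enumeration is exponential in candidate count; the 50 000-set
  guard caps the panel at roughly 20 genes at max_size 4, which covers
  practical qRT-PCR panels but not genome-scale screens.
- The single-pass M comparator is not full geNorm (no iterative
  exclusion, no pairwise-variation V statistic for choosing the number of
  references).
- RV compares platforms on log2 fold changes only; systematic compression
  of array fold changes relative to qPCR (a known platform effect) will
  inflate RV for every reference set alike rather than being modelled.
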