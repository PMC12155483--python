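# Methods

## Problem and scope

`methclock` builds *minimized* epigenetic clocks — regression models that
predict culture passage number (replicative age) or donor chronological age
from the DNA methylation of a handful of targeted amplicons — from
high-coverage targeted bisulfite sequencing. Unlike microarray or
pyrosequencing pipelines, targeted BS-seq resolves the joint methylation
pattern of consecutive CpGs on each DNA molecule, so the package computes
both the conventional per-CpG mean methylation (beta values) and six
read-level within-sample heterogeneity (WSH) scores, and lets the two
channels be combined in one model. The package starts from aligned reads
(Bismark-convention `XM`/`XG` tags); trimming and alignment are out of
scope.

## Read-pattern extraction

A *read pattern* is the string of M/U states of one sequenced molecule over
the consecutive CpGs of a target region. Coordinates are 0-based half-open;
a CpG is identified by its forward-strand C position and calls from
bottom-strand alignments are shifted one base left onto it. Paired mates
sharing a read name are merged into a single molecule; where overlapping
mates disagree, the call with the higher base quality wins (ties go to mate
1 — a deterministic convention, since protocols differ in which mate is
more reliable). If an alignment gap (deletion) skips a listed CpG, the
pattern is split at the gap rather than imputed, because all heterogeneity
scores below assume consecutively *observed* states.

Regions eligible for heterogeneity analysis must carry at least five CpGs
within a 150 bp span — the density needed for pattern-level scores under
2×75 bp paired-end amplicon sequencing; the predicate is exposed as
`TargetRegion.eligible`.

## Heterogeneity scores

Let reads at a block of L consecutive CpGs be given. With epiallele
frequencies p_k over the 2^w patterns of a w-CpG window:

* **MHL** = Σᵢ wᵢ·MHᵢ / Σᵢ wᵢ with wᵢ = i, where MHᵢ is the fraction of
  observed i-long substrings (windows fully covered by a single read) that
  are fully methylated; lengths with no observed substring are dropped from
  both sums. Evaluated on the full CpG run of each region.
* **PDR**: a read covering ≥ 4 CpGs (`min_cpgs_per_read`) is discordant iff
  it carries both M and U; PDR is the discordant fraction of classified
  reads. Region-level, like MHL.
* **PM (epipolymorphism)** = 1 − Σₖ pₖ² and **ME (methylation entropy)** =
  −(1/4) Σₖ pₖ log₂ pₖ, both over the 16 epiallele frequencies of reads
  fully covering a sliding window of exactly 4 CpGs (0·log 0 ≡ 0, so
  PM ∈ [0, 15/16], ME ∈ [0, 1]).
* **FDRP / qFDRP**, per CpG: over pairs of reads covering the focal CpG,
  compare the states at every CpG both reads observe within ±50 bp
  (`window`) of it. FDRP is the fraction of pairs differing anywhere;
  qFDRP averages the pairwise Hamming distance divided by the number of
  shared CpGs. When the number of pairs exceeds `max_pairs` (default 40),
  pairs are sampled without replacement from a per-(sample, CpG) random
  stream derived from the global seed by hashing the feature id, after a
  canonical sort of the reads — results are therefore reproducible and
  independent of read order.

All thresholds (`min_reads` = 10, `min_cpgs_per_read` = 4, `window` = 50,
`max_pairs` = 40, 4-CpG PM/ME windows) follow the common conventions of the
read-level heterogeneity literature and are configurable. Scores with
insufficient read support are **missing, never zero**: zero is a meaningful
value for every metric. Every metric is checked against an independent
exhaustive-enumeration oracle in the test suite.

Block-level scores can optionally be broadcast to their member CpGs
(`unit="cpg"`, averaging overlapping windows), for workflows that count
features per CpG rather than per block.

## Feature selection

Each feature (beta value or WSH score) is correlated with the target over
pairwise-complete samples — Pearson for mean methylation, Spearman rank
correlation for WSH scores — and p-values are Benjamini–Hochberg adjusted
across all testable features of the matrix ("adjusted" is read as FDR
control; Bonferroni is available). Constant features are flagged undefined
and excluded from the adjustment denominator. A passage clock keeps
features with adjusted p < α (default 0.05) for passage **and not** for
donor age: any CpG that also tracks chronological age is discarded so the
clock measures culture time alone. The age filter requires ≥ 3 samples with
known age; otherwise it is skipped with a warning. Selected features are
ordered by |statistic| descending (deterministic, column-order invariant).

## Clock construction

**Random Forest + LOOCV** (`LoocvForestClock`). For N samples, N forests
are trained, each predicting the one held-out sample; MAE and
R² = 1 − SS_res/SS_tot are computed on the pooled held-out predictions
(R² can be negative, and is reported missing for a constant target). Each
fold's impurity importances (which sum to 1) are accumulated into a
cumulative importance per feature, summing to N. Defaults: 500 trees,
scikit-learn split defaults, a fixed `random_state` recorded with the
feature list in `config_fingerprint_`. Samples with any missing selected
feature are dropped with a logged list — imputation would leak information
across LOOCV folds.

**Minimization sweep** (`ImportanceSweepClock`). Features with cumulative
importance exactly zero are removed (it is an error if none remain); the
rest are ranked most-important-first, and a LOOCV model is scored for each
prefix of the ranking. The chosen size minimizes MAE, ties broken toward
fewer features; R² is reported but not used for selection, MAE being the
clock's headline unit. Beyond `sweep_cap` features (default 256) the sweep
switches to a logarithmic size grid.

**Hybrid models** concatenate feature matrices of different provenance
(mean beta, MHL, PDR, …) over an identical sample set, with the provenance
tag prefixed to each column so identical feature ids stay distinct.

**LASSO hold-out** (`LassoHoldoutClock`), for larger cohorts: an 80/20
train/test split, features standardized on the training split only, the
penalty α chosen from a log grid (50 points, 1e−4…1e1) by 10-fold CV mean
absolute error within the training split, and a single evaluation on the
untouched test split. Coefficients are reported on the original feature
scale.

## The cohort simulator

Because real MSC passage-series data cannot ship with the package, every
pipeline stage is validated on simulated cohorts with known ground truth
(`methclock.synthetic`). The stock benchmark
(`default_benchmark_config()`) mirrors a realistic small targeted panel:
44 samples with passages cycling 1–12 and donor ages uniform on 20–70
years (independent of passage), 4 regions × 15 CpGs spaced 10 bp (all
eligible), Poisson(1000) reads per region per sample, each read covering
5–10 consecutive CpGs from a uniform start. Signal classes:

| class | count | parameters |
|---|---|---|
| mean_drift | 24 CpGs | slope ±0.02/passage from baselines 0.25 / 0.74 |
| age_drift | 7 CpGs | slope 0.004/year from baseline 0.15 |
| disorder | 2 blocks × 5 CpGs | π₀ = 0.05, γ = 0.045/passage, p₀ = 0.5 |
| null | 19 CpGs | baselines 0.12 / 0.88 |

Disorder blocks draw each read from an ordered/disordered mixture: with
probability π(passage) the read is a uniform random epiallele, otherwise it
is fully-M with probability p₀, else fully-U. With p₀ = 0.5 the expected
mean methylation is pinned at 0.5 while PDR/PM/ME/MHL drift with passage —
the signal channel only read-level data can see. This mixture was chosen
over per-CpG variance inflation precisely because it moves pattern-level
scores at constant mean; alternative generators can be plugged in.

Null baselines sit near 0 and 1 because most genomic CpGs are strongly
un-/methylated; a 0.5 i.i.d. null would itself be maximally heterogeneous
and mask the disorder gradient. On top of binomial read sampling, every
(sample, CpG) probability gets Gaussian jitter (sd 0.03 on the probability
scale) emulating biological and technical between-sample variation, so
that per-CpG selection at n = 44 is powerful but not trivially so. All
probabilities are clamped to [0.02, 0.98] (incomplete conversion /
measurement floor); configurations whose noiseless trajectories leave the
clamp band are rejected before generation. Effect sizes are calibrated
only to make selection and clock recovery non-trivial at this cohort size;
they are not fitted to any particular cell system.

`mixed_signal_config()` generates the hybrid-model testbed: one region with
5 mean-drift CpGs among nulls plus two pure disorder blocks, both channels
at matched effect sizes (36 samples, depth 500), so each single-channel
clock is informative but noisy and the benefit of combining channels is
expressible.

What the simulator does **not** model: sequencing error, bisulfite
conversion failure, PCR duplicates, linked epialleles beyond the block
mixture, or cell-type composition shifts. Passing tests therefore show the
pipeline recovers planted signal of the stated form — not that any real
tissue behaves like the generator.

## Numerical and scale choices

* LOOCV forests use 500 trees by default; test and acceptance runs on
  reduced cohorts use 60–300 trees and a sweep cap of 16 grid sizes —
  these are the package's chosen desk-scale problem sizes, stated here so
  results are reproducible; the statistical properties under test do not
  depend on them.
* FDRP/qFDRP pair sampling uses `numpy` Generator streams seeded by
  (global seed, CRC32 of "sample|feature"), keeping every value
  reproducible under any iteration order; all seeds in CLI workflows are
  mandatory arguments.
* Ties in feature rankings are broken by stable (mergesort) ordering; the
  sweep's best size takes the smallest minimizer.
* Degenerate inputs: constant features are kept by forests (logged),
  flagged undefined by the correlation filter; empty selections return
  empty lists with warnings rather than errors; a constant truth vector
  yields missing R².

## Known limitations

* MHL/PDR operate on the full region run; very long regions would dilute
  local signal (amplicons here are ≤ 150 bp dense stretches, so this is
  the intended regime).
* The age/passage confound filter is marginal (per-feature); it does not
  model joint passage+age effects, and a cohort where age and passage are
  strongly collinear will defeat it.
* LOOCV R² on small cohorts is an optimistic-variance estimate; MAE is the
  primary model-selection criterion throughout.
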