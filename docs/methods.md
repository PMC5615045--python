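# Methods

`sporoseq` reimplements, as a tested pipeline over synthetic data, the
computational workflow of a three-time-point bulk RNA-seq study of a
developmental switch: a starving *Physarum polycephalum* plasmodium is
induced to sporulate by a light pulse and sampled at 0 h (dark control),
6 h (around the commitment point) and 10 h (onset of morphogenesis).
This note records the models, the parameter choices that matter, and the
limits of what the synthetic experiments demonstrate.

## Reference-transcriptome consolidation

Assembled reference transcriptomes are redundant: one gene may appear as
two abutting fragments, as separated fragments whose protein homology ties
them together, or as several splice variants. Consolidation applies three
rules over candidate pairs and merges the resulting graph with union-find:

1. **Overlap join.** Two transcripts that are rank-adjacent on the same
   scaffold and strand are joined when the upstream 3' end exactly matches
   the downstream 5' start over at least `min_overlap` nt (default 50).
   "Neighbouring" must be an explicit input (the locus table) because
   transcripts carry no genomic context of their own; without locus
   metadata the rule is skipped with a warning. Only exact matches count —
   the rule is meant to be conservative and fully reproducible. Joined
   sequences are spliced with the overlap counted once.
2. **Homology join.** Rank-adjacent transcripts hitting the same database
   subject join when their subject intervals overlap by at most 10% of the
   shorter interval and appear in an order consistent with transcription
   direction (strand-aware). The joined sequence is the concatenation with
   a 10-nt N spacer: the gap is real, and inventing sequence there would
   fabricate data. N runs never seed or extend downstream substring
   matches.
3. **Splice-variant deduplication.** Any two same-strand transcripts
   sharing an identical block of **more than** 100 nt (strict reading of
   the "more than 100 bases" convention; configurable) are treated as
   variants of one gene; the longest member represents the group, ties
   broken by lexicographically smallest ID. Detection uses k-mer seeding
   (k = threshold + 1) with left/right extension, which is exact for any
   block at or above the seed length; a hash-based k-mer shortlist keeps
   the pair scan near-linear and cannot lose candidates (collisions only
   add pairs that the exact check then rejects).

Candidates of all three rules enter one union-find pass; inside a
component, adjacency chains are stitched first (rule priority
overlap > homology join), then splice-duplicate selection keeps the
longest stitched sequence. Components whose adjacency edges branch (a
fragment claimed by two conflicting chains) are left unmerged and flagged
rather than guessed at. Detection and merging iterate to a fixpoint; on
all tested scenarios one round suffices and a second round finds nothing,
which the idempotence tests assert.

On small instances (≤ 50 transcripts of ≤ 1 kb) splice-duplicate detection
is verified exactly — same pairs, same block lengths — against an O(n·m)
dynamic-programming longest-common-substring oracle.

## Differential expression

Counts for transcript *i* in sample *j* are modelled as negative binomial
with mean `s_j · q_ij` and variance `μ + α·μ²`, where `s_j` is a sample
size factor and `α` the per-transcript dispersion.

* **Size factors** use the median-of-ratios estimator over transcripts
  with nonzero counts in every sample, rescaled to geometric mean 1; if no
  such transcript exists the code falls back to total-count scaling with a
  warning.
* **Dispersion** is estimated per transcript by method of moments pooled
  across within-group (time-point) replicates — the excess of the
  within-group variance of normalised counts over the counting (Poisson)
  part estimates `α·μ²` — then shrunk toward a mean–dispersion trend
  `α(μ) = a₀ + a₁/μ` fitted across transcripts by iteratively trimmed
  least squares. The shrinkage weight defaults to 0.8: with 3–5 replicates
  per group the gene-wise estimate is very noisy and the trend, fitted on
  thousands of transcripts, carries most of the information. Dispersions
  are floored at 1e-8; all-zero transcripts are flagged untestable.
* **Wald test.** Group means are `μ̂_g = Σ_j k_ij / Σ_j s_j`. The reported
  effect is `log2FC = log2(μ̂_B + c) − log2(μ̂_A + c)` with pseudo-mean
  `c = 0.5` (mild shrinkage that stabilises low-count fold changes). The
  standard error is the delta-method variance of `log(μ̂ + c)` under the NB
  variance function — using `μ̂ + c` in the denominator keeps the statistic
  self-consistent with the shrunk effect and, empirically, calibrated at
  low counts. Two-sided p-values come from the normal approximation of
  the Wald statistic. Transcripts with total count below 10 are flagged
  untestable rather than dropped: the normal approximation is unreliable
  there.

The three contrasts 0–6 h, 6–10 h and 0–10 h share size factors and
dispersions. Replicates are pooled across strains and experiments per time
point; strain is deliberately not a model covariate, mirroring the study's
pooling of strains to suppress genotype-specific effects, and 8 h/10.5 h
samplings are mapped to the 10 h class in the sample sheet (data, not
code). Significance uses raw p-values at α = 0.025 by default because that
is how the original significance rule is stated; Benjamini–Hochberg
adjustment is available via `DEParams(adjust="BH")` as the ambiguity is
real.

**Maximal-change classification.** Per transcript, among contrasts with
p < α the one with largest |log2FC| is chosen (ties broken in the order
0–6 h, 6–10 h, 0–10 h); its sign gives the direction. Transcripts with no
significant contrast are excluded from the DE set, so the DE set
partitions exactly into the three contrast bins. Fold changes are quoted
as `2^|log2FC|`, rounded to integers at ≥ 10 and one decimal below.

**Calibration and recovery** are the design goals, not numerical identity
with any external tool: on null simulations the empirical type-I error at
α = 0.025 stays within ±0.01 of nominal, and planted log2FC = 2 effects at
mean counts ≥ 100 with 5+5 replicates are recovered within ±0.2 on
average. Both are asserted by the acceptance tests.

**PCA QC.** Counts are size-factor-normalised, log2(x+1)-transformed,
restricted to the 500 most variable transcripts, feature-centred, and
projected onto the first two components via SVD. Component signs are fixed
by making each component's largest-magnitude loading positive, so results
are deterministic. With a dominant induction effect the sample coordinates
rank-order by sampling time; the maximal attainable Spearman correlation
is below 1 because time points are tied groups (5/4/3 samples), and the
synthetic check observes the exact perfect-separation value (≈ 0.94).

## Core-set comparison

The cross-species reference is a core set of 1167 genes whose
developmental up-regulation is conserved across social amoebae. Each
transcript maps to at most one core gene: best hit by bit score at
e-value ≤ 1e-5 (ties: lower e-value, then lexicographic subject ID); both
cutoff and policy are conventional choices, configurable, since no
specific criterion is fixed by the source material. The summary table
counts DE transcripts per direction × interval, split by presence of a
protein-database annotation, plus the number of *distinct* core genes hit
(duplicate gene identifiers collapsed). The percentage column is
100 · unique genes / annotated transcripts — the only denominator
consistent with all published cells of the corresponding table (17/102 =
16.7, 42/307 = 13.7, 233/1610 = 14.5). Down-direction percentages, printed
as "nd" in the original table, are computed here as an extension and
flagged in the output metadata.

## Master annotation table and grouping

The comprehensive table anchors on the transcript set with left-join
semantics: one row per domain hit, at least one row per transcript, with
similarity and DE fields repeated across a transcript's rows; row order is
deterministic. Coverage percentages count transcripts, not rows (the
row-vs-transcript ambiguity is real; transcripts are the more
interpretable unit). The originally manual functional grouping is made
reproducible as a shipped, editable YAML rule file: case-insensitive
substring match terms plus exclusion terms over annotation descriptions,
no stemming — transparent and auditable, at the cost of missing synonyms
a curator would catch. A transcript may join several groups. Null fields
render as empty strings in TSV output.

## Synthetic data

The generators produce every pipeline input with planted truth:

* **Reference scenario.** Genes (default 400–1200 nt, uniform) laid out
  consecutively on scaffolds; planted fractions are corrupted into
  overlap-split pairs (overlap 55–90 nt), homology-split pairs (with
  supporting hit rows to a synthetic subject), or splice-variant pairs
  sharing one contiguous identical block of threshold + 1…100 nt —
  the simplest structure satisfying the dedup rule. Alphabet is strict
  A/C/G/T so substring oracles are exact; random 1 kb sequences share
  common substrings of only ~10–20 nt, so planted events are the only
  long matches.
* **Count scenario.** The default design mirrors the study layout: three
  experiments, four strain/ploidy combinations, 5/4/3 pooled replicates at
  0/6/10 h (12 samples). A planted fraction (default 0.2) of transcripts is
  DE with |log2FC| ~ Normal(2, 1) truncated at 0.5 — matching the reported
  dynamic range of significant changes (|log2FC| ≈ 0.6–9) — assigned to one
  of three monotone trajectory classes (step at 6 h, step at 10 h,
  gradual), so interval additivity log2FC(0–10) = log2FC(0–6) +
  log2FC(6–10) holds exactly. Baseline means are log-uniform on
  [5, 2000]; library-size factors log-uniform over a 4-fold range
  (exercising size-factor estimation); dispersion follows
  α(μ) = 0.02 + 2/μ, a typical bulk RNA-seq mean–dispersion profile.
  Counts are drawn as Gamma–Poisson mixtures.
* **Homology scenario.** 47% of transcripts get a protein-database best
  hit and 54% one to three domain hits (the coverage levels of the real
  reference); a configurable fraction hits the core set, with deliberate
  many-to-one and one-to-many hits to exercise duplicate elimination.

All randomness flows from one integer seed with one generator stream per
output, so all outputs are byte-reproducible; the end-to-end manifest
hashes every file and is asserted identical across same-seed runs.

**What the synthetic data does not emulate:** real sequences (composition
bias, repeats, paralogy — homology is injected, not computed), alignment
artifacts and multi-mapping, the 3'-bias of the poly(A)-tailing library
protocol, non-monotone expression trajectories, and strain-specific
expression beyond an optional Gaussian offset. Passing tests therefore
demonstrate correctness of the algorithms and calibration of the test
under the stated model — not performance on real libraries, where
dispersion outliers and systematic biases are harsher.

## Problem sizes

The shipped analysis scripts use 400 genes (640 transcripts pre-revision)
and 12 samples; statistical checks use 4000–10 000 transcripts where rates
are estimated (type-I error, recovery). These sizes give Monte-Carlo error
comfortably inside the asserted bands while keeping any single check in
the seconds-to-a-minute range.

## Known limitations

* The Wald test uses a normal reference distribution, not t; with very few
  replicates and no trend shrinkage it would be anticonservative. The
  default shrinkage weight (0.8) assumes the mean–dispersion trend form
  fits; data violating it (e.g. bimodal dispersion) would bias gene-wise
  estimates toward the trend.
* Homology joins trust the hit table; spurious shared subjects create
  false joins. The subject-overlap tolerance (10%) is a heuristic.
* The consolidation fixpoint guarantees no *detected* candidate remains;
  it does not prove global optimality of the grouping when rules conflict.
* Splice-dedup discards minor isoforms entirely; expression attributable
  to them is counted against the retained representative.
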