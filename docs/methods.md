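# Methods

## The model

`tfcoop` predicts whether a target transcription factor (TF) binds a
regulatory sequence *s* from two kinds of predictors: the affinity scores
of a whole PWM library on *s* and the (di)nucleotide composition of *s*.
The linear predictor is

    logit P(y_s = 1) = alpha + sum_{m in Motifs} beta_m * Score_{m,s}
                             + sum_{n in Nucl}  beta_n * Rate_{n,s}

where `y_s` is the Boolean ChIP-seq outcome for the target TF,
`Score_{m,s}` is motif *m*'s score on *s*, and `Rate_{n,s}` is one of 12
reverse-complement-collapsed composition rates.  The coefficients are
estimated by LASSO-penalized maximum likelihood,

    min over (alpha, beta):  (1/n) * sum_s -log L(y_s) + lambda * ||beta||_1

with an unpenalized intercept on internally standardized features.  The
motifs with nonzero `beta_m` are interpreted as the target TF's partners:
a positive coefficient suggests cooperation (the partner's predicted sites
are indicative of the target's presence), a negative one competition.
The target's own PWM competes for selection on equal terms with every
other motif.

### Features

* **Best-hit score** (default): PWMs are derived from position count
  matrices by the log-odds construction `log2(p / bg)` with
  `p = (count + pc * bg) / (total + pc)`, pseudocount `pc = 0.8`
  distributed according to the background (uniform by default; both
  configurable per run).  The score of a sequence is the maximum summed
  log-odds over all positions of *both* strands; the reverse strand is
  scanned by reverse-complementing the matrix, which makes every score
  strand-symmetric.  Windows containing N are skipped; a sequence whose
  every window contains N receives the motif's minimum achievable score so
  it ranks last.
* **TRAP affinity** (alternative scorer): expected bound-molecule count
  summed over all sites of both strands,
  `sum_i R0 e^{-E_i} / (1 + R0 e^{-E_i})`, with the mismatch energy
  `E_i = (1/lambda) sum_j ln(f_j(best) / f_j(b_ij))` computed from
  pseudocount-corrected base frequencies, `lambda = 0.7`, and the width
  dependent default `R0(W) = exp(0.584 W - 5.66)`; both parameters are
  exposed.
* **Composition**: the 2 mononucleotide classes A|T and G|C and the 10
  reverse-complement dinucleotide classes.  All counts are divided by the
  sequence length L — also for dinucleotides, of which there are only
  L−1, so dinucleotide class rates sum to (L−1)/L.  N is excluded from
  the counts but not from L.

### Windows

Regulatory windows are `[anchor − flank, anchor + flank)` in BED
(0-based, half-open) coordinates, 1000 bp by default (`flank = 500`):
promoters anchored at the annotated gene start, enhancers at the interval
mid-point (integer division).  Minus-strand promoters are *not*
reverse-complemented: every downstream feature is strand-symmetric, so
orientation is irrelevant (asserted by tests).  Windows reaching past a
chromosome end, and all-N windows, are dropped and logged.  A window is a
positive example when it overlaps a ChIP-seq peak interval by at least
1 bp (half-open overlap).

### Training sets

Training sets are balanced by construction.  Two sampling modes:

* `uncontrolled`: all positives plus an equal number of uniformly drawn
  negatives.
* `expression_controlled`: positives restricted to expressed sequences
  (expression > 0); negatives drawn to match the positives' expression
  distribution so the model cannot learn an open-vs-closed chromatin
  surrogate.  "Similar expression" is implemented as quantile-bin matching
  on log1p expression (10 bins by default, defined on the positives),
  with shortfalls borrowed from the nearest bins and logged.  The binning
  is a declared convention of this package — the matching tolerance is
  genuinely open — chosen because it is simple, reproducible and testable
  (a paired simulation shows the matched medians track far better than
  uniform sampling).  Replicate expression columns are aggregated by mean
  (CAGE-style replicates) or sum (mature-miRNA to pri-miRNA), selectable.

### Fitting and lambda tiers

The solver is an iteratively-reweighted coordinate descent of the glmnet
family, written for this package (numba-compiled): warm starts down a
60-point geometric lambda path from `lambda_max = max_j |x_j' (y - ybar)| / n`
to `1e-3 * lambda_max` (`1e-2` when p ≥ n), sequential strong-rule
screening with a full KKT check, active-set inner iteration, and
convergence on the weighted squared coefficient change (tolerance `1e-8`;
the single-lambda entry point used in verification runs at `1e-16`).  The
path stops early once 99.9% of the null deviance is explained; the
saturated tail carries no information.  Tests verify the solver against
an independent proximal-gradient (FISTA) implementation of the same
objective to 1e-6.

Penalty selection is stratified 10-fold cross-validation on binomial
deviance ("prediction error"); deviance rather than AUC or
misclassification is the package's choice where the selection loss was
open.  Three tiers are kept:

* `lambda_min` — the CV-error minimum;
* `lambda_1se` / `lambda_3se` — the largest penalties whose CV error is
  within 1 resp. 3 standard errors of the minimum (ties broken toward the
  larger penalty).

LASSO paths do not formally guarantee that the three selection sets nest,
so the documented invariant `S_3se ⊆ S_1se ⊆ S_min` is enforced by
downward intersection; removed features are logged on the model object
(`nesting_removed`) and zeroed in the reported coefficients.  Selected
variables are ranked by the lambda at which they first enter the path
(first entry = most important); ranking by |standardized beta| is an
option.

Out-of-fold predicted probabilities are stored per tier for every
training sequence.  Any evaluation of a model on data that includes its
own training sequences uses these cached predictions (`self_auc`,
`transfer_auc`), never refit predictions — the "keep the CV predictions"
discipline that prevents optimistic AUCs.

### Evaluation

AUC is the rank-based (Mann–Whitney) area with half-credit for ties.
`transfer_auc(model_A, dataset_B)` scores B's sequences with A's CV cache
where available and the fitted predictor otherwise; on A's own training
set it reduces exactly to the cross-validated AUC.
`auc_difference_analysis` groups pairs of experiments (same/different
TF × same/different cell type) by `self_auc(A) − transfer_auc(B on A)`
and compares groups with Welch t-tests (two-sided by default; the paired
analyses in the literature do not state sidedness or variance
assumptions).

### Interpretation layer

* **Jaccard co-binding support**: for each TF B selected in target A's
  model, `|bound(A) ∩ bound(B)| / |bound(A) ∪ bound(B)|` (0 for two empty
  sets, by convention), reported over the three cumulative tier cutoffs
  (every selected pair at `lambda_min` down to the highest-confidence
  pairs at `lambda_3se`) and compared with unselected TFs by a one-sided
  Welch t-test.  Self-pairs (B = A) are excluded.  Sequence ids must be
  globally unique across experiments — the transfer evaluation's CV cache
  is keyed on them (the simulator seed-tags its ids for this reason).
* **Target-PWM inclusion**: a model counts as containing its target when
  the target motif, or any motif whose score column correlates with the
  target's at Pearson r ≥ 0.75, is selected.
* **Motif composition** (for composition-similarity analyses): a motif's
  expected 12-class composition under independent per-column PFM
  distributions, with adjacent-column products for dinucleotides, divided
  by the motif width so it mirrors the per-sequence rates.  This
  definition is the package's own (the quantity is not formally defined
  in the literature we follow): it is consensus-free, length-robust and
  directly comparable to sequence rates.
* **Model clustering**: k-means on Boolean selection vectors (Euclidean
  on 0/1), best of 200 restarts by within-cluster sum of squares, with
  the dispersion-vs-k curve returned for the elbow heuristic.
* **Enrichment**: hypergeometric upper-tail or chi-square tests for
  differential variable selection between model groups; Fisher exact
  tests (one-sided by default) for annotation terms in sequence clusters,
  with the best p per term kept and Benjamini–Hochberg q-values reported
  alongside raw p-values.  Ranked-list (GSEA-style) enrichment is out of
  scope; top-N cutoffs with the hypergeometric test are the provided
  substitute.
* **Promoter/enhancer discrimination**: KNN (k = 1..20) on z-scored
  columns of any sequence description (model scores, raw motif scores, or
  composition rates), 70/30 stratified split.
* **Gini ubiquity**: the mean-difference Gini index of a non-negative
  expression vector; 0 = uniformly expressed, → 1 = sample-specific.

## The synthetic-data generator

The generator produces complete experiments with known ground truth so the
whole pipeline — FASTA/BED/TSV parsing, window building, peak-intersection
labeling, scoring, balancing, fitting, interpretation — runs end to end
without downloads.

* **Background**: first-order Markov chains (not i.i.d., so dinucleotide
  features are informative).  The default chain is CpG-depleted
  (joint CpG mass scaled to 25% of its product value on a mildly AT-rich
  base composition), and the published default composition vector is the
  chain's exact stationary collapsed rates.  User-specified 12-class
  vectors are mapped to a chain by splitting non-self-complementary
  classes equally between orientations; the match is approximate when the
  request is not realizable by a stationary chain.
* **Planting**: per sequence and motif, a site is planted with
  probability 0.5 at a uniform non-overlapping position (informative
  motifs are planted first so decoys never overwrite them), with the word
  drawn from the PFM column distributions and a uniformly random strand.
* **Labels**: Bernoulli with
  `logit p = intercept + sum_partners strength * planted`, strengths +4
  for the target and cooperative partners and −4 for competitive ones by
  default, and an intercept that centers the positive rate slightly below
  one half (−0.6 shift) so balanced subsampling never runs out of
  negatives.  Decoy plantings are independent of the label.  The default
  strengths were fixed by a design calculation before any pipeline
  tuning: the Bayes-optimal AUC of the generative rule at ±4 is ≈ 0.95,
  so a correct implementation has headroom to exceed 0.9 after the loss
  from observing scores rather than planted indicators.
* **Motif library**: random sharp PFMs, width 10–14, one dominant base
  per column at probability 0.95 (≈ 1.7 bits/column, typical of
  well-defined vertebrate core motifs).  Sharpness and width were chosen
  so that a planted site is detectable above the best-hit background of a
  1 kb window — the regime the validation studies assume.
* **Outputs**: a synthetic chromosome with the windows embedded between
  100 bp background gaps (FASTA + window BED), 200 bp peaks centered in
  positive windows (BED) so the interval-intersection labeling path is
  exercised literally, a zero-inflated lognormal expression table linking
  positives to higher expression, and a truth table recording every
  planted site and the generative coefficients.

### What the generator does not emulate

Real promoters are not Markovian at first order; real motif co-occurrence
has spatial structure (spacing, orientation preferences) that the
position-uniform planting ignores; peak strength, mappability artifacts
and cell-type-specific chromatin are absent; expression is generated
directly from the label rather than from a shared latent chromatin state.
Passing the validation studies therefore demonstrates the correctness of
the machinery and its statistical behavior under the stated generative
model — not performance on real ENCODE/FANTOM-scale data.

## Problem sizes used in the validation studies

The standard simulated study is 2000 windows of 1000 bp with 55 motifs
(target + 3 cooperative + 1 competitive + 50 decoys).  The replicated
validation runs 20 seeds of this study for partner recovery and 20 for
null calibration; Jaccard validation pools pairs over 5 replicates; the
transfer study uses 4 datasets over a shared 40-motif library.  The
acceptance script reruns the same studies at 5/5/3 replicates.

## Numerical notes and degenerate inputs

* Constant feature columns are dropped with a warning before fitting; a
  column constant within a single CV fold is harmless (its standardized
  values are zero).
* Probabilities are clipped to [1e-12, 1 − 1e-12] in deviances; IRLS
  weights are floored at 1e-6.
* Quantile bin edges that collapse (ties in positive expression) are
  deduplicated; a fully degenerate distribution falls back to a single
  bin.
* Windows are deduplicated on identical (chrom, start, end, role);
  anchors given as 1-based points are converted on read via a flag.
* Model serialization is plain JSON of all floats at full `repr`
  precision; save/load round-trips are bit-exact and tested.

## Known limitations

* The nesting of tier selection sets is enforced, not emergent; the
  `nesting_removed` log shows when the raw path disagreed.
* Only first-order composition features are implemented; higher-order
  k-mer rates are a documented extension point (reported gains in the
  literature are slight).
* DNA-shape descriptors, dinucleotide PWMs and external deep-learning
  baselines are out of scope.
* The expression-matching convention (quantile bins) is one of several
  defensible choices; results of expression-controlled analyses should be
  read with that in mind.
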