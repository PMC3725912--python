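# Methods

This note documents the statistical procedures `votefuse` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## The integration ensemble

The model is a balanced-bagging late-fusion classifier.  From a labelled
training cohort, `K` predictors are trained on genotype features and `N` on
cytokine features, each on an independent subset of `size/2` cases and
`size/2` controls drawn uniformly without replacement within each class.
Equal class counts keep every base problem balanced regardless of cohort
imbalance; sampling *without* replacement avoids duplicating discrete
genotype rows, which aggravates multicollinearity in small subsets.  Each
fitted predictor casts a hard vote per test sample and the final call is the
unweighted majority of all `K + N` votes.

`K = N + 1` exactly.  The extra predictor goes to the genotype pool (the
larger attribute block) and makes the total vote count `2N + 1`, odd, so a
tie vote is structurally impossible — `tie impossibility` is asserted by the
prediction invariant `final = positive ⇔ K·r_g + N·r_c > (K+N)/2`, where
`r_g`, `r_c` are the per-sample positive-vote fractions of each pool.  When
the single-attribute arms are reported on their own, their pool sizes can be
even; those votes break ties toward negative (control), the conservative
direction for a diagnostic screen.

All predictors within a run use one base-classifier family.  The five
families and their frozen hyperparameters: LDA (priors from training
counts; pooled covariance with a `1e-8` ridge so collinear or constant
features degrade gracefully instead of crashing); SVM with linear,
polynomial (degree 3, `gamma = 1/d`, `coef0 = 0`) and RBF
(`gamma = 1/d`) kernels at cost `C = 1`; Gaussian naive Bayes (normalized
genotype dosages are treated as continuous); and CART (Gini, minimum node
size to split 20, cost-complexity pruning `alpha = 0.01`).  Freezing the
table in code and in run manifests makes runs reproducible across library
versions.  Decision-score ties at exactly the class boundary resolve to
negative.  A predictor that cannot score a sample is a hard error, never an
abstention, preserving the odd vote count.

Randomness: one master seed feeds a single generator; the `K` genotype
subsets are drawn first, then the `N` cytokine subsets.  Sweeps spawn one
child seed per grid cell from the master seed (`numpy` `SeedSequence`), so
cells are independent and order-insensitive.  If a subset turns out
untrainable (e.g. a constant feature under a degenerate draw), a fresh
subset is drawn, up to 10 times, before the run errors.

## Genotype preprocessing

*Risk allele*: per marker, the allele with strictly higher frequency among
non-missing case calls.  An exact 0.5 tie breaks toward the allele that is
*minor* in controls, then lexicographically — deterministic and still
label-driven.  Calls become additive risk-allele dosages (2/1/0).

*Normalization* follows the EIGENSTRAT convention: subtract the training
mean and divide by `sqrt(p(1−p))`, with
`p = (1 + Σg) / (2 + 2n)` the posterior allele-frequency estimate over the
`n` non-missing training genotypes.  Test cohorts reuse the training
statistics unchanged.  Missing calls become exactly 0.0 *after*
normalization, i.e. they sit at the training mean and carry no signal.
A marker whose scale falls below `1e-12` would be dropped as monomorphic;
with the posterior estimator this cannot occur at realistic `n`, so markers
that are constant in training are additionally flagged
(`constant_in_training`) for the record.

*LD pruning*: pairwise `r² = D²/(p_A p_a p_B p_b)` from two-locus haplotype
frequencies estimated by EM under Hardy–Weinberg equilibrium (tolerance
`1e-10`, cap 1000 iterations; only double heterozygotes are
phase-ambiguous, so on tables without them the EM fixed point equals the
closed-form count estimate, which the tests exploit as an oracle).  Markers
are scanned greedily in priority order (caller-supplied, e.g. ascending
GWAS p-value; input order otherwise) and dropped at `r² ≥ 0.8` (default,
configurable) against any kept marker on the same chromosome.  A marker
monomorphic on the joint samples gets `r² = 0` with a warning.

## Cytokine preprocessing

The QC cascade runs in a fixed order on raw concentrations, with "over 5 %"
read as a strict inequality: (1) drop analytes whose missing-cell fraction
exceeds 0.05 (measurement failures); (2) among survivors, drop those whose
exact-zero fraction exceeds 0.05; (3) among the rest, a two-sided
pooled-variance Student's *t* test of case vs control concentrations, drop
when `p > 0.05`.  The *t* statistic is scale-free, so the selection is
invariant to unit changes.  The kept list is decided on the training set
and frozen for the test set.

Standardization is anchored on controls: `n_ij = (c_ij − m_i)/s_i` with
`m_i`, `s_i` the mean and sample SD (`n−1`) of the control samples — of the
data set being standardized, i.e. refit per data set, on the assumption
that healthy controls behave consistently across assay conditions while
cases may not.  Missing cells map to 0.0 (the control mean) after
standardization, mirroring the genotype convention; the alternative of
excluding samples with failed assays is available by dropping them before
alignment.

## Synthetic cohorts

The generator's defaults emulate the study design the package targets:
42/42 training and 73/52 test samples; 40 markers = 29 independent SNPs at
the packaged pooled-frequency presets + 11 planted duplicates; 29
cytokines, 3 informative.  Cases split into aetiological subgroups —
default (0.5 genetic-only, 0.5 cytokine-only, 0 both, 0 neither), allocated
by largest remainder — and a case expresses a signal only in its own
subgroup's attribute block.  That is precisely the regime in which
attribute-separated voting helps: each pool recognizes its own subgroup and
votes near its false-positive rate on the other.

Numeric choices, made once:

* genotypes are HWE draws; the case frequency in genetic subgroups is
  `p1 = min(p0 + 0.2, 0.95)` — a per-marker effect small enough that no
  single SNP classifies well, large enough that the 29-marker panel does;
* cytokines are log-normal (`sigma = 0.5` on the log scale) because serum
  concentrations are positive and right-skewed; informative analytes gain a
  case log-shift of 0.75 (standardized difference ≈ 1.5 per analyte) in
  cytokine subgroups;
* planted LD duplicates are copy-with-flip-noise clones (each allele copy
  flips with probability 0.02) of *common* source markers (risk-allele
  frequency in [0.2, 0.8]), because r² between a common and a rare variant
  is bounded low by frequency mismatch and would not reliably exceed the
  pruning threshold;
* genotype missing rate 0.01.

The fixed QC fixture (84 samples, 29 analytes) plants 7 high-missing, 14
high-zero, 5 null-effect and 3 strong-effect analytes.  The null analytes
use identical case and control value multisets, so their *t* statistic is
exactly zero and the cascade outcome (7/14/5 dropped, 3 kept) is
deterministic by construction rather than by seed luck.

What the synthetic data does **not** emulate: realistic LD block structure
(duplicates only), population stratification, batch effects beyond the
control anchoring, assay detection limits, or correlated cytokines.
Passing tests therefore demonstrate that the machinery is correct and that
the ensemble behaves as designed under its assumed signal structure — not
that any particular accuracy transfers to a real cohort.

## Evaluation

Accuracy, sensitivity (case recall) and specificity (control recall) come
from the fused calls with case as the positive class.  The parameter sweep
covers sampling sizes 40..80 step 2 (21 values) × `N` = 25..1500 step 25
(60 values), 1,260 cells; each cell fits one ensemble and reports all three
arms from the same fitted pools, so integrated vote counts decompose
exactly into the two single-attribute counts.  Summaries are per-arm mean
± SD over all cells, including the unstable small-size cells.  Tests and
examples use reduced grids and moderate pool sizes (e.g. `N` ≤ 500, ≤ 20
seeds), which is where the reported summary statistics stabilize; the full
default grid is a single `run_sweep`/`votefuse sweep` call.

The scatter/corner analysis uses cutoff 0.9 by default: corner IV
(`r_g ≥ 0.9` and `r_c ≥ 0.9`) holds samples confidently positive on both
blocks, corner I (both `≤ 0.1`) confidently negative, corner II
(`r_g ≥ 0.9`, `r_c ≤ 0.1`) genotype-driven and corner III the reverse.
Any cutoff > 0.5 keeps the four corner bands disjoint.

## Known limitations

* Two attribute blocks only; extending to more pools would need a
  generalization of the `K = N + 1` odd-total rule (e.g. an odd overall
  total with a documented allocation), which is deliberately not built.
* Votes are unweighted; no stacking, calibration, or per-pool weighting.
* The LD pruner is panel-scale (tens of markers); it is quadratic in marker
  count and not meant for genome-wide use.
* TSV genotype files do not carry chromosome assignments; without a
  chromosome map all markers are treated as comparable for pruning
  (conservative).  VCF input preserves chromosomes.
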