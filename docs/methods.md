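# Methods

## Scope and model

The pipeline estimates, for every drug in a spontaneous-report database,
the disproportionality of one rare target adverse event (osteonecrosis of
the jaw as the default preferred term), labels drugs positive or negative
for that event, and then learns a chemical-structure classifier for the
label. The statistical model of stage 1 is the standard 2×2 reporting
framework: conditional on the margins, the target-event count for a drug
is hypergeometric under independence, which justifies the Fisher exact
test; the reporting odds ratio (ROR) is the effect measure, and the φ
coefficient an effect-size summary. Stage 2 is a supervised binary
classification on numeric molecular descriptors with a held-out
validation set.

## Cleaning rules (stage 1)

* **Deduplication keys.** Drug (primaryid, drug_seq, drug_name,
  role_code); Reaction (primaryid, pt); Demographic (primaryid, keeping
  the highest case version when present); Therapy (primaryid, drug_seq,
  start, end). Without a version column the last occurrence wins, the
  convention for resubmitted reports. Multi-quarter versioning in real
  extracts is richer than this; the rule is deliberately deterministic.
* **Suspect-role filter.** Only first/second-suspect rows (PS, SS)
  survive; concomitant and interacting rows are dropped, unknown codes are
  dropped with a warning.
* **Joins.** All inner: Drug+Therapy on (primaryid, drug_seq), then
  Demographic and Reaction on primaryid. A retained row therefore always
  carries a drug, a therapy window, an onset and an event term.
* **Time-series filter.** Keep iff start ≤ onset ≤ end, inclusive at both
  ends. Partial dates (year or year-month) and unparseable dates are
  excluded and counted separately from ordering violations. Provenance
  counters reconcile exactly to the output row count.

## Disproportionality statistics

The +½ Haldane–Anscombe correction applies to the ROR only; the exact
test and φ use raw integer counts (an exact test needs integers; the
correction exists to stabilize the odds-ratio estimate). The two-sided
Fisher p-value follows the point-probability (minimum-likelihood) rule.
For tables with total count ≤ 500 it is computed by exact integer
enumeration of the hypergeometric support, so probability ties are
resolved without floating-point ambiguity; larger tables use scipy's
implementation of the same rule, which is numerically indistinguishable at
that scale and much cheaper than big-integer arithmetic. Labeling uses
strict inequalities (ROR exactly 1 or p exactly 0.05 → unclassified), and
the report-count gate is the drug's own total, a+b ≥ 100. −log₁₀(p) is
clipped at 300 so underflowing p-values stay plottable.

## QSAR preparation and modeling

Row curation is flag-driven (mixture, large peptide, biologic, inorganic,
organometallic, unresolved name), mirroring a manual curation step;
structure-based detection of these categories is out of scope. Duplicate
drug rows keep the first occurrence. Column pruning drops, in order:
columns with any missing value, constant columns (correlation undefined),
then the later member of any pair with Pearson r² ≥ 1 − 1e−12 (the earlier
column in input order is kept; ties must be broken somehow and input order
is reproducible). Pruning never alters surviving values and is idempotent.

The 3:1 training:validation split is stratified by class so a 60/108 table
yields a 15/27 validation set; whether the original hold-out was
stratified is unknowable from the reported tables, but stratification is
the only variant consistent with the reconstructed validation matrices.

Learners are scikit-learn estimators behind the module surface:
`RandomForestClassifier` (100 trees, min(81, p) candidate features per
split, minimum leaf 5), `GradientBoostingClassifier` (48 stages,
learning rate 0.02, ≤ 3 leaves per tree ≙ two splits), and
`MLPClassifier` with one hidden layer of 3 tanh units. "Three layers" is
read as input/hidden/output with 3 hidden units; an averaged ensemble of
re-seeded nets is available (`boosting_stages`) but off by default. The
neural network standardizes its inputs internally — a practical
requirement for a small multilayer perceptron — and trains with L-BFGS by
default, which is deterministic and robust on tables of this size; the
configured learning rate (default 0.1) takes effect when an SGD-family
solver is selected. No attempt is made to reproduce any particular
software's training trajectory; equivalence is at the algorithm level.

Descriptor importance is total impurity decrease in the random forest,
ties broken alphabetically, with per-descriptor split counts reported.
AUROC is the Mann–Whitney statistic (ties ½). The Youden cutoff
(maximizing sensitivity + specificity − 1) is taken on the **validation**
ROC — the source of the reported cutoff is not derivable from the output
tables, and the validation curve is where the reported thresholded
metrics live — then normalized to 0.5 by the monotone piecewise-linear
map s′ = ½·s/c (s ≤ c), ½ + ½·(s−c)/(1−c) (s > c), which leaves the ROC
point set and AUROC bit-identical. The applicability domain at band w
excludes drugs with |s′ − 0.5| ≤ w, so band 0 removes only exact ties;
retained counts are non-increasing in w. Metric conventions: any 0/0
ratio is defined as 0 and flagged, including an MCC with a zero
denominator; outputs are rounded to 3 decimals, full precision kept
internally.

## What the synthetic data emulate — and what they do not

The report generator plants each positive drug so its odds of the target
event equal lift × background odds; with a rare event the population ROR
of a planted drug essentially equals its lift. It reproduces the
pathologies the ETL must handle: exact duplicate submissions with an
incremented case version (≈2% by default), date triples violating exactly
one of the two window inequalities (≈5%), heavy-tailed per-drug report
totals (log-normal, σ = 1), and concomitant-drug rows. One global seed
fans out to per-table child streams (`SeedSequence.spawn` in a fixed
order) so partial regeneration is stable. It does **not** emulate
drug-name synonymy, MedDRA term hierarchies, multi-drug interaction
reporting, reporting-over-time trends, or informative missingness —
passing tests show the pipeline's rules behave as specified, not that the
rules suffice for real extracts.

The descriptor generator draws each informative feature per class from a
normal censored at zero (negative draws clipped to 0). Censoring, rather
than resampling, was chosen because resampling a wide negative-class
distribution (176.09 ± 193.00) above zero inflates its mean past the
positive class (220.72 ± 84.95) and inverts the documented ordering;
clipping keeps the ordering and piles apolar drugs at exactly 0, which is
what real surface-area descriptors look like. Realized class means are
reported because censoring biases wide classes upward. Collinear columns
are exact affine copies (r² = 1 by construction); missing-value columns
carry ≈5% missing cells.

## Problem sizes used by the test and acceptance runs

Chosen as desk-scale study conditions: signal recovery uses 50 drugs and
10⁵ reports per replicate with five planted lift-5 drugs and a background
event rate of 0.005 — at the headline rarity (2.7 × 10⁻⁴) a 10⁵-report
database holds only ~27 target events in total, so no per-drug statistic
is estimable at this scale (the original database had 1.2 × 10⁷ records);
0.005 keeps the event rare while giving planted drugs expected counts in
the tens. Descriptor recovery uses 200 drugs per class with four
informative features at 1 pooled-SD separation each (overall Mahalanobis
separation 2) among 30 noise features. The exhaustive Fisher check
enumerates every 2×2 table with total ≤ 60 against an independent exact
integer oracle.

## Known limitations

* Event-term matching is case-insensitive exact string equality on the
  preferred term; no term-hierarchy expansion.
* The duplicate model (exact copies with a version bump) is an assumption;
  real resubmissions also revise fields.
* Negative-label recovery is weaker than positive-label recovery at small
  scales: detecting a *deficit* of a rare event needs far more reports
  than detecting an excess, so simulations assert planted-positive
  sensitivity only.
* Scores are used as rankings and thresholds, not calibrated
  probabilities.
* Confidence intervals for the ROR, Bayesian signal detection,
  cross-validation and feature-attribution tools are out of scope.
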