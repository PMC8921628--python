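# Methods

## Scope and model

`mvprof` treats variant effect prediction as supervised binary
classification over a fully enumerable hypothesis space: every protein
variant reachable by a single-nucleotide substitution of one coding
sequence. The target label is *functional abnormality* (D) rather than
clinical pathogenicity — the model learns from functional-assay and
in-silico scores, and the clinical harnesses (annotation databases,
familial cohorts, survival) serve as external validation, not training
signal.

### Variant enumeration

An ORF of L bases sustains exactly 3L substitution events (three
alternative bases per position). Each event is translated in place —
only the affected codon changes — which is equivalent to re-translating
the whole mutant ORF, a property the test suite checks against exactly
that brute-force oracle. Conventions, each configurable:

* initiator-codon non-synonymous events are counted as missense protein
  variants and flagged `start_codon=True`. Methionine-loss variants do
  abolish translation of the canonical product, so they belong in a
  functional screen's scope even though their mechanism differs;
* substitutions inside the stop codon are classified `stop_loss` /
  `stop_retained` and excluded from the missense protein space;
* protein-level deduplication is on (ref AA, codon, alt AA); the
  producing cDNA events remain addressable through an index.

### Labels from multi-database prevalence

The positive rule requires presence (count ≥1) in **every** supplied
database; with ≥2 independent databases, joint recurrence across
disjoint patient sets and technologies is strong evidence of positive
selection. The negative rule takes variants with an **aggregate** count
≤1 over the whole corpus. The aggregate interpretation (rather than
per-database) was chosen because the negative set's rationale is
saturation — a variant seen once anywhere, ever, is compatible with a
sequencing artifact or passenger; both rules are exposed as options
(`per_dataset=`, `max_total_count=`). Labels live at the protein level:
counts of distinct cDNA events yielding the same amino-acid change are
summed before thresholding. Hold-out variants are removed from the
training pools but keep their original label for later experimental
comparison.

### Feature table

42 features in two groups: 14 functional (eight yeast promoter
transactivation readouts, their average and median, one
cell-cycle-arrest readout measured only inside a codon interval, three
mammalian-screen readouts) and 28 computational. Missing values are
filled with per-feature medians; the default fits medians on the whole
table (matching whole-table preprocessing pipelines), and a
`fit_on=` argument restricts fitting to training keys for
leakage-averse workflows — with tree ensembles and features this strong
the difference is negligible, but both modes are first-class. Features
are deliberately untransformed: tree ensembles are invariant to
monotone rescaling, so standardization would only obscure the audit
trail. Multiple score rows mapping to one protein variant should be
aggregated (mean) before table construction.

The representativeness check is classical (Torgerson) MDS on pairwise
Euclidean distances: double-center the squared distance matrix,
eigendecompose, embed on the top two components. For Euclidean input
this equals PCA scores and is deterministic up to sign; the test suite
cross-checks against sklearn's PCA.

### Training protocol

* **Split** 60:20:20, stratified by label (the positive class is ~22% of
  the cohort; stratification stabilizes fold composition). Validation
  and test sizes are floor(0.2·n) each, remainder to train: 1294 labeled
  variants split 778/258/258.
* **Tuning**: random search (50 candidates by default) scored by mean
  10-fold cross-validated AUC on the training split only. The GBM search
  space — depth 2–8, learning rate log-uniform on [0.01, 0.3], 100–1000
  rounds, subsample 0.5–1.0 — is a documented package default, not a
  claim about any published grid; bit-exact reproduction of published
  AUCs is impossible without the original seeds, so agreement is
  statistical.
* **Selection**: argmax of mean validation AUC over repeated tuned runs
  (10 by default), ties broken by mean accuracy, then by algorithm
  order (GBM preferred — boosting's sequential residual fitting tends
  to win on tabular data of this size).
* **Final test**: refit on train+validation (80%), evaluate once on the
  sealed 20%. Index sets are disjoint by construction and a leak check
  raises if they overlap.
* **Decision threshold**: 0.5 by default, boundary inclusive (P(D)=0.5
  → D). `tune_threshold` optionally maximizes validation accuracy over
  score midpoints, keeping the cutoff nearest 0.5 on ties.

### Metrics

Confusion statistics use positive = D; sensitivity is recall on
deleterious variants. Percentages print at two decimals (one decimal
for familial-cohort accuracies, matching the field's reporting
convention); zero-denominator statistics are `None`, never 0. AUC is
the Mann–Whitney rank statistic with mid-rank ties — the probability a
random positive outscores a random negative, ties counting ½ — checked
to 1e-12 against a brute-force pairwise oracle.

### Prevalence statistics

The GVS (germline-to-somatic) ratio is implemented as a ratio of
relative frequencies with an additive pseudocount (default 0.5):
((g_v+a)/(G+a)) / ((s_v+a)/(S+a)). This is an *interpretation* — the
source procedure names the statistic without a formula — and is
documented as such; with pseudocount 0 it is antisymmetric under
compartment swap. MMF counts tumors (records), not occurrence events,
in its denominator. Under the default 91/7/2% single/double/triple
tumor composition with uniform variant assignment, the expected
per-variant MMF is slot-weighted: (2·0.07 + 3·0.02)/(0.91 + 2·0.07 +
3·0.02) ≈ 0.180, which the simulation tests confirm.

### Survival analysis

Samples are partitioned into no-mutation / missense-ND / missense-D /
truncating; truncating means frameshift ins/del, nonsense, or
splice-region/site (case-insensitive, configurable vocabulary mapped
from MAF-style class names). Samples with >1 mutation, patients with >1
sample, and other non-missense classes are excluded, with accounting. A
configurable tumor-type exclusion list (default PCPG, TGCT, DLBC —
types whose tiny mutated-sample counts couple with extreme survival) is
applied before any comparison. Pairwise comparisons use the log-rank
test — the score test of a two-group proportional-hazards model — and
the multivariable analysis is a Cox fit on the D-vs-ND indicator plus
tumor-type dummies (small ridge penalty for separation robustness).

## The synthetic study generator

The generator emulates what matters statistically about each real
input, with one latent variable doing the causal work: each variant has
a loss-of-function degree `z ~ N(Δ·1[D], σ²)` (σ = 1), and every score
is an affine function of z plus independent noise. Functional readouts
see z strongly (noise 0.5σ); computational scores see it at half weight
with unit noise — reproducing the observed ordering in which functional
features outperform computational ones. The transactivation average and
median are computed from the eight promoter readouts, not drawn
independently. The cell-cycle-arrest readout is missing outside a codon
interval (default 94–312), emulating a DNA-binding-domain-restricted
assay; computational scores have a small uniform missing rate (2%).

**Class separation default Δ = 3.4.** With training priors ~22/78 (283
D / 1011 ND), the Bayes-optimal rule on z sits at z* = Δ/2 + ln(π₀/π₁)/Δ
≈ 2.05, giving error π₀·Φ(z*−Δ)+... ≈ 3.5%, i.e. Bayes accuracy ≈
96.5%. The default therefore places the synthetic study in the same
accuracy regime the method is designed for; a model near the Bayes rule
lands in the mid-90s on a 258-variant test set.

Occurrence counts: planted shared variants receive count ≥1 in every
database with lognormal-Poisson intensities (creating hot-spot-like
skew); singletons one count in one database; absent variants none;
unlabeled variants appear in 1–3 databases with total ≥2, so neither
labeling rule captures them. Recovery of the planted sets is exact by
construction and asserted exactly.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: empirical (non-Gaussian)
assay score distributions, correlated missingness beyond one domain
restriction, sequencing-artifact contamination of the negative set,
linkage between occurrence frequency and assay score, or real
tumor-type-specific survival baselines. Synthetic results validate the
*machinery* (rules, protocol, accounting, estimator consistency), not
the biological claim.

Survival fixtures use exponential event times scaled by per-category
hazard ratios (defaults: ND reference 1.0, D 2.0, truncating 2.0,
no-mutation 0.7) with independent exponential censoring; a two-group
Cox fit recovers a planted HR of 2 within 15% at n = 2000, and the null
configuration keeps the log-rank type-I error within its nominal band.

## Numerical choices

* Median of an even count of observations is the mean of the middle two
  (numpy convention), asserted against a sorted-list oracle.
* MDS eigendecomposition symmetrizes B before `eigh` and clips
  negative eigenvalues at 0; output is centered to machine precision.
* Frequency rankings break count ties by variant key (stable mergesort)
  so outputs are reproducible.
* HGVS parsing accepts one- and three-letter amino-acid codes and
  optional accession prefixes; indel/splice/intronic notation yields an
  `UnsupportedVariant` marker rather than an exception, so curation can
  drop such records with accounting.
* All stochastic components consume `numpy.random.default_rng` seeded
  from a single integer; sklearn/xgboost seeds derive from the same
  config field.

## Problem sizes

Default test-suite problem sizes are the study-scale ones (≈2300-variant
spaces, 1294 labeled variants, 10-fold CV) with reduced random-search
budgets (1–5 candidates) — the search budget changes which
hyperparameters win, not the protocol being exercised, and keeps any
single pipeline test in the tens of seconds. Simulation-heavy checks
(tumor corpus composition, type-I calibration) use 5·10⁴–10⁵ draws /
1000 replicates.

## Known limitations

* The enumeration assumes a single transcript and CDS coordinates; no
  genomic liftover, splice-effect prediction or multi-transcript
  handling.
* The classifier consumes precomputed scores only; none of the upstream
  predictors or assays are recomputed.
* The GVS ratio's normalization and any outlier cutoffs on GVS/MMF are
  descriptive choices, not reproductions of a published formula.
* Published headline numbers tied to proprietary score tables can only
  be checked in distributional terms through the synthetic study, at
  the generator's documented calibration.
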