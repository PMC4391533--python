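# Methods

This note documents the statistical model behind `exonsplice`: what each
detector computes, what the synthetic benchmark simulates (and what it
deliberately does not), every tunable parameter with its default, and the
numerical conventions that make results reproducible.

## The detection problem

Input is a log2-scale exon × sample expression matrix per gene, with each
sample assigned to one of two conditions, each condition holding at least
two samples. Differential splicing (DS) is an exon-level expression change
between conditions that is *not* explained by the gene-level change, so
every detector normalizes exon signal against a gene summary in some form.
Genes are processed independently; no cross-gene normalization is applied
(inputs are assumed already preprocessed/normalized upstream). Exactly two
conditions are supported. Where a method is orientation-dependent (per-exon
SI sign, ARH), the reference condition is the lexicographically smaller
label, so results never depend on column order.

Aggregation convention: the per-condition exon expression x_{e,c} is the
arithmetic mean of log2 values over that condition's samples, and the
gene-level summary **x**_c is the mean of the per-exon means. Means on the
log scale are the exon-array convention and keep all six methods on one
shared summarization.

## KLAS

Per condition, deviations d_{e,c} = x_{e,c} − **x**_c are softmax-
transformed base 2 into a probability distribution p_{e,c} ∝ 2^{d_{e,c}}
describing each exon's share of the gene's (linear-scale) expression. The
score is the spread-weighted symmetrized Kullback–Leibler divergence

    kl(c1,c2) = Q_c1 Σ_e p_{e,c1} log2(p_{e,c1}/p_{e,c2})
              + Q_c2 Σ_e p_{e,c2} log2(p_{e,c2}/p_{e,c1}).

All exponentials and logarithms are base 2, consistent with the log2 input
scale (a deviation of d log2 units weighs an exon by the fold change 2^d).
The score is ≥ 0 whenever both Q weights are ≥ 0, zero iff the two
distributions coincide, symmetric in the conditions, and invariant under
adding a constant to the whole matrix. At least 2 exons and 2 samples per
condition are required; 1-exon genes are skipped explicitly in batch mode.

**The Q weight** measures within-condition deviation spread as a ratio of
the 0.75 and 0.25 quantiles. A literal quotient of log-scale deviation
quantiles is undefined whenever a quantile is zero or the two differ in
sign (log-scale deviations are centered, so this is the typical case, not
the exception). `klas.q_mode` therefore offers three modes:

* `quotient_linear` (default) — quotient of the quantiles of the
  linear-scale weights 2^{d_e}. Always positive, ≥ 1 for ordered
  quantiles, and preserves the quotient functional form.
* `iqr_log` — plain interquartile range of d (the same spread notion ARH
  uses); can be 0, never negative.
* `fixed_1` — disables weighting; useful for analytic tests since the
  score reduces to the plain symmetrized divergence.

Quantiles use linear interpolation (numpy default).

## Comparator methods

* **SI**: per-exon SI_e = (x_{e,c1} − **x**_{c1}) − (x_{e,c2} − **x**_{c2});
  gene score max_e |SI_e|. Antisymmetric per exon under condition swap,
  gene score symmetric. Published decision cutoffs 1.5 and 2 (log2 scale)
  are exposed as `si.cutoff` (default 1.5); benchmark classification uses
  permutation p-values instead, avoiding the cutoff choice.
* **ARH**: s_e = SI_e − median_e(SI); q = softmax2(s); score =
  IQR(s) · (1 − H(q)/log2(E)) with H the Shannon entropy (base 2) and E
  the exon count. Zero when all exons behave alike (uniform q attains the
  maximal entropy log2 E). Published cutoff 0.03 exposed as `arh.cutoff`.
  The formula is reconstructed from the method's published description
  (deviation from the median exon ratio, entropy corrected by its
  theoretical maximum, IQR weighting); the original implementation may
  differ in detail.
* **MIDAS**: each sample's exon values are centered by that sample's
  gene-level mean; each exon gets a two-sided equal-variance two-sample
  t-test (equivalently one-way ANOVA) between conditions; gene p =
  min(E · min_e p_e, 1) (Bonferroni over exons — conservative, matching
  the method's characteristically high specificity). Degenerate exons
  (zero pooled variance) give p = 1 when the group means agree.
* **PAC**: per exon, the Pearson correlation across *all* samples between
  the exon's values and the per-sample gene-level values; score =
  1 − min_e r_e. Zero-variance exons are skipped with a logged warning.
  Using all samples jointly (rather than per-condition correlations)
  makes the score *invariant under condition relabeling*; its permutation
  p-value is therefore identically 1 and PAC is effectively a score-only
  (ranking) method in this package — its benchmark AUC comes from scores,
  while its p-value-based accuracy sits at 0.5 by construction.
* **ANOSVA**: F-test of the exon × condition interaction in the two-way
  fixed-effects model `log2 expr ~ exon + condition + exon:condition` by
  model comparison. Every exon is measured in every sample, so cell
  counts are proportional and the additive least-squares fit has the
  closed form (exon margin + condition margin − grand mean); the
  implementation agrees with `statsmodels.anova_lm` (typ=2) to machine
  precision on balanced and unbalanced designs. The design must leave
  positive residual degrees of freedom (≥ 2 samples per condition).

## Permutation p-values

Score methods get gene-wise p-values by relabeling samples while
preserving group sizes. Monte Carlo mode uses the add-one estimator
p = (1 + #{T_perm ≥ T_obs})/(n_perm + 1) — a valid p-value at any finite
n_perm, never zero, with ties counted as exceedances (conservative). When
the total number of distinct assignments C(n, n1) is ≤ `perm.n` and
`perm.exhaustive` is true, all assignments are enumerated instead and
p = #{T ≥ T_obs}/C(n, n1) with the observed assignment included.

Each gene derives its RNG seed from a CRC32 hash of the master seed and
the gene id, so a gene's p-value does not depend on gene order or on
which other genes are present. KLAS, SI and ARH depend on the data only
through per-condition exon means, so all relabelings are scored in one
vectorized pass (group means for every assignment form one matrix
product); the fast path draws the same assignments and applies the same
estimator as the generic per-block loop and is tested to agree exactly.

Defaults: `perm.n = 1000` (the benchmark harness and acceptance script
use 200 to keep grid runs fast), `perm.exhaustive = true`.

## The synthetic benchmark

One benchmark dataset holds 200 genes — 100 true positives (TP) carrying
an injected DS event and 100 true negatives (TN) — in one cell of a
2×2×2×2 factorial design:

| factor | levels | meaning |
| --- | --- | --- |
| `expr` | high / low | baseline log2 expression 10 / 7 (`sim.cmean_high/low`) |
| `enum` | 10 / 30 | exons per gene |
| `pcnt` | 60 / 100 | percent of the affected group's samples carrying the event |
| `snum` | 15:15 / 15:5 | samples per condition (balanced / imbalanced) |

Scenario names encode `expression.exons.percent.samples` with the last
field the smaller group size, e.g. `H.10.100.5`.

The generative model is additive on the log2 scale:

    x[e, s] = cmean(expr) + a_s + b_e + eps[e, s]

with a per-sample gene-level effect a_s ~ N(0, σ_sample²) (the "chip"
effect: biological plus array-level variation of the gene's overall
expression), a per-exon affinity b_e ~ N(0, σ_exon²) (probe-set affinity
differences between exons), and residual noise eps ~ N(0, σ_noise²). This
is the chip-plus-probe decomposition underlying model-based exon-array
summarization. Defaults (log2 units): σ_sample = 0.5, σ_exon = 1.0,
σ_noise = 0.3, all configurable.

A DS event subtracts `sim.ds_delta` (default 2.0, i.e. a 4-fold change)
from the affected exon rows in the affected samples only — exon-skipping
semantics; `sim.ds_sign = +1` flips it to inclusion. Truth layout is
deterministic: TP genes come first; TP 1–50 carry one DS exon and TP
51–100 two (the spliced exons chosen uniformly at random per gene, to
avoid positional artifacts); with `pcnt` = 60, round-half-up of 60% of
the group is affected (9 of 15, 3 of 5). In imbalanced designs half the
TP genes of each DS-exon-count stratum place the event in the large group
and half in the small group — detecting an event carried by 3 of 5
samples is the benchmark's hardest setting; balanced designs place it in
c2 (all methods are label-symmetric up to the fixed orientation, so the
choice is immaterial there). Identical seed, config and scenario give a
bit-identical dataset.

**Low expression.** `sim.noise_expr_factor` (default 2.0) multiplies
σ_noise in low-expression scenarios. On real arrays the residual
log2-scale noise of weakly expressed probe sets is substantially larger
than for strongly expressed ones — near background the signal-to-noise
separation collapses — and this is what makes low expression the harder
setting for every detector. The point matters structurally: all six
methods are invariant under adding a constant to the matrix, so with the
factor at 1.0 the expression level would be a pure location shift with
*no* effect on any method and the benchmark's expression factor would be
vacuous. A doubling of residual noise reproduces the expected behaviour
(every method loses accuracy at low expression) without destroying
detectability. The factor scales only σ_noise: the sample and exon
effects are dominated by biology and probe affinity, not by background.

**What the simulator does not emulate**: probe-level signal and
cross-hybridization, non-Gaussian/heavy-tailed noise, drastic single-
sample outliers, correlated genes, paired designs, annotation errors, and
DS events touching more than two exons. Passing benchmarks here therefore
show correctness and relative behaviour of the detectors under a clean
additive Gaussian model, not performance on raw array data; notably, SI's
known fragility to drastic outliers is invisible under this model.

## Evaluation

Binary calls use strict p < α with `eval.alpha = 0.05` (strict is the
conservative reading of a cutoff "set to 0.05"). No correction across
genes by default; `eval.fdr = true` switches on Benjamini–Hochberg. Genes
without a p-value (skipped by a method) count as not called and are
logged. Accuracy, sensitivity and specificity come from the confusion
counts; ratios with zero denominator are reported absent rather than 0.
AUC is the rank-based (Mann–Whitney) probability that a random TP
outranks a random TN with ties at ½ — computed from scores for the score
methods (no cutoff involved) and from p-values (smaller = more evidence)
for MIDAS and ANOSVA. On balanced truth, binary-call accuracy equals
(sensitivity + specificity)/2, which is the AUC of the 0/1 call vector.

`benchmark_grid` simulates each scenario with a seed derived from the
master seed and the scenario index, runs every method, tabulates the four
metrics per cell, flags per-scenario accuracy maxima (ties allowed), and
emits per-method averages over the 16 scenarios. A failed cell is
recorded as absent and the run continues. Identical config and master
seed reproduce the grid byte for byte.

`anova_parameter_influence` fits, per method, a main-effects linear model
of accuracy on the four binary factors over replicated grids (≥ 2
independent simulation seeds are required — variance between replicates
is the error term) and flags a factor '+' when its F-test p < 0.05. A
per-gene bootstrap within a single dataset would be a cheaper alternative
but conflates gene-level and replicate-level variation, so it is not the
default path.

## Numerical choices and degenerate inputs

* Softmax is computed with max-subtraction; probabilities are strictly
  positive and sum to 1 to machine precision.
* Test statistics that are exactly 0, or undefined through zero variance
  with equal means, yield p = 1; separated means with zero variance yield
  p = 0 (only reachable on constructed data).
* Permutation ties count as exceedances (p biased up, never down).
* Expression TSVs are written with 17 significant digits so a write/read
  round trip is float-exact; grid TSVs use 10.
* Master seeds derive per-scenario and per-gene sub-seeds by offset and
  CRC32 respectively; all derived seeds stay below 2³¹.

## Known limitations

* Exactly two conditions. The KLAS construction would extend to more
  (per-condition distributions pairwise compared), but this is not
  implemented.
* No missing values; matrices must be complete and finite.
* ANOSVA's model contains no per-sample term, so the simulator's a_s
  effect inflates its residual variance: under the default σ_sample = 0.5
  its null rejection rate is far below the nominal α (it is hyper-
  specific rather than calibrated). This mirrors the method's published
  behaviour and is a property of the method, not of this implementation —
  with σ_sample = 0 the test is exactly calibrated.
* PAC's permutation p-value is degenerate (see above); rank PAC by score.
* MIDAS's Bonferroni gene p is mildly conservative under the negative
  correlation that gene-level centering induces between exons.
* The paper-style benchmark runs here use reduced problem sizes by
  default (50 TP + 50 TN per scenario, 200 permutations in the harness);
  both are single flags/config keys away from the full 100 + 100 × 1000
  setting.
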