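# Methods

## Model and procedure

The scan treats each cell line as its own ranking universe. For cell line
*c*, the viabilities of all perturbed genes with an observed score are
ranked ascending (average ranks on ties) and mapped to [0, 1] by
(rank − 1)/(M_c − 1), where M_c is the number of observed genes in that
column. Lower viability → lower rank. With thousands of genes the
normalized rank is fine-grained enough to treat as continuous, so under the
null that a perturbation does not affect a cell line its normalized rank is
Uniform(0, 1).

For driver *d* with mutated cell-line set C_d of size n, the per-partner
statistic T = Σ_{c∈C_d} r_{c|g} follows the Irwin–Hall distribution of
order n under the null. The reported p is the lower tail P(T < t_obs):
synthetic lethality makes the partner knockdown rank consistently near the
bottom of every mutated cell line. Wild-type cell lines are tested
two-sidedly (doubled smaller tail) and a pair is discarded when its
wild-type p falls below `wt_alpha`, i.e. when the knockdown is not neutral
in cells lacking the driver mutation. The wild-type filter is disabled in
the pan-cancer setting, where the wild-type pool mixes many lineages and
neutrality across all of them is too strong a requirement.

Multiple testing is controlled by the family-wise threshold 1/(M × N) over
M perturbed genes and N drivers: the expected number of null pairs passing
is ≈ 1 per scan, a deliberately blunt rule that favors precision over
recall. Per driver, statistics are sorted ascending within groups of equal
n (missing viabilities make n vary by partner) and evaluated until the
first p ≥ threshold; because the Irwin–Hall CDF is monotone in t at fixed
n, this early stop returns exactly the exhaustive-scan result (asserted
empirically against a brute-force all-pairs scan).

Only the driver → partner direction is tested. A driver that is itself in
the perturbation panel can pair with itself; such hits are flagged as
oncogene addiction rather than synthetic lethality.

## Preprocessing rules

* **Essentiality filter**: a gene is removed when its RSA score is ≤ −3 in
  strictly more than 50% of the analysis universe's cell lines (pan-cancer:
  all screened lines; cancer-specific: that cancer's lines). Essential genes
  rank low everywhere and would otherwise dominate every driver's hit list.
* **Mutation binarization**: a (gene, cell line) entry is 1 iff a
  non-synonymous MAF call exists — plus, in the pan-cancer mode only, a
  discrete deep-deletion call (−2 on the GISTIC-like scale). Copy number is
  ignored in the cancer-specific mode, where it is too noisy to binarize
  reliably.
* **Driver selection**: pan-cancer keeps genes altered in more than 30 cell
  lines (stored as `min_pan = 31` to make the strict inequality explicit,
  counted after intersecting with the screened lines); cancer-specific keeps
  genes mutated in ≥ 2 lines that also appear in a supplied
  significantly-mutated-gene list (q ≤ 0.05 from an external driver caller,
  consumed as input).
* **CRISPR scores** are median-centered per gene across cell lines before
  ranking (idempotent; missing entries excluded from the median and
  preserved).
* Cell lines absent from either the screen or the mutation data are dropped
  by intersection; a missing viability removes that gene from that cell
  line's ranking universe only.

## Causal resolution of shared partners

Co-mutation makes several drivers claim the same partner. For each driver d
in such a set S, treated = cells mutated in d, controls = the rest,
covariates = mutation status of S∖{d}, outcome = raw viability of the
partner knockdown. Propensity scores come from a ridge-penalized logistic
regression (C = 100): sparse binary mutation covariates routinely separate
the arms perfectly and an unpenalized fit diverges. Matching is 1-to-1
nearest-neighbor with replacement; a treated cell is dropped when its
nearest control is farther than `caliper` (default 0.1) standard deviations
of the score distribution. Exact distance ties — the norm with binary
covariates, where scores take few distinct values — are broken at random
per treated unit; matching is therefore stochastic, and it is repeated over
`n_reshuffles = 50` sample orders, keeping the run with the smallest total
absolute standardized mean difference (mean difference / pooled SD, the
standard balance diagnostic). The kept run feeds a one-sided paired t-test
(treated < control, `paired_alpha = 0.05`). Random tie-breaking matters:
deterministic first-in-order ties would match every treated cell in a
stratum to the same control, leaving the paired test riding on a single
control draw and badly miscalibrated. Drivers with no confounders pass
through as resolved; fewer than 2 matched pairs is flagged unresolvable
rather than silently dropped.

The paired test's sidedness (treated < control) follows the SL direction;
unmatched treated units simply do not enter the test.

## Cross-screen integration

Hits from a primary (shRNA) and secondary (CRISPR) screen are unioned; a
pair unique to one screen gets its p looked up in the other screen's
exhaustive p matrix. The two mutant p-values are combined by Fisher's
method (upper tail of χ²₄ at −2(ln p₁ + ln p₂); exact zeros floored at the
smallest positive float with a warning) and kept when the combined p clears
the primary screen's 1/(M × N). Outside the pan-cancer mode a pair is
dropped only when wild-type-significant in *both* screens — failing in one
screen alone is tolerated, so the combination can rescue pairs a single
screen's filter would discard. Pairs untestable in one screen (partner not
perturbed, or driver left without mutated lines there) are reported with a
single-screen flag and never combined; imputing p = 1 would bias the union.

## Validation statistics

* **Drug response**: one-sided Welch t-test that cell lines mutated in the
  driver respond more strongly (lower viability) to a drug targeting the
  partner; Welch because drug-screen group variances are heterogeneous.
  One test per (pair, drug); Benjamini–Hochberg q-values across all tests.
  Oncogene-addiction pairs are excluded — the drug targets the driver
  itself there, confounding the contrast.
* **Permutation control**: empirical p = #{random K-subsets of the
  candidate universe with ≥ observed significant-drug count}/B, B = 1000 by
  default, matching a 1/B granularity; the (x+1)/(B+1) convention is a flag.
* **Recovery**: hypergeometric upper tail of the overlap between predicted
  and established pairs inside the testable universe, plus
  sensitivity/specificity/accuracy from the 2×2 confusion table. Established
  pairs outside the universe are excluded before testing — they were never
  discoverable.
* **Baselines** (simulation benchmark): one-sided tests that mutated cell
  lines' *raw* viabilities lie below zero — a one-sample signed-rank test
  and a one-sample t-test per pair. The signed-rank p is computed by a
  vectorized implementation (exact null CDF by generating-function
  convolution for n ≤ 25 and no ties, normal approximation with tie and
  continuity correction above — the same switch scipy makes), validated
  against `scipy.stats.wilcoxon` in the tests; the per-pair scipy call is
  three orders of magnitude too slow for the replicate benchmark.
  Two-sample variants (rank-sum / Welch) are provided for users who read
  the baseline as a mutant-vs-wild-type comparison.
* **ROC / PR**: p-values as scores (smaller = more significant),
  trapezoidal AUROC and step-wise average precision via scikit-learn.

## The simulator

`simulate_screen` emulates a single-site screen: background viabilities are
i.i.d. N(μ_s, σ_s²) with defaults μ_s = 0, σ_s = 1 on the (unitless)
viability-score scale, and min_s = −6 standing in for the worst observed
knockdown score of a site. `estimate_sim_params` plugs in a real screen's
per-site mean, SD and minimum instead. Each of the `n_true = 30` planted
pairs — drawn uniformly without replacement over the driver × gene grid —
*replaces* the partner gene's entries in the driver's mutated cell lines
with draws from N((min_s + μ_s)/2, (1.2·σ_s)²): shifted halfway toward the
site minimum, variance mildly inflated. Mutation matrices are Bernoulli
(default prevalence 0.3 per entry, roughly the co-mutation density of
recurrently mutated drivers in small per-cancer panels) with drivers
resampled deterministically until they carry ≥ 2 mutated lines.

What the simulator does **not** emulate: gene–gene correlation of
viabilities (shared pathways, seed effects), per-cell-line screen-quality
offsets, missing values, copy-number-driven artifacts, or reagent-level
noise — real screens violate i.i.d. backgrounds in all these ways. Passing
benchmarks therefore demonstrate correctness and the small-sample power
advantage of ranking, not field performance on real data.

The deterministic fixture (`make_fixture_fig1c`) is a 15-gene × 10-cell
screen whose base values follow the pattern (7·i + 3·j) mod 15 — a
Latin-square-like layout spreading every gene's ranks evenly across
columns, so no non-planted pair can approach the 1/(M×N) boundary — with
one planted pair (driver DG1, partner PG8 given the four lowest viabilities
in DG1's mutated cell lines CL2–CL5). Seeded jitter of ±0.4 on unit-spaced
values cannot reorder any column, so the scan's output is seed-invariant.

## Numerical choices

* Exact Irwin–Hall CDF (n ≤ 20): alternating series
  F(t; n) = (1/n!) Σ_k (−1)^k C(n,k)(t−k)^n with terms in log space,
  compensated (fsum) signed accumulation, and the reflection
  F(t) = 1 − F(n − t) for t > n/2 to keep the series short and cancellation
  mild. Above n = 20 (strict: exact at 20, Gaussian at 21) the N(n/2, n/12)
  approximation is used; at the boundary the two differ by < 0.0014
  everywhere. Arguments outside [0, n] clamp to 0/1.
* Rank normalization default is min-max on average ranks,
  (rank − 1)/(M_c − 1), giving support exactly [0, 1]; the strictly
  interior alternative rank/(M_c + 1) is available as `method="shifted"`.
  Min-max lets an extreme column produce p = 0 exactly; Fisher combination
  floors such zeros with a warning.
* Ties in viability share average ranks; the early-stop sort is stable, and
  reported pairs are sorted by (p, driver, target) for deterministic output.
* Seeds: every stochastic routine takes an explicit seed or Generator; the
  pipeline fans one seed out per stage.

## Problem sizes used in the checks

Null calibration uses 100 replicate global-null screens of 1000 genes × 20
cell lines × 10 drivers; Irwin–Hall Monte-Carlo uses 10⁶ samples per order;
the benchmark uses 50 replicate screens of 500 genes × 8 drivers at 13, 14
and 7 cell lines with 30 planted pairs; causal resolution uses 20 seeds of
a 40-cell two-driver setup. These sizes put Monte-Carlo error well below
the effects being checked while a full run stays in the minutes range on a
single CPU.

## Known limitations

* The 1/(M × N) rule controls the expected false-positive count, not the
  FDR; it is conservative for large M×N and its recall drops accordingly.
* Matching-based resolution inherits nearest-neighbor matching's known
  weaknesses: with-replacement reuse of controls inflates the effective
  sample size of the paired test, and binary covariates give coarse
  propensity strata. The reshuffle + minimum-SMD selection mitigates order
  dependence but cannot create balance that the covariate distribution does
  not support.
* Fisher combination assumes the two screens are independent; shared cell
  lines violate this mildly in the robust-pair direction (anti-conservative
  for concordant noise).
* The wild-type two-sided filter is evaluated within the analysis universe
  being scanned (per cancer in the cancer-specific mode), so a pair may
  pass in one cancer while failing pan-cancer.
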