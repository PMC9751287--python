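# slidr

Rank-based discovery of **synthetic-lethal (SL) gene pairs** from large-scale
perturbation screens.

A pair (driver *d*, partner *g*) is synthetically lethal when cells tolerate
either aberration alone but die when the mutated driver is combined with
knockdown/knockout of the partner — the principle behind PARP inhibition in
*BRCA*-mutant tumors. Genome-scale shRNA and CRISPR screens across mutation-
annotated cancer cell lines contain this signal, but per-cancer sample sizes
are tiny (often < 15 cell lines), where tests on raw viability values lose
power and produce floods of false positives. This package targets
computational biologists mining such screens (Project-DRIVE-style shRNA
ATARiS scores, DepMap-style CRISPR CERES scores) for druggable SL candidates.

## The statistic

For each cell line *c*, rank the viability of *c* under every gene
perturbation and normalize the ranks to [0, 1]. With thousands of perturbed
genes the normalized rank r<sub>c|g</sub> is effectively continuous, and
under the null hypothesis that perturbing *g* does not affect *c*,
r<sub>c|g</sub> ~ Uniform(0, 1). For a driver *d* mutated in the cell-line
set C<sub>d</sub> (|C<sub>d</sub>| = n), the test statistic is

> T = Σ<sub>c ∈ C<sub>d</sub></sub> r<sub>c|g</sub>

which under H₀ follows the **Irwin–Hall distribution** of order *n* (sum of
*n* independent standard uniforms; mean n/2, variance n/12). Synthetic
lethality produces an unusually *small* T; the p-value is the exact lower
tail P(T < t<sub>obs</sub>) for n ≤ 20 and the Gaussian approximation
N(n/2, n/12) above. A two-sided Irwin–Hall test on the driver-wild-type cell
lines filters out perturbations that are simply toxic everywhere (off in the
pan-cancer setting). All M × N pairs are scanned against the family-wise
threshold **1/(M × N)** — calibrated so a full scan reports about one false
positive on average — with sorted early stopping that provably returns the
exhaustive-scan result.

Downstream modules resolve co-mutated drivers that claim the same partner
(propensity-score matching with a 0.1-SD caliper, 50 reshuffled matchings,
minimum total standardized mean difference, one-sided paired t-test),
combine hits across an shRNA and a CRISPR screen with Fisher's method
(χ² with 4 df), and validate predictions against drug-response screens
(one-sided Welch t-tests, BH q-values, 1000-set permutation controls) and
established SL lists (hypergeometric enrichment).

## Worked example

Simulate a 13-cell-line screen with 30 planted SL pairs and scan it:

```python
from slidr import (SimConfig, simulate_mutation_matrix, simulate_screen,
                   normalize_ranks, slidr_scan)

muts = simulate_mutation_matrix(n_drivers=8, n_cells=13, prevalence=0.3, seed=7)
cfg = SimConfig(mu_s=0.0, sigma_s=1.0, min_s=-6.0, n_true=30, seed=7)
screen, truth = simulate_screen(muts, n_genes=500, cfg=cfg)

result = slidr_scan(normalize_ranks(screen), muts, apply_wt_filter=True)
print(f"M={result.M} perturbed genes, N={result.N} drivers, "
      f"threshold 1/(M*N) = {result.alpha_threshold:.2e}")
print(result.to_frame().head(3).to_string(index=False))
found = result.pairs() & truth.true_pairs
print(f"{len(result.tests)} significant pairs, {len(found)} of them planted")
```

prints

```
M=500 perturbed genes, N=8 drivers, threshold 1/(M*N) = 2.50e-04
driver target  n_mut    t_obs        p_mut     p_wt  alpha_threshold  oncogene_addiction            mode
   DG7   PG55      5 0.022044 4.337899e-11 0.311062          0.00025               False cancer_specific
   DG6  PG361      4 0.006012 5.443417e-11 0.890508          0.00025               False cancer_specific
   DG3  PG139      5 0.070140 1.414674e-08 0.159490          0.00025               False cancer_specific
24 significant pairs, 24 of them planted
```

Each row is one candidate pair: `n_mut` mutated cell lines contributed,
`t_obs` is their normalized-rank sum (near 0 = consistently among the most
lethal knockdowns), `p_mut` its lower-tail Irwin–Hall probability, and
`p_wt` the two-sided wild-type p (large = neutral in wild-type cells, as an
SL pair should be). Here every reported pair is a planted one (precision
1.00) at 80% recall — the expected behavior of the 1/(M×N) rule, which
trades recall for ≈ 1 expected false positive per scan.

The same flow is available from the shell:

```sh
slidr simulate --drivers 8 --cells 13 --genes 500 --n-true 30 --seed 7 --out-prefix sim
slidr run --viability sim_viability.tsv --mutations sim_mutations.tsv --out pairs.tsv
slidr benchmark --replicates 20 --seed 0 --out bench.tsv
```

## Layout

| module | contents |
| --- | --- |
| `slidr.screen_io` | TSV loading, mutation binarization, driver selection, RSA essentiality filter, median centering |
| `slidr.ih_core` | rank normalization, Irwin–Hall CDF, the early-stopped scan |
| `slidr.causal_matching` | propensity matching and shared-partner resolution |
| `slidr.screen_integration` | Fisher combination of two screens into robust pairs |
| `slidr.validation_bench` | drug-response tests, q-values, permutation controls, recovery stats, ROC/PR benchmark |
| `slidr.synthetic_data` | ground-truth simulator and the deterministic pipeline fixture |
| `slidr.pipeline`, `slidr.cli` | YAML-configured end-to-end runs and the `slidr` command |

See `docs/methods.md` for the statistical model, parameter defaults and
design decisions.
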