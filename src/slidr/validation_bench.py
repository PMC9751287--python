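"""Downstream validation statistics and the simulation benchmark.

Covers four independent lines of evidence for a predicted SL pair set:

* drug response — a one-sided Welch t-test asking whether the drug targeting
  the partner gene inhibits driver-mutated cell lines more than wild-type
  ones, with Benjamini-Hochberg q-values across all (pair, drug) tests;
* permutation controls — empirical p-values comparing the number of
  significant drug responses among predicted pairs against random pair sets
  of the same size;
* recovery — hypergeometric enrichment of predictions in experimentally
  established SL lists, plus sensitivity / specificity / accuracy over the
  testable pair universe;
* simulation benchmark — ROC / precision-recall comparison of the rank scan
  against one-sided Wilcoxon and t-test baselines on screens with planted
  ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skm

from .ih_core import RankMatrix, all_pair_pvalues, normalize_ranks
from .screen_io import MutationMatrix, ViabilityScreen

__all__ = [
    "DrugValidation",
    "RecoveryReport",
    "BenchmarkCurves",
    "drug_response_test",
    "validate_drug_response",
    "bh_qvalues",
    "permutation_control",
    "recovery_stats",
    "baseline_tests",
    "roc_pr_curves",
    "benchmark_methods",
]


@dataclass(frozen=True)
class DrugValidation:
    driver: str
    target: str
    drug: str
    p: float | None
    q: float | None
    n_mut: int
    n_wt: int
    reason: str = ""


@dataclass(frozen=True)
class RecoveryReport:
    n_predicted: int
    n_established: int
    n_overlap: int
    universe_size: int
    hypergeom_p: float
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass(frozen=True)
class BenchmarkCurves:
    method: str
    fpr: np.ndarray
    tpr: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    auroc: float
    aupr: float


# ---------------------------------------------------------------------------
# drug-response validation


def drug_response_test(
    drug_viab: np.ndarray, mut_status: np.ndarray
) -> tuple[float | None, str]:
    """One-sided Welch t-test: mutated cell lines respond more (lower viability).

    Returns (p, reason); p is None with a reason code when either group has
    fewer than two observed values.
    """
    v = np.asarray(drug_viab, dtype=float)
    m = np.asarray(mut_status, dtype=int)
    mut = v[(m == 1) & ~np.isnan(v)]
    wt = v[(m == 0) & ~np.isnan(v)]
    if len(mut) < 2 or len(wt) < 2:
        return None, "fewer than 2 observed values in a group"
    if np.ptp(mut) == 0 and np.ptp(wt) == 0:
        if mut.mean() == wt.mean():
            return 0.5, ""  # no variance, no difference
        return (0.0 if mut.mean() < wt.mean() else 1.0), ""
    res = stats.ttest_ind(mut, wt, equal_var=False, alternative="less")
    return float(res.pvalue), ""


def validate_drug_response(
    pairs: Iterable[tuple[str, str]],
    drug_screen: pd.DataFrame,
    drug_targets: pd.DataFrame,
    muts: MutationMatrix,
    drop_oncogene_addiction: bool = True,
) -> list[DrugValidation]:
    """Test every (pair, drug) combination with a targetable partner.

    ``drug_screen`` is drugs × cell lines; ``drug_targets`` has columns
    ``drug`` and ``target`` (one row per drug-target link, so a drug mapped
    to several genes yields one test per predicted pair it matches).
    Q-values are Benjamini-Hochberg across all computed tests.
    """
    target_to_drugs: dict[str, list[str]] = {}
    for _, row in drug_targets.iterrows():
        target_to_drugs.setdefault(str(row["target"]), []).append(str(row["drug"]))

    common = [c for c in drug_screen.columns if c in set(muts.cell_ids)]
    results: list[DrugValidation] = []
    for driver, target in pairs:
        if drop_oncogene_addiction and driver == target:
            continue
        for drug in target_to_drugs.get(target, []):
            if drug not in drug_screen.index:
                continue
            v = drug_screen.loc[drug, common].to_numpy(dtype=float)
            m = muts.values.loc[driver, common].to_numpy(dtype=int)
            obs = ~np.isnan(v)
            p, reason = drug_response_test(v, m)
            results.append(
                DrugValidation(
                    driver=driver,
                    target=target,
                    drug=drug,
                    p=p,
                    q=None,
                    n_mut=int((m[obs] == 1).sum()),
                    n_wt=int((m[obs] == 0).sum()),
                    reason=reason,
                )
            )
    ps = [r.p for r in results if r.p is not None]
    if ps:
        qs = iter(bh_qvalues(np.array(ps)))
        results = [
            DrugValidation(
                r.driver, r.target, r.drug, r.p,
                float(next(qs)) if r.p is not None else None,
                r.n_mut, r.n_wt, r.reason,
            )
            for r in results
        ]
    return results


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, monotone-enforced."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


# ---------------------------------------------------------------------------
# permutation control


def permutation_control(
    universe: list[tuple[str, str]],
    K: int,
    tester: Callable[[tuple[str, str]], bool],
    observed_count: int,
    B: int = 1000,
    seed: int = 0,
    plus_one: bool = False,
) -> tuple[float, np.ndarray]:
    """Empirical p: fraction of random K-subsets of the universe whose count of
    test-significant pairs reaches the observed count.

    ``tester`` maps a pair to a significance flag (e.g. "any targeting drug
    shows a significant one-sided response").  The default convention is
    #{null ≥ obs} / B, matching a granularity of 1/B; ``plus_one`` switches
    to the (x+1)/(B+1) convention.  Returns (p, null counts).
    """
    if K > len(universe):
        raise ValueError(f"K={K} exceeds universe size {len(universe)}")
    rng = np.random.default_rng(seed)
    flags = np.array([bool(tester(pair)) for pair in universe])
    counts = np.empty(B, dtype=int)
    for b in range(B):
        idx = rng.choice(len(universe), size=K, replace=False)
        counts[b] = int(flags[idx].sum())
    hits = int((counts >= observed_count).sum())
    p = (hits + 1) / (B + 1) if plus_one else hits / B
    return float(p), counts


# ---------------------------------------------------------------------------
# recovery against established interactions


def recovery_stats(
    predicted: set[tuple[str, str]],
    established: set[tuple[str, str]],
    universe: set[tuple[str, str]],
) -> RecoveryReport:
    """Overlap enrichment and confusion-matrix rates over the testable universe.

    The hypergeometric upper tail is P(X ≥ overlap) for drawing
    ``n_predicted`` pairs from a universe containing ``n_established``
    successes.  Established pairs outside the universe must be excluded by
    the caller (they were never testable).
    """
    if not established:
        raise ValueError("established set is empty")
    if not predicted <= universe or not established <= universe:
        raise ValueError("predicted and established sets must lie inside the universe")
    n_u, n_p, n_e = len(universe), len(predicted), len(established)
    overlap = len(predicted & established)
    p = float(stats.hypergeom.sf(overlap - 1, n_u, n_e, n_p))
    tp = overlap
    fp = n_p - overlap
    fn = n_e - overlap
    tn = n_u - n_p - n_e + overlap
    return RecoveryReport(
        n_predicted=n_p,
        n_established=n_e,
        n_overlap=overlap,
        universe_size=n_u,
        hypergeom_p=p,
        sensitivity=tp / n_e,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
        accuracy=(tp + tn) / n_u,
    )


def exhaustive_permutation_p(
    flags: list[bool], K: int, observed_count: int
) -> float:
    """Exact analogue of ``permutation_control`` by enumerating all K-subsets.

    Only feasible for tiny universes; serves as the small-sample oracle.
    """
    n = len(flags)
    total = hits = 0
    for comb in combinations(range(n), K):
        total += 1
        if sum(flags[i] for i in comb) >= observed_count:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# simulation baselines


def _signed_rank_null_cdf(n: int) -> np.ndarray:
    """Null CDF of the one-sample signed-rank statistic W+ for sample size n.

    Built by the standard generating-function convolution: each rank k
    contributes (1 + z^k) / 2.  Index w gives P(W+ <= w).
    """
    max_w = n * (n + 1) // 2
    pmf = np.zeros(max_w + 1)
    pmf[0] = 1.0
    for k in range(1, n + 1):
        nxt = pmf.copy()
        nxt[k:] += pmf[:-k] if k > 0 else pmf
        pmf = nxt
    pmf /= 2.0**n
    return np.cumsum(pmf)


def _wilcoxon_less_zero(x: np.ndarray) -> np.ndarray:
    """Vectorized one-sample signed-rank test of location < 0.

    ``x`` is (n_genes, n_cells); rows are independent samples.  Zeros are
    dropped (Wilcoxon convention); with no ties and n ≤ 25 the p-value is
    exact via the convolved null CDF, otherwise a normal approximation with
    tie correction and continuity correction is used — the same switch
    scipy's implementation makes.  Rows whose values are all zero get NaN.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty(x.shape[0])
    exact_cdfs: dict[int, np.ndarray] = {}
    for i, row in enumerate(x):
        r = row[row != 0]
        n = len(r)
        if n == 0:
            out[i] = np.nan
            continue
        ranks = stats.rankdata(np.abs(r))
        w_plus = float(ranks[r > 0].sum())
        has_ties = len(np.unique(np.abs(r))) != n
        if n <= 25 and not has_ties:
            cdf = exact_cdfs.setdefault(n, _signed_rank_null_cdf(n))
            out[i] = cdf[int(round(w_plus))]
        else:
            mn = n * (n + 1) / 4.0
            _, tie_counts = np.unique(ranks, return_counts=True)
            tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
            sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
            out[i] = stats.norm.cdf((w_plus - mn + 0.5) / sd)
    return out


def baseline_tests(
    screen: ViabilityScreen,
    muts: MutationMatrix,
    method: Literal["wilcoxon", "ttest", "wilcoxon_two_sample", "ttest_two_sample"],
) -> pd.DataFrame:
    """Per-pair baseline p-values (genes × drivers) on raw viabilities.

    The default variants test whether the driver-mutated cell lines'
    viabilities under each perturbation are located below zero (one-sample
    signed-rank / one-sample t).  ``*_two_sample`` variants compare mutated
    against wild-type cells directly (rank-sum / Welch t), provided for
    users who prefer the two-group reading of the baseline.
    """
    vals = screen.values
    out = pd.DataFrame(np.nan, index=vals.index, columns=muts.driver_ids, dtype=float)
    for driver in muts.driver_ids:
        mut_cells = [c for c in muts.mutated_cells(driver) if c in vals.columns]
        if len(mut_cells) < 2:
            continue
        x = vals[mut_cells].to_numpy(dtype=float)
        if method == "wilcoxon":
            out[driver] = _wilcoxon_less_zero(x)
        elif method == "ttest":
            res = stats.ttest_1samp(x, popmean=0.0, axis=1, alternative="less")
            out[driver] = res.pvalue
        elif method in ("wilcoxon_two_sample", "ttest_two_sample"):
            wt_cells = [c for c in vals.columns if c not in set(mut_cells)]
            y = vals[wt_cells].to_numpy(dtype=float)
            if method == "wilcoxon_two_sample":
                res = stats.mannwhitneyu(x, y, axis=1, alternative="less")
            else:
                res = stats.ttest_ind(x, y, axis=1, equal_var=False, alternative="less")
            out[driver] = res.pvalue
        else:
            raise ValueError(f"unknown baseline method {method!r}")
    return out


# ---------------------------------------------------------------------------
# ROC / PR benchmarking


def roc_pr_curves(
    scores: np.ndarray, truth: np.ndarray, method: str = ""
) -> BenchmarkCurves:
    """ROC and precision-recall curves for p-value-like scores.

    ``scores`` are per-pair values where smaller means more significant
    (p-values); ``truth`` the binary ground-truth labels.  Both classes must
    be present.  AUROC is trapezoidal; the PR area is the step-wise average
    precision.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=int)
    obs = ~np.isnan(s)
    s, y = s[obs], y[obs]
    if y.min() == y.max():
        raise ValueError("both positive and negative labels required")
    ranked = -s  # larger = more significant for sklearn's sweep
    fpr, tpr, _ = _skm.roc_curve(y, ranked)
    precision, recall, _ = _skm.precision_recall_curve(y, ranked)
    return BenchmarkCurves(
        method=method,
        fpr=fpr,
        tpr=tpr,
        recall=recall[::-1],
        precision=precision[::-1],
        auroc=float(_skm.auc(fpr, tpr)),
        aupr=float(_skm.average_precision_score(y, ranked)),
    )


def benchmark_methods(
    screen: ViabilityScreen,
    muts: MutationMatrix,
    truth_labels: pd.DataFrame,
    rank_method: str = "minmax",
) -> dict[str, BenchmarkCurves]:
    """Score every pair with the rank scan and both baselines on one screen.

    Returns curves keyed by method name ("slidr", "wilcoxon", "ttest").
    ``truth_labels`` is the genes × drivers binary matrix from
    :meth:`SimTruth.labels`.
    """
    ranks = normalize_ranks(screen, method=rank_method)
    p_slidr = all_pair_pvalues(ranks, muts, cells="mutant")
    curves = {}
    y = truth_labels.loc[p_slidr.index, p_slidr.columns].to_numpy().ravel()
    for name, p in (
        ("slidr", p_slidr),
        ("wilcoxon", baseline_tests(screen, muts, "wilcoxon")),
        ("ttest", baseline_tests(screen, muts, "ttest")),
    ):
        curves[name] = roc_pr_curves(p.to_numpy().ravel(), y, method=name)
    return curves
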