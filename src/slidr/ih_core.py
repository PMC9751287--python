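"""Irwin-Hall rank statistics and the driver × perturbed-gene scan.

For a driver gene ``d`` mutated in ``n`` cell lines, the statistic for a
candidate partner ``g`` is the sum of the mutated cell lines' normalized
viability ranks under knockdown of ``g``::

    T = sum over mutated cells c of r_{c|g},   r_{c|g} in [0, 1]

Under the null (knockdown of ``g`` does not affect the mutated cells) each
normalized rank is approximately Uniform(0, 1), so ``T`` follows the
Irwin-Hall distribution of order ``n``.  Synthetic lethality shows up as an
unusually small ``T``: the one-sided p-value is the lower tail P(T < t_obs).
A two-sided Irwin-Hall test on the wild-type cell lines filters out
perturbations that are not neutral in the absence of the driver mutation.

The scan tests every (driver, gene) pair against a family-wise significance
level of ``1/(M × N)`` (M genes, N drivers) so that, on average, one false
positive is expected among all reported hits.  Sorting statistics per driver
lets the scan stop early: p is monotone in ``t`` at fixed ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import fsum, lgamma, log
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .screen_io import MutationMatrix, ViabilityScreen

__all__ = [
    "RankMatrix",
    "SLTest",
    "SLResult",
    "normalize_ranks",
    "irwin_hall_cdf",
    "ih_p_lower",
    "ih_p_two_sided",
    "slidr_scan",
    "all_pair_pvalues",
]

#: Largest order for which the exact alternating-series CDF is used; above
#: this the Gaussian approximation N(n/2, n/12) takes over.
EXACT_N_MAX = 20

RankMethod = Literal["minmax", "shifted"]


@dataclass(frozen=True)
class RankMatrix:
    """Per-cell-line normalized viability ranks in [0, 1].

    ``universe_size[c]`` is the number of genes with an observed viability in
    cell line ``c`` — the ranking universe whose size may vary across columns
    when entries are missing.
    """

    ranks: pd.DataFrame
    universe_size: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.ranks.columns)


@dataclass(frozen=True)
class SLTest:
    """One tested (driver, partner) pair."""

    driver: str
    target: str
    n_mut: int
    t_obs: float
    p_mut: float
    p_wt: float | None = None
    oncogene_addiction: bool = False


@dataclass(frozen=True)
class SLResult:
    """Significant pairs of one scan plus the thresholds that defined it."""

    tests: list[SLTest]
    M: int
    N: int
    alpha_threshold: float
    wt_alpha: float
    mode: str
    stop_positions: dict[str, int] = field(default_factory=dict)

    def pairs(self) -> set[tuple[str, str]]:
        return {(t.driver, t.target) for t in self.tests}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "driver": t.driver,
                "target": t.target,
                "n_mut": t.n_mut,
                "t_obs": t.t_obs,
                "p_mut": t.p_mut,
                "p_wt": t.p_wt,
                "alpha_threshold": self.alpha_threshold,
                "oncogene_addiction": t.oncogene_addiction,
                "mode": self.mode,
            }
            for t in self.tests
        ]
        cols = [
            "driver", "target", "n_mut", "t_obs", "p_mut", "p_wt",
            "alpha_threshold", "oncogene_addiction", "mode",
        ]
        return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# rank normalization


def normalize_ranks(
    screen: ViabilityScreen, method: RankMethod = "minmax"
) -> RankMatrix:
    """Rank each cell line's viabilities across genes and map to [0, 1].

    Within a column, observed viabilities get ascending average ranks (ties
    share their mean rank).  The default ``minmax`` normalization maps rank
    ``r`` out of ``M_c`` observed genes to ``(r - 1) / (M_c - 1)`` so the
    support is exactly [0, 1]; ``shifted`` uses ``r / (M_c + 1)``, which
    keeps ranks strictly inside the unit interval.  Missing entries are
    excluded from the universe and stay missing.
    """
    vals = screen.values.to_numpy(dtype=float)
    out = np.full_like(vals, np.nan)
    sizes = {}
    for j, cell in enumerate(screen.cell_ids):
        col = vals[:, j]
        obs = ~np.isnan(col)
        m = int(obs.sum())
        sizes[cell] = m
        if m < 2:
            raise ValueError(
                f"cell line {cell!r} has {m} observed gene(s); ranks need at least 2"
            )
        r = stats.rankdata(col[obs], method="average")
        if method == "minmax":
            out[obs, j] = (r - 1.0) / (m - 1.0)
        elif method == "shifted":
            out[obs, j] = r / (m + 1.0)
        else:
            raise ValueError(f"unknown rank normalization {method!r}")
    ranks = pd.DataFrame(out, index=screen.values.index, columns=screen.values.columns)
    return RankMatrix(ranks=ranks, universe_size=pd.Series(sizes))


# ---------------------------------------------------------------------------
# Irwin-Hall distribution


def _ih_cdf_exact(t: np.ndarray, n: int) -> np.ndarray:
    """Exact Irwin-Hall CDF via the alternating series, order ``n`` ≤ 20.

    F(t; n) = (1/n!) * sum_{k=0}^{floor(t)} (-1)^k C(n, k) (t - k)^n

    Terms are evaluated in log space and accumulated with compensated
    summation.  For t > n/2 the reflection F(t) = 1 - F(n - t) keeps the
    series short and the cancellation mild.
    """
    t = np.asarray(t, dtype=float)
    out = np.empty(t.shape)
    flat_t = t.ravel()
    flat_o = out.ravel()
    log_nfact = lgamma(n + 1)
    for i, ti in enumerate(flat_t):
        if ti <= 0.0:
            flat_o[i] = 0.0
            continue
        if ti >= n:
            flat_o[i] = 1.0
            continue
        reflect = ti > n / 2.0
        x = n - ti if reflect else ti
        terms = []
        for k in range(int(np.floor(x)) + 1):
            if x == k:
                continue
            log_mag = (
                lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)
                + n * log(x - k) - log_nfact
            )
            terms.append((-1.0) ** k * np.exp(log_mag))
        val = min(max(fsum(terms), 0.0), 1.0)
        flat_o[i] = 1.0 - val if reflect else val
    return out.reshape(t.shape)


def irwin_hall_cdf(t: float | np.ndarray, n: int) -> float | np.ndarray:
    """CDF of the sum of ``n`` independent Uniform(0, 1) variables.

    Exact for ``n`` ≤ 20; Gaussian N(n/2, n/12) beyond that, where the exact
    series is numerically fragile and the approximation is already tight.
    Arguments outside [0, n] clamp to 0 / 1.
    """
    if n <= 0:
        raise ValueError(f"Irwin-Hall order must be positive, got {n}")
    scalar = np.isscalar(t)
    if n <= EXACT_N_MAX:
        res = _ih_cdf_exact(np.asarray(t, dtype=float), n)
    else:
        arr = np.clip(np.asarray(t, dtype=float), 0.0, float(n))
        res = stats.norm.cdf(arr, loc=n / 2.0, scale=np.sqrt(n / 12.0))
        res = np.where(np.asarray(t) <= 0, 0.0, np.where(np.asarray(t) >= n, 1.0, res))
    return float(res) if scalar else res


def ih_p_lower(t_obs: float | np.ndarray, n: int) -> float | np.ndarray:
    """Lower-tail p-value P(T < t_obs) of the order-``n`` Irwin-Hall law."""
    return irwin_hall_cdf(t_obs, n)


def ih_p_two_sided(t_obs: float | np.ndarray, n: int) -> float | np.ndarray:
    """Two-sided p-value: twice the smaller tail, capped at 1."""
    lower = np.asarray(irwin_hall_cdf(t_obs, n), dtype=float)
    p = 2.0 * np.minimum(lower, 1.0 - lower)
    p = np.minimum(p, 1.0)
    return float(p) if np.isscalar(t_obs) else p


# ---------------------------------------------------------------------------
# the scan


def _pair_stats(
    ranks: RankMatrix, cells: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (t_obs, n) over the given cell subset, skipping missing."""
    sub = ranks.ranks[cells].to_numpy(dtype=float)
    n = (~np.isnan(sub)).sum(axis=1)
    t = np.nansum(sub, axis=1)
    return t, n


def slidr_scan(
    ranks: RankMatrix,
    muts: MutationMatrix,
    wt_alpha: float = 0.1,
    apply_wt_filter: bool = True,
    alpha: float | None = None,
) -> SLResult:
    """Scan every (driver, perturbed gene) pair for synthetic lethality.

    Per driver, statistics are sorted ascending within groups of equal
    ``n_mut`` and tested sequentially against the family-wise threshold
    ``1/(M × N)`` (overridable via ``alpha``); the first non-significant p
    stops the group, which is exact because p is monotone in ``t`` at fixed
    ``n``.  Pairs surviving the mutant test are then checked with the
    two-sided wild-type filter at ``wt_alpha`` unless ``apply_wt_filter`` is
    off (the pan-cancer convention).  A driver pairing with itself is
    flagged as oncogene addiction.
    """
    gene_ids = np.asarray(ranks.gene_ids)
    cell_set = set(ranks.cell_ids)
    M = len(gene_ids)
    N = len(muts.driver_ids)
    threshold = (1.0 / (M * N)) if alpha is None else alpha

    tests: list[SLTest] = []
    stop_positions: dict[str, int] = {}
    for driver in muts.driver_ids:
        mut_cells = [c for c in muts.mutated_cells(driver) if c in cell_set]
        if not mut_cells:
            raise ValueError(f"driver {driver!r} has no mutated cell lines in the screen")
        wt_cells = [c for c in ranks.cell_ids if c not in set(mut_cells)]
        t_all, n_all = _pair_stats(ranks, mut_cells)

        hits: list[tuple[int, float, float, int]] = []  # (gene idx, t, p, n)
        tested = 0
        for n in np.unique(n_all):
            if n == 0:
                continue
            idx = np.where(n_all == n)[0]
            order = idx[np.argsort(t_all[idx], kind="stable")]
            for gi in order:
                p = float(irwin_hall_cdf(t_all[gi], int(n)))
                tested += 1
                if p >= threshold:
                    break
                hits.append((gi, float(t_all[gi]), p, int(n)))
        stop_positions[driver] = tested

        if hits and apply_wt_filter and wt_cells:
            t_wt, n_wt = _pair_stats(ranks, wt_cells)
        for gi, t_obs, p, n in hits:
            p_wt = None
            if apply_wt_filter and wt_cells and n_wt[gi] > 0:
                p_wt = float(ih_p_two_sided(t_wt[gi], int(n_wt[gi])))
                if p_wt < wt_alpha:
                    continue
            tests.append(
                SLTest(
                    driver=driver,
                    target=str(gene_ids[gi]),
                    n_mut=n,
                    t_obs=t_obs,
                    p_mut=p,
                    p_wt=p_wt,
                    oncogene_addiction=driver == gene_ids[gi],
                )
            )
    tests.sort(key=lambda t: (t.p_mut, t.driver, t.target))
    return SLResult(
        tests=tests,
        M=M,
        N=N,
        alpha_threshold=threshold,
        wt_alpha=wt_alpha,
        mode="pan_cancer" if not apply_wt_filter else muts.mode,
        stop_positions=stop_positions,
    )


def all_pair_pvalues(
    ranks: RankMatrix,
    muts: MutationMatrix,
    cells: Literal["mutant", "wt"] = "mutant",
) -> pd.DataFrame:
    """Exhaustive p-value matrix (genes × drivers), no early stopping.

    ``cells="mutant"`` gives the one-sided lower-tail p over each driver's
    mutated cell lines; ``cells="wt"`` the two-sided p over its wild-type
    cell lines.  Untestable entries (no observed cells) are NaN.  Used by
    the benchmark ROC sweep, cross-screen lookups and as the oracle check
    for the early-stopped scan.
    """
    cell_set = set(ranks.cell_ids)
    out = pd.DataFrame(
        np.nan, index=ranks.gene_ids, columns=muts.driver_ids, dtype=float
    )
    for driver in muts.driver_ids:
        mut_cells = [c for c in muts.mutated_cells(driver) if c in cell_set]
        use = (
            mut_cells
            if cells == "mutant"
            else [c for c in ranks.cell_ids if c not in set(mut_cells)]
        )
        if not use:
            continue
        t_all, n_all = _pair_stats(ranks, use)
        p = np.full(len(t_all), np.nan)
        for n in np.unique(n_all):
            if n == 0:
                continue
            sel = n_all == n
            if cells == "mutant":
                p[sel] = irwin_hall_cdf(t_all[sel], int(n))
            else:
                p[sel] = ih_p_two_sided(t_all[sel], int(n))
        out[driver] = p
    return out
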