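"""Causal resolution of co-mutated drivers sharing one SL partner.

Cell lines carry several driver mutations at once, so two drivers mutated in
overlapping cell-line sets can both pair with the same partner gene in the
scan while only one dependency is real.  For each driver ``d`` in such a set
``S``, the cells mutated in ``d`` form the treated group, the wild-type
cells the controls, and the mutation status of the other drivers
``S \\ {d}`` the confounding covariates.  Propensity-score matching (logistic
model, nearest neighbor with replacement, caliper in SD units of the score)
balances the covariates; because nearest-neighbor matching depends on sample
order, matching is repeated over reshuffled orders and the run with the
smallest total absolute standardized mean difference is kept.  A one-sided
paired t-test (treated viability < matched control viability) on that run
decides whether the driver's association survives adjustment for its
co-mutated confounders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .ih_core import SLResult
from .screen_io import MutationMatrix, ViabilityScreen

__all__ = [
    "MatchSpec",
    "MatchOutcome",
    "propensity_scores",
    "match_groups",
    "standardized_mean_difference",
    "resolve_shared_partner",
    "resolve_result",
]


@dataclass(frozen=True)
class MatchSpec:
    """Matching configuration.

    ``caliper`` is measured in SD units of the estimated propensity score
    (set ``caliper_absolute`` to interpret it on the raw probability scale).
    """

    caliper: float = 0.1
    n_reshuffles: int = 50
    paired_alpha: float = 0.05
    seed: int = 0
    caliper_absolute: bool = False
    ridge_c: float = 100.0

    def __post_init__(self) -> None:
        if self.caliper <= 0:
            raise ValueError("caliper must be positive")
        if self.n_reshuffles < 1:
            raise ValueError("n_reshuffles must be at least 1")


@dataclass(frozen=True)
class MatchOutcome:
    """Resolution verdict for one driver of a shared-partner set."""

    driver: str
    target: str
    confounders: frozenset[str]
    n_matched: int
    smd_per_covariate: tuple[float, ...]
    smd_total: float
    paired_p: float | None
    resolved: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# matching primitives


def propensity_scores(
    covariates: np.ndarray, treatment: np.ndarray, ridge_c: float = 100.0
) -> np.ndarray:
    """Fitted probability of treatment given binary mutation covariates.

    A ridge-penalized logistic regression: sparse binary covariates routinely
    separate the groups perfectly, where an unpenalized fit diverges; the
    penalty keeps every score strictly inside (0, 1).  With zero covariate
    columns the model is uninformative and all scores equal the treated
    fraction.
    """
    covariates = np.asarray(covariates, dtype=float)
    treatment = np.asarray(treatment, dtype=int)
    if covariates.ndim != 2 or covariates.shape[0] != treatment.shape[0]:
        raise ValueError("covariates must be (n_cells, n_confounders)")
    if treatment.sum() == 0 or treatment.sum() == len(treatment):
        raise ValueError("need at least one treated and one control cell")
    n = len(treatment)
    if covariates.shape[1] == 0:
        return np.full(n, treatment.mean())
    model = LogisticRegression(C=ridge_c, solver="lbfgs", max_iter=1000, tol=1e-8)
    model.fit(covariates, treatment)
    return model.predict_proba(covariates)[:, 1]


def match_groups(
    scores: np.ndarray,
    treatment: np.ndarray,
    caliper: float,
    caliper_absolute: bool = False,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """1-to-1 nearest-neighbor matching on the propensity score, with replacement.

    Each treated unit is matched to its nearest control by |score difference|.
    Exact ties between controls are broken at random per treated unit when an
    ``rng`` is supplied (the cited matching package's convention, and the
    reason repeated runs differ), or by the first control in the current
    sample order otherwise.  Treated units whose nearest control lies beyond
    ``caliper × SD(scores)`` (or beyond the raw ``caliper`` when absolute)
    are dropped.  Returns (treated, control) index pairs; may be empty.
    """
    scores = np.asarray(scores, dtype=float)
    treatment = np.asarray(treatment, dtype=int)
    t_idx = np.where(treatment == 1)[0]
    c_idx = np.where(treatment == 0)[0]
    if len(c_idx) == 0:
        return []
    sd = scores.std(ddof=0)
    max_dist = caliper if caliper_absolute else caliper * sd
    pairs: list[tuple[int, int]] = []
    for ti in t_idx:
        d = np.abs(scores[c_idx] - scores[ti])
        d_min = d.min()
        if d_min > max_dist:
            continue
        if rng is None:
            j = int(np.argmin(d))  # first minimum in sample order
        else:
            j = int(rng.choice(np.where(d == d_min)[0]))
        pairs.append((int(ti), int(c_idx[j])))
    return pairs


def standardized_mean_difference(
    cov: np.ndarray, treated_idx: np.ndarray, control_idx: np.ndarray
) -> float:
    """(mean_treated − mean_control) / pooled SD for one covariate.

    Pooled SD is the root mean of the two group variances.  Both variances
    zero: 0 when the means agree, signed infinity otherwise (flagging
    irreparable imbalance).
    """
    cov = np.asarray(cov, dtype=float)
    a, b = cov[np.asarray(treated_idx)], cov[np.asarray(control_idx)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both matched groups must be non-empty")
    diff = a.mean() - b.mean()
    pooled = np.sqrt((a.var(ddof=0) + b.var(ddof=0)) / 2.0)
    if pooled == 0:
        return 0.0 if diff == 0 else np.sign(diff) * np.inf
    return float(diff / pooled)


# ---------------------------------------------------------------------------
# the resolution loop


def _resolve_one(
    driver: str,
    target: str,
    confounders: list[str],
    outcome: np.ndarray,
    treatment: np.ndarray,
    covariates: np.ndarray,
    spec: MatchSpec,
    rng: np.random.Generator,
) -> MatchOutcome:
    n = len(treatment)
    best: tuple[float, list[tuple[int, int]], tuple[float, ...]] | None = None
    scores = propensity_scores(covariates, treatment, ridge_c=spec.ridge_c)
    for _ in range(spec.n_reshuffles):
        order = rng.permutation(n)
        pairs_o = match_groups(
            scores[order], treatment[order], spec.caliper, spec.caliper_absolute, rng
        )
        pairs = [(int(order[a]), int(order[b])) for a, b in pairs_o]
        if not pairs:
            continue
        t_ids = np.array([a for a, _ in pairs])
        c_ids = np.array([b for _, b in pairs])
        smds = tuple(
            standardized_mean_difference(covariates[:, k], t_ids, c_ids)
            for k in range(covariates.shape[1])
        )
        total = float(np.sum(np.abs(smds))) if smds else 0.0
        if best is None or total < best[0]:
            best = (total, pairs, smds)

    if best is None or len(best[1]) < 2:
        n_matched = 0 if best is None else len(best[1])
        return MatchOutcome(
            driver=driver,
            target=target,
            confounders=frozenset(confounders),
            n_matched=n_matched,
            smd_per_covariate=() if best is None else best[2],
            smd_total=np.nan if best is None else best[0],
            paired_p=None,
            resolved=False,
            reason="insufficient matched pairs",
        )

    total, pairs, smds = best
    y_t = outcome[[a for a, _ in pairs]]
    y_c = outcome[[b for _, b in pairs]]
    if np.allclose(y_t, y_c):
        paired_p = 0.5  # t statistic 0: no evidence of a directional effect
    else:
        paired_p = float(stats.ttest_rel(y_t, y_c, alternative="less").pvalue)
    return MatchOutcome(
        driver=driver,
        target=target,
        confounders=frozenset(confounders),
        n_matched=len(pairs),
        smd_per_covariate=smds,
        smd_total=total,
        paired_p=paired_p,
        resolved=paired_p < spec.paired_alpha,
    )


def resolve_shared_partner(
    shared: list[str],
    target: str,
    screen: ViabilityScreen,
    muts: MutationMatrix,
    spec: MatchSpec,
) -> list[MatchOutcome]:
    """Resolve a set of drivers all paired with the same partner gene.

    For each driver the treated group is its mutated cells, controls are its
    wild-type cells, covariates are the mutation status of the other shared
    drivers, and the outcome is the raw viability of the partner knockdown.
    Matching is repeated over ``spec.n_reshuffles`` sample orders; the run
    minimizing total |SMD| feeds a one-sided paired t-test.  A driver with
    no confounders (singleton set) passes through as resolved.
    """
    if not shared:
        raise ValueError("shared driver set must be non-empty")
    if target not in screen.values.index:
        raise ValueError(f"target {target!r} not in screen")
    rng = np.random.default_rng(spec.seed)
    cells = [c for c in screen.cell_ids if c in set(muts.cell_ids)]
    outcome_full = screen.values.loc[target, cells].to_numpy(dtype=float)

    outcomes: list[MatchOutcome] = []
    for driver in shared:
        confounders = [d for d in shared if d != driver]
        if not confounders:
            outcomes.append(
                MatchOutcome(
                    driver=driver,
                    target=target,
                    confounders=frozenset(),
                    n_matched=0,
                    smd_per_covariate=(),
                    smd_total=0.0,
                    paired_p=None,
                    resolved=True,
                    reason="no confounders",
                )
            )
            continue
        treatment = muts.values.loc[driver, cells].to_numpy(dtype=int)
        covariates = muts.values.loc[confounders, cells].to_numpy(dtype=int).T
        observed = ~np.isnan(outcome_full)
        outcomes.append(
            _resolve_one(
                driver,
                target,
                confounders,
                outcome_full[observed],
                treatment[observed],
                covariates[observed],
                spec,
                rng,
            )
        )
    return outcomes


def resolve_result(
    result: SLResult,
    screen: ViabilityScreen,
    muts: MutationMatrix,
    spec: MatchSpec,
) -> pd.DataFrame:
    """Apply shared-partner resolution to every confounded group of a scan.

    Groups the scan's pairs by partner gene; any partner claimed by two or
    more drivers goes through matching-based resolution, singletons pass
    through.  Returns a tidy frame with one row per (driver, target).
    """
    by_target: dict[str, list[str]] = {}
    for t in result.tests:
        by_target.setdefault(t.target, []).append(t.driver)

    rows = []
    for target, drivers in sorted(by_target.items()):
        for oc in resolve_shared_partner(sorted(drivers), target, screen, muts, spec):
            rows.append(
                {
                    "driver": oc.driver,
                    "target": oc.target,
                    "confounders": ";".join(sorted(oc.confounders)),
                    "n_matched": oc.n_matched,
                    "smd_total": oc.smd_total,
                    "paired_p": oc.paired_p,
                    "resolved": oc.resolved,
                    "reason": oc.reason,
                }
            )
    cols = [
        "driver", "target", "confounders", "n_matched",
        "smd_total", "paired_p", "resolved", "reason",
    ]
    return pd.DataFrame(rows, columns=cols)
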