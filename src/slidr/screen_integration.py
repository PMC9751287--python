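"""Cross-screen integration of scan results via Fisher's method.

Hits from a primary shRNA screen and a secondary CRISPR screen are merged by
taking the union of each screen's significant pairs, looking up the missing
screen's p-value for pairs unique to one screen, combining the two mutant
p-values with Fisher's method (−2·(ln p1 + ln p2) ~ χ² with 4 df), and
keeping pairs whose combined p clears the primary screen's 1/(M × N)
threshold.  Outside the pan-cancer setting a pair is additionally dropped
when its wild-type two-sided test is significant in BOTH screens; failing in
only one screen is tolerated, which rescues pairs a single screen's WT
filter would discard.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ih_core import SLResult

__all__ = ["CombinedPair", "fisher_combine", "robust_pairs"]


@dataclass(frozen=True)
class CombinedPair:
    driver: str
    target: str
    p_mut_screen1: float | None
    p_mut_screen2: float | None
    p_fisher: float | None
    wt_pass_screen1: bool
    wt_pass_screen2: bool
    robust: bool
    single_screen: bool = False


def fisher_combine(p1: float, p2: float) -> float:
    """Combine two independent p-values: upper tail of χ²₄ at −2(ln p1 + ln p2).

    Exact zeros are floored at the smallest positive float with a warning —
    a literal zero would make the statistic infinite.
    """
    ps = []
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {p}")
        if p == 0.0:
            warnings.warn("p-value of 0 floored to smallest positive float", stacklevel=2)
            p = sys.float_info.min
        ps.append(p)
    stat = -2.0 * (np.log(ps[0]) + np.log(ps[1]))
    return float(stats.chi2.sf(stat, df=4))


def robust_pairs(
    res1: SLResult,
    res2: SLResult,
    full_p1: pd.DataFrame,
    full_p2: pd.DataFrame,
    full_wt1: pd.DataFrame | None = None,
    full_wt2: pd.DataFrame | None = None,
    wt_alpha: float = 0.1,
    pan_mode: bool = False,
) -> list[CombinedPair]:
    """Merge two scans into robust pairs.

    ``full_p1`` / ``full_p2`` are exhaustive genes × drivers mutant p-value
    lookups for each screen (``all_pair_pvalues``); ``full_wt1`` / ``full_wt2``
    the corresponding two-sided wild-type lookups, required unless
    ``pan_mode``.  The significance threshold for the combined p is the
    primary screen's ``1/(M × N)``.  Pairs untestable in one screen (gene
    not perturbed or driver absent there) are reported with
    ``single_screen=True`` and are never Fisher-combined.
    """
    if not pan_mode and (full_wt1 is None or full_wt2 is None):
        raise ValueError("wild-type p-value lookups required outside pan-cancer mode")
    threshold = res1.alpha_threshold

    def lookup(df: pd.DataFrame | None, target: str, driver: str) -> float | None:
        if df is None or target not in df.index or driver not in df.columns:
            return None
        v = df.loc[target, driver]
        return None if pd.isna(v) else float(v)

    union = sorted(res1.pairs() | res2.pairs())
    out: list[CombinedPair] = []
    for driver, target in union:
        p1 = lookup(full_p1, target, driver)
        p2 = lookup(full_p2, target, driver)
        wt1 = lookup(full_wt1, target, driver)
        wt2 = lookup(full_wt2, target, driver)
        wt_pass1 = wt1 is None or wt1 >= wt_alpha
        wt_pass2 = wt2 is None or wt2 >= wt_alpha
        if p1 is None or p2 is None:
            out.append(
                CombinedPair(
                    driver=driver,
                    target=target,
                    p_mut_screen1=p1,
                    p_mut_screen2=p2,
                    p_fisher=None,
                    wt_pass_screen1=wt_pass1,
                    wt_pass_screen2=wt_pass2,
                    robust=False,
                    single_screen=True,
                )
            )
            continue
        pf = fisher_combine(p1, p2)
        robust = pf < threshold
        if not pan_mode and not (wt_pass1 or wt_pass2):
            robust = False  # WT-significant in both screens
        out.append(
            CombinedPair(
                driver=driver,
                target=target,
                p_mut_screen1=p1,
                p_mut_screen2=p2,
                p_fisher=pf,
                wt_pass_screen1=wt_pass1,
                wt_pass_screen2=wt_pass2,
                robust=robust,
            )
        )
    return out


def combined_to_frame(pairs: list[CombinedPair]) -> pd.DataFrame:
    cols = [
        "driver", "target", "p_drive", "p_crispr", "p_fisher",
        "robust", "wt_pass_drive", "wt_pass_crispr", "single_screen",
    ]
    rows = [
        {
            "driver": p.driver,
            "target": p.target,
            "p_drive": p.p_mut_screen1,
            "p_crispr": p.p_mut_screen2,
            "p_fisher": p.p_fisher,
            "robust": p.robust,
            "wt_pass_drive": p.wt_pass_screen1,
            "wt_pass_crispr": p.wt_pass_screen2,
            "single_screen": p.single_screen,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=cols)
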