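"""Synthetic screens with known ground truth.

The generator mirrors the simulation protocol used to benchmark the scan:
background viabilities for every (gene, cell line) entry are drawn from
``N(mu_s, sigma_s^2)`` — the empirical mean and SD of a primary site's real
viability scores — and each planted synthetic-lethal pair overwrites the
entries of its partner gene in the driver's mutated cell lines with draws
from ``N((min_s + mu_s)/2, (1.2 * sigma_s)^2)``: shifted halfway toward the
site's minimum score, with mildly inflated variance.

Also provides a small deterministic 15-gene × 10-cell fixture in which one
driver/partner pair is planted by construction, so the full pipeline is
testable without any downloaded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen_io import MutationMatrix, ViabilityScreen

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_mutation_matrix",
    "simulate_screen",
    "estimate_sim_params",
    "make_fixture_fig1c",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the viability simulator, all on the viability-score scale.

    Defaults (mu_s = 0, sigma_s = 1, min_s = -6) stand in for site-estimated
    values when no real screen is supplied; ``estimate_sim_params`` produces
    data-derived configs.  ``var_inflation`` scales the planted pairs' SD.
    """

    mu_s: float = 0.0
    sigma_s: float = 1.0
    min_s: float = -6.0
    n_true: int = 30
    var_inflation: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_s < 0:
            raise ValueError("sigma_s must be non-negative")
        if self.min_s > self.mu_s:
            raise ValueError("min_s must not exceed mu_s")

    @property
    def mu_mut(self) -> float:
        return (self.min_s + self.mu_s) / 2.0

    @property
    def sigma_mut(self) -> float:
        return self.var_inflation * self.sigma_s


@dataclass(frozen=True)
class SimTruth:
    """Planted pairs and the generator settings that produced a screen."""

    true_pairs: set[tuple[str, str]]
    config: SimConfig
    muts: MutationMatrix

    def labels(self, gene_ids: list[str]) -> pd.DataFrame:
        """Binary truth matrix (genes × drivers) over all possible pairs."""
        out = pd.DataFrame(0, index=gene_ids, columns=self.muts.driver_ids, dtype=int)
        for d, g in self.true_pairs:
            out.loc[g, d] = 1
        return out


def simulate_mutation_matrix(
    n_drivers: int,
    n_cells: int,
    prevalence: float | list[int] = 0.3,
    seed: int = 0,
    min_mutated: int = 2,
) -> MutationMatrix:
    """Random binary driver × cell-line matrix.

    ``prevalence`` is either a per-entry Bernoulli probability or a list of
    exact per-driver mutation counts.  Drivers ending up with fewer than
    ``min_mutated`` mutated cells are resampled (deterministically under the
    seed); an infeasible request errors out.
    """
    rng = np.random.default_rng(seed)
    drivers = [f"DG{i + 1}" for i in range(n_drivers)]
    cells = [f"CL{i + 1}" for i in range(n_cells)]
    if isinstance(prevalence, (int, float)):
        p = float(prevalence)
        if p <= 0 or p > 1:
            raise ValueError("prevalence probability must be in (0, 1]")
        if n_cells * p < min_mutated and p < 1:
            if n_cells < min_mutated:
                raise ValueError(
                    f"cannot place {min_mutated} mutations in {n_cells} cells"
                )
        rows = []
        for _ in drivers:
            for _attempt in range(1000):
                row = (rng.random(n_cells) < p).astype(int)
                if row.sum() >= min_mutated:
                    break
            else:
                raise ValueError(
                    f"prevalence {p} cannot yield {min_mutated} mutated cells"
                )
            rows.append(row)
        values = np.vstack(rows)
    else:
        counts = list(prevalence)
        if len(counts) != n_drivers:
            raise ValueError("one count per driver required")
        if any(c < min_mutated or c > n_cells for c in counts):
            raise ValueError(
                f"counts must lie in [{min_mutated}, {n_cells}]: {counts}"
            )
        values = np.zeros((n_drivers, n_cells), dtype=int)
        for i, c in enumerate(counts):
            values[i, rng.choice(n_cells, size=c, replace=False)] = 1
    df = pd.DataFrame(values, index=drivers, columns=cells)
    df.index.name = "gene"
    return MutationMatrix(values=df, mode="cancer_specific")


def simulate_screen(
    muts: MutationMatrix,
    n_genes: int,
    cfg: SimConfig,
) -> tuple[ViabilityScreen, SimTruth]:
    """Simulate a viability screen with ``cfg.n_true`` planted SL pairs.

    Background entries are N(mu_s, sigma_s^2); each planted (driver, gene)
    pair replaces the gene's entries in the driver's mutated cell lines with
    N(mu_mut, sigma_mut^2) draws.  Planted pairs are drawn uniformly without
    replacement over the driver × gene grid.  Fully reproducible from
    ``cfg.seed``.
    """
    n_drivers = len(muts.driver_ids)
    n_cells = len(muts.cell_ids)
    n_pairs = n_drivers * n_genes
    if cfg.n_true > n_pairs:
        raise ValueError(f"cannot plant {cfg.n_true} pairs in a {n_pairs}-pair grid")
    rng = np.random.default_rng(cfg.seed)
    genes = [f"PG{i + 1}" for i in range(n_genes)]
    values = rng.normal(cfg.mu_s, cfg.sigma_s, size=(n_genes, n_cells))

    flat = rng.choice(n_pairs, size=cfg.n_true, replace=False)
    true_pairs: set[tuple[str, str]] = set()
    mut_arr = muts.values.to_numpy()
    for f in flat:
        di, gi = int(f) // n_genes, int(f) % n_genes
        cells_idx = np.where(mut_arr[di] == 1)[0]
        values[gi, cells_idx] = rng.normal(cfg.mu_mut, cfg.sigma_mut, size=len(cells_idx))
        true_pairs.add((muts.driver_ids[di], genes[gi]))
    assert len(true_pairs) == cfg.n_true

    df = pd.DataFrame(values, index=genes, columns=muts.cell_ids)
    df.index.name = "gene"
    screen = ViabilityScreen(values=df, screen_kind="shRNA")
    return screen, SimTruth(true_pairs=true_pairs, config=cfg, muts=muts)


def estimate_sim_params(
    screen: ViabilityScreen,
    site: str | None = None,
    n_true: int = 30,
    seed: int = 0,
) -> SimConfig:
    """Plug a site's empirical mean, SD and minimum viability into a SimConfig.

    With ``site`` given, only cell lines mapped to that primary site (via the
    screen's ``site_of``) contribute; otherwise all cells do.
    """
    if site is not None:
        if not screen.site_of:
            raise ValueError("screen has no site annotations")
        cells = [c for c in screen.cell_ids if screen.site_of.get(c) == site]
        if not cells:
            raise ValueError(f"no cell lines annotated with site {site!r}")
    else:
        cells = screen.cell_ids
    vals = screen.values[cells].to_numpy(dtype=float)
    obs = vals[~np.isnan(vals)]
    if obs.size == 0:
        raise ValueError("no observed viabilities for parameter estimation")
    return SimConfig(
        mu_s=float(obs.mean()),
        sigma_s=float(obs.std(ddof=0)),
        min_s=float(obs.min()),
        n_true=n_true,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# deterministic pipeline fixture


def make_fixture_fig1c(seed: int = 0) -> tuple[ViabilityScreen, MutationMatrix]:
    """Deterministic 15-gene × 10-cell screen with one planted SL pair.

    Four drivers; DG1 is mutated in CL2-CL5 and PG8 carries the four lowest
    viabilities in exactly those columns, so a scan must report (DG1, PG8)
    and nothing else.  Base values follow a Latin-square-style pattern
    ``(7*i + 3*j) mod 15`` that spreads each gene's ranks evenly across
    columns, keeping every non-planted rank sum far from significance; the
    seed only adds jitter smaller than half the value spacing, which cannot
    change any within-column ordering.
    """
    rng = np.random.default_rng(seed)
    n_genes, n_cells = 15, 10
    genes = [f"PG{i + 1}" for i in range(n_genes)]
    cells = [f"CL{j + 1}" for j in range(n_cells)]

    base = np.empty((n_genes, n_cells))
    for i in range(n_genes):
        for j in range(n_cells):
            base[i, j] = (7 * i + 3 * j) % n_genes
    # plant (DG1, PG8): below every other value in CL2-CL5 (0-based cols 1..4)
    base[7, 1:5] = -2.0
    base += rng.uniform(-0.4, 0.4, size=base.shape)

    screen = ViabilityScreen(
        values=pd.DataFrame(base, index=genes, columns=cells),
        screen_kind="shRNA",
    )

    # Driver cell sets chosen so their pattern offsets (3*j mod 15) are well
    # separated; the minimal non-planted rank sum then stays above the
    # 1/(M*N) significance boundary with a wide margin.
    mut = np.zeros((4, n_cells), dtype=int)
    mut[0, 1:5] = 1          # DG1: CL2-CL5 (the planted driver)
    mut[1, [0, 6, 7]] = 1    # DG2
    mut[2, [6, 9]] = 1       # DG3
    mut[3, [5, 8]] = 1       # DG4
    muts = MutationMatrix(
        values=pd.DataFrame(mut, index=[f"DG{k + 1}" for k in range(4)], columns=cells),
        mode="cancer_specific",
    )
    return screen, muts
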