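"""End-to-end pipeline: preprocess → scan → causal resolution.

``run_pipeline`` wires the library modules together behind one config object
so a whole analysis is re-derivable from (inputs, config, seed) alone.  All
outputs are TSV plus a JSON run log recording M, N, the significance
threshold, the seed and package versions.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .causal_matching import MatchSpec, resolve_result
from .ih_core import normalize_ranks, slidr_scan
from .screen_io import (
    MutationMatrix,
    ViabilityScreen,
    filter_essential,
    intersect_cells,
    load_matrix,
    load_rsa,
    median_center,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; loadable from YAML."""

    viability: str
    mutations: str
    out_dir: str
    mode: str = "cancer_specific"
    screen_kind: str = "shRNA"
    rsa: str | None = None
    rsa_cut: float = -3.0
    rsa_frac: float = 0.5
    wt_alpha: float = 0.1
    paired_alpha: float = 0.05
    caliper: float = 0.1
    reshuffles: int = 50
    rank_method: str = "minmax"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _load_mutation_matrix(path: str | Path, mode: str) -> MutationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MutationMatrix(values=df.astype(int), mode=mode)  # type: ignore[arg-type]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute preprocessing, the scan, and (when needed) causal resolution.

    Returns the output directory.  Stage errors propagate with the stage
    name prefixed so a failing run names its offending input.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    with stage("load"):
        screen = load_matrix(cfg.viability, screen_kind=cfg.screen_kind)  # type: ignore[arg-type]
        muts = _load_mutation_matrix(cfg.mutations, cfg.mode)
        screen, muts = intersect_cells(screen, muts)

    removed: list[str] = []
    with stage("preprocess"):
        if cfg.rsa is not None:
            screen, removed = filter_essential(
                screen, load_rsa(cfg.rsa), rsa_cut=cfg.rsa_cut, frac=cfg.rsa_frac
            )
        if cfg.screen_kind == "CRISPR":
            screen = median_center(screen)

    with stage("scan"):
        ranks = normalize_ranks(screen, method=cfg.rank_method)  # type: ignore[arg-type]
        result = slidr_scan(
            ranks,
            muts,
            wt_alpha=cfg.wt_alpha,
            apply_wt_filter=cfg.mode != "pan_cancer",
        )
        result.to_frame().to_csv(out / "sl_pairs.tsv", sep="\t", index=False)

    with stage("resolve"):
        shared = pd.Series([t.target for t in result.tests]).value_counts()
        if (shared > 1).any():
            spec = MatchSpec(
                caliper=cfg.caliper,
                n_reshuffles=cfg.reshuffles,
                paired_alpha=cfg.paired_alpha,
                seed=cfg.seed,
            )
            resolved = resolve_result(result, screen, muts, spec)
        else:
            resolved = pd.DataFrame(
                [
                    {
                        "driver": t.driver,
                        "target": t.target,
                        "confounders": "",
                        "n_matched": 0,
                        "smd_total": 0.0,
                        "paired_p": None,
                        "resolved": True,
                        "reason": "no confounders",
                    }
                    for t in result.tests
                ]
            )
        resolved.to_csv(out / "resolved_pairs.tsv", sep="\t", index=False)

    log = {
        "M": result.M,
        "N": result.N,
        "alpha_threshold": result.alpha_threshold,
        "wt_alpha": cfg.wt_alpha,
        "mode": cfg.mode,
        "seed": cfg.seed,
        "n_significant": len(result.tests),
        "n_resolved": int(resolved["resolved"].sum()) if len(resolved) else 0,
        "essential_removed": removed,
        "stop_positions": result.stop_positions,
        "versions": {"slidr": __version__, "python": platform.python_version()},
        "config": asdict(cfg),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return out
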