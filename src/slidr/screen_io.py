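"""Reading, binarization and filtering of perturbation-screen inputs.

The functions here turn delimited text files (viability matrices, MAF-style
mutation calls, discrete copy-number calls, RSA essentiality scores) into the
in-memory containers the scan operates on, and implement the preprocessing
rules: essential-gene removal, mutation binarization, driver selection and
median centering of CRISPR scores.

All matrices are pandas DataFrames with gene identifiers on the rows and cell
line identifiers on the columns; missing viabilities are ``NaN``, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

ScreenKind = Literal["shRNA", "CRISPR"]
Mode = Literal["pan_cancer", "cancer_specific"]

# MAF variant-classification vocabulary, partitioned once so that an unknown
# token is a hard error rather than a silent wild-type call.
NON_SYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "De_novo_Start_OutOfFrame",
        "Start_Codon_SNP",
        "Start_Codon_Del",
        "Start_Codon_Ins",
        "Stop_Codon_Del",
        "Stop_Codon_Ins",
    }
)
SYNONYMOUS_CLASSES = frozenset(
    {
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
        "lincRNA",
        "De_novo_Start_InFrame",
    }
)
#: GISTIC-style discrete copy-number vocabulary; −2 is a deep (homozygous)
#: deletion, the only level that contributes to driver status.
CNV_CALLS = frozenset({-2, -1, 0, 1, 2})
DEEP_DELETION_CALL = -2

MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class ViabilityScreen:
    """Gene-level viability scores for one perturbation screen.

    Parameters
    ----------
    values
        Real matrix, rows = perturbed genes, columns = cell lines.  Entries
        are unitless relative viability scores (ATARiS-style for shRNA
        screens, CERES-style for CRISPR screens); missing entries are NaN.
    screen_kind
        ``"shRNA"`` or ``"CRISPR"``.
    site_of
        Optional map from cell-line id to primary-site label, used by the
        simulation parameter estimator.
    """

    values: pd.DataFrame
    screen_kind: ScreenKind = "shRNA"
    site_of: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "cell line")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_cells(self, cells: Iterable[str]) -> "ViabilityScreen":
        cells = [c for c in cells if c in self.values.columns]
        return replace(self, values=self.values[cells])


@dataclass(frozen=True)
class MutationMatrix:
    """Binary driver-gene × cell-line mutation-status matrix.

    Row support of driver ``d`` is the mutated cell-line set used as the
    conditioning side of every test.
    """

    values: pd.DataFrame
    mode: Mode = "pan_cancer"

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "driver")
        _check_unique(self.values.columns, "cell line")
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mutation matrix entries must be 0 or 1")

    @property
    def driver_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    def mutated_cells(self, driver: str) -> list[str]:
        row = self.values.loc[driver]
        return list(row.index[row == 1])

    def subset_cells(self, cells: Iterable[str]) -> "MutationMatrix":
        cells = [c for c in cells if c in self.values.columns]
        return replace(self, values=self.values[cells])


@dataclass(frozen=True)
class RsaMatrix:
    """RSA gene-level scores used only for the essentiality filter."""

    values: pd.DataFrame


def _check_unique(idx: pd.Index, what: str) -> None:
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {what} ids: {dups}")


# ---------------------------------------------------------------------------
# loading


def load_matrix(
    path: str | Path,
    orientation: Literal["genes_by_cells", "cells_by_genes"] = "genes_by_cells",
    screen_kind: ScreenKind = "shRNA",
    site_of: Mapping[str, str] | None = None,
) -> ViabilityScreen:
    """Load a TSV viability matrix into a :class:`ViabilityScreen`.

    The file must have one header row of cell-line ids, a leading id column,
    and a numeric body in which missing values are spelled ``NA``.  Row and
    column order are preserved.  Duplicated ids and non-numeric body cells
    are errors, the latter reported with their coordinates.
    """
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    if orientation == "cells_by_genes":
        raw = raw.T
    _check_unique(raw.index, "gene")
    _check_unique(raw.columns, "cell line")
    body = raw.mask(raw == MISSING_TOKEN)
    values = body.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & body.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {raw.iloc[r, c]!r} at gene "
            f"{raw.index[r]!r}, cell line {raw.columns[c]!r}"
        )
    values.index.name = "gene"
    return ViabilityScreen(values=values, screen_kind=screen_kind, site_of=site_of)


def write_matrix(screen: ViabilityScreen | pd.DataFrame, path: str | Path) -> None:
    """Write a viability (or any gene × cell) matrix as TSV with NA missing."""
    df = screen.values if isinstance(screen, ViabilityScreen) else screen
    df = df.copy()
    df.index.name = df.index.name or "gene"
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)


def load_rsa(path: str | Path) -> RsaMatrix:
    """Load an RSA score matrix (same layout as a viability matrix)."""
    return RsaMatrix(values=load_matrix(path).values)


def load_mutation_calls(path: str | Path) -> pd.DataFrame:
    """Load MAF-style mutation calls: columns gene, cell_line, variant_classification."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "cell_line", "variant_classification"}
    if missing := required - set(df.columns):
        raise ValueError(f"mutation call table lacks columns: {sorted(missing)}")
    return df


def load_cnv_calls(path: str | Path) -> pd.DataFrame:
    """Load discrete gene-level copy-number calls: columns gene, cell_line, call."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "cell_line": str})
    required = {"gene", "cell_line", "call"}
    if missing := required - set(df.columns):
        raise ValueError(f"CNV call table lacks columns: {sorted(missing)}")
    df["call"] = df["call"].astype(int)
    return df


# ---------------------------------------------------------------------------
# preprocessing rules


def filter_essential(
    screen: ViabilityScreen,
    rsa: RsaMatrix,
    rsa_cut: float = -3.0,
    frac: float = 0.5,
) -> tuple[ViabilityScreen, list[str]]:
    """Drop essential genes: RSA ≤ ``rsa_cut`` in strictly more than ``frac``
    of the screen's cell lines.

    Returns the reduced screen and the list of removed genes.  Every screen
    gene must be present in the RSA matrix; silent pass-through of unscored
    genes would let essential genes leak into the scan.
    """
    missing = [g for g in screen.gene_ids if g not in rsa.values.index]
    if missing:
        raise ValueError(f"genes absent from RSA matrix: {missing[:10]}")
    cells = [c for c in screen.cell_ids if c in rsa.values.columns]
    if len(cells) < len(screen.cell_ids):
        absent = sorted(set(screen.cell_ids) - set(cells))
        raise ValueError(f"cell lines absent from RSA matrix: {absent[:10]}")
    sub = rsa.values.loc[screen.gene_ids, screen.cell_ids]
    n_obs = sub.notna().sum(axis=1)
    n_low = (sub <= rsa_cut).sum(axis=1)
    essential = n_low > frac * n_obs
    removed = list(sub.index[essential])
    kept = replace(screen, values=screen.values.drop(index=removed))
    return kept, removed


def binarize_mutations(
    mut_calls: pd.DataFrame,
    cnv_calls: pd.DataFrame | None,
    mode: Mode,
    genes: Iterable[str] | None = None,
    cells: Iterable[str] | None = None,
) -> MutationMatrix:
    """Binarize mutation (and, pan-cancer only, deep-deletion) calls.

    A driver/cell entry is 1 iff the cell carries a non-synonymous mutation
    in the gene or — in pan-cancer mode — a deep deletion (call −2).
    Cancer-specific mode ignores copy number entirely.  Unknown
    variant-classification tokens are an error.
    """
    unknown = set(mut_calls["variant_classification"]) - NON_SYNONYMOUS_CLASSES - SYNONYMOUS_CLASSES
    if unknown:
        raise ValueError(f"unknown variant_classification tokens: {sorted(unknown)}")
    hits = mut_calls[mut_calls["variant_classification"].isin(NON_SYNONYMOUS_CLASSES)]
    pairs = set(zip(hits["gene"], hits["cell_line"]))
    if mode == "pan_cancer" and cnv_calls is not None:
        bad = set(cnv_calls["call"]) - CNV_CALLS
        if bad:
            raise ValueError(f"unknown CNV call levels: {sorted(bad)}")
        deep = cnv_calls[cnv_calls["call"] == DEEP_DELETION_CALL]
        pairs |= set(zip(deep["gene"], deep["cell_line"]))

    gene_list = sorted({g for g, _ in pairs}) if genes is None else list(genes)
    cell_list = sorted({c for _, c in pairs}) if cells is None else list(cells)
    values = pd.DataFrame(0, index=gene_list, columns=cell_list, dtype=int)
    for g, c in pairs:
        if g in values.index and c in values.columns:
            values.loc[g, c] = 1
    values.index.name = "gene"
    return MutationMatrix(values=values, mode=mode)


def select_drivers(
    mat: MutationMatrix,
    mode: Mode | None = None,
    min_pan: int = 31,
    min_specific: int = 2,
    significant_genes: Iterable[str] | None = None,
) -> MutationMatrix:
    """Retain driver rows meeting the mode's recurrence rule.

    Pan-cancer keeps drivers altered in more than 30 cell lines (encoded as
    ``min_pan = 31``); cancer-specific keeps drivers with non-synonymous
    mutations in at least ``min_specific`` cell lines that additionally
    appear in the supplied significance list (a q ≤ 0.05 driver list is
    consumed as input, not computed here).
    """
    mode = mode or mat.mode
    counts = mat.values.sum(axis=1)
    if mode == "pan_cancer":
        keep = counts >= min_pan
    else:
        if significant_genes is None:
            raise ValueError("cancer_specific driver selection requires significant_genes")
        sig = set(significant_genes)
        keep = (counts >= min_specific) & mat.values.index.isin(sig)
    result = MutationMatrix(values=mat.values.loc[keep], mode=mode)
    if result.values.shape[0] == 0:
        import warnings

        warnings.warn("driver selection retained no genes", stacklevel=2)
    return result


def median_center(screen: ViabilityScreen) -> ViabilityScreen:
    """Subtract each gene's across-cell-line median (CRISPR preprocessing).

    Missing entries are excluded from the median and stay missing.  The
    operation is idempotent.
    """
    med = screen.values.median(axis=1, skipna=True)
    return replace(screen, values=screen.values.sub(med, axis=0))


def intersect_cells(
    screen: ViabilityScreen, muts: MutationMatrix
) -> tuple[ViabilityScreen, MutationMatrix]:
    """Restrict both matrices to their common cell lines, in screen order."""
    common = [c for c in screen.cell_ids if c in set(muts.cell_ids)]
    if not common:
        raise ValueError("no common cell lines between screen and mutation matrix")
    return screen.subset_cells(common), muts.subset_cells(common)
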