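"""Reading and writing count matrices, design tables, gene lists and fixtures.

File dialects
-------------
Count matrix: TSV, UTF-8, first column header ``gene_id``, remaining column
headers are sample ids, cells are non-negative integers (HTSeq-count style).
Design table: TSV with columns ``sample_id``, ``cell_line``, ``condition``
(``treated`` or ``control``) and ``replicate`` (positive integer).
Gene list: one gene id per line.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

CONDITIONS = ("treated", "control")

_S2_FIXTURE = "s2_cell_line_counts.tsv"


class CountsFormatError(ValueError):
    """A count matrix or design table violates the expected format."""


class DesignMismatchError(ValueError):
    """Sample sets of a count matrix and its design table disagree."""


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer counts.

    ``counts`` is a DataFrame indexed by gene id with one column per sample.
    Construction validates rectangularity, uniqueness and integrality.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise CountsFormatError(f"duplicate gene ids: {dup[:5]}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise CountsFormatError(f"duplicate sample ids: {dup[:5]}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            bad = np.argwhere(arr != np.floor(arr))
            if bad.size:
                g, s = bad[0]
                raise CountsFormatError(
                    f"non-integer count {arr[g, s]!r} at gene "
                    f"{df.index[g]!r}, sample {df.columns[s]!r}"
                )
            df = df.astype(np.int64)
            arr = df.to_numpy()
            self.counts = df
        if arr.size and arr.min() < 0:
            g, s = np.argwhere(arr < 0)[0]
            raise CountsFormatError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)])


@dataclass
class SampleDesign:
    """Per-sample annotation: cell line, condition and replicate number."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "cell_line", "condition", "replicate")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise CountsFormatError(f"design table missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise CountsFormatError(f"duplicate sample ids in design: {dup}")
        bad = sorted(set(df["condition"]) - set(CONDITIONS))
        if bad:
            raise CountsFormatError(
                f"unknown conditions {bad}; expected one of {CONDITIONS}"
            )
        rep = pd.to_numeric(df["replicate"], errors="raise")
        if (rep < 1).any() or (rep != rep.astype(int)).any():
            raise CountsFormatError("replicate numbers must be positive integers")
        dup = df.duplicated(subset=["cell_line", "condition", "replicate"])
        if dup.any():
            rows = df.loc[dup, ["cell_line", "condition", "replicate"]]
            raise CountsFormatError(
                f"duplicate replicate numbers within a condition:\n{rows}"
            )
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def cell_lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for cl in self.table["cell_line"]:
            seen.setdefault(cl, None)
        return list(seen)

    def samples_for(self, cell_line: str, condition: str | None = None) -> list[str]:
        df = self.table
        mask = df["cell_line"] == cell_line
        if not mask.any():
            raise KeyError(f"unknown cell line {cell_line!r}")
        if condition is not None:
            mask &= df["condition"] == condition
        return list(df.loc[mask, "sample_id"])

    def subset(self, sample_ids: Iterable[str]) -> "SampleDesign":
        ids = set(sample_ids)
        return SampleDesign(self.table[self.table["sample_id"].isin(ids)].copy())


@dataclass
class GeneList:
    """An unordered collection of unique gene ids."""

    gene_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.gene_ids = frozenset(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    def __iter__(self):
        return iter(sorted(self.gene_ids))


def _check_sample_match(matrix: CountMatrix, design: SampleDesign) -> None:
    m, d = set(matrix.sample_ids), set(design.sample_ids)
    if m != d:
        only_m = sorted(m - d)
        only_d = sorted(d - m)
        raise DesignMismatchError(
            "count matrix and design table disagree on samples; "
            f"matrix-only: {only_m}, design-only: {only_d}"
        )


def read_counts(path: str | Path, design_path: str | Path) -> tuple[CountMatrix, SampleDesign]:
    """Read a count TSV plus design TSV and validate them against each other."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        series = df[col]
        if not np.issubdtype(series.dtype, np.integer):
            as_num = pd.to_numeric(series, errors="coerce")
            bad = series.index[as_num.isna() | (as_num != np.floor(as_num))]
            if len(bad):
                raise CountsFormatError(
                    f"non-integer count {series[bad[0]]!r} at gene {bad[0]!r}, "
                    f"sample {col!r} in {path}"
                )
            df[col] = as_num.astype(np.int64)
    matrix = CountMatrix(df)
    design = SampleDesign(pd.read_csv(design_path, sep="\t", dtype={"sample_id": str}))
    _check_sample_match(matrix, design)
    return matrix, design


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV with a header; empty tables keep the header."""
    records.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> GeneList:
    ids = [line.strip() for line in Path(path).read_text().splitlines()]
    return GeneList(frozenset(i for i in ids if i))


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes.gene_ids)) + "\n")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Long-format category annotation: category_id, category_name, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"category_id", "category_name", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise CountsFormatError(f"annotation table missing columns: {sorted(missing)}")
    return df


def load_s2_fixture() -> pd.DataFrame:
    """Load the packaged gene-by-cell-line-count table.

    Returns a DataFrame with columns ``gene_id`` and ``n_cell_lines_de``
    (the number of cell lines in which the gene was called differentially
    expressed), one row per gene.
    """
    ref = importlib.resources.files("crossde.data").joinpath(_S2_FIXTURE)
    if not ref.is_file():
        raise FileNotFoundError(
            f"packaged fixture {_S2_FIXTURE!r} not found; reinstall the package "
            "with package data included (see pyproject [tool.setuptools.package-data])"
        )
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype={"gene_id": str, "n_cell_lines_de": int})
    if df["gene_id"].duplicated().any():
        raise CountsFormatError("fixture contains duplicate gene ids")
    return df


def qc_sample_correlations(matrix: CountMatrix) -> pd.DataFrame:
    """Spearman correlation between samples on log2(mean-normalized count + 1).

    The log transform is monotone per sample, so rank correlations equal those
    on the normalized counts themselves; it is applied for parity with the
    usual visual QC. Requires at least two samples.
    """
    if matrix.n_samples < 2:
        raise ValueError("sample correlation QC needs at least 2 samples")
    arr = matrix.counts.to_numpy(dtype=float)
    col_means = arr.mean(axis=0)
    col_means[col_means == 0] = 1.0
    norm = arr / col_means * col_means.mean()
    logged = np.log2(norm + 1.0)
    rho = stats.spearmanr(logged, axis=0).statistic
    if matrix.n_samples == 2:  # spearmanr returns a scalar for 2 columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=matrix.sample_ids, columns=matrix.sample_ids)
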