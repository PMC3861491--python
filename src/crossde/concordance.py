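"""Cross-cell-line concordance of DE calls.

Three analyses: pairwise DE-set overlaps standardized against a resampling
null (random gene sets of the same sizes drawn from each cell line's expressed
genes), per-cell-line averages of the higher/lower direction indicator
stratified by how many cell lines call a gene DE, and the empirical tail
probability of the overlap between a gene set and an external reference list.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from crossde.counts_io import GeneList


@dataclass
class OverlapStats:
    cell_line_a: str
    cell_line_b: str
    observed: int
    null_mean: float
    null_sd: float
    z: float  # NaN when the null SD is zero or a DE set is empty
    n_draws: int


@dataclass
class ListOverlapResult:
    observed: int
    n_draws: int
    n_ge_observed: int
    empirical_p: float
    seed: int


def pairwise_overlap(de_a: GeneList | set, de_b: GeneList | set) -> int:
    sa = set(de_a.gene_ids) if isinstance(de_a, GeneList) else set(de_a)
    sb = set(de_b.gene_ids) if isinstance(de_b, GeneList) else set(de_b)
    return len(sa & sb)


def overlap_null(
    expressed_a,
    expressed_b,
    n_a: int,
    n_b: int,
    n_draws: int,
    rng: np.random.Generator | int,
) -> tuple[float, float]:
    """Mean and SD (population denominator) of the overlap between independent
    uniform draws of ``n_a`` genes from ``expressed_a`` and ``n_b`` from
    ``expressed_b``."""
    ua = sorted(set(expressed_a.gene_ids) if isinstance(expressed_a, GeneList) else set(expressed_a))
    ub = sorted(set(expressed_b.gene_ids) if isinstance(expressed_b, GeneList) else set(expressed_b))
    if n_a > len(ua):
        raise ValueError(f"cannot draw {n_a} genes from a universe of {len(ua)}")
    if n_b > len(ub):
        raise ValueError(f"cannot draw {n_b} genes from a universe of {len(ub)}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    shared = sorted(set(ua) & set(ub))
    code = {g: i for i, g in enumerate(shared)}
    codes_a = np.array([code.get(g, -1) for g in ua])
    codes_b = np.array([code.get(g, -1) for g in ub])
    overlaps = np.empty(n_draws)
    for d in range(n_draws):
        da = codes_a[rng.choice(len(ua), size=n_a, replace=False)]
        db = codes_b[rng.choice(len(ub), size=n_b, replace=False)]
        overlaps[d] = np.intersect1d(da[da >= 0], db[db >= 0]).size
    return float(overlaps.mean()), float(overlaps.std())


def overlap_zscores(
    de_sets: dict[str, set],
    expressed: dict[str, GeneList],
    n_draws: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """One record per unordered cell-line pair: observed DE overlap, null
    mean/SD from ``n_draws`` resamples, and the z-score (NaN for degenerate
    pairs)."""
    cell_lines = sorted(de_sets)
    if len(cell_lines) < 2:
        raise ValueError("need at least 2 cell lines")
    rows = []
    for i, j in combinations(range(len(cell_lines)), 2):
        a, b = cell_lines[i], cell_lines[j]
        observed = pairwise_overlap(de_sets[a], de_sets[b])
        n_a, n_b = len(de_sets[a]), len(de_sets[b])
        if min(n_a, n_b) == 0:
            rows.append((a, b, observed, np.nan, np.nan, np.nan, 0))
            continue
        # pair-specific deterministic stream: insensitive to evaluation order
        rng = np.random.default_rng([seed, i, j])
        mean, sd = overlap_null(expressed[a], expressed[b], n_a, n_b, n_draws, rng)
        z = (observed - mean) / sd if sd > 0 else np.nan
        rows.append((a, b, observed, mean, sd, z, n_draws))
    return pd.DataFrame(
        rows,
        columns=[
            "cell_line_a",
            "cell_line_b",
            "observed",
            "null_mean",
            "null_sd",
            "z",
            "n_draws",
        ],
    )


def direction_summary(
    de_results: dict[str, pd.DataFrame],
    n_cell_lines_de: pd.Series,
) -> pd.DataFrame:
    """Mean of the 1/0 direction indicator per cell line and gene stratum.

    ``n_cell_lines_de`` maps gene id -> number of cell lines calling it DE
    (genes absent from the index count as 0). Strata: all genes with a defined
    direction, genes DE in >= 1 cell line, and genes DE in exactly k cell
    lines for k = 2..max. Genes with an undefined (NaN) direction are
    excluded from every mean.
    """
    max_k = int(n_cell_lines_de.max()) if len(n_cell_lines_de) else 0
    rows = []
    for cl in sorted(de_results):
        res = de_results[cl].set_index("gene_id")
        direction = res["direction"].dropna()
        k = n_cell_lines_de.reindex(direction.index).fillna(0).astype(int)

        def add(gene_class: str, mask) -> None:
            vals = direction[mask]
            rows.append(
                (
                    cl,
                    gene_class,
                    float(vals.mean()) if len(vals) else np.nan,
                    int(len(vals)),
                )
            )

        add("all_genes", np.ones(len(direction), dtype=bool))
        add("de_in_ge1", (k >= 1).to_numpy())
        for kk in range(2, max_k + 1):
            add(f"de_in_{kk}", (k == kk).to_numpy())
    return pd.DataFrame(
        rows, columns=["cell_line", "gene_class", "mean_indicator", "n_genes"]
    )


def list_overlap_empirical_p(
    foreground: GeneList,
    reference_list: GeneList,
    universe: GeneList,
    n_draws: int = 1000,
    seed: int = 0,
    tail: str = "ge",
) -> ListOverlapResult:
    """Empirical tail probability of |foreground ∩ reference| against random
    same-size gene sets drawn from ``universe`` without replacement.

    ``tail='ge'`` counts draws with overlap >= observed (default); ``'gt'``
    uses strict inequality.
    """
    fg = sorted(foreground.gene_ids)
    uni = sorted(universe.gene_ids)
    if len(fg) > len(uni):
        raise ValueError(
            f"foreground ({len(fg)}) larger than universe ({len(uni)})"
        )
    if tail not in ("ge", "gt"):
        raise ValueError("tail must be 'ge' or 'gt'")
    ref = set(reference_list.gene_ids)
    observed = len(set(fg) & ref)
    in_ref = np.array([g in ref for g in uni])
    rng = np.random.default_rng(seed)
    n_fg = len(fg)
    draws = np.empty(n_draws, dtype=int)
    for d in range(n_draws):
        draws[d] = int(in_ref[rng.choice(len(uni), size=n_fg, replace=False)].sum())
    n_ge = int((draws >= observed).sum()) if tail == "ge" else int((draws > observed).sum())
    return ListOverlapResult(
        observed=observed,
        n_draws=n_draws,
        n_ge_observed=n_ge,
        empirical_p=n_ge / n_draws,
        seed=seed,
    )
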