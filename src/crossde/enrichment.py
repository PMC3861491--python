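"""Hypergeometric category over-representation with redundancy pruning.

Per category: upper-tail hypergeometric p of the foreground/category overlap
within the analysis universe; a min-p permutation criterion for family-wise
error control; and two pruning rules — categories with fewer than
``min_size`` universe genes are dropped, and a significant category is
dropped as redundant when more than ``redundancy`` of its universe genes lie
in the union of retained significant categories with strictly lower p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from crossde.counts_io import GeneList


@dataclass(frozen=True)
class EnrichmentConfig:
    p_threshold: float = 0.1
    fwer_threshold: float = 0.1
    min_size: int = 5
    redundancy: float = 0.9
    n_perms: int = 1000
    seed: int = 0


def hypergeom_p(
    n_universe: int, n_category: int, n_foreground: int, n_overlap: int
) -> float:
    """P(X >= n_overlap) for X ~ Hypergeom(n_universe, n_category, n_foreground)."""
    if not (
        0 <= n_overlap <= min(n_category, n_foreground)
        and max(n_category, n_foreground) <= n_universe
    ):
        raise ValueError(
            f"inconsistent counts: universe={n_universe} category={n_category} "
            f"foreground={n_foreground} overlap={n_overlap}"
        )
    p = float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_category, n_foreground))
    return min(max(p, 0.0), 1.0)


def _category_membership(
    annotations: dict[str, set[str]], universe: list[str]
) -> tuple[list[str], np.ndarray]:
    """Boolean universe-genes x categories membership matrix."""
    cats = sorted(annotations)
    idx = {g: i for i, g in enumerate(universe)}
    member = np.zeros((len(universe), len(cats)), dtype=bool)
    for j, c in enumerate(cats):
        for g in annotations[c]:
            i = idx.get(g)
            if i is not None:
                member[i, j] = True
    return cats, member


def fwer_adjust(
    p_values: dict[str, float],
    n_foreground: int,
    universe: GeneList | set,
    annotations: dict[str, set[str]],
    n_perms: int = 1000,
    seed: int = 0,
    fwer_threshold: float = 0.1,
) -> dict[str, bool]:
    """Min-p permutation FWER criterion.

    Random foregrounds of the observed size are drawn from the universe;
    a category meets the criterion iff the fraction of permutations whose
    minimum category p is <= its p stays below ``fwer_threshold``.
    """
    uni = sorted(universe.gene_ids) if isinstance(universe, GeneList) else sorted(universe)
    if n_foreground > len(uni):
        raise ValueError("foreground larger than universe")
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    cats, member = _category_membership(annotations, uni)
    n_uni = len(uni)
    cat_sizes = member.sum(axis=0)
    # per category, p depends only on the overlap count: precompute lookup
    lookups = [
        np.array(
            [
                hypergeom_p(n_uni, int(cat_sizes[j]), n_foreground, k)
                for k in range(min(int(cat_sizes[j]), n_foreground) + 1)
            ]
        )
        for j in range(len(cats))
    ]
    rng = np.random.default_rng(seed)
    min_ps = np.ones(n_perms)
    for t in range(n_perms):
        draw = rng.choice(n_uni, size=n_foreground, replace=False)
        ov = member[draw].sum(axis=0)
        min_ps[t] = min(
            (lookups[j][ov[j]] for j in range(len(cats))), default=1.0
        )
    return {
        c: float(np.mean(min_ps <= p_values[c])) < fwer_threshold
        for c in p_values
    }


def prune_categories(
    results: pd.DataFrame,
    annotations: dict[str, set[str]],
    universe: set[str],
    min_size: int = 5,
    redundancy: float = 0.9,
) -> pd.DataFrame:
    """Apply the size and redundancy pruning rules; returns results with
    ``pruned``/``prune_reason`` columns and significance restricted to
    unpruned categories.

    The redundancy scan walks candidate-significant categories in ascending p
    (ties broken by category id); a category is pruned when more than
    ``redundancy`` of its universe genes already lie in the union of retained
    lower-p significant categories. Pruned categories never contribute to the
    union.
    """
    res = results.sort_values(
        ["p", "category_id"], kind="mergesort"
    ).reset_index(drop=True)
    pruned = np.zeros(len(res), dtype=bool)
    reason = np.array(["none"] * len(res), dtype=object)

    uni_sets = {c: annotations[c] & universe for c in res["category_id"]}
    small = np.array([len(uni_sets[c]) < min_size for c in res["category_id"]])
    pruned |= small
    reason[small] = "too_small"

    covered: set[str] = set()
    prev_p: float | None = None
    pending: list[tuple[int, set[str]]] = []  # same-p block awaiting union update
    candidate = res["candidate_significant"].to_numpy()
    for i in range(len(res)):
        if not candidate[i] or pruned[i]:
            continue
        p_i = res.at[i, "p"]
        if prev_p is not None and p_i > prev_p:
            for _, gs in pending:
                covered |= gs
            pending = []
        genes = uni_sets[res.at[i, "category_id"]]
        if genes and len(genes & covered) > redundancy * len(genes):
            pruned[i] = True
            reason[i] = "redundant"
        else:
            pending.append((i, genes))
        prev_p = p_i
    res["pruned"] = pruned
    res["prune_reason"] = reason
    res["significant"] = res["candidate_significant"] & ~res["pruned"]
    return res


def run_enrichment(
    foreground: GeneList,
    universe: GeneList,
    annotations: dict[str, set[str]],
    config: EnrichmentConfig = EnrichmentConfig(),
    category_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full enrichment analysis of ``foreground`` against ``universe``."""
    uni = set(universe.gene_ids)
    if not uni:
        raise ValueError("empty universe")
    fg = set(foreground.gene_ids)
    if not fg <= uni:
        raise ValueError(
            f"foreground contains {len(fg - uni)} genes outside the universe"
        )
    rows = []
    for cat in sorted(annotations):
        cat_uni = annotations[cat] & uni
        overlap = len(cat_uni & fg)
        p = hypergeom_p(len(uni), len(cat_uni), len(fg), overlap)
        rows.append((cat, len(cat_uni), overlap, p))
    res = pd.DataFrame(
        rows,
        columns=["category_id", "n_category_in_universe", "n_category_in_foreground", "p"],
    )
    fwer_ok = fwer_adjust(
        dict(zip(res["category_id"], res["p"])),
        len(fg),
        uni,
        annotations,
        n_perms=config.n_perms,
        seed=config.seed,
        fwer_threshold=config.fwer_threshold,
    )
    res["fwer_ok"] = res["category_id"].map(fwer_ok)
    res["candidate_significant"] = (res["p"] < config.p_threshold) & res["fwer_ok"]
    res = prune_categories(
        res,
        annotations,
        uni,
        min_size=config.min_size,
        redundancy=config.redundancy,
    )
    if category_names:
        res.insert(1, "category_name", res["category_id"].map(category_names))
    return res.drop(columns=["candidate_significant"])
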