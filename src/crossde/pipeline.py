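"""End-to-end orchestration: per-cell-line DE, cross-cell-line aggregation,
permutation FDR, concordance and enrichment from a single configuration."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from zlib import crc32

import numpy as np
import pandas as pd

from crossde import __version__
from crossde.counts_io import (
    CountMatrix,
    GeneList,
    SampleDesign,
    read_annotations,
    read_counts,
    read_gene_list,
    write_table,
)
from crossde.concordance import direction_summary, list_overlap_empirical_p, overlap_zscores
from crossde.de_test import DEParams, detect_expressed, run_de
from crossde.enrichment import EnrichmentConfig, run_enrichment
from crossde.permutation_fdr import permutation_de_counts, summary_frame
from crossde.synthetic_data import SynthConfig, generate_counts

logger = logging.getLogger("crossde")

DIRECTION_SYMBOLS = {1.0: "up", 0.0: "down"}


@dataclass
class RunConfig:
    """Configuration of a full run; either real input paths or a synthetic
    generator config must be given."""

    counts_path: str | None = None
    design_path: str | None = None
    annotations_path: str | None = None
    reference_list_path: str | None = None
    synthetic: dict | None = None
    padj_threshold: float = 0.01
    overlap_draws: int = 10_000
    list_overlap_draws: int = 1000
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    run_permutations: bool = True
    seed: int = 0
    out_dir: str = "crossde_out"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        enr = raw.pop("enrichment", {})
        cfg = cls(**raw)
        cfg.enrichment = EnrichmentConfig(**enr)
        return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return int((master_seed * 0x9E3779B1 + crc32(stage.encode())) % 2**31)


def aggregate(
    de_results: dict[str, pd.DataFrame],
    de_sets: dict[str, set[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine per-cell-line DE calls into the per-gene cell-line-count table
    and the cumulative cascade.

    Returns (aggregate table, cascade). The aggregate table has one row per
    gene DE in >= 1 cell line with its count and per-cell-line
    direction/significance symbols; the cascade has, for each k, the number
    of genes DE in >= k and in exactly k cell lines.
    """
    if len(set(de_results)) != len(de_results):
        raise ValueError("duplicate cell-line results")
    if set(de_results) != set(de_sets):
        raise ValueError("de_results and de_sets must cover the same cell lines")
    cell_lines = sorted(de_results)
    all_de = sorted(set().union(*de_sets.values())) if de_sets else []
    rows = []
    for gene in all_de:
        n = sum(gene in de_sets[cl] for cl in cell_lines)
        row: dict = {"gene_id": gene, "n_cell_lines_de": n}
        for cl in cell_lines:
            res = de_results[cl]
            hit = res.loc[res["gene_id"] == gene]
            if hit.empty:
                row[f"dir_{cl}"] = "NA"
                row[f"sig_{cl}"] = False
            else:
                d = hit["direction"].iloc[0]
                row[f"dir_{cl}"] = DIRECTION_SYMBOLS.get(d, "NA")
                row[f"sig_{cl}"] = gene in de_sets[cl]
        rows.append(row)
    agg = pd.DataFrame(rows)
    if not agg.empty:
        agg = agg.sort_values(
            ["n_cell_lines_de", "gene_id"], ascending=[False, True]
        ).reset_index(drop=True)
    counts = agg["n_cell_lines_de"] if not agg.empty else pd.Series([], dtype=int)
    cascade = cascade_from_counts(counts, max_k=len(cell_lines))
    return agg, cascade


def cascade_from_counts(n_cell_lines_de: pd.Series, max_k: int | None = None) -> pd.DataFrame:
    """Cumulative (>= k) and exact (== k) gene counts per number of cell lines."""
    vals = np.asarray(n_cell_lines_de, dtype=int)
    if max_k is None:
        max_k = int(vals.max()) if vals.size else 1
    rows = [
        (k, int((vals >= k).sum()), int((vals == k).sum()))
        for k in range(1, max_k + 1)
    ]
    return pd.DataFrame(rows, columns=["k", "n_genes_ge_k", "n_genes_eq_k"])


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        synth = SynthConfig(**{**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
        ds = generate_counts(synth)
        return ds.combined_counts(), ds.combined_design(), ds.truth
    if config.counts_path is None or config.design_path is None:
        raise ValueError("config needs either synthetic parameters or counts/design paths")
    matrix, design = read_counts(config.counts_path, config.design_path)
    return matrix, design, None


def run_all(config: RunConfig) -> Path:
    """Execute every stage and write all result tables plus a JSON manifest.

    Deterministic: the master seed fully determines all stochastic stages.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = DEParams(padj_threshold=config.padj_threshold)

    stage = "load"
    try:
        matrix, design, truth = _load_inputs(config)
        cell_lines = design.cell_lines
        logger.info(
            "load: %d genes x %d samples, %d cell lines",
            matrix.n_genes, matrix.n_samples, len(cell_lines),
        )
        if truth is not None:
            write_table(truth, out / "truth.tsv")

        stage = "de"
        de_results: dict[str, pd.DataFrame] = {}
        de_sets: dict[str, set[str]] = {}
        expressed: dict[str, GeneList] = {}
        for cl in cell_lines:
            expressed[cl] = detect_expressed(matrix, design, cl, params.min_detected_replicates)
            res, de = run_de(matrix, design, cl, params, expressed=expressed[cl])
            de_results[cl], de_sets[cl] = res, de
            write_table(res, out / f"de_{cl}.tsv")
            logger.info("de %s: %d expressed, %d DE", cl, len(expressed[cl]), len(de))

        stage = "permutation"
        if config.run_permutations:
            summaries = [
                permutation_de_counts(matrix, design, cl, params)
                for cl in cell_lines
            ]
            for s in summaries:
                write_table(s.to_frame(), out / f"permutations_{s.cell_line}.tsv")
            write_table(summary_frame(summaries), out / "permutation_summary.tsv")

        stage = "aggregate"
        agg, cascade = aggregate(de_results, de_sets)
        write_table(agg, out / "aggregate.tsv")
        write_table(cascade, out / "cascade.tsv")

        stage = "concordance"
        overlap = None
        if len(cell_lines) >= 2:
            overlap = overlap_zscores(
                de_sets,
                expressed,
                n_draws=config.overlap_draws,
                seed=stage_seed(config.seed, "overlap"),
            )
            write_table(overlap, out / "overlap_zscores.tsv")
        n_de = (
            agg.set_index("gene_id")["n_cell_lines_de"]
            if not agg.empty
            else pd.Series([], dtype=int)
        )
        directions = direction_summary(de_results, n_de)
        write_table(directions, out / "direction_summary.tsv")

        list_overlap = None
        if config.reference_list_path:
            reference = read_gene_list(config.reference_list_path)
            fg = GeneList(frozenset(n_de.index[n_de >= 2]))
            universe_ge2 = _expressed_in_at_least(expressed, 2)
            if len(fg):
                r = list_overlap_empirical_p(
                    fg,
                    reference,
                    universe_ge2,
                    n_draws=config.list_overlap_draws,
                    seed=stage_seed(config.seed, "list_overlap"),
                )
                list_overlap = asdict(r)
                (out / "list_overlap.json").write_text(json.dumps(list_overlap, indent=2))

        stage = "enrichment"
        enrich = None
        if config.annotations_path:
            ann_df = read_annotations(config.annotations_path)
            annotations = {
                c: set(g["gene_id"]) for c, g in ann_df.groupby("category_id")
            }
            names = dict(zip(ann_df["category_id"], ann_df["category_name"]))
            fg = GeneList(frozenset(n_de.index[n_de >= 2]))
            universe_ge2 = _expressed_in_at_least(expressed, 2)
            fg = GeneList(fg.gene_ids & universe_ge2.gene_ids)
            if len(fg):
                enrich = run_enrichment(
                    fg, universe_ge2, annotations,
                    EnrichmentConfig(
                        **{**asdict(config.enrichment), "seed": stage_seed(config.seed, "enrichment")}
                    ),
                    category_names=names,
                )
                write_table(enrich, out / "enrichment.tsv")
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            s: stage_seed(config.seed, s) for s in ("overlap", "list_overlap", "enrichment")
        },
        "padj_threshold": config.padj_threshold,
        "overlap_draws": config.overlap_draws,
        "list_overlap_draws": config.list_overlap_draws,
        "cell_lines": cell_lines,
        "n_genes": matrix.n_genes,
        "n_samples": matrix.n_samples,
        "de_counts": {cl: len(de_sets[cl]) for cl in cell_lines},
        "n_overlap_records": 0 if overlap is None else int(len(overlap)),
        "cascade": cascade.to_dict(orient="list"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    lines = [f"crossde {__version__} run (seed {config.seed})"]
    for cl in cell_lines:
        lines.append(f"  {cl}: {len(de_sets[cl])} DE genes of {len(expressed[cl])} expressed")
    ge = dict(zip(cascade["k"], cascade["n_genes_ge_k"]))
    lines.append("  cascade >=k: " + ", ".join(f"{k}:{v}" for k, v in ge.items()))
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return out


def _expressed_in_at_least(expressed: dict[str, GeneList], k: int) -> GeneList:
    from collections import Counter

    c: Counter = Counter()
    for gl in expressed.values():
        c.update(gl.gene_ids)
    return GeneList(frozenset(g for g, n in c.items() if n >= k))
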