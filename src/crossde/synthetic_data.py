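"""Synthetic NB count matrices with planted, partially shared treatment effects.

Each simulated cell line gets its own log-normal per-gene baselines, per-sample
library-size factors, and negative-binomial counts (variance = mu + alpha*mu^2).
A configurable subset of genes carries a treatment effect; effect genes are
re-planted in additional cell lines with probability ``share_prob`` and keep
their sign with probability ``concordance_prob``, which gives downstream
overlap and direction analyses a known ground truth.

RNG layout: one independent stream per cell line seeded from
``(seed, cell_line_index)``, plus one stream for the planting structure, so
adding cell lines never perturbs counts of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from crossde.counts_io import CountMatrix, SampleDesign

_PLANT_STREAM = 1_000_003  # fixed tag for the planting stream, distinct from cell-line indices


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    n_genes: int = 5000
    n_cell_lines: int = 10
    n_treated: int = 6
    n_control: int = 3
    baseline_log_mean: float = 4.0  # natural-log scale of per-gene baseline means
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05
    size_factor_log_sd: float = 0.1
    n_effect_genes: int = 300
    effect_lfc_magnitude: float = 2.0  # log2 units
    share_prob: float = 0.5
    concordance_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cell_lines < 1:
            raise ConfigError("n_genes and n_cell_lines must be positive")
        if self.n_treated < 1 or self.n_control < 1:
            raise ConfigError("need at least one sample per condition")
        if self.n_effect_genes < 0 or self.n_effect_genes > self.n_genes:
            raise ConfigError(
                f"n_effect_genes={self.n_effect_genes} must be in [0, n_genes={self.n_genes}]"
            )
        for name in ("share_prob", "concordance_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.dispersion < 0 or self.baseline_log_sd < 0 or self.size_factor_log_sd < 0:
            raise ConfigError("dispersion and log-sd parameters must be >= 0")
        if self.n_effect_genes and self.effect_lfc_magnitude <= 0:
            raise ConfigError("effect_lfc_magnitude must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SynthDataset:
    """Per-cell-line count matrices and designs plus the planted truth table."""

    config: SynthConfig
    cell_lines: list[str]
    matrices: dict[str, CountMatrix]
    designs: dict[str, SampleDesign]
    truth: pd.DataFrame  # gene_id, cell_line, planted_lfc, planted_direction
    gene_ids: list[str] = field(default_factory=list)

    def combined_design(self) -> SampleDesign:
        return SampleDesign(
            pd.concat([self.designs[cl].table for cl in self.cell_lines], ignore_index=True)
        )

    def combined_counts(self) -> CountMatrix:
        return CountMatrix(
            pd.concat([self.matrices[cl].counts for cl in self.cell_lines], axis=1)
        )


def _plant_effects(config: SynthConfig) -> pd.DataFrame:
    """Decide which (gene, cell line) pairs carry an effect and its sign.

    Every effect gene is planted in the first cell line; for each further cell
    line it is re-planted with probability share_prob, keeping the anchor sign
    with probability concordance_prob.
    """
    rng = np.random.default_rng([config.seed, _PLANT_STREAM])
    effect_idx = np.sort(
        rng.choice(config.n_genes, size=config.n_effect_genes, replace=False)
    )
    anchor_sign = rng.choice([-1.0, 1.0], size=config.n_effect_genes)
    rows = []
    for ci in range(config.n_cell_lines):
        # per-cell-line stream for replanting keeps earlier cell lines stable
        cl_rng = np.random.default_rng([config.seed, _PLANT_STREAM, ci])
        if ci == 0:
            planted = np.ones(config.n_effect_genes, dtype=bool)
            sign = anchor_sign
        else:
            planted = cl_rng.random(config.n_effect_genes) < config.share_prob
            keep = cl_rng.random(config.n_effect_genes) < config.concordance_prob
            sign = np.where(keep, anchor_sign, -anchor_sign)
        for gi, pl, sg in zip(effect_idx, planted, sign):
            if pl:
                rows.append((int(gi), ci, sg * config.effect_lfc_magnitude))
    df = pd.DataFrame(rows, columns=["gene_index", "cell_line_index", "planted_lfc"])
    return df.astype({"gene_index": int, "cell_line_index": int, "planted_lfc": float})


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB counts with variance mean + alpha*mean^2; Poisson when alpha == 0."""
    if alpha == 0.0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def cell_line_name(index: int) -> str:
    return f"CL{index + 1:02d}"


def generate_counts(config: SynthConfig) -> SynthDataset:
    """Simulate all cell lines of a study under ``config``.

    Sample ids are ``<cell line>_T<k>`` / ``<cell line>_C<k>``; gene ids
    ``G<00001>`` are shared across cell lines. Deterministic in
    ``config.seed``.
    """
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    plantings = _plant_effects(config)
    cell_lines = [cell_line_name(i) for i in range(config.n_cell_lines)]

    matrices: dict[str, CountMatrix] = {}
    designs: dict[str, SampleDesign] = {}
    n_samples = config.n_treated + config.n_control
    treated_mask = np.array([True] * config.n_treated + [False] * config.n_control)

    for ci, cl in enumerate(cell_lines):
        rng = np.random.default_rng([config.seed, ci])
        mu = np.exp(
            rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
        )
        size_factors = np.exp(rng.normal(0.0, config.size_factor_log_sd, n_samples))
        lfc = np.zeros(config.n_genes)
        here = plantings[plantings["cell_line_index"] == ci]
        lfc[here["gene_index"].to_numpy()] = here["planted_lfc"].to_numpy()

        fold = np.where(treated_mask[None, :], 2.0 ** lfc[:, None], 1.0)
        mean = mu[:, None] * size_factors[None, :] * fold
        counts = _nb_draw(rng, mean, config.dispersion)

        sample_ids = [
            f"{cl}_T{k + 1}" for k in range(config.n_treated)
        ] + [f"{cl}_C{k + 1}" for k in range(config.n_control)]
        matrices[cl] = CountMatrix(
            pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
        )
        designs[cl] = SampleDesign(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "cell_line": cl,
                    "condition": ["treated"] * config.n_treated
                    + ["control"] * config.n_control,
                    "replicate": list(range(1, config.n_treated + 1))
                    + list(range(1, config.n_control + 1)),
                }
            )
        )

    truth = pd.DataFrame(
        {
            "gene_id": [gene_ids[i] for i in plantings["gene_index"]],
            "cell_line": [cell_lines[i] for i in plantings["cell_line_index"]],
            "planted_lfc": plantings["planted_lfc"].to_numpy(),
        }
    )
    truth["planted_direction"] = np.where(truth["planted_lfc"] > 0, "up", "down")
    return SynthDataset(
        config=config,
        cell_lines=cell_lines,
        matrices=matrices,
        designs=designs,
        truth=truth,
        gene_ids=gene_ids,
    )


def truth_direction_matrix(truth: pd.DataFrame) -> pd.DataFrame:
    """Gene x cell-line indicator: 1 planted up, 0 planted down, NaN unplanted."""
    if truth.empty:
        return pd.DataFrame()
    ind = truth.assign(
        indicator=(truth["planted_lfc"] > 0).astype(float)
    ).pivot(index="gene_id", columns="cell_line", values="indicator")
    return ind
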