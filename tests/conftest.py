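import numpy as np
import pandas as pd
import pytest

from crossde.counts_io import CountMatrix, SampleDesign
from crossde.synthetic_data import SynthConfig, generate_counts


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    return CountMatrix(
        pd.DataFrame(
            {"s1": [5, 0], "s2": [3, 2], "s3": [7, 1]},
            index=["g1", "g2"],
        )
    )


@pytest.fixture
def tiny_design() -> SampleDesign:
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "cell_line": ["A", "A", "A"],
                "condition": ["treated", "treated", "control"],
                "replicate": [1, 2, 1],
            }
        )
    )


def make_cell_line(counts: np.ndarray, gene_ids=None, cell_line="A",
                   n_treated=None, n_control=None):
    """Wrap a genes x samples array as (CountMatrix, SampleDesign) with the
    first columns treated."""
    counts = np.asarray(counts)
    n_samples = counts.shape[1]
    if n_treated is None:
        n_treated = (n_samples * 2) // 3
    if n_control is None:
        n_control = n_samples - n_treated
    gene_ids = gene_ids or [f"g{i}" for i in range(counts.shape[0])]
    sample_ids = [f"{cell_line}_T{i+1}" for i in range(n_treated)] + [
        f"{cell_line}_C{i+1}" for i in range(n_control)
    ]
    matrix = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "cell_line": cell_line,
                "condition": ["treated"] * n_treated + ["control"] * n_control,
                "replicate": list(range(1, n_treated + 1))
                + list(range(1, n_control + 1)),
            }
        )
    )
    return matrix, design


@pytest.fixture(scope="session")
def small_synth():
    """One modest synthetic cell line with planted effects (session-cached)."""
    cfg = SynthConfig(
        n_genes=800, n_cell_lines=1, n_effect_genes=60,
        effect_lfc_magnitude=2.5, dispersion=0.05, seed=42,
    )
    return generate_counts(cfg)
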