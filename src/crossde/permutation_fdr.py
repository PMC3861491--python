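"""Exhaustive treated/control relabeling within a cell line.

Every way of assigning the observed group sizes to the samples (minus the true
assignment) is evaluated with the identical DE procedure; the distribution of
DE counts under relabeling against the true-label DE count is the empirical
FDR summary. The detection filter and the size factors do not depend on the
labels and are computed once; dispersions are re-estimated per relabeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from crossde.counts_io import CountMatrix, SampleDesign
from crossde.de_test import DEParams, detect_expressed, estimate_size_factors, run_de


@dataclass(frozen=True)
class Relabeling:
    """One alternative treated/control assignment (group sizes preserved)."""

    control_ids: tuple[str, ...]

    def assignment(self, sample_ids) -> dict[str, str]:
        ctrl = set(self.control_ids)
        return {s: ("control" if s in ctrl else "treated") for s in sample_ids}


@dataclass
class PermutationSummary:
    cell_line: str
    real_de_count: int
    perm_de_counts: list[int]
    relabelings: list[Relabeling]

    @property
    def ratio_max(self) -> float:
        if self.real_de_count == 0:
            return float("nan")
        return max(self.perm_de_counts) / self.real_de_count

    @property
    def ratio_mean(self) -> float:
        if self.real_de_count == 0:
            return float("nan")
        return float(np.mean(self.perm_de_counts)) / self.real_de_count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "relabeling": range(len(self.relabelings)),
                "control_samples": [
                    ",".join(r.control_ids) for r in self.relabelings
                ],
                "de_count": self.perm_de_counts,
            }
        )


def enumerate_relabelings(
    n_treated: int,
    n_control: int,
    true_assignment: dict[str, str],
) -> list[Relabeling]:
    """All C(n_treated + n_control, n_control) control-set choices except the
    true one, in lexicographic order of sorted sample ids."""
    if n_treated < 1 or n_control < 1:
        raise ValueError("both groups need at least one sample")
    sample_ids = sorted(true_assignment)
    if len(sample_ids) != n_treated + n_control:
        raise ValueError(
            f"true assignment has {len(sample_ids)} samples, expected "
            f"{n_treated + n_control}"
        )
    true_control = tuple(
        sorted(s for s, cond in true_assignment.items() if cond == "control")
    )
    if len(true_control) != n_control:
        raise ValueError(
            f"true assignment has {len(true_control)} controls, expected {n_control}"
        )
    out = [
        Relabeling(ctrl)
        for ctrl in combinations(sample_ids, n_control)
        if ctrl != true_control
    ]
    assert len(out) == comb(n_treated + n_control, n_control) - 1
    return out


def permutation_de_counts(
    counts: CountMatrix,
    design: SampleDesign,
    cell_line: str,
    params: DEParams = DEParams(),
    max_perms: int | None = None,
    seed: int = 0,
) -> PermutationSummary:
    """DE counts under the true labels and under every relabeling.

    ``max_perms`` caps the number of relabelings by seeded subsampling for
    designs where exhaustive enumeration is impractical.
    """
    samples = design.samples_for(cell_line)
    sub_design = design.subset(samples)
    true_assignment = dict(
        zip(sub_design.table["sample_id"], sub_design.table["condition"])
    )
    n_treated = sum(1 for c in true_assignment.values() if c == "treated")
    n_control = len(true_assignment) - n_treated

    expressed = detect_expressed(counts, design, cell_line, params.min_detected_replicates)
    factors = estimate_size_factors(counts.subset_samples(samples))

    _, real_de = run_de(
        counts, design, cell_line, params, expressed=expressed, factors=factors
    )

    relabelings = enumerate_relabelings(n_treated, n_control, true_assignment)
    if max_perms is not None and max_perms < len(relabelings):
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(relabelings), size=max_perms, replace=False))
        relabelings = [relabelings[i] for i in idx]

    perm_counts = []
    base = sub_design.table.set_index("sample_id")
    for rel in relabelings:
        assignment = rel.assignment(samples)
        perm_table = base.copy()
        perm_table["condition"] = [assignment[s] for s in perm_table.index]
        # renumber replicates within the new groups to keep the design valid
        for cond in ("treated", "control"):
            mask = perm_table["condition"] == cond
            perm_table.loc[mask, "replicate"] = range(1, int(mask.sum()) + 1)
        perm_design = SampleDesign(perm_table.reset_index())
        _, de = run_de(
            counts,
            perm_design,
            cell_line,
            params,
            expressed=expressed,
            factors=factors,
        )
        perm_counts.append(len(de))

    return PermutationSummary(
        cell_line=cell_line,
        real_de_count=len(real_de),
        perm_de_counts=perm_counts,
        relabelings=relabelings,
    )


def summary_frame(summaries: list[PermutationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_line": [s.cell_line for s in summaries],
            "real_de_count": [s.real_de_count for s in summaries],
            "n_relabelings": [len(s.perm_de_counts) for s in summaries],
            "perm_de_max": [max(s.perm_de_counts) for s in summaries],
            "perm_de_mean": [float(np.mean(s.perm_de_counts)) for s in summaries],
            "ratio_max": [s.ratio_max for s in summaries],
            "ratio_mean": [s.ratio_mean for s in summaries],
        }
    )
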