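"""Functional-category composition of the purified interactome.

Each quantified protein is assigned to a functional category (unmapped
proteins fall into "other"); per run, a category's share is the summed
top-3 peak area of its proteins as a percentage of the run's total peak
area, and shares are averaged across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .stoichiometry import RunQuant

OTHER_CATEGORY = "other"


@dataclass
class CompositionSummary:
    """Per-category peak-area percentages, per run and averaged."""

    per_run: pd.DataFrame  # runs × categories, rows sum to 100
    mean_percent: pd.Series  # per category
    n_runs: int

    def validate(self) -> None:
        if self.n_runs and len(self.per_run):
            sums = self.per_run.sum(axis=1)
            if not ((sums - 100.0).abs() < 1e-6).all():
                raise ValueError("per-run composition percentages must sum to 100")
        if (self.per_run < 0).any().any():
            raise ValueError("negative composition percentage")

    def to_frame(self) -> pd.DataFrame:
        out = self.per_run.T
        out.insert(0, "mean_percent", self.mean_percent)
        out.index.name = "category"
        return out.reset_index()


def composition_percentages(
    run_quants: Sequence[RunQuant],
    category_map: Mapping[str, str] | None = None,
) -> CompositionSummary:
    """Category composition from summed top-3 areas, averaged over runs.

    Runs with zero total area are excluded with a warning.  Categories
    absent from a run contribute zero percent to that run.
    """
    category_map = category_map or {}
    rows: dict[str, pd.Series] = {}
    for quant in run_quants:
        f = quant.frame
        total = float(f["top3_area"].sum()) if len(f) else 0.0
        if total <= 0:
            warnings.warn(
                f"run {quant.run_id!r} has zero total peak area; excluded "
                "from composition",
                stacklevel=2,
            )
            continue
        cats = pd.Series(
            [category_map.get(pid, OTHER_CATEGORY) for pid in f.index],
            index=f.index,
        )
        shares = 100.0 * f["top3_area"].groupby(cats).sum() / total
        rows[quant.run_id] = shares
    per_run = pd.DataFrame(rows).T.fillna(0.0)  # runs × categories
    per_run = per_run[sorted(per_run.columns)] if len(per_run) else per_run
    mean = (
        per_run.mean(axis=0) if len(per_run) else pd.Series(dtype=float)
    )
    summary = CompositionSummary(
        per_run=per_run, mean_percent=mean, n_runs=len(per_run)
    )
    summary.validate()
    return summary
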