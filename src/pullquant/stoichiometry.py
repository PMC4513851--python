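"""Bait-normalized abundance and stoichiometry estimation.

The abundance statistic is the protein abundance factor (PAF): the number
of distinct peptides identifying a protein (optionally its spectral count)
divided by its molecular weight in Daltons and scaled by 1e4.  Within each
pull-down run, mean control-run PAF is subtracted (clamped at zero), the
remainder is normalized to the bait protein's PAF, and the per-run relative
values are averaged across independent replicate experiments into an
abundance table whose mean relative PAF estimates the stoichiometry of each
prey relative to the bait.

A second, intensity-based abundance proxy is carried alongside: the top-3
peak area, the mean intensity of the protein's three most intense peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import protein_mw  # noqa: F401  (public surface of this module)
from .filtering import PsmInput, as_psm_frame
from .io_formats import PipelineConfig, ProteinRecord


class BaitMissingError(ValueError):
    """A bait run without quantifiable bait signal is an invalid pull-down."""


@dataclass
class RunQuant:
    """Per-run per-protein evidence.

    ``frame`` is indexed by protein_id with columns ``U`` (distinct
    peptides), ``S`` (spectral count), ``top3_area`` and ``paf``; after
    control subtraction a ``paf_adj`` column is added.
    """

    run_id: str
    frame: pd.DataFrame

    def validate(self, paf_scale: float = 1e4, min_peptides: int = 1) -> None:
        f = self.frame
        if ((f["U"] > 0) & (f["S"] < f["U"])).any():
            raise ValueError(f"{self.run_id}: spectral count below peptide count")
        if (f["U"] < min_peptides).any():
            raise ValueError(f"{self.run_id}: protein below min_peptides quantified")
        if (f[["U", "S", "top3_area", "paf"]] < 0).any().any():
            raise ValueError(f"{self.run_id}: negative quantity")


@dataclass
class AbundanceTable:
    """Cross-replicate abundance report (one row per surviving protein)."""

    frame: pd.DataFrame
    bait_id: str
    n_bait_runs: int
    n_control_runs: int
    params: dict = field(default_factory=dict)

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        """Report view; relative PAFs and SDs to 2 decimals, MW in kDa to 1."""
        out = self.frame.reset_index().rename(columns={"index": "protein_id"})
        if rounded and len(out):
            out["mean_rel_paf"] = out["mean_rel_paf"].round(2)
            out["sd_rel_paf"] = out["sd_rel_paf"].round(2)
            out["mw_kda"] = out["mw_kda"].round(1)
        return out

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4g")


def paf(U: float, mw_da: float, paf_scale: float = 1e4) -> float:
    """Protein abundance factor: (count / molecular weight) × scale."""
    if mw_da <= 0:
        raise ValueError("molecular weight must be positive")
    if U < 0:
        raise ValueError("count must be non-negative")
    return (U / mw_da) * paf_scale


def top3_area(peptide_intensities: Sequence[float], n: int = 3) -> float:
    """Mean of the ``n`` most intense peptides (all of them if fewer)."""
    values = sorted(peptide_intensities, reverse=True)[:n]
    if not values:
        return 0.0
    return float(np.mean(values))


def _proteome_index(proteome: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    if isinstance(proteome, dict):
        return proteome
    return {rec.protein_id: rec for rec in proteome}


def quantify_run(
    retained: PsmInput,
    proteome: Iterable[ProteinRecord] | Mapping[str, ProteinRecord],
    passing_proteins: set[str],
    config: PipelineConfig | None = None,
    run_id: str | None = None,
) -> RunQuant:
    """Count evidence for every passing protein of one run.

    Peptides shared between proteins count toward every mapped protein by
    default; in razor mode a shared peptide is credited only to the mapped
    protein with the most uniquely-mapped peptides (ties broken by id).
    Per-peptide intensity is the maximum PSM intensity of that peptide in
    the run.
    """
    config = config or PipelineConfig()
    records = _proteome_index(proteome)
    frame = as_psm_frame(retained)
    run_id = run_id or (str(frame["run_id"].iloc[0]) if len(frame) else "run")

    if len(frame) == 0 or not passing_proteins:
        empty = pd.DataFrame(columns=["U", "S", "top3_area", "paf"])
        empty.index.name = "protein_id"
        return RunQuant(run_id=run_id, frame=empty)

    pairs = frame.assign(protein_id=frame["protein_ids"].str.split(";")).explode(
        "protein_id"
    )
    unknown = set(pairs["protein_id"]) - set(records)
    if unknown:
        raise ValueError(f"proteins absent from proteome: {sorted(unknown)[:5]}")

    if config.shared_peptides == "razor":
        # unique evidence per protein, then give each shared peptide to the
        # mapped protein with the most of it
        n_mapped = frame["protein_ids"].str.count(";") + 1
        unique_pairs = pairs[n_mapped.reindex(pairs.index) == 1]
        unique_counts = unique_pairs.groupby("protein_id")["peptide_seq"].nunique()
        def razor_owner(ids: str) -> str:
            candidates = ids.split(";")
            return max(
                candidates,
                key=lambda p: (unique_counts.get(p, 0), p),
            )
        owners = frame["protein_ids"].map(razor_owner)
        pairs = frame.assign(protein_id=owners)

    pairs = pairs[pairs["protein_id"].isin(passing_proteins)]
    if len(pairs) == 0:
        empty = pd.DataFrame(columns=["U", "S", "top3_area", "paf"])
        empty.index.name = "protein_id"
        return RunQuant(run_id=run_id, frame=empty)

    grouped = pairs.groupby("protein_id")
    U = grouped["peptide_seq"].nunique()
    S = grouped.size()
    per_peptide = pairs.groupby(["protein_id", "peptide_seq"])["intensity"].max()
    areas = per_peptide.groupby(level="protein_id").apply(
        lambda s: top3_area(s.to_numpy(), config.top_n_area)
    )
    quant = pd.DataFrame({"U": U, "S": S, "top3_area": areas})
    mw = pd.Series({pid: records[pid].mw_da for pid in quant.index})
    basis = quant["U"] if config.paf_basis == "unique" else quant["S"]
    quant["paf"] = basis / mw * config.paf_scale
    quant.index.name = "protein_id"
    return RunQuant(run_id=run_id, frame=quant.sort_index())


def subtract_control(
    bait_quants: Sequence[RunQuant],
    control_quants: Sequence[RunQuant],
) -> list[RunQuant]:
    """Subtract mean control-run PAF from each bait run, clamped at zero.

    The control background of a protein is the mean of its PAF over all
    control runs (zero where undetected).  Proteins whose adjusted PAF is
    zero in every bait run are removed entirely; with no control runs the
    operation is the identity (``paf_adj = paf``).
    """
    if control_quants:
        pooled = pd.concat([q.frame["paf"] for q in control_quants], axis=1)
        control_mean = pooled.fillna(0.0).sum(axis=1) / len(control_quants)
    else:
        control_mean = pd.Series(dtype=float)

    adjusted: list[RunQuant] = []
    survivors: set[str] = set()
    for quant in bait_quants:
        f = quant.frame.copy()
        background = control_mean.reindex(f.index).fillna(0.0)
        f["paf_adj"] = (f["paf"] - background).clip(lower=0.0)
        f = f[f["paf_adj"] > 0.0]
        survivors |= set(f.index)
        adjusted.append(RunQuant(run_id=quant.run_id, frame=f))
    # proteins cancelled in every bait run have vanished already; the
    # survivors set documents what remains for downstream reporting
    for quant in adjusted:
        quant.frame = quant.frame[quant.frame.index.isin(survivors)]
    return adjusted


def relative_to_bait(adjusted: RunQuant, bait_id: str) -> pd.Series:
    """Per-run relative PAF: each protein's adjusted PAF over the bait's.

    Raises :class:`BaitMissingError` when the bait is absent or has zero
    adjusted PAF in the run — a pull-down without its bait is invalid.
    """
    f = adjusted.frame
    if bait_id not in f.index or f.loc[bait_id, "paf_adj"] <= 0:
        raise BaitMissingError(
            f"bait {bait_id!r} not quantified in bait run {adjusted.run_id!r}"
        )
    rel = f["paf_adj"] / f.loc[bait_id, "paf_adj"]
    rel.name = adjusted.run_id
    return rel


def aggregate_replicates(
    rel_by_run: Mapping[str, pd.Series],
    area_by_run: Mapping[str, pd.Series],
    proteome: Iterable[ProteinRecord] | Mapping[str, ProteinRecord],
    bait_id: str,
    n_control_runs: int = 0,
    category_map: Mapping[str, str] | None = None,
    config: PipelineConfig | None = None,
) -> AbundanceTable:
    """Average per-run relative PAFs (and areas) across bait replicates.

    Means use the sample SD (n−1 denominator; SD = 0 when n = 1).  By
    default a replicate in which a protein is undetected contributes zero
    to its mean (``missing_as_zero``); the alternative averages only over
    runs where the protein was detected.
    """
    config = config or PipelineConfig()
    records = _proteome_index(proteome)
    category_map = category_map or {}
    if not rel_by_run:
        raise ValueError("at least one bait run is required")

    rel = pd.DataFrame(dict(rel_by_run))  # proteins × runs, NaN = undetected
    area = pd.DataFrame(dict(area_by_run)).reindex(rel.index)
    n_runs = rel.shape[1]
    n_detected = rel.notna().sum(axis=1)

    if config.missing_as_zero:
        rel_filled = rel.fillna(0.0)
        area_filled = area.fillna(0.0)
        mean_rel = rel_filled.mean(axis=1)
        sd_rel = rel_filled.std(axis=1, ddof=1) if n_runs > 1 else pd.Series(
            0.0, index=rel.index
        )
        mean_area = area_filled.mean(axis=1)
    else:
        mean_rel = rel.mean(axis=1)
        sd_rel = rel.std(axis=1, ddof=1).fillna(0.0)
        mean_area = area.mean(axis=1)
    if n_runs > 1:
        sd_rel = sd_rel.fillna(0.0)

    frame = pd.DataFrame(
        {
            "mean_rel_paf": mean_rel,
            "sd_rel_paf": sd_rel,
            "mean_area": mean_area,
            "n_runs_detected": n_detected.astype(int),
        }
    )
    frame["mw_kda"] = [records[pid].mw_da / 1000.0 for pid in frame.index]
    frame["description"] = [records[pid].description for pid in frame.index]
    frame["category"] = [category_map.get(pid, "other") for pid in frame.index]
    frame.index.name = "protein_id"

    # bait first, then by decreasing stoichiometry
    order = frame.index == bait_id
    frame = frame.iloc[
        np.lexsort((frame.index, -frame["mean_rel_paf"].to_numpy(), ~order))
    ]
    return AbundanceTable(
        frame=frame,
        bait_id=bait_id,
        n_bait_runs=n_runs,
        n_control_runs=n_control_runs,
        params={
            "paf_basis": config.paf_basis,
            "paf_scale": config.paf_scale,
            "missing_as_zero": config.missing_as_zero,
        },
    )
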