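"""End-to-end orchestration: filter → quantify → subtract → normalize →
aggregate → composition → report."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .composition import CompositionSummary, composition_percentages
from .filtering import FilterReport, compute_qvalues, filter_proteins, filter_psms
from .io_formats import (
    PipelineConfig,
    ProteinRecord,
    RunManifest,
    read_category_map,
    read_fasta,
    read_manifest,
    read_psm_frame,
)
from .stoichiometry import (
    AbundanceTable,
    RunQuant,
    aggregate_replicates,
    quantify_run,
    relative_to_bait,
    subtract_control,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    abundance: AbundanceTable
    composition: CompositionSummary
    filter_reports: dict[str, FilterReport]
    stage_counts: dict[str, int] = field(default_factory=dict)
    output_paths: dict[str, Path] = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def process_run(
    psm_frame: pd.DataFrame,
    proteome: Mapping[str, ProteinRecord],
    config: PipelineConfig,
    run_id: str,
) -> tuple[RunQuant, FilterReport]:
    """Filter and quantify one run (fractions pooled)."""
    with_q = compute_qvalues(psm_frame)
    retained, report = filter_psms(
        with_q, fdr_threshold=config.fdr_threshold, ppm_tolerance=config.ppm_tolerance
    )
    passing = filter_proteins(retained, config.min_peptides, report=report)
    quant = quantify_run(retained, proteome, passing, config, run_id=run_id)
    return quant, report


def build_report(
    abundance: AbundanceTable,
    composition: CompositionSummary,
    filter_reports: Mapping[str, FilterReport],
    output_dir,
    params: Mapping | None = None,
) -> dict[str, Path]:
    """Write the abundance, composition and filter-report TSVs plus a log.

    Output is deterministic: identical inputs give byte-identical files.
    The log is JSON-lines, one record per pipeline artifact.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": output_dir / "abundance.tsv",
        "composition": output_dir / "composition.tsv",
        "filter_report": output_dir / "filter_report.tsv",
        "log": output_dir / "run_log.jsonl",
    }
    abundance.to_tsv(paths["abundance"])
    composition.to_frame().to_csv(
        paths["composition"], sep="\t", index=False, float_format="%.6g"
    )
    report_frames = []
    for run_id, report in filter_reports.items():
        f = report.to_frame()
        f.insert(0, "run_id", run_id)
        report_frames.append(f)
    if report_frames:
        pd.concat(report_frames, ignore_index=True).to_csv(
            paths["filter_report"], sep="\t", index=False, float_format="%.6g"
        )
    else:
        pd.DataFrame(columns=["run_id", "quantity", "value"]).to_csv(
            paths["filter_report"], sep="\t", index=False
        )
    with open(paths["log"], "w", encoding="utf-8") as fh:
        fh.write(
            json.dumps(
                {
                    "event": "parameters",
                    "bait_id": abundance.bait_id,
                    "n_bait_runs": abundance.n_bait_runs,
                    "n_control_runs": abundance.n_control_runs,
                    **{k: v for k, v in (params or {}).items()},
                },
                sort_keys=True,
            )
            + "\n"
        )
        for run_id, report in filter_reports.items():
            fh.write(
                json.dumps(
                    {
                        "event": "filter",
                        "run_id": run_id,
                        "n_input": report.n_input,
                        "n_retained": report.n_retained,
                        "removed_by": report.removed_by,
                    },
                    sort_keys=True,
                )
                + "\n"
            )
        fh.write(
            json.dumps(
                {
                    "event": "report",
                    "n_proteins": int(len(abundance.frame)),
                    "n_categories": int(len(composition.mean_percent)),
                },
                sort_keys=True,
            )
            + "\n"
        )
    return paths


def run_pipeline(
    config: PipelineConfig | str | Path,
    manifest: RunManifest | str | Path,
    proteome: list[ProteinRecord] | str | Path,
    category_map: Mapping[str, str] | str | Path | None = None,
    output_dir: str | Path = "pullquant_out",
) -> PipelineResult:
    """Execute the full quantification pipeline and write its report.

    Accepts in-memory objects or file paths for the config, manifest,
    proteome and category map.  Stage failures propagate as
    :class:`PipelineError` naming the stage.
    """
    from .io_formats import load_config

    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    config.validate()
    if not isinstance(manifest, RunManifest):
        manifest = read_manifest(manifest)
    if not isinstance(proteome, list):
        proteome = read_fasta(proteome, decoy_prefix=config.decoy_prefix)
    if category_map is not None and not isinstance(category_map, Mapping):
        category_map = read_category_map(category_map)
    category_map = dict(category_map or {})
    records = {r.protein_id: r for r in proteome}
    if manifest.bait_protein_id not in records:
        raise PipelineError(
            f"stage 'setup' failed: bait {manifest.bait_protein_id!r} absent "
            "from proteome"
        )

    bait_quants: list[RunQuant] = []
    control_quants: list[RunQuant] = []
    filter_reports: dict[str, FilterReport] = {}
    stage_counts: dict[str, int] = {}
    for entry in manifest.entries:
        try:
            frame = read_psm_frame(entry.psm_table_path, config.decoy_prefix)
        except Exception as exc:
            raise PipelineError(f"stage 'read' failed for {entry.run_id}: {exc}")
        try:
            quant, report = process_run(frame, records, config, entry.run_id)
        except Exception as exc:
            raise PipelineError(
                f"stage 'filter/quantify' failed for {entry.run_id}: {exc}"
            )
        filter_reports[entry.run_id] = report
        stage_counts[f"{entry.run_id}.input"] = report.n_input
        stage_counts[f"{entry.run_id}.retained"] = report.n_retained
        stage_counts[f"{entry.run_id}.quantified"] = len(quant.frame)
        (bait_quants if entry.role == "bait" else control_quants).append(quant)

    try:
        adjusted = subtract_control(bait_quants, control_quants)
    except Exception as exc:
        raise PipelineError(f"stage 'subtract' failed: {exc}")

    if all(len(q.frame) == 0 for q in adjusted):
        warnings.warn(
            "no protein survived filtering and control subtraction; "
            "writing an empty abundance table",
            stacklevel=2,
        )
        empty = pd.DataFrame(
            columns=[
                "mean_rel_paf",
                "sd_rel_paf",
                "mean_area",
                "n_runs_detected",
                "mw_kda",
                "description",
                "category",
            ]
        )
        empty.index.name = "protein_id"
        abundance = AbundanceTable(
            frame=empty,
            bait_id=manifest.bait_protein_id,
            n_bait_runs=len(bait_quants),
            n_control_runs=len(control_quants),
        )
        composition = CompositionSummary(
            per_run=pd.DataFrame(), mean_percent=pd.Series(dtype=float), n_runs=0
        )
    else:
        try:
            rel_by_run = {
                q.run_id: relative_to_bait(q, manifest.bait_protein_id)
                for q in adjusted
            }
            area_by_run = {q.run_id: q.frame["top3_area"] for q in adjusted}
            abundance = aggregate_replicates(
                rel_by_run,
                area_by_run,
                records,
                manifest.bait_protein_id,
                n_control_runs=len(control_quants),
                category_map=category_map,
                config=config,
            )
        except Exception as exc:
            raise PipelineError(f"stage 'normalize/aggregate' failed: {exc}")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                composition = composition_percentages(adjusted, category_map)
        except Exception as exc:
            raise PipelineError(f"stage 'composition' failed: {exc}")

    try:
        paths = build_report(
            abundance,
            composition,
            filter_reports,
            output_dir,
            params={
                "fdr_threshold": config.fdr_threshold,
                "min_peptides": config.min_peptides,
                "ppm_tolerance": config.ppm_tolerance,
                "paf_basis": config.paf_basis,
                "paf_scale": config.paf_scale,
                "missing_as_zero": config.missing_as_zero,
            },
        )
    except Exception as exc:
        raise PipelineError(f"stage 'report' failed: {exc}")

    return PipelineResult(
        abundance=abundance,
        composition=composition,
        filter_reports=filter_reports,
        stage_counts=stage_counts,
        output_paths=paths,
    )
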