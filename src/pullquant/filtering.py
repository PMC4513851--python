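"""Confidence filtering of peptide-spectrum matches.

Implements the standard AP-MS identification filters: top search rank,
mass accuracy, target-decoy false-discovery-rate control at the PSM level
(q ≤ 1% by default) and a minimum number of distinct peptides per protein.

The FDR estimator is the plain decoy/target ratio

    FDR̂(t) = #decoys with score ≥ t / max(1, #targets with score ≥ t)

monotonized into q-values, q(s) = min over thresholds t ≤ s of FDR̂(t),
so that q is non-increasing in score.  No +1 correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .io_formats import PeptideMatch, frame_to_psms, psms_to_frame

PsmInput = Union[pd.DataFrame, Iterable[PeptideMatch]]

#: Filter criteria in report-attribution order.
FILTER_CRITERIA = ("rank", "mass_accuracy", "fdr", "decoy")


def as_psm_frame(psms: PsmInput) -> pd.DataFrame:
    """Accept either a PSM DataFrame or typed PeptideMatch rows."""
    if isinstance(psms, pd.DataFrame):
        return psms
    return psms_to_frame(list(psms))


@dataclass
class FilterReport:
    """Audit trail of one filtering pass.

    Counts are conserved: ``n_input = n_retained + Σ removed_by.values()``
    with each removed PSM attributed to the first criterion it fails, in
    the order rank → mass accuracy → FDR → decoy.
    """

    n_input: int
    n_retained: int
    removed_by: dict[str, int]
    decoy_fraction_after: float
    proteins_dropped_min_peptides: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_input != self.n_retained + sum(self.removed_by.values()):
            raise ValueError("filter report counts are not conserved")

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input), ("retained", self.n_retained)]
        rows += [(f"removed_{k}", v) for k, v in self.removed_by.items()]
        rows.append(("decoy_fraction_after", self.decoy_fraction_after))
        rows.append(
            ("proteins_dropped_min_peptides", len(self.proteins_dropped_min_peptides))
        )
        return pd.DataFrame(rows, columns=["quantity", "value"])


def compute_qvalues(psms: PsmInput) -> pd.DataFrame:
    """Assign target-decoy q-values to every PSM (decoys included).

    Returns a copy of the table with a ``q_value`` column.  With no decoy
    PSMs present every q-value is 0.
    """
    frame = as_psm_frame(psms).copy()
    n = len(frame)
    if n == 0:
        frame["q_value"] = pd.Series(dtype=float)
        return frame
    scores = frame["score"].to_numpy(dtype=float)
    is_decoy = frame["is_decoy"].to_numpy(dtype=bool)

    order = np.argsort(-scores, kind="stable")  # descending score
    dec_sorted = is_decoy[order]
    cum_decoys = np.cumsum(dec_sorted)
    cum_targets = np.cumsum(~dec_sorted)
    # at threshold = score of PSM i, counts must include every tied PSM:
    # use the last index of each tie group
    sorted_scores = scores[order]
    # indices of last occurrence per tie group, applied to all group members
    boundaries = np.flatnonzero(np.diff(sorted_scores) != 0)
    last_idx = np.empty(n, dtype=int)
    start = 0
    for b in list(boundaries) + [n - 1]:
        last_idx[start : b + 1] = b
        start = b + 1
    fdr = cum_decoys[last_idx] / np.maximum(1, cum_targets[last_idx])
    # q(s) = min over thresholds t ≤ s  →  suffix minimum in descending order
    qvals_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n, dtype=float)
    q[order] = qvals_sorted
    frame["q_value"] = np.clip(q, 0.0, 1.0)
    return frame


def filter_psms(
    psms: PsmInput,
    fdr_threshold: float = 0.01,
    ppm_tolerance: float = 10.0,
) -> tuple[pd.DataFrame, FilterReport]:
    """Retain rank-1, mass-accurate, low-q, non-decoy PSMs.

    A PSM survives iff rank = 1, \\|mass_error_ppm\\| ≤ ``ppm_tolerance``,
    q_value ≤ ``fdr_threshold`` and it is not a decoy.  Removals are
    attributed to the first failing criterion in that order.
    """
    frame = as_psm_frame(psms)
    if "q_value" not in frame.columns:
        raise ValueError("q-values must be computed before filtering")
    fail_rank = frame["rank"].to_numpy() != 1
    fail_mass = np.abs(frame["mass_error_ppm"].to_numpy(dtype=float)) > ppm_tolerance
    fail_fdr = frame["q_value"].to_numpy(dtype=float) > fdr_threshold
    fail_decoy = frame["is_decoy"].to_numpy(dtype=bool)

    removed_by = dict.fromkeys(FILTER_CRITERIA, 0)
    still_in = np.ones(len(frame), dtype=bool)
    for name, fails in zip(
        FILTER_CRITERIA, (fail_rank, fail_mass, fail_fdr, fail_decoy)
    ):
        newly = still_in & fails
        removed_by[name] = int(newly.sum())
        still_in &= ~fails

    pass_other = ~fail_rank & ~fail_mass & ~fail_fdr
    n_pass_other = int(pass_other.sum())
    decoy_fraction = (
        float((pass_other & fail_decoy).sum() / n_pass_other) if n_pass_other else 0.0
    )
    retained = frame.loc[still_in].reset_index(drop=True)
    report = FilterReport(
        n_input=len(frame),
        n_retained=len(retained),
        removed_by=removed_by,
        decoy_fraction_after=decoy_fraction,
    )
    report.validate()
    return retained, report


def peptide_counts(retained: PsmInput) -> pd.Series:
    """Distinct peptide sequences per protein (fractions merged)."""
    frame = as_psm_frame(retained)
    if len(frame) == 0:
        return pd.Series(dtype=int)
    pairs = frame.assign(protein_id=frame["protein_ids"].str.split(";")).explode(
        "protein_id"
    )
    return pairs.groupby("protein_id")["peptide_seq"].nunique()


def filter_proteins(
    retained: PsmInput,
    min_peptides: int = 2,
    report: FilterReport | None = None,
) -> set[str]:
    """Proteins of one run with ≥ ``min_peptides`` distinct peptides.

    Gel-fraction structure is ignored: peptides are counted per run after
    merging fractions.  When a :class:`FilterReport` is passed, the proteins
    failing the rule are appended to its audit list.
    """
    counts = peptide_counts(retained)
    passing = set(counts.index[counts >= min_peptides])
    if report is not None:
        report.proteins_dropped_min_peptides = sorted(
            set(counts.index) - passing
        )
    return passing


def retained_as_matches(retained: pd.DataFrame) -> list[PeptideMatch]:
    """Typed view of a retained-PSM table."""
    return frame_to_psms(retained)
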