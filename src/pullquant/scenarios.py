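"""Reference ground-truth scenarios for the synthetic generator.

The default scenario emulates the pull-down that motivated this package:
an SBP-tagged LeishIF3e bait capturing the 12-subunit *Leishmania* eIF3
complex, with each subunit at its observed stoichiometry relative to the
bait and with the subunit molecular weights used to size the synthetic
sequences.  An extended scenario adds the translation factors observed in
the same interactome (eIF1, eIF1A, eIF2 subunits, eIF5 and elongation
factors), whose small molecular weights make them the hardest recovery
cases.  Twenty shared high-abundance background contaminants and one
mock-bait (luciferase-style) control run complete the study design of
four independent bait replicates.
"""

from __future__ import annotations

import numpy as np

from .io_formats import DEFAULT_DECOY_PREFIX
from .synthetic import (
    GroundTruth,
    SimulationParams,
    _append_decoys,
    _make_records,
)

#: eIF3 subunits: relative stoichiometry to the eIF3e bait and MW in kDa.
EIF3_SUBUNITS: dict[str, tuple[float, float]] = {
    "IF3A": (0.65, 87.6),
    "IF3B": (0.59, 80.7),
    "IF3C": (0.47, 82.0),
    "IF3D": (0.42, 60.6),
    "IF3E": (1.00, 46.3),  # bait
    "IF3F": (0.68, 36.7),
    "IF3G": (0.48, 28.8),
    "IF3H": (0.78, 37.9),
    "IF3I": (0.34, 45.4),
    "IF3J": (0.13, 23.5),
    "IF3K": (0.67, 26.3),
    "IF3L": (0.58, 62.7),
}

BAIT_ID = "IF3E"

#: Translation factors co-purifying with eIF3: stoichiometry, MW (kDa).
TRANSLATION_FACTORS: dict[str, tuple[float, float]] = {
    "IF1": (0.51, 12.3),
    "IF2ALPHA": (0.25, 46.6),
    "IF2BETA": (0.17, 38.0),
    "IF2GAMMA": (0.11, 52.5),
    "IF5": (0.19, 42.9),
    "IF1A": (0.34, 18.6),
    "EF1B": (0.32, 25.6),
    "EF2": (0.25, 94.1),
    "EF1GAMMA": (0.12, 46.2),
    "EF1ALPHA": (0.15, 49.1),
}

#: Functional-category vocabulary used for synthetic composition reports.
CONTAMINANT_CATEGORIES = (
    "chaperones",
    "metabolic enzymes",
    "cytoskeleton",
    "ribosomal proteins",
    "ubiquitination",
)

#: Mean residue mass (Da) used to size synthetic sequences from a target MW.
_MEAN_RESIDUE_DA = 110.0


def _length_for_mw(mw_kda: float) -> int:
    return max(21, int(round(mw_kda * 1000.0 / _MEAN_RESIDUE_DA)))


def eif3_pulldown_truth(
    seed: int = 0,
    include_translation_factors: bool = False,
    n_contaminants: int = 20,
    n_bait_runs: int = 4,
    n_control_runs: int = 1,
    contaminant_abundance_range: tuple[float, float] = (50.0, 150.0),
    contaminant_length_range: tuple[int, int] = (80, 160),
    params: SimulationParams | None = None,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
) -> GroundTruth:
    """Ground truth for the reference eIF3e pull-down study.

    Twelve complex members at their observed stoichiometries (bait = 1),
    optionally the associated translation factors, plus ``n_contaminants``
    background proteins present at equal expected abundance in bait and
    control runs.  Deterministic under ``seed``.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)

    members = dict(EIF3_SUBUNITS)
    if include_translation_factors:
        members.update(TRANSLATION_FACTORS)
    member_sizes = [
        (pid, _length_for_mw(mw_kda)) for pid, (_, mw_kda) in members.items()
    ]
    cont_ids = [f"CONT{i:02d}" for i in range(1, n_contaminants + 1)]
    cont_sizes = [
        (pid, int(rng.integers(*contaminant_length_range))) for pid in cont_ids
    ]
    records = _make_records(rng, member_sizes + cont_sizes, decoy_prefix)
    records = _append_decoys(records, decoy_prefix)

    c_lo, c_hi = contaminant_abundance_range
    cont_abundance = (
        np.exp(rng.uniform(np.log(c_lo), np.log(c_hi), size=n_contaminants))
        if n_contaminants
        else np.empty(0)
    )

    categories = {pid: "eIF3 subunits" for pid in EIF3_SUBUNITS}
    if include_translation_factors:
        for pid in TRANSLATION_FACTORS:
            categories[pid] = (
                "elongation factors" if pid.startswith("EF") else "initiation factors"
            )
    for i, pid in enumerate(cont_ids):
        categories[pid] = CONTAMINANT_CATEGORIES[i % len(CONTAMINANT_CATEGORIES)]

    return GroundTruth(
        bait_id=BAIT_ID,
        stoichiometry={pid: s for pid, (s, _) in members.items()},
        contaminants=dict(zip(cont_ids, cont_abundance)),
        proteome=records,
        seed=int(seed),
        n_bait_runs=n_bait_runs,
        n_control_runs=n_control_runs,
        params=params,
        categories=categories,
    )
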