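"""Synthetic AP-MS pull-down generator with known ground truth.

Emulates a bait pull-down of a multi-protein complex: complex members
co-purify at fixed stoichiometries relative to the bait, high-abundance
background contaminants appear in bait and mock-bait (control) runs alike,
and each LC-MS/MS run yields a PSM table with decoy hits, spurious (noise)
matches, rank-2 candidates and log-normal replicate noise.

Detection model (deliberately minimal):

* every protein is built from tryptic fragments of 7–9 residues, so its
  detectable peptide count is proportional to its molecular weight with a
  common constant across proteins — the regime in which the expected
  unique-peptide count, and hence the PAF, is proportional to abundance;
* each detectable peptide of a protein at relative abundance ``a``
  independently yields ``Poisson(depth · a)`` PSMs; unique-peptide counts
  therefore saturate once ``depth · a`` is large (the intended regime for
  background contaminants, whose evidence then cancels exactly between
  bait and control runs);
* peptide intensities are log-normal around ``a · intensity_scale``;
* PSM scores are Gaussian: one channel for correct matches, a lower one
  shared by decoy and noise matches, so the 1% FDR filter is exercised;
* mass errors are N(0, 3 ppm) for correct matches while a configurable
  fraction of false matches is U(−20, 20) ppm.

All randomness flows from the single ground-truth seed through per-run
derived seeds; identical inputs give byte-identical PSM tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .chem import tryptic_digest
from .io_formats import (
    DEFAULT_DECOY_PREFIX,
    ManifestEntry,
    ProteinRecord,
    RunManifest,
    write_category_map,
    write_fasta,
    write_manifest,
    write_psm_frame,
)

#: Default expected PSMs per unit abundance per detectable peptide.  At the
#: default the bait (abundance 1) sees ≈33% of its peptides per run — the
#: non-saturated regime — while contaminants at 50–150× saturate completely.
DEFAULT_DEPTH = 0.4

#: Residues eligible inside a tryptic fragment (no internal cleavage sites).
_INTERNAL_POOL = np.array(list("ACDEFGHILMNQSTVWYP"))
_START_POOL = np.array(list("ACDEFGHILMNQSTVWY"))  # no P: would mask cleavage
_CLEAVAGE_POOL = np.array(list("KR"))


@dataclass
class SimulationParams:
    """Noise/detection channel parameters shared by all runs."""

    depth: float = DEFAULT_DEPTH
    noise_cv: float = 0.1
    score_mu_target: float = 4.0
    score_mu_decoy: float = 0.0
    score_sigma: float = 1.0
    noise_psm_rate: float = 0.10
    decoy_psm_rate: float = 0.10
    wide_mass_fraction: float = 0.5
    rank2_rate: float = 0.02
    intensity_scale: float = 1e7
    intensity_sigma: float = 0.6
    mass_sigma_ppm: float = 3.0
    n_fractions: int = 3
    detect_length_range: tuple[int, int] = (7, 30)
    detect_missed_cleavages: int = 1


@dataclass
class GroundTruth:
    """Complete description of a simulated pull-down study."""

    bait_id: str
    stoichiometry: dict[str, float]
    contaminants: dict[str, float]
    proteome: list[ProteinRecord]
    seed: int
    n_bait_runs: int = 4
    n_control_runs: int = 1
    control_only_level: float = 1.0
    params: SimulationParams = field(default_factory=SimulationParams)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if abs(self.stoichiometry.get(self.bait_id, 0.0) - 1.0) > 1e-12:
            raise ValueError("bait stoichiometry must be exactly 1")
        if any(s <= 0 for s in self.stoichiometry.values()):
            raise ValueError("stoichiometries must be positive")
        if any(c <= 0 for c in self.contaminants.values()):
            raise ValueError("contaminant abundances must be positive")
        known = {r.protein_id for r in self.proteome}
        missing = (set(self.stoichiometry) | set(self.contaminants)) - known
        if missing:
            raise ValueError(f"ground-truth ids absent from proteome: {missing}")
        self._detectable: dict[str, list[str]] = {}

    @property
    def member_ids(self) -> list[str]:
        return list(self.stoichiometry)

    @property
    def contaminant_ids(self) -> list[str]:
        return list(self.contaminants)

    def detectable_peptides(self, protein_id: str) -> list[str]:
        """Detectable tryptic peptides of a proteome entry (cached)."""
        if protein_id not in self._detectable:
            record = next(
                r for r in self.proteome if r.protein_id == protein_id
            )
            self._detectable[protein_id] = tryptic_digest(
                record.sequence,
                self.params.detect_missed_cleavages,
                self.params.detect_length_range,
            )
        return self._detectable[protein_id]


@dataclass
class SimulatedRun:
    """One simulated LC-MS/MS run: PSM table plus its hidden truth.

    ``frame`` carries the on-disk PSM columns plus a ``true_class`` column
    (``true`` / ``noise`` / ``decoy`` / ``rank2``) that is never written to
    the PSM TSV.  Control runs contain no complex-member signal.
    """

    run_id: str
    role: str
    frame: pd.DataFrame
    true_abundance: dict[str, float]


def _random_fragment_protein(rng: np.random.Generator, length: int) -> str:
    """A protein whose tryptic fragments are all 7–9 residues long."""
    if length < 7:
        raise ValueError("protein length must be ≥ 7 residues")
    pieces: list[str] = []
    remaining = length
    while remaining > 0:
        frag_len = int(rng.integers(7, 10))
        if remaining - frag_len < 7:
            frag_len = remaining  # absorb the remainder into the last fragment
        body = rng.choice(_INTERNAL_POOL, size=frag_len - 2)
        start = rng.choice(_START_POOL)
        end = rng.choice(_CLEAVAGE_POOL)
        pieces.append(start + "".join(body) + str(end))
        remaining -= frag_len
    return "".join(pieces)


def _make_records(
    rng: np.random.Generator,
    ids_and_lengths: list[tuple[str, int]],
    decoy_prefix: str,
    description: str = "synthetic protein",
) -> list[ProteinRecord]:
    records = []
    for pid, length in ids_and_lengths:
        seq = _random_fragment_protein(rng, length)
        records.append(
            ProteinRecord.from_sequence(
                pid, seq, description=description, decoy_prefix=decoy_prefix
            )
        )
    return records


def _append_decoys(
    records: list[ProteinRecord], decoy_prefix: str = DEFAULT_DECOY_PREFIX
) -> list[ProteinRecord]:
    """Matched reversed-sequence decoys, one per target."""
    decoys = [
        ProteinRecord.from_sequence(
            decoy_prefix + r.protein_id,
            r.sequence[::-1],
            description="reversed decoy",
            decoy_prefix=decoy_prefix,
        )
        for r in records
    ]
    return records + decoys


def generate_proteome(
    n_complex: int,
    n_contaminants: int,
    length_range: tuple[int, int] = (200, 800),
    seed: int = 0,
    contaminant_length_range: tuple[int, int] = (80, 160),
    contaminant_abundance_range: tuple[float, float] = (50.0, 150.0),
    min_detectable: int = 4,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
    params: SimulationParams | None = None,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Random proteome plus a ground-truth skeleton.

    Complex members get uniform lengths within ``length_range`` and unit
    stoichiometry (caller adjusts); contaminants are shorter, high-abundance
    background shared between bait and control runs.  Matched reversed
    decoys are appended.  Deterministic under ``seed``.
    """
    if n_complex < 1:
        raise ValueError("need at least the bait in the complex")
    lo, hi = length_range
    if lo < 50 or hi > 2000 or lo > hi:
        raise ValueError("length_range must lie within [50, 2000]")
    params = params or SimulationParams()
    min_len = 7 * (min_detectable + 2)
    if lo < min_len:
        lo = min_len  # guarantee the detectable-peptide floor by construction
    rng = np.random.default_rng(seed)
    member_ids = [f"CPLX{i:02d}" for i in range(1, n_complex + 1)]
    cont_ids = [f"CONT{i:02d}" for i in range(1, n_contaminants + 1)]
    members = [(pid, int(rng.integers(lo, hi + 1))) for pid in member_ids]
    conts = [
        (pid, int(rng.integers(*contaminant_length_range)))
        for pid in cont_ids
    ]
    records = _make_records(rng, members + conts, decoy_prefix)
    records = _append_decoys(records, decoy_prefix)
    c_lo, c_hi = contaminant_abundance_range
    abundances = np.exp(
        rng.uniform(np.log(c_lo), np.log(c_hi), size=n_contaminants)
    )
    truth = GroundTruth(
        bait_id=member_ids[0],
        stoichiometry={pid: 1.0 for pid in member_ids},
        contaminants=dict(zip(cont_ids, abundances)),
        proteome=records,
        seed=int(seed),
        params=params,
    )
    return records, truth


def _run_seed(master_seed: int, role: str, run_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [int(master_seed), 0 if role == "bait" else 1, zlib.crc32(run_id.encode())]
    )


def simulate_run(
    ground_truth: GroundTruth,
    role: str,
    run_id: str,
    seed: int | np.random.SeedSequence | None = None,
) -> SimulatedRun:
    """Simulate one LC-MS/MS run of the pull-down (bait or control)."""
    if role not in ("bait", "control"):
        raise ValueError(f"unknown role {role!r}")
    gt = ground_truth
    p = gt.params
    if seed is None:
        seed = _run_seed(gt.seed, role, run_id)
    rng = np.random.default_rng(seed)
    sigma_ln = float(np.sqrt(np.log1p(p.noise_cv**2)))

    # --- per-protein abundance in this run -------------------------------
    abundance: dict[str, float] = {}
    if role == "bait":
        for pid, s in gt.stoichiometry.items():
            noise = rng.lognormal(-(sigma_ln**2) / 2.0, sigma_ln) if sigma_ln else 1.0
            abundance[pid] = s * noise
    for pid, c in gt.contaminants.items():
        level = c * (gt.control_only_level if role == "control" else 1.0)
        noise = rng.lognormal(-(sigma_ln**2) / 2.0, sigma_ln) if sigma_ln else 1.0
        abundance[pid] = level * noise

    # --- true PSMs -------------------------------------------------------
    peptides: list[str] = []
    proteins: list[str] = []
    intensities: list[np.ndarray] = []
    for pid, a in abundance.items():
        peps = gt.detectable_peptides(pid)
        if not peps or a <= 0:
            continue
        counts = rng.poisson(p.depth * a, size=len(peps))
        base = a * p.intensity_scale * rng.lognormal(
            0.0, p.intensity_sigma, size=len(peps)
        )
        detected = counts > 0
        for pep, cnt, inten in zip(
            np.asarray(peps)[detected], counts[detected], base[detected]
        ):
            peptides.append(pep)
            proteins.append(pid)
            intensities.append(
                inten * rng.lognormal(0.0, 0.1, size=int(cnt))
            )
    n_true = int(sum(len(v) for v in intensities))
    pep_rep = np.repeat(
        np.asarray(peptides, dtype=object),
        [len(v) for v in intensities] if intensities else [],
    )
    prot_rep = np.repeat(
        np.asarray(proteins, dtype=object),
        [len(v) for v in intensities] if intensities else [],
    )
    inten_rep = (
        np.concatenate(intensities) if intensities else np.empty(0)
    )

    rows = {
        "peptide_seq": list(pep_rep),
        "protein_ids": list(prot_rep),
        "score": rng.normal(p.score_mu_target, p.score_sigma, n_true),
        "mass_error_ppm": rng.normal(0.0, p.mass_sigma_ppm, n_true),
        "intensity": inten_rep,
        "is_decoy": np.zeros(n_true, dtype=bool),
        "true_class": np.array(["true"] * n_true, dtype=object),
    }
    frame = pd.DataFrame(rows)

    # --- injected noise matches (wrong spectra on real peptides) ---------
    # spurious assignments track abundance: chimeric/co-eluting spectra come
    # predominantly from abundant species
    pool = [
        (pid, pep)
        for pid in abundance
        for pep in gt.detectable_peptides(pid)
    ]
    pool_weights = np.array(
        [abundance[pid] for pid, _ in pool], dtype=float
    )
    n_noise = int(rng.poisson(p.noise_psm_rate * max(n_true, 1)))
    if pool and n_noise:
        idx = rng.choice(
            len(pool), size=n_noise, p=pool_weights / pool_weights.sum()
        )
        wide = rng.random(n_noise) < p.wide_mass_fraction
        mass_err = np.where(
            wide,
            rng.uniform(-20.0, 20.0, n_noise),
            rng.normal(0.0, p.mass_sigma_ppm, n_noise),
        )
        median_int = float(np.median(inten_rep)) if n_true else p.intensity_scale
        noise_frame = pd.DataFrame(
            {
                "peptide_seq": [pool[i][1] for i in idx],
                "protein_ids": [pool[i][0] for i in idx],
                "score": rng.normal(p.score_mu_decoy, p.score_sigma, n_noise),
                "mass_error_ppm": mass_err,
                "intensity": median_int
                * rng.lognormal(0.0, p.intensity_sigma, n_noise),
                "is_decoy": np.zeros(n_noise, dtype=bool),
                "true_class": np.array(["noise"] * n_noise, dtype=object),
            }
        )
        frame = pd.concat([frame, noise_frame], ignore_index=True)

    # --- decoy matches ---------------------------------------------------
    decoy_pool = [
        (r.protein_id, pep)
        for r in gt.proteome
        if r.is_decoy
        for pep in tryptic_digest(
            r.sequence, p.detect_missed_cleavages, p.detect_length_range
        )
    ]
    n_decoy = int(rng.poisson(p.decoy_psm_rate * max(n_true, 1)))
    if decoy_pool and n_decoy:
        idx = rng.integers(0, len(decoy_pool), size=n_decoy)
        wide = rng.random(n_decoy) < p.wide_mass_fraction
        mass_err = np.where(
            wide,
            rng.uniform(-20.0, 20.0, n_decoy),
            rng.normal(0.0, p.mass_sigma_ppm, n_decoy),
        )
        median_int = float(np.median(inten_rep)) if n_true else p.intensity_scale
        decoy_frame = pd.DataFrame(
            {
                "peptide_seq": [decoy_pool[i][1] for i in idx],
                "protein_ids": [decoy_pool[i][0] for i in idx],
                "score": rng.normal(p.score_mu_decoy, p.score_sigma, n_decoy),
                "mass_error_ppm": mass_err,
                "intensity": median_int
                * rng.lognormal(0.0, p.intensity_sigma, n_decoy),
                "is_decoy": np.ones(n_decoy, dtype=bool),
                "true_class": np.array(["decoy"] * n_decoy, dtype=object),
            }
        )
        frame = pd.concat([frame, decoy_frame], ignore_index=True)

    # --- spectrum bookkeeping: ids, fractions, rank-2 candidates ---------
    n = len(frame)
    frame["spectrum_id"] = [f"{run_id}.{i + 1:06d}" for i in range(n)]
    frame["rank"] = 1
    frame["run_id"] = run_id
    frame["fraction_id"] = [
        f"F{int(k) + 1}" for k in rng.integers(0, p.n_fractions, size=n)
    ]
    is_rank2 = rng.random(n) < p.rank2_rate
    if is_rank2.any():
        second = frame.loc[is_rank2].copy()
        second["rank"] = 2
        second["score"] = second["score"] - rng.exponential(1.0, len(second)) - 0.1
        second["true_class"] = "rank2"
        frame = pd.concat([frame, second], ignore_index=True)

    frame = frame[
        [
            "spectrum_id",
            "run_id",
            "fraction_id",
            "peptide_seq",
            "protein_ids",
            "rank",
            "score",
            "mass_error_ppm",
            "intensity",
            "is_decoy",
            "true_class",
        ]
    ]
    return SimulatedRun(
        run_id=run_id, role=role, frame=frame, true_abundance=abundance
    )


def simulate_experiment_set(
    ground_truth: GroundTruth,
    out_dir,
) -> tuple[RunManifest, list[SimulatedRun]]:
    """Simulate and write a full experiment set to ``out_dir``.

    Writes one PSM TSV per run (bait runs first), the proteome FASTA
    (targets plus decoys), the run manifest and, when the ground truth
    carries categories, a category map.  Returns the manifest and the
    in-memory runs (with their hidden truth columns).
    """
    gt = ground_truth
    if gt.n_bait_runs < 1:
        raise ValueError("need at least one bait run")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    runs: list[SimulatedRun] = []
    entries: list[ManifestEntry] = []
    for role, count in (("bait", gt.n_bait_runs), ("control", gt.n_control_runs)):
        for i in range(1, count + 1):
            run_id = f"{role}_{i}"
            run = simulate_run(gt, role, run_id)
            path = out_dir / f"{run_id}.psms.tsv"
            write_psm_frame(run.frame, path)
            runs.append(run)
            entries.append(ManifestEntry(run_id, role, str(path)))

    write_fasta(gt.proteome, out_dir / "proteome.fasta")
    manifest = RunManifest(entries=entries, bait_protein_id=gt.bait_id)
    write_manifest(manifest, out_dir / "manifest.tsv")
    if gt.categories:
        write_category_map(gt.categories, out_dir / "categories.tsv")
    return manifest, runs
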