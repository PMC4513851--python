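"""On-disk formats for the pull-down quantification pipeline.

Everything the pipeline reads or writes lives here: FASTA proteomes
(via Biopython), PSM tables, protein→category maps, run manifests
(all tab-separated, UTF-8, ``.`` decimal) and plain ``key=value``
configuration files.  Readers validate and reject malformed input with the
offending line number rather than silently coercing it.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem import AMINO_ACIDS, protein_mw

DEFAULT_DECOY_PREFIX = "DECOY_"

#: Column order of the PSM table schema.
PSM_COLUMNS = [
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
]
#: Optional columns preserved when present.
PSM_OPTIONAL_COLUMNS = ["q_value"]

MANIFEST_ROLES = ("bait", "control")


class ParseError(ValueError):
    """Malformed on-disk input; message carries file and line number."""

    def __init__(self, path, lineno: int | None, message: str):
        self.path = str(path)
        self.lineno = lineno
        where = f"{self.path}:{lineno}" if lineno is not None else self.path
        super().__init__(f"{where}: {message}")


class SchemaError(ParseError):
    """A table is missing required columns."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ProteinRecord:
    """One proteome entry (target or decoy)."""

    protein_id: str
    description: str
    sequence: str
    mw_da: float
    is_decoy: bool
    category: str = ""

    @classmethod
    def from_sequence(
        cls,
        protein_id: str,
        sequence: str,
        description: str = "",
        category: str = "",
        decoy_prefix: str = DEFAULT_DECOY_PREFIX,
    ) -> "ProteinRecord":
        return cls(
            protein_id=protein_id,
            description=description,
            sequence=sequence,
            mw_da=protein_mw(sequence),
            is_decoy=protein_id.startswith(decoy_prefix),
            category=category,
        )

    def validate(self, decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"{self.protein_id}: illegal residues {sorted(bad)}")
        if self.mw_da <= 0:
            raise ValueError(f"{self.protein_id}: non-positive molecular weight")
        if abs(self.mw_da - protein_mw(self.sequence)) > 0.01:
            raise ValueError(
                f"{self.protein_id}: stored mw_da deviates from sequence mass"
            )
        if self.is_decoy != self.protein_id.startswith(decoy_prefix):
            raise ValueError(
                f"{self.protein_id}: is_decoy inconsistent with prefix "
                f"{decoy_prefix!r}"
            )

    @property
    def mw_kda(self) -> float:
        return self.mw_da / 1000.0


@dataclass
class PeptideMatch:
    """One peptide-spectrum match (PSM) row."""

    spectrum_id: str
    run_id: str
    fraction_id: str
    peptide_seq: str
    protein_ids: list[str]
    rank: int
    score: float
    mass_error_ppm: float
    intensity: float
    is_decoy: bool
    q_value: float | None = None

    def validate(self) -> None:
        if self.rank < 1:
            raise ValueError(f"{self.spectrum_id}: rank must be ≥ 1")
        if self.intensity < 0:
            raise ValueError(f"{self.spectrum_id}: negative intensity")
        if not self.protein_ids:
            raise ValueError(f"{self.spectrum_id}: no mapped proteins")
        if self.q_value is not None and not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"{self.spectrum_id}: q_value outside [0, 1]")


@dataclass
class ManifestEntry:
    run_id: str
    role: str
    psm_table_path: str


@dataclass
class RunManifest:
    """Designates bait runs, control (mock-bait) runs and the bait protein."""

    entries: list[ManifestEntry]
    bait_protein_id: str

    def __post_init__(self):
        roles = {e.role for e in self.entries}
        bad = roles - set(MANIFEST_ROLES)
        if bad:
            raise ValueError(f"unknown manifest roles: {sorted(bad)}")
        if not any(e.role == "bait" for e in self.entries):
            raise ValueError("manifest must designate at least one bait run")
        if not self.bait_protein_id:
            raise ValueError("manifest must name the bait protein")

    @property
    def bait_runs(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.role == "bait"]

    @property
    def control_runs(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.role == "control"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Validated pipeline parameters with their defaults.

    fdr_threshold
        PSM q-value cut-off (target-decoy FDR), default 1%.
    min_peptides
        Minimum distinct peptides per protein per run, default 2.
    ppm_tolerance
        Absolute mass-accuracy window in ppm, default 10.
    top_n_area
        Number of most intense peptides averaged into the protein area.
    paf_scale
        Scale factor applied to count/MW, default 1e4.
    paf_basis
        "unique" (distinct peptides, default) or "spectral" (PSM count).
    missing_as_zero
        Whether a replicate in which a protein is undetected contributes a
        zero to its cross-replicate mean (default) or is skipped.
    shared_peptides
        "all" credits a shared peptide to every mapped protein (default);
        "razor" assigns it only to the mapped protein with most unique
        evidence.
    """

    fdr_threshold: float = 0.01
    min_peptides: int = 2
    ppm_tolerance: float = 10.0
    decoy_prefix: str = DEFAULT_DECOY_PREFIX
    top_n_area: int = 3
    paf_scale: float = 1e4
    paf_basis: str = "unique"
    missing_as_zero: bool = True
    shared_peptides: str = "all"

    def validate(self) -> None:
        if not (0.0 < self.fdr_threshold <= 1.0):
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be ≥ 1")
        if self.ppm_tolerance <= 0:
            raise ValueError("ppm_tolerance must be > 0")
        if not self.decoy_prefix:
            raise ValueError("decoy_prefix must be non-empty")
        if self.top_n_area < 1:
            raise ValueError("top_n_area must be ≥ 1")
        if self.paf_scale <= 0:
            raise ValueError("paf_scale must be > 0")
        if self.paf_basis not in ("unique", "spectral"):
            raise ValueError("paf_basis must be 'unique' or 'spectral'")
        if self.shared_peptides not in ("all", "razor"):
            raise ValueError("shared_peptides must be 'all' or 'razor'")


_CONFIG_TYPES = {
    "fdr_threshold": float,
    "min_peptides": int,
    "ppm_tolerance": float,
    "decoy_prefix": str,
    "top_n_area": int,
    "paf_scale": float,
    "paf_basis": str,
    "missing_as_zero": bool,
    "shared_peptides": str,
}


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {text!r}")


def load_config(path) -> PipelineConfig:
    """Read a ``key=value`` config file; absent keys take their defaults."""
    values: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(path, lineno, f"expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in _CONFIG_TYPES:
                raise ParseError(path, lineno, f"unknown config key {key!r}")
            caster = _parse_bool if _CONFIG_TYPES[key] is bool else _CONFIG_TYPES[key]
            try:
                values[key] = caster(value)
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad value for {key}: {exc}") from None
    config = PipelineConfig(**values)
    try:
        config.validate()
    except ValueError as exc:
        raise ParseError(path, None, str(exc)) from None
    return config


def write_config(config: PipelineConfig, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for f in dataclasses.fields(config):
            value = getattr(config, f.name)
            if isinstance(value, bool):
                value = "true" if value else "false"
            fh.write(f"{f.name}={value}\n")
    return path


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path, decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> list[ProteinRecord]:
    """Parse a FASTA proteome into :class:`ProteinRecord` values in file order.

    Molecular weights are computed from the sequence; the decoy flag follows
    the header prefix.  Malformed headers and illegal residues raise
    :class:`ParseError` naming the line number.
    """
    path = Path(path)
    # map each record (in order) to the line number of its header
    header_lines: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith(">"):
                if len(line) == 1 or line[1].isspace():
                    raise ParseError(path, lineno, "FASTA header without identifier")
                header_lines.append(lineno)
            elif line and not header_lines:
                raise ParseError(path, lineno, "sequence data before first '>' header")

    records: list[ProteinRecord] = []
    for idx, seq_record in enumerate(SeqIO.parse(str(path), "fasta")):
        lineno = header_lines[idx]
        sequence = str(seq_record.seq).upper()
        if not sequence:
            raise ParseError(path, lineno, f"{seq_record.id}: empty sequence")
        bad = set(sequence) - set(AMINO_ACIDS)
        if bad:
            raise ParseError(
                path, lineno, f"{seq_record.id}: illegal residues {sorted(bad)}"
            )
        description = seq_record.description[len(seq_record.id) :].strip()
        records.append(
            ProteinRecord.from_sequence(
                seq_record.id,
                sequence,
                description=description,
                decoy_prefix=decoy_prefix,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> Path:
    path = Path(path)
    seq_records = []
    for rec in records:
        seq_records.append(
            SeqRecord(Seq(rec.sequence), id=rec.protein_id, description=rec.description)
        )
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(seq_records, fh, "fasta")
    return path


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------


def psms_to_frame(psms: Iterable[PeptideMatch]) -> pd.DataFrame:
    """Represent PSMs as a DataFrame (protein_ids ';'-joined)."""
    rows = []
    for p in psms:
        row = dataclasses.asdict(p)
        row["protein_ids"] = ";".join(p.protein_ids)
        rows.append(row)
    columns = PSM_COLUMNS + PSM_OPTIONAL_COLUMNS
    frame = pd.DataFrame(rows, columns=columns)
    if frame["q_value"].isna().all():
        frame = frame.drop(columns=["q_value"])
    return frame


def frame_to_psms(frame: pd.DataFrame) -> list[PeptideMatch]:
    has_q = "q_value" in frame.columns
    out = []
    for row in frame.itertuples(index=False):
        q = getattr(row, "q_value", None) if has_q else None
        if q is not None and (q is pd.NA or (isinstance(q, float) and math.isnan(q))):
            q = None
        out.append(
            PeptideMatch(
                spectrum_id=str(row.spectrum_id),
                run_id=str(row.run_id),
                fraction_id=str(row.fraction_id),
                peptide_seq=str(row.peptide_seq),
                protein_ids=str(row.protein_ids).split(";"),
                rank=int(row.rank),
                score=float(row.score),
                mass_error_ppm=float(row.mass_error_ppm),
                intensity=float(row.intensity),
                is_decoy=bool(row.is_decoy),
                q_value=q,
            )
        )
    return out


def _validate_psm_frame(frame: pd.DataFrame, path, decoy_prefix: str) -> None:
    """Enforce PeptideMatch invariants on a parsed table; line-numbered errors."""

    def lineno(mask) -> int:
        # +2: one for the header line, one for 1-based numbering
        return int(np.flatnonzero(mask.to_numpy())[0]) + 2

    bad = frame["rank"] < 1
    if bad.any():
        raise ParseError(path, lineno(bad), "rank must be ≥ 1")
    bad = frame["intensity"] < 0
    if bad.any():
        raise ParseError(path, lineno(bad), "intensity must be ≥ 0")
    bad = frame["protein_ids"].str.len() == 0
    if bad.any():
        raise ParseError(path, lineno(bad), "empty protein_ids")
    # is_decoy ⇔ every mapped protein carries the decoy prefix
    all_decoy = frame["protein_ids"].map(
        lambda ids: all(p.startswith(decoy_prefix) for p in ids.split(";"))
    )
    bad = frame["is_decoy"] != all_decoy
    if bad.any():
        raise ParseError(
            path, lineno(bad), "is_decoy inconsistent with mapped protein ids"
        )
    if "q_value" in frame.columns:
        q = frame["q_value"]
        bad = q.notna() & ((q < 0) | (q > 1))
        if bad.any():
            raise ParseError(path, lineno(bad), "q_value outside [0, 1]")
    dup = frame.duplicated(subset=["run_id", "fraction_id", "spectrum_id", "rank"])
    if dup.any():
        raise ParseError(
            path, lineno(dup), "(spectrum_id, rank) duplicated within run+fraction"
        )


def read_psm_frame(
    path, decoy_prefix: str = DEFAULT_DECOY_PREFIX
) -> pd.DataFrame:
    """Read and validate a PSM table as a DataFrame (bulk in-memory form)."""
    path = Path(path)
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            dtype={
                "spectrum_id": str,
                "run_id": str,
                "fraction_id": str,
                "peptide_seq": str,
                "protein_ids": str,
            },
        )
    except pd.errors.EmptyDataError:
        raise SchemaError(path, None, "empty PSM table (no header)") from None
    missing = [c for c in PSM_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(path, None, f"missing columns: {', '.join(missing)}")
    for col in ("rank",):
        try:
            frame[col] = frame[col].astype(int)
        except (ValueError, TypeError):
            bad = pd.to_numeric(frame[col], errors="coerce").isna()
            raise ParseError(
                path, int(np.flatnonzero(bad.to_numpy())[0]) + 2, f"non-integer {col}"
            ) from None
    for col in ("score", "mass_error_ppm", "intensity"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any() or coerced.isna().any():
            bad_mask = coerced.isna()
            raise ParseError(
                path,
                int(np.flatnonzero(bad_mask.to_numpy())[0]) + 2,
                f"non-numeric {col}",
            )
        frame[col] = coerced.astype(float)
    if frame["is_decoy"].dtype != bool:
        try:
            frame["is_decoy"] = frame["is_decoy"].map(
                lambda v: _parse_bool(str(v))
            )
        except ValueError:
            raise ParseError(path, None, "is_decoy must be boolean") from None
    _validate_psm_frame(frame, path, decoy_prefix)
    return frame


def read_psm_table(
    path, decoy_prefix: str = DEFAULT_DECOY_PREFIX
) -> list[PeptideMatch]:
    """Read a PSM table into typed :class:`PeptideMatch` rows."""
    return frame_to_psms(read_psm_frame(path, decoy_prefix=decoy_prefix))


def write_psm_frame(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    columns = [c for c in PSM_COLUMNS + PSM_OPTIONAL_COLUMNS if c in frame.columns]
    out = frame[columns].copy()
    out["is_decoy"] = out["is_decoy"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def write_psm_table(psms: Iterable[PeptideMatch], path) -> Path:
    return write_psm_frame(psms_to_frame(psms), path)


# ---------------------------------------------------------------------------
# category map, manifest
# ---------------------------------------------------------------------------


def read_category_map(path) -> dict[str, str]:
    """Read a 2-column TSV mapping protein_id → functional category.

    Consistent duplicates collapse; conflicting duplicates are an error.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(path, lineno, "expected 2 tab-separated columns")
            pid, category = parts[0].strip(), parts[1].strip()
            if pid in mapping and mapping[pid] != category:
                raise ParseError(
                    path,
                    lineno,
                    f"{pid}: conflicting categories {mapping[pid]!r} vs {category!r}",
                )
            mapping[pid] = category
    return mapping


def write_category_map(mapping: Mapping[str, str], path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for pid, category in mapping.items():
            fh.write(f"{pid}\t{category}\n")
    return path


def read_manifest(path) -> RunManifest:
    """Read a run manifest TSV (columns run_id, role, path).

    The bait protein is carried in a ``#bait_protein_id=...`` comment line.
    """
    path = Path(path)
    bait_protein_id = ""
    entries: list[ManifestEntry] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("bait_protein_id="):
                    bait_protein_id = body.partition("=")[2].strip()
                continue
            parts = line.split("\t")
            if parts[0] == "run_id":  # header
                continue
            if len(parts) != 3:
                raise ParseError(path, lineno, "expected 3 tab-separated columns")
            run_id, role, psm_path = (p.strip() for p in parts)
            if role not in MANIFEST_ROLES:
                raise ParseError(path, lineno, f"unknown role {role!r}")
            entries.append(ManifestEntry(run_id, role, psm_path))
    try:
        return RunManifest(entries=entries, bait_protein_id=bait_protein_id)
    except ValueError as exc:
        raise ParseError(path, None, str(exc)) from None


def write_manifest(manifest: RunManifest, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#bait_protein_id={manifest.bait_protein_id}\n")
        fh.write("run_id\trole\tpath\n")
        for e in manifest.entries:
            fh.write(f"{e.run_id}\t{e.role}\t{e.psm_table_path}\n")
    return path
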