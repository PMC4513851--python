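"""Protein chemistry primitives: average molecular mass and tryptic digestion.

Molecular masses use the standard average (isotope-weighted) residue masses,
matching how molecular weights are reported in protein tables (kDa to one
decimal).  Digestion follows the Keil rule for trypsin: cleavage C-terminal
to K or R, suppressed when the next residue is proline.
"""

from __future__ import annotations

from functools import lru_cache

from pyteomics import mass as _mass

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Average mass of a water molecule (Da), added once per peptide chain.
WATER_DA = _mass.calculate_mass(formula="H2O", average=True)


@lru_cache(maxsize=1)
def average_residue_masses() -> dict[str, float]:
    """Average residue (amino-acid minus water) masses in Daltons."""
    return {
        aa: _mass.calculate_mass(sequence=aa, average=True) - WATER_DA
        for aa in AMINO_ACIDS
    }


def protein_mw(sequence: str) -> float:
    """Average molecular mass of a polypeptide in Daltons.

    Sum of standard average residue masses plus one water.  Raises
    ``ValueError`` on an empty sequence or a residue outside the 20-letter
    alphabet.
    """
    if not sequence:
        raise ValueError("empty sequence has no molecular weight")
    masses = average_residue_masses()
    try:
        return sum(masses[aa] for aa in sequence) + WATER_DA
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r} in sequence") from None


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions after which trypsin cleaves (Keil rule)."""
    n = len(sequence)
    return [
        i
        for i in range(n - 1)  # never "cleave" after the last residue
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(
    sequence: str,
    missed_cleavages: int = 0,
    length_range: tuple[int, int] = (1, 10**9),
) -> list[str]:
    """In-silico tryptic digest of ``sequence``.

    Cleaves C-terminal to K/R except before P.  With ``missed_cleavages=m``
    every concatenation of up to ``m+1`` adjacent fragments is produced, then
    peptides outside ``length_range`` (inclusive) are dropped.  Peptides are
    returned N→C by start position, shorter spans first at equal start.
    """
    if missed_cleavages not in (0, 1, 2):
        raise ValueError("missed_cleavages must be 0, 1 or 2")
    if not sequence:
        return []
    lo, hi = length_range
    cuts = [0] + [i + 1 for i in cleavage_sites(sequence)] + [len(sequence)]
    fragments = [sequence[a:b] for a, b in zip(cuts, cuts[1:])]
    peptides: list[str] = []
    for start in range(len(fragments)):
        for span in range(1, missed_cleavages + 2):
            if start + span > len(fragments):
                break
            pep = "".join(fragments[start : start + span])
            if lo <= len(pep) <= hi:
                peptides.append(pep)
    return peptides
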