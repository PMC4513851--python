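import numpy as np
import pytest
from hypothesis import settings

from pullquant.io_formats import PeptideMatch, ProteinRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_proteome() -> list[ProteinRecord]:
    """Three small proteins with known tryptic structure."""
    return [
        ProteinRecord.from_sequence("P1", "MKAYDLEGKGFVTWR", description="alpha"),
        ProteinRecord.from_sequence("P2", "AADERGGFLKMNPQSTVWYK", description="beta"),
        ProteinRecord.from_sequence("P3", "GGHHLLIIMMNNQQSSTTVV", description="gamma"),
    ]


@pytest.fixture
def make_psm():
    """Factory for PeptideMatch rows with sensible defaults."""

    counter = {"n": 0}

    def _make(**overrides) -> PeptideMatch:
        counter["n"] += 1
        values = dict(
            spectrum_id=f"S{counter['n']:04d}",
            run_id="run1",
            fraction_id="F1",
            peptide_seq="AYDLEGK",
            protein_ids=["P1"],
            rank=1,
            score=5.0,
            mass_error_ppm=1.0,
            intensity=1e6,
            is_decoy=False,
            q_value=None,
        )
        values.update(overrides)
        return PeptideMatch(**values)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
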