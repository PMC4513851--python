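"""PAF/top-3 quantification, control subtraction, bait normalization and
replicate aggregation, cross-checked against brute-force recounts."""

import numpy as np
import pandas as pd
import pytest

from pullquant.io_formats import PipelineConfig, ProteinRecord
from pullquant.stoichiometry import (
    BaitMissingError,
    RunQuant,
    aggregate_replicates,
    paf,
    quantify_run,
    relative_to_bait,
    subtract_control,
    top3_area,
)


class TestPaf:
    def test_direct_formula(self):
        assert paf(20, 100000.0, 1e4) == pytest.approx(2.0)

    def test_zero_count(self):
        assert paf(0, 50000.0) == 0.0

    def test_linearity(self):
        assert paf(10, 40000.0) == pytest.approx(2 * paf(5, 40000.0))

    def test_nonpositive_mw_rejected(self):
        with pytest.raises(ValueError):
            paf(5, 0.0)


class TestTop3Area:
    @pytest.mark.parametrize(
        "intensities, expected",
        [([9, 7, 5, 1], 7.0), ([8, 2], 5.0), ([], 0.0), ([4], 4.0)],
    )
    def test_examples(self, intensities, expected):
        assert top3_area(intensities) == pytest.approx(expected)


def brute_force_quant(psms, proteome, passing, config):
    """Independent recount with plain nested loops over PSM rows."""
    mw = {r.protein_id: r.mw_da for r in proteome}
    out = {}
    for pid in sorted(passing):
        peptide_best: dict[str, float] = {}
        n_psms = 0
        for p in psms:
            if pid in p.protein_ids:
                n_psms += 1
                if p.intensity > peptide_best.get(p.peptide_seq, -1.0):
                    peptide_best[p.peptide_seq] = p.intensity
        if n_psms == 0:
            continue
        top = sorted(peptide_best.values(), reverse=True)[: config.top_n_area]
        U = len(peptide_best)
        basis = U if config.paf_basis == "unique" else n_psms
        out[pid] = {
            "U": U,
            "S": n_psms,
            "top3_area": sum(top) / len(top),
            "paf": basis / mw[pid] * config.paf_scale,
        }
    return out


class TestQuantifyRun:
    def test_counting_and_formula(self, tiny_proteome, make_psm):
        psms = [
            make_psm(peptide_seq="AYDLEGK", intensity=5.0),
            make_psm(peptide_seq="AYDLEGK", intensity=9.0),
            make_psm(peptide_seq="GFVTWR", intensity=7.0),
            make_psm(peptide_seq="MK", intensity=1.0),
        ]
        quant = quantify_run(psms, tiny_proteome, {"P1"})
        row = quant.frame.loc["P1"]
        assert row["U"] == 3
        assert row["S"] == 4
        # per-peptide max then mean of top 3: (9 + 7 + 1)/3
        assert row["top3_area"] == pytest.approx(17.0 / 3.0)
        mw = tiny_proteome[0].mw_da
        assert row["paf"] == pytest.approx(3 / mw * 1e4)

    def test_shared_peptide_credits_both_proteins(self, tiny_proteome, make_psm):
        psms = [
            make_psm(peptide_seq="AYDLEGK", protein_ids=["P1", "P2"]),
            make_psm(peptide_seq="GFVTWR", protein_ids=["P1", "P2"]),
        ]
        quant = quantify_run(psms, tiny_proteome, {"P1", "P2"})
        assert quant.frame.loc["P1", "U"] == 2
        assert quant.frame.loc["P2", "U"] == 2

    def test_razor_mode_assigns_to_best_supported(self, tiny_proteome, make_psm):
        config = PipelineConfig(shared_peptides="razor", min_peptides=1)
        psms = [
            make_psm(peptide_seq="AYDLEGK", protein_ids=["P1"]),
            make_psm(peptide_seq="GFVTWR", protein_ids=["P1"]),
            make_psm(peptide_seq="GGFLK", protein_ids=["P1", "P2"]),
        ]
        quant = quantify_run(psms, tiny_proteome, {"P1", "P2"}, config)
        assert quant.frame.loc["P1", "U"] == 3
        assert "P2" not in quant.frame.index

    def test_unknown_protein_is_error(self, tiny_proteome, make_psm):
        psms = [make_psm(protein_ids=["P99"])]
        with pytest.raises(ValueError, match="absent from proteome"):
            quantify_run(psms, tiny_proteome, {"P99"})

    def test_empty_input_gives_empty_quant(self, tiny_proteome):
        quant = quantify_run([], tiny_proteome, set())
        assert len(quant.frame) == 0

    def test_spectral_count_basis(self, tiny_proteome, make_psm):
        config = PipelineConfig(paf_basis="spectral")
        psms = [make_psm(peptide_seq="AYDLEGK"), make_psm(peptide_seq="AYDLEGK"),
                make_psm(peptide_seq="GFVTWR")]
        quant = quantify_run(psms, tiny_proteome, {"P1"}, config)
        mw = tiny_proteome[0].mw_da
        assert quant.frame.loc["P1", "paf"] == pytest.approx(3 / mw * 1e4)

    @pytest.mark.parametrize("case", range(10))
    def test_matches_brute_force_recount(self, tiny_proteome, make_psm, case):
        rng = np.random.default_rng(2000 + case)
        peptides = ["AYDLEGK", "GFVTWR", "MK", "GGFLK", "MNPQSTVWYK", "AADER"]
        mapping = {
            "AYDLEGK": ["P1"],
            "GFVTWR": ["P1"],
            "MK": ["P1"],
            "GGFLK": ["P2"],
            "MNPQSTVWYK": ["P2"],
            "AADER": ["P1", "P2"],
        }
        psms = [
            make_psm(
                peptide_seq=pep,
                protein_ids=mapping[pep],
                intensity=float(rng.integers(1, 100)),
            )
            for pep in rng.choice(peptides, size=int(rng.integers(1, 100)))
        ]
        config = PipelineConfig()
        quant = quantify_run(psms, tiny_proteome, {"P1", "P2"}, config)
        expected = brute_force_quant(psms, tiny_proteome, {"P1", "P2"}, config)
        assert set(quant.frame.index) == set(expected)
        for pid, exp in expected.items():
            for key, value in exp.items():
                assert quant.frame.loc[pid, key] == pytest.approx(value), (pid, key)


def quant_of(run_id, **pafs) -> RunQuant:
    frame = pd.DataFrame(
        {
            "U": 2,
            "S": 3,
            "top3_area": 10.0,
            "paf": list(pafs.values()),
        },
        index=pd.Index(list(pafs), name="protein_id"),
    )
    return RunQuant(run_id=run_id, frame=frame)


class TestSubtractControl:
    def test_subtracts_control_mean(self):
        bait = [quant_of("b1", P1=2.0)]
        control = [quant_of("c1", P1=0.5)]
        (adj,) = subtract_control(bait, control)
        assert adj.frame.loc["P1", "paf_adj"] == pytest.approx(1.5)

    def test_clamped_to_zero_and_removed_when_zero_everywhere(self):
        bait = [quant_of("b1", P1=0.4, P2=1.0)]
        control = [quant_of("c1", P1=0.5)]
        (adj,) = subtract_control(bait, control)
        assert "P1" not in adj.frame.index
        assert adj.frame.loc["P2", "paf_adj"] == pytest.approx(1.0)

    def test_survivor_in_one_run_only(self):
        bait = [quant_of("b1", P1=0.4), quant_of("b2", P1=0.9)]
        control = [quant_of("c1", P1=0.5)]
        adj = subtract_control(bait, control)
        assert "P1" not in adj[0].frame.index  # cancelled in run 1
        assert adj[1].frame.loc["P1", "paf_adj"] == pytest.approx(0.4)

    def test_no_control_runs_is_identity(self):
        bait = [quant_of("b1", P1=2.0, P2=0.1)]
        (adj,) = subtract_control(bait, [])
        assert (adj.frame["paf_adj"] == adj.frame["paf"]).all()

    def test_mean_over_multiple_controls_counts_absences_as_zero(self):
        bait = [quant_of("b1", P1=2.0)]
        controls = [quant_of("c1", P1=1.0), quant_of("c2", P2=1.0)]
        (adj,) = subtract_control(bait, controls)
        assert adj.frame.loc["P1", "paf_adj"] == pytest.approx(1.5)


class TestRelativeToBait:
    def test_ratio_and_bait_unity(self):
        quant = quant_of("b1", BAIT=4.0, PREY=2.6)
        quant.frame["paf_adj"] = quant.frame["paf"]
        rel = relative_to_bait(quant, "BAIT")
        assert rel["BAIT"] == pytest.approx(1.0)
        assert rel["PREY"] == pytest.approx(0.65)

    def test_missing_bait_is_hard_error_naming_run(self):
        quant = quant_of("bait_3", PREY=2.0)
        quant.frame["paf_adj"] = quant.frame["paf"]
        with pytest.raises(BaitMissingError, match="bait_3"):
            relative_to_bait(quant, "BAIT")

    def test_scale_invariance(self):
        quant = quant_of("b1", BAIT=4.0, P1=1.0, P2=0.25)
        quant.frame["paf_adj"] = quant.frame["paf"]
        scaled = quant_of("b1", BAIT=16.0, P1=4.0, P2=1.0)
        scaled.frame["paf_adj"] = scaled.frame["paf"]
        pd.testing.assert_series_equal(
            relative_to_bait(quant, "BAIT"), relative_to_bait(scaled, "BAIT")
        )


class TestAggregateReplicates:
    @pytest.fixture
    def proteome(self):
        return [
            ProteinRecord.from_sequence("BAIT", "MKAYDLEGKGFVTWR"),
            ProteinRecord.from_sequence("PREY", "AADERGGFLKMNPQSTVWYK"),
        ]

    def test_bait_row_exact(self, proteome):
        rel = {f"b{i}": pd.Series({"BAIT": 1.0}) for i in range(4)}
        area = {f"b{i}": pd.Series({"BAIT": 10.0}) for i in range(4)}
        table = aggregate_replicates(rel, area, proteome, "BAIT")
        row = table.frame.loc["BAIT"]
        assert row["mean_rel_paf"] == 1.0
        assert row["sd_rel_paf"] == 0.0

    def test_mean_and_sample_sd(self, proteome):
        values = [0.2, 0.0, 0.2, 0.1]
        rel = {
            f"b{i}": pd.Series({"BAIT": 1.0, **({"PREY": v} if v else {})})
            for i, v in enumerate(values)
        }
        area = {f"b{i}": pd.Series({"BAIT": 10.0}) for i in range(4)}
        table = aggregate_replicates(rel, area, proteome, "BAIT")
        row = table.frame.loc["PREY"]
        # undetected replicate contributes 0 to the mean (default policy)
        assert row["mean_rel_paf"] == pytest.approx(0.125)
        assert row["sd_rel_paf"] == pytest.approx(0.09574, abs=1e-4)
        assert row["n_runs_detected"] == 3

    def test_missing_skip_policy(self, proteome):
        config = PipelineConfig(missing_as_zero=False)
        rel = {
            "b0": pd.Series({"BAIT": 1.0, "PREY": 0.2}),
            "b1": pd.Series({"BAIT": 1.0}),
        }
        area = {k: pd.Series({"BAIT": 1.0}) for k in rel}
        table = aggregate_replicates(rel, area, proteome, "BAIT", config=config)
        assert table.frame.loc["PREY", "mean_rel_paf"] == pytest.approx(0.2)

    def test_single_run_sd_zero(self, proteome):
        rel = {"b0": pd.Series({"BAIT": 1.0, "PREY": 0.4})}
        area = {"b0": pd.Series({"BAIT": 1.0, "PREY": 1.0})}
        table = aggregate_replicates(rel, area, proteome, "BAIT")
        assert (table.frame["sd_rel_paf"] == 0.0).all()

    def test_report_rounding_only_on_output(self, proteome):
        rel = {
            "b0": pd.Series({"BAIT": 1.0, "PREY": 0.333333}),
            "b1": pd.Series({"BAIT": 1.0, "PREY": 0.333333}),
        }
        area = {k: pd.Series({"BAIT": 1.0}) for k in rel}
        table = aggregate_replicates(rel, area, proteome, "BAIT")
        assert table.frame.loc["PREY", "mean_rel_paf"] == pytest.approx(0.333333)
        out = table.to_frame().set_index("protein_id")
        assert out.loc["PREY", "mean_rel_paf"] == 0.33
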