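"""Target-decoy q-values and confidence filters, checked against a
brute-force threshold-enumeration oracle."""

import numpy as np
import pandas as pd
import pytest

from pullquant.filtering import (
    compute_qvalues,
    filter_proteins,
    filter_psms,
    peptide_counts,
)


def qvalue_oracle(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """O(n²) enumeration: q(s) = min over thresholds t ≤ s of D(t)/max(1,T(t))."""
    thresholds = np.unique(scores)
    q = np.empty(len(scores))
    for i, s in enumerate(scores):
        fdrs = []
        for t in thresholds[thresholds <= s]:
            decoys = int(((scores >= t) & is_decoy).sum())
            targets = int(((scores >= t) & ~is_decoy).sum())
            fdrs.append(decoys / max(1, targets))
        q[i] = min(1.0, min(fdrs))  # q-values are capped at 1 by convention
    return q


def psm_frame(scores, is_decoy, **extra):
    n = len(scores)
    base = dict(
        spectrum_id=[f"s{i}" for i in range(n)],
        run_id="r1",
        fraction_id="F1",
        peptide_seq=[f"PEPTIDE{i}K" for i in range(n)],
        protein_ids=["DECOY_P1" if d else "P1" for d in is_decoy],
        rank=1,
        score=list(scores),
        mass_error_ppm=0.0,
        intensity=1e6,
        is_decoy=list(is_decoy),
    )
    base.update(extra)
    return pd.DataFrame(base)


class TestComputeQvalues:
    def test_four_targets_one_decoy(self):
        """Thresholds enumerated by hand: FDR̂ = 0, 0, 1/3, 1/4 from the top;
        monotonization makes q non-increasing in score."""
        frame = psm_frame([10.0, 9.0, 8.0, 7.0, 8.5], [False] * 4 + [True])
        q = compute_qvalues(frame).set_index("spectrum_id")["q_value"]
        assert q["s0"] == 0.0
        assert q["s1"] == 0.0
        assert q["s2"] == pytest.approx(0.25)  # min(1/3 at 8, 1/4 at 7)
        assert q["s3"] == pytest.approx(0.25)

    def test_no_decoys_gives_all_zero(self):
        frame = psm_frame([5.0, 1.0, 3.0], [False] * 3)
        assert (compute_qvalues(frame)["q_value"] == 0.0).all()

    def test_all_decoys_retains_no_targets(self):
        frame = psm_frame([5.0, 1.0], [True, True])
        retained, _ = filter_psms(compute_qvalues(frame), 0.01, 10.0)
        assert len(retained) == 0

    def test_decoys_also_receive_qvalues(self):
        frame = psm_frame([10.0, 8.5], [False, True])
        q = compute_qvalues(frame).set_index("spectrum_id")["q_value"]
        assert q["s1"] == pytest.approx(1.0)

    @pytest.mark.parametrize("case", range(25))
    def test_matches_enumeration_oracle(self, case):
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(1, 51))
        is_decoy = rng.random(n) < 0.3
        # duplicate scores with positive probability to exercise ties
        scores = np.round(rng.normal(2.0, 2.0, n) * 2) / 2
        frame = psm_frame(scores, is_decoy)
        got = compute_qvalues(frame)["q_value"].to_numpy()
        expected = qvalue_oracle(scores, is_decoy)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_q_monotone_in_score(self):
        rng = np.random.default_rng(7)
        frame = psm_frame(rng.normal(size=60), rng.random(60) < 0.4)
        out = compute_qvalues(frame).sort_values("score", ascending=False)
        assert (np.diff(out["q_value"].to_numpy()) >= -1e-12).all()


class TestFilterPsms:
    def test_criteria_attribution_and_conservation(self):
        frame = psm_frame([9.0, 8.0, 7.0, 6.0, 5.0], [False] * 4 + [True])
        frame.loc[0, "rank"] = 2  # removed: rank
        frame.loc[1, "mass_error_ppm"] = 15.0  # removed: mass accuracy
        with_q = compute_qvalues(frame)
        retained, report = filter_psms(with_q, fdr_threshold=0.01, ppm_tolerance=10.0)
        assert report.removed_by["rank"] == 1
        assert report.removed_by["mass_accuracy"] == 1
        assert report.removed_by["decoy"] >= 0
        assert report.n_input == report.n_retained + sum(report.removed_by.values())
        assert not retained["is_decoy"].any()
        assert (retained["rank"] == 1).all()

    def test_psm_within_all_thresholds_is_retained(self):
        frame = psm_frame([9.0], [False])
        frame["mass_error_ppm"] = 2.0
        retained, _ = filter_psms(compute_qvalues(frame), 0.01, 10.0)
        assert len(retained) == 1

    def test_tightening_thresholds_shrinks_retained_set(self):
        """Monotonicity: lower FDR or ppm tolerance ⇒ subset retained."""
        rng = np.random.default_rng(11)
        n = 300
        is_decoy = rng.random(n) < 0.2
        scores = np.where(is_decoy, rng.normal(0, 1, n), rng.normal(3, 1, n))
        frame = psm_frame(scores, is_decoy)
        frame["mass_error_ppm"] = rng.normal(0, 6, n)
        with_q = compute_qvalues(frame)
        loose, _ = filter_psms(with_q, 0.05, 12.0)
        for fdr, ppm in [(0.01, 12.0), (0.05, 5.0), (0.01, 5.0)]:
            tight, _ = filter_psms(with_q, fdr, ppm)
            assert set(tight["spectrum_id"]) <= set(loose["spectrum_id"])

    def test_requires_qvalues(self):
        frame = psm_frame([1.0], [False])
        with pytest.raises(ValueError, match="q-values"):
            filter_psms(frame, 0.01, 10.0)


class TestFilterProteins:
    def test_one_peptide_many_psms_fails(self, make_psm):
        psms = [make_psm(peptide_seq="AYDLEGK") for _ in range(5)]
        assert filter_proteins(psms, min_peptides=2) == set()

    def test_two_peptides_one_psm_each_passes(self, make_psm):
        psms = [make_psm(peptide_seq="AYDLEGK"), make_psm(peptide_seq="GFVTWR")]
        assert filter_proteins(psms, min_peptides=2) == {"P1"}

    def test_empty_input(self):
        assert filter_proteins([], min_peptides=2) == set()

    def test_fractions_merged_before_counting(self, make_psm):
        psms = [
            make_psm(peptide_seq="AYDLEGK", fraction_id="F1"),
            make_psm(peptide_seq="GFVTWR", fraction_id="F2"),
        ]
        assert filter_proteins(psms, min_peptides=2) == {"P1"}

    def test_shared_peptides_count_for_every_mapped_protein(self, make_psm):
        psms = [
            make_psm(peptide_seq="AYDLEGK", protein_ids=["P1", "P2"]),
            make_psm(peptide_seq="GFVTWR", protein_ids=["P1", "P2"]),
        ]
        counts = peptide_counts(psms)
        assert counts["P1"] == 2 and counts["P2"] == 2

    def test_dropped_proteins_recorded_in_report(self, make_psm):
        frame = compute_qvalues(
            pd.concat(
                [
                    pd.DataFrame(
                        [vars(make_psm(peptide_seq="AYDLEGK")) | {"protein_ids": "P1"}]
                    ),
                    pd.DataFrame(
                        [vars(make_psm(peptide_seq="GGHHLLK")) | {"protein_ids": "P3"}]
                    ),
                    pd.DataFrame(
                        [vars(make_psm(peptide_seq="GFVTWR")) | {"protein_ids": "P1"}]
                    ),
                ],
                ignore_index=True,
            )
        )
        retained, report = filter_psms(frame, 0.01, 10.0)
        passing = filter_proteins(retained, 2, report=report)
        assert passing == {"P1"}
        assert report.proteins_dropped_min_peptides == ["P3"]
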