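"""Ratio arithmetic, blood normalisation, the t-test and gDNA-shift calls."""

import math

import numpy as np
import pytest

from poromech.aei import (
    AeiConfig,
    aei_test,
    aei_test_signals,
    gdna_shift_test,
    measurements_to_signalset,
    normalized_ratios,
    raw_ratio,
    splice_fragment_ratio,
)
from poromech.datamodel import CnvCall, Direction
from poromech.simulate import SimulationConfig, gen_allele_signals


class TestRawRatio:
    @pytest.mark.parametrize("mutant, wild, expected", [
        (5000, 5000, 1.0),
        (7500, 2500, 3.0),  # the threefold gDNA-shift scenario
        (0, 5000, 0.0),
    ])
    def test_values(self, mutant, wild, expected):
        assert raw_ratio(mutant, wild) == expected

    def test_zero_wild_is_undefined(self):
        assert math.isnan(raw_ratio(5000, 0))


def _signal_set(lt_gdna=(7500.0, 2500.0), blood=(5000.0, 5000.0)):
    return measurements_to_signalset(
        "F-31", "c.395delT",
        [
            ("blood", "gDNA", 1, *blood),
            ("LT", "gDNA", 1, *lt_gdna),
        ],
    )


class TestNormalizedRatios:
    def test_threefold_shift_against_balanced_blood(self):
        ratios = normalized_ratios(_signal_set())
        assert ratios[("LT", "gDNA", 1)] == pytest.approx(3.0)

    def test_self_normalization(self):
        s = _signal_set(lt_gdna=(5000.0, 5000.0))
        ratios = normalized_ratios(s)
        assert all(r == pytest.approx(1.0) for r in ratios.values())

    def test_assay_bias_cancels(self):
        # identical bias in blood and tissue divides out
        s = _signal_set(lt_gdna=(4000.0, 5000.0), blood=(4000.0, 5000.0))
        ratios = normalized_ratios(s)
        assert ratios[("LT", "gDNA", 1)] == pytest.approx(1.0)

    def test_no_blood_reference_is_error(self):
        s = _signal_set(blood=(5000.0, 0.0))
        with pytest.raises(ValueError, match="blood gDNA"):
            normalized_ratios(s)

    def test_scale_invariance(self):
        cfg = SimulationConfig(seed=3)
        s, _ = gen_allele_signals("epigenetic_silencing_unknown", "missense",
                                  cfg)
        base = normalized_ratios(s)
        for m in s.measurements:
            m.mutant_signal *= 7.5
            m.wild_signal *= 7.5
        scaled = normalized_ratios(s)
        for key in base:
            assert scaled[key] == pytest.approx(base[key])


class TestAeiTest:
    def test_strong_imbalance_matches_hand_computed_t(self):
        # pooled t = 32.924, p = 5.07e-6 by the textbook formula
        res = aei_test([9.5, 10.2, 10.4], [1.00, 1.05, 0.95])
        assert res.p_value == pytest.approx(5.074887969473746e-06, rel=1e-9)
        assert res.significant and res.direction is Direction.wild_reduced

    def test_identical_constant_groups_are_degenerate(self):
        res = aei_test([1.0, 1.0], [1.0, 1.0])
        assert res.p_value == 1.0
        assert not res.significant
        assert "degenerate" in res.flags

    def test_insufficient_replicates_is_no_call(self):
        res = aei_test([1.0], [1.0, 1.1])
        assert res.p_value is None
        assert "insufficient replicates" in res.flags

    def test_welch_option_differs_from_pooled(self):
        lt, nns = [5.1, 5.4, 4.2], [1.0, 1.01, 0.99]
        pooled = aei_test(lt, nns, AeiConfig(test_variant="student_pooled"))
        welch = aei_test(lt, nns, AeiConfig(test_variant="welch"))
        assert pooled.p_value != welch.p_value

    def test_nan_ratios_excluded_and_flagged(self):
        res = aei_test([2.0, 2.1, math.nan], [1.0, 1.1, 0.9])
        assert "undefined_ratios_excluded" in res.flags
        assert len(res.lt_ratios) == 2

    def test_direction_correct_under_wild_suppression(self):
        # every significant call under true wild-allele loss points that way
        cfg = SimulationConfig(seed=5)
        rng = np.random.default_rng(5)
        n_sig = 0
        for _ in range(300):
            s, _ = gen_allele_signals(
                "epigenetic_silencing_unknown", "missense", cfg, rng=rng
            )
            res = aei_test_signals(s, "cDNA")
            if res.significant:
                n_sig += 1
                assert res.direction is Direction.wild_reduced
        assert n_sig >= 285  # power sanity at true ratio 5, cv 0.10


class TestGdnaShift:
    def test_threefold_shift_without_cnv_is_conversion_candidate(self):
        cfg = SimulationConfig(seed=6)
        s, _ = gen_allele_signals("gene_conversion", "frameshift_indel", cfg)
        flag, estimate, res = gdna_shift_test(s)
        assert flag
        assert estimate == pytest.approx(3.0, rel=0.35)

    def test_cnv_loss_routes_away_from_conversion(self):
        cfg = SimulationConfig(seed=7)
        s, _ = gen_allele_signals("cnv_loss", "missense", cfg)
        cnv = CnvCall(
            gene="MVK", sample="SIM-1",
            state_per_probe={"E01": "loss", "E02": "loss"},
            deleted_segments=[object()],  # any non-empty segment list
        )
        flag, _, res = gdna_shift_test(s, cnv=cnv)
        assert res.significant  # the shift is real
        assert not flag  # but explained by the deletion

    def test_balanced_gdna_is_not_a_candidate(self):
        cfg = SimulationConfig(seed=8)
        s, _ = gen_allele_signals("none", "missense", cfg)
        flag, _, _ = gdna_shift_test(s)
        assert not flag


class TestSpliceFragmentRatio:
    def test_equal_areas_give_unity(self):
        out = splice_fragment_ratio([(100.0, 100.0)] * 3, [(50.0, 50.0)] * 2)
        assert out == pytest.approx([1.0, 1.0, 1.0])

    def test_zero_mutant_area_gives_zero_ratio(self):
        out = splice_fragment_ratio([(0.0, 80.0)], [(50.0, 50.0)])
        assert out == [0.0]

    def test_constant_area_scaling_cancels(self):
        peaks = [(120.0, 40.0), (90.0, 30.0)]
        ref = [(60.0, 55.0)]
        base = splice_fragment_ratio(peaks, ref)
        scaled = splice_fragment_ratio(
            [(m * 4, w * 4) for m, w in peaks], [(m * 4, w * 4) for m, w in ref]
        )
        assert scaled == pytest.approx(base)
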