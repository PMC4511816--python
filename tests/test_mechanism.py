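"""Methylation summarisation and the mechanism-classifier decision rules."""

import numpy as np
import pandas as pd
import pytest

from poromech.datamodel import (
    AeiResult,
    CnvCall,
    Direction,
    EditingEvent,
    MechanismLabel,
    Phase,
    TissuePairEvidence,
    VariantType,
)
from poromech.mechanism import (
    classify_mechanism,
    methylation_status,
    recovery_report,
)


def _meth(fractions, coverage):
    return pd.DataFrame({
        "gene": ["MVK"] * len(fractions),
        "cpg_position": range(1, len(fractions) + 1),
        "meth_fraction": fractions,
        "coverage": coverage,
    })


class TestMethylationStatus:
    def test_unmethylated_promoter(self):
        assert methylation_status(_meth([0.0] * 5, [100] * 5)) == "not_detected"

    def test_fully_methylated_promoter(self):
        assert methylation_status(_meth([1.0] * 5, [100] * 5)) == "detected"

    def test_zero_coverage_is_insufficient(self):
        assert methylation_status(_meth([0.5] * 5, [0] * 5)) == "insufficient"

    def test_low_coverage_sites_ignored(self):
        table = _meth([0.9, 0.0], [3, 50])
        assert methylation_status(table) == "not_detected"


def _aei(direction, significant=True, lt=None, nns=None, alpha=0.01):
    return AeiResult(
        patient_id="P", mutation="c.1G>A", molecule="cDNA",
        lt_ratios=lt if lt is not None else [5.0, 5.1, 4.9],
        nns_ratios=nns if nns is not None else [1.0, 1.05, 0.95],
        p_value=0.001 if significant else 0.5,
        significant=significant, direction=direction, alpha=alpha,
    )


def _evidence(**kw):
    defaults = dict(
        patient_id="P", mutation="c.1G>A",
        aei_cdna=_aei(Direction.wild_reduced),
        gdna_shift=False, cnv=None, methylation_detected=False,
        editing_events=[], germline_vtype=VariantType.missense,
    )
    defaults.update(kw)
    return TissuePairEvidence(**defaults)


def _loss_cnv():
    return CnvCall(gene="MVK", sample="P",
                   state_per_probe={"E01": "loss", "E02": "loss"},
                   deleted_segments=[("E01", "E02")])


class TestClassifyMechanism:
    def test_wild_reduced_without_other_evidence_is_epigenetic(self):
        call = classify_mechanism(_evidence())
        assert call.label is MechanismLabel.epigenetic_silencing_unknown

    def test_gdna_shift_is_gene_conversion(self):
        call = classify_mechanism(_evidence(gdna_shift=True))
        assert call.label is MechanismLabel.gene_conversion

    def test_cnv_takes_precedence_over_conversion(self):
        call = classify_mechanism(
            _evidence(gdna_shift=True, cnv=_loss_cnv())
        )
        assert call.label is MechanismLabel.cnv_loss

    def test_editing_without_aei_is_rna_editing(self):
        event = EditingEvent(1003, "G", "A",
                             phase_vs_germline=Phase.cis_with_wild)
        call = classify_mechanism(
            _evidence(
                aei_cdna=_aei(Direction.none, significant=False,
                              lt=[1.0, 1.02, 0.98]),
                editing_events=[event],
            )
        )
        assert call.label is MechanismLabel.rna_editing

    def test_unphased_event_with_wild_aei_does_not_preempt(self):
        event = EditingEvent(1003, "G", "A", phase_vs_germline=Phase.unknown)
        call = classify_mechanism(_evidence(editing_events=[event]))
        assert call.label is MechanismLabel.epigenetic_silencing_unknown

    def test_methylation_guard_blocks_epigenetic_label(self):
        call = classify_mechanism(_evidence(methylation_detected=True))
        assert call.label is MechanismLabel.none
        assert any("methylation" in a for a in call.advisory)

    def test_no_evidence_is_none(self):
        call = classify_mechanism(
            _evidence(aei_cdna=_aei(Direction.none, significant=False,
                                    lt=[1.0, 1.02, 0.98]))
        )
        assert call.label is MechanismLabel.none

    def test_mismatched_patient_is_error(self):
        import dataclasses

        bad = dataclasses.replace(_aei(Direction.none), patient_id="Q")
        with pytest.raises(ValueError, match="different patient"):
            _evidence(aei_cdna=bad)

    def test_precedence_is_total_and_deterministic(self):
        # every combination of evidence flags maps to exactly one label
        import itertools

        event = EditingEvent(1003, "G", "A",
                             phase_vs_germline=Phase.cis_with_wild)
        for cnv, shift, editing, meth, aei_sig in itertools.product(
            [None, _loss_cnv()], [False, True], [False, True],
            [False, True], [False, True],
        ):
            e = _evidence(
                cnv=cnv, gdna_shift=shift,
                editing_events=[event] if editing else [],
                methylation_detected=meth,
                aei_cdna=_aei(
                    Direction.wild_reduced if aei_sig else Direction.none,
                    significant=aei_sig,
                    lt=None if aei_sig else [1.0, 1.02, 0.98],
                ),
            )
            first = classify_mechanism(e)
            second = classify_mechanism(e)
            assert first.label is second.label
            if meth:
                assert first.label is not (
                    MechanismLabel.epigenetic_silencing_unknown
                )

    def test_nmd_side_channel_for_truncating_allele(self):
        aei = _aei(Direction.wild_reduced, lt=[9.8, 10.1, 10.3],
                   nns=[0.31, 0.29, 0.30])
        call = classify_mechanism(
            _evidence(aei_cdna=aei,
                      germline_vtype=VariantType.frameshift_indel)
        )
        assert call.nns_mutant_reduction

    def test_no_nmd_side_channel_for_missense(self):
        aei = _aei(Direction.wild_reduced, nns=[0.31, 0.29, 0.30])
        call = classify_mechanism(
            _evidence(aei_cdna=aei, germline_vtype=VariantType.missense)
        )
        assert not call.nns_mutant_reduction


class TestRecoveryReport:
    def test_perfect_calls_give_identity_matrix(self):
        from poromech.datamodel import MechanismCall

        labels = list(MechanismLabel)
        calls = [MechanismCall(label=m) for m in labels]
        matrix, recall = recovery_report(calls, labels)
        assert (np.diag(matrix.values) == 1).all()
        assert all(r == 1.0 for r in recall.values())

    def test_empty_input_gives_empty_matrix(self):
        matrix, recall = recovery_report([], [])
        assert matrix.values.sum() == 0
        assert all(r is None for r in recall.values())
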