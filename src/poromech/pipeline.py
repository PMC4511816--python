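"""End-to-end evidence assembly: from raw inputs to a mechanism call.

Glue used by the analysis drivers, the CLI and the acceptance checks: runs
the AEI tests, the gDNA-shift (conversion) test, CNV calling, methylation
summarisation and RNA-editing detection for one lesion and bundles the
results for the mechanism classifier.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .aei import AeiConfig, aei_test_signals, gdna_shift_test
from .cnv import CnvThresholds, call_sample_cnv
from .datamodel import (
    AlleleSignalSet,
    CnvCall,
    MechanismCall,
    Phase,
    ProbeTrack,
    TissuePairEvidence,
    VariantType,
)
from .mechanism import classify_mechanism, methylation_status
from .transcript import TissueVariantSets, detect_rna_editing, phase_by_reads


def build_evidence(
    signals: AlleleSignalSet,
    germline_vtype: Optional[VariantType] = None,
    probe_track: Optional[ProbeTrack] = None,
    methylation_table: Optional[pd.DataFrame] = None,
    tissue_sets: Optional[TissueVariantSets] = None,
    phase_groups: Optional[dict] = None,
    aei_cfg: Optional[AeiConfig] = None,
    cnv_thr: Optional[CnvThresholds] = None,
) -> TissuePairEvidence:
    """Run every per-lesion assay computation and bundle the evidence."""
    aei_cfg = aei_cfg or AeiConfig()

    aei_cdna = aei_test_signals(signals, "cDNA", aei_cfg)

    cnv: Optional[CnvCall] = None
    if probe_track is not None:
        cnv = call_sample_cnv(probe_track, signals.patient_id, cnv_thr)

    shift, estimate, aei_gdna = gdna_shift_test(signals, cnv, aei_cfg)

    methylation_detected: Optional[bool] = None
    if methylation_table is not None:
        status = methylation_status(methylation_table)
        methylation_detected = None if status == "insufficient" else (
            status == "detected"
        )

    editing_events = []
    if tissue_sets is not None:
        detection = detect_rna_editing(tissue_sets)
        for event in detection.events:
            phase = Phase.unknown
            if phase_groups is not None:
                phase = phase_by_reads(event, phase_groups)
            editing_events.append(
                type(event)(
                    cdna_pos=event.cdna_pos, ref=event.ref, alt=event.alt,
                    present_in=event.present_in, phase_vs_germline=phase,
                )
            )

    return TissuePairEvidence(
        patient_id=signals.patient_id,
        mutation=signals.mutation,
        aei_cdna=aei_cdna,
        aei_gdna=aei_gdna,
        gdna_shift=shift,
        gdna_shift_estimate=estimate,
        cnv=cnv,
        methylation_detected=methylation_detected,
        editing_events=editing_events,
        germline_vtype=germline_vtype,
    )


def call_mechanism(evidence: TissuePairEvidence) -> MechanismCall:
    return classify_mechanism(evidence)
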