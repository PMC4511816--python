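"""Second-hit mechanism classification per lesion.

Each lesion of this dominant skin disorder is expected to have lost the
function of the remaining wild-type allele.  The classifier integrates the
evidence bundle — cDNA/gDNA allelic-imbalance results, the probe CNV call,
promoter methylation status, and RNA-editing events — into one mechanism
label using a fixed precedence reflecting evidential strength: a physical
copy-number change explains everything downstream of it; a gDNA allelic
shift without CNV is gene conversion; a cDNA-only variant is RNA editing;
remaining cDNA-only wild-allele loss with no methylation is an unknown
methylation-independent epigenetic silencing.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import (
    Direction,
    MechanismCall,
    MechanismLabel,
    Phase,
    TissuePairEvidence,
    TRUNCATING_TYPES,
)


def methylation_status(
    table: pd.DataFrame,
    min_coverage: int = 10,
    fraction_threshold: float = 0.2,
) -> str:
    """Summarise per-CpG bisulfite fractions for one promoter island.

    ``insufficient`` when no site reaches ``min_coverage``; otherwise
    ``detected`` iff the mean methylated fraction over covered sites is at
    least ``fraction_threshold``.
    """
    if not (0.0 <= fraction_threshold <= 1.0):
        raise ValueError("fraction_threshold must lie in [0, 1]")
    covered = table[table["coverage"] >= min_coverage]
    if covered.empty:
        return "insufficient"
    mean_fraction = float(covered["meth_fraction"].mean())
    return "detected" if mean_fraction >= fraction_threshold else "not_detected"


def classify_mechanism(e: TissuePairEvidence) -> MechanismCall:
    """Label one lesion's second-hit mechanism; first matching rule wins.

    1. any CNV loss/gain in the gene in LT -> ``cnv_loss``;
    2. the gDNA-shift (conversion candidate) flag -> ``gene_conversion``;
    3. an editing event phased cis with the wild allele — or of unknown
       phase when there is no cDNA AEI — -> ``rna_editing``;
    4. significant cDNA AEI with the wild allele reduced, no gDNA shift and
       no detected methylation -> ``epigenetic_silencing_unknown``;
    5. otherwise ``none``.

    A methylation-detected lesion never receives the epigenetic-unknown
    label; since the study defines no methylation category, it falls
    through to ``none`` with an advisory.  The independent side channel
    ``nns_mutant_reduction`` records the expected nonsense-mediated-decay
    signature: significant mutant-allele reduction in NNS cDNA for a
    truncating germline allele.
    """
    advisory: list[str] = []
    aei = e.aei_cdna

    nns_mutant_reduction = bool(
        e.germline_vtype in TRUNCATING_TYPES
        and _nns_below_unity(aei.nns_ratios, aei.alpha)
    )

    def call(label: MechanismLabel) -> MechanismCall:
        return MechanismCall(
            label=label,
            nns_mutant_reduction=nns_mutant_reduction,
            advisory=tuple(advisory),
        )

    if e.cnv is not None and e.cnv.has_change:
        return call(MechanismLabel.cnv_loss)
    if e.gdna_shift:
        return call(MechanismLabel.gene_conversion)

    wild_aei = aei.significant and aei.direction == Direction.wild_reduced
    for event in e.editing_events:
        if event.phase_vs_germline == Phase.cis_with_wild:
            return call(MechanismLabel.rna_editing)
        if event.phase_vs_germline == Phase.unknown and not wild_aei:
            return call(MechanismLabel.rna_editing)

    if e.methylation_detected:
        advisory.append("promoter methylation detected; no mechanism category")
        return call(MechanismLabel.none)
    if wild_aei:
        return call(MechanismLabel.epigenetic_silencing_unknown)
    return call(MechanismLabel.none)


def _nns_below_unity(nns_ratios: list[float], alpha: float) -> bool:
    """One-sample check that NNS cDNA mutant/wild ratios sit below 1.

    Normal tissue of a truncating-allele carrier is expected to degrade the
    mutant transcript (nonsense-mediated decay), pushing the normalised
    ratio under the genomic 1:1 expectation.
    """
    a = np.asarray(nns_ratios, dtype=float)
    if a.size < 2:
        return False
    if a.std(ddof=1) == 0:
        return bool(a.mean() < 1.0)
    from scipy import stats

    res = stats.ttest_1samp(a, 1.0)
    return bool(res.pvalue < alpha and a.mean() < 1.0)


def recovery_report(
    calls: list[MechanismCall],
    truth_labels: list[MechanismLabel],
) -> tuple[pd.DataFrame, dict[str, Optional[float]]]:
    """Confusion matrix (truth rows x called columns) and per-class recall."""
    if len(calls) != len(truth_labels):
        raise ValueError("calls and truth labels differ in length")
    labels = [m.value for m in MechanismLabel]
    matrix = pd.DataFrame(
        np.zeros((len(labels), len(labels)), dtype=int),
        index=labels, columns=labels,
    )
    for call, truth in zip(calls, truth_labels):
        matrix.loc[truth.value, call.label.value] += 1
    recall: dict[str, Optional[float]] = {}
    for label in labels:
        total = int(matrix.loc[label].sum())
        recall[label] = (
            float(matrix.loc[label, label] / total) if total else None
        )
    return matrix, recall
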