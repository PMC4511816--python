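"""Allelic-expression-imbalance (AEI) quantification and testing.

For each lesion the assay measures a mutant and a wild allele signal
(primer-extension peak heights, or fluorescent-fragment peak areas for
splice-site alleles) in paired lesional tissue (LT) and neighbouring
normal-appearing skin (NNS), in both gDNA and cDNA.  Raw mutant/wild ratios
are normalised to the patient's blood gDNA — a constitutively heterozygous
1:1 reference — which cancels any constant per-allele assay bias.  LT vs
NNS ratios are then compared by a two-sided Student t-test at the 1% level.

A significant *gDNA* ratio shift in LT without any copy-number change is
the signature of somatic gene conversion of the wild to the mutant allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .datamodel import (
    AeiResult,
    AlleleSignalSet,
    CnvCall,
    Direction,
    SignalMeasurement,
)


@dataclass
class AeiConfig:
    alpha: float = 0.01
    min_replicates: int = 2
    ratio_scale: str = "raw"  # raw | log
    conversion_fold_min: float = 2.0
    test_variant: str = "student_pooled"  # student_pooled | welch

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.conversion_fold_min <= 1.0:
            raise ValueError("conversion_fold_min must be > 1")
        if self.ratio_scale not in ("raw", "log"):
            raise ValueError(f"unknown ratio_scale {self.ratio_scale!r}")
        if self.test_variant not in ("student_pooled", "welch"):
            raise ValueError(f"unknown test_variant {self.test_variant!r}")


def raw_ratio(mutant_signal: float, wild_signal: float) -> float:
    """Mutant/wild signal ratio; undefined (NaN) when the wild signal is 0.

    A vanished wild signal is itself informative (possible conversion or
    homozygosity) but cannot enter ratio-based testing; callers flag it.
    """
    if wild_signal == 0:
        return math.nan
    return mutant_signal / wild_signal


def normalized_ratios(
    s: AlleleSignalSet,
) -> dict[tuple[str, str, int], float]:
    """Blood-gDNA-normalised mutant/wild ratio per (tissue, molecule, rep).

    Each raw ratio is divided by the mean blood gDNA raw ratio, so blood
    gDNA normalised ratios average exactly 1 and constant per-allele assay
    bias cancels.  Measurements with zero wild signal come out as NaN and
    are excluded from testing downstream.
    """
    blood = [
        raw_ratio(m.mutant_signal, m.wild_signal)
        for m in s.stratum("blood", "gDNA")
    ]
    blood = [r for r in blood if not math.isnan(r)]
    if not blood:
        raise ValueError(
            f"{s.patient_id}/{s.mutation}: no usable blood gDNA reference"
        )
    reference = float(np.mean(blood))
    if reference == 0:
        raise ValueError(
            f"{s.patient_id}/{s.mutation}: blood gDNA reference ratio is 0"
        )
    return {
        (m.tissue, m.molecule, m.replicate):
            raw_ratio(m.mutant_signal, m.wild_signal) / reference
        for m in s.measurements
    }


def _finite(values: list[float]) -> list[float]:
    return [v for v in values if not math.isnan(v)]


def aei_test(
    lt_ratios: list[float],
    nns_ratios: list[float],
    cfg: Optional[AeiConfig] = None,
    patient_id: str = "",
    mutation: str = "",
    molecule: str = "cDNA",
) -> AeiResult:
    """Two-sided t-test of LT vs NNS normalised ratios.

    Default is the pooled-variance Student t-test with df = n1 + n2 - 2;
    Welch and log-scale testing are available through the config.  The
    direction of a significant shift: a higher LT ratio means the mutant
    allele is over-represented, i.e. the wild allele is reduced.
    """
    cfg = cfg or AeiConfig()
    lt = _finite(list(lt_ratios))
    nns = _finite(list(nns_ratios))
    flags: list[str] = []
    if len(lt) < len(lt_ratios) or len(nns) < len(nns_ratios):
        flags.append("undefined_ratios_excluded")

    def result(p, significant, direction, extra_flags=()):
        return AeiResult(
            patient_id=patient_id, mutation=mutation, molecule=molecule,
            lt_ratios=lt, nns_ratios=nns, p_value=p,
            significant=significant, direction=direction, alpha=cfg.alpha,
            flags=tuple(flags) + tuple(extra_flags),
        )

    if len(lt) < cfg.min_replicates or len(nns) < cfg.min_replicates:
        return result(None, False, Direction.none, ("insufficient replicates",))

    a = np.asarray(lt, dtype=float)
    b = np.asarray(nns, dtype=float)
    if cfg.ratio_scale == "log":
        if (a <= 0).any() or (b <= 0).any():
            return result(None, False, Direction.none,
                          ("nonpositive ratio on log scale",))
        a, b = np.log(a), np.log(b)

    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return result(1.0, False, Direction.none, ("degenerate",))
        p = 0.0
        flags.append("degenerate")
    else:
        equal_var = cfg.test_variant == "student_pooled"
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)

    significant = p < cfg.alpha
    if not significant:
        direction = Direction.none
    elif float(np.mean(lt)) > float(np.mean(nns)):
        direction = Direction.wild_reduced
    else:
        direction = Direction.mutant_reduced
    return result(p, significant, direction)


def aei_test_signals(
    s: AlleleSignalSet,
    molecule: str,
    cfg: Optional[AeiConfig] = None,
) -> AeiResult:
    """Normalise one signal set and test LT vs NNS for the given molecule."""
    cfg = cfg or AeiConfig()
    ratios = normalized_ratios(s)
    lt = [r for (t, m, _), r in sorted(ratios.items()) if t == "LT" and m == molecule]
    nns = [r for (t, m, _), r in sorted(ratios.items()) if t == "NNS" and m == molecule]
    return aei_test(
        lt, nns, cfg,
        patient_id=s.patient_id, mutation=s.mutation, molecule=molecule,
    )


def gdna_shift_test(
    s: AlleleSignalSet,
    cnv: Optional[CnvCall] = None,
    cfg: Optional[AeiConfig] = None,
) -> tuple[bool, Optional[float], AeiResult]:
    """Gene-conversion candidate detection from gDNA allelic ratios.

    Flags a lesion when the LT gDNA mutant/wild ratio is significantly
    shifted versus NNS, the point estimate reaches ``conversion_fold_min``,
    and no copy-number change in the gene explains the shift.  Returns
    (flag, mean LT gDNA normalised ratio, underlying AEI result).
    """
    cfg = cfg or AeiConfig()
    res = aei_test_signals(s, "gDNA", cfg)
    estimate = float(np.mean(res.lt_ratios)) if res.lt_ratios else None
    flag = (
        res.significant
        and estimate is not None
        and estimate >= cfg.conversion_fold_min
        and (cnv is None or not cnv.has_change)
    )
    return flag, estimate, res


def splice_fragment_ratio(
    fragment_peaks: list[tuple[float, float]],
    blood_reference_peaks: list[tuple[float, float]],
) -> list[float]:
    """Normalised transcript ratios from fluorescent-fragment peak areas.

    For splice-site alleles the two transcripts differ in length, so allele
    quantification uses capillary-electrophoresis peak *areas* instead of
    primer-extension signals; the arithmetic is identical to
    :func:`normalized_ratios` and the output feeds :func:`aei_test`
    unchanged.
    """
    ref_ratios = [raw_ratio(m, w) for m, w in blood_reference_peaks]
    ref_ratios = [r for r in ref_ratios if not math.isnan(r)]
    if not ref_ratios:
        raise ValueError("no usable blood reference peaks")
    reference = float(np.mean(ref_ratios))
    if reference == 0:
        raise ValueError("blood reference ratio is 0")
    return [raw_ratio(m, w) / reference for m, w in fragment_peaks]


def measurements_to_signalset(
    patient_id: str,
    mutation: str,
    rows: list[tuple[str, str, int, float, float]],
    tissue_site: str = "",
) -> AlleleSignalSet:
    """Convenience constructor from (tissue, molecule, rep, mutant, wild)."""
    return AlleleSignalSet(
        patient_id=patient_id,
        mutation=mutation,
        tissue_site=tissue_site,
        measurements=[
            SignalMeasurement(t, m, r, mut, wld) for t, m, r, mut, wld in rows
        ],
    )
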