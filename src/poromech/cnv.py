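"""Probe-based exon CNV calling and deletion-breakpoint analysis.

An MLPA/CNVplex-style assay yields one normalised copy ratio per probe
(diploid expectation 1.0, heterozygous deletion 0.5) over a gene's promoter
and exons.  This module thresholds the ratios into per-probe states,
segments runs of loss probes into deletion calls, bounds each breakpoint by
the neighbouring probe target sites with different copy number, and sizes a
deletion exactly from a junction-spanning read anchored on both flanks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .datamodel import (
    BreakpointInterval,
    CnvCall,
    DeletedSegment,
    ProbeTrack,
)


@dataclass
class CnvThresholds:
    """Copy-ratio bands for per-probe state calls.

    The assay itself publishes no cutoffs; these are midpoints between the
    expected heterozygous-loss (0.5) and diploid (1.0) ratios with a guard
    band — ratios between bands are called indeterminate rather than forced.
    """

    loss_max: float = 0.65
    normal_min: float = 0.80
    normal_max: float = 1.20
    gain_min: float = 1.35
    min_segment_probes: int = 2
    deep_loss_max: float = 0.15  # homozygous-loss annotation only

    def __post_init__(self) -> None:
        if not (self.loss_max < self.normal_min <= self.normal_max
                < self.gain_min):
            raise ValueError("thresholds must satisfy "
                             "loss_max < normal_min <= normal_max < gain_min")
        if self.min_segment_probes < 1:
            raise ValueError("min_segment_probes must be >= 1")


def call_probe_states(
    track: ProbeTrack, sample: str, thr: Optional[CnvThresholds] = None
) -> dict[str, str]:
    """Threshold one sample's copy ratios into per-probe states."""
    thr = thr or CnvThresholds()
    try:
        ratios = track.ratios[sample]
    except KeyError:
        raise KeyError(f"sample {sample!r} not in track") from None
    states = {}
    for probe in track.probes:
        r = ratios[probe.probe_id]
        if r < 0:
            raise ValueError(f"negative ratio for probe {probe.probe_id}")
        if r <= thr.loss_max:
            states[probe.probe_id] = "loss"
        elif thr.normal_min <= r <= thr.normal_max:
            states[probe.probe_id] = "normal"
        elif r >= thr.gain_min:
            states[probe.probe_id] = "gain"
        else:
            states[probe.probe_id] = "indeterminate"
    return states


def segment_deletions(
    states: list[tuple[str, str]], thr: Optional[CnvThresholds] = None
) -> list[tuple[str, str]]:
    """Collapse per-probe states into deleted segments.

    ``states`` is ordered by genomic position as ``(probe_id, state)``.
    A segment is a maximal run of loss probes containing at least
    ``min_segment_probes`` losses; interior indeterminate probes neither
    break the run nor count toward its length.  Returns ``(first_loss_probe,
    last_loss_probe)`` per segment.
    """
    thr = thr or CnvThresholds()
    segments: list[tuple[str, str]] = []
    run: list[str] = []  # loss probes of the current run

    def close_run() -> None:
        nonlocal run
        if len(run) >= thr.min_segment_probes:
            segments.append((run[0], run[-1]))
        run = []

    for probe_id, state in states:
        if state == "loss":
            run.append(probe_id)
        elif state == "indeterminate":
            continue
        else:
            close_run()
    close_run()
    return segments


def breakpoint_interval(
    segment: tuple[str, str],
    track: ProbeTrack,
    states: Optional[dict[str, str]] = None,
) -> tuple[BreakpointInterval, BreakpointInterval]:
    """Bound the two breakpoints of one deleted segment.

    The true breakpoints lie between neighbouring probe target sites with
    different copy number: left in ``(last normal position, first deleted
    position]``, right in ``[last deleted position, first normal position)``.
    A segment touching the track end yields an unbounded side.  When
    ``states`` is given, indeterminate probes are skipped when looking for
    the flanking normal probe (they carry no copy-number information).
    """
    first_id, last_id = segment
    i = track.probe_index(first_id)
    j = track.probe_index(last_id)
    if j < i:
        raise ValueError("segment probes out of order")

    left_bound = None
    for k in range(i - 1, -1, -1):
        pid = track.probes[k].probe_id
        if states is None or states.get(pid) == "normal":
            left_bound = track.probes[k].position
            break
    right_bound = None
    for k in range(j + 1, len(track.probes)):
        pid = track.probes[k].probe_id
        if states is None or states.get(pid) == "normal":
            right_bound = track.probes[k].position
            break

    left = BreakpointInterval(left=left_bound, right=track.probes[i].position)
    right = BreakpointInterval(left=track.probes[j].position, right=right_bound)
    return left, right


def call_sample_cnv(
    track: ProbeTrack, sample: str, thr: Optional[CnvThresholds] = None
) -> CnvCall:
    """Full per-sample CNV call: states, segments and breakpoint intervals."""
    thr = thr or CnvThresholds()
    states = call_probe_states(track, sample, thr)
    ordered = [(p.probe_id, states[p.probe_id]) for p in track.probes]
    segments = []
    for first_id, last_id in segment_deletions(ordered, thr):
        left, right = breakpoint_interval((first_id, last_id), track, states)
        i, j = track.probe_index(first_id), track.probe_index(last_id)
        deep = all(
            track.ratios[sample][p.probe_id] <= thr.deep_loss_max
            for p in track.probes[i:j + 1]
            if states[p.probe_id] == "loss"
        )
        segments.append(
            DeletedSegment(
                first_probe=first_id, last_probe=last_id,
                left_interval=left, right_interval=right, deep=deep,
            )
        )
    return CnvCall(
        gene=track.gene, sample=sample,
        state_per_probe=states, deleted_segments=segments,
    )


# ---------------------------------------------------------------------------
# junction-read deletion sizing

@dataclass
class JunctionCall:
    """Outcome of sizing a deletion from a junction-spanning read.

    Coordinates are 0-based half-open on the reference: ``left_end`` is one
    past the last reference base retained on the left flank, ``right_start``
    the first base retained on the right.  ``size = right_start - left_end``.
    """

    status: str  # "deletion" | "no_deletion" | "no_call"
    size: Optional[int] = None
    left_end: Optional[int] = None
    right_start: Optional[int] = None
    message: str = ""


def _unique_match(reference: str, seed: str) -> Optional[int]:
    first = reference.find(seed)
    if first == -1:
        return None
    if reference.find(seed, first + 1) != -1:
        return None
    return first


def junction_size(
    reference: str, junction_read: str, seed_length: int = 20
) -> JunctionCall:
    """Size a deletion by anchoring both flanks of a junction read.

    The read's first and last ``seed_length`` bases must each map uniquely
    and exactly to the reference; each anchor is then extended inward as far
    as it matches.  Microhomology at the junction is assigned to the left
    flank (left-aligned breakpoints).  A read whose flanks reconstruct a
    contiguous reference window reports ``no_deletion``.
    """
    if seed_length < 1:
        raise ValueError("seed_length must be >= 1")
    if len(junction_read) < 2 * seed_length:
        return JunctionCall("no_call",
                            message="read shorter than two seeds")

    left_seed = junction_read[:seed_length]
    right_seed = junction_read[-seed_length:]
    a = _unique_match(reference, left_seed)
    if a is None:
        return JunctionCall("no_call",
                            message="left flank seed ambiguous or unmapped")
    b = _unique_match(reference, right_seed)
    if b is None:
        return JunctionCall("no_call",
                            message="right flank seed ambiguous or unmapped")

    # extend the left anchor rightward through the read
    prefix_len = 0
    while (prefix_len < len(junction_read)
           and a + prefix_len < len(reference)
           and junction_read[prefix_len] == reference[a + prefix_len]):
        prefix_len += 1
    # extend the right anchor leftward
    b_end = b + seed_length  # one past the right seed's reference match
    suffix_len = 0
    while (suffix_len < len(junction_read)
           and b_end - suffix_len - 1 >= 0
           and junction_read[len(junction_read) - suffix_len - 1]
           == reference[b_end - suffix_len - 1]):
        suffix_len += 1

    microhomology = prefix_len + suffix_len - len(junction_read)
    if microhomology < 0:
        return JunctionCall("no_call",
                            message="flanks leave unmatched read bases")

    left_end = a + prefix_len
    right_start = b_end - suffix_len + microhomology  # overlap goes left
    size = right_start - left_end
    if size < 0:
        return JunctionCall("no_call",
                            message="flanks map in inconsistent order")
    if size == 0:
        return JunctionCall("no_deletion", size=0,
                            left_end=left_end, right_start=right_start)
    return JunctionCall("deletion", size=size,
                        left_end=left_end, right_start=right_start)
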