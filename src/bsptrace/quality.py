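"""Bisulfite conversion-rate QC of aligned reads.

Cytosines of the amplified strand that are *outside* CpG context are
deaminated by the bisulfite reaction regardless of methylation, so after
PCR they must read as T (forward) or A (reverse).  Residual C (forward) /
G (reverse) signal at these conversion-control positions measures
incomplete conversion.  Per control position the conversion rate is

* forward read:  ``peakT / (peakC + peakT)``
* reverse read:  ``peakA / (peakG + peakA)``

and the unweighted mean over usable control positions is the read's
conversion rate.  A read passes QC when aligned length, identity and mean
conversion rate all reach their thresholds (defaults 30 bp, 75%, 0.9).
Control positions falling in alignment gaps, or with zero denominator,
carry no evidence and are skipped (recorded, not scored).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import AlignedRead
from .reference import ReferenceRegion, TemplatePair
from .trace_io import ChromatogramTrace
from .trimming import TrimmedRead

#: peak-height column indices in the fixed A, C, G, T order
_COL = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class QCParams:
    """Validation gates for an aligned sequencing read."""

    min_length: int = 30
    min_identity: float = 75.0
    min_conversion: float = 0.9


@dataclass
class ReadQC:
    """QC verdict and metrics for one aligned read."""

    aligned_length: int
    identity_pct: float
    mismatch_positions: list[int]
    indel_positions: list[tuple[str, int, int]]
    mean_conversion_rate: float | None
    per_site_conversion: list[tuple[int, float]]  # (genomic coordinate, rate)
    skipped_sites: list[int]                      # genomic coordinates
    passed: bool
    failed_gates: list[str]


def conversion_rate_at(trace: ChromatogramTrace, trace_pos: int,
                       direction: str) -> float | None:
    """Conversion rate from the peak heights at one called base.

    *trace_pos* is 1-based over the full trace.  Returns ``None`` when the
    relevant denominator is zero (site must be skipped, not scored).
    """
    h = trace.peak_heights[trace_pos - 1]
    if direction == "forward":
        num, den = h[_COL["T"]], h[_COL["C"]] + h[_COL["T"]]
    else:
        num, den = h[_COL["A"]], h[_COL["G"]] + h[_COL["A"]]
    if den <= 0:
        return None
    return float(num / den)


def control_positions_on_template(templates: TemplatePair,
                                  template_used: str) -> list[int]:
    """Conversion-control positions in the frame of the used template."""
    if template_used == "sense":
        return sorted(templates.non_cpg_c_positions_sense)
    return sorted(templates.mirror(p)
                  for p in templates.non_cpg_c_positions_sense)


def assess_read(aligned: AlignedRead, read: TrimmedRead,
                templates: TemplatePair, ref: ReferenceRegion,
                params: QCParams | None = None) -> ReadQC:
    """Full QC of one aligned read.

    Maps every conversion-control position of the template through the
    gap-corrected position map, computes per-site conversion rates from the
    trace peak heights, averages them, and applies the three gates.
    """
    params = params or QCParams()
    rates: list[tuple[int, float]] = []
    skipped: list[int] = []
    L = len(templates)
    for tpos in control_positions_on_template(templates, aligned.template_used):
        sense_pos = tpos if aligned.template_used == "sense" else templates.mirror(tpos)
        coord = ref.sense_position_to_coordinate(sense_pos)
        read_pos = aligned.position_map.get(tpos)
        if read_pos is None:
            if tpos in aligned.position_map:
                skipped.append(coord)  # inside a read gap
            continue
        rate = conversion_rate_at(read.trace, read.to_trace_position(read_pos),
                                  aligned.direction)
        if rate is None:
            skipped.append(coord)
        else:
            rates.append((coord, rate))

    mean_rate = float(np.mean([r for _, r in rates])) if rates else None

    failed = []
    if aligned.aligned_length < params.min_length:
        failed.append("min-length")
    if aligned.identity_pct < params.min_identity:
        failed.append("min-identity")
    if mean_rate is None:
        failed.append("no-conversion-sites")
    elif mean_rate < params.min_conversion:
        failed.append("min-conversion")

    return ReadQC(
        aligned_length=aligned.aligned_length,
        identity_pct=aligned.identity_pct,
        mismatch_positions=list(aligned.mismatch_positions),
        indel_positions=list(aligned.gap_events),
        mean_conversion_rate=mean_rate,
        per_site_conversion=rates,
        skipped_sites=skipped,
        passed=not failed,
        failed_gates=failed,
    )
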