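"""Local alignment of trimmed reads to the converted templates.

Reads are aligned with Smith-Waterman local alignment (affine gap
penalties) against the bisulfite-converted sense and antisense templates.
Because cloning vectors accept inserts in either orientation, the read
direction is not trusted from the file: the read is aligned to both
templates and the longer alignment wins (forward <=> sense).

The essential product is the gap-corrected ``position_map`` from template
positions to read positions.  For an ungapped alignment starting at
template position ``s_start`` and read position ``p_start`` it reduces to
the closed form ``read_pos = template_pos - s_start + p_start``; indels
shift the mapping and template positions falling in read gaps map to
``None``.

Identity is computed over aligned (non-gap) columns.  Columns at CpG
positions are excluded from the identity calculation: at a CpG the read
legitimately carries either C or T (forward; G or A reverse) depending on
methylation, and counting those columns would let the methylation level
itself degrade the alignment QC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio import Align

from .errors import NoAlignmentError
from .reference import ReferenceRegion, TemplatePair
from .trimming import TrimmedRead


@dataclass
class AlignParams:
    """Smith-Waterman scoring and alignment validity gates."""

    match_score: float = 2.0
    mismatch_score: float = -1.0
    open_gap_score: float = -5.0
    extend_gap_score: float = -2.0
    min_length: int = 30        # minimum aligned length (bp)
    min_identity: float = 75.0  # percent


@dataclass
class AlignedRead:
    """A trimmed read locally aligned to one template."""

    direction: str              # "forward" | "reverse"
    template_used: str          # "sense" | "antisense"
    s_start: int                # first aligned template position (1-based)
    s_end: int                  # last aligned template position
    p_start: int                # first aligned read position (1-based)
    p_end: int
    score: float
    aligned_length: int         # template span of the alignment
    identity_pct: float
    mismatch_positions: list[int]
    gap_events: list[tuple[str, int, int]]  # (frame, template position, length)
    position_map: dict[int, int | None]
    valid: bool = False
    failure_reason: str = ""

    def map_position(self, template_pos: int) -> int | None:
        """Read position aligned to *template_pos*, or ``None``."""
        return self.position_map.get(template_pos)


@dataclass(frozen=True)
class CoveredRegion:
    """Genomic span covered by at least one validated read."""

    alg_coord_start: int
    alg_coord_end: int
    uncovered_gaps: tuple[tuple[int, int], ...] = ()

    def covers(self, coordinate: int) -> bool:
        if not (self.alg_coord_start <= coordinate <= self.alg_coord_end):
            return False
        return not any(a <= coordinate <= b for a, b in self.uncovered_gaps)


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.open_gap_score
    aligner.extend_gap_score = params.extend_gap_score
    return aligner


def align_to_template(read: TrimmedRead, template: str,
                      params: AlignParams | None = None,
                      exclude_positions: Iterable[int] = (),
                      direction: str = "forward",
                      template_used: str = "sense") -> AlignedRead:
    """Smith-Waterman alignment of a trimmed read against one template.

    *exclude_positions* are template positions (1-based) whose columns are
    left out of the identity computation (the CpG columns).  Validity
    requires aligned length >= ``min_length`` and identity >=
    ``min_identity`` percent.
    """
    params = params or AlignParams()
    excluded = frozenset(exclude_positions)
    seq = read.sequence
    if not seq:
        raise NoAlignmentError("empty read sequence")
    aligner = _aligner(params)
    try:
        alignments = aligner.align(template, seq)
        alignment = alignments[0] if len(alignments) else None
    except (ValueError, IndexError):
        alignment = None
    if alignment is None or alignment.score <= 0:
        raise NoAlignmentError("no local alignment between read and template")

    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        raise NoAlignmentError("empty alignment")

    position_map: dict[int, int | None] = {}
    mismatches: list[int] = []
    gap_events: list[tuple[str, int, int]] = []
    matches = 0
    columns = 0
    prev_t_end = prev_q_end = None
    for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
        if prev_t_end is not None:
            if t0 > prev_t_end:  # deletion in read: template positions unaligned
                gap_events.append(("read", prev_t_end + 1, t0 - prev_t_end))
                for t in range(prev_t_end, t0):
                    position_map[t + 1] = None
            if q0 > prev_q_end:  # insertion in read relative to template
                gap_events.append(("template", prev_t_end, q0 - prev_q_end))
        for k in range(t1 - t0):
            tpos = t0 + k + 1
            qpos = q0 + k + 1
            position_map[tpos] = qpos
            if tpos in excluded:
                continue
            columns += 1
            tb = template[tpos - 1]
            qb = seq[qpos - 1]
            if tb == qb and tb != "N":
                matches += 1
            else:
                mismatches.append(tpos)
        prev_t_end, prev_q_end = t1, q1

    s_start = int(t_blocks[0][0]) + 1
    s_end = int(t_blocks[-1][1])
    p_start = int(q_blocks[0][0]) + 1
    p_end = int(q_blocks[-1][1])
    aligned_length = s_end - s_start + 1
    identity = 100.0 * matches / columns if columns else 0.0

    aligned = AlignedRead(
        direction=direction,
        template_used=template_used,
        s_start=s_start,
        s_end=s_end,
        p_start=p_start,
        p_end=p_end,
        score=float(alignment.score),
        aligned_length=aligned_length,
        identity_pct=identity,
        mismatch_positions=mismatches,
        gap_events=gap_events,
        position_map=position_map,
    )
    failures = []
    if aligned_length < params.min_length:
        failures.append(
            f"aligned length {aligned_length} < min length {params.min_length}")
    if identity < params.min_identity:
        failures.append(
            f"identity {identity:.1f}% < {params.min_identity}%")
    if failures:
        aligned.failure_reason = "; ".join(failures)
    else:
        aligned.valid = True
    return aligned


def detect_direction(read: TrimmedRead, templates: TemplatePair,
                     params: AlignParams | None = None) -> AlignedRead:
    """Align the read to both templates and keep the better pairing.

    The pairing with the longer aligned length wins; ties go to the higher
    score, then to sense.  Forward direction corresponds to the sense
    template.  Raises :class:`NoAlignmentError` when neither template
    produces an alignment of at least the minimum usable length.
    """
    params = params or AlignParams()
    anti_excluded = {templates.mirror(p) for p in templates.cpg_positions_sense}
    candidates = []
    for template, name, direction, excluded in (
        (templates.sense, "sense", "forward", templates.cpg_positions_sense),
        (templates.antisense, "antisense", "reverse", anti_excluded),
    ):
        try:
            candidates.append(align_to_template(
                read, template, params, excluded, direction, name))
        except NoAlignmentError:
            continue
    if not candidates:
        raise NoAlignmentError("read aligns to neither template")
    candidates.sort(
        key=lambda a: (a.aligned_length, a.score, a.template_used == "sense"),
        reverse=True,
    )
    best = candidates[0]
    if not best.valid:
        # spurious short/low-identity local hits arise even for unrelated
        # sequences; a best pairing that fails the validity gates means the
        # read matches neither template
        raise NoAlignmentError(
            f"read matches neither template ({best.failure_reason})")
    return best


def _genomic_span(aligned: AlignedRead, ref: ReferenceRegion) -> tuple[int, int]:
    """Genomic (plus-strand) span covered by one aligned read."""
    L = len(ref)
    if aligned.template_used == "sense":
        sense_span = (aligned.s_start, aligned.s_end)
    else:  # mirror antisense span into the sense frame
        sense_span = (L - aligned.s_end + 1, L - aligned.s_start + 1)
    coords = (ref.sense_position_to_coordinate(sense_span[0]),
              ref.sense_position_to_coordinate(sense_span[1]))
    return (min(coords), max(coords))


def covered_region(fwd: AlignedRead | None, rev: AlignedRead | None,
                   ref: ReferenceRegion) -> CoveredRegion:
    """Union of the genomic spans covered by the valid aligned reads.

    Internal coordinates covered by neither read are recorded as
    uncovered gaps.
    """
    spans = [_genomic_span(a, ref) for a in (fwd, rev)
             if a is not None and a.valid]
    if not spans:
        raise NoAlignmentError("no valid aligned read to compute coverage from")
    spans.sort()
    start = spans[0][0]
    end = max(s[1] for s in spans)
    gaps = []
    reach = spans[0][1]
    for a, b in spans[1:]:
        if a > reach + 1:
            gaps.append((reach + 1, a - 1))
        reach = max(reach, b)
    return CoveredRegion(start, end, tuple(gaps))
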