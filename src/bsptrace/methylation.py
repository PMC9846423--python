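"""Per-CpG methylation quantification for one sample.

At a CpG the sequenced population is a mixture of methylated molecules
(reading C on the forward strand, G on the reverse) and unmethylated,
bisulfite-converted molecules (reading T forward, A reverse).  The dye
signal is assumed proportional to the molecule fraction, so

* forward read:  ``methylation % = peakC / (peakC + peakT) * 100``
* reverse read:  ``methylation % = peakG / (peakG + peakA) * 100``

No normalization is applied to the peak heights.  When both sequencing
directions cover a CpG, the two percentages are combined into a mean and a
(two-value, n-1 denominator) standard deviation.

:func:`analyze_sample` runs the whole individual pipeline — trace parsing,
trimming, direction detection + alignment, conversion-rate QC and per-CpG
quantification — and emits the per-sample methylation table consumed by
the grouped analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import trace_io
from .alignment import AlignedRead, AlignParams, CoveredRegion, covered_region, detect_direction
from .errors import BsptraceError, NoAlignmentError
from .quality import QCParams, ReadQC, assess_read
from .reference import ReferenceRegion, bisulfite_convert, find_cpg_sites
from .trimming import TrimParams, TrimmedRead, final_trim

logger = logging.getLogger("bsptrace")

_COL = {"A": 0, "C": 1, "G": 2, "T": 3}

#: frozen schema of the per-sample methylation CSV
CSV_COLUMNS = [
    "sequence_name", "collection", "group", "replicate_or_clone",
    "experiment_type", "cpg_index", "c_coordinate",
    "meth_fwd", "meth_rev", "meth_mean", "meth_sd", "n_reads",
    "qc_pass_fwd", "qc_pass_rev", "conversion_rate_fwd", "conversion_rate_rev",
]


@dataclass(frozen=True)
class SampleKey:
    """Identity of one sequencing sample (PCR product or clone)."""

    sequence_name: str
    collection: str
    group: str
    replicate_or_clone: str
    experiment_type: str  # "direct" | "cloning"

    def __post_init__(self):
        for name in ("sequence_name", "collection", "group", "replicate_or_clone"):
            if not getattr(self, name):
                raise ValueError(f"sample key field {name!r} must be non-empty")
        if self.experiment_type not in ("direct", "cloning"):
            raise ValueError("experiment_type must be 'direct' or 'cloning'")

    @property
    def sample_id(self) -> str:
        return f"{self.collection}_{self.group}_{self.replicate_or_clone}"


@dataclass
class MethylationRecord:
    """Methylation measurements of one CpG site in one sample."""

    cpg_index: int
    c_coordinate: int
    meth_fwd: float | None
    meth_rev: float | None
    meth_mean: float | None
    meth_sd: float | None
    n_reads: int


@dataclass
class MethylationTable:
    """Full individual-analysis result for one sample."""

    key: SampleKey
    covered: CoveredRegion | None
    records: list[MethylationRecord]
    qc_fwd: ReadQC | None = None
    qc_rev: ReadQC | None = None
    trim_fwd: TrimmedRead | None = None
    trim_rev: TrimmedRead | None = None
    failure_notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "sequence_name": self.key.sequence_name,
                "collection": self.key.collection,
                "group": self.key.group,
                "replicate_or_clone": self.key.replicate_or_clone,
                "experiment_type": self.key.experiment_type,
                "cpg_index": r.cpg_index,
                "c_coordinate": r.c_coordinate,
                "meth_fwd": _round2(r.meth_fwd),
                "meth_rev": _round2(r.meth_rev),
                "meth_mean": _round2(r.meth_mean),
                "meth_sd": _round2(r.meth_sd),
                "n_reads": r.n_reads,
                "qc_pass_fwd": self.qc_fwd.passed if self.qc_fwd else False,
                "qc_pass_rev": self.qc_rev.passed if self.qc_rev else False,
                "conversion_rate_fwd": _round4(
                    self.qc_fwd.mean_conversion_rate if self.qc_fwd else None),
                "conversion_rate_rev": _round4(
                    self.qc_rev.mean_conversion_rate if self.qc_rev else None),
            })
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def write_csv(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / f"{self.key.sample_id}.csv"
        self.to_frame().to_csv(path, index=False)
        return path


def _round2(v):
    return None if v is None else round(float(v), 2)


def _round4(v):
    return None if v is None else round(float(v), 4)


def methylation_pct(heights, direction: str) -> float | None:
    """Methylation percentage from the four peak heights at one base.

    Forward reads use C/(C+T), reverse reads G/(G+A), times 100.  Returns
    ``None`` on a zero denominator (the site cannot be quantified).
    """
    h = np.asarray(heights, dtype=float)
    if direction == "forward":
        num, den = h[_COL["C"]], h[_COL["C"]] + h[_COL["T"]]
    else:
        num, den = h[_COL["G"]], h[_COL["G"]] + h[_COL["A"]]
    if den <= 0:
        return None
    return float(num / den * 100.0)


def combine_directions(meth_fwd: float | None, meth_rev: float | None
                       ) -> tuple[float | None, float | None, int]:
    """Combine forward/reverse percentages into (mean, sd, n_reads).

    The standard deviation uses the sample (n-1) denominator and is
    defined only when both directions are present.
    """
    values = [v for v in (meth_fwd, meth_rev) if v is not None]
    if not values:
        return None, None, 0
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) == 2 else None
    return mean, sd, len(values)


def process_read(path, ref: ReferenceRegion, templates,
                 trim_params: TrimParams, align_params: AlignParams,
                 qc_params: QCParams):
    """Run one trace file through trimming, alignment and QC.

    Returns ``(trimmed, aligned, qc, note)``; *aligned*/*qc* are ``None``
    when an earlier stage failed, with the reason in *note*.
    """
    trace = trace_io.read_abif(path)
    trimmed = final_trim(trace, trim_params)
    if not trimmed.valid:
        return trimmed, None, None, f"{Path(str(path)).name}: {trimmed.failure_reason}"
    try:
        aligned = detect_direction(trimmed, templates, align_params)
    except NoAlignmentError as exc:
        return trimmed, None, None, f"{Path(str(path)).name}: {exc}"
    qc = assess_read(aligned, trimmed, templates, ref, qc_params)
    note = ""
    if not qc.passed:
        note = (f"{Path(str(path)).name}: failed QC gates "
                f"{', '.join(qc.failed_gates)}")
    return trimmed, aligned, qc, note


def analyze_sample(key: SampleKey, ref: ReferenceRegion, trace_paths,
                   trim_params: TrimParams | None = None,
                   align_params: AlignParams | None = None,
                   qc_params: QCParams | None = None,
                   outdir=None) -> MethylationTable:
    """Individual analysis of one sample from 1-2 unlabeled trace files.

    The direction of each file is auto-detected.  Reads failing trimming,
    alignment or QC contribute no methylation percentages (their failure
    is recorded in the table, not raised).  CpG sites outside the covered
    region yield records with ``None`` values.  When *outdir* is given the
    per-sample CSV and genomic plot are written there.
    """
    trim_params = trim_params or TrimParams()
    align_params = align_params or AlignParams()
    qc_params = qc_params or QCParams()
    if not 1 <= len(trace_paths) <= 2:
        raise BsptraceError("a sample takes one or two trace files")

    templates = bisulfite_convert(ref)
    sites = find_cpg_sites(ref)

    slots: dict[str, tuple[TrimmedRead, AlignedRead, ReadQC]] = {}
    trims: dict[str, TrimmedRead] = {}
    notes: list[str] = []
    for path in trace_paths:
        trimmed, aligned, qc, note = process_read(
            path, ref, templates, trim_params, align_params, qc_params)
        if note:
            notes.append(note)
        if aligned is None:
            continue
        direction = aligned.direction
        if direction in slots:
            logger.warning(
                "sample %s: two %s reads detected; ignoring %s",
                key.sample_id, direction, path)
            notes.append(f"{Path(str(path)).name}: extra {direction} read ignored")
            continue
        slots[direction] = (trimmed, aligned, qc)
        trims[direction] = trimmed

    usable = {d: v for d, v in slots.items() if v[2].passed and v[1].valid}
    fwd = usable.get("forward")
    rev = usable.get("reverse")

    covered = None
    if fwd or rev:
        covered = covered_region(fwd[1] if fwd else None,
                                 rev[1] if rev else None, ref)

    records = []
    for site in sites:
        p_sense = ref.cpg_sense_position(site)
        meth_fwd = meth_rev = None
        if fwd is not None:
            read_pos = fwd[1].position_map.get(p_sense)
            if read_pos is not None:
                meth_fwd = methylation_pct(
                    fwd[0].trace.peak_heights[fwd[0].to_trace_position(read_pos) - 1],
                    "forward")
        if rev is not None:
            p_anti = templates.mirror(p_sense)
            read_pos = rev[1].position_map.get(p_anti)
            if read_pos is not None:
                meth_rev = methylation_pct(
                    rev[0].trace.peak_heights[rev[0].to_trace_position(read_pos) - 1],
                    "reverse")
        mean, sd, n = combine_directions(meth_fwd, meth_rev)
        records.append(MethylationRecord(
            cpg_index=site.index,
            c_coordinate=site.c_coordinate,
            meth_fwd=meth_fwd,
            meth_rev=meth_rev,
            meth_mean=mean,
            meth_sd=sd,
            n_reads=n,
        ))

    table = MethylationTable(
        key=key,
        covered=covered,
        records=records,
        qc_fwd=slots["forward"][2] if "forward" in slots else None,
        qc_rev=slots["reverse"][2] if "reverse" in slots else None,
        trim_fwd=trims.get("forward"),
        trim_rev=trims.get("reverse"),
        failure_notes=notes,
    )
    if outdir is not None:
        table.write_csv(outdir)
        plot_genomic(table, ref, Path(outdir) / f"{key.sample_id}_genomic.png")
    return table


def plot_genomic(table: MethylationTable, ref: ReferenceRegion, path) -> Path:
    """Per-sample genomic plot: sequence track, CpG ticks, grey-scale levels.

    Serves as a visual control that CpG coordinates land on CG dinucleotides
    of the reference.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 2.2))
    ax.hlines(0, ref.seq_start, ref.seq_end, color="0.4", lw=2, zorder=1)
    for rec in table.records:
        ax.vlines(rec.c_coordinate, -0.15, 0.15, color="0.6", lw=1, zorder=2)
        if rec.meth_mean is None:
            ax.scatter([rec.c_coordinate], [0.45], marker="x", color="0.5", s=40)
        else:
            ax.scatter([rec.c_coordinate], [0.45], s=90, zorder=3,
                       c=[rec.meth_mean], cmap="Greys", vmin=0, vmax=100,
                       edgecolors="black", linewidths=0.8)
    if table.covered is not None:
        ax.hlines(-0.45, table.covered.alg_coord_start,
                  table.covered.alg_coord_end, color="tab:blue", lw=3)
        ax.text(table.covered.alg_coord_start, -0.7, "covered", fontsize=7,
                color="tab:blue")
    ax.set_ylim(-1, 1)
    ax.set_yticks([])
    ax.set_xlabel("genomic coordinate")
    ax.set_title(f"{table.key.sequence_name} — {table.key.sample_id}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)
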