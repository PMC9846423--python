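"""Reference region handling: CpG sites and in-silico bisulfite PCR.

The reference is a short genomic region (the PCR amplicon neighbourhood)
with 1-based, fully-closed genomic coordinates: the first base of the
sequence has coordinate ``seq_start`` and the last ``seq_end``, so a
reference position ``p`` maps to coordinate ``seq_start + p - 1``.

Because bisulfite treatment destroys strand complementarity, only one
strand is amplified by the PCR (``amplified_strand``).  The *in-silico*
counterpart of the wet-lab workflow converts that strand (every cytosine
outside CpG context becomes thymine; CpG cytosines are kept, as they may be
methylated) and then "PCR-amplifies" it, yielding the two sequencing
templates:

* ``sense``     — converted amplified strand, template of the forward read;
* ``antisense`` — its reverse complement, template of the reverse read.

Cytosines of the amplified strand that are *not* in CpG context are fully
converted regardless of methylation; they become the conversion-control
positions used by the QC stage to estimate bisulfite conversion efficiency.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import ReferenceFormatError

_HEADER_RE = re.compile(
    r"^(?P<name>\S+)\s+\S*?(?P<start>\d+)-(?P<end>\d+)\s+(?P<strand>plus|minus|[+-])\s*$"
)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class ReferenceRegion:
    """A genomic reference region with coordinates and amplified strand."""

    name: str
    sequence: str
    seq_start: int
    seq_end: int
    amplified_strand: str  # "plus" | "minus"

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if self.amplified_strand not in ("plus", "minus"):
            raise ReferenceFormatError(
                f"amplified_strand must be 'plus' or 'minus', got {self.amplified_strand!r}"
            )
        if set(seq) - set("ACGTN"):
            raise ReferenceFormatError(
                f"reference contains illegal characters: {sorted(set(seq) - set('ACGTN'))}"
            )
        if self.seq_end - self.seq_start + 1 != len(seq):
            raise ReferenceFormatError(
                f"coordinate span {self.seq_start}-{self.seq_end} "
                f"({self.seq_end - self.seq_start + 1} bp) does not match "
                f"sequence length {len(seq)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def amplified_sequence(self) -> str:
        """The strand actually amplified by the PCR, 5'→3'."""
        if self.amplified_strand == "plus":
            return self.sequence
        return reverse_complement(self.sequence)

    def position_to_coordinate(self, p: int) -> int:
        """Genomic coordinate of reference (plus-frame) position ``p``."""
        return self.seq_start + p - 1

    def sense_position_to_coordinate(self, p: int) -> int:
        """Genomic coordinate of position ``p`` of the sense template frame.

        The sense frame equals the plus frame when the plus strand was
        amplified, and is mirrored otherwise; coordinates are always
        reported on the plus strand.
        """
        if self.amplified_strand == "plus":
            return self.seq_start + p - 1
        return self.seq_end - p + 1

    def cpg_sense_position(self, site: "CpGSite") -> int:
        """Sense-frame position of the cytosine measured for *site*.

        For a minus-strand amplicon the measured cytosine is the complement
        of the plus-strand guanine, i.e. the mirror of ``c_position + 1``.
        """
        if self.amplified_strand == "plus":
            return site.c_position
        return len(self) - site.c_position


@dataclass(frozen=True)
class CpGSite:
    """One CG dinucleotide of the reference, numbered in plus-frame order."""

    index: int          # 1-based ordinal (CG #k)
    strand: str         # strand carrying the C at c_position
    c_position: int     # 1-based position of the C on the reference
    c_coordinate: int   # genomic coordinate of that C


@dataclass(frozen=True)
class TemplatePair:
    """The two converted sequencing templates produced by in-silico PCR."""

    sense: str
    antisense: str
    cpg_positions_sense: tuple[int, ...]
    non_cpg_c_positions_sense: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.sense)

    def mirror(self, p: int) -> int:
        """Map a sense-frame position to the antisense frame (and back)."""
        return len(self.sense) - p + 1


def load_reference(fasta_path, seq_start: int | None = None,
                   seq_end: int | None = None,
                   amplified_strand: str | None = None) -> ReferenceRegion:
    """Load a single-record FASTA file into a :class:`ReferenceRegion`.

    Coordinates and strand are normally supplied as arguments; as a
    convenience a header of the form ``>name chrom:6000-6999 plus`` (or
    ``+``/``-``) is also understood when any of them is omitted.
    """
    try:
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
    except (OSError, ValueError) as exc:
        raise ReferenceFormatError(f"cannot read FASTA {fasta_path}: {exc}") from exc
    if len(records) != 1:
        raise ReferenceFormatError(
            f"reference FASTA must contain exactly one record, found {len(records)}"
        )
    rec = records[0]
    if seq_start is None or seq_end is None or amplified_strand is None:
        m = _HEADER_RE.match(rec.description)
        if not m:
            raise ReferenceFormatError(
                "seq_start/seq_end/amplified_strand not supplied and the FASTA "
                "header does not follow the '>name chrom:start-end strand' convention"
            )
        seq_start = int(m.group("start")) if seq_start is None else seq_start
        seq_end = int(m.group("end")) if seq_end is None else seq_end
        if amplified_strand is None:
            amplified_strand = {"+": "plus", "-": "minus"}.get(
                m.group("strand"), m.group("strand"))
    return ReferenceRegion(
        name=rec.id,
        sequence=str(rec.seq).upper(),
        seq_start=int(seq_start),
        seq_end=int(seq_end),
        amplified_strand=amplified_strand,
    )


def find_cpg_sites(ref: ReferenceRegion) -> list[CpGSite]:
    """Locate every CG dinucleotide of the reference.

    Sites are numbered 1..K in ascending plus-frame position of the C.
    Overlapping occurrences (``CGCG``) are each reported.  A trailing C at
    the final base is not a site: only complete CG dinucleotides inside the
    region count, and N never matches.  The CG dinucleotide is its own
    reverse complement, so this plus-frame scan captures the site on both
    strands; the reported ``c_position``/``c_coordinate`` refer to the
    plus-strand cytosine.
    """
    seq = ref.sequence
    sites = []
    k = 0
    for m in re.finditer("(?=CG)", seq):
        k += 1
        pos = m.start() + 1
        sites.append(CpGSite(
            index=k,
            strand="plus",
            c_position=pos,
            c_coordinate=ref.position_to_coordinate(pos),
        ))
    return sites


def bisulfite_convert(ref: ReferenceRegion) -> TemplatePair:
    """In-silico bisulfite conversion + PCR of the amplified strand.

    On the amplified strand every C not followed by G becomes T (complete
    conversion is assumed for the template); CpG cytosines are kept as C
    (the potentially methylated state the sequencing resolves).  The
    antisense template is the reverse complement of the converted sense
    strand.  N converts to N and never forms a CpG.
    """
    amp = ref.amplified_sequence
    sense = list(amp)
    cpg_pos = []
    control_pos = []
    for i, b in enumerate(amp):
        if b != "C":
            continue
        if i + 1 < len(amp) and amp[i + 1] == "G":
            cpg_pos.append(i + 1)          # 1-based, kept as C
        else:
            sense[i] = "T"
            control_pos.append(i + 1)      # conversion-control position
    sense_str = "".join(sense)
    return TemplatePair(
        sense=sense_str,
        antisense=reverse_complement(sense_str),
        cpg_positions_sense=tuple(cpg_pos),
        non_cpg_c_positions_sense=tuple(control_pos),
    )
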