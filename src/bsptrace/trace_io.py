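"""Reading and writing ABIF (*.ab1*) chromatogram trace files.

A Sanger chromatogram stores, for every *called* base, the analyzed dye
signal of the four channels (A, C, G, T).  The per-base peak heights are the
raw material of every downstream ratio in this package: primary peak ratio
(trimming), bisulfite conversion rate (QC) and methylation percentage.

Parsing is delegated to Biopython's ABIF reader; this module extracts the
five required record groups (base calls, per-base Phred qualities, peak
locations, channel order and the four analyzed trace channels), samples each
channel at each base call's peak location, and reorders the channels into
fixed A, C, G, T column order using the file's channel-order record (FWO_),
which is *never* assumed to be a particular permutation.

A minimal ABIF writer is provided so synthetic chromatograms can be stored
as genuine ``.ab1`` files and round-tripped through the same reader.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import AbifError, MissingFieldError

BASES = "ACGT"

# directory entry: name, number, element type, element size, #elements,
# data size, data offset, handle (all big-endian)
_DIRFMT = ">4sI2H4I"
_HEADFMT = ">H4sI2H3I"

#: spacing of base-call peak locations in the synthetic trace arrays
_TRACE_SPACING = 2


@dataclass
class ChromatogramTrace:
    """Per-called-base view of one Sanger sequencing read.

    Attributes
    ----------
    read_id : str
        Identifier of the read (sample name from the file, or synthetic id).
    called_bases : str
        Base calls, one of ``A/C/G/T/N``, length ``L``.
    phred : numpy.ndarray
        Integer Phred quality per called base, shape ``(L,)``.
    peak_heights : numpy.ndarray
        Analyzed-signal peak height per channel at each called base, shape
        ``(L, 4)`` with columns in fixed A, C, G, T order.
    source_path : str
        Path of the file the trace was read from ("" for in-memory traces).
    """

    read_id: str
    called_bases: str
    phred: np.ndarray
    peak_heights: np.ndarray
    source_path: str = ""

    def __post_init__(self):
        self.phred = np.asarray(self.phred, dtype=int)
        self.peak_heights = np.asarray(self.peak_heights)
        L = len(self.called_bases)
        if L < 1:
            raise ValueError("trace must contain at least one called base")
        if self.phred.shape != (L,):
            raise ValueError("phred length does not match called bases")
        if self.peak_heights.shape != (L, 4):
            raise ValueError("peak_heights must have shape (L, 4)")
        if (self.phred < 0).any():
            raise ValueError("phred values must be non-negative")
        if (self.peak_heights < 0).any():
            raise ValueError("peak heights must be non-negative")
        bad = set(self.called_bases) - set("ACGTN")
        if bad:
            raise ValueError(f"illegal base symbols in trace: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.called_bases)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ChromatogramTrace):
            return NotImplemented
        return (
            self.called_bases == other.called_bases
            and np.array_equal(self.phred, other.phred)
            and np.array_equal(self.peak_heights, other.peak_heights)
        )


def _tag(raw: dict, name: str, path: str):
    """Fetch an ABIF tag preferring the edited (#1) copy over the raw (#2)."""
    for number in (1, 2):
        key = f"{name}{number}"
        if key in raw and raw[key] is not None:
            return raw[key]
    raise MissingFieldError(name, path)


def _as_int_list(value) -> list[int]:
    if isinstance(value, bytes):
        return list(value)
    if isinstance(value, (int, np.integer)):
        return [int(value)]
    return [int(v) for v in value]


def read_abif(path) -> ChromatogramTrace:
    """Read an ABIF chromatogram file into a :class:`ChromatogramTrace`.

    The four peak-height columns are sampled from the analyzed trace
    channels (``DATA9``–``DATA12``) at each base call's peak location
    (``PLOC``) and permuted into A, C, G, T order according to the file's
    field-order record (``FWO_``).

    Raises
    ------
    AbifError
        Missing file, bad magic number, or truncated container.
    MissingFieldError
        A required tag (base calls, qualities, peak locations, field order
        or a trace channel) is absent.
    """
    path = Path(path)
    if not path.exists():
        raise AbifError(f"no such file: {path}")
    try:
        record = SeqIO.read(str(path), "abi")
    except MemoryError:
        raise
    except (ValueError, struct.error, AssertionError, OSError) as exc:
        raise AbifError(f"cannot parse {path} as ABIF: {exc}") from exc
    raw = record.annotations.get("abif_raw", {})

    bases_raw = _tag(raw, "PBAS", str(path))
    if isinstance(bases_raw, bytes):
        called = bases_raw.decode("ascii")
    else:
        called = str(bases_raw)
    called = called.upper().replace("U", "T")
    # any IUPAC ambiguity call other than ACGT is treated as N
    called = "".join(b if b in "ACGTN" else "N" for b in called)

    phred = _as_int_list(_tag(raw, "PCON", str(path)))
    ploc = _as_int_list(_tag(raw, "PLOC", str(path)))

    fwo = _tag(raw, "FWO_", str(path))
    if isinstance(fwo, bytes):
        fwo = fwo.decode("ascii")
    fwo = fwo.upper()
    if sorted(fwo) != sorted(BASES):
        raise AbifError(f"invalid channel order record {fwo!r} in {path}")

    channels = {}
    for i, base in enumerate(fwo):
        key = f"DATA{9 + i}"
        if key not in raw or raw[key] is None:
            raise MissingFieldError(key, str(path))
        channels[base] = np.asarray(_as_int_list(raw[key]))

    L = len(called)
    if len(phred) != L or len(ploc) != L:
        raise AbifError(
            f"inconsistent array lengths in {path}: "
            f"{L} bases, {len(phred)} qualities, {len(ploc)} peak locations"
        )
    n_points = min(len(channels[b]) for b in BASES)
    ploc_arr = np.asarray(ploc)
    if (ploc_arr < 0).any() or (ploc_arr >= n_points).any():
        raise AbifError(f"peak location outside trace data in {path}")

    heights = np.empty((L, 4), dtype=int)
    for col, base in enumerate(BASES):
        heights[:, col] = channels[base][ploc_arr]
    heights = np.clip(heights, 0, None)

    return ChromatogramTrace(
        read_id=record.id if record.id else path.stem,
        called_bases=called,
        phred=np.asarray(phred),
        peak_heights=heights,
        source_path=str(path),
    )


# --------------------------------------------------------------------------
# minimal ABIF writer
# --------------------------------------------------------------------------

def _dir_entry(name: bytes, number: int, etype: int, esize: int,
               n_elem: int, data: bytes, offset: int) -> tuple[bytes, bytes]:
    """Return (entry_bytes, data_block). Data of <= 4 bytes is inlined."""
    size = len(data)
    if size <= 4:
        inline = data.ljust(4, b"\x00")
        entry = struct.pack(_DIRFMT, name, number, etype, esize, n_elem,
                            size, struct.unpack(">I", inline)[0], 0)
        return entry, b""
    entry = struct.pack(_DIRFMT, name, number, etype, esize, n_elem,
                        size, offset, 0)
    return entry, data


def write_abif(trace: ChromatogramTrace, path, channel_order: str = "GATC"):
    """Write a minimal but valid ABIF file for *trace*.

    The file contains base calls (PBAS), per-base qualities (PCON), peak
    locations (PLOC), the channel-order record (FWO_) and the four analyzed
    trace channels (DATA9-12) laid out in *channel_order* — everything
    :func:`read_abif` needs, such that the round trip is exact on
    (called_bases, phred, peak_heights).

    Peak heights must be integer-valued and fit in a signed 16-bit trace
    sample (0..32767), matching real sequencer output.
    """
    path = Path(path)
    if sorted(channel_order.upper()) != sorted(BASES):
        raise ValueError(f"channel_order must permute ACGT, got {channel_order!r}")
    channel_order = channel_order.upper()

    heights = np.asarray(trace.peak_heights)
    if not np.allclose(heights, np.round(heights)):
        raise ValueError("peak heights must be integer-valued for ABIF export")
    heights = np.round(heights).astype(int)
    if heights.max(initial=0) > 32767:
        raise ValueError("peak heights exceed the 16-bit ABIF trace range")
    phred = np.clip(np.asarray(trace.phred, dtype=int), 0, 93)

    L = len(trace)
    n_points = _TRACE_SPACING * L
    ploc = np.arange(L) * _TRACE_SPACING

    bases_b = trace.called_bases.encode("ascii")
    phred_b = bytes(int(q) for q in phred)
    ploc_b = struct.pack(f">{L}h", *ploc)

    tags: list[tuple[bytes, int, int, int, int, bytes]] = []

    def add(name: str, number: int, etype: int, esize: int, n: int, data: bytes):
        tags.append((name.encode("ascii"), number, etype, esize, n, data))

    for number in (1, 2):
        add("PBAS", number, 2, 1, L, bases_b)
        add("PCON", number, 2, 1, L, phred_b)
        add("PLOC", number, 4, 2, L, ploc_b)
    add("FWO_", 1, 2, 1, 4, channel_order.encode("ascii"))
    for i, base in enumerate(channel_order):
        col = BASES.index(base)
        data = np.zeros(n_points, dtype=int)
        data[ploc] = heights[:, col]
        add("DATA", 9 + i, 4, 2, n_points, struct.pack(f">{n_points}h", *data))
    rid = trace.read_id.encode("ascii", "replace")[:255]
    add("SMPL", 1, 18, 1, len(rid) + 1, bytes([len(rid)]) + rid)

    # layout: 4-byte magic + 124-byte header block, data blocks, directory
    header_len = 128
    blocks = []
    offset = header_len
    entries = []
    for name, number, etype, esize, n, data in tags:
        entry, block = _dir_entry(name, number, etype, esize, n, data, offset)
        entries.append(entry)
        if block:
            blocks.append(block)
            offset += len(block)
    dir_offset = offset
    n_entries = len(entries)

    header = struct.pack(_HEADFMT, 101, b"tdir", 1, 1023, 28, n_entries,
                         28 * n_entries, dir_offset)
    header = (b"ABIF" + header).ljust(header_len, b"\x00")

    try:
        with open(path, "wb") as fh:
            fh.write(header)
            for block in blocks:
                fh.write(block)
            for entry in entries:
                fh.write(entry)
    except OSError as exc:
        raise AbifError(f"cannot write ABIF file {path}: {exc}") from exc
    return path
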