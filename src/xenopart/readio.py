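"""Reading, normalising, trimming and writing of read and alignment formats.

Everything downstream (classification, quantification, variant post-processing)
consumes the types defined here: :class:`ReadRecord` / :class:`ReadPair` for
FASTQ data and :class:`AlignmentObservation` for SAM/BAM records reduced to the
fields that matter for species-of-origin classification.

Quality encoding is fixed at Phred+33; gzip input/output is sniffed from the
``.gz`` extension.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

import numpy as np

MAPQ_UNAVAILABLE = 255

# SAM FLAG bits
_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_MATE_UNMAPPED = 0x8
_FLAG_REVERSE = 0x10
_FLAG_MATE_REVERSE = 0x20
_FLAG_MATE1 = 0x40
_FLAG_MATE2 = 0x80
_FLAG_SECONDARY = 0x100
_FLAG_QCFAIL = 0x200
_FLAG_DUP = 0x400
_FLAG_SUPPLEMENTARY = 0x800


@dataclass
class ReadRecord:
    """One mate of a sequenced fragment.

    ``id`` is the canonical fragment id: no whitespace, no trailing ``/1`` or
    ``/2`` mate suffix. ``qualities`` are Phred scores, one per base.
    """

    id: str
    mate: int
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    """A fragment's two mates, sharing one canonical id."""

    id: str
    mate1: ReadRecord
    mate2: ReadRecord

    def __post_init__(self) -> None:
        if not (self.mate1.id == self.mate2.id == self.id):
            raise ValueError(
                f"pair id mismatch: {self.id!r} vs mates "
                f"{self.mate1.id!r}/{self.mate2.id!r}"
            )


@dataclass
class AlignmentObservation:
    """One SAM record reduced to classification-relevant fields.

    ``mapq`` of 255 means "unavailable" (SAM convention). When ``mapped`` is
    False, ``reference``/``position``/``strand`` are None. ``position`` is
    1-based (SAM convention). The optional ``sequence``/``qualities``/
    ``ref_span`` fields carry payload needed by duplicate marking, fragment
    assignment and pileup; they are absent from minimal observations.
    """

    id: str
    mate: int
    mapped: bool
    mapq: int
    proper_pair: bool
    reference: Optional[str]
    position: Optional[int]
    strand: Optional[str]
    primary: bool = True
    duplicate: bool = False
    sequence: Optional[str] = None
    qualities: Optional[list[int]] = None
    ref_span: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.mapped and not (
            self.reference is None and self.position is None and self.strand is None
        ):
            raise ValueError(f"unmapped record {self.id!r} carries coordinates")
        if self.mapped and (self.position is None or self.position < 1):
            raise ValueError(f"mapped record {self.id!r} needs a 1-based position")

    @property
    def mapq_unavailable(self) -> bool:
        return self.mapq == MAPQ_UNAVAILABLE

    @property
    def end(self) -> Optional[int]:
        """1-based inclusive rightmost reference coordinate."""
        if not self.mapped:
            return None
        span = self.ref_span
        if span is None and self.sequence is not None:
            span = len(self.sequence)
        if span is None:
            span = 1
        return self.position + span - 1


@dataclass
class TrimConfig:
    """Sliding-window quality-trimming parameters.

    Defaults: 6-base windows, minimum mean Phred 20, minimum kept length 50 nt.
    """

    window: int = 6
    min_mean_quality: float = 20.0
    min_length: int = 50

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def normalize_read_id(raw_header: str) -> tuple[str, Optional[int]]:
    """Canonicalise a FASTQ header into (fragment id, mate index or None).

    Handles both the legacy ``NAME/1`` suffix dialect and the Casava 1.8+
    ``NAME 1:N:0:BARCODE`` comment dialect. A leading ``@`` is tolerated.
    """
    header = raw_header.strip()
    if header.startswith("@"):
        header = header[1:]
    if not header:
        raise ValueError("empty FASTQ header")
    parts = header.split(None, 1)
    name = parts[0]
    mate: Optional[int] = None
    if len(name) > 2 and name[-2] == "/" and name[-1] in "12":
        mate = int(name[-1])
        name = name[:-2]
    elif len(parts) == 2:
        comment_first = parts[1].split(":", 1)
        if len(comment_first) == 2 and comment_first[0] in ("1", "2"):
            mate = int(comment_first[0])
    if not name:
        raise ValueError(f"malformed FASTQ header {raw_header!r}")
    return name, mate


_DISCARDED = object()


def sliding_window_trim(read: ReadRecord, cfg: TrimConfig) -> Optional[ReadRecord]:
    """Truncate ``read`` before the first window whose mean quality fails.

    Scans ``cfg.window``-base windows left to right; at the first window whose
    mean quality is below ``cfg.min_mean_quality`` the read is truncated before
    that window. Returns None ("discarded") when the surviving prefix is
    shorter than ``cfg.min_length``. The output is always a prefix of the
    input, so re-trimming a trimmed read is the identity.
    """
    n = len(read)
    w = cfg.window
    cut = n
    if n >= w:
        q = np.asarray(read.qualities, dtype=np.float64)
        # mean over each window via cumulative sums; first failing window wins
        csum = np.concatenate(([0.0], np.cumsum(q)))
        means = (csum[w:] - csum[:-w]) / w
        failing = np.nonzero(means < cfg.min_mean_quality)[0]
        if failing.size:
            cut = int(failing[0])
    if cut < cfg.min_length:
        return None
    if cut == n:
        return read
    return replace(read, sequence=read.sequence[:cut], qualities=read.qualities[:cut])


def trim_pair(pair: ReadPair, cfg: TrimConfig) -> Optional[ReadPair]:
    """Trim both mates; the whole pair is discarded if either mate is."""
    m1 = sliding_window_trim(pair.mate1, cfg)
    if m1 is None:
        return None
    m2 = sliding_window_trim(pair.mate2, cfg)
    if m2 is None:
        return None
    return ReadPair(pair.id, m1, m2)


def _cigar_ref_span(cigar: str) -> Optional[int]:
    if cigar == "*":
        return None
    span = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise ValueError(f"malformed CIGAR {cigar!r}")
            if ch in "MDN=X":
                span += int(num)
            num = ""
    return span


def decode_flag(flag: int) -> dict:
    """Decode a SAM FLAG into the fields AlignmentObservation needs."""
    paired = bool(flag & _FLAG_PAIRED)
    mapped = not (flag & _FLAG_UNMAPPED)
    if flag & _FLAG_MATE1:
        mate = 1
    elif flag & _FLAG_MATE2:
        mate = 2
    else:
        mate = 1
    return {
        "mapped": mapped,
        "mate": mate,
        "proper_pair": paired and bool(flag & _FLAG_PROPER),
        "reverse": bool(flag & _FLAG_REVERSE),
        "primary": not (flag & (_FLAG_SECONDARY | _FLAG_SUPPLEMENTARY)),
        "duplicate": bool(flag & _FLAG_DUP),
    }


def parse_sam_stream(
    lines: Iterable[str], keep_payload: bool = True
) -> Iterator[AlignmentObservation]:
    """Parse a SAM text stream into AlignmentObservations.

    Header lines (``@``-prefixed) are skipped. Secondary/supplementary records
    are emitted with ``primary=False``. A record line with fewer than the 11
    mandatory tab-separated fields raises, naming the line number.
    """
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise ValueError(
                f"SAM line {lineno}: expected >= 11 fields, got {len(fields)}"
            )
        qname, flag_s, rname, pos_s, mapq_s, cigar = fields[:6]
        seq, qual = fields[9], fields[10]
        flag = int(flag_s)
        bits = decode_flag(flag)
        name, _ = normalize_read_id(qname)
        mapped = bits["mapped"] and rname != "*"
        sequence = seq if (keep_payload and seq != "*") else None
        qualities = (
            [ord(c) - 33 for c in qual] if (keep_payload and qual != "*") else None
        )
        yield AlignmentObservation(
            id=name,
            mate=bits["mate"],
            mapped=mapped,
            mapq=int(mapq_s),
            proper_pair=bits["proper_pair"],
            reference=rname if mapped else None,
            position=int(pos_s) if mapped else None,
            strand=("-" if bits["reverse"] else "+") if mapped else None,
            primary=bits["primary"],
            duplicate=bits["duplicate"],
            sequence=sequence,
            qualities=qualities,
            ref_span=_cigar_ref_span(cigar) if mapped else None,
        )


def read_alignments(path, keep_payload: bool = True) -> list[AlignmentObservation]:
    """Read SAM (text) or BAM alignments from ``path``.

    BAM goes through pysam; SAM text goes through :func:`parse_sam_stream`.
    """
    spath = str(path)
    if spath.endswith(".bam"):
        import pysam

        obs: list[AlignmentObservation] = []
        with pysam.AlignmentFile(spath, "rb") as bam:
            for rec in bam.fetch(until_eof=True):
                name, _ = normalize_read_id(rec.query_name)
                mapped = not rec.is_unmapped
                quals = list(rec.query_qualities) if rec.query_qualities is not None else None
                obs.append(
                    AlignmentObservation(
                        id=name,
                        mate=2 if rec.is_read2 else 1,
                        mapped=mapped,
                        mapq=rec.mapping_quality,
                        proper_pair=rec.is_paired and rec.is_proper_pair,
                        reference=rec.reference_name if mapped else None,
                        position=rec.reference_start + 1 if mapped else None,
                        strand=("-" if rec.is_reverse else "+") if mapped else None,
                        primary=not (rec.is_secondary or rec.is_supplementary),
                        duplicate=rec.is_duplicate,
                        sequence=rec.query_sequence if keep_payload else None,
                        qualities=quals if keep_payload else None,
                        ref_span=(rec.reference_length if mapped else None),
                    )
                )
        return obs
    with _open_text(spath, "rt") as fh:
        return list(parse_sam_stream(fh, keep_payload=keep_payload))


def _open_text(path, mode: str) -> IO[str]:
    spath = str(path)
    if spath.endswith(".gz"):
        return gzip.open(spath, mode)  # type: ignore[return-value]
    return open(spath, mode)


def _parse_fastq_records(fh: IO[str], path: str) -> Iterator[ReadRecord]:
    while True:
        header = fh.readline()
        if not header:
            return
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise ValueError(f"{path}: expected '@' header line, got {header!r}")
        seq = fh.readline().rstrip("\n")
        plus = fh.readline().rstrip("\n")
        qual = fh.readline().rstrip("\n")
        if not plus.startswith("+"):
            raise ValueError(f"{path}: malformed FASTQ record at {header!r}")
        if len(seq) != len(qual):
            raise ValueError(f"{path}: sequence/quality length mismatch at {header!r}")
        if any(ord(c) < 33 for c in qual):
            raise ValueError(
                f"{path}: quality characters below '!' — not Phred+33 encoded"
            )
        name, mate = normalize_read_id(header)
        yield ReadRecord(
            id=name, mate=mate or 1, sequence=seq, qualities=[ord(c) - 33 for c in qual]
        )


def read_fastq(path) -> list[ReadRecord]:
    """Read a 4-line FASTQ file (optionally gzipped, Phred+33)."""
    with _open_text(path, "rt") as fh:
        return list(_parse_fastq_records(fh, str(path)))


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    """Read two mate files into ReadPairs, checking id agreement in order."""
    mates1 = read_fastq(path1)
    mates2 = read_fastq(path2)
    if len(mates1) != len(mates2):
        raise ValueError(
            f"mate files differ in record count: {len(mates1)} vs {len(mates2)}"
        )
    pairs = []
    for m1, m2 in zip(mates1, mates2):
        if m1.id != m2.id:
            raise ValueError(f"mate id mismatch: {m1.id!r} vs {m2.id!r}")
        m1.mate, m2.mate = 1, 2
        pairs.append(ReadPair(m1.id, m1, m2))
    return pairs


def _format_fastq(read: ReadRecord) -> str:
    qual = "".join(chr(q + 33) for q in read.qualities)
    return f"@{read.id}/{read.mate}\n{read.sequence}\n+\n{qual}\n"


def write_fastq(pairs: Iterable[ReadPair], dest1, dest2) -> int:
    """Write pairs as two mate FASTQ files/streams in identical fragment order.

    Returns the number of pairs written. Round-trips bit-exactly with
    :func:`read_fastq_pairs`.
    """
    own1 = own2 = False
    if not hasattr(dest1, "write"):
        dest1, own1 = _open_text(dest1, "wt"), True
    if not hasattr(dest2, "write"):
        dest2, own2 = _open_text(dest2, "wt"), True
    n = 0
    try:
        for pair in pairs:
            dest1.write(_format_fastq(pair.mate1))
            dest2.write(_format_fastq(pair.mate2))
            n += 1
    finally:
        if own1:
            dest1.close()
        if own2:
            dest2.close()
    return n
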