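"""Minimal seed-and-extend read aligner over small genomes.

This exists so the whole deconvolution pipeline — including the 1,000 bp
host-contamination window check — runs on synthetic fixtures without external
aligners or reference downloads. It seeds with exact k-mers from both strands
and extends ungapped, reporting a BWA-like (but internally defined) mapping
quality: ``min(60, 10 * (second_best_mismatches - best_mismatches))``, and 0
whenever two equal-best placements exist, so the classifier's MAPQ gate
removes reads from exact repeats. Any real SAM/BAM producer can stand in for
it downstream; the classifier treats both identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .readio import ReadPair, ReadRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeedIndex:
    """Exact k-mer index of one genome (forward strand, all positions)."""

    genome_id: str
    sequence: str
    k: int
    seed_map: dict[str, list[int]]
    _arr: np.ndarray = None  # uint8 view of sequence for fast mismatch counts

    def __post_init__(self) -> None:
        if self._arr is None:
            self._arr = np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8)


@dataclass
class AlignmentHit:
    id: str
    mate: int
    reference: str
    position: int  # 1-based leftmost
    strand: str
    mismatches: int
    score: int
    mapq_like: int


def build_index(genome: str, k: int = 21, genome_id: str = "ref") -> SeedIndex:
    """Index every forward-strand k-mer occurrence of ``genome``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(genome) < k:
        raise ValueError(f"genome length {len(genome)} shorter than k={k}")
    seed_map: dict[str, list[int]] = {}
    for i in range(len(genome) - k + 1):
        seed_map.setdefault(genome[i : i + k], []).append(i)
    return SeedIndex(genome_id=genome_id, sequence=genome, k=k, seed_map=seed_map)


def _read_as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _candidates(seq: str, index: SeedIndex) -> set[int]:
    """Candidate 0-based start positions from non-overlapping k-mer seeds."""
    k = index.k
    n = len(seq)
    starts = set()
    offsets = list(range(0, n - k + 1, k))
    if offsets and offsets[-1] != n - k:
        offsets.append(n - k)
    for off in offsets:
        for hit in index.seed_map.get(seq[off : off + k], ()):
            start = hit - off
            if 0 <= start <= len(index.sequence) - n:
                starts.add(start)
    return starts


def align_read(
    read: ReadRecord, index: SeedIndex, max_mismatch: int = 5
) -> Optional[AlignmentHit]:
    """Best ungapped placement of ``read`` on either strand, or None.

    Ties are broken toward the '+' strand then the lowest coordinate; tied
    best placements force ``mapq_like`` to 0.
    """
    n = len(read.sequence)
    if n < index.k:
        return None
    garr = index._arr
    # (mismatches, strand_order, start) triples; strand_order 0='+', 1='-'
    best: Optional[tuple[int, int, int]] = None
    second_mm: Optional[int] = None
    tie = False
    for strand_order, seq in enumerate((read.sequence, reverse_complement(read.sequence))):
        rarr = _read_as_array(seq)
        for start in sorted(_candidates(seq, index)):
            mm = int(np.count_nonzero(garr[start : start + n] != rarr))
            key = (mm, strand_order, start)
            if best is None:
                best = key
            elif mm < best[0]:
                second_mm = best[0]
                best = key
                tie = False
            elif mm == best[0]:
                tie = True
                second_mm = mm if second_mm is None else min(second_mm, mm)
                if key < best:
                    best = key
            elif second_mm is None or mm < second_mm:
                second_mm = mm
    if best is None or best[0] > max_mismatch:
        return None
    mm, strand_order, start = best
    if tie:
        mapq = 0
    elif second_mm is None:
        mapq = 60
    else:
        mapq = min(60, 10 * (second_mm - mm))
    return AlignmentHit(
        id=read.id,
        mate=read.mate,
        reference=index.genome_id,
        position=start + 1,
        strand="-" if strand_order else "+",
        mismatches=mm,
        score=n - mm,
        mapq_like=mapq,
    )


def align_pair(
    pair: ReadPair,
    index: SeedIndex,
    insert_min: int = 100,
    insert_max: int = 400,
    max_mismatch: int = 5,
) -> tuple[Optional[AlignmentHit], Optional[AlignmentHit], bool]:
    """Align both mates independently and judge pair concordance.

    The pair is "proper" iff both mates hit the same reference on opposite
    strands with an inferred fragment length inside [insert_min, insert_max].
    """
    hit1 = align_read(pair.mate1, index, max_mismatch)
    hit2 = align_read(pair.mate2, index, max_mismatch)
    proper = False
    if hit1 is not None and hit2 is not None and hit1.reference == hit2.reference:
        if hit1.strand != hit2.strand:
            left = min(hit1.position, hit2.position)
            right = max(
                hit1.position + len(pair.mate1.sequence),
                hit2.position + len(pair.mate2.sequence),
            )
            frag = right - left
            proper = insert_min <= frag <= insert_max
    return hit1, hit2, proper


def _sam_record(
    read: ReadRecord,
    hit: Optional[AlignmentHit],
    mate_hit: Optional[AlignmentHit],
    proper: bool,
    mate_index: int,
) -> str:
    flag = 0x1 | (0x40 if mate_index == 1 else 0x80)
    if proper:
        flag |= 0x2
    if hit is None:
        flag |= 0x4
    elif hit.strand == "-":
        flag |= 0x10
    if mate_hit is None:
        flag |= 0x8
    elif mate_hit.strand == "-":
        flag |= 0x20
    if hit is None:
        rname, pos, mapq, cigar = "*", 0, 0, "*"
        seq, qual = read.sequence, read.qualities
    else:
        rname, pos, mapq = hit.reference, hit.position, hit.mapq_like
        cigar = f"{len(read.sequence)}M"
        if hit.strand == "-":
            seq = reverse_complement(read.sequence)
            qual = read.qualities[::-1]
        else:
            seq, qual = read.sequence, read.qualities
    rnext = "*" if mate_hit is None else "="
    pnext = 0 if mate_hit is None else mate_hit.position
    qstr = "".join(chr(q + 33) for q in qual)
    nm = f"NM:i:{hit.mismatches}" if hit is not None else "NM:i:0"
    return "\t".join(
        [
            read.id,
            str(flag),
            rname,
            str(pos),
            str(mapq),
            cigar,
            rnext,
            str(pnext),
            "0",
            seq,
            qstr,
            nm,
        ]
    )


def align_pairs_to_sam(
    pairs: Iterable[ReadPair],
    index: SeedIndex,
    dest,
    insert_min: int = 100,
    insert_max: int = 400,
    max_mismatch: int = 5,
) -> int:
    """Align pairs and write a SAM text file (mapped and unmapped records)."""
    own = False
    if not hasattr(dest, "write"):
        dest, own = open(dest, "w"), True
    n = 0
    try:
        dest.write("@HD\tVN:1.6\tSO:unsorted\n")
        dest.write(f"@SQ\tSN:{index.genome_id}\tLN:{len(index.sequence)}\n")
        for pair in pairs:
            h1, h2, proper = align_pair(pair, index, insert_min, insert_max, max_mismatch)
            dest.write(_sam_record(pair.mate1, h1, h2, proper, 1) + "\n")
            dest.write(_sam_record(pair.mate2, h2, h1, proper, 2) + "\n")
            n += 1
    finally:
        if own:
            dest.close()
    return n
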