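"""Expression quantification over exon models: fragment counts and RPKM.

Runs identically on graft-specific and host-specific alignment sets (the same
code path quantifies tumour and stromal expression). Fragments are assigned
to the single gene whose exons they overlap the most; RPKM normalises counts
by exonic length (kb) and by the total mapped fragments of the category being
quantified (millions):

    RPKM = 1e9 * count / (total_mapped * exonic_length)

The cross-platform comparison is Spearman's rank correlation of log2-scaled
expression (log2 is a monotone map, so it cannot change the rank correlation;
it is kept because exported matrices are log2-scaled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .readio import AlignmentObservation


@dataclass
class GeneModel:
    """One gene: sorted, non-overlapping exons as 0-based half-open intervals."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: empty exon [{s}, {e})")

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def read_bed12(path) -> list[GeneModel]:
    """Parse gene models from a BED12 file (0-based, half-open)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 fields")
            chrom, start, _end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{lineno}: blockCount disagrees with lists")
            exons = [(start + off, start + off + ln) for off, ln in zip(starts, sizes)]
            genes.append(GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=exons))
    return genes


def write_bed12(path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.start, g.end
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(start),
                        str(end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


@dataclass
class FragmentAssignment:
    """Per-gene fragment counts plus assignment diagnostics."""

    counts: dict[str, int]
    assigned: int
    unassigned: int
    ambiguous: int

    @property
    def total(self) -> int:
        return self.assigned + self.unassigned + self.ambiguous


def _fragment_intervals(
    mates: dict[int, AlignmentObservation]
) -> list[tuple[str, int, int]]:
    """0-based half-open reference intervals covered by each mapped mate."""
    out = []
    for obs in mates.values():
        if obs.mapped:
            span = obs.ref_span or (len(obs.sequence) if obs.sequence else 1)
            out.append((obs.reference, obs.position - 1, obs.position - 1 + span))
    return out


def assign_fragments(
    alignments: Iterable[AlignmentObservation],
    genes: Sequence[GeneModel],
    count_unit: str = "fragment",
) -> FragmentAssignment:
    """Assign each fragment to the gene with maximal exonic overlap.

    A fragment counts once toward the single gene whose exons overlap its
    aligned mate intervals by the most bases. No overlap -> unassigned; a tie
    across genes -> discarded as ambiguous (tallied in the diagnostics).
    ``count_unit='read'`` counts each mapped mate independently instead.
    """
    if count_unit not in ("fragment", "read"):
        raise ValueError("count_unit must be 'fragment' or 'read'")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            tree.addi(s, e, g.gene_id)
    per_fragment: dict[str, dict[int, AlignmentObservation]] = {}
    for obs in alignments:
        if not obs.primary or obs.duplicate:
            continue
        per_fragment.setdefault(obs.id, {})[obs.mate] = obs
    counts: dict[str, int] = {g.gene_id: 0 for g in genes}
    assigned = unassigned = ambiguous = 0
    units: list[list[tuple[str, int, int]]] = []
    for mates in per_fragment.values():
        ivals = _fragment_intervals(mates)
        if not ivals:
            continue
        if count_unit == "fragment":
            units.append(ivals)
        else:
            units.extend([iv] for iv in ivals)
    for ivals in units:
        overlap: dict[str, int] = {}
        for chrom, start, end in ivals:
            tree = trees.get(chrom)
            if tree is None:
                continue
            for hit in tree.overlap(start, end):
                bases = min(end, hit.end) - max(start, hit.begin)
                overlap[hit.data] = overlap.get(hit.data, 0) + bases
        if not overlap:
            unassigned += 1
            continue
        best = max(overlap.values())
        winners = [g for g, b in overlap.items() if b == best]
        if len(winners) > 1:
            ambiguous += 1
        else:
            counts[winners[0]] += 1
            assigned += 1
    return FragmentAssignment(
        counts=counts, assigned=assigned, unassigned=unassigned, ambiguous=ambiguous
    )


def rpkm(count: int, exonic_length: int, total_mapped: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exonic_length < 1:
        raise ValueError("exonic_length must be >= 1")
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    return 1e9 * count / (total_mapped * exonic_length)


def expression_table(
    assignment: FragmentAssignment,
    genes: Sequence[GeneModel],
    total_mapped: Optional[int] = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene count / exonic length / RPKM / log2(RPKM + pseudocount) table.

    The normalisation denominator defaults to the fragments assigned within
    this category (quantification happens after species separation, so the
    category's own mapped fragments are the natural library size).
    """
    total = total_mapped if total_mapped is not None else max(assignment.assigned, 1)
    rows = []
    for g in genes:
        c = assignment.counts.get(g.gene_id, 0)
        r = rpkm(c, g.exonic_length, total)
        rows.append(
            {
                "gene_id": g.gene_id,
                "count": c,
                "exonic_length": g.exonic_length,
                "rpkm": r,
                "log2_rpkm": float(np.log2(r + pseudocount)),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def spearman_log2(
    x: Sequence[float], y: Sequence[float], pseudocount: float = 1.0
) -> float:
    """Spearman rank correlation of log2(value + pseudocount) vectors.

    Ranks use average tie handling. Raises on length mismatch or fewer than 3
    points; returns NaN for constant input (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    lx = np.log2(x + pseudocount)
    ly = np.log2(y + pseudocount)
    if np.all(lx == lx[0]) or np.all(ly == ly[0]):
        return float("nan")
    rho, _ = stats.spearmanr(lx, ly)
    return float(rho)
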