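"""Species-of-origin partitioning of sequenced fragments.

The central operation of the package: given alignments of the same fragments
against a graft reference and a host reference, split the fragment universe
into four disjoint sets —

* graft-specific: mapped (well) to the graft genome only,
* host-specific: mapped to the host genome only,
* common: mapped to both (homologous regions),
* unmapped: mapped to neither.

Two equivalent routes are provided: the direct set algebra over mapped-id
sets, and the sequential align / realign / subtract recipe that mirrors how
the workflow runs with external aligners (primary alignment to graft; both
graft-mapped and graft-unmapped reads realigned to host; common ids
subtracted from the primary set). They provably produce identical partitions
and are cross-checked in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .readio import AlignmentObservation, ReadPair, write_fastq

CATEGORIES = ("graft_specific", "host_specific", "common", "unmapped")


@dataclass
class ClassifyConfig:
    """Fragment classification gates.

    ``min_mapq`` (default 20): a fragment counts as mapped to a genome only if
    the smaller of its two mate MAPQs reaches this. MAPQ 255 means the aligner
    reported no quality; ``treat_mapq_unavailable_as`` decides whether such
    records pass ("mapped", default: the aligner asserted a location) or fail
    the gate. ``require_proper_pair`` defaults to True for DNA libraries;
    RNA-seq mates spanning splice junctions may be discordant, so it is
    switched off there.
    """

    min_mapq: int = 20
    require_proper_pair: bool = True
    unit: str = "pair"  # pair | single
    treat_mapq_unavailable_as: str = "mapped"  # mapped | unmapped

    def __post_init__(self) -> None:
        if not 0 <= self.min_mapq <= 60:
            raise ValueError("min_mapq must be in [0, 60]")
        if self.unit not in ("pair", "single"):
            raise ValueError("unit must be 'pair' or 'single'")
        if self.treat_mapq_unavailable_as not in ("mapped", "unmapped"):
            raise ValueError("treat_mapq_unavailable_as must be 'mapped' or 'unmapped'")


@dataclass
class SpeciesPartition:
    """The four disjoint fragment-id sets covering the universe."""

    graft_specific: set[str]
    host_specific: set[str]
    common: set[str]
    unmapped: set[str]
    universe_size: int

    def __post_init__(self) -> None:
        sets = [self.graft_specific, self.host_specific, self.common, self.unmapped]
        total = sum(len(s) for s in sets)
        union = set().union(*sets)
        if len(union) != total:
            raise ValueError("partition categories are not disjoint")
        if total != self.universe_size:
            raise ValueError(
                f"partition covers {total} ids but universe_size={self.universe_size}"
            )

    def category_of(self, fragment_id: str) -> Optional[str]:
        for name in CATEGORIES:
            if fragment_id in getattr(self, name):
                return name
        return None

    def counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name)) for name in CATEGORIES}


@dataclass
class PartitionSummary:
    """Per-category counts and percentages of the read universe."""

    library_type: str
    counts: dict[str, int]
    percentages: dict[str, float]
    universe_size: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "library_type": self.library_type,
                "universe_size": self.universe_size,
                "counts": self.counts,
                "percentages": self.percentages,
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["category\tcount\tpercent"]
        for name in CATEGORIES:
            lines.append(f"{name}\t{self.counts[name]}\t{self.percentages[name]:.1f}")
        lines.append(f"total\t{self.universe_size}\t100.0")
        return "\n".join(lines) + "\n"


def _pair_passes(
    mates: dict[int, AlignmentObservation], cfg: ClassifyConfig
) -> bool:
    if set(mates) != {1, 2}:
        return False
    obs = [mates[1], mates[2]]
    if not all(o.mapped for o in obs):
        return False
    if cfg.require_proper_pair and not all(o.proper_pair for o in obs):
        return False
    for o in obs:
        if o.mapq_unavailable:
            if cfg.treat_mapq_unavailable_as == "unmapped":
                return False
        elif o.mapq < cfg.min_mapq:
            return False
    return True


def _single_passes(o: AlignmentObservation, cfg: ClassifyConfig) -> bool:
    if not o.mapped:
        return False
    if o.mapq_unavailable:
        return cfg.treat_mapq_unavailable_as == "mapped"
    return o.mapq >= cfg.min_mapq


def collect_mapped_ids(
    alignments: Iterable[AlignmentObservation], cfg: Optional[ClassifyConfig] = None
) -> set[str]:
    """Fragment ids counted as mapped to one genome under the config gates.

    With ``unit='pair'`` a fragment is mapped iff both mates are FLAG-mapped,
    (if required) properly paired, and the minimum mate MAPQ reaches
    ``min_mapq``. Only primary records are considered; more than two primary
    records for a fragment indicates malformed input and raises.
    """
    cfg = cfg or ClassifyConfig()
    per_fragment: dict[str, dict[int, AlignmentObservation]] = {}
    mapped: set[str] = set()
    for obs in alignments:
        if not obs.primary:
            continue
        if cfg.unit == "single":
            if _single_passes(obs, cfg):
                mapped.add(obs.id)
            continue
        mates = per_fragment.setdefault(obs.id, {})
        if obs.mate in mates:
            raise ValueError(
                f"fragment {obs.id!r} has more than one primary record for mate "
                f"{obs.mate}"
            )
        mates[obs.mate] = obs
        if len(mates) > 2:
            raise ValueError(f"fragment {obs.id!r} has >2 primary records")
    if cfg.unit == "pair":
        mapped = {fid for fid, mates in per_fragment.items() if _pair_passes(mates, cfg)}
    return mapped


def partition_ids(
    universe: set[str], graft_mapped: set[str], host_mapped: set[str]
) -> SpeciesPartition:
    """Direct set algebra: specific = difference, common = intersection."""
    stray = (graft_mapped | host_mapped) - universe
    if stray:
        preview = ", ".join(sorted(stray)[:5])
        raise ValueError(f"mapped ids outside the universe: {preview}")
    common = graft_mapped & host_mapped
    return SpeciesPartition(
        graft_specific=graft_mapped - host_mapped,
        host_specific=host_mapped - graft_mapped,
        common=common,
        unmapped=universe - (graft_mapped | host_mapped),
        universe_size=len(universe),
    )


def partition_sequential(
    universe: set[str], graft_mapped: set[str], host_mapped: set[str]
) -> SpeciesPartition:
    """The sequential align / realign / subtract recipe.

    Primary alignment to the graft genome divides the universe into
    graft-mapped and graft-unmapped read sets; both are realigned to the host
    genome, identifying common graft-host ids (from the graft-mapped set) and
    host-specific ids (from the graft-unmapped set); finally the common set is
    subtracted from the primary graft-mapped set to leave graft-specific ids.
    Identical in outcome to :func:`partition_ids`.
    """
    stray = (graft_mapped | host_mapped) - universe
    if stray:
        preview = ", ".join(sorted(stray)[:5])
        raise ValueError(f"mapped ids outside the universe: {preview}")
    graft_unmapped = universe - graft_mapped
    common = {fid for fid in graft_mapped if fid in host_mapped}
    host_specific = {fid for fid in graft_unmapped if fid in host_mapped}
    graft_specific = graft_mapped - common
    unmapped = graft_unmapped - host_specific
    return SpeciesPartition(
        graft_specific=graft_specific,
        host_specific=host_specific,
        common=common,
        unmapped=unmapped,
        universe_size=len(universe),
    )


def split_reads(
    pairs: Iterable[ReadPair], partition: SpeciesPartition, outdir
) -> dict[str, int]:
    """Write one paired-FASTQ file set per category, preserving input order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    buckets: dict[str, list[ReadPair]] = {name: [] for name in CATEGORIES}
    for pair in pairs:
        cat = partition.category_of(pair.id)
        if cat is None:
            raise ValueError(f"fragment {pair.id!r} is missing from the partition")
        buckets[cat].append(pair)
    counts = {}
    for name in CATEGORIES:
        counts[name] = write_fastq(
            buckets[name], outdir / f"{name}_1.fastq", outdir / f"{name}_2.fastq"
        )
    return counts


def summarize_partition(
    partition: SpeciesPartition, tag: str = "wgs"
) -> PartitionSummary:
    """Counts and percentages (1 decimal place) of the universe per category."""
    if partition.universe_size == 0:
        raise ValueError("cannot summarize an empty universe")
    counts = partition.counts()
    percentages = {
        name: round(100.0 * counts[name] / partition.universe_size, 1)
        for name in CATEGORIES
    }
    return PartitionSummary(
        library_type=tag,
        counts=counts,
        percentages=percentages,
        universe_size=partition.universe_size,
    )


def mark_duplicates(
    alignments: Sequence[AlignmentObservation],
) -> list[AlignmentObservation]:
    """Flag PCR/optical duplicate fragments by mapping coordinates.

    Fragments sharing (mate1 reference, mate1 leftmost position, mate1 strand,
    mate2 reference, mate2 position) form one duplicate group; the member with
    the highest summed base quality stays unflagged, ties broken by fragment
    id. Fragments without both mates mapped are passed through untouched.
    """
    by_fragment: dict[str, dict[int, AlignmentObservation]] = {}
    order: list[str] = []
    for obs in alignments:
        if obs.id not in by_fragment:
            order.append(obs.id)
        by_fragment.setdefault(obs.id, {})[obs.mate] = obs
    groups: dict[tuple, list[str]] = {}
    for fid in order:
        mates = by_fragment[fid]
        m1, m2 = mates.get(1), mates.get(2)
        if m1 is None or m2 is None or not (m1.mapped and m2.mapped):
            continue
        key = (m1.reference, m1.position, m1.strand, m2.reference, m2.position)
        groups.setdefault(key, []).append(fid)

    def qual_sum(fid: str) -> int:
        total = 0
        for obs in by_fragment[fid].values():
            if obs.qualities:
                total += sum(obs.qualities)
        return total

    flagged: set[str] = set()
    for members in groups.values():
        if len(members) < 2:
            continue
        keeper = max(members, key=lambda fid: (qual_sum(fid), fid))
        flagged.update(fid for fid in members if fid != keeper)
    return [
        replace(obs, duplicate=True) if obs.id in flagged else obs
        for obs in alignments
    ]


def classify_fragments(
    universe_ids: Iterable[str],
    graft_alignments: Iterable[AlignmentObservation],
    host_alignments: Iterable[AlignmentObservation],
    cfg: Optional[ClassifyConfig] = None,
) -> SpeciesPartition:
    """End-to-end: gate both alignment sets and partition the universe."""
    cfg = cfg or ClassifyConfig()
    universe = set(universe_ids)
    graft_mapped = collect_mapped_ids(graft_alignments, cfg) & universe
    host_mapped = collect_mapped_ids(host_alignments, cfg) & universe
    return partition_ids(universe, graft_mapped, host_mapped)
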