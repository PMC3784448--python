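"""End-to-end helpers wiring the aligner, classifier and truth evaluation.

These are the in-memory equivalents of the file-based CLI workflow: align a
read mixture against both genomes, gate and partition the fragments, and (on
synthetic data) score the partition against truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .classify import ClassifyConfig, SpeciesPartition, classify_fragments
from .microalign import AlignmentHit, SeedIndex, align_pair
from .readio import AlignmentObservation, ReadPair
from .simulate import TruthLabel


def _hit_to_observation(
    hit: Optional[AlignmentHit], pair_id: str, mate: int, proper: bool
) -> AlignmentObservation:
    if hit is None:
        return AlignmentObservation(
            id=pair_id, mate=mate, mapped=False, mapq=0, proper_pair=False,
            reference=None, position=None, strand=None,
        )
    return AlignmentObservation(
        id=pair_id, mate=mate, mapped=True, mapq=hit.mapq_like, proper_pair=proper,
        reference=hit.reference, position=hit.position, strand=hit.strand,
    )


def align_pairs(
    reads: Sequence[ReadPair],
    index: SeedIndex,
    insert_min: int = 50,
    insert_max: int = 600,
    max_mismatch: int = 5,
) -> list[AlignmentObservation]:
    """Align every pair against one genome, returning flat observations."""
    obs: list[AlignmentObservation] = []
    for pair in reads:
        h1, h2, proper = align_pair(pair, index, insert_min, insert_max, max_mismatch)
        obs.append(_hit_to_observation(h1, pair.id, 1, proper))
        obs.append(_hit_to_observation(h2, pair.id, 2, proper))
    return obs


def deconvolve(
    reads: Sequence[ReadPair],
    graft_index: SeedIndex,
    host_index: SeedIndex,
    cfg: Optional[ClassifyConfig] = None,
    insert_min: int = 50,
    insert_max: int = 600,
    max_mismatch: int = 5,
) -> SpeciesPartition:
    """Align a read mixture to both genomes and partition the fragments."""
    graft_obs = align_pairs(reads, graft_index, insert_min, insert_max, max_mismatch)
    host_obs = align_pairs(reads, host_index, insert_min, insert_max, max_mismatch)
    return classify_fragments((p.id for p in reads), graft_obs, host_obs, cfg)


@dataclass
class RecoveryReport:
    """Agreement between a species partition and simulation truth labels."""

    n_classified: int  # fragments placed in graft- or host-specific sets
    n_correct: int
    n_common: int
    n_unmapped: int
    estimated_host_fraction: float  # host / (host + graft) among specific sets
    true_host_fraction: float

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_classified if self.n_classified else float("nan")


def score_partition(
    partition: SpeciesPartition, labels: Sequence[TruthLabel]
) -> RecoveryReport:
    """Score GRAFT/HOST-classified fragments against their truth labels."""
    origin = {lb.fragment_id: lb.origin for lb in labels}
    n_correct = sum(1 for fid in partition.graft_specific if origin.get(fid) == "GRAFT")
    n_correct += sum(1 for fid in partition.host_specific if origin.get(fid) == "HOST")
    n_graft = len(partition.graft_specific)
    n_host = len(partition.host_specific)
    n_classified = n_graft + n_host
    est = n_host / n_classified if n_classified else float("nan")
    true_host = sum(1 for lb in labels if lb.origin == "HOST") / max(len(labels), 1)
    return RecoveryReport(
        n_classified=n_classified,
        n_correct=n_correct,
        n_common=len(partition.common),
        n_unmapped=len(partition.unmapped),
        estimated_host_fraction=est,
        true_host_fraction=true_host,
    )
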