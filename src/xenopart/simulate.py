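"""Synthetic xenograft data: genome pairs, mixed reads, gene models, variants.

The generator emulates the structure of a xenograft sequencing experiment —
two homologous genomes (graft ~ human tumour, host ~ mouse) at configurable
divergence, paired-end reads drawn from a mixture of the two with truth
labels, exonic read sampling against a gene model for expression tests, and
subclonal spike-in variants at configurable allele fractions. Every operation
is a pure function of its inputs and a seed.

Defaults follow the sequencing design the pipeline targets: 101 nt paired-end
reads, 200 bp inserts, and a human/mouse-like divergence of 0.12 per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .microalign import reverse_complement
from .readio import ReadPair, ReadRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class GenomePair:
    """Synthetic graft/host genomes plus the site correspondence map.

    ``correspondence[i]`` is the host coordinate homologous to graft
    coordinate ``i``, or -1 where the host lineage deleted the site. The map
    is strictly increasing over its defined domain.
    """

    graft_sequence: str
    host_sequence: str
    divergence: float
    correspondence: np.ndarray
    seed: int


@dataclass
class SimParams:
    """Read-mixture simulation parameters (101 nt reads, 200 bp inserts)."""

    n_pairs: int
    host_fraction: float
    read_length: int = 101
    insert_mean: int = 200
    insert_sd: float = 20.0
    error_rate: float = 0.0
    seed: int = 0
    base_quality: int = 37

    def __post_init__(self) -> None:
        if not 0.0 <= self.host_fraction <= 1.0:
            raise ValueError("host_fraction must be in [0, 1]")
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")


@dataclass
class TruthLabel:
    """Ground-truth origin of one simulated fragment.

    ``insert_length`` is carried so downstream spiking can reconstruct each
    mate's genomic span without re-parsing reads.
    """

    fragment_id: str
    origin: str  # GRAFT | HOST
    source_position: int  # 0-based leftmost fragment coordinate
    source_strand: str  # + | -
    insert_length: int = 0


@dataclass
class SpikeVariant:
    """A subclonal SNV to plant into graft-origin reads (0-based position)."""

    position: int
    ref_base: str
    alt_base: str
    vaf: float

    def __post_init__(self) -> None:
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base must differ from ref_base")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError("vaf must be in [0, 1]")


def _substitution_rate(divergence: float) -> float:
    # Each lineage substitutes independently at rate q (uniform among the
    # other 3 bases). Pairwise difference probability:
    #   P(diff) = 2 q (1-q) + q^2 * (2/3)
    # Solve (4/3) q^2 - 2 q + D = 0 for the small root.
    if divergence == 0.0:
        return 0.0
    disc = 4.0 - (16.0 / 3.0) * divergence
    return (2.0 - float(np.sqrt(disc))) / (8.0 / 3.0)


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate``, uniform over the other 3."""
    out = arr.copy()
    mask = rng.random(arr.size) < rate
    n = int(mask.sum())
    if n:
        idx = np.searchsorted(_BASES, out[mask])  # ACGT are sorted bytes
        shift = rng.integers(1, 4, size=n)
        out[mask] = _BASES[(idx + shift) % 4]
    return out


def evolve_genomes(
    ancestor_length: int,
    divergence: float,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> GenomePair:
    """Draw a random ancestor and evolve two lineages from it.

    Substitutions are applied independently to each lineage so the expected
    pairwise divergence at corresponding sites equals ``divergence``. Host
    indels (geometric lengths, mean 2) optionally perturb the correspondence.
    """
    if not 0.0 <= divergence < 0.75:
        raise ValueError("divergence must be in [0, 0.75)")
    if ancestor_length < 1000:
        raise ValueError("ancestor_length must be >= 1000")
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(_BASES, size=ancestor_length)
    q = _substitution_rate(divergence)
    graft = _mutate(ancestor, q, rng)
    host = _mutate(ancestor, q, rng)
    if indel_rate > 0.0:
        host, correspondence = _apply_host_indels(host, indel_rate, rng)
    else:
        correspondence = np.arange(ancestor_length, dtype=np.int64)
    return GenomePair(
        graft_sequence=graft.tobytes().decode("ascii"),
        host_sequence=host.tobytes().decode("ascii"),
        divergence=divergence,
        correspondence=correspondence,
        seed=seed,
    )


def _apply_host_indels(
    host: np.ndarray, indel_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = host.size
    event_sites = np.nonzero(rng.random(n) < indel_rate)[0]
    corr = np.arange(n, dtype=np.int64)
    pieces: list[np.ndarray] = []
    prev = 0
    offset = 0
    for site in event_sites:
        if site < prev:
            continue
        length = min(int(rng.geometric(0.5)), 10)
        pieces.append(host[prev:site])
        if rng.random() < 0.5:  # deletion from host
            corr[site : site + length] = -1
            corr[site + length :] -= length
            prev = site + length
        else:  # insertion into host
            pieces.append(rng.choice(_BASES, size=length))
            corr[site:] += length
            offset += length
            prev = site
    pieces.append(host[prev:])
    new_host = np.concatenate(pieces)
    corr = np.where(corr >= 0, np.clip(corr, -1, new_host.size - 1), -1)
    return new_host, corr


def observed_divergence(pair: GenomePair) -> float:
    """Mismatch fraction at corresponding (non-deleted) sites."""
    g = np.frombuffer(pair.graft_sequence.encode(), dtype=np.uint8)
    h = np.frombuffer(pair.host_sequence.encode(), dtype=np.uint8)
    dom = pair.correspondence >= 0
    return float(np.mean(g[dom] != h[dom]))


def simulate_mixture(
    pair: GenomePair, params: SimParams
) -> tuple[list[ReadPair], list[TruthLabel]]:
    """Draw paired-end fragments from a graft/host mixture with truth labels.

    Fragment origin is Bernoulli(host_fraction); start positions are uniform;
    insert lengths are normal, truncated to [read_length, genome length];
    mate2 is sequenced from the opposite strand; sequencing errors are applied
    per base at ``error_rate``. Fragment ids (``FRAG000001`` …) carry no
    origin information — truth travels separately as labels.
    """
    rng = np.random.default_rng(params.seed)
    n, rl = params.n_pairs, params.read_length
    genomes = {"GRAFT": pair.graft_sequence, "HOST": pair.host_sequence}
    for name, g in genomes.items():
        if len(g) <= params.insert_mean + 6 * params.insert_sd:
            raise ValueError(f"{name} genome too short for the insert distribution")
    origins = np.where(rng.random(n) < params.host_fraction, "HOST", "GRAFT")
    inserts = np.rint(rng.normal(params.insert_mean, params.insert_sd, size=n)).astype(
        np.int64
    )
    inserts = np.clip(inserts, rl, None)
    strands = np.where(rng.integers(0, 2, size=n) == 0, "+", "-")
    u = rng.random(n)
    err_mask = (
        rng.random((n, 2, rl)) < params.error_rate if params.error_rate > 0 else None
    )
    qual = [params.base_quality] * rl
    reads: list[ReadPair] = []
    labels: list[TruthLabel] = []
    for i in range(n):
        genome = genomes[origins[i]]
        glen = len(genome)
        insert = int(min(inserts[i], glen))
        start = int(u[i] * (glen - insert + 1))
        end = start + insert
        fwd = genome[start : start + rl]
        rev = reverse_complement(genome[end - rl : end])
        if strands[i] == "+":
            s1, s2 = fwd, rev
        else:
            s1, s2 = rev, fwd
        if err_mask is not None:
            s1 = _apply_errors(s1, err_mask[i, 0], rng)
            s2 = _apply_errors(s2, err_mask[i, 1], rng)
        fid = f"FRAG{i + 1:06d}"
        reads.append(
            ReadPair(
                fid,
                ReadRecord(fid, 1, s1, list(qual)),
                ReadRecord(fid, 2, s2, list(qual)),
            )
        )
        labels.append(
            TruthLabel(
                fragment_id=fid,
                origin=str(origins[i]),
                source_position=start,
                source_strand=str(strands[i]),
                insert_length=insert,
            )
        )
    return reads, labels


def _apply_errors(seq: str, mask: np.ndarray, rng: np.random.Generator) -> str:
    sites = np.nonzero(mask)[0]
    if sites.size == 0:
        return seq
    buf = bytearray(seq, "ascii")
    for p in sites:
        old = chr(buf[p])
        choices = [b for b in "ACGT" if b != old]
        buf[p] = ord(choices[int(rng.integers(0, 3))])
    return buf.decode("ascii")


def _mate_layout(label: TruthLabel, read_length: int):
    """Genomic span and orientation of each mate: (start, end, is_forward)."""
    start = label.source_position
    end = start + label.insert_length
    left = (start, start + read_length, True)
    right = (end - read_length, end, False)
    if label.source_strand == "+":
        return left, right
    return (right[0], right[1], False), (left[0], left[1], True)


def spike_variants(
    pair: GenomePair,
    reads: Sequence[ReadPair],
    labels: Sequence[TruthLabel],
    variants: Sequence[SpikeVariant],
    seed: int = 0,
) -> list[ReadPair]:
    """Plant subclonal variants into graft-origin reads.

    Each graft fragment covering a variant site carries the alternate allele
    with probability ``vaf``; the draw is made once per fragment so both mates
    agree. Host fragments are never edited.
    """
    for v in variants:
        if not 0 <= v.position < len(pair.graft_sequence):
            raise ValueError(f"variant position {v.position} outside graft genome")
        if pair.graft_sequence[v.position] != v.ref_base:
            raise ValueError(
                f"variant ref {v.ref_base!r} at {v.position} does not match genome "
                f"base {pair.graft_sequence[v.position]!r}"
            )
    rng = np.random.default_rng(seed)
    out = list(reads)
    by_id = {rp.id: i for i, rp in enumerate(reads)}
    for label in labels:
        if label.origin != "GRAFT":
            continue
        frag_start = label.source_position
        frag_end = frag_start + label.insert_length
        rp = out[by_id[label.fragment_id]]
        rl = len(rp.mate1.sequence)
        edited = None
        for v in variants:
            if not frag_start <= v.position < frag_end:
                continue
            if rng.random() >= v.vaf:
                continue
            if edited is None:
                edited = ReadPair(
                    rp.id,
                    replace(rp.mate1, qualities=list(rp.mate1.qualities)),
                    replace(rp.mate2, qualities=list(rp.mate2.qualities)),
                )
            layouts = _mate_layout(label, rl)
            mates = [edited.mate1, edited.mate2]
            for mi, (mstart, mend, is_fwd) in enumerate(layouts):
                if not mstart <= v.position < mend:
                    continue
                mate = mates[mi]
                if is_fwd:
                    offset = v.position - mstart
                    base = v.alt_base
                else:
                    offset = mend - 1 - v.position
                    base = _COMPLEMENT_BASE[v.alt_base]
                mate.sequence = (
                    mate.sequence[:offset] + base + mate.sequence[offset + 1 :]
                )
        if edited is not None:
            out[by_id[label.fragment_id]] = edited
    return out


_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def generate_spike_variants(
    pair: GenomePair,
    n_variants: int,
    vaf: float,
    transition_fraction: float = 2.0 / 3.0,
    min_spacing: int = 150,
    seed: int = 0,
) -> list[SpikeVariant]:
    """Draw spaced SNV sites with a configurable transition:transversion mix.

    ``transition_fraction`` is the probability that a variant is a transition
    (A<->G, C<->T); the remainder splits evenly over the two transversions.
    """
    rng = np.random.default_rng(seed)
    glen = len(pair.graft_sequence)
    positions: list[int] = []
    taken = np.zeros(glen, dtype=bool)
    attempts = 0
    while len(positions) < n_variants and attempts < 100 * n_variants:
        attempts += 1
        p = int(rng.integers(0, glen))
        lo, hi = max(0, p - min_spacing), min(glen, p + min_spacing)
        if taken[lo:hi].any():
            continue
        taken[p] = True
        positions.append(p)
    if len(positions) < n_variants:
        raise ValueError("could not place variants with the requested spacing")
    variants = []
    for p in sorted(positions):
        ref = pair.graft_sequence[p]
        if rng.random() < transition_fraction:
            alt = _TRANSITIONS[ref]
        else:
            alt = _TRANSVERSIONS[ref][int(rng.integers(0, 2))]
        variants.append(SpikeVariant(position=p, ref_base=ref, alt_base=alt, vaf=vaf))
    return variants


def generate_gene_model(
    genome_length: int,
    n_genes: int,
    exons_per_gene: tuple[int, int] = (1, 4),
    exon_length: tuple[int, int] = (200, 500),
    intron_length: tuple[int, int] = (60, 200),
    gene_gap: int = 100,
    chrom: str = "ref",
    seed: int = 0,
):
    """Pack non-overlapping genes with sorted non-overlapping exons.

    Returns a list of :class:`xenopart.quantify.GeneModel` laid out left to
    right; raises when the requested genes cannot fit in ``genome_length``.
    """
    from .quantify import GeneModel

    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    cursor = int(rng.integers(0, gene_gap + 1))
    for gi in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        exons = []
        pos = cursor
        for ei in range(n_ex):
            ln = int(rng.integers(exon_length[0], exon_length[1] + 1))
            exons.append((pos, pos + ln))
            pos += ln
            if ei < n_ex - 1:
                pos += int(rng.integers(intron_length[0], intron_length[1] + 1))
        if pos > genome_length:
            raise ValueError(
                f"cannot fit gene {gi + 1}/{n_genes} within genome of "
                f"length {genome_length}"
            )
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        genes.append(
            GeneModel(gene_id=f"GENE{gi + 1:04d}", chrom=chrom, strand=strand, exons=exons)
        )
        cursor = pos + gene_gap
    return genes


def simulate_exonic_mixture(
    pair: GenomePair,
    genes,
    params: SimParams,
    dirichlet_alpha: float = 1.0,
) -> tuple[list[ReadPair], list[TruthLabel], dict[str, str]]:
    """RNA-seq-like mixture: graft fragments drawn from exonic intervals only.

    Graft fragments pick a gene with Dirichlet-drawn abundance weights, then an
    exon long enough to hold the fragment (probability proportional to the
    number of valid start positions). Host fragments are drawn genome-wide, as
    stromal DNA contamination would be. Returns reads, truth labels, and the
    source gene of each graft fragment.
    """
    rng = np.random.default_rng(params.seed)
    n, rl = params.n_pairs, params.read_length
    insert = params.insert_mean  # fixed insert keeps fragments inside exons
    eligible = []
    for g in genes:
        slots = [(s, e) for s, e in g.exons if e - s >= insert]
        if slots:
            eligible.append((g, slots))
    if not eligible:
        raise ValueError("no exon can hold a fragment of insert_mean length")
    weights = rng.dirichlet([dirichlet_alpha] * len(eligible))
    qual = [params.base_quality] * rl
    reads: list[ReadPair] = []
    labels: list[TruthLabel] = []
    gene_of: dict[str, str] = {}
    host_len = len(pair.host_sequence)
    for i in range(n):
        fid = f"FRAG{i + 1:06d}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if rng.random() < params.host_fraction:
            start = int(rng.integers(0, host_len - insert + 1))
            genome, origin = pair.host_sequence, "HOST"
        else:
            gi = int(rng.choice(len(eligible), p=weights))
            gene, slots = eligible[gi]
            caps = np.array([e - s - insert + 1 for s, e in slots], dtype=float)
            si = int(rng.choice(len(slots), p=caps / caps.sum()))
            start = int(rng.integers(slots[si][0], slots[si][1] - insert + 1))
            genome, origin = pair.graft_sequence, "GRAFT"
            gene_of[fid] = gene.gene_id
        end = start + insert
        fwd = genome[start : start + rl]
        rev = reverse_complement(genome[end - rl : end])
        s1, s2 = (fwd, rev) if strand == "+" else (rev, fwd)
        reads.append(
            ReadPair(
                fid,
                ReadRecord(fid, 1, s1, list(qual)),
                ReadRecord(fid, 2, s2, list(qual)),
            )
        )
        labels.append(TruthLabel(fid, origin, start, strand, insert))
    return reads, labels, gene_of


def truth_alignments(
    reads: Sequence[ReadPair],
    labels: Sequence[TruthLabel],
    origin: str = "GRAFT",
    reference: str = "graft",
    mapq: int = 60,
):
    """Perfect-knowledge alignments of one origin's fragments.

    Places each mate of the selected fragments at its true source coordinate,
    reference-oriented (reverse mates stored as their reverse complement, as a
    SAM record would), bypassing the aligner. Useful as a truth oracle for
    pileup and fragment-assignment tests.
    """
    from .readio import AlignmentObservation

    by_id = {rp.id: rp for rp in reads}
    obs = []
    for lb in labels:
        if lb.origin != origin:
            continue
        rp = by_id[lb.fragment_id]
        rl = len(rp.mate1.sequence)
        layouts = _mate_layout(lb, rl)
        for mate, (mstart, mend, is_fwd) in zip((rp.mate1, rp.mate2), layouts):
            seq = mate.sequence if is_fwd else reverse_complement(mate.sequence)
            quals = mate.qualities if is_fwd else mate.qualities[::-1]
            obs.append(
                AlignmentObservation(
                    id=lb.fragment_id, mate=mate.mate, mapped=True, mapq=mapq,
                    proper_pair=True, reference=reference, position=mstart + 1,
                    strand="+" if is_fwd else "-", sequence=seq,
                    qualities=list(quals), ref_span=rl,
                )
            )
    return obs


def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    """Write sequences as FASTA (plain text)."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_labels(path, labels: Iterable[TruthLabel]) -> None:
    with open(path, "w") as fh:
        fh.write("fragment_id\torigin\tsource_position\tsource_strand\tinsert_length\n")
        for lb in labels:
            fh.write(
                f"{lb.fragment_id}\t{lb.origin}\t{lb.source_position}\t"
                f"{lb.source_strand}\t{lb.insert_length}\n"
            )


def write_spike_variants(path, variants: Iterable[SpikeVariant]) -> None:
    with open(path, "w") as fh:
        fh.write("position\tref\talt\tvaf\n")
        for v in variants:
            fh.write(f"{v.position}\t{v.ref_base}\t{v.alt_base}\t{v.vaf}\n")
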