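"""Somatic-variant post-processing: pileup, hard filters, rescue, host check.

Variant *calling* is deliberately out of scope — this layer consumes VCF from
any caller and implements the downstream analysis: per-locus allele counting
with base-quality / MAPQ / pair gating, hard filtering (depth, call quality,
Fisher strand bias, SNP clusters), germline subtraction, known/novel
annotation against a dbSNP-like table, strand-collapsed mutation spectra, the
allele-frequency rescue classification of variants discordant between two
samples of the same tumour, and the 1,000 bp host-contamination window check.

Default thresholds: depth >= 5, QUAL >= 50, FisherStrand < 60 (Phred-scaled),
SNP clusters of >= 3 SNVs within 10 bp, rescue allele-fraction threshold 0.2
at depth >= 10, pileup base quality >= 20.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .microalign import SeedIndex, align_read
from .readio import AlignmentObservation, ReadRecord

FS_CAP = 10000.0

FILTER_LOW_DEPTH = "LowDepth"
FILTER_LOW_QUAL = "LowQual"
FILTER_STRAND_BIAS = "StrandBias"
FILTER_SNP_CLUSTER = "SnpCluster"
_HARD_FILTERS = {
    FILTER_LOW_DEPTH,
    FILTER_LOW_QUAL,
    FILTER_STRAND_BIAS,
    FILTER_SNP_CLUSTER,
}


class RescueCategory(enum.Enum):
    """Outcome of re-examining a discordant variant in the counterpart sample."""

    CALLED = "CALLED"
    DETECTED_BELOW_THRESHOLD = "DETECTED_BELOW_THRESHOLD"
    NOT_DETECTED_LOW_DEPTH = "NOT_DETECTED_LOW_DEPTH"
    NOT_DETECTED_NO_ALT = "NOT_DETECTED_NO_ALT"


@dataclass
class VariantRecord:
    """One called variant reduced to the fields the filters need."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    depth: int
    allele_depths: tuple[int, int]  # (ref_count, alt_count)
    strand_table: Optional[tuple[int, int, int, int]] = None  # rf, rr, af, ar
    genotype: str = "het"
    filters: set = field(default_factory=set)
    known: Optional[bool] = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in "ACGT"
            and self.alt in "ACGT"
        )

    @property
    def allele_fraction(self) -> float:
        if self.depth == 0:
            return 0.0
        return self.allele_depths[1] / self.depth


@dataclass
class FilterConfig:
    """Hard-filter and rescue thresholds (see module docstring for defaults)."""

    min_depth: int = 5
    min_qual: float = 50.0
    max_fs: float = 60.0
    cluster_count: int = 3
    cluster_window: int = 10
    min_af_call: float = 0.2
    rescue_min_depth: int = 10
    min_base_quality: int = 20

    def __post_init__(self) -> None:
        for name in (
            "min_depth",
            "min_qual",
            "max_fs",
            "cluster_count",
            "cluster_window",
            "min_af_call",
            "rescue_min_depth",
            "min_base_quality",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PileupCounts:
    """Strand-resolved base counts at one locus after read/base gating."""

    chrom: str
    pos: int  # 1-based
    base_counts: dict  # base -> (fwd, rev)
    excluded_mapq_unavailable: int = 0
    excluded_improper: int = 0
    excluded_duplicate: int = 0
    excluded_low_baseq: int = 0

    @property
    def depth_after_filters(self) -> int:
        return sum(f + r for f, r in self.base_counts.values())

    def count_of(self, base: str) -> int:
        f, r = self.base_counts.get(base.upper(), (0, 0))
        return f + r

    def strand_table(self, ref: str, alt: str) -> tuple[int, int, int, int]:
        rf, rr = self.base_counts.get(ref.upper(), (0, 0))
        af, ar = self.base_counts.get(alt.upper(), (0, 0))
        return (rf, rr, af, ar)


def pileup_allele_counts(
    alignments: Iterable[AlignmentObservation],
    chrom: str,
    pos: int,
    min_base_q: int = 20,
    use_dedup: bool = True,
    require_proper_pair: bool = True,
) -> PileupCounts:
    """Count bases covering ``(chrom, pos)`` (1-based) with quality gating.

    Records that are MAPQ-unavailable (255), duplicate-flagged (when
    ``use_dedup``), or improperly paired are excluded and tallied. Bases below
    ``min_base_q`` are excluded. Reads whose aligned span differs from their
    sequence length (indel-containing alignments) are skipped: extraction here
    assumes ungapped placements. A locus nobody covers yields zero depth.
    """
    counts: dict[str, tuple[int, int]] = {}
    excl_mapq = excl_improper = excl_dup = excl_baseq = 0
    for obs in alignments:
        if not obs.mapped or not obs.primary or obs.reference != chrom:
            continue
        if obs.sequence is None:
            continue
        span = obs.ref_span if obs.ref_span is not None else len(obs.sequence)
        offset = pos - obs.position
        if not 0 <= offset < span:
            continue
        if obs.mapq_unavailable:
            excl_mapq += 1
            continue
        if use_dedup and obs.duplicate:
            excl_dup += 1
            continue
        if require_proper_pair and not obs.proper_pair:
            excl_improper += 1
            continue
        if span != len(obs.sequence):
            continue
        if obs.qualities is not None and obs.qualities[offset] < min_base_q:
            excl_baseq += 1
            continue
        base = obs.sequence[offset].upper()
        f, r = counts.get(base, (0, 0))
        if obs.strand == "-":
            counts[base] = (f, r + 1)
        else:
            counts[base] = (f + 1, r)
    return PileupCounts(
        chrom=chrom,
        pos=pos,
        base_counts=counts,
        excluded_mapq_unavailable=excl_mapq,
        excluded_improper=excl_improper,
        excluded_duplicate=excl_dup,
        excluded_low_baseq=excl_baseq,
    )


def fisher_strand_phred(table: tuple[int, int, int, int]) -> float:
    """Phred-scaled two-sided Fisher exact p for ref/alt x fwd/rev counts.

    Returns -10*log10(p), capped at 10,000 so a numerically-zero p stays
    finite. Perfectly balanced tables (independence) give 0.
    """
    rf, rr, af, ar = table
    if any(c < 0 for c in table):
        raise ValueError("strand table counts must be non-negative")
    if rf + rr + af + ar == 0:
        raise ValueError("strand table is all zero")
    _, p = stats.fisher_exact([[rf, rr], [af, ar]], alternative="two-sided")
    if p <= 0:
        return FS_CAP
    return float(min(FS_CAP, max(0.0, -10.0 * np.log10(p))))


def flag_snp_clusters(
    records: Sequence[VariantRecord],
    cluster_count: int = 3,
    cluster_window: int = 10,
) -> list[VariantRecord]:
    """Tag SNVs occurring in dense local runs (alignment-artifact hallmark).

    Any SNV belonging to a run of >= ``cluster_count`` SNVs on one chromosome
    spanning at most ``cluster_window`` bases receives the SnpCluster tag.
    Input must be sorted by (chrom, pos); indels never participate.
    """
    keys = [(r.chrom, r.pos) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, pos)")
    out = [replace(r, filters=set(r.filters) - {FILTER_SNP_CLUSTER}) for r in records]
    snv_idx = [i for i, r in enumerate(out) if r.is_snv]
    c = cluster_count
    for j in range(len(snv_idx) - c + 1):
        first, last = out[snv_idx[j]], out[snv_idx[j + c - 1]]
        if first.chrom != last.chrom:
            continue
        if last.pos - first.pos <= cluster_window:
            for i in snv_idx[j : j + c]:
                out[i].filters.add(FILTER_SNP_CLUSTER)
    return out


def apply_hard_filters(
    records: Sequence[VariantRecord], cfg: Optional[FilterConfig] = None
) -> list[VariantRecord]:
    """Attach {LowDepth, LowQual, StrandBias, SnpCluster} tags; PASS if none.

    Previous hard-filter tags are recomputed from scratch, so the operation is
    idempotent. Input order is preserved.
    """
    cfg = cfg or FilterConfig()
    out = []
    for r in records:
        if r.depth is None or r.qual is None:
            raise ValueError(f"record {r.chrom}:{r.pos} lacks depth or qual")
        tags = set(r.filters) - _HARD_FILTERS
        if r.depth < cfg.min_depth:
            tags.add(FILTER_LOW_DEPTH)
        if r.qual < cfg.min_qual:
            tags.add(FILTER_LOW_QUAL)
        if r.strand_table is None:
            raise ValueError(f"record {r.chrom}:{r.pos} lacks a strand table")
        if sum(r.strand_table) > 0 and fisher_strand_phred(r.strand_table) >= cfg.max_fs:
            tags.add(FILTER_STRAND_BIAS)
        out.append(replace(r, filters=tags))
    return flag_snp_clusters(out, cfg.cluster_count, cfg.cluster_window)


def passing(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    return [r for r in records if not r.filters]


def subtract_germline(
    sample: Iterable[VariantRecord], control: Iterable[VariantRecord]
) -> list[VariantRecord]:
    """Somatic set: sample variants whose (chrom, pos, ref, alt) key is absent
    from the matched control (e.g. peripheral blood)."""
    control_keys = {r.key for r in control}
    return [r for r in sample if r.key not in control_keys]


@dataclass
class KnownNovelSummary:
    n_known: int
    n_novel: int

    @property
    def known_to_novel_ratio(self) -> float:
        return self.n_known / self.n_novel if self.n_novel else float("inf")


def load_known_sites(path) -> set[tuple[str, int, str, str]]:
    """Load a dbSNP-like TSV of (chrom, pos, ref, alt) known sites."""
    sites = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected chrom/pos/ref/alt")
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad position {fields[1]!r}") from exc
            sites.add((fields[0], pos, fields[2].upper(), fields[3].upper()))
    return sites


def annotate_known(
    somatic: Sequence[VariantRecord],
    known_sites: set,
) -> tuple[list[VariantRecord], KnownNovelSummary]:
    """Flag variants present in the known-sites catalogue; report the ratio."""
    out = [replace(r, known=(r.key in known_sites)) for r in somatic]
    n_known = sum(1 for r in out if r.known)
    return out, KnownNovelSummary(n_known=n_known, n_novel=len(out) - n_known)


_PURINE = {"A", "G"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

SPECTRUM_CLASSES = (
    "A>C/T>G",
    "A>G/T>C",
    "A>T/T>A",
    "G>A/C>T",
    "G>C/C>G",
    "G>T/C>A",
)


def substitution_class(ref: str, alt: str) -> str:
    """Strand-collapsed class of a substitution, written purine-ref first."""
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref == alt is not a substitution")
    if ref not in _COMP or alt not in _COMP:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if ref not in _PURINE:
        ref, alt = _COMP[ref], _COMP[alt]
    return f"{ref}>{alt}/{_COMP[ref]}>{_COMP[alt]}"


def mutation_spectrum(
    snvs: Iterable[VariantRecord],
) -> tuple[dict[str, int], dict[str, float]]:
    """Counts and proportions over the six strand-collapsed SNV classes."""
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    n = 0
    for r in snvs:
        if not r.is_snv:
            raise ValueError(
                f"record {r.chrom}:{r.pos} {r.ref}>{r.alt} is not a single-base SNV"
            )
        counts[substitution_class(r.ref, r.alt)] += 1
        n += 1
    proportions = {c: (counts[c] / n if n else 0.0) for c in SPECTRUM_CLASSES}
    return counts, proportions


def rescue_classify(
    variant: VariantRecord,
    counterpart: PileupCounts,
    cfg: Optional[FilterConfig] = None,
) -> RescueCategory:
    """Classify a variant absent from the counterpart sample's call set.

    Direct pileup in the counterpart distinguishes a subclonal presence
    (alt seen but allele fraction < 0.2), inadequate coverage (depth < 10),
    and genuine absence (adequate depth, no alt reads).
    """
    cfg = cfg or FilterConfig()
    depth = counterpart.depth_after_filters
    alt = counterpart.count_of(variant.alt)
    if depth < cfg.rescue_min_depth:
        return RescueCategory.NOT_DETECTED_LOW_DEPTH
    af = alt / depth
    if af >= cfg.min_af_call:
        return RescueCategory.CALLED
    if alt >= 1:
        return RescueCategory.DETECTED_BELOW_THRESHOLD
    return RescueCategory.NOT_DETECTED_NO_ALT


def host_window_check(
    chrom: str,
    pos: int,
    graft_alignments: Iterable[AlignmentObservation],
    host_index: SeedIndex,
    window: int = 1000,
    max_mismatch: int = 3,
) -> tuple[int, int]:
    """Try to align the reads around a variant locus to the host genome.

    Extracts reads whose graft alignments overlap [pos - window, pos + window]
    and attempts to align each against the host genome; returns
    (reads_examined, reads_host_alignable). Zero alignable reads supports a
    graft (not host-contamination) origin for the variant.

    The default mismatch budget (3 over a 101 nt read, ~3%) mirrors the edit
    distance stringency short-read DNA aligners apply; at human/mouse-like
    divergence a genuine graft read then has a ~1e-3 chance of a spurious
    host placement, while a genuine host read (sequencing error ~0.1%) aligns
    essentially always.
    """
    lo, hi = pos - window, pos + window
    examined = alignable = 0
    for obs in graft_alignments:
        if not obs.mapped or obs.reference != chrom or obs.sequence is None:
            continue
        span = obs.ref_span if obs.ref_span is not None else len(obs.sequence)
        if obs.position + span - 1 < lo or obs.position > hi:
            continue
        examined += 1
        read = ReadRecord(
            id=obs.id, mate=obs.mate, sequence=obs.sequence,
            qualities=obs.qualities or [30] * len(obs.sequence),
        )
        if align_read(read, host_index, max_mismatch=max_mismatch) is not None:
            alignable += 1
    return examined, alignable
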