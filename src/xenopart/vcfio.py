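"""VCF v4.x reading/writing for the variant post-processing layer (pysam).

Multi-allelic records are split into bi-allelic :class:`VariantRecord` objects
on ingest, with per-allele depths carried along. Filter tags are written back
to the FILTER column and the known/novel flag to ``INFO/KNOWN``.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pysam

from .variants import (
    FILTER_LOW_DEPTH,
    FILTER_LOW_QUAL,
    FILTER_SNP_CLUSTER,
    FILTER_STRAND_BIAS,
    VariantRecord,
)

_FILTER_DESCRIPTIONS = {
    FILTER_LOW_DEPTH: "Depth of coverage below threshold",
    FILTER_LOW_QUAL: "Call quality below threshold",
    FILTER_STRAND_BIAS: "Phred-scaled Fisher strand-bias at or above threshold",
    FILTER_SNP_CLUSTER: "SNV within a dense local cluster",
}


def read_vcf(path) -> list[VariantRecord]:
    """Read VCF into VariantRecords, splitting multi-allelic sites."""
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        has_dp = "DP" in vcf.header.info
        has_sb = "SB" in vcf.header.info
        has_known = "KNOWN" in vcf.header.info
        for rec in vcf:
            depth = rec.info.get("DP") if has_dp else None
            sb = rec.info.get("SB") if has_sb else None
            sample = rec.samples[0] if rec.samples else None
            ad = sample.get("AD") if sample is not None else None
            gt = sample.get("GT") if sample is not None else None
            filters = set(rec.filter.keys()) - {"PASS", "."}
            for ai, alt in enumerate(rec.alts or (), start=1):
                ref_count = int(ad[0]) if ad else 0
                alt_count = int(ad[ai]) if ad and len(ad) > ai else 0
                if depth is None:
                    dp = ref_count + alt_count
                else:
                    dp = int(depth)
                genotype = "het"
                if gt and all(a == ai for a in gt if a is not None):
                    genotype = "hom"
                strand_table = None
                if sb is not None and len(rec.alts) == 1 and len(sb) == 4:
                    strand_table = tuple(int(x) for x in sb)
                known = rec.info.get("KNOWN") if has_known else None
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        depth=dp,
                        allele_depths=(ref_count, alt_count),
                        strand_table=strand_table,
                        genotype=genotype,
                        filters=set(filters),
                        known=bool(known) if known is not None else None,
                    )
                )
    return records


def _build_header(
    contigs: dict[str, int], sample: str = "SAMPLE"
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("DP", 1, "Integer", "Usable depth of coverage")
    header.info.add(
        "SB", 4, "Integer", "Strand counts: ref-fwd, ref-rev, alt-fwd, alt-rev"
    )
    header.info.add("KNOWN", 0, "Flag", "Present in the known-sites catalogue")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Per-allele read depths")
    for tag, desc in _FILTER_DESCRIPTIONS.items():
        header.filters.add(tag, None, None, desc)
    header.add_sample(sample)
    return header


def write_vcf(
    path,
    records: Sequence[VariantRecord],
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Write VariantRecords as uncompressed VCF (filters -> FILTER column)."""
    if contigs is None:
        contigs = {}
        for r in records:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.pos + 1000)
    header = _build_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, r.alt),
                qual=r.qual,
            )
            rec.info["DP"] = r.depth
            if r.strand_table is not None:
                rec.info["SB"] = tuple(int(x) for x in r.strand_table)
            if r.known:
                rec.info["KNOWN"] = True
            if r.filters:
                for tag in sorted(r.filters):
                    rec.filter.add(tag)
            else:
                rec.filter.add("PASS")
            sample = rec.samples[0]
            sample["GT"] = (1, 1) if r.genotype == "hom" else (0, 1)
            sample["AD"] = tuple(int(x) for x in r.allele_depths)
            out.write(rec)
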