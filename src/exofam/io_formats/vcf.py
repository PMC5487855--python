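"""Multi-sample VCF reading/writing on top of pysam.

Reading normalises records to biallelic, left-trimmed form and coerces male
chrX (non-PAR) genotypes to hemizygous states.  QC flags are populated from
the FILTER column (plus an optional INFO-key mapping); the flag statistics
themselves are computed upstream and only carried here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple, Union

import pysam

from .models import (
    QC_FLAGS,
    FormatError,
    Genotype,
    Pedigree,
    Sex,
    VariantRecord,
    is_x_chromosome,
)

log = logging.getLogger(__name__)

_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##FILTER=<ID=low_base_quality,Description="Low base quality">',
    '##FILTER=<ID=low_mapping_quality,Description="Low mapping quality">',
    '##FILTER=<ID=strand_bias,Description="Strand bias">',
    '##FILTER=<ID=aberrant_read_position,Description="Aberrant read position distribution">',
    '##FILTER=<ID=ref_alt_quality_discrepancy,Description="Reference vs alternate quality score discrepancy">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">',
]


def trim_alleles(pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Minimal (left-aligned within the record) allele representation.

    Shared suffix bases are removed first, then shared prefix bases, always
    keeping at least one base of each allele; the position is advanced by the
    number of prefix bases removed.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _diploid_genotype(alt_count: int) -> Genotype:
    return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[alt_count]


def read_vcf(
    path: Union[str, Path],
    pedigree: Pedigree,
    par_regions: Sequence[Tuple[int, int]] = (),
    info_flag_keys: Optional[Mapping[str, str]] = None,
) -> list[VariantRecord]:
    """Read a VCF into biallelic, normalised :class:`VariantRecord` objects.

    Multi-allelic records are split per alternate allele (other alternates
    count as reference for the split record).  Heterozygous calls for males
    on non-PAR chrX are treated as uncallable and coerced to missing.
    """
    path = str(path)
    vf = pysam.VariantFile(path)
    vcf_samples = list(vf.header.samples)
    offenders = [s for s in vcf_samples if s not in pedigree]
    if offenders:
        raise FormatError(
            f"VCF samples not present in pedigree: {sorted(offenders)}"
        )
    if "GT" not in vf.header.formats:
        raise FormatError(f"{path}: VCF has no GT FORMAT field")
    info_flag_keys = dict(info_flag_keys or {})

    records: list[VariantRecord] = []
    for rec in vf:
        if rec.alts is None:
            continue
        flags = set()
        for name in rec.filter.keys():
            if name in QC_FLAGS:
                flags.add(name)
            elif name != "PASS":
                log.warning("%s: ignoring unknown FILTER %r", path, name)
        for info_key, flag in info_flag_keys.items():
            if info_key in rec.info and flag in QC_FLAGS:
                flags.add(flag)

        for alt_index, alt in enumerate(rec.alts, start=1):
            genotypes: dict[str, Genotype] = {}
            alt_depth: dict[str, int] = {}
            pos, ref, alt_trim = trim_alleles(rec.pos, rec.ref, alt)
            hemi_site = is_x_chromosome(rec.chrom, pos, par_regions)
            for sid in vcf_samples:
                call = rec.samples[sid]
                alleles = call.get("GT")
                if alleles is None:
                    raise FormatError(
                        f"{path}: sample {sid} at {rec.chrom}:{rec.pos} has no GT"
                    )
                male = pedigree[sid].sex is Sex.MALE
                called = [a for a in alleles if a is not None]
                if not called:
                    gt = Genotype.MISSING
                else:
                    alt_count = sum(1 for a in called if a == alt_index)
                    if hemi_site and male:
                        if len(called) == 1:
                            gt = Genotype.HEMI_ALT if alt_count else Genotype.HEMI_REF
                        elif len(set(called)) == 1:
                            gt = Genotype.HEMI_ALT if alt_count else Genotype.HEMI_REF
                        else:
                            # het male on X outside PAR: uncallable
                            gt = Genotype.MISSING
                    elif len(called) == 1:
                        # haploid call off chrX / for a female: fold to homozygous
                        gt = Genotype.HOM_ALT if alt_count else Genotype.HOM_REF
                    else:
                        gt = _diploid_genotype(min(alt_count, 2))
                genotypes[sid] = gt
                ad = call.get("AD")
                if ad is not None and len(ad) > alt_index and ad[alt_index] is not None:
                    alt_depth[sid] = int(ad[alt_index])
            variant = VariantRecord(
                chrom=rec.chrom,
                pos=pos,
                ref=ref,
                alt=alt_trim,
                genotypes=genotypes,
                alt_depth=alt_depth,
                qc_flags=frozenset(flags),
            )
            variant.validate_against(pedigree)
            records.append(variant)
    return records


_GT_OUT = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.HEMI_REF: "0",
    Genotype.HEMI_ALT: "1",
    Genotype.MISSING: "./.",
}


def write_vcf(
    variants: Sequence[VariantRecord],
    pedigree: Pedigree,
    path: Union[str, Path],
) -> None:
    """Write plain-text VCF 4.2 with GT:AD per sample, sorted by position.

    Hemizygous genotypes are written haploid; unknown reference depth is
    written as ``.`` in AD.
    """
    sample_ids = [s for s in pedigree.sample_ids]
    contigs = sorted({v.chrom for v in variants}, key=_contig_sort_key)
    with open(path, "w") as fh:
        for line in _HEADER_LINES:
            fh.write(line + "\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for v in sorted(variants, key=lambda v: (_contig_sort_key(v.chrom), v.pos, v.ref, v.alt)):
            filt = ";".join(sorted(v.qc_flags)) if v.qc_flags else "PASS"
            cols = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", filt, ".", "GT:AD"]
            for sid in sample_ids:
                gt = _GT_OUT[v.genotypes.get(sid, Genotype.MISSING)]
                ad = v.alt_depth.get(sid)
                cols.append(f"{gt}:.,{ad}" if ad is not None else f"{gt}:.")
            fh.write("\t".join(cols) + "\n")


def _contig_sort_key(chrom: str) -> Tuple[int, str]:
    from .models import normalize_chrom

    c = normalize_chrom(chrom)
    if c.isdigit():
        return (int(c), "")
    return ({"X": 23, "Y": 24, "MT": 25}.get(c, 99), c)
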