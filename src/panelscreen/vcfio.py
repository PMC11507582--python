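"""Reading and writing per-sample VCF v4.2 files.

Writing emits minimal single-sample VCFs carrying QUAL, INFO/MQ and
FORMAT AD:DP. Reading goes through cyvcf2 and splits multi-allelic
records into one call per alternate allele, with per-allele AD.
"""

from __future__ import annotations

import os
from typing import Optional

import pandas as pd

from .qc import CALL_COLUMNS, classify_alleles

__all__ = ["write_sample_vcf", "read_sample_vcf"]

_CONTIGS = "".join(f"##contig=<ID=chr{i}>\n"
                   for i in list(range(1, 23)) + ["X", "Y"])

_VCF_HEADER = """\
##fileformat=VCFv4.2
""" + _CONTIGS + """\
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mean mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##ALT=<ID=DEL,Description="Deletion">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_sample_vcf(calls: pd.DataFrame, sample_id: str, path: str) -> None:
    """Write one sample's calls as a VCF v4.2 text file.

    ``calls`` rows must belong to ``sample_id``; an empty frame yields a
    headers-only file.
    """
    sub = calls[calls["sample_id"] == sample_id] if not calls.empty else calls
    lines = [_VCF_HEADER.format(sample=sample_id)]
    if not sub.empty:
        sub = sub.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort")
        for row in sub.itertuples(index=False):
            lines.append(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                f"{row.qual:.1f}\t.\tMQ={row.mapq:.1f}\tGT:AD:DP\t"
                f"0/1:{row.ref_depth},{row.alt_depth}:{row.depth}\n"
            )
    with open(path, "w") as fh:
        fh.writelines(lines)


def read_sample_vcf(path: str, sample_id: Optional[str] = None) -> pd.DataFrame:
    """Read a single-sample VCF into the call-table schema.

    Multi-allelic records are split into one row per alternate allele
    with that allele's AD entry; variant classes are re-derived from the
    allele strings.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else os.path.basename(path)
    records = []
    for rec in vcf:
        dp_arr = rec.format("DP")
        dp = int(dp_arr[0][0]) if dp_arr is not None else 0
        ad = rec.format("AD")
        ad_row = ad[0] if ad is not None else None
        mq = rec.INFO.get("MQ")
        for ai, alt in enumerate(rec.ALT):
            ref_depth = int(ad_row[0]) if ad_row is not None else 0
            alt_depth = (int(ad_row[ai + 1])
                         if ad_row is not None and len(ad_row) > ai + 1 else 0)
            records.append({
                "sample_id": sample_id,
                "chrom": rec.CHROM,
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": alt,
                "variant_class": classify_alleles(rec.REF, alt),
                # written at one decimal; round away float32 noise
                "qual": round(float(rec.QUAL), 1) if rec.QUAL is not None else 0.0,
                "mapq": round(float(mq), 1) if mq is not None else 0.0,
                "depth": dp,
                "ref_depth": max(ref_depth, 0),
                "alt_depth": max(alt_depth, 0),
            })
    vcf.close()
    return pd.DataFrame.from_records(records, columns=list(CALL_COLUMNS))
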