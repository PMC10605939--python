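"""Somatic call ingestion: minimal TSV dialect and true VCF.

The TSV dialect is canonical for fixtures (human-diffable); real caller
output can be supplied as a VCF with per-caller PASS flags in INFO and
tumor/normal depths in the sample FORMAT fields.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pysam

from .core import Consequence, SomaticCall, parse_optional_int

TSV_HEADER = [
    "chrom", "pos", "ref", "alt", "gene", "consequence",
    "pass_caller_a", "pass_caller_b", "tumor_depth", "normal_depth",
    "tumor_alt", "normal_alt", "acmg_class",
]


def read_somatic_calls_tsv(path: str | Path) -> list[SomaticCall]:
    calls = []
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            calls.append(
                SomaticCall(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    gene=row["gene"] or None,
                    consequence=Consequence(row["consequence"]),
                    pass_caller_a=row["pass_caller_a"].lower() == "true",
                    pass_caller_b=row["pass_caller_b"].lower() == "true",
                    tumor_depth=int(row["tumor_depth"]),
                    normal_depth=int(row["normal_depth"]),
                    tumor_alt=int(row["tumor_alt"]),
                    normal_alt=int(row["normal_alt"]),
                    acmg_class=parse_optional_int(row["acmg_class"]),
                )
            )
    return calls


def write_somatic_calls_tsv(calls, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_HEADER)
        for c in calls:
            writer.writerow([
                c.chrom, c.pos, c.ref, c.alt, c.gene or "", c.consequence.value,
                str(c.pass_caller_a).lower(), str(c.pass_caller_b).lower(),
                c.tumor_depth, c.normal_depth, c.tumor_alt, c.normal_alt,
                "NA" if c.acmg_class is None else c.acmg_class,
            ])


def read_somatic_calls_vcf(
    path: str | Path,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
    pass_a_key: str = "PASS_A",
    pass_b_key: str = "PASS_B",
) -> list[SomaticCall]:
    """Read a tumor/normal VCF with per-caller PASS flags in INFO.

    Expects INFO flag keys for the two callers' PASS status (configurable),
    optional ``GENE``/``CSQ_CLASS``/``ACMG`` INFO fields, and per-sample
    ``DP`` (depth) and ``AD`` (ref,alt allele depths) FORMAT fields.
    """
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            tumor = rec.samples[tumor_sample]
            normal = rec.samples[normal_sample]
            t_ad = tumor.get("AD") or (0, 0)
            n_ad = normal.get("AD") or (0, 0)
            csq = rec.info.get("CSQ_CLASS", "other")
            calls.append(
                SomaticCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else "",
                    gene=rec.info.get("GENE"),
                    consequence=Consequence(csq),
                    pass_caller_a=bool(rec.info.get(pass_a_key, False)),
                    pass_caller_b=bool(rec.info.get(pass_b_key, False)),
                    tumor_depth=tumor.get("DP") or sum(t_ad),
                    normal_depth=normal.get("DP") or sum(n_ad),
                    tumor_alt=t_ad[1] if len(t_ad) > 1 else 0,
                    normal_alt=n_ad[1] if len(n_ad) > 1 else 0,
                    acmg_class=rec.info.get("ACMG"),
                )
            )
    return calls
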