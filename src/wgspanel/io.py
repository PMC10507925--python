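"""Readers and writers for the pipeline's on-disk formats.

Small variants travel as VCF v4.2 (annotations in INFO) or flat TSV; SV/CNV
calls, gene tables, verdicts and audits as TSV; regions as BED (0-based,
half-open); the economic configuration as YAML.  VCF handling goes through
pysam; internal interval coordinates are 0-based half-open and converted at
the VCF boundary (VCF POS is 1-based).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from .synth import SUBPOPULATIONS
from .svcnv import RegionSet

__all__ = [
    "write_small_variants_vcf",
    "read_small_variants_vcf",
    "write_tsv",
    "read_tsv",
    "write_bed",
    "read_bed",
    "write_genes_tsv",
    "read_genes_tsv",
]

_INFO_FLOAT = ["VAF", "COHORT_AF", "INHOUSE_AF", "REVEL", "PROVEAN", "CADD"]


def _vcf_header(chroms: dict[str, int], subpops: Iterable[str]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in chroms.items():
        h.contigs.add(name, length=length)
    for key in _INFO_FLOAT:
        h.info.add(key, 1, "Float", f"{key} annotation")
    for pop in subpops:
        h.info.add(f"GNEX_{pop.upper()}", 1, "Float", f"gnomAD exome AF, {pop}")
        h.info.add(f"GNGE_{pop.upper()}", 1, "Float", f"gnomAD genome AF, {pop}")
    h.info.add("CLINVAR", 1, "String", "ClinVar status")
    h.info.add("CSQ", 1, "String", "Molecular consequence")
    h.info.add("GENE", 1, "String", "Gene symbol")
    h.info.add("VCLASS", 1, "String", "Variant class (snv/indel/dnv)")
    h.info.add("SPLICE", 0, "Flag", "Splice impact predicted")
    return h


def write_small_variants_vcf(df: pd.DataFrame, path, chroms: dict[str, int]) -> None:
    header = _vcf_header(chroms, SUBPOPULATIONS)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for _, r in df.iterrows():
            rec = out.new_record(
                contig=r["chrom"], start=int(r["pos"]) - 1,
                alleles=(r["ref"], r["alt"]), id=r["variant_id"],
            )
            rec.info["VAF"] = float(r["vaf"])
            rec.info["COHORT_AF"] = float(r["cohort_af"])
            rec.info["INHOUSE_AF"] = float(r["inhouse_af"])
            for key, col in (("REVEL", "revel"), ("PROVEAN", "provean"), ("CADD", "cadd")):
                if not np.isnan(r[col]):
                    rec.info[key] = float(r[col])
            for pop in SUBPOPULATIONS:
                rec.info[f"GNEX_{pop.upper()}"] = float(r[f"gnex_{pop}"])
                rec.info[f"GNGE_{pop.upper()}"] = float(r[f"gnge_{pop}"])
            rec.info["CLINVAR"] = r["clinvar_status"]
            rec.info["CSQ"] = r["consequence"]
            rec.info["GENE"] = r["gene"]
            rec.info["VCLASS"] = r["variant_class"]
            if bool(r["splice_impact_predicted"]):
                rec.info["SPLICE"] = True
            out.write(rec)


def read_small_variants_vcf(path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            row = {
                "variant_id": rec.id,
                "chrom": rec.contig,
                "pos": rec.pos,  # back to 1-based
                "ref": rec.ref,
                "alt": rec.alts[0],
                "variant_class": rec.info["VCLASS"],
                "consequence": rec.info["CSQ"],
                "gene": rec.info["GENE"],
                "clinvar_status": rec.info["CLINVAR"],
                "vaf": float(rec.info["VAF"]),
                "cohort_af": float(rec.info["COHORT_AF"]),
                "inhouse_af": float(rec.info["INHOUSE_AF"]),
                "splice_impact_predicted": bool(rec.info.get("SPLICE", False)),
            }
            for pop in SUBPOPULATIONS:
                row[f"gnex_{pop}"] = float(rec.info[f"GNEX_{pop.upper()}"])
                row[f"gnge_{pop}"] = float(rec.info[f"GNGE_{pop.upper()}"])
            for key, col in (("REVEL", "revel"), ("PROVEAN", "provean"), ("CADD", "cadd")):
                row[col] = float(rec.info[key]) if key in rec.info else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(regions: RegionSet, path) -> None:
    regions.to_frame().to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> RegionSet:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"],
                     usecols=[0, 1, 2])
    return RegionSet(
        (r["chrom"], int(r["start"]), int(r["end"])) for _, r in df.iterrows()
    )


def write_genes_tsv(genes: pd.DataFrame, path) -> None:
    """Gene table as a 6-column BED-like TSV (chrom, start, end, gene, ., strand)."""
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["tx_start"],
            "end": genes["tx_end"],
            "gene": genes["gene"],
            "score": ".",
            "strand": genes["strand"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_genes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene", "score", "strand"],
    )
    return pd.DataFrame(
        {
            "gene": df["gene"],
            "chrom": df["chrom"],
            "tx_start": df["start"],
            "tx_end": df["end"],
            "strand": df["strand"],
        }
    )
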