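"""Readers and writers for the flat-file interfaces.

Expression matrices travel as TSV (genes in rows, samples in columns,
first header cell ignored), gene sets as GMT, genomic profiles and variant
tables as TSV, and variants alternatively as VCF 4.2 with INFO keys
CALLERS, TVAF, NVAF and CSQ_CLASS.  Gene identifiers are HGNC symbols
matched case-sensitively.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, GeneSet, GenomicProfile
from .truth import BRCAnessLabel
from .variants import CALLERS, BinderPrediction, VariantRecord

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_genomic_profiles",
    "write_genomic_profiles",
    "read_variants",
    "write_variants_tsv",
    "write_variants_vcf",
    "read_binders",
    "write_labels",
]

VARIANT_TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "mutect2", "somaticsniper", "varscan2", "strelka2",
    "tumor_vaf", "normal_vaf", "consequence", "clinvar_class",
]

PROFILE_COLUMNS = [
    "sample_id", "loh", "tai", "lst", "sig3_mutations", "total_mutations",
    "hrr_pathogenic_mutation", "brca1_promoter_beta",
]


def read_expression_matrix(path: str | os.PathLike, layer: str) -> ExpressionMatrix:
    """Read a genes x samples TSV into an :class:`ExpressionMatrix`.

    Non-numeric cells and duplicate gene rows are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    return ExpressionMatrix(df, layer)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    # %.17g keeps doubles round-trippable bit-exactly
    matrix.data.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_gene_sets(path: str | os.PathLike) -> list[GeneSet]:
    """Read a GMT file: name, description (discarded), tab-separated genes."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            sets.append(GeneSet(name=fields[0], genes=[g for g in fields[2:] if g]))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")


def read_genomic_profiles(path: str | os.PathLike) -> list[GenomicProfile]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile table {path} lacks columns: {missing}")
    profiles = []
    for row in df.itertuples(index=False):
        beta = getattr(row, "brca1_promoter_beta")
        profiles.append(
            GenomicProfile(
                sample_id=str(row.sample_id),
                loh=int(row.loh),
                tai=int(row.tai),
                lst=int(row.lst),
                sig3_mutations=int(row.sig3_mutations),
                total_mutations=int(row.total_mutations),
                hrr_pathogenic_mutation=bool(row.hrr_pathogenic_mutation),
                brca1_promoter_beta=None if pd.isna(beta) else float(beta),
            )
        )
    return profiles


def write_genomic_profiles(profiles: Iterable[GenomicProfile], path: str | os.PathLike) -> None:
    rows = []
    for p in profiles:
        rows.append(
            {
                "sample_id": p.sample_id,
                "loh": p.loh,
                "tai": p.tai,
                "lst": p.lst,
                "sig3_mutations": p.sig3_mutations,
                "total_mutations": p.total_mutations,
                "hrr_pathogenic_mutation": int(p.hrr_pathogenic_mutation),
                "brca1_promoter_beta": "" if p.brca1_promoter_beta is None else p.brca1_promoter_beta,
            }
        )
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def _variant_from_tsv_row(row) -> VariantRecord:
    cls = row.clinvar_class
    return VariantRecord(
        chrom=str(row.chrom),
        pos=int(row.pos),
        ref=str(row.ref),
        alt=str(row.alt),
        mutect2=bool(int(row.mutect2)),
        somaticsniper=bool(int(row.somaticsniper)),
        varscan2=bool(int(row.varscan2)),
        strelka2=bool(int(row.strelka2)),
        tumor_vaf=float(row.tumor_vaf),
        normal_vaf=float(row.normal_vaf),
        consequence=str(row.consequence),
        pathogenicity_class=None if pd.isna(cls) else int(cls),
    )


def read_variants(path: str | os.PathLike) -> list[VariantRecord]:
    """Read variants from VCF (.vcf) or flat TSV, dispatching on extension."""
    if str(path).endswith((".vcf", ".vcf.gz")):
        return _read_variants_vcf(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in VARIANT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} lacks columns: {missing}")
    return [_variant_from_tsv_row(row) for row in df.itertuples(index=False)]


def _read_variants_vcf(path: str | os.PathLike) -> list[VariantRecord]:
    from cyvcf2 import VCF

    records = []
    for v in VCF(str(path)):
        callers = str(v.INFO.get("CALLERS") or "").split(",")
        callers = {c.strip().lower() for c in callers if c.strip()}
        unknown = callers - set(CALLERS)
        if unknown:
            raise ValueError(f"unknown caller names in CALLERS INFO field: {sorted(unknown)}")
        csq_class = v.INFO.get("CSQ_CLASS")
        cons = v.INFO.get("CSQ") or "other"
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0] if v.ALT else "",
                mutect2="mutect2" in callers,
                somaticsniper="somaticsniper" in callers,
                varscan2="varscan2" in callers,
                strelka2="strelka2" in callers,
                tumor_vaf=float(v.INFO.get("TVAF")),
                normal_vaf=float(v.INFO.get("NVAF")),
                consequence=str(cons),
                pathogenicity_class=None if csq_class is None else int(csq_class),
            )
        )
    return records


def write_variants_tsv(variants: Iterable[VariantRecord], path: str | os.PathLike) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "mutect2": int(v.mutect2),
                "somaticsniper": int(v.somaticsniper),
                "varscan2": int(v.varscan2),
                "strelka2": int(v.strelka2),
                "tumor_vaf": v.tumor_vaf,
                "normal_vaf": v.normal_vaf,
                "consequence": v.consequence,
                "clinvar_class": "" if v.pathogenicity_class is None else v.pathogenicity_class,
            }
        )
    pd.DataFrame(rows, columns=VARIANT_TSV_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting somatic variant callers">
##INFO=<ID=TVAF,Number=1,Type=Float,Description="Tumor variant allele frequency">
##INFO=<ID=NVAF,Number=1,Type=Float,Description="Normal variant allele frequency">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence tag">
##INFO=<ID=CSQ_CLASS,Number=1,Type=Integer,Description="Pathogenicity class 1-5">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants_vcf(variants: Iterable[VariantRecord], path: str | os.PathLike) -> None:
    """Write a minimal VCF 4.2 with the filter-relevant fields in INFO."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        for v in variants:
            info = [
                f"CALLERS={','.join(v.supporting_callers)}" if v.caller_count else "CALLERS=",
                f"TVAF={v.tumor_vaf:g}",
                f"NVAF={v.normal_vaf:g}",
                f"CSQ={v.consequence}",
            ]
            if v.pathogenicity_class is not None:
                info.append(f"CSQ_CLASS={v.pathogenicity_class}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{';'.join(info)}\n"
            )


def read_binders(path: str | os.PathLike) -> list[BinderPrediction]:
    df = pd.read_csv(path, sep="\t")
    for col in ("peptide", "hla_allele", "percent_rank"):
        if col not in df.columns:
            raise ValueError(f"binder table {path} lacks column {col!r}")
    return [
        BinderPrediction(str(r.peptide), str(r.hla_allele), float(r.percent_rank))
        for r in df.itertuples(index=False)
    ]


def write_labels(labels: Iterable[BRCAnessLabel], path: str | os.PathLike) -> None:
    rows = [
        {
            "sample_id": l.sample_id,
            "label": l.label,
            "hrd_score": l.hrd_score,
            "sig3_ratio": "" if l.sig3_ratio is None else l.sig3_ratio,
            "triggered_criteria": ";".join(l.triggered_criteria),
        }
        for l in labels
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "label", "hrd_score", "sig3_ratio", "triggered_criteria"]
    ).to_csv(path, sep="\t", index=False)
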