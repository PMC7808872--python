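"""Readers and writers for the study's file dialects.

Genotypes can be exchanged as (a) a plain TSV code matrix (first column
``iid``, one column per rsID, values 0/1/2 or NA), (b) the PLINK text
ped/map dialect (two allele characters per SNP, '0 0' = missing), or (c) a
minimal uncompressed VCF restricted to biallelic records with GT fields.
Phenotypes travel as a TSV with ``iid, sex, age`` plus either the 13 raw
questionnaire items (``cs1..cs13``) or a precomputed ``cs_total``.  SNP
annotation is a TSV with id, gene, chromosome, position and alleles.

VCF reading goes through cyvcf2; the other dialects are simple enough to
parse directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cs_scoring import score_cs
from .datatypes import MISSING, GenotypeMatrix, SnpRecord

DEFAULT_SEX_MAP = {"M": 0, "F": 1, "1": 0, "2": 1, "0": 0}


# --- annotation -----------------------------------------------------------


def write_annotation_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    rows = [
        {
            "snp_id": s.id,
            "gene": s.gene,
            "chromosome": s.chromosome,
            "position": s.position,
            "allele_major": s.alleles[0],
            "allele_minor": s.alleles[1],
            "maf": s.maf,
        }
        for s in matrix.snps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return [
        SnpRecord(
            id=str(r.snp_id),
            gene=str(r.gene),
            chromosome=str(r.chromosome),
            position=int(r.position),
            alleles=(str(r.allele_major), str(r.allele_minor)),
            maf=None if pd.isna(r.maf) else float(r.maf),
        )
        for r in df.itertuples()
    ]


# --- genotype TSV ---------------------------------------------------------


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        np.where(matrix.values == MISSING, np.nan, matrix.values),
        columns=matrix.snp_ids,
    )
    df.insert(0, "iid", matrix.iids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.0f")


def read_genotype_tsv(
    path: str | Path, annotation: list[SnpRecord] | None = None
) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.columns[0] != "iid":
        raise ValueError("genotype TSV must have 'iid' as its first column")
    iids = [str(v) for v in df["iid"]]
    snp_ids = list(df.columns[1:])
    values = df[snp_ids].to_numpy(dtype=float)
    values = np.where(np.isnan(values), MISSING, values).astype(np.int8)
    snps = _match_annotation(snp_ids, annotation)
    return GenotypeMatrix(values=values, snps=snps, iids=iids)


def _match_annotation(
    snp_ids: list[str], annotation: list[SnpRecord] | None
) -> list[SnpRecord]:
    if annotation is None:
        return [
            SnpRecord(id=s, gene="unknown", chromosome="0", position=i + 1, alleles=("A", "B"))
            for i, s in enumerate(snp_ids)
        ]
    by_id = {r.id: r for r in annotation}
    missing = [s for s in snp_ids if s not in by_id]
    if missing:
        raise ValueError(f"annotation lacks SNPs: {missing}")
    return [by_id[s] for s in snp_ids]


# --- PLINK text ped/map ---------------------------------------------------


def write_ped_map(matrix: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for s in matrix.snps:
            fh.write(f"{s.chromosome}\t{s.id}\t0\t{s.position}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(matrix.iids):
            fields = [iid, iid, "0", "0", "0", "-9"]
            for j, s in enumerate(matrix.snps):
                code = matrix.values[i, j]
                major, minor = s.alleles
                if code == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [minor] * int(code) + [major] * (2 - int(code))
            fh.write("\t".join(fields) + "\n")


def read_ped_map(
    prefix: str | Path, annotation: list[SnpRecord] | None = None
) -> GenotypeMatrix:
    """Read the ped/map text dialect; codes count the rarer observed allele.

    Without annotation, allele orientation is determined from the data
    (ties broken alphabetically), exactly as downstream QC would re-orient
    anyway.
    """
    prefix = Path(prefix)
    map_rows = []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            chrom, snp_id, _cm, pos = line.split()
            map_rows.append((chrom, snp_id, int(pos)))
    snp_ids = [r[1] for r in map_rows]

    iids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * len(snp_ids):
                raise ValueError("ped row length does not match map")
            iids.append(parts[1])
            alleles = [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(len(snp_ids))]
            allele_rows.append(alleles)

    n, p = len(iids), len(snp_ids)
    values = np.full((n, p), MISSING, dtype=np.int8)
    records: list[SnpRecord] = []
    by_id = {r.id: r for r in annotation} if annotation else {}
    for j in range(p):
        chrom, snp_id, pos = map_rows[j]
        if snp_id in by_id:
            rec = by_id[snp_id]
            counted = rec.alleles[1]  # count the annotated minor allele
            pair = rec.alleles
        else:
            seen: dict[str, int] = {}
            for row in allele_rows:
                for a in row[j]:
                    if a != "0":
                        seen[a] = seen.get(a, 0) + 1
            if not seen:
                raise ValueError(f"SNP {snp_id}: no genotyped individuals")
            ordered = sorted(seen.items(), key=lambda kv: (kv[1], kv[0]))
            if len(ordered) == 1:
                counted = ordered[0][0]
                pair = (counted, "N") if counted != "N" else (counted, "X")
                pair = (pair[1], pair[0])  # monomorphic: counted allele still 'minor' slot
            else:
                counted = ordered[0][0]
                pair = (ordered[-1][0], counted)
        for i, row in enumerate(allele_rows):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            values[i, j] = (a1 == counted) + (a2 == counted)
        records.append(
            SnpRecord(id=snp_id, gene=by_id[snp_id].gene if snp_id in by_id else "unknown",
                      chromosome=chrom, position=pos, alleles=pair)
        )
    return GenotypeMatrix(values=values, snps=records, iids=iids)


# --- VCF ------------------------------------------------------------------


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Minimal uncompressed VCF; REF = major allele, ALT = minor."""
    cols = sorted(range(matrix.n_snps),
                  key=lambda j: (matrix.snps[j].chromosome, matrix.snps[j].position))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(matrix.snps[j].chromosome for j in cols):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.iids) + "\n")
        gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in cols:
            s = matrix.snps[j]
            row = [s.chromosome, str(s.position), s.id, s.alleles[0], s.alleles[1],
                   ".", "PASS", ".", "GT"]
            row += [gt[int(c)] for c in matrix.values[:, j]]
            fh.write("\t".join(row) + "\n")


def read_vcf(path: str | Path, annotation: list[SnpRecord] | None = None) -> GenotypeMatrix:
    """Read biallelic records from a VCF; codes count the ALT allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    iids = list(vcf.samples)
    by_id = {r.id: r for r in annotation} if annotation else {}
    columns: list[np.ndarray] = []
    records: list[SnpRecord] = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic records only
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        codes = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        columns.append(codes.astype(np.int8))
        rid = var.ID or f"{var.CHROM}:{var.POS}"
        rec = by_id.get(rid)
        records.append(
            SnpRecord(
                id=rid,
                gene=rec.gene if rec else "unknown",
                chromosome=str(var.CHROM),
                position=int(var.POS),
                alleles=(var.REF, var.ALT[0]),
            )
        )
    if not columns:
        raise ValueError(f"no biallelic records in {path}")
    return GenotypeMatrix(values=np.column_stack(columns), snps=records, iids=iids)


# --- phenotype ------------------------------------------------------------


def read_phenotype_tsv(
    path: str | Path, sex_map: dict[str, int] | None = None
) -> pd.DataFrame:
    """Phenotype table with iid, sex (0=M, 1=F), age and cs_total.

    Accepts either a precomputed ``cs_total`` column or the 13 raw items
    ``cs1..cs13``, which are scored here.
    """
    sex_map = sex_map or DEFAULT_SEX_MAP
    df = pd.read_csv(path, sep="\t")
    required = {"iid", "sex", "age"}
    if not required <= set(df.columns):
        raise ValueError(f"phenotype TSV must contain columns {sorted(required)}")
    sex = df["sex"].astype(str).map(sex_map)
    if sex.isna().any():
        bad = sorted(set(df["sex"].astype(str)[sex.isna()]))
        raise ValueError(f"unrecognised sex codes: {bad}")
    out = pd.DataFrame({"iid": df["iid"].astype(str), "sex": sex.astype(int),
                        "age": df["age"].astype(float)})
    item_cols = [f"cs{i}" for i in range(1, 14)]
    if "cs_total" in df.columns:
        out["cs_total"] = df["cs_total"].astype(int)
    elif all(c in df.columns for c in item_cols):
        out["cs_total"] = [
            score_cs([int(v) for v in row]) for row in df[item_cols].to_numpy()
        ]
    else:
        raise ValueError("phenotype TSV needs either cs_total or cs1..cs13 columns")
    return out


def write_phenotype_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
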