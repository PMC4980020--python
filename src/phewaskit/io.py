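"""Plain-text formats used between pipeline stages.

Genotypes travel either as VCF (FORMAT ``GT`` and ``DS``, per-SNP INFO key
``INFO_SCORE``) or as a self-contained dosage TSV whose first six columns
are the SNP metadata and whose remaining columns are one sample each.
Events are CSV ``person_id,icd9_code,event_date``; covariates, status
matrices, association/replication/meta tables, QC reports and keep-lists
are all TSV.  Every intermediate is re-readable by the stage that wrote it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParseError
from .genoqc import SNP_META_COLUMNS, GenotypeMatrix

# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    meta = geno.snps[SNP_META_COLUMNS].copy()
    dos = pd.DataFrame(geno.dosages.T, columns=list(geno.samples))
    pd.concat([meta, dos], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    missing = [c for c in SNP_META_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: dosage TSV missing metadata columns {missing}")
    samples = [c for c in df.columns if c not in SNP_META_COLUMNS]
    dosages = df[samples].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages=dosages, samples=np.array(samples, dtype=object),
                          snps=df[SNP_META_COLUMNS])


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with GT (rounded dosage) and DS fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO_SCORE,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Coded-allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, geno.samples)) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, snp in geno.snps.iterrows():
            # coded allele written as ALT so DS counts ALT copies
            fields = [
                str(snp["chrom"]), str(int(snp["pos"])), snp["snp_id"],
                snp["allele_other"], snp["allele_coded"], ".", "PASS",
                f"INFO_SCORE={snp['info_score']:.6g}", "GT:DS",
            ]
            col = geno.dosages[:, j]
            cells = []
            for d in col:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    cells.append(f"{gt_codes[int(round(d))]}:{d:.4g}")
            fh.write("\t".join(fields + cells) + "\n")


def read_vcf(path, info_sidecar=None) -> GenotypeMatrix:
    """Read genotypes from VCF via cyvcf2; DS preferred, else GT dosage.

    ``INFO_SCORE`` is taken from INFO or, failing that, from a 2-column
    sidecar TSV ``snp_id <tab> info`` (no header); SNPs absent from both get
    info score 1.0.
    """
    from cyvcf2 import VCF

    sidecar = {}
    if info_sidecar is not None:
        sc = pd.read_csv(info_sidecar, sep="\t", header=None, names=["snp_id", "info"])
        sidecar = dict(zip(sc["snp_id"], sc["info"]))

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    meta_rows, dosage_cols = [], []
    for var in vcf:
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = ds.astype(float).reshape(-1)
        else:
            # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
            col = np.array(
                [np.nan if t == 2 else (2.0 if t == 3 else float(t)) for t in var.gt_types]
            )
        info = var.INFO.get("INFO_SCORE")
        if info is None:
            info = sidecar.get(var.ID, 1.0)
        meta_rows.append((var.ID, var.CHROM, var.POS, var.ALT[0], var.REF, float(info)))
        dosage_cols.append(col)
    snps = pd.DataFrame(meta_rows, columns=SNP_META_COLUMNS)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages=dosages, samples=samples, snps=snps)


# ---------------------------------------------------------------------------
# Events, covariates, statuses, tables
# ---------------------------------------------------------------------------

def write_events_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"icd9_code": str, "person_id": str})
    need = {"person_id", "icd9_code"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: events CSV needs columns {sorted(need)}")
    return df


def write_covariates_tsv(covars: pd.DataFrame, path) -> None:
    covars.to_csv(path, sep="\t", index=False)


def read_covariates_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"person_id": str})
    need = {"person_id", "age", "sex"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: covariates TSV needs columns {sorted(need)}")
    return df


def write_status_matrix(statuses: pd.DataFrame, path) -> None:
    statuses.to_csv(path, sep="\t", index_label="person_id")


def read_status_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="person_id")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_association_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"icd9_code": str, "category": str})


def write_keep_list(ids, path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_keep_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_catalog_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "trait": str})
    need = {"snp_id", "trait", "p"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: catalog TSV needs columns {sorted(need)}")
    if "source" not in df.columns:
        df["source"] = "catalog"
    return df


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
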