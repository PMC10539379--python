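"""Readers and writers for the pipeline's file formats.

Genotypes travel as PLINK bed/bim/fam (2-bit packed, SNP-major) or
VCF; register tables (subjects, prescriptions, ECT events, truth) as
CSV; variant weight tables as whitespace/tab-delimited text with
header autodetection for the common summary-statistics column aliases.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genoprs import GenotypeMatrix, WEIGHT_COLUMNS

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major PLINK .bed

# dosage of a1 -> 2-bit PLINK code (00 hom a1, 10 het, 11 hom a2, 01 missing)
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write bed/bim/fam files under ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    v = G.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "id": v["id"],
            "cm": 0,
            "pos": v["pos"],
            "a1": v["a1"],
            "a2": v["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": G.subjects,
            "iid": G.subjects,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n = G.n_subjects
    codes = np.full(G.dosages.shape, 0b01, dtype=np.uint8)  # missing
    for dos, code in _DOSAGE_TO_CODE.items():
        codes[G.dosages == dos] = code
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(G.n_variants):
            col = codes[:, j]
            packed = np.zeros(n_bytes, dtype=np.uint8)
            for k in range(4):
                chunk = col[k::4]
                packed[: len(chunk)] |= chunk << (2 * k)
            fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read bed/bim/fam files written by PLINK (SNP-major layout)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != n_bytes * m:
        raise ValueError("bed payload size inconsistent with bim/fam")
    body = body.reshape(m, n_bytes)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(fam["iid"].to_numpy(dtype=object), variants, dosages)


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Plain-text VCF 4.2 with GT fields; a2 is REF, a1 is ALT.

    The dosage counts a1 copies, so dosage 2 -> 1/1, 1 -> 0/1,
    0 -> 0/0, missing -> ./. .
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_map = {2.0: "1/1", 1.0: "0/1", 0.0: "0/0"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, G.subjects))
            + "\n"
        )
        v = G.variants
        for j in range(G.n_variants):
            gts = [gt_map.get(d, "./.") for d in G.dosages[:, j]]
            fh.write(
                f"{v['chrom'].iat[j]}\t{v['pos'].iat[j]}\t{v['id'].iat[j]}\t"
                f"{v['a2'].iat[j]}\t{v['a1'].iat[j]}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (ALT-allele dosage) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = np.array(vcf.samples, dtype=object)
    ids, chroms, poss, a1s, a2s, rows = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic only
        ids.append(var.ID)
        chroms.append(int(str(var.CHROM).removeprefix("chr")))
        poss.append(var.POS)
        a1s.append(var.ALT[0])
        a2s.append(var.REF)
        gt = np.asarray(var.genotype.array())[:, :2].astype(float)
        gt[gt < 0] = np.nan
        rows.append(gt.sum(axis=1))
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "a1": a1s, "a2": a2s}
    )
    dosages = np.column_stack(rows) if rows else np.empty((len(subjects), 0))
    return GenotypeMatrix(subjects, variants, dosages)


# ---------------------------------------------------------------------------
# weight tables

_ALIASES = {
    "id": ("id", "snp", "rsid", "marker", "markername"),
    "chrom": ("chrom", "chr", "chromosome"),
    "pos": ("pos", "bp", "position", "base_pair_location"),
    "effect_allele": ("effect_allele", "a1", "ea", "allele1"),
    "other_allele": ("other_allele", "a2", "oa", "allele2", "ref"),
    "eaf": ("eaf", "freq", "af", "effect_allele_frequency", "frq", "maf"),
    "weight": ("weight", "beta", "b", "effect", "es"),
    "info": ("info", "imputation_quality", "r2"),
    "p": ("p", "pval", "p_value", "pvalue"),
}


def read_weight_table(path: str | Path) -> pd.DataFrame:
    """Read a whitespace/tab-delimited weight table, mapping column aliases."""
    df = pd.read_csv(path, sep=r"\s+")
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for canon, aliases in _ALIASES.items():
        for a in aliases:
            if a in lower:
                rename[lower[a]] = canon
                break
    df = df.rename(columns=rename)
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weight table {path} missing columns {missing}")
    return df


def write_weight_table(weights: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical tab-delimited header (SNP CHR BP A1 A2 FREQ BETA INFO P)."""
    out = pd.DataFrame(
        {
            "SNP": weights["id"],
            "CHR": weights["chrom"],
            "BP": weights["pos"],
            "A1": weights["effect_allele"],
            "A2": weights["other_allele"],
            "FREQ": weights["eaf"],
            "BETA": weights["weight"],
            "INFO": weights["info"],
            "P": weights.get("p", pd.Series(np.nan, index=weights.index)),
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# register tables


def read_prescriptions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "atc_code": str})
    return df[["subject_id", "atc_code", "dispense_date"]]


def read_ect_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    return df[["subject_id", "date"]]


def write_study(study, out_dir: str | Path) -> dict:
    """Write every component of a synthetic study; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("subjects", study.subjects),
        ("prescriptions", study.prescriptions),
        ("ect_events", study.ect_events),
        ("truth", study.truth),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = p
    for trait, tbl in study.weights.items():
        p = out / f"weights_{trait}.tsv"
        write_weight_table(tbl, p)
        paths[f"weights_{trait}"] = p
    write_plink(study.genotypes, out / "genotypes")
    write_vcf(study.genotypes, out / "genotypes.vcf")
    paths["genotypes"] = out / "genotypes"
    return paths
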