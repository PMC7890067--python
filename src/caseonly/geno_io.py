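"""Readers and writers for the on-disk formats the pipeline touches.

All tabular files are tab-separated UTF-8 with ``.`` for missing values and
1-based inclusive genomic positions (interval tracks on disk are BED, i.e.
0-based half-open; they are converted at this boundary and kept half-open
internally).  Every reader validates the container invariants; corrupt input
is rejected with an error naming the offending record or column.
"""

from __future__ import annotations

import decimal
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "AnnotationBundle",
    "read_dosages",
    "write_dosages_tsv",
    "write_dosages_vcf",
    "read_samples",
    "write_samples",
    "read_known_snps",
    "read_annotations",
    "write_assoc_results",
    "read_assoc_results",
    "round_half_up",
    "load_known_modifier_summary",
    "load_study_counts",
]

VARIANT_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt",
    "genotyped", "r2_bcac", "r2_cimba", "maf_bcac_cases",
]

SAMPLE_COLUMNS = [
    "sample_id", "cohort", "status", "carrier_gene", "age", "country", "er_status",
]

COHORTS = {"BCAC", "CIMBA"}
STATUSES = {"case", "control"}
CARRIER_GENES = {"BRCA1", "BRCA2", "none"}
ER_STATUSES = {"positive", "negative", "unknown"}

ASSOC_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "ref_allele",
    "freq", "r2", "beta", "se", "or", "p", "analysis", "n",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed summary-table style."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class GenotypeMatrix:
    """Samples x variants allelic dosages in [0, 2] with per-variant metadata.

    ``dosages[i, j]`` is the expected count of the alt (effect) allele for
    sample ``i`` at variant ``j``; missing dosages are ``NaN``, never 0.
    ``variants`` carries id, 1-based position, alleles, the genotyped flag and
    per-consortium imputation accuracy r^2 (1 by convention when genotyped).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        self.variants = self.variants.reset_index(drop=True)
        self.validate()

    # -- container protocol -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (samples x variants)")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage matrix shape does not match sample/variant tables")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing mandatory columns: {missing}")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            j = np.argwhere((self.dosages < 0) | (self.dosages > 2))[0]
            vid = self.variants["variant_id"].iloc[int(j[1])]
            raise ValueError(f"dosage outside [0, 2] at variant {vid!r}")
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not non-decreasing on chromosome {chrom}")
        geno = self.variants["genotyped"].astype(bool)
        r2 = self.variants[["r2_bcac", "r2_cimba"]].to_numpy(dtype=float)
        if np.any((r2 <= 0) | (r2 > 1)):
            raise ValueError("imputation r2 must lie in (0, 1]")
        if geno.any() and not np.allclose(r2[geno.to_numpy()], 1.0):
            raise ValueError("genotyped variants must carry r2 = 1 in both cohorts")

    def subset_variants(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, (list, pd.Index, set)):
            mask = self.variants["variant_id"].isin(list(mask_or_ids)).to_numpy()
        else:
            mask = np.asarray(mask_or_ids)
        return GenotypeMatrix(self.dosages[:, mask], self.variants.loc[mask].copy(), self.sample_ids)

    def subset_samples(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(self.dosages[mask], self.variants.copy(), self.sample_ids[mask])

    def dosage_for(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) != 1:
            raise KeyError(variant_id)
        return self.dosages[:, int(idx[0])]


# ---------------------------------------------------------------------------
# dosage matrices
# ---------------------------------------------------------------------------

def read_dosages(path, fmt: str = None) -> GenotypeMatrix:
    """Read a dosage matrix from a VCF (FORMAT DS) or a TSV dosage file.

    ``fmt`` is inferred from the extension when not given.  VCF records must
    be bi-allelic; the DS field is used when present, otherwise hard-call
    genotypes are converted to dosages.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".gz"} or str(path).endswith(".vcf.gz") else "tsv"
    if fmt == "vcf":
        return _read_dosages_vcf(path)
    if fmt == "tsv":
        return _read_dosages_tsv(path)
    raise ValueError(f"unknown dosage format {fmt!r}")


def _read_dosages_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.asarray(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multi-allelic record {rec.ID or rec.CHROM + ':' + str(rec.POS)!r} not supported")
        if "DS" in (rec.FORMAT or ""):
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        else:
            gts = np.asarray(rec.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            ds = np.where(gts == 3, 2.0, gts)
            ds[gts == 2] = np.nan
        ds = np.where(ds < -0.5, np.nan, ds)  # cyvcf2 missing sentinel
        vid = rec.ID or f"{rec.CHROM}_{rec.POS}_{rec.REF}_{rec.ALT[0]}"
        bad = ds[np.isfinite(ds)]
        if bad.size and (bad.min() < 0 or bad.max() > 2):
            raise ValueError(f"dosage outside [0, 2] in record {vid!r}")
        info = dict(rec.INFO)
        meta.append({
            "variant_id": vid, "chrom": rec.CHROM, "pos": rec.POS,
            "ref": rec.REF, "alt": rec.ALT[0],
            "genotyped": bool(info.get("GENOTYPED", 0)),
            "r2_bcac": float(info.get("R2_BCAC", 1.0)),
            "r2_cimba": float(info.get("R2_CIMBA", 1.0)),
            "maf_bcac_cases": float(info.get("MAF_BCAC_CASES", np.nan)),
        })
        rows.append(ds)
    dos = np.asarray(rows, dtype=float).T if rows else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(dos, pd.DataFrame(meta, columns=VARIANT_COLUMNS), sample_ids)


def _read_dosages_tsv(path) -> GenotypeMatrix:
    # variants x samples matrix with the variant metadata in leading columns
    df = pd.read_csv(path, sep="\t", na_values=["."])
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV missing mandatory columns: {missing}")
    sample_cols = [c for c in df.columns if c not in VARIANT_COLUMNS]
    dos = df[sample_cols].to_numpy(dtype=float).T
    variants = df[VARIANT_COLUMNS].copy()
    variants["genotyped"] = variants["genotyped"].astype(bool)
    bad = np.argwhere((dos < 0) | (dos > 2))
    if bad.size:
        vid = variants["variant_id"].iloc[int(bad[0][1])]
        raise ValueError(f"dosage outside [0, 2] at variant {vid!r}")
    return GenotypeMatrix(dos, variants, np.asarray(sample_cols))


def write_dosages_tsv(matrix: GenotypeMatrix, path) -> None:
    df = matrix.variants[VARIANT_COLUMNS].copy()
    body = pd.DataFrame(matrix.dosages.T, columns=list(matrix.sample_ids))
    out = pd.concat([df.reset_index(drop=True), body], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")


def write_dosages_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with per-sample DS and the r2 metadata in INFO."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENOTYPED,Number=0,Type=Flag,Description="Directly genotyped">\n')
        fh.write('##INFO=<ID=R2_BCAC,Number=1,Type=Float,Description="Imputation r2, BCAC">\n')
        fh.write('##INFO=<ID=R2_CIMBA,Number=1,Type=Float,Description="Imputation r2, CIMBA">\n')
        fh.write('##INFO=<ID=MAF_BCAC_CASES,Number=1,Type=Float,Description="MAF in BCAC cases">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, matrix.sample_ids)) + "\n")
        for j, row in matrix.variants.iterrows():
            info = []
            if bool(row["genotyped"]):
                info.append("GENOTYPED")
            info.append(f"R2_BCAC={row['r2_bcac']:.4f}")
            info.append(f"R2_CIMBA={row['r2_cimba']:.4f}")
            if np.isfinite(row["maf_bcac_cases"]):
                info.append(f"MAF_BCAC_CASES={row['maf_bcac_cases']:.6f}")
            ds = matrix.dosages[:, j]
            ds_str = "\t".join("." if not np.isfinite(d) else f"{d:.4f}" for d in ds)
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{row['variant_id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\t.\t{';'.join(info)}\tDS\t{ds_str}\n")


# ---------------------------------------------------------------------------
# sample tables
# ---------------------------------------------------------------------------

def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing mandatory columns: {missing}")
    df = df.copy()
    df["er_status"] = df["er_status"].fillna("unknown").replace({"": "unknown"})
    for col, allowed in [("cohort", COHORTS), ("status", STATUSES),
                         ("carrier_gene", CARRIER_GENES), ("er_status", ER_STATUSES)]:
        bad = set(df[col].unique()) - allowed
        if bad:
            raise ValueError(f"invalid {col} value(s) {sorted(bad)}")
    if ((df["cohort"] == "CIMBA") & (df["carrier_gene"] == "none")).any():
        raise ValueError("CIMBA samples must carry a BRCA1 or BRCA2 mutation")
    if ((df["cohort"] == "BCAC") & (df["carrier_gene"] != "none")).any():
        raise ValueError("BCAC samples must have carrier_gene = none")
    if (df["age"] <= 0).any():
        raise ValueError("age must be positive")
    if df["country"].isna().any() or (df["country"].astype(str) == "").any():
        raise ValueError("country must be non-empty")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    return df


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "country": str},
                     na_values=["."], keep_default_na=True)
    return validate_samples(df)


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# known susceptibility SNPs
# ---------------------------------------------------------------------------

def read_known_snps(path) -> pd.DataFrame:
    """Population summary statistics for the established susceptibility SNPs.

    Columns: variant_id, source (overall / er_negative), or_bcac, p_bcac,
    effect_allele, ref_allele.  ``source`` selects which population contrast
    the odds ratio was estimated in.
    """
    df = pd.read_csv(path, sep="\t", na_values=["."])
    required = ["variant_id", "source", "or_bcac", "p_bcac", "effect_allele", "ref_allele"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"known-SNP table missing mandatory columns: {missing}")
    if (df["or_bcac"] <= 0).any():
        raise ValueError("or_bcac must be positive")
    bad = set(df["source"].unique()) - {"overall", "er_negative"}
    if bad:
        raise ValueError(f"invalid source value(s) {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# annotation bundle
# ---------------------------------------------------------------------------

TRACK_NAMES = [
    "chia_pet_link", "hic_link", "computational_ep", "super_enhancer",
    "promoter_histone", "enriched_feature", "tad_boundary",
]


@dataclass
class AnnotationBundle:
    """Genomic evidence tracks used for target-gene prioritisation.

    Interval tracks are half-open 0-based internally (converted from BED);
    gene models carry the strand-aware TSS in 1-based coordinates.
    """

    tracks: dict = field(default_factory=dict)
    gene_models: pd.DataFrame = None
    coding: pd.DataFrame = None
    expressed_genes: set = field(default_factory=set)
    driver_genes: set = field(default_factory=set)
    eqtl: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.gene_models is None:
            self.gene_models = pd.DataFrame(columns=["gene", "chrom", "tss", "strand"])
        if self.coding is None:
            self.coding = pd.DataFrame(
                columns=["variant_id", "gene", "consequence", "revel", "splice_ada", "splice_rf"])
        if self.eqtl is None:
            self.eqtl = pd.DataFrame(columns=["variant_id", "gene", "p", "source"])
        for name, track in self.tracks.items():
            if len(track) and (track["start"] > track["end"]).any():
                raise ValueError(f"track {name!r} has interval with start > end")
        known = set(self.gene_models["gene"])
        for tab, label in [(self.coding, "coding"), (self.eqtl, "eqtl")]:
            extra = set(tab["gene"]) - known
            if extra:
                raise ValueError(f"{label} table references unknown gene(s) {sorted(extra)}")


def _read_bed_track(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    cols = ["chrom", "start", "end"] + (["gene"] if ncol > 3 else [])
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    if "gene" not in df.columns:
        df["gene"] = None
    if (df["start"] > df["end"]).any():
        raise ValueError(f"BED file {path} has interval with start > end")
    if (df["start"] < 0).any():
        raise ValueError(f"BED file {path} has negative start")
    df["chrom"] = df["chrom"].astype(str)
    return df


def _read_gene_models_gff3(path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique", keep_order=True)
    rows = []
    for feat in db.features_of_type("gene"):
        gene = feat.attributes.get("ID", [feat.id])[0]
        tss = feat.start if feat.strand != "-" else feat.end
        rows.append({"gene": gene, "chrom": str(feat.seqid), "tss": int(tss),
                     "strand": feat.strand or "+"})
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


def read_annotations(directory) -> AnnotationBundle:
    """Assemble an :class:`AnnotationBundle` from a directory of standard files.

    Expected names: ``<track>.bed`` for each interval track, ``genes.gff3``,
    ``coding.tsv``, ``eqtl.tsv``, ``expressed_genes.txt``, ``driver_genes.txt``.
    Missing files yield empty components.
    """
    directory = Path(directory)
    tracks = {}
    for name in TRACK_NAMES:
        p = directory / f"{name}.bed"
        tracks[name] = _read_bed_track(p) if p.exists() else pd.DataFrame(
            columns=["chrom", "start", "end", "gene"])
    gff = directory / "genes.gff3"
    genes = _read_gene_models_gff3(gff) if gff.exists() else None
    coding_path = directory / "coding.tsv"
    coding = pd.read_csv(coding_path, sep="\t", na_values=["."]) if coding_path.exists() else None
    eqtl_path = directory / "eqtl.tsv"
    eqtl = pd.read_csv(eqtl_path, sep="\t", na_values=["."]) if eqtl_path.exists() else None

    def _read_set(fname):
        p = directory / fname
        if not p.exists():
            return set()
        return {line.strip() for line in p.read_text().splitlines() if line.strip()}

    return AnnotationBundle(
        tracks=tracks, gene_models=genes, coding=coding,
        expressed_genes=_read_set("expressed_genes.txt"),
        driver_genes=_read_set("driver_genes.txt"), eqtl=eqtl,
    )


# ---------------------------------------------------------------------------
# association results
# ---------------------------------------------------------------------------

def write_assoc_results(results: pd.DataFrame, path) -> None:
    """Write summary statistics with fixed column order and deterministic bytes.

    Full-precision OR plus a 2-dp half-up rounded column mirroring the style
    of published summary tables.
    """
    df = results.copy()
    missing = [c for c in ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"association results missing columns: {missing}")
    df = df[ASSOC_COLUMNS]
    out = df.copy()
    out["or"] = [f"{v:.6f}" if np.isfinite(v) else "." for v in df["or"]]
    out["or_rounded"] = [f"{round_half_up(v):.2f}" if np.isfinite(v) else "." for v in df["or"]]
    for col in ["freq", "r2", "beta", "se"]:
        out[col] = [f"{v:.6g}" if np.isfinite(v) else "." for v in df[col]]
    out["p"] = [f"{v:.6e}" if np.isfinite(v) else "." for v in df["p"]]
    out.to_csv(path, sep="\t", index=False, na_rep=".")


def read_assoc_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    return df


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_known_modifier_summary() -> pd.DataFrame:
    """Published per-SNP summary rows (case-only OR, population OR, labels)."""
    return pd.read_csv(_data_path("known_modifier_summary.tsv"), sep="\t", na_values=["."])


def load_study_counts() -> dict:
    """Published per-stage SNP and sample counts of the two-consortium study."""
    with open(_data_path("study_counts.json")) as fh:
        return json.load(fh)
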