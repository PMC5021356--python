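"""Genotype, sample-table and gene-map IO plus the marker/sample QC filters.

Supported genotype formats:

* VCF v4.x — dosages taken from the ``DS`` FORMAT field when present, else the
  ``GT`` alternate-allele count; multi-allelic records are rejected (the
  analysis targets biallelic common SNPs).  Reading uses cyvcf2; writing emits
  plain uncompressed text.
* dosage table — tab-delimited, one row per sample: sample id then one column
  per SNP id, values in [0, 2] or ``NA``.

QC follows the usual case-control GWAS convention: samples below the call-rate
cutoff are dropped first, then markers are filtered on recomputed MAF, call
rate and (when present) imputation info score.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

SAMPLE_COLUMNS = ["sample_id", "phenotype", "age", "sex", "site", "platform"]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_genotypes(path: str, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from ``vcf`` or ``dosage-table`` format."""
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage-table":
        return _read_dosage_table(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    dosage_cols: list[np.ndarray] = []
    records = []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS} (variant #{i + 1}): "
                "only biallelic SNPs are supported"
            )
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where((col < -0.5) | (col > 2.5), np.nan, col)
        else:
            gts = np.asarray(var.gt_types, dtype=float)  # 0,1,2; 3 = unknown
            # cyvcf2 genotype entries are [allele_1, ..., allele_k, phased]
            ploidies = {len(g) - 1 for g in var.genotypes} if var.genotypes else set()
            if ploidies and ploidies != {2}:
                raise ValueError(
                    f"mixed or non-diploid ploidy at {var.CHROM}:{var.POS} (variant #{i + 1})"
                )
            col = np.where(gts > 2.5, np.nan, gts)
        info = var.INFO.get("IS")
        records.append(
            (
                var.ID or f"{var.CHROM}:{var.POS}",
                str(var.CHROM),
                int(var.POS),
                var.REF,
                var.ALT[0],
                float(info) if info is not None else np.nan,
            )
        )
        dosage_cols.append(col)
    if not records:
        raise ValueError(f"no variant records in {path}")
    variants = pd.DataFrame(records, columns=["snp_id", "chrom", "pos", "ref", "alt", "info_score"])
    G = GenotypeMatrix(np.column_stack(dosage_cols), samples, variants)
    G.refresh_metadata()
    return G


def _read_dosage_table(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    if df.shape[1] < 2:
        raise ValueError(f"dosage table {path} needs a sample column plus >=1 SNP column")
    samples = df.iloc[:, 0].astype(str).tolist()
    dos = df.iloc[:, 1:].to_numpy(dtype=float)
    snp_ids = list(df.columns[1:])
    variants = pd.DataFrame(
        {"snp_id": snp_ids, "chrom": "1", "pos": np.arange(1, len(snp_ids) + 1),
         "ref": "A", "alt": "B", "info_score": np.nan}
    )
    G = GenotypeMatrix(dos, samples, variants)
    G.refresh_metadata()
    return G


def read_sample_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("sample_id", "phenotype") if c not in df.columns]
    if missing:
        raise ValueError(f"sample table lacks columns: {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    bad = set(df["phenotype"].unique()) - {0, 1}
    if bad:
        raise ValueError(f"phenotype must be 0/1; found {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample table")
    return df


def read_gene_map(path: str) -> pd.DataFrame:
    gm = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "gene"], dtype={"chrom": str})
    return validate_gene_map(gm[["gene", "chrom", "start", "end"]])


def validate_gene_map(gm: pd.DataFrame) -> pd.DataFrame:
    gm = gm.copy()
    if gm["gene"].duplicated().any():
        dups = gm.loc[gm["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene names in gene map: {dups[:5]}")
    if (gm["start"] > gm["end"]).any():
        raise ValueError("gene map contains start > end")
    return gm.reset_index(drop=True)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write VCF v4.2 with GT (hard call when dosage is integral) and DS."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=IS,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.samples) + "\n")
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, row in G.variants.iterrows():
            info = "." if not np.isfinite(row.get("info_score", np.nan)) else f"IS={row['info_score']:.4f}"
            fields = [str(row["chrom"]), str(int(row["pos"])), str(row["snp_id"]),
                      str(row["ref"]), str(row["alt"]), ".", "PASS", info, "GT:DS"]
            col = G.dosages[:, j]
            cells = []
            for d in col:
                if math.isnan(d):
                    cells.append("./.:.")
                else:
                    gt = gt_codes.get(float(d), "./.")
                    cells.append(f"{gt}:{d:.6g}")
            fh.write("\t".join(fields + cells) + "\n")


def write_dosage_table(G: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(G.dosages, columns=G.variants["snp_id"])
    df.insert(0, "sample_id", G.samples)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def write_sample_table(samples: pd.DataFrame, path: str) -> None:
    samples.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_gene_map(gm: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tgene  (1-based inclusive coordinates)\n")
        gm[["chrom", "start", "end", "gene"]].to_csv(fh, sep="\t", index=False, header=False)


def write_truth(truth: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Counts and removal lists for each QC filter, in application order."""

    n_samples_in: int = 0
    n_samples_out: int = 0
    n_variants_in: int = 0
    n_variants_out: int = 0
    removed_samples: list[str] = field(default_factory=list)
    removed_by_filter: dict[str, list[str]] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "samples": {"in": self.n_samples_in, "out": self.n_samples_out,
                        "removed": self.removed_samples},
            "variants": {"in": self.n_variants_in, "out": self.n_variants_out,
                         "removed_by_filter": self.removed_by_filter},
            "thresholds": self.thresholds,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_tsv(self, path: str) -> None:
        rows = [("sample_call_rate", "sample", s) for s in self.removed_samples]
        for filt, ids in self.removed_by_filter.items():
            rows += [(filt, "variant", s) for s in ids]
        pd.DataFrame(rows, columns=["filter", "kind", "id"]).to_csv(path, sep="\t", index=False)


def qc_filter(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.99,
    info_min: float = 0.7,
) -> tuple[GenotypeMatrix, QCReport]:
    """Sample then marker QC at the standard common-variant thresholds.

    Retained variants satisfy MAF >= maf_min, call rate >= call_rate_min and
    (info score absent OR info >= info_min); samples below call_rate_min are
    removed first and variant metadata recomputed on the survivors.
    """
    for name, t in (("maf_min", maf_min), ("call_rate_min", call_rate_min), ("info_min", info_min)):
        if not 0 <= t <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    report = QCReport(
        n_samples_in=G.n_samples,
        n_variants_in=G.n_variants,
        thresholds={"maf_min": maf_min, "call_rate_min": call_rate_min, "info_min": info_min},
    )
    sample_cr = 1.0 - np.isnan(G.dosages).mean(axis=1)
    keep_samples = np.flatnonzero(sample_cr >= call_rate_min)
    report.removed_samples = [G.samples[i] for i in np.flatnonzero(sample_cr < call_rate_min)]
    G2 = G.take_samples(keep_samples) if len(keep_samples) < G.n_samples else G
    G2.refresh_metadata()

    v = G2.variants
    ids = v["snp_id"].to_numpy()
    fail_maf = v["maf"].to_numpy() < maf_min
    fail_cr = v["call_rate"].to_numpy() < call_rate_min
    info = v["info_score"].to_numpy(dtype=float)
    fail_info = np.isfinite(info) & (info < info_min)
    report.removed_by_filter = {
        "maf": ids[fail_maf].tolist(),
        "call_rate": ids[fail_cr & ~fail_maf].tolist(),
        "info_score": ids[fail_info & ~fail_maf & ~fail_cr].tolist(),
    }
    keep = ~(fail_maf | fail_cr | fail_info)
    if not keep.any():
        raise ValueError("QC removed every variant; review thresholds")
    out = G2.take_variants(np.flatnonzero(keep))
    report.n_samples_out = out.n_samples
    report.n_variants_out = out.n_variants
    return out, report


def encode_additive(G: GenotypeMatrix, missing_policy: str = "mean-impute") -> np.ndarray:
    """Numeric analysis matrix under the additive (0-2 dosage) encoding.

    ``mean-impute`` replaces missing entries by the variant's observed mean
    dosage; ``drop-sample-per-test`` leaves NaN in place for per-test
    complete-case handling downstream.
    """
    if missing_policy not in ("mean-impute", "drop-sample-per-test"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    dos = G.dosages
    all_missing = np.isnan(dos).all(axis=0)
    if all_missing.any():
        bad = G.variants.loc[all_missing, "snp_id"].tolist()
        raise ValueError(f"variants with all genotypes missing: {bad[:5]}")
    if missing_policy == "drop-sample-per-test" or not np.isnan(dos).any():
        return dos.copy()
    means = np.nanmean(dos, axis=0)
    out = dos.copy()
    idx = np.where(np.isnan(out))
    out[idx] = means[idx[1]]
    return out


def align_samples(G: GenotypeMatrix, S: pd.DataFrame) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Reorder genotypes and sample table to their shared sample ids.

    The output order follows the genotype matrix restricted to the
    intersection; samples present in only one input are dropped.
    """
    s_ids = set(S["sample_id"])
    order = [i for i, s in enumerate(G.samples) if s in s_ids]
    if not order:
        raise ValueError("no overlap between genotype and sample-table ids")
    G2 = G.take_samples(np.array(order), refresh=False)
    S2 = S.set_index("sample_id").loc[G2.samples].reset_index()
    return G2, S2
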