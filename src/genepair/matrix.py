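"""Core genotype container shared by every stage of the pipeline.

Dosages are additive allele counts (or imputed expected counts) in [0, 2],
stored as a dense float array with NaN marking missing genotypes.  Per-variant
metadata (position, MAF, call rate, optional imputation info score) travels
with the matrix so QC filters and gene-window annotation never need to re-read
the source files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "info_score", "call_rate", "maf"]


def maf_from_dosages(dos: np.ndarray) -> np.ndarray:
    """Minor allele frequency per variant: min(p, 1-p) with p = mean(dosage)/2.

    Missing entries (NaN) are ignored. `dos` is (n_samples, n_variants).
    """
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        p = np.nanmean(dos, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def call_rate_from_dosages(dos: np.ndarray) -> np.ndarray:
    return 1.0 - np.isnan(dos).mean(axis=0)


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage matrix with variant metadata.

    Attributes
    ----------
    dosages : float ndarray, shape (n_samples, n_variants), NaN = missing
    samples : list of sample identifiers, row order of `dosages`
    variants : DataFrame with columns ``snp_id, chrom, pos, ref, alt,
        info_score, call_rate, maf`` (``info_score`` may be NaN = not imputed)
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} dosage rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant records for {m} dosage columns")
        self.variants = self.variants.reset_index(drop=True)
        missing = [c for c in ("snp_id", "chrom", "pos") if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks required columns: {missing}")
        for col, default in (("ref", "A"), ("alt", "B"), ("info_score", np.nan)):
            if col not in self.variants.columns:
                self.variants[col] = default
        if self.variants["snp_id"].duplicated().any():
            dup = self.variants.loc[self.variants["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate variant ids: {dup[:5]}")
        self.refresh_metadata(only_missing=True)

    # -- metadata -------------------------------------------------------
    def refresh_metadata(self, only_missing: bool = False) -> None:
        """(Re)compute per-variant MAF and call rate from the dosage values."""
        have = only_missing and {"maf", "call_rate"} <= set(self.variants.columns)
        if not have:
            self.variants["maf"] = maf_from_dosages(self.dosages)
            self.variants["call_rate"] = call_rate_from_dosages(self.dosages)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.variants["snp_id"].tolist()

    def variant_index(self, snp_ids) -> np.ndarray:
        """Column indices for the given snp ids (order preserved, KeyError if absent)."""
        lookup = {s: i for i, s in enumerate(self.variants["snp_id"])}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown snp id {e.args[0]!r}") from None

    def dosage(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_index([snp_id])[0]]

    # -- subsetting ------------------------------------------------------
    def take_samples(self, idx: np.ndarray, refresh: bool = True) -> "GenotypeMatrix":
        out = GenotypeMatrix(
            dosages=self.dosages[np.asarray(idx, dtype=int)],
            samples=[self.samples[i] for i in idx],
            variants=self.variants.copy(),
        )
        if refresh:
            out.refresh_metadata()
        return out

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
        )

    def select_snps(self, snp_ids) -> "GenotypeMatrix":
        return self.take_variants(self.variant_index(snp_ids))
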