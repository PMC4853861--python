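"""Shared in-memory containers for the pipeline.

Genotypes are additive dosages in {0, 1, 2} (alternate-allele count);
expression is a continuous samples x genes matrix; gene annotation is a
DataFrame indexed by gene id with columns ``chrom, start, end, strand, tss``
(interval 0-based half-open; ``tss`` a 0-based coordinate).  SNP metadata
uses 1-based positions (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SNP_COLUMNS = ["chrom", "pos", "ref", "alt", "n_alleles"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix plus per-SNP metadata.

    Attributes
    ----------
    dosages : DataFrame, samples x SNPs, integer values in {0, 1, 2}.
    snps : DataFrame indexed by SNP id (rsID), columns at least
        ``chrom`` and ``pos`` (1-based); optionally ``ref``, ``alt``,
        ``n_alleles``.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.snps.index):
            if set(self.dosages.columns) != set(self.snps.index):
                raise ValueError("dosage columns and SNP metadata disagree")
            self.snps = self.snps.loc[self.dosages.columns]
        missing = {"chrom", "pos"} - set(self.snps.columns)
        if missing:
            raise ValueError(f"SNP metadata missing columns: {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    def dosage_vector(self, snp_id: str) -> np.ndarray:
        return self.dosages[snp_id].to_numpy(dtype=float)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        ids = [s for s in snp_ids if s in self.dosages.columns]
        return GenotypeMatrix(dosages=self.dosages.loc[:, ids].copy(),
                              snps=self.snps.loc[ids].copy())


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    missing = {"chrom", "start", "end", "strand", "tss"} - set(annotation.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    return annotation
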