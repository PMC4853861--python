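"""Readers and writers for the pipeline's file formats.

Formats: genotype TSV (SNP metadata + per-sample dosage columns), a
minimal text VCF subset (GT field, biallelic records), expression TSV
(samples x genes), gene-annotation TSV, BED3/BED5 (score column carries
peak fold-enrichment; name column carries labels such as chromatin
states), GWAS catalog TSV, edge-list TSV and a JSON run manifest.

Coordinates: BED files are 0-based half-open; VCF and the genotype/GWAS
TSVs use 1-based positions.  Readers convert to the in-memory conventions
documented in :mod:`eqtldecon.types` at the boundary.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .types import GenotypeMatrix

logger = logging.getLogger(__name__)

_META_COLS = ["snp", "chrom", "pos", "ref", "alt", "n_alleles"]


def write_genotypes_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    meta = geno.snps.copy()
    meta.index.name = "snp"
    for col in ("ref", "alt"):
        if col not in meta.columns:
            meta[col] = "."
    if "n_alleles" not in meta.columns:
        meta["n_alleles"] = 2
    df = meta[["chrom", "pos", "ref", "alt", "n_alleles"]].join(
        geno.dosages.T)
    df.reset_index().to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"snp", "chrom", "pos"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.set_index("snp")
    meta_cols = [c for c in _META_COLS[1:] if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_cols].T
    dosages = _impute_missing(dosages, str(path))
    return GenotypeMatrix(dosages=dosages, snps=df[meta_cols])


def _impute_missing(dosages: pd.DataFrame, source: str) -> pd.DataFrame:
    if dosages.isna().any().any():
        n_missing = int(dosages.isna().sum().sum())
        warnings.warn(f"{source}: imputed {n_missing} missing dosage(s) "
                      "with the rounded per-SNP mean", stacklevel=3)
        means = dosages.mean(axis=0).round().fillna(0)
        dosages = dosages.fillna(means)
    bad = ~dosages.isin([0, 1, 2]).all(axis=None)
    if bad:
        raise ValueError(f"{source}: dosages must be 0/1/2")
    return dosages.astype(np.int8)


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, int]:
    """Minimal VCF reader: GT field only, biallelic records.

    Multi-allelic records are skipped (count returned).  GT codes:
    0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2; missing (./.) imputed with the
    rounded per-SNP mean afterwards.  Malformed lines raise with the line
    number.
    """
    samples: list[str] = []
    meta_rows: list[dict] = []
    dosage_rows: list[list[float]] = []
    skipped_multiallelic = 0
    gt_map = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
              "1/1": 2, "1|1": 2}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ValueError(f"{path}:{line_no}: VCF header has no samples")
                samples = fields[9:]
                continue
            if not samples:
                raise ValueError(f"{path}:{line_no}: record before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise ValueError(
                    f"{path}:{line_no}: expected {9 + len(samples)} fields, "
                    f"got {len(fields)}")
            chrom, pos, snp_id, ref, alt = fields[0], fields[1], fields[2], \
                fields[3], fields[4]
            if "," in alt:
                skipped_multiallelic += 1
                continue
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise ValueError(f"{path}:{line_no}: no GT in FORMAT")
            gt_idx = fmt.index("GT")
            row: list[float] = []
            for s_field in fields[9:]:
                gt = s_field.split(":")[gt_idx]
                if gt in gt_map:
                    row.append(gt_map[gt])
                elif gt in ("./.", ".|.", "."):
                    row.append(np.nan)
                else:
                    raise ValueError(f"{path}:{line_no}: unparseable GT {gt!r}")
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: bad POS {pos!r}") from exc
            meta_rows.append({"snp": snp_id, "chrom": chrom, "pos": pos_i,
                              "ref": ref, "alt": alt, "n_alleles": 2})
            dosage_rows.append(row)
    meta = pd.DataFrame(meta_rows, columns=_META_COLS).set_index("snp")
    dosages = pd.DataFrame(np.array(dosage_rows, dtype=float).T
                           if dosage_rows else np.empty((len(samples), 0)),
                           index=samples, columns=meta.index)
    dosages = _impute_missing(dosages, str(path))
    return GenotypeMatrix(dosages=dosages, snps=meta), skipped_multiallelic


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    dose_to_gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        mat = geno.dosages.to_numpy()
        for j, (snp_id, rec) in enumerate(geno.snps.iterrows()):
            gts = "\t".join(dose_to_gt[int(d)] for d in mat[:, j])
            fh.write(f"{rec['chrom']}\t{rec['pos']}\t{snp_id}\t"
                     f"{rec.get('ref', 'A')}\t{rec.get('alt', 'G')}\t.\t.\t.\t"
                     f"GT\t{gts}\n")


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    if format == "tsv":
        return read_genotypes_tsv(path)
    if format == "vcf":
        geno, skipped = read_vcf(path)
        if skipped:
            logger.info("%s: skipped %d multi-allelic record(s)", path, skipped)
        return geno
    raise ValueError(f"unknown genotype format {format!r}")


# -- matrices and tables -------------------------------------------------

def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    out = expr.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"chrom": str})
    missing = {"chrom", "start", "end", "strand", "tss"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation missing {sorted(missing)}")
    return df


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    cols = ["chrom", "start", "end"]
    df = intervals.df
    for col in ("name", "score", "strand"):
        if col in df.columns:
            cols.append(col)
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    return IntervalSet(df)


def write_gwas_tsv(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"trait", "snp", "chrom", "pos"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: GWAS catalog missing {sorted(missing)}")
    return df


def write_edges_tsv(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edges_tsv(path: str | Path):
    import networkx as nx
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs two columns")
    g = nx.Graph()
    g.add_edges_from(df.iloc[:, :2].itertuples(index=False, name=None))
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def write_manifest(path: str | Path, **entries) -> None:
    from . import __version__
    payload = {"version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
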