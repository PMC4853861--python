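"""Pipeline driver: chain QC -> expression adjustment -> eQTL scan -> LD
expansion -> deconvolution -> enrichment -> network statistics from files
on disk, writing every stage's table plus a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .adjust import AdjustmentConfig, adjust_expression
from .deconv import DeconvolutionConfig, connection_matrix, deconvolve
from .enrichment import catalog_enrichment, state_fold_enrichment
from .eqtl import EqtlScan, EqtlScanConfig
from .ld import expand
from .network import lcc_size, lcc_zscore, mean_shortest_distance
from .qc import QcThresholds, filter_snps, genotype_pca

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and per-stage settings for a full run.

    ``peak_paths`` maps cell type -> mark -> BED path.  ``covariate_path``
    (optional TSV, samples x covariates, e.g. age) is concatenated with the
    genotype PCs.
    """

    genotype_path: str = ""
    genotype_format: str = "tsv"
    expression_path: str = ""
    annotation_path: str = ""
    gwas_path: str = ""
    peak_paths: dict = field(default_factory=dict)
    segmentation_path: str | None = None
    network_path: str | None = None
    covariate_path: str | None = None
    output_dir: str = "pipeline_out"
    seed: int = 0
    n_genotype_pcs: int = 3
    qc: QcThresholds = field(default_factory=QcThresholds)
    adjustment: AdjustmentConfig = field(default_factory=AdjustmentConfig)
    scan: EqtlScanConfig = field(default_factory=lambda: EqtlScanConfig(
        n_permutations=10))
    deconvolution: DeconvolutionConfig = field(default_factory=DeconvolutionConfig)
    ld_r2_min: float = 0.8
    ld_window: int = 1_000_000
    network_permutations: int = 10_000
    genome_lengths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {}
        for key, value in raw.items():
            if key == "qc":
                value = QcThresholds(**value)
            elif key == "adjustment":
                value = AdjustmentConfig(**value)
            elif key == "scan":
                value = EqtlScanConfig(**value)
            elif key == "deconvolution":
                value = DeconvolutionConfig(**value)
            known[key] = value
        return cls(**known)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a dict of in-memory stage outputs and
    writes TSV/JSON artifacts under ``config.output_dir``."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s", name)
                fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, exc) from exc
        return deco

    state: dict = {}

    @stage("load")
    def _load():
        state["geno"] = io.read_genotypes(config.genotype_path,
                                          config.genotype_format)
        state["expr"] = io.read_expression_tsv(config.expression_path)
        state["annotation"] = io.read_annotation_tsv(config.annotation_path)
        state["gwas"] = io.read_gwas_tsv(config.gwas_path)

    @stage("qc")
    def _qc():
        geno, removed = filter_snps(state["geno"], config.qc)
        state["geno"] = geno
        outputs["qc_removed"] = removed
        removed.rename_axis("criterion").to_frame().to_csv(
            out_dir / "qc_report.tsv", sep="\t")
        io.write_genotypes_tsv(geno, out_dir / "genotypes_filtered.tsv")
        pcs = genotype_pca(geno, config.n_genotype_pcs)
        cov = pcs.scores
        if config.covariate_path:
            extra = pd.read_csv(config.covariate_path, sep="\t", index_col=0)
            cov = cov.join(extra.loc[cov.index])
        state["covariates"] = cov if cov.shape[1] else None

    @stage("adjust")
    def _adjust():
        expr = state["expr"]
        geno = state["geno"]
        if set(expr.index) != set(geno.sample_ids):
            diff = set(expr.index) ^ set(geno.sample_ids)
            raise ValueError(f"expression/genotype sample mismatch: {sorted(diff)[:5]}")
        expr = expr.loc[geno.sample_ids]
        state["adjusted"] = adjust_expression(expr, config.adjustment)
        io.write_expression_tsv(state["adjusted"],
                                out_dir / "expression_adjusted.tsv")

    @stage("eqtl")
    def _eqtl():
        scan = EqtlScan(state["geno"], state["adjusted"], state["annotation"],
                        covariates=state["covariates"], config=config.scan)
        res = scan.fit()
        state["eqtl"] = res
        res.records.to_csv(out_dir / "eqtl_records.tsv", sep="\t", index=False)
        (out_dir / "eqtl_summary.txt").write_text(res.summary() + "\n")

    @stage("ld")
    def _ld():
        index_snps = sorted(set(state["gwas"]["snp"]))
        state["ld"] = expand(index_snps, state["geno"],
                             r2_min=config.ld_r2_min,
                             search_window=config.ld_window)
        state["ld"].to_frame().to_csv(out_dir / "ld_proxies.tsv",
                                      sep="\t", index=False)

    @stage("deconvolve")
    def _deconvolve():
        epigenomes = {
            ct: {mark: io.read_bed(path) for mark, path in marks.items()}
            for ct, marks in config.peak_paths.items()}
        records, epis = deconvolve(
            epigenomes, sorted(set(state["gwas"]["snp"])), state["ld"],
            state["geno"], state["adjusted"], state["annotation"],
            covariates=state["covariates"], config=config.deconvolution)
        state["connections"] = records
        records.to_csv(out_dir / "connections.tsv", sep="\t", index=False)
        connection_matrix(records).to_csv(out_dir / "connection_matrix.tsv",
                                          sep="\t")

    @stage("enrich")
    def _enrich():
        sig = state["eqtl"].significant("cis")
        query = set(sig["snp"])
        enr = catalog_enrichment(query, state["gwas"])
        enr.to_csv(out_dir / "catalog_enrichment.tsv", sep="\t", index=False)
        outputs["catalog_enrichment"] = enr
        if config.segmentation_path and config.genome_lengths:
            seg = io.read_bed(config.segmentation_path)
            pos = state["geno"].snps.loc[
                state["geno"].snps.index.intersection(query),
                ["chrom", "pos"]]
            if len(pos):
                folds = state_fold_enrichment(pos, seg, config.genome_lengths)
                folds.rename_axis("state").to_frame().to_csv(
                    out_dir / "state_fold_enrichment.tsv", sep="\t")
                outputs["state_folds"] = folds

    @stage("network")
    def _network():
        if not config.network_path:
            return
        net = io.read_edges_tsv(config.network_path)
        genes = set(state["connections"]["gene"].dropna())
        if len(genes & set(net.nodes)) >= 2:
            stats = lcc_zscore(genes, net, n_perm=config.network_permutations,
                               seed=config.seed)
            stats.update(mean_shortest_distance(genes, net))
            stats["lcc_size"] = lcc_size(genes, net)
        else:
            stats = {"lcc_size": lcc_size(genes, net), "z": None}
        outputs["network"] = stats
        io.write_manifest(out_dir / "network_stats.json", **stats)

    outputs["connections"] = state.get("connections")
    outputs["eqtl"] = state.get("eqtl")
    io.write_manifest(
        out_dir / "manifest.json",
        seed=config.seed,
        parameters={
            "qc": vars(config.qc), "adjustment": vars(config.adjustment),
            "scan": {k: v for k, v in vars(config.scan).items()},
            "ld_r2_min": config.ld_r2_min,
            "n_genotype_pcs": config.n_genotype_pcs,
        },
        inputs={name: _checksum(p) for name, p in [
            ("genotypes", config.genotype_path),
            ("expression", config.expression_path),
            ("annotation", config.annotation_path),
            ("gwas", config.gwas_path)] if p and Path(p).exists()},
    )
    return outputs
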