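"""Synthetic cohort generator with planted ground truth.

Every input the pipeline consumes can be generated here: biallelic SNP
dosages in LD blocks, expression with planted cis effects and low-rank
confounding, gene annotation, histone-mark peak sets (with planted
enhancers over named SNPs and active/inactive promoter marks), a
chromatin-state segmentation, a GWAS catalog whose index SNPs tag planted
enhancer SNPs through LD, and an interaction network with a planted
connected module.  All randomness flows from one integer seed through
per-stage child generators, so a fixed config reproduces every artifact
exactly; planted truth is returned so downstream stages can be verified by
recovery.

LD is generated by a haplotype-copy scheme: each block has a latent "core"
allele per haplotype; each SNP copies the core allele with probability
``theta = r2_target ** 0.25`` and otherwise draws a fresh allele at the
block frequency.  The allele-allele correlation is then ``theta**2`` so the
realized dosage r² concentrates on the target.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .intervals import IntervalSet, promoter_windows
from .types import GenotypeMatrix

NINE_STATES = ("TSS", "Tx", "Enh", "EnhA", "Het", "EnhBiv", "TssBiv",
               "ReprPC", "Quies")

MIN_SNP_SPACING = 100  # bp


@dataclass(frozen=True)
class PlantedEffect:
    snp: str
    gene: str
    beta: float


@dataclass(frozen=True)
class PlantedEnhancer:
    cell_type: str
    mark: str
    snp: str
    fold: float = 6.0
    length: int = 1000


@dataclass(frozen=True)
class PeakSpec:
    cell_types: tuple[str, ...] = ("monocyte", "bcell", "tcell")
    marks: tuple[str, ...] = ("H3K27ac", "H3K4me1", "H3K4me3")
    n_background_peaks: int = 40          # per (cell type, mark)
    peak_length_range: tuple[int, int] = (300, 2000)
    fold_range: tuple[float, float] = (0.5, 7.5)  # half of mass below 4
    planted_enhancers: tuple[PlantedEnhancer, ...] = ()
    inactive_gene_fraction: float = 0.2   # genes lacking promoter marks


@dataclass(frozen=True)
class GwasSpec:
    traits: tuple[tuple[str, tuple[str, ...]], ...] = ()


@dataclass(frozen=True)
class NetworkSpec:
    n_extra_nodes: int = 50
    edge_density: float = 0.01
    module_genes: tuple[str, ...] = ()
    module_shape: str = "clique"  # or "path"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a blood eQTL cohort: 377 samples, SNPs in LD blocks
    with MAF in (0.05, 0.5), strong planted cis effects on the expression-SD
    scale, unit expression noise and low-rank confounding.
    """

    n_samples: int = 377
    genome: tuple[tuple[str, int], ...] = (("chr1", 20_000_000),
                                           ("chr2", 20_000_000),
                                           ("chr6", 40_000_000))
    n_snps: int = 300
    ld_blocks: tuple[tuple[int, float], ...] = ((4, 0.9), (3, 0.5), (3, 0.0))
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 100
    planted_cis_effects: tuple[PlantedEffect, ...] = ()
    noise_sd: float = 1.0
    n_confounder_pcs: int = 0
    confounder_scale: float = 1.0
    peak_spec: PeakSpec = field(default_factory=PeakSpec)
    gwas_spec: GwasSpec = field(default_factory=GwasSpec)
    network_spec: NetworkSpec = field(default_factory=NetworkSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_snps, self.n_genes) <= 0:
            raise ValueError("all counts must be > 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for size, r2t in self.ld_blocks:
            if size < 1 or not 0 <= r2t <= 1:
                raise ValueError("ld_blocks entries must be (size>=1, r2 in [0,1])")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def snp_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_snps))
    return [f"rs{str(i + 1).zfill(width)}" for i in range(config.n_snps)]


def gene_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_genes))
    return [f"g{str(i + 1).zfill(width)}" for i in range(config.n_genes)]


def snp_map(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic SNP metadata: chrom, 1-based pos, LD block id and
    per-block r² target.  Positions are strictly increasing per chromosome;
    LD blocks never span chromosomes (truncated at boundaries).
    """
    rng = _rng(config, 0)
    total_len = sum(length for _, length in config.genome)
    ids = snp_ids(config)
    # allocate SNPs to chromosomes proportional to length (largest remainder)
    raw = np.array([length / total_len * config.n_snps
                    for _, length in config.genome])
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: config.n_snps - counts.sum()]:
        counts[i] += 1
    rows = []
    i_snp = 0
    block_id = 0
    block_pattern = list(config.ld_blocks)
    pat_pos = 0
    remaining_in_block = 0
    for (chrom, length), n_chrom in zip(config.genome, counts):
        if n_chrom == 0:
            continue
        if n_chrom * MIN_SNP_SPACING > length:
            raise ValueError(
                f"{n_chrom} SNPs do not fit on {chrom} ({length} bp) at "
                f"{MIN_SNP_SPACING} bp minimum spacing")
        spacing = length // (n_chrom + 1)
        jitter = rng.integers(0, max(spacing // 4, 1), size=n_chrom)
        pos = (np.arange(1, n_chrom + 1) * spacing + jitter).astype(np.int64)
        pos = np.minimum(pos, length - 1)
        pos = np.maximum.accumulate(pos)  # keep strictly increasing after clamp
        pos += np.arange(n_chrom)  # break any equalities
        remaining_in_block = 0     # blocks do not span chromosomes
        for p in pos:
            if remaining_in_block == 0:
                size, r2t = block_pattern[pat_pos % len(block_pattern)]
                pat_pos += 1
                block_id += 1
                remaining_in_block = size
                current_r2 = r2t
            rows.append({"snp": ids[i_snp], "chrom": chrom, "pos": int(p),
                         "block": block_id, "block_r2": current_r2})
            remaining_in_block -= 1
            i_snp += 1
    df = pd.DataFrame(rows).set_index("snp")
    df["ref"] = "A"
    df["alt"] = "G"
    df["n_alleles"] = 2
    return df


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Dosage matrix with block-structured LD at the configured r² targets."""
    smap = snp_map(config)
    rng = _rng(config, 1)
    n = config.n_samples
    dosage = np.zeros((n, len(smap)), dtype=np.int8)
    cols = np.arange(len(smap))
    for _, idx in pd.Series(cols, index=smap.index).groupby(smap["block"].to_numpy()):
        j = idx.to_numpy()
        m = len(j)
        r2t = smap["block_r2"].iloc[j[0]]
        theta = float(r2t) ** 0.25
        p = rng.uniform(*config.maf_range)
        core = rng.random((n, 2)) < p                     # core allele per haplotype
        copy = rng.random((n, 2, m)) < theta              # copy core or fresh draw
        fresh = rng.random((n, 2, m)) < p
        haps = np.where(copy, core[:, :, None], fresh)
        dosage[:, j] = haps.sum(axis=1)
    dosages = pd.DataFrame(dosage, columns=smap.index,
                           index=[f"sample{str(i + 1).zfill(3)}" for i in range(n)])
    return GenotypeMatrix(dosages=dosages,
                          snps=smap[["chrom", "pos", "ref", "alt",
                                     "n_alleles", "block", "block_r2"]])


def simulate_expression(geno: GenotypeMatrix, config: SimulationConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression = planted cis effects + low-rank confounders + noise.

    Returns (samples x genes DataFrame, ground-truth table of planted
    (snp, gene, beta)).
    """
    genes = gene_ids(config)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for eff in config.planted_cis_effects:
        if eff.snp not in geno.dosages.columns:
            raise ValueError(f"planted effect references unknown SNP {eff.snp}")
        if eff.gene not in gene_pos:
            raise ValueError(f"planted effect references unknown gene {eff.gene}")
    rng = _rng(config, 5)
    n = config.n_samples
    expr = rng.normal(0.0, config.noise_sd, size=(n, len(genes)))
    if config.n_confounder_pcs > 0:
        factors = rng.normal(size=(n, config.n_confounder_pcs))
        loadings = rng.normal(0.0, config.confounder_scale,
                              size=(config.n_confounder_pcs, len(genes)))
        expr += factors @ loadings
        self_factors = factors
    else:
        self_factors = np.zeros((n, 0))
    for eff in config.planted_cis_effects:
        expr[:, gene_pos[eff.gene]] += eff.beta * geno.dosage_vector(eff.snp)
    truth = pd.DataFrame(
        [{"snp": e.snp, "gene": e.gene, "beta": e.beta}
         for e in config.planted_cis_effects],
        columns=["snp", "gene", "beta"])
    df = pd.DataFrame(expr, index=geno.dosages.index, columns=genes)
    df.attrs["confounder_factors"] = self_factors
    return df, truth


def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Gene annotation: chrom, start, end (0-based half-open), strand, tss."""
    rng = _rng(config, 2)
    total_len = sum(length for _, length in config.genome)
    genes = gene_ids(config)
    raw = np.array([length / total_len * config.n_genes
                    for _, length in config.genome])
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: config.n_genes - counts.sum()]:
        counts[i] += 1
    rows = []
    i_gene = 0
    for (chrom, length), n_chrom in zip(config.genome, counts):
        if n_chrom == 0:
            continue
        spacing = length // (n_chrom + 1)
        for k in range(n_chrom):
            g_len = int(rng.integers(2_000, min(20_000, max(spacing // 2, 2_001))))
            start = int((k + 1) * spacing)
            start = min(start, length - g_len - 600)
            strand = "+" if rng.random() < 0.5 else "-"
            end = start + g_len
            tss = start if strand == "+" else end
            rows.append({"gene": genes[i_gene], "chrom": chrom, "start": start,
                         "end": end, "strand": strand, "tss": tss})
            i_gene += 1
    return pd.DataFrame(rows).set_index("gene")


def simulate_annotation_and_peaks(config: SimulationConfig) -> tuple[
        pd.DataFrame, dict[tuple[str, str], IntervalSet], IntervalSet, dict]:
    """Gene annotation, per-(cell type, mark) peak sets, a nine-state
    segmentation tiling the genome, and the planted-truth record.

    Background peaks carry fold-enrichment scores straddling 4 so the
    ``> 4`` filter removes roughly the configured fraction; planted enhancer
    peaks cover their named SNP and score above 4.  Per cell type, each gene
    drawn "active" receives an H3K4me3 promoter peak (fold > 4) at its TSS;
    the inactive fraction receives none.
    """
    spec = config.peak_spec
    annotation = simulate_annotation(config)
    smap = snp_map(config)
    for pe in spec.planted_enhancers:
        if pe.snp not in smap.index:
            raise ValueError(f"planted enhancer names unknown SNP {pe.snp}")
    chrom_lengths = dict(config.genome)
    promoters = promoter_windows(annotation, chrom_lengths=chrom_lengths)
    rng = _rng(config, 3)

    # SNP positions whose LD block is tagged by a planted enhancer or GWAS
    # index SNP: background peaks stay clear of them so that recovery of a
    # planted chain is attributable to the planted peak alone.
    tagged = {pe.snp for pe in spec.planted_enhancers}
    for _, snps_t in config.gwas_spec.traits:
        tagged.update(snps_t)
    tagged &= set(smap.index)
    tagged_blocks = set(smap.loc[sorted(tagged), "block"]) if tagged else set()
    protected = smap[smap["block"].isin(tagged_blocks)]
    protected_pos = {(c, int(p) - 1) for c, p in
                     zip(protected["chrom"], protected["pos"])}

    genes = list(annotation.index)
    planted_genes = {e.gene for e in config.planted_cis_effects}
    active: dict[str, list[str]] = {}
    inactive_sets: dict[str, set[str]] = {}
    for ct in spec.cell_types:
        candidates = [g for g in genes if g not in planted_genes]
        n_inactive = min(int(round(spec.inactive_gene_fraction * len(genes))),
                         len(candidates))
        inactive = set(rng.choice(candidates, size=n_inactive, replace=False))
        inactive_sets[ct] = inactive
        active[ct] = [g for g in genes if g not in inactive]

    def _covers_protected(chrom: str, start: int, end: int) -> bool:
        return any(c == chrom and start <= b < end for c, b in protected_pos)

    def _on_inactive_promoter(ct: str, chrom: str, start: int, end: int) -> bool:
        pr = promoters.df
        sub = pr[(pr["chrom"] == chrom) & pr["name"].isin(inactive_sets[ct])]
        return bool(((sub["start"] < end) & (sub["end"] > start)).any())

    activity_marks = {"H3K27ac", "H3K4me3"}
    peaks: dict[tuple[str, str], IntervalSet] = {}
    for ct in spec.cell_types:
        for mark in spec.marks:
            rows = []
            lo, hi = spec.peak_length_range
            for i in range(spec.n_background_peaks):
                chrom, length = config.genome[int(rng.integers(len(config.genome)))]
                plen = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, max(length - plen, 1)))
                fold = float(rng.uniform(*spec.fold_range))
                if _covers_protected(chrom, start, start + plen):
                    continue
                if (mark in activity_marks
                        and _on_inactive_promoter(ct, chrom, start, start + plen)):
                    continue
                rows.append({"chrom": chrom, "start": start, "end": start + plen,
                             "name": f"{ct}_{mark}_bg{i}", "score": fold})
            if mark == "H3K4me3":
                # planted promoter marks for active genes
                for g in active[ct]:
                    tss = int(annotation.loc[g, "tss"])
                    chrom = annotation.loc[g, "chrom"]
                    rows.append({"chrom": chrom, "start": max(tss - 400, 0),
                                 "end": tss + 400,
                                 "name": f"{ct}_{mark}_prom_{g}",
                                 "score": float(rng.uniform(4.5, 8.0))})
            for pe in spec.planted_enhancers:
                if pe.cell_type == ct and pe.mark == mark:
                    pos0 = int(smap.loc[pe.snp, "pos"]) - 1
                    half = pe.length // 2
                    rows.append({"chrom": smap.loc[pe.snp, "chrom"],
                                 "start": max(pos0 - half, 0),
                                 "end": pos0 + half + 1,
                                 "name": f"{ct}_{mark}_enh_{pe.snp}",
                                 "score": float(pe.fold)})
            peaks[(ct, mark)] = IntervalSet(pd.DataFrame(
                rows, columns=["chrom", "start", "end", "name", "score"]))

    seg_rows = []
    rng_seg = _rng(config, 4)
    for chrom, length in config.genome:
        pos = 0
        while pos < length:
            seg_len = int(rng_seg.integers(50_000, 500_000))
            end = min(pos + seg_len, length)
            state = NINE_STATES[int(rng_seg.integers(len(NINE_STATES)))]
            seg_rows.append({"chrom": chrom, "start": pos, "end": end,
                             "name": state})
            pos = end
    segmentation = IntervalSet(pd.DataFrame(seg_rows))
    truth = {"active_genes": active,
             "planted_enhancers": list(spec.planted_enhancers),
             "promoters": promoters}
    return annotation, peaks, segmentation, truth


def simulate_gwas_and_network(config: SimulationConfig
                              ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """GWAS catalog (trait, snp, chrom, pos) and an undirected simple
    network edge list containing the planted module as a connected induced
    subgraph.
    """
    smap = snp_map(config)
    rows = []
    for trait, snps in config.gwas_spec.traits:
        for s in snps:
            if s not in smap.index:
                raise ValueError(f"GWAS spec names unknown SNP {s}")
            rows.append({"trait": trait, "snp": s,
                         "chrom": smap.loc[s, "chrom"],
                         "pos": int(smap.loc[s, "pos"])})
    catalog = pd.DataFrame(rows, columns=["trait", "snp", "chrom", "pos"])

    nspec = config.network_spec
    genes = gene_ids(config)
    nodes = genes + [f"x{str(i + 1).zfill(3)}" for i in range(nspec.n_extra_nodes)]
    for g in nspec.module_genes:
        if g not in nodes:
            raise ValueError(f"planted module node {g} absent from node set")
    rng = _rng(config, 6)
    graph = nx.fast_gnp_random_graph(len(nodes), nspec.edge_density,
                                     seed=int(rng.integers(2 ** 31)))
    graph = nx.relabel_nodes(graph, dict(enumerate(nodes)))
    module = list(nspec.module_genes)
    if nspec.module_shape == "clique":
        for i in range(len(module)):
            for j in range(i + 1, len(module)):
                graph.add_edge(module[i], module[j])
    else:  # path
        for a, b in zip(module, module[1:]):
            graph.add_edge(a, b)
    graph.remove_edges_from(nx.selfloop_edges(graph))
    edges = pd.DataFrame(sorted((min(a, b), max(a, b)) for a, b in graph.edges()),
                         columns=["node_a", "node_b"])
    truth = {"module_genes": module, "nodes": nodes}
    return catalog, edges, truth


@dataclass
class SimulatedStudy:
    """All pipeline inputs plus planted ground truth."""

    config: SimulationConfig
    geno: GenotypeMatrix
    expr: pd.DataFrame
    annotation: pd.DataFrame
    peaks: dict[tuple[str, str], IntervalSet]
    segmentation: IntervalSet
    gwas_catalog: pd.DataFrame
    network_edges: pd.DataFrame
    truth: dict


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate every pipeline input from one config."""
    geno = simulate_genotypes(config)
    expr, effect_truth = simulate_expression(geno, config)
    annotation, peaks, segmentation, epi_truth = simulate_annotation_and_peaks(config)
    catalog, edges, net_truth = simulate_gwas_and_network(config)
    truth = {"planted_effects": effect_truth, **epi_truth, **net_truth,
             "snp_map": snp_map(config)}
    return SimulatedStudy(config=config, geno=geno, expr=expr,
                          annotation=annotation, peaks=peaks,
                          segmentation=segmentation, gwas_catalog=catalog,
                          network_edges=edges, truth=truth)


def plant_cis_effects(config: SimulationConfig, n_effects: int,
                      beta: float = 1.0,
                      cis_window: int = 1_000_000) -> SimulationConfig:
    """Return a copy of ``config`` with ``n_effects`` cis effects planted:
    evenly spread genes, each paired with the SNP nearest its TSS (must lie
    within ``cis_window``)."""
    smap = snp_map(config)
    annotation = simulate_annotation(config)
    genes = list(annotation.index)
    if n_effects > len(genes):
        raise ValueError("more effects than genes")
    step = max(len(genes) // n_effects, 1)
    chosen = genes[::step][:n_effects]
    effects = []
    for g in chosen:
        row = annotation.loc[g]
        same = smap[smap["chrom"] == row["chrom"]]
        if same.empty:
            raise ValueError(f"no SNPs on {row['chrom']} for gene {g}")
        dist = (same["pos"] - int(row["tss"])).abs()
        snp = dist.idxmin()
        if dist.loc[snp] >= cis_window:
            raise ValueError(f"nearest SNP to {g} is outside the cis window")
        effects.append(PlantedEffect(snp=snp, gene=g, beta=beta))
    return dataclasses.replace(config, planted_cis_effects=tuple(effects))


def make_planted_study(n_chains: int = 5, beta: float = 1.5,
                       noise_sd: float = 0.3, n_samples: int = 377,
                       n_confounder_pcs: int = 0, seed: int = 0,
                       n_decoy_hla: int = 2,
                       cell_types: tuple[str, ...] = ("monocyte", "bcell", "tcell"),
                       marks: tuple[str, ...] = ("H3K27ac", "H3K4me1"),
                       ) -> SimulationConfig:
    """Build a config with planted GWAS -> LD proxy -> enhancer -> active
    gene chains plus decoys (inactive genes, HLA-excluded index SNPs).

    Each chain picks a high-LD block: the first block SNP is the GWAS index
    SNP, the second is the enhancer proxy; a cis gene (within 1 Mb, promoter
    > 2.5 kb away from the proxy) is the planted eQTL target and the
    enhancer peak covers the proxy in every requested (cell type, mark).
    HLA decoy index SNPs sit in chr6:25-35 Mb and must contribute nothing.
    """
    base = SimulationConfig(seed=seed, n_samples=n_samples, noise_sd=noise_sd,
                            n_confounder_pcs=n_confounder_pcs)
    smap = snp_map(base)
    annotation = simulate_annotation(base)
    prom = promoter_windows(annotation).df

    hla = ((smap["chrom"] == "chr6") & (smap["pos"] >= 25_000_000)
           & (smap["pos"] < 35_000_000))
    blocks = smap[smap["block_r2"] >= 0.8]
    chain_snps: list[tuple[str, str]] = []  # (index snp, proxy snp)
    chain_genes: list[str] = []
    used_genes: set[str] = set()
    for block_id, members in blocks.groupby("block"):
        if len(chain_snps) >= n_chains:
            break
        if len(members) < 2 or hla.loc[members.index].any():
            continue
        index_snp, proxy_snp = members.index[0], members.index[1]
        ppos = int(members["pos"].iloc[1])
        pchrom = members["chrom"].iloc[1]
        cands = annotation[(annotation["chrom"] == pchrom)
                           & (abs(annotation["tss"] - ppos) < 900_000)
                           & (~annotation.index.isin(used_genes))]
        # proxy must be clear of every promoter window (enhancer geometry)
        ok_gene = None
        for g, row in cands.iterrows():
            clear = True
            for _, w in prom[prom["chrom"] == pchrom].iterrows():
                if w["start"] - 600 <= ppos - 1 < w["end"] + 600:
                    clear = False
                    break
            if clear:
                ok_gene = g
                break
        if ok_gene is None:
            continue
        chain_snps.append((index_snp, proxy_snp))
        chain_genes.append(ok_gene)
        used_genes.add(ok_gene)
    if len(chain_snps) < n_chains:
        raise ValueError(f"could only place {len(chain_snps)} of "
                         f"{n_chains} planted chains")

    effects = tuple(PlantedEffect(snp=proxy, gene=g, beta=beta)
                    for (_, proxy), g in zip(chain_snps, chain_genes))
    enhancers = tuple(
        PlantedEnhancer(cell_type=ct, mark=mk, snp=proxy, fold=6.0)
        for (_, proxy) in chain_snps for ct in cell_types for mk in marks)
    index_snps = [idx for idx, _ in chain_snps]
    hla_snps = list(smap.index[hla][:n_decoy_hla])
    gwas = GwasSpec(traits=(("RA", tuple(index_snps + hla_snps)),))
    all_marks = tuple(marks) + (("H3K4me3",) if "H3K4me3" not in marks else ())
    peak_spec = PeakSpec(cell_types=cell_types, marks=all_marks,
                         planted_enhancers=enhancers)
    network = NetworkSpec(module_genes=tuple(chain_genes))
    return dataclasses.replace(
        base, planted_cis_effects=effects, peak_spec=peak_spec,
        gwas_spec=gwas, network_spec=network)
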