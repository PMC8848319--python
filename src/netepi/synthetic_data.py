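"""Self-contained synthetic fixtures for the whole pipeline.

Generates case-control genotype data with block LD structure, a many-to-many
SNP-gene annotation, an evidence-weighted gene co-function network, gene-set
collections, and a binary phenotype with optional planted main effects,
planted gene-pair interactions, and a latent ancestry confounder — so every
downstream stage is testable without any external download.

Genotype model: per LD block, a latent multivariate Gaussian with
exchangeable correlation; two independent draws per sample are thresholded
at the allele-frequency quantile and summed, giving 0/1/2 dosages that
satisfy Hardy-Weinberg proportions marginally with tunable within-block LD.

Phenotype model (log-odds scale):

    logit P(case) = intercept + sum_k beta_k g_k
                  + sum_m gamma_m g_a(m) g_b(m) + c * u

where each planted gene-pair interaction m is carried by exactly one
representative SNP pair (the first mapped SNP of each gene) and u is a
standard-normal latent ancestry axis, also emitted as covariate column 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .io_formats import (
    GeneNetwork,
    GenotypeDataset,
    MappingEntry,
    SnpGeneMap,
    SnpRecord,
    GeneSetCollection,
    ValidationError,
    MISSING,
)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_dataset",
    "empirical_maf_check",
    "simulate_gene_sets",
]


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults give a null dataset of 500 samples and 200 SNPs in LD blocks of
    5 (within-block latent correlation 0.3), annotated to 40 genes of 5 SNPs
    each, connected by 60 co-function edges — a desk-scale miniature of a
    network-guided interaction study with no genetic effects planted.
    """

    n_samples: int = 500
    n_snps: int = 200
    ld_block_size: int = 5
    within_block_corr: float = 0.3
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_genes: int = 40
    snps_per_gene: Union[int, tuple[int, int]] = 5
    n_gene_edges: int = 60
    # distribution over integer evidence counts >= 1, as {value: probability}
    evidence_count_dist: dict[int, float] = field(default_factory=lambda: {2: 0.6, 3: 0.4})
    # (gene_a, gene_b, interaction effect gamma on the log-odds scale)
    planted_models: list[tuple[str, str, float]] = field(default_factory=list)
    # (snp_id, beta on the log-odds scale)
    main_effects: list[tuple[str, float]] = field(default_factory=list)
    confounder_effect: float = 0.0
    prevalence_intercept: float = 0.0
    mapping_source_probs: dict[str, float] = field(
        default_factory=lambda: {"positional": 1.0}
    )
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_samples, self.n_snps, self.ld_block_size, self.n_genes) < 1:
            raise ConfigError("all sizes must be positive")
        if not (0.0 <= self.within_block_corr < 1.0):
            raise ConfigError("within_block_corr must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if abs(sum(self.evidence_count_dist.values()) - 1.0) > 1e-9:
            raise ConfigError("evidence_count_dist probabilities must sum to 1")
        if any(v < 1 for v in self.evidence_count_dist):
            raise ConfigError("evidence counts must be >= 1")
        if self.seed is None:
            raise ConfigError("seed is mandatory")


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset, for power/recovery accounting."""

    planted_gene_models: list[tuple[str, str, float]]
    planted_snp_pairs: list[tuple[str, str, float]]
    main_effect_snps: list[tuple[str, float]]
    confounder: np.ndarray


def _gene_spans(config: SimulationConfig, rng: np.random.Generator) -> list[list[int]]:
    """Tile the SNP axis into per-gene SNP index lists."""
    if isinstance(config.snps_per_gene, int):
        sizes = [config.snps_per_gene] * config.n_genes
    else:
        lo, hi = config.snps_per_gene
        sizes = rng.integers(lo, hi + 1, size=config.n_genes).tolist()
    spans, cursor = [], 0
    for size in sizes:
        if cursor >= config.n_snps:
            raise ConfigError("gene tiling exceeds n_snps; reduce n_genes or snps_per_gene")
        span = list(range(cursor, min(cursor + size, config.n_snps)))
        spans.append(span)
        cursor += size
    return spans


def _simulate_genotypes(config: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Block-LD genotypes via the Gaussian threshold model; returns (G, maf)."""
    n, m = config.n_samples, config.n_snps
    rho = config.within_block_corr
    maf = rng.uniform(*config.maf_range, size=m)
    thresholds = stats.norm.ppf(maf)
    G = np.zeros((n, m), dtype=np.int8)
    for start in range(0, m, config.ld_block_size):
        stop = min(start + config.ld_block_size, m)
        width = stop - start
        for _ in range(2):  # two haploid draws per sample
            shared = rng.standard_normal((n, 1))
            noise = rng.standard_normal((n, width))
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
            G[:, start:stop] += (z < thresholds[start:stop]).astype(np.int8)
    return G, maf


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeDataset, SnpGeneMap, GeneNetwork, TruthRecord]:
    """Generate a full synthetic study reproducibly from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    G, _ = _simulate_genotypes(config, rng)
    snps = [
        SnpRecord(f"rs{j + 1}", "1", (j + 1) * 5000, "A", "B")
        for j in range(config.n_snps)
    ]
    snp_ids = [s.snp_id for s in snps]

    # annotation: genes tile the SNP axis
    spans = _gene_spans(config, rng)
    gene_ids = [f"G{g + 1}" for g in range(config.n_genes)]
    sources = list(config.mapping_source_probs)
    probs = np.array([config.mapping_source_probs[s] for s in sources], dtype=float)
    probs = probs / probs.sum()
    entries: set[MappingEntry] = set()
    for gene, span in zip(gene_ids, spans):
        for j in span:
            src = sources[rng.choice(len(sources), p=probs)]
            entries.add(MappingEntry(snp_ids[j], gene, src))
    mapping = SnpGeneMap(entries)
    gene_to_snps = {g: [snp_ids[j] for j in spans[i]] for i, g in enumerate(gene_ids)}

    # network: planted edges first, then random distinct pairs
    ev_values = sorted(config.evidence_count_dist)
    ev_probs = np.array([config.evidence_count_dist[v] for v in ev_values], dtype=float)

    def draw_evidence() -> int:
        return ev_values[rng.choice(len(ev_values), p=ev_probs)]

    network = GeneNetwork()
    for ga, gb, _gamma in config.planted_models:
        if ga not in gene_to_snps or gb not in gene_to_snps:
            raise ConfigError(f"planted model ({ga},{gb}) names a gene outside the annotation")
        if not gene_to_snps[ga] or not gene_to_snps[gb]:
            raise ConfigError(f"planted model ({ga},{gb}): a gene has no mapped SNPs")
        network.add_edge(ga, gb, max(draw_evidence(), 2))
    guard = 0
    while len(network) < config.n_gene_edges:
        a, b = rng.choice(config.n_genes, size=2, replace=False)
        network.add_edge(gene_ids[a], gene_ids[b], draw_evidence())
        guard += 1
        if guard > 100 * config.n_gene_edges:
            raise ConfigError("cannot place n_gene_edges distinct edges; too few genes")

    # phenotype
    logit = np.full(config.n_samples, config.prevalence_intercept, dtype=float)
    snp_index = {s: j for j, s in enumerate(snp_ids)}
    for snp, beta in config.main_effects:
        logit += beta * G[:, snp_index[snp]]
    planted_pairs: list[tuple[str, str, float]] = []
    for ga, gb, gamma in config.planted_models:
        sa, sb = gene_to_snps[ga][0], gene_to_snps[gb][0]
        planted_pairs.append((sa, sb, gamma))
        logit += gamma * G[:, snp_index[sa]] * G[:, snp_index[sb]]
    u = rng.standard_normal(config.n_samples)
    logit += config.confounder_effect * u
    y = (rng.uniform(size=config.n_samples) < 1.0 / (1.0 + np.exp(-logit))).astype(np.int8)

    dataset = GenotypeDataset(
        sample_ids=[f"S{i + 1}" for i in range(config.n_samples)],
        snps=snps,
        genotypes=G,
        phenotype=y,
        covariates=u[:, None],
        covariate_names=["ancestry_axis"],
    )
    truth = TruthRecord(
        planted_gene_models=list(config.planted_models),
        planted_snp_pairs=planted_pairs,
        main_effect_snps=list(config.main_effects),
        confounder=u,
    )
    return dataset, mapping, network, truth


def empirical_maf_check(dataset: GenotypeDataset) -> np.ndarray:
    """Per-SNP empirical allele-1 frequency: mean dosage / 2 (no missing allowed)."""
    if (dataset.genotypes == MISSING).any():
        raise ValidationError("empirical_maf_check expects a complete fixture")
    return dataset.genotypes.mean(axis=0) / 2.0


def simulate_gene_sets(
    config: SimulationConfig,
    network: GeneNetwork,
    *,
    enriched_around: Optional[Sequence[str]] = None,
    n_background: int = 10,
    set_size: int = 15,
    seed: Optional[int] = None,
) -> GeneSetCollection:
    """Gene sets over the network's gene universe: optionally one set enriched
    for a chosen neighborhood, plus uniformly sampled background sets."""
    universe = sorted(network.genes())
    if not universe:
        raise ValidationError("network has no genes")
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed)
    )
    coll = GeneSetCollection()
    if enriched_around:
        members = set(enriched_around)
        missing = members - set(universe)
        if missing:
            raise ValidationError(f"enriched genes absent from network: {sorted(missing)}")
        pad = [g for g in universe if g not in members]
        extra = max(0, set_size - len(members))
        if extra and pad:
            picks = rng.choice(len(pad), size=min(extra, len(pad)), replace=False)
            members |= {pad[i] for i in picks}
        coll.sets["ENRICHED"] = members
        coll.descriptions["ENRICHED"] = "set enriched for a chosen neighborhood"
    size = min(set_size, len(universe))
    for k in range(n_background):
        picks = rng.choice(len(universe), size=size, replace=False)
        coll.sets[f"BG{k + 1}"] = {universe[i] for i in picks}
        coll.descriptions[f"BG{k + 1}"] = "background set sampled uniformly"
    return coll
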