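"""End-to-end orchestration of the network-guided epistasis protocol.

Stage order: load inputs -> gene models (co-function edges with >= 2
evidence sources) -> SNP models (via the SNP-gene mapping; or all pairs in
*standard* mode) -> SNP-model QC -> phenotype adjustment -> permutation FWER
threshold -> interaction scan -> significant SNP pairs -> ATPM gene-level
test -> PRS-conditioned re-testing -> pathway neighborhoods + enrichment ->
TSV outputs. Also provides the type-I-error and 80%-subsample robustness
harnesses and the command-line interface.

All randomness flows from one master seed; each stochastic stage draws its
sub-seed from a fixed counter (recorded in the config snapshot), so a run is
reproducible byte for byte.
"""

from __future__ import annotations

import itertools
import logging
import os
import sys
import time
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml
import click
from scipy import stats as sp_stats

from . import io_formats as iof
from .io_formats import (
    GeneNetwork,
    GeneSetCollection,
    GenotypeDataset,
    SnpGeneMap,
    ValidationError,
)
from .model_building import (
    GeneModel,
    QCConfig,
    SnpModel,
    apply_snp_model_qc,
    combine_mappings,
    enumerate_snp_models,
    filter_gene_models,
)
from .association import (
    AdjustedPhenotype,
    InteractionResult,
    PairScanner,
    adjust_phenotype,
    clump,
    compute_prs,
    single_snp_assoc,
)
from .significance import (
    DEFAULT_TAUS,
    GeneModelResult,
    ThresholdResult,
    fwer_threshold,
    gene_level_analysis,
    permute_columns,
    select_significant,
)
from .pathway_analysis import (
    EnrichmentResult,
    Neighborhood,
    build_neighborhood,
    build_universe,
    gene_model_graph,
    hypergeom_enrich,
)
from . import synthetic_data as synth

log = logging.getLogger("netepi")

__all__ = [
    "ProtocolConfig",
    "PipelineInputs",
    "RunBundle",
    "run_protocol",
    "estimate_type1_error",
    "robustness_subsample",
    "cli",
]

# fixed sub-seed counters per stochastic stage (master seed + counter)
_STAGE_SEEDS = {"threshold": 1, "atpm": 2, "type1": 3, "robustness": 4}


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([master_seed, _STAGE_SEEDS[stage]])


@dataclass
class ProtocolConfig:
    """Configuration of one protocol run; defaults mirror the published constants."""

    mode: str = "biofiltered"  # or "standard" (exhaustive pair scan)
    mapping_sources: Optional[list[str]] = None  # None = all sources
    tissues: Optional[list[str]] = None
    min_evidence: int = 2
    qc: QCConfig = field(default_factory=QCConfig)
    n_perm_threshold: int = 400
    fwer: float = 0.05
    atpm_taus: tuple[float, ...] = DEFAULT_TAUS
    atpm_b: int = 999
    atpm_alpha: float = 0.05
    store_threshold: float = 0.05
    prs_enabled: bool = True
    prs_clump_kb: float = 250.0
    prs_clump_p: float = 1.0
    prs_clump_r2: float = 0.1
    pathway_enabled: bool = True
    pathway_alpha: float = 0.05
    pathway_bonferroni_scope: str = "global"
    pathway_set_size_bounds: Optional[tuple[int, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "biofiltered"):
            raise ValidationError(f"unknown analysis mode {self.mode!r}")

    def snapshot(self) -> dict:
        d = asdict(self)
        d["stage_seed_counters"] = dict(_STAGE_SEEDS)
        return d


@dataclass
class PipelineInputs:
    dataset: GenotypeDataset
    mappings: list[SnpGeneMap]
    network: GeneNetwork
    gene_sets: Optional[GeneSetCollection] = None


@dataclass
class RunBundle:
    """Everything one protocol run produced, ready for :func:`iof.write_results`."""

    config: dict
    threshold_result: Optional[ThresholdResult]
    scan_results: list[InteractionResult]
    significant_snp_models: list[InteractionResult]
    gene_model_results: list[GeneModelResult]
    prs_diagnostics: list[dict]
    neighborhoods: list[Neighborhood]
    enrichments: list[EnrichmentResult]
    logs: dict[str, list]

    def significant_gene_models(self) -> list[GeneModelResult]:
        return [g for g in self.gene_model_results if g.significant]


def _all_pairs_models(dataset: GenotypeDataset) -> list[SnpModel]:
    """Exhaustive C(m, 2) SNP pairs for the standard analysis."""
    ids = sorted(dataset.snp_ids)
    return [SnpModel(a, b) for a, b in itertools.combinations(ids, 2)]


def _positional_map(mappings: Sequence[SnpGeneMap]) -> SnpGeneMap:
    return combine_mappings(mappings, sources=["positional"])


def _standard_gene_assignment(
    significant: Sequence[InteractionResult],
    snp_models: Sequence[SnpModel],
    mappings: Sequence[SnpGeneMap],
) -> None:
    """Standard mode: assign gene pairs to significant SNP pairs post hoc by
    positional mapping, attaching the parents in place."""
    pos = _positional_map(mappings)
    genes_of: dict[str, set[str]] = {}
    for snp, gene in pos.project():
        genes_of.setdefault(snp, set()).add(gene)
    sig_pairs = {(r.snp_a, r.snp_b) for r in significant}
    for m in snp_models:
        if m.pair not in sig_pairs:
            continue
        for ga in genes_of.get(m.snp_a, ()):
            for gb in genes_of.get(m.snp_b, ()):
                if ga != gb:
                    m.parent_gene_models.add(GeneModel(ga, gb))


def run_protocol(config: ProtocolConfig, inputs: PipelineInputs) -> RunBundle:
    """Run the full protocol on loaded inputs and return a :class:`RunBundle`."""
    t0 = time.time()
    dataset = inputs.dataset
    logs: dict[str, list] = {}

    gene_models = filter_gene_models(inputs.network, config.min_evidence)
    log.info("stage=gene_models kept=%d", len(gene_models))

    if config.mode == "biofiltered":
        mapping = combine_mappings(inputs.mappings, config.mapping_sources, config.tissues)
        snp_models, childless = enumerate_snp_models(gene_models, mapping)
        logs["childless_gene_models"] = [gm.pair for gm in childless]
    else:
        mapping = _positional_map(inputs.mappings)
        snp_models = _all_pairs_models(dataset)
    log.info("stage=snp_models enumerated=%d", len(snp_models))

    snp_models, rejection_log = apply_snp_model_qc(snp_models, dataset, config.qc)
    logs["qc_rejections"] = rejection_log
    log.info("stage=qc kept=%d rejected=%d", len(snp_models), len(rejection_log))
    if not snp_models:
        raise ValidationError("no SNP models survive QC; nothing to test")

    y_adj = adjust_phenotype(
        dataset.phenotype, dataset.covariates, dataset.covariate_names
    )

    thr_seed = int(stage_seed(config.seed, "threshold").generate_state(1)[0] % 2**31)
    threshold_result = fwer_threshold(
        dataset, y_adj, snp_models,
        n_perm=config.n_perm_threshold, level=config.fwer, seed=thr_seed,
    )
    log.info("stage=threshold value=%.3g", threshold_result.threshold)

    scanner = PairScanner(dataset, snp_models)
    scan_results = scanner.results(y_adj.values)
    logs["degenerate_pairs"] = [
        (r.snp_a, r.snp_b, r.reason) for r in scan_results if r.degenerate
    ]
    stored = [r for r in scan_results if not r.degenerate and r.p <= config.store_threshold]
    stored.sort(key=lambda r: (r.p, r.snp_a, r.snp_b))
    significant = select_significant(scan_results, threshold_result.threshold)
    log.info("stage=scan stored=%d significant=%d", len(stored), len(significant))

    if config.mode == "standard":
        _standard_gene_assignment(significant, snp_models, inputs.mappings)

    atpm_seed = int(stage_seed(config.seed, "atpm").generate_state(1)[0] % 2**31)
    gene_results = gene_level_analysis(
        significant, snp_models, dataset, y_adj,
        n_perm=config.atpm_b, taus=config.atpm_taus,
        alpha=config.atpm_alpha, seed=atpm_seed,
    )
    sig_gene_models = [GeneModel(g.gene_a, g.gene_b) for g in gene_results if g.significant]
    log.info("stage=atpm candidates=%d significant=%d", len(gene_results), len(sig_gene_models))

    prs_diag: list[dict] = []
    if config.prs_enabled and significant:
        prs_diag = _prs_diagnostics(config, dataset, y_adj, significant, snp_models)

    neighborhoods: list[Neighborhood] = []
    enrichments: list[EnrichmentResult] = []
    if config.pathway_enabled and sig_gene_models and inputs.gene_sets is not None:
        graph = gene_model_graph(gene_models)
        for gm in sig_gene_models:
            if gm.gene_a in graph and gm.gene_b in graph:
                neighborhoods.append(build_neighborhood(gm, graph, sig_gene_models))
            else:
                logs.setdefault("pathway_skipped", []).append(
                    f"{gm.gene_a}--{gm.gene_b}: gene absent from gene-model graph"
                )
        try:
            universe = build_universe(
                inputs.gene_sets, mapping, gene_models,
                mode=config.mode if config.mode == "standard" else "biofiltered",
            )
            enrichments, skipped = hypergeom_enrich(
                neighborhoods, inputs.gene_sets, universe,
                alpha=config.pathway_alpha,
                bonferroni_scope=config.pathway_bonferroni_scope,
                set_size_bounds=config.pathway_set_size_bounds,
            )
            logs.setdefault("pathway_skipped", []).extend(skipped)
        except ValidationError as exc:
            logs.setdefault("pathway_skipped", []).append(str(exc))

    log.info("stage=done elapsed=%.1fs", time.time() - t0)
    return RunBundle(
        config=config.snapshot(),
        threshold_result=threshold_result,
        scan_results=stored,
        significant_snp_models=significant,
        gene_model_results=gene_results,
        prs_diagnostics=prs_diag,
        neighborhoods=neighborhoods,
        enrichments=enrichments,
        logs=logs,
    )


def _prs_diagnostics(
    config: ProtocolConfig,
    dataset: GenotypeDataset,
    y_adj: AdjustedPhenotype,
    significant: Sequence[InteractionResult],
    snp_models: Sequence[SnpModel],
) -> list[dict]:
    """Re-test significant pairs conditioning on a clumping+scoring PRS.

    The PRS absorbs the additive main effects; a pair whose interaction
    signal collapses under adjustment is a phantom-epistasis suspect. The
    adjusted p-values are descriptive — inference keeps the unadjusted ones.
    """
    summary: dict[str, tuple[float, float]] = {}
    for j, sid in enumerate(dataset.snp_ids):
        beta, _, p = single_snp_assoc(dataset.genotypes[:, j], y_adj.values)
        if np.isfinite(p):
            summary[sid] = (beta, p)
    kept = clump(
        summary, dataset, window_kb=config.prs_clump_kb,
        p_max=config.prs_clump_p, r2_max=config.prs_clump_r2,
    )
    if not kept:
        return []
    prs = compute_prs(dataset, kept, {s: summary[s][0] for s in kept})
    by_pair = {m.pair: m for m in snp_models}
    models = [by_pair[(r.snp_a, r.snp_b)] for r in significant]
    scanner = PairScanner(dataset, models, extra_covariates=prs.scores[:, None])
    adjusted = scanner.results(y_adj.values, adjusted_for_prs=True)
    return [
        {
            "snp_a": r.snp_a, "snp_b": r.snp_b,
            "p_unadjusted": r.p, "p_prs_adjusted": adj.p,
            "beta3_unadjusted": r.beta3, "beta3_prs_adjusted": adj.beta3,
            "n_prs_snps": len(kept),
        }
        for r, adj in zip(significant, adjusted)
    ]


@dataclass
class Type1Result:
    rate: float
    n_false_positive: int
    n_outer: int
    ci_low: float
    ci_high: float


def estimate_type1_error(
    config: ProtocolConfig,
    inputs: PipelineInputs,
    n_outer: int = 1000,
    threshold: Optional[float] = None,
    snp_models: Optional[list[SnpModel]] = None,
) -> Type1Result:
    """Empirical type I error of the whole scan -> select -> ATPM cascade.

    The SNP-level threshold is computed once from the observed dataset and
    reused; each outer iteration permutes the adjusted phenotype, rescans
    every SNP model, and runs the gene-level ATPM on the candidates. An
    iteration with >= 1 significant gene model is a false positive; the rate
    comes with its exact binomial 95% CI.
    """
    import warnings as _warnings

    if n_outer < 50:
        _warnings.warn("n_outer < 50: the binomial CI will be very wide")
    dataset = inputs.dataset
    if snp_models is None:
        gene_models = filter_gene_models(inputs.network, config.min_evidence)
        mapping = combine_mappings(inputs.mappings, config.mapping_sources, config.tissues)
        snp_models, _ = enumerate_snp_models(gene_models, mapping)
        snp_models, _ = apply_snp_model_qc(snp_models, dataset, config.qc)
    y_adj = adjust_phenotype(dataset.phenotype, dataset.covariates, dataset.covariate_names)
    if threshold is None:
        thr_seed = int(stage_seed(config.seed, "threshold").generate_state(1)[0] % 2**31)
        threshold = fwer_threshold(
            dataset, y_adj, snp_models,
            n_perm=config.n_perm_threshold, level=config.fwer, seed=thr_seed,
        ).threshold

    rng = np.random.default_rng(stage_seed(config.seed, "type1"))
    scanner = PairScanner(dataset, snp_models)
    Y = permute_columns(np.asarray(y_adj.values, dtype=float), n_outer, rng)
    _, _, _, pvals = scanner.scan(Y)

    n_fp = 0
    for b in range(n_outer):
        hit_rows = np.where(pvals[:, b] <= threshold)[0]
        if hit_rows.size == 0:
            continue
        sig = [
            InteractionResult(
                snp_a=snp_models[i].snp_a, snp_b=snp_models[i].snp_b,
                beta3=float("nan"), se3=float("nan"), statistic=float("nan"),
                p=float(pvals[i, b]), n_used=dataset.n_samples,
            )
            for i in hit_rows
        ]
        inner_seed = int(rng.integers(0, 2**31))
        gene_results = gene_level_analysis(
            sig, snp_models, dataset, y_adj,
            n_perm=config.atpm_b, taus=config.atpm_taus,
            alpha=config.atpm_alpha, seed=inner_seed,
            y_observed=Y[:, b],
        )
        if any(g.significant for g in gene_results):
            n_fp += 1
    ci = sp_stats.binomtest(n_fp, n_outer).proportion_ci(confidence_level=0.95)
    return Type1Result(
        rate=n_fp / n_outer, n_false_positive=n_fp, n_outer=n_outer,
        ci_low=float(ci.low), ci_high=float(ci.high),
    )


@dataclass
class RobustnessResult:
    per_rep_significant: list[list[tuple[str, str]]]
    recovery_per_rep: list[float]
    mean_recovery: Optional[float]
    se_recovery: Optional[float]
    applicable: bool


def robustness_subsample(
    config: ProtocolConfig,
    inputs: PipelineInputs,
    full_bundle: RunBundle,
    fraction: float = 0.8,
    reps: int = 10,
) -> RobustnessResult:
    """Stability of the significant gene models under 80% subsampling.

    Each repetition draws a case-fraction-preserving subset of samples,
    rescans the QC-passed SNP models with the FULL-data SNP threshold, and
    reruns the ATPM at the full-data gene cutoff. Reports, per repetition,
    the fraction of the full-data significant gene models recovered. With an
    empty full-data result the recovery is not applicable.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("fraction must lie in (0, 1]")
    dataset = inputs.dataset
    full_sig = {(g.gene_a, g.gene_b) for g in full_bundle.significant_gene_models()}
    threshold = full_bundle.threshold_result.threshold

    gene_models = filter_gene_models(inputs.network, config.min_evidence)
    if config.mode == "biofiltered":
        mapping = combine_mappings(inputs.mappings, config.mapping_sources, config.tissues)
        snp_models, _ = enumerate_snp_models(gene_models, mapping)
    else:
        snp_models = _all_pairs_models(dataset)
    snp_models, _ = apply_snp_model_qc(snp_models, dataset, config.qc)

    rng = np.random.default_rng(stage_seed(config.seed, "robustness"))
    cases = np.where(dataset.phenotype == 1)[0]
    controls = np.where(dataset.phenotype == 0)[0]
    per_rep_sig: list[list[tuple[str, str]]] = []
    recovery: list[float] = []
    for _rep in range(reps):
        take = np.concatenate([
            rng.choice(cases, size=int(round(fraction * cases.size)), replace=False),
            rng.choice(controls, size=int(round(fraction * controls.size)), replace=False),
        ])
        take.sort()
        sub = GenotypeDataset(
            sample_ids=[dataset.sample_ids[i] for i in take],
            snps=dataset.snps,
            genotypes=dataset.genotypes[take],
            phenotype=dataset.phenotype[take],
            covariates=None if dataset.covariates is None else dataset.covariates[take],
            covariate_names=dataset.covariate_names,
        )
        y_adj = adjust_phenotype(sub.phenotype, sub.covariates, sub.covariate_names)
        scanner = PairScanner(sub, snp_models)
        results = scanner.results(y_adj.values)
        sig = select_significant(results, threshold)
        inner_seed = int(rng.integers(0, 2**31))
        gene_results = gene_level_analysis(
            sig, snp_models, sub, y_adj,
            n_perm=config.atpm_b, taus=config.atpm_taus,
            alpha=config.atpm_alpha, seed=inner_seed,
        )
        got = {(g.gene_a, g.gene_b) for g in gene_results if g.significant}
        per_rep_sig.append(sorted(got))
        if full_sig:
            recovery.append(len(got & full_sig) / len(full_sig))
    if full_sig:
        mean = float(np.mean(recovery))
        se = float(np.std(recovery, ddof=1) / np.sqrt(len(recovery))) if len(recovery) > 1 else 0.0
        return RobustnessResult(per_rep_sig, recovery, mean, se, applicable=True)
    return RobustnessResult(per_rep_sig, [], None, None, applicable=False)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def _load_inputs(paths: dict) -> PipelineInputs:
    dataset = iof.read_plink(paths["bed"], paths["bim"], paths["fam"])
    if paths.get("covariates"):
        cov, names = iof.read_covariates(paths["covariates"], dataset.sample_ids)
        dataset.covariates, dataset.covariate_names = cov, names
    mappings = [iof.read_mapping_table(p) for p in paths["mappings"]]
    network = iof.read_network_table(paths["network"])
    gene_sets = iof.read_gmt(paths["gene_sets"]) if paths.get("gene_sets") else None
    return PipelineInputs(dataset, mappings, network, gene_sets)


def _protocol_config_from_yaml(path: str, seed: int) -> tuple[ProtocolConfig, dict]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    paths = raw.pop("paths", {})
    qc_raw = raw.pop("qc", {})
    if "hla_region" in qc_raw and qc_raw["hla_region"] is not None:
        qc_raw["hla_region"] = tuple(qc_raw["hla_region"])
    if "whitelist" in qc_raw:
        qc_raw["whitelist"] = set(qc_raw["whitelist"])
    raw.pop("seed", None)
    cfg = ProtocolConfig(qc=QCConfig(**qc_raw), seed=seed, **raw)
    return cfg, paths


@click.group()
def cli() -> None:
    """Network-guided gene-level epistasis detection."""
    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(asctime)s %(name)s %(message)s")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=False)
@click.option("--seed", type=int, required=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def simulate(config_path: Optional[str], seed: int, out_dir: str) -> None:
    """Generate a synthetic study (PLINK fileset, mapping, network, truth)."""
    raw = {}
    if config_path:
        with open(config_path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.pop("seed", None)
    if "planted_models" in raw:
        raw["planted_models"] = [tuple(t) for t in raw["planted_models"]]
    if "main_effects" in raw:
        raw["main_effects"] = [tuple(t) for t in raw["main_effects"]]
    if "maf_range" in raw:
        raw["maf_range"] = tuple(raw["maf_range"])
    cfg = synth.SimulationConfig(seed=seed, **raw)
    dataset, mapping, network, truth = synth.simulate_dataset(cfg)
    os.makedirs(out_dir, exist_ok=True)
    iof.write_plink(dataset, os.path.join(out_dir, "synthetic"))
    iof.write_mapping_table(mapping, os.path.join(out_dir, "mapping.tsv"))
    iof.write_network_table(network, os.path.join(out_dir, "network.tsv"))
    with open(os.path.join(out_dir, "covariates.tsv"), "w") as fh:
        fh.write("sample_id\t" + "\t".join(dataset.covariate_names) + "\n")
        for sid, row in zip(dataset.sample_ids, dataset.covariates):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
        fh.write("kind\ta\tb\teffect\n")
        for ga, gb, gamma in truth.planted_gene_models:
            fh.write(f"gene_model\t{ga}\t{gb}\t{gamma}\n")
        for sa, sb, gamma in truth.planted_snp_pairs:
            fh.write(f"snp_pair\t{sa}\t{sb}\t{gamma}\n")
        for sid, beta in truth.main_effect_snps:
            fh.write(f"main_effect\t{sid}\t\t{beta}\n")
    click.echo(f"wrote synthetic study to {out_dir}")


def _paths_from_options(directory: str) -> dict:
    return {
        "bed": os.path.join(directory, "synthetic.bed"),
        "bim": os.path.join(directory, "synthetic.bim"),
        "fam": os.path.join(directory, "synthetic.fam"),
        "covariates": os.path.join(directory, "covariates.tsv"),
        "mappings": [os.path.join(directory, "mapping.tsv")],
        "network": os.path.join(directory, "network.tsv"),
        "gene_sets": None,
    }


def _resolve_paths(config_path: Optional[str], data_dir: Optional[str], seed: int):
    if config_path:
        cfg, paths = _protocol_config_from_yaml(config_path, seed)
        if data_dir:  # data dir fills any path the YAML omitted
            defaults = _paths_from_options(data_dir)
            for key, value in defaults.items():
                paths.setdefault(key, value)
    elif data_dir:
        cfg, paths = ProtocolConfig(seed=seed), _paths_from_options(data_dir)
    else:
        raise click.UsageError("provide --config and/or --data-dir")
    for key in ("bed", "bim", "fam", "network"):
        if not paths.get(key) or not os.path.exists(paths[key]):
            raise click.UsageError(f"missing input file for {key!r}: {paths.get(key)}")
    for p in paths.get("mappings", []):
        if not os.path.exists(p):
            raise click.UsageError(f"missing mapping table: {p}")
    if paths.get("covariates") and not os.path.exists(paths["covariates"]):
        paths["covariates"] = None
    return cfg, paths


@cli.command()
@click.option("--config", "config_path", type=click.Path(), required=False)
@click.option("--data-dir", type=click.Path(), required=False)
@click.option("--seed", type=int, required=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--mode", type=click.Choice(["biofiltered", "standard"]), default=None)
def run(config_path, data_dir, seed, out_dir, mode) -> None:
    """Run the full detection protocol and write TSV results."""
    cfg, paths = _resolve_paths(config_path, data_dir, seed)
    if mode:
        cfg.mode = mode
    inputs = _load_inputs(paths)
    bundle = run_protocol(cfg, inputs)
    written = iof.write_results(bundle, out_dir)
    click.echo(yaml.safe_dump({
        "threshold": float(bundle.threshold_result.threshold),
        "significant_snp_models": len(bundle.significant_snp_models),
        "significant_gene_models": len(bundle.significant_gene_models()),
        "outputs": written,
    }))


@cli.command()
@click.option("--config", "config_path", type=click.Path(), required=False)
@click.option("--data-dir", type=click.Path(), required=False)
@click.option("--seed", type=int, required=True)
@click.option("--n-outer", type=int, default=1000, show_default=True)
def type1(config_path, data_dir, seed, n_outer) -> None:
    """Estimate the protocol's empirical type I error on the given dataset."""
    cfg, paths = _resolve_paths(config_path, data_dir, seed)
    inputs = _load_inputs(paths)
    res = estimate_type1_error(cfg, inputs, n_outer=n_outer)
    click.echo(yaml.safe_dump({
        "type1_rate": res.rate, "false_positives": res.n_false_positive,
        "n_outer": res.n_outer, "ci95": [res.ci_low, res.ci_high],
    }))


@cli.command()
@click.option("--config", "config_path", type=click.Path(), required=False)
@click.option("--data-dir", type=click.Path(), required=False)
@click.option("--seed", type=int, required=True)
@click.option("--fraction", type=float, default=0.8, show_default=True)
@click.option("--reps", type=int, default=10, show_default=True)
def robustness(config_path, data_dir, seed, fraction, reps) -> None:
    """Gene-model recovery under repeated subsampling of the cohort."""
    cfg, paths = _resolve_paths(config_path, data_dir, seed)
    inputs = _load_inputs(paths)
    bundle = run_protocol(cfg, inputs)
    res = robustness_subsample(cfg, inputs, bundle, fraction=fraction, reps=reps)
    click.echo(yaml.safe_dump({
        "applicable": res.applicable,
        "mean_recovery": res.mean_recovery,
        "se_recovery": res.se_recovery,
        "per_rep_significant": [len(s) for s in res.per_rep_significant],
    }))


@cli.command()
@click.option("--config", "config_path", type=click.Path(), required=False)
@click.option("--data-dir", type=click.Path(), required=False)
@click.option("--gmt", "gmt_path", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, required=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def pathways(config_path, data_dir, gmt_path, seed, out_dir) -> None:
    """Run the protocol and the pathway stage against a GMT collection."""
    cfg, paths = _resolve_paths(config_path, data_dir, seed)
    paths["gene_sets"] = gmt_path
    inputs = _load_inputs(paths)
    bundle = run_protocol(cfg, inputs)
    written = iof.write_results(bundle, out_dir)
    click.echo(yaml.safe_dump({
        "tested_neighborhoods": sum(nb.tested for nb in bundle.neighborhoods),
        "significant_pathways": sum(e.significant for e in bundle.enrichments),
        "outputs": written,
    }))


if __name__ == "__main__":  # pragma: no cover
    cli()
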