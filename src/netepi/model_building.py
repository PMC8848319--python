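"""From prior knowledge to the tested hypothesis space.

Filters the co-function network into gene models (candidate gene pairs),
combines SNP-gene mappings across sources/tissues, enumerates the SNP pairs
("SNP models") each gene model induces, and applies SNP-model quality
control: minor allele frequency, exact Hardy-Weinberg test, an HLA-region
exclusion, and a pairwise-LD ceiling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import (
    GeneNetwork,
    GenotypeDataset,
    SnpGeneMap,
    ValidationError,
    MISSING,
)

__all__ = [
    "GeneModel",
    "SnpModel",
    "QCConfig",
    "filter_gene_models",
    "combine_mappings",
    "enumerate_snp_models",
    "snp_maf",
    "hwe_exact_test",
    "pairwise_r2",
    "apply_snp_model_qc",
]


@dataclass(frozen=True, order=True)
class GeneModel:
    """Candidate gene-gene interaction pair; ids stored lexicographically sorted."""

    gene_a: str
    gene_b: str
    evidence_count: int = 1

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"gene model may not be a self pair: {self.gene_a}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class SnpModel:
    """Testable SNP pair with the gene models that induced it."""

    snp_a: str
    snp_b: str
    parent_gene_models: set[GeneModel] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.snp_a == self.snp_b:
            raise ValidationError(f"SNP model may not be a self pair: {self.snp_a}")
        if self.snp_a > self.snp_b:
            self.snp_a, self.snp_b = self.snp_b, self.snp_a

    @property
    def pair(self) -> tuple[str, str]:
        return (self.snp_a, self.snp_b)


@dataclass
class QCConfig:
    """SNP-model quality-control thresholds.

    Boundary conventions: a SNP is dropped when MAF is strictly below
    ``maf_min`` or the HWE exact p is strictly below ``hwe_alpha``; a pair is
    dropped when r^2 is strictly above ``ld_r2_max``, or when BOTH SNPs lie
    inside the closed HLA interval. Whitelisted SNPs are exempt from the
    MAF and HWE rules only.
    """

    maf_min: float = 0.05
    hwe_alpha: float = 0.001
    ld_r2_max: float = 0.75
    hla_region: Optional[tuple[str, int, int]] = None
    whitelist: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, v in (("maf_min", self.maf_min), ("hwe_alpha", self.hwe_alpha),
                        ("ld_r2_max", self.ld_r2_max)):
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0,1), got {v}")
        if self.hla_region is not None:
            _, start, end = self.hla_region
            if start > end:
                raise ValidationError("hla_region start > end")


#: GRCh37 extended MHC, the conventional exclusion window on chromosome 6.
DEFAULT_HLA_REGION = ("6", 25_000_000, 34_000_000)


def filter_gene_models(network: GeneNetwork, min_evidence: int = 2) -> list[GeneModel]:
    """Gene models: network edges with >= ``min_evidence`` sources, self-loops removed."""
    models = [
        GeneModel(a, b, ev)
        for (a, b), ev in network.edges.items()
        if ev >= min_evidence and a != b
    ]
    return sorted(models)


def combine_mappings(
    maps: Iterable[SnpGeneMap],
    sources: Optional[Iterable[str]] = None,
    tissues: Optional[Iterable[str]] = None,
) -> SnpGeneMap:
    """Union of mapping entries restricted to the requested sources (and tissues).

    Tissue filtering keeps entries whose tissue tag is in ``tissues``;
    untagged entries are kept only when no tissue filter is given. A
    requested source present in no map raises a warning, not an error.
    """
    source_set = set(sources) if sources is not None else None
    tissue_set = set(tissues) if tissues is not None else None
    combined: set = set()
    seen_sources: set[str] = set()
    for m in maps:
        for e in m.entries:
            seen_sources.add(e.source)
            if source_set is not None and e.source not in source_set:
                continue
            if tissue_set is not None and e.tissue not in tissue_set:
                continue
            combined.add(e)
    if source_set is not None:
        absent = source_set - seen_sources
        if absent:
            warnings.warn(f"requested mapping sources absent from all maps: {sorted(absent)}")
    return SnpGeneMap(combined)


def enumerate_snp_models(
    gene_models: Sequence[GeneModel], mapping: SnpGeneMap
) -> tuple[list[SnpModel], list[GeneModel]]:
    """All SNP pairs induced by the gene models through the (snp, gene) relation.

    For gene model (A, B) every unordered pair (a, b) with a mapped to A and
    b mapped to B (a != b) is a SNP model; a pair induced by several gene
    models appears once with all parents recorded. Returns (snp_models,
    gene models that induced no pair) — the latter can never be significant.
    """
    snps_for_gene = mapping.snps_for_gene()
    by_pair: dict[tuple[str, str], SnpModel] = {}
    childless: list[GeneModel] = []
    for gm in gene_models:
        sa = snps_for_gene.get(gm.gene_a, set())
        sb = snps_for_gene.get(gm.gene_b, set())
        produced = False
        for a in sa:
            for b in sb:
                if a == b:
                    continue
                key = (a, b) if a < b else (b, a)
                model = by_pair.get(key)
                if model is None:
                    model = SnpModel(key[0], key[1])
                    by_pair[key] = model
                model.parent_gene_models.add(gm)
                produced = True
        if not produced:
            childless.append(gm)
    return [by_pair[k] for k in sorted(by_pair)], childless


def snp_maf(column: np.ndarray) -> float:
    """Minor allele frequency of one dosage column, complete-case."""
    g = np.asarray(column)
    g = g[g != MISSING]
    if g.size == 0:
        raise ValidationError("all genotypes missing; MAF undefined")
    f = float(g.sum()) / (2.0 * g.size)
    return min(f, 1.0 - f)


def hwe_exact_test(n_hom_a1: int, n_het: int, n_hom_a2: int) -> float:
    """Exact test of Hardy-Weinberg proportions for one biallelic SNP.

    Conditions on the observed allele counts and sums, over all attainable
    heterozygote counts, the probabilities of tables no more probable than
    the observed one (the standard exact formulation). Computed in log space
    with exact integer support enumeration; p = 1 for monomorphic SNPs.
    """
    counts = (n_hom_a1, n_het, n_hom_a2)
    if any(c < 0 for c in counts):
        raise ValidationError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n < 1:
        raise ValidationError("empty genotype table")
    n_rare = 2 * min(n_hom_a1, n_hom_a2) + n_het
    if n_rare == 0:
        return 1.0  # monomorphic: single attainable table
    # heterozygote count shares n_rare's parity, bounded by allele counts
    h_min = n_rare % 2 if n_rare <= n else 2 * n_rare - 2 * n + (n_rare % 2)
    h_support = np.arange(max(h_min, n_rare % 2), min(n_rare, 2 * n - n_rare) + 1, 2)
    lg = math.lgamma
    log_probs = np.empty(h_support.size)
    for i, h in enumerate(h_support):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        log_probs[i] = (
            lg(n + 1) - lg(rare_hom + 1) - lg(h + 1) - lg(common_hom + 1)
            + h * math.log(2.0)
        )
    log_probs -= _logsumexp(log_probs)
    obs_idx = int(np.where(h_support == n_het)[0][0])
    keep = log_probs <= log_probs[obs_idx] + 1e-12
    return float(min(1.0, np.exp(_logsumexp(log_probs[keep]))))


def _logsumexp(x: np.ndarray) -> float:
    m = float(np.max(x))
    return m + math.log(float(np.sum(np.exp(x - m))))


def pairwise_r2(g_a: np.ndarray, g_b: np.ndarray) -> Optional[float]:
    """Composite LD: squared Pearson correlation of dosages over complete cases.

    Returns None when either column is monomorphic after complete-case
    restriction (the LD filter then does not apply and the pair is flagged).
    """
    a = np.asarray(g_a, dtype=float)
    b = np.asarray(g_b, dtype=float)
    ok = (np.asarray(g_a) != MISSING) & (np.asarray(g_b) != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValidationError("fewer than 2 complete-case samples for LD")
    if a.std() == 0.0 or b.std() == 0.0:
        return None
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def _per_snp_qc_stats(
    dataset: GenotypeDataset, snp_ids: Iterable[str]
) -> dict[str, tuple[float, float]]:
    """(MAF, HWE exact p) per SNP, computed once on the full cohort."""
    index = dataset.snp_index()
    out: dict[str, tuple[float, float]] = {}
    for sid in snp_ids:
        col = dataset.genotypes[:, index[sid]]
        g = col[col != MISSING]
        n2 = int(np.sum(g == 2))
        n1 = int(np.sum(g == 1))
        n0 = int(np.sum(g == 0))
        out[sid] = (snp_maf(col), hwe_exact_test(n2, n1, n0))
    return out


def apply_snp_model_qc(
    models: Sequence[SnpModel],
    dataset: GenotypeDataset,
    qc: QCConfig,
) -> tuple[list[SnpModel], list[tuple[str, str, str, float]]]:
    """Apply MAF / HWE / HLA / LD rules to SNP models.

    Returns (kept models, rejection log). The log records one
    (snp_a, snp_b, rule, value) row per dropped model; rules are checked in
    the order maf, hwe, hla, ld and the first failure is recorded. Pairs
    whose LD is undefined (monomorphic member) are kept and flagged with an
    ``ld_undefined`` log row with value nan.
    """
    index = dataset.snp_index()
    pos = {s.snp_id: (s.chromosome, s.position) for s in dataset.snps}
    involved = {sid for m in models for sid in m.pair}
    missing_snps = involved - set(index)
    if missing_snps:
        raise ValidationError(f"SNP models reference SNPs absent from dataset: {sorted(missing_snps)[:5]}")
    stats_by_snp = _per_snp_qc_stats(dataset, involved)

    def in_hla(sid: str) -> bool:
        if qc.hla_region is None:
            return False
        chrom, start, end = qc.hla_region
        c, p = pos[sid]
        return c == str(chrom) and start <= p <= end  # closed interval

    kept: list[SnpModel] = []
    log: list[tuple[str, str, str, float]] = []
    for m in sorted(models, key=lambda x: x.pair):
        fail = None
        for sid in m.pair:
            maf, hwe_p = stats_by_snp[sid]
            if sid in qc.whitelist:
                continue
            if maf < qc.maf_min:
                fail = ("maf", maf)
                break
            if hwe_p < qc.hwe_alpha:
                fail = ("hwe", hwe_p)
                break
        if fail is None and in_hla(m.snp_a) and in_hla(m.snp_b):
            fail = ("hla", float("nan"))
        if fail is None:
            r2 = pairwise_r2(
                dataset.genotypes[:, index[m.snp_a]],
                dataset.genotypes[:, index[m.snp_b]],
            )
            if r2 is None:
                log.append((m.snp_a, m.snp_b, "ld_undefined", float("nan")))
            elif r2 > qc.ld_r2_max:
                fail = ("ld", r2)
        if fail is None:
            kept.append(m)
        else:
            log.append((m.snp_a, m.snp_b, fail[0], fail[1]))
    return kept, log
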