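"""Permutation-based SNP-level FWER control and ATPM gene-level testing.

SNP level: the family-wise error rate across all tested SNP pairs is
controlled with the permutation distribution of the minimum p-value — the
phenotype is permuted ``n_perm`` times, the smallest interaction p of each
permutation is recorded, and the significance threshold is the
``floor(level * n_perm)``-th smallest of these minima.

Gene level: the p-values of the SNP models mapped to one gene pair are
combined with the adaptive truncated product method (ATPM). For truncation
point tau the statistic is

    W(tau) = prod_i p_i ** 1[p_i <= tau]

computed for the observed data (b = 0) and B phenotype permutations. Its
permutation p-value pi_b(tau) = #{l : W_b(tau) >= W_l(tau)} / (B + 1) uses
the inclusive comparison over l = 0..B (the observed statistic is part of
the null reference). The adaptive statistic is pi*_b = min_tau pi_b(tau),
and the gene-model p-value is P0 = #{l : pi*_0 >= pi*_l} / (B + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .association import AdjustedPhenotype, PairScanner, InteractionResult
from .io_formats import GenotypeDataset, ValidationError
from .model_building import GeneModel, SnpModel

__all__ = [
    "ThresholdResult",
    "PermutedPvalStore",
    "GeneModelResult",
    "DEFAULT_TAUS",
    "threshold_from_min_p",
    "fwer_threshold",
    "select_significant",
    "truncated_product",
    "atpm_test",
    "gene_level_analysis",
]

DEFAULT_TAUS: tuple[float, ...] = (0.001, 0.01, 0.05)


@dataclass
class ThresholdResult:
    """Permutation null of the minimum interaction p and the FWER threshold."""

    min_p_per_permutation: np.ndarray
    threshold: float
    fwer_level: float
    n_perm: int
    seed: int


@dataclass
class PermutedPvalStore:
    """Per-SNP-model p-values for the observed data (column 0) and B permutations.

    ``pvals[i, b]`` is the interaction p of SNP model i in dataset b; entries
    above ``store_threshold`` are stored as nan with the convention that an
    absent value lies in (store_threshold, 1] — exact for every truncated
    product with tau <= store_threshold.
    """

    snp_models: list[SnpModel]
    pvals: np.ndarray  # (n_models, B+1), nan = "> store_threshold"
    store_threshold: float
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pvals.shape[0] != len(self.snp_models):
            raise ValidationError("p-value store row count != number of SNP models")
        if self.pvals.shape[1] < 1:
            raise ValidationError("store must include the observed column b=0")

    @property
    def n_perm(self) -> int:
        return self.pvals.shape[1] - 1

    def rows_for(self, model_indices: Sequence[int]) -> np.ndarray:
        return self.pvals[list(model_indices), :]


@dataclass
class GeneModelResult:
    """ATPM outcome for one gene pair."""

    gene_a: str
    gene_b: str
    n_snp_models: int
    pi0: dict[float, float]
    pi_star0: float
    p0: float
    significant: bool


def permute_columns(y: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n, n_perm) matrix whose columns are independent permutations of y."""
    n = y.size
    out = np.empty((n, n_perm), dtype=float)
    for b in range(n_perm):
        out[:, b] = y[rng.permutation(n)]
    return out


def threshold_from_min_p(min_p: np.ndarray, level: float) -> float:
    """The floor(level * n_perm)-th smallest permutation minimum p-value;
    falls back to the smallest minimum (with a warning) when that rank is 0."""
    n_perm = len(min_p)
    k = int(np.floor(level * n_perm))
    ordered = np.sort(np.asarray(min_p, dtype=float))
    if k == 0:
        warnings.warn("level * n_perm < 1; using the smallest permutation minimum")
        return float(ordered[0])
    return float(ordered[k - 1])


def fwer_threshold(
    dataset: GenotypeDataset,
    y_adj: AdjustedPhenotype,
    snp_models: Sequence[SnpModel],
    n_perm: int = 400,
    level: float = 0.05,
    seed: int = 0,
) -> ThresholdResult:
    """Dataset-dependent SNP-level significance threshold at a given FWER.

    Permutes the adjusted phenotype ``n_perm`` times, scans every SNP model
    per permutation, records the minimum p, and returns the
    ``floor(level * n_perm)``-th smallest minimum (with k = 0 falling back
    to the smallest minimum, with a warning).
    """
    if not snp_models:
        raise ValidationError("no SNP models to derive a threshold from")
    if n_perm < 20:
        raise ValidationError("n_perm must be >= 20 for a usable tail percentile")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scanner = PairScanner(dataset, snp_models)
    Y = permute_columns(np.asarray(y_adj.values, dtype=float), n_perm, rng)
    _, _, _, pvals = scanner.scan(Y)
    min_p = pvals.min(axis=0)
    threshold = threshold_from_min_p(min_p, level)
    return ThresholdResult(
        min_p_per_permutation=min_p, threshold=threshold,
        fwer_level=level, n_perm=n_perm, seed=seed,
    )


def select_significant(
    results: Iterable[InteractionResult], threshold: float
) -> list[InteractionResult]:
    """SNP models significant at the permutation threshold (p <= threshold)."""
    out = [r for r in results if not r.degenerate and r.p <= threshold]
    out.sort(key=lambda r: (r.p, r.snp_a, r.snp_b))
    return out


def truncated_product(pvals: Sequence[float], tau: float) -> float:
    """log W(tau): summed log of the p-values <= tau (inclusive); empty product -> 0.

    Returned in log space to avoid underflow; W itself is exp of the result.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) <= 0.0 or np.nanmax(p) > 1.0):
        raise ValidationError("p-values must lie in (0, 1]")
    if not (0.0 < tau < 1.0):
        raise ValidationError("tau must lie in (0, 1)")
    mask = p <= tau  # nan (absent, > store_threshold) compares False
    if not mask.any():
        return 0.0
    return float(np.log(p[mask]).sum())


def _log_w_matrix(P: np.ndarray, taus: Sequence[float]) -> np.ndarray:
    """(n_taus, B+1) matrix of log W_b(tau); nan entries contribute nothing."""
    out = np.zeros((len(taus), P.shape[1]))
    logp = np.where(np.isnan(P), 0.0, np.log(np.maximum(P, np.finfo(float).tiny)))
    for t, tau in enumerate(taus):
        mask = P <= tau
        out[t] = np.where(mask, logp, 0.0).sum(axis=0)
    return out


def atpm_test(
    pvals: np.ndarray,
    gene_model: GeneModel,
    taus: Sequence[float] = DEFAULT_TAUS,
    alpha: float = 0.05,
) -> GeneModelResult:
    """Adaptive truncated product test for one gene pair.

    ``pvals`` is the (n_snp_models, B+1) slice of the permutation store for
    this gene pair, observed data in column 0, nan marking values above the
    storage threshold. All comparisons are inclusive and the observed
    dataset takes part in its own null reference, so every pi and P0 lies on
    the grid {1/(B+1), ..., 1}.
    """
    P = np.asarray(pvals, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValidationError("need the observed column plus >= 1 permutation")
    finite = P[np.isfinite(P)]
    if finite.size and (finite.min() <= 0.0 or finite.max() > 1.0):
        raise ValidationError("p-values must lie in (0, 1]")
    n_total = P.shape[1]  # B + 1
    log_w = _log_w_matrix(P, taus)
    pi = np.empty_like(log_w)
    for t in range(len(taus)):
        # pi_b = #{l : W_l <= W_b} / (B+1), inclusive (counts b itself)
        order = np.sort(log_w[t])
        pi[t] = np.searchsorted(order, log_w[t], side="right") / n_total
    pi_star = pi.min(axis=0)
    p0 = float(np.sum(pi_star <= pi_star[0])) / n_total
    return GeneModelResult(
        gene_a=gene_model.gene_a,
        gene_b=gene_model.gene_b,
        n_snp_models=P.shape[0],
        pi0={float(tau): float(pi[t, 0]) for t, tau in enumerate(taus)},
        pi_star0=float(pi_star[0]),
        p0=p0,
        significant=p0 <= alpha,
    )


def build_pval_store(
    dataset: GenotypeDataset,
    y_adj: AdjustedPhenotype,
    snp_models: Sequence[SnpModel],
    n_perm: int,
    store_threshold: float,
    seed: int,
    y_observed: Optional[np.ndarray] = None,
) -> PermutedPvalStore:
    """Scan all SNP models against the observed phenotype and ``n_perm``
    seeded permutations of it, keeping p-values <= store_threshold."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    y0 = np.asarray(y_adj.values if y_observed is None else y_observed, dtype=float)
    Y = np.column_stack([y0, permute_columns(y0, n_perm, rng)])
    scanner = PairScanner(dataset, snp_models)
    _, _, _, pvals = scanner.scan(Y)
    pvals = np.where(pvals <= store_threshold, pvals, np.nan)
    return PermutedPvalStore(
        snp_models=list(snp_models), pvals=pvals,
        store_threshold=store_threshold, seed=seed,
    )


def gene_level_analysis(
    significant_snp_models: Sequence[InteractionResult],
    snp_models: Sequence[SnpModel],
    dataset: GenotypeDataset,
    y_adj: AdjustedPhenotype,
    n_perm: int = 999,
    taus: Sequence[float] = DEFAULT_TAUS,
    alpha: float = 0.05,
    seed: int = 0,
    y_observed: Optional[np.ndarray] = None,
) -> list[GeneModelResult]:
    """ATPM over every gene model that parents >= 1 significant SNP model.

    One shared set of B seeded phenotype permutations is scanned once for
    the SNP models of all candidate gene pairs (storage threshold
    max(taus)), then the ATPM runs per candidate. Returns results sorted by
    ascending P0; an empty candidate set is a valid (empty) outcome.
    """
    sig_pairs = {(r.snp_a, r.snp_b) for r in significant_snp_models}
    if not sig_pairs:
        return []
    candidates: set[GeneModel] = set()
    for m in snp_models:
        if m.pair in sig_pairs:
            candidates |= m.parent_gene_models
    rows_by_gm: dict[GeneModel, list[int]] = {gm: [] for gm in candidates}
    scan_models: list[SnpModel] = []
    for m in snp_models:
        parents = m.parent_gene_models & candidates
        if parents:
            idx = len(scan_models)
            scan_models.append(m)
            for gm in parents:
                rows_by_gm[gm].append(idx)
    store = build_pval_store(
        dataset, y_adj, scan_models,
        n_perm=n_perm, store_threshold=max(taus), seed=seed,
        y_observed=y_observed,
    )
    results = [
        atpm_test(store.rows_for(rows_by_gm[gm]), gm, taus=taus, alpha=alpha)
        for gm in sorted(candidates)
    ]
    results.sort(key=lambda r: (r.p0, r.gene_a, r.gene_b))
    return results
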