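"""Phenotype adjustment, single-SNP association, pairwise interaction tests,
and polygenic-score construction.

The case-control phenotype is adjusted for population structure once, by
logistic regression on the covariates: the working phenotype is the response
residual y - p_hat. Interaction testing then uses the linear model

    Y = b0 + b1 g_A + b2 g_B + b3 g_A g_B (+ b4 PRS)

per SNP pair, with a two-sided Student-t test on b3. :class:`PairScanner`
factors the per-pair linear algebra out of the phenotype so that the same
set of pairs can be scanned against many (permuted) phenotype vectors at
once — the workhorse of the permutation stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from .io_formats import GenotypeDataset, SnpRecord, ValidationError, MISSING
from .model_building import SnpModel, pairwise_r2

__all__ = [
    "AdjustedPhenotype",
    "InteractionResult",
    "PrsVector",
    "SeparationError",
    "adjust_phenotype",
    "single_snp_assoc",
    "interaction_test",
    "PairScanner",
    "scan_pairs",
    "clump",
    "compute_prs",
]

#: Smallest reportable p-value; p is never exactly 0.
P_FLOOR = float(np.nextafter(0.0, 1.0))


class SeparationError(ValueError):
    """Perfect separation in the logistic adjustment fit."""


@dataclass
class AdjustedPhenotype:
    """Response residuals y - fitted probability, with covariate provenance."""

    values: np.ndarray
    provenance: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValidationError("non-finite adjusted phenotype values")


@dataclass
class InteractionResult:
    snp_a: str
    snp_b: str
    beta3: float
    se3: float
    statistic: float
    p: float
    n_used: int
    adjusted_for_prs: bool = False
    degenerate: bool = False
    reason: Optional[str] = None


@dataclass
class PrsVector:
    """Per-sample polygenic score (average effect size over non-missing SNPs)."""

    scores: np.ndarray  # nan where no kept SNP was genotyped
    included_snps: list[str]
    weights: dict[str, float]


def adjust_phenotype(
    y: np.ndarray, covariates: Optional[np.ndarray] = None,
    covariate_names: Optional[Sequence[str]] = None,
) -> AdjustedPhenotype:
    """Logistic regression of the binary phenotype on intercept + covariates,
    fit by iteratively reweighted least squares (gradient norm <= 1e-8 or
    100 iterations); returns the response residuals y - p_hat.

    With no covariates this reduces to ``y - mean(y)``. Raises
    :class:`SeparationError` on perfect separation (naming the covariate
    with the steepest coefficient) and :class:`ValidationError` on a
    rank-deficient design.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("phenotype must be binary 0/1 for adjustment")
    n = y.size
    if covariates is None or covariates.size == 0:
        names: list[str] = []
        X = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        names = list(covariate_names) if covariate_names is not None else [
            f"cov{j + 1}" for j in range(covariates.shape[1])
        ]
        X = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("covariate design is rank deficient")

    beta = np.zeros(X.shape[1])
    for _ in range(100):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if float(np.linalg.norm(grad)) <= 1e-8:
            break
        w = mu * (1.0 - mu)
        if np.max(np.abs(eta)) > 30.0 and np.allclose(mu[y == 1], 1.0, atol=1e-8) \
                and np.allclose(mu[y == 0], 0.0, atol=1e-8):
            worst = int(np.argmax(np.abs(beta[1:]))) if beta.size > 1 else 0
            name = names[worst] if names else "intercept"
            raise SeparationError(f"perfect separation detected (covariate {name!r})")
        H = X.T @ (X * w[:, None])
        try:
            beta = beta + np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            worst = int(np.argmax(np.abs(beta[1:]))) if beta.size > 1 else 0
            name = names[worst] if names else "intercept"
            raise SeparationError(f"singular IRLS step (covariate {name!r})") from exc
    else:
        eta = X @ beta
        mu = expit(eta)
        if np.allclose(mu[y == 1], 1.0, atol=1e-6) and np.allclose(mu[y == 0], 0.0, atol=1e-6):
            raise SeparationError("perfect separation detected (no convergence)")
    return AdjustedPhenotype(values=y - expit(X @ beta), provenance=names)


def _t_pvalue(t_stat: np.ndarray, df: int) -> np.ndarray:
    p = 2.0 * stats.t.sf(np.abs(t_stat), df)
    return np.clip(p, P_FLOOR, 1.0)


def single_snp_assoc(g: np.ndarray, y_adj: np.ndarray) -> tuple[float, float, float]:
    """Simple linear regression of the adjusted phenotype on one dosage column.

    Returns (beta, se, p) with a two-sided Student-t p (df = n - 2), complete
    case. A column monomorphic among complete cases yields (nan, nan, nan)
    and must be excluded downstream.
    """
    g = np.asarray(g)
    ok = g != MISSING
    x = g[ok].astype(float)
    y = np.asarray(y_adj, dtype=float)[ok]
    n = x.size
    if n < 3:
        raise ValidationError("fewer than 3 complete-case samples")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        return (float("nan"), float("nan"), float("nan"))
    beta = float(np.sum((x - x.mean()) * (y - y.mean()))) / sxx
    resid = y - y.mean() - beta * (x - x.mean())
    sigma2 = float(resid @ resid) / (n - 2)
    se = float(np.sqrt(sigma2 / sxx)) if sigma2 > 0 else 0.0
    if se == 0.0:
        return beta, 0.0, P_FLOOR
    t_stat = beta / se
    return beta, se, float(_t_pvalue(np.array([t_stat]), n - 2)[0])


class PairScanner:
    """Pre-factored interaction tests for a fixed set of SNP pairs.

    The design matrix [1, gA, gB, gA*gB, extra...] of each pair does not
    depend on the phenotype, so its normal-equations factorisation is
    computed once; :meth:`scan` then tests any batch of phenotype columns
    (e.g. permutations) against every pair with two matrix products per
    pair. Samples missing either genotype are dropped for that pair only.
    """

    def __init__(
        self,
        dataset: GenotypeDataset,
        snp_models: Sequence[SnpModel],
        extra_covariates: Optional[np.ndarray] = None,
    ):
        self.snp_models = list(snp_models)
        index = dataset.snp_index()
        G = dataset.genotypes
        n = dataset.n_samples
        if extra_covariates is not None:
            extra_covariates = np.asarray(extra_covariates, dtype=float)
            if extra_covariates.ndim == 1:
                extra_covariates = extra_covariates[:, None]
        self._extra = extra_covariates
        self._masks: list[Optional[np.ndarray]] = []
        self._proj: list[Optional[np.ndarray]] = []  # (X'X)^-1 X'
        self._xtx_list: list[Optional[np.ndarray]] = []
        self._xtx_inv33: list[float] = []
        self._df: list[int] = []
        self.degenerate: list[Optional[str]] = []
        for m in self.snp_models:
            ga = G[:, index[m.snp_a]].astype(float)
            gb = G[:, index[m.snp_b]].astype(float)
            ok = (G[:, index[m.snp_a]] != MISSING) & (G[:, index[m.snp_b]] != MISSING)
            if extra_covariates is not None:
                ok &= np.isfinite(extra_covariates).all(axis=1)
            full = bool(ok.all())
            cols = [np.ones(int(ok.sum())), ga[ok], gb[ok], (ga * gb)[ok]]
            if extra_covariates is not None:
                cols.extend(extra_covariates[ok].T)
            X = np.column_stack(cols)
            k = X.shape[1]
            n_used = X.shape[0]
            self._masks.append(None if full else ok)
            if n_used < k + 1:
                self._proj.append(None)
                self._xtx_list.append(None)
                self._xtx_inv33.append(float("nan"))
                self._df.append(0)
                self.degenerate.append("too_few_complete_cases")
                continue
            xtx = X.T @ X
            if np.linalg.matrix_rank(xtx, tol=1e-8 * float(np.trace(xtx))) < k:
                self._proj.append(None)
                self._xtx_list.append(None)
                self._xtx_inv33.append(float("nan"))
                self._df.append(0)
                self.degenerate.append("rank_deficient_design")
                continue
            xtx_inv = np.linalg.inv(xtx)
            self._proj.append(xtx_inv @ X.T)
            self._xtx_list.append(xtx)
            self._xtx_inv33.append(float(xtx_inv[3, 3]))
            self._df.append(n_used - k)
            self.degenerate.append(None)

    @property
    def n_pairs(self) -> int:
        return len(self.snp_models)

    def scan(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Test every pair against every phenotype column.

        ``Y`` is (n_samples,) or (n_samples, n_phenotypes). Returns
        (beta3, se3, t, p), each (n_pairs, n_phenotypes). Degenerate pairs
        carry beta3 = nan and p = 1 (recorded with their reason).
        """
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        B = Y.shape[1]
        beta3 = np.full((self.n_pairs, B), np.nan)
        se3 = np.full((self.n_pairs, B), np.nan)
        tval = np.full((self.n_pairs, B), np.nan)
        pval = np.ones((self.n_pairs, B))
        for i, proj in enumerate(self._proj):
            if proj is None:
                continue
            mask = self._masks[i]
            Yi = Y if mask is None else Y[mask]
            coef = proj @ Yi  # (k, B)
            # RSS = y'y - beta'(X'X)beta since beta solves the normal equations
            rss = np.sum(Yi * Yi, axis=0) - np.einsum("kb,kb->b", coef, self._xtx_list[i] @ coef)
            rss = np.maximum(rss, 0.0)
            df = self._df[i]
            sigma2 = rss / df
            se = np.sqrt(np.maximum(sigma2 * self._xtx_inv33[i], 0.0))
            b3 = coef[3]
            with np.errstate(divide="ignore", invalid="ignore"):
                t_stat = np.where(se > 0, b3 / se, np.inf * np.sign(b3))
            t_stat = np.where((se == 0) & (b3 == 0), 0.0, t_stat)
            beta3[i] = b3
            se3[i] = se
            tval[i] = t_stat
            pval[i] = _t_pvalue(t_stat, df)
        return beta3, se3, tval, pval

    def results(self, y: np.ndarray, adjusted_for_prs: bool = False) -> list[InteractionResult]:
        """Full :class:`InteractionResult` list for one phenotype vector."""
        beta3, se3, tval, pval = self.scan(np.asarray(y, dtype=float))
        out = []
        for i, m in enumerate(self.snp_models):
            reason = self.degenerate[i]
            n_used = (self._masks[i].sum() if self._masks[i] is not None
                      else len(y))
            out.append(
                InteractionResult(
                    snp_a=m.snp_a, snp_b=m.snp_b,
                    beta3=float(beta3[i, 0]), se3=float(se3[i, 0]),
                    statistic=float(tval[i, 0]), p=float(pval[i, 0]),
                    n_used=int(n_used), adjusted_for_prs=adjusted_for_prs,
                    degenerate=reason is not None, reason=reason,
                )
            )
        return out


def interaction_test(
    g_a: np.ndarray,
    g_b: np.ndarray,
    y_adj: np.ndarray,
    extra_covariates: Optional[np.ndarray] = None,
    snp_a: str = "snp_a",
    snp_b: str = "snp_b",
) -> InteractionResult:
    """One interaction test: OLS of y_adj on [1, gA, gB, gA*gB, extra...],
    two-sided Student-t p for the product coefficient."""
    ds = GenotypeDataset(
        sample_ids=[f"s{i}" for i in range(len(y_adj))],
        snps=[SnpRecord(snp_a, "0", 1), SnpRecord(snp_b, "0", 2)],
        genotypes=np.column_stack([g_a, g_b]),
        phenotype=np.zeros(len(y_adj), dtype=np.int8),
    )
    model = SnpModel(snp_a, snp_b)
    scanner = PairScanner(ds, [model], extra_covariates=extra_covariates)
    res = scanner.results(y_adj, adjusted_for_prs=extra_covariates is not None)[0]
    res.snp_a, res.snp_b = model.pair
    return res


def scan_pairs(
    snp_models: Sequence[SnpModel],
    dataset: GenotypeDataset,
    y_adj: AdjustedPhenotype,
    store_threshold: float = 0.05,
    extra_covariates: Optional[np.ndarray] = None,
) -> tuple[list[InteractionResult], list[InteractionResult]]:
    """Interaction-test every SNP model; keep results with p <= store_threshold.

    Returns (retained results sorted by (p, ids), degenerate results).
    """
    scanner = PairScanner(dataset, snp_models, extra_covariates=extra_covariates)
    all_results = scanner.results(y_adj.values, adjusted_for_prs=extra_covariates is not None)
    kept = [r for r in all_results if not r.degenerate and r.p <= store_threshold]
    degenerate = [r for r in all_results if r.degenerate]
    kept.sort(key=lambda r: (r.p, r.snp_a, r.snp_b))
    return kept, degenerate


def clump(
    summary: dict[str, tuple[float, float]],
    dataset: GenotypeDataset,
    window_kb: float = 250.0,
    p_max: float = 1.0,
    r2_max: float = 0.1,
) -> list[str]:
    """Greedy LD clumping of single-SNP summary statistics.

    ``summary`` maps snp_id -> (beta, p). SNPs are visited by ascending p
    (ties broken by position then id); each index SNP removes every
    still-unclumped SNP within ±window_kb on its chromosome with p <= p_max
    and dosage r^2 > r2_max. Returns the index SNPs in visiting order.
    """
    index = dataset.snp_index()
    meta = {s.snp_id: s for s in dataset.snps}
    order = sorted(
        (sid for sid in summary if sid in index and np.isfinite(summary[sid][1])),
        key=lambda sid: (summary[sid][1], meta[sid].position, sid),
    )
    alive = set(order)
    kept: list[str] = []
    window_bp = window_kb * 1000.0
    for sid in order:
        if sid not in alive:
            continue
        kept.append(sid)
        alive.discard(sid)
        s = meta[sid]
        for other in list(alive):
            o = meta[other]
            if o.chromosome != s.chromosome or abs(o.position - s.position) > window_bp:
                continue
            if summary[other][1] > p_max:
                continue
            r2 = pairwise_r2(
                dataset.genotypes[:, index[sid]], dataset.genotypes[:, index[other]]
            )
            if r2 is not None and r2 > r2_max:
                alive.discard(other)
    return kept


def compute_prs(
    dataset: GenotypeDataset, kept_snps: Sequence[str], betas: dict[str, float]
) -> PrsVector:
    """Average-effect-size polygenic score: per sample, the mean of
    beta_j * dosage_j over the kept SNPs with a non-missing genotype."""
    if not kept_snps:
        raise ValidationError("no SNPs kept for PRS")
    index = dataset.snp_index()
    cols = dataset.genotypes[:, [index[s] for s in kept_snps]].astype(float)
    present = cols != MISSING
    w = np.array([betas[s] for s in kept_snps], dtype=float)
    contrib = np.where(present, cols, 0.0) * w[None, :]
    denom = present.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, contrib.sum(axis=1) / denom, np.nan)
    return PrsVector(scores=scores, included_snps=list(kept_snps),
                     weights={s: betas[s] for s in kept_snps})
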