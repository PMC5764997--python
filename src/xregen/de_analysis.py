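"""Replicate-free differential expression for regeneration time courses.

Each post-injury time point is compared against the baseline (first)
time point with a two-sided exact test on the pair of raw counts,
conditioned on their total, under a negative-binomial model with a fixed
common dispersion phi (variance = mu + phi * mu^2).  Without replicates
the dispersion cannot be estimated per gene; it is a stated model input
(default 0.1, config-exposed, with an optional most-genes-null moment
estimator).  P-values are Benjamini-Hochberg adjusted per time point and
genes are called DE when |log2FC| > fc_threshold and adjusted p < alpha
at any non-baseline time point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix

__all__ = [
    "DEConfig",
    "DETable",
    "filter_expressed",
    "normalize_libsizes",
    "compute_log2fc",
    "nb_exact_test",
    "bh_adjust",
    "call_de",
    "run_de",
    "estimate_dispersion",
]


@dataclass(frozen=True)
class DEConfig:
    """Thresholds and model parameters of the DE analysis.

    fc_threshold:
        |log2FC| cutoff; default 2.0.  Hydra time courses use 0.5 (their
        fold changes are globally damped), set per species in the run
        config.
    alpha:
        Adjusted p-value cutoff (default 0.05).
    min_count / min_rpkm:
        Expression filter: a gene is analysed when its raw count exceeds
        ``min_count`` in at least one time point, or its rpkm exceeds
        ``min_rpkm`` when gene lengths are available.
    dispersion:
        Common NB dispersion phi (variance = mu + phi mu^2); phi = 0
        degenerates the exact test to the binomial (Poisson) case.
    pseudocount:
        Added to normalized counts before taking log2 so fold changes at
        zero counts stay finite.
    """

    fc_threshold: float = 2.0
    alpha: float = 0.05
    min_count: int = 20
    min_rpkm: float = 1.0
    dispersion: float = 0.1
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.alpha <= 0 or self.pseudocount <= 0:
            raise ValueError("thresholds and pseudocount must be > 0")
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")


@dataclass
class DETable:
    """Long-form DE results plus the per-gene any-time-point DE flag."""

    species: str
    table: pd.DataFrame  # gene_id, time_h, log2fc, p_raw, p_adj, is_de
    gene_de: dict[str, bool]

    def de_genes(self) -> set[str]:
        return {g for g, flag in self.gene_de.items() if flag}


def filter_expressed(counts: CountMatrix, cfg: DEConfig) -> list[str]:
    """Gene ids passing the expression filter.

    Retained iff max raw count over time points is strictly greater than
    ``min_count``, or — when gene lengths are known — max rpkm strictly
    exceeds ``min_rpkm`` (rpkm = count * 1e9 / (library_size * length)).
    """
    max_count = counts.counts.max(axis=1) if counts.n_times else np.zeros(counts.n_genes)
    keep = max_count > cfg.min_count
    if counts.gene_length_bp is not None:
        libsizes = counts.counts.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rpkm = counts.counts * 1e9 / (libsizes[None, :] * counts.gene_length_bp[:, None])
        keep |= np.nan_to_num(rpkm).max(axis=1) > cfg.min_rpkm
    return [g for g, k in zip(counts.gene_ids, keep) if k]


def normalize_libsizes(counts: CountMatrix, method: str = "total") -> np.ndarray:
    """Per-time-point size factors.

    ``method="total"`` (default): column sum / geometric mean of column
    sums — equal-depth libraries get unit factors and the product of
    factors is 1.  ``method="median_ratio"``: median-of-ratios factors
    (median over everywhere-positive genes of the ratio to the per-gene
    geometric mean), robust to composition shifts when differential
    expression is mass-asymmetric.  TMM trimming is deliberately not
    offered (its trimming constants are an extrinsic choice — the moment
    they would matter, supply externally normalized counts instead).
    """
    sums = counts.counts.sum(axis=0).astype(float)
    if np.any(sums <= 0):
        raise ValueError("cannot normalize: a time-point column has zero total count")
    if method == "total":
        geo = float(np.exp(np.mean(np.log(sums))))
        return sums / geo
    if method == "median_ratio":
        c = counts.counts.astype(float)
        pos = (c > 0).all(axis=1)
        if not np.any(pos):
            raise ValueError("median_ratio normalization needs genes positive at every time point")
        logc = np.log(c[pos])
        factors = np.exp(np.median(logc - logc.mean(axis=1)[:, None], axis=0))
        return factors
    raise ValueError(f"unknown normalization method '{method}'")


def compute_log2fc(
    counts: CountMatrix, factors: np.ndarray, cfg: DEConfig
) -> np.ndarray:
    """log2 fold change of each gene at each time point vs the baseline.

    log2fc(g, t) = log2((c(g,t)/f(t) + pc) / (c(g,0)/f(0) + pc)); the
    baseline column is identically zero.
    """
    factors = np.asarray(factors, dtype=float)
    norm = counts.counts / factors[None, :] + cfg.pseudocount
    return np.log2(norm / norm[:, [0]])


def _nb_split_logpmf(k: np.ndarray, s: int, mu_a: float, mu_b: float, phi: float) -> np.ndarray:
    """Unnormalized log probability of the split (A=k, B=s-k)."""
    if phi == 0.0:
        return stats.poisson.logpmf(k, mu_a) + stats.poisson.logpmf(s - k, mu_b)
    r = 1.0 / phi
    p_a = r / (r + mu_a)
    p_b = r / (r + mu_b)
    return stats.nbinom.logpmf(k, r, p_a) + stats.nbinom.logpmf(s - k, r, p_b)


def nb_exact_test(
    count_a: int,
    count_b: int,
    size_a: float = 1.0,
    size_b: float = 1.0,
    dispersion: float = 0.1,
) -> float:
    """Two-sided exact test of two NB counts, conditioned on their total.

    Under the null the two counts share one underlying expression rate;
    conditioning on s = a + b, the expected split is proportional to the
    effective library sizes (mu_a = s * size_a / (size_a + size_b)).
    The p-value sums, over all splits k = 0..s, the probabilities
    P(A=k, B=s-k) not exceeding that of the observed split, normalized by
    the total — the method of small p-values, as used by exact NB tests
    in the replicate-free setting.  dispersion = 0 reduces to the
    binomial (conditional Poisson) exact test.

    Returns a p-value in (0, 1].
    """
    if dispersion < 0:
        raise ValueError(f"dispersion must be >= 0, got {dispersion}")
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if size_a <= 0 or size_b <= 0:
        raise ValueError("library sizes must be positive")
    s = count_a + count_b
    if s == 0:
        return 1.0
    frac = size_a / (size_a + size_b)
    mu_a = s * frac
    mu_b = s * (1.0 - frac)
    k = np.arange(s + 1)
    logf = _nb_split_logpmf(k, s, mu_a, mu_b, dispersion)
    logf -= logf.max()
    f = np.exp(logf)
    f_obs = f[count_a]
    # relative tolerance absorbs last-ulp asymmetry between f(k) and f(s-k)
    p = float(f[f <= f_obs * (1.0 + 1e-9)].sum() / f.sum())
    return min(max(p, np.nextafter(0, 1)), 1.0)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} p_(j) * m / j over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("p-values contain NaN")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def call_de(
    log2fc: np.ndarray, p_adj: np.ndarray, cfg: DEConfig
) -> tuple[np.ndarray, np.ndarray]:
    """DE calls per gene x time point and the per-gene any-time flag.

    is_de(g, t) iff |log2fc(g, t)| strictly exceeds fc_threshold and
    p_adj(g, t) is strictly below alpha.  The baseline column (log2fc
    identically 0) can never be called.  Gene-level DE = DE at >= 1
    non-baseline time point.
    """
    is_de = (np.abs(log2fc) > cfg.fc_threshold) & (p_adj < cfg.alpha)
    is_de[:, 0] = False
    return is_de, is_de[:, 1:].any(axis=1)


def estimate_dispersion(counts: CountMatrix, factors: np.ndarray | None = None) -> float:
    """Most-genes-null moment estimate of the common dispersion phi.

    Treats each gene's normalized counts across time points as if drawn
    from one NB law (true for unchanging genes, the bulk), computes the
    per-gene method-of-moments phi = (var - mean) / mean^2 and returns
    the median over genes with mean > 0, floored at 0.  A crude but
    serviceable common-dispersion estimate when no replicates exist;
    genes genuinely regulated in time inflate it slightly, making the
    exact test conservative.
    """
    if factors is None:
        factors = normalize_libsizes(counts)
    norm = counts.counts / np.asarray(factors)[None, :]
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    ok = mean > 0
    if not np.any(ok):
        return 0.0
    phi = (var[ok] - mean[ok]) / mean[ok] ** 2
    return float(max(0.0, np.median(phi)))


def run_de(counts: CountMatrix, cfg: DEConfig | None = None) -> DETable:
    """Full per-species DE analysis of a raw count time course.

    Filters unexpressed genes, normalizes library depths, computes
    log2FC vs baseline, exact-tests every non-baseline time point
    against the baseline, BH-adjusts within each time point, and calls
    DE genes.  Identical (a, b, sizes) count pairs share one exact-test
    evaluation via a memo table.
    """
    cfg = cfg or DEConfig()
    kept = filter_expressed(counts, cfg)
    idx = {g: i for i, g in enumerate(counts.gene_ids)}
    rows = [idx[g] for g in kept]
    sub = CountMatrix(
        species=counts.species,
        gene_ids=kept,
        time_points_h=counts.time_points_h.copy(),
        counts=counts.counts[rows, :],
        gene_length_bp=(
            counts.gene_length_bp[rows] if counts.gene_length_bp is not None else None
        ),
    )
    factors = normalize_libsizes(sub)
    log2fc = compute_log2fc(sub, factors, cfg)
    libsizes = sub.counts.sum(axis=0).astype(float)

    n_genes, n_times = sub.counts.shape
    p_raw = np.ones((n_genes, n_times))
    memo: dict[tuple[int, int, int], float] = {}
    base = sub.counts[:, 0]
    for t in range(1, n_times):
        col = sub.counts[:, t]
        for g in range(n_genes):
            key = (int(col[g]), int(base[g]), t)
            p = memo.get(key)
            if p is None:
                p = nb_exact_test(
                    int(col[g]), int(base[g]), libsizes[t], libsizes[0], cfg.dispersion
                )
                memo[key] = p
            p_raw[g, t] = p

    p_adj = np.ones_like(p_raw)
    for t in range(1, n_times):
        p_adj[:, t] = bh_adjust(p_raw[:, t])

    is_de, gene_de = call_de(log2fc, p_adj, cfg)

    long = pd.DataFrame(
        {
            "gene_id": np.repeat(sub.gene_ids, n_times),
            "time_h": np.tile(sub.time_points_h, n_genes),
            "log2fc": log2fc.ravel(),
            "p_raw": p_raw.ravel(),
            "p_adj": p_adj.ravel(),
            "is_de": is_de.ravel(),
        }
    )
    return DETable(
        species=counts.species,
        table=long,
        gene_de={g: bool(f) for g, f in zip(sub.gene_ids, gene_de)},
    )
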