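"""Permutation-based PBS selection index for polygenic adaptation.

Each gene's SNPs (position-ordered) are chunked into bins of 11 — the
mode of the SNP-per-gene distribution — and a bin's index is the
permutation tail probability that an equal-sized random draw of SNPs from
the genome-wide pool has mean PBS at least as large as the bin's observed
mean. Small indices mark coordinated allele-frequency shifts too subtle
for single-SNP sweep statistics. Bin indices are FDR-adjusted; a gene's
index is the mean over its bins, significant below 0.01; term-level
signal is assessed with a one-sided two-sample proportion test of
significant-gene fractions against the complement, after term filtering
(gene count >= median) and redundancy pruning (Ward clustering of
1 - Jaccard distances cut at 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .datatypes import GeneMap, TermMap, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BinSpec",
    "BinIndexResult",
    "GeneIndexResult",
    "TermTestResult",
    "make_bins",
    "null_mean_pbs",
    "selection_index",
    "bh_fdr",
    "gene_index",
    "check_size_bias",
    "filter_terms",
    "prune_terms",
    "term_proportion_test",
]

#: default within-gene bin width — the mode of the SNP-per-gene distribution
DEFAULT_WINDOW = 11
#: remainders below this merge into the preceding bin (keeps bins in [6, 16])
MIN_REMAINDER = 6


@dataclass(frozen=True)
class BinSpec:
    gene: str
    ordinal: int
    snps: tuple[str, ...]


@dataclass
class BinIndexResult:
    bin: BinSpec
    observed_mean: float
    index: float  # permutation tail probability, (0, 1]
    q: float = np.nan  # BH-adjusted index


@dataclass
class GeneIndexResult:
    gene: str
    index: float  # mean of the gene's raw bin indices
    q_index: float  # mean of the gene's BH-adjusted bin indices
    n_bins: int
    significant: bool  # index < 0.01, strict


@dataclass
class TermTestResult:
    term: str
    n_term: int
    n_background: int
    k_term: int
    k_background: int
    z: float
    p: float  # one-sided: term proportion greater than background


def make_bins(
    gene_map: GeneMap,
    positions: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
) -> list[BinSpec]:
    """Chunk each gene's position-sorted SNPs into consecutive bins.

    All bins except possibly the last have exactly ``window`` SNPs; a
    remainder of >= MIN_REMAINDER forms its own bin, a smaller remainder
    is merged into the preceding bin. A gene with <= ``window`` SNPs is a
    single bin.
    """
    out: list[BinSpec] = []
    for gene in sorted(gene_map.gene_to_snps):
        snps = gene_map.gene_to_snps[gene]
        missing = [s for s in snps if s not in positions]
        if missing:
            raise ValidationError(f"gene {gene!r}: SNPs missing positions: {sorted(missing)[:5]}")
        ordered = sorted(snps, key=lambda s: (positions[s], s))
        n = len(ordered)
        if n <= window:
            bounds = [(0, n)]
        else:
            rem = n % window
            nfull = n // window
            if rem == 0:
                bounds = [(i * window, (i + 1) * window) for i in range(nfull)]
            elif rem >= MIN_REMAINDER:
                bounds = [(i * window, (i + 1) * window) for i in range(nfull)]
                bounds.append((nfull * window, n))
            else:
                bounds = [(i * window, (i + 1) * window) for i in range(nfull - 1)]
                bounds.append(((nfull - 1) * window, n))
        for i, (lo, hi) in enumerate(bounds):
            out.append(BinSpec(gene, i, tuple(ordered[lo:hi])))
    return out


def null_mean_pbs(
    pbs_pool: np.ndarray,
    k: int,
    n_perm: int = 100_000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sorted null sample of mean PBS over ``n_perm`` draws of ``k``
    distinct SNPs from the genome-wide pool (uniform, without replacement).
    """
    pool = np.asarray(pbs_pool, dtype=float)
    m = len(pool)
    if k > m:
        raise ValidationError(f"bin size {k} exceeds pool size {m}")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, m, size=(n_perm, k))
    if k > 1:
        # redraw rows containing duplicate indices (rare for k << m)
        while True:
            srt = np.sort(idx, axis=1)
            bad = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
            if not bad.any():
                break
            idx[bad] = rng.integers(0, m, size=(int(bad.sum()), k))
    return np.sort(pool[idx].mean(axis=1))


def selection_index(
    bins: Sequence[BinSpec],
    pbs_values: Mapping[str, float],
    pbs_pool: np.ndarray | None = None,
    n_perm: int = 100_000,
    seed: int = 0,
) -> list[BinIndexResult]:
    """Permutation tail probability per bin.

    ``index = (1 + #{null means >= observed mean}) / (1 + n_perm)`` with
    one cached null sample per bin size (shared across equal-sized bins;
    each size's RNG stream is derived from ``seed`` and the size, so a
    subset of bins reproduces the full run's values). Bins containing a
    SNP without finite PBS are skipped with a logged reason. The pool
    defaults to all finite values of ``pbs_values``.
    """
    if pbs_pool is None:
        pbs_pool = np.array([v for v in pbs_values.values() if np.isfinite(v)])
    pool = np.asarray(pbs_pool, dtype=float)
    pool = pool[np.isfinite(pool)]
    nulls: dict[int, np.ndarray] = {}
    out: list[BinIndexResult] = []
    for b in bins:
        vals = np.array([pbs_values.get(s, np.nan) for s in b.snps])
        if not np.all(np.isfinite(vals)):
            logger.info("selection_index: bin %s#%d skipped (missing PBS)", b.gene, b.ordinal)
            continue
        k = len(vals)
        if k not in nulls:
            rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
            nulls[k] = null_mean_pbs(pool, k, n_perm=n_perm, rng=rng)
        null = nulls[k]
        obs = float(vals.mean())
        n_ge = len(null) - int(np.searchsorted(null, obs, side="left"))
        out.append(BinIndexResult(b, obs, (1.0 + n_ge) / (1.0 + n_perm)))
    return out


def bh_fdr(values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (monotone, capped at 1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def adjust_bin_indices(results: Sequence[BinIndexResult]) -> list[BinIndexResult]:
    """Fill the ``q`` field with BH-adjusted indices across all bins."""
    qs = bh_fdr([r.index for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return list(results)


def gene_index(
    bin_results: Sequence[BinIndexResult],
    sig_threshold: float = 0.01,
) -> list[GeneIndexResult]:
    """Aggregate bins to a per-gene selection index.

    The gene's index is the unweighted mean of its bins' raw permutation
    indices (this keeps the genome-wide fraction of significant genes at
    the nominal level under the null); the mean of BH-adjusted bin
    indices is reported alongside as ``q_index``. Significance is strict:
    index < ``sig_threshold``.
    """
    if any(np.isnan(r.q) for r in bin_results):
        adjust_bin_indices(list(bin_results))
    by_gene: dict[str, list[BinIndexResult]] = {}
    for r in bin_results:
        by_gene.setdefault(r.bin.gene, []).append(r)
    out = []
    for gene in sorted(by_gene):
        rs = by_gene[gene]
        idx = float(np.mean([r.index for r in rs]))
        qidx = float(np.mean([r.q for r in rs]))
        out.append(GeneIndexResult(gene, idx, qidx, len(rs), idx < sig_threshold))
    return out


def check_size_bias(
    gene_results: Sequence[GeneIndexResult],
    gene_sizes: Mapping[str, int],
) -> tuple[float, float, float]:
    """OLS of gene index on gene size (in SNPs).

    Returns (slope, adjusted R², F-test p). A flat, non-significant fit
    indicates the index is not confounded by gene length.
    """
    y = np.array([r.index for r in gene_results])
    x = np.array([gene_sizes[r.gene] for r in gene_results], dtype=float)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.rsquared_adj), float(fit.f_pvalue)


def filter_terms(term_map: TermMap, universe: Iterable[str]) -> TermMap:
    """Drop terms whose in-universe gene count falls below the median.

    Gene sets are intersected with the universe first; empty terms are
    discarded before the median is taken; ties at the median are retained.
    """
    universe = set(universe)
    trimmed = {
        t: g & universe for t, g in term_map.term_to_genes.items() if g & universe
    }
    counts = np.array([len(g) for g in trimmed.values()])
    med = float(np.median(counts))
    kept = {t: g for t, g in trimmed.items() if len(g) >= med}
    logger.info("filter_terms: median count %.1f; kept %d of %d terms", med, len(kept), len(trimmed))
    return TermMap(kept, {t: term_map.term_name.get(t, "") for t in kept})


def prune_terms(
    term_map: TermMap,
    cut_height: float = 0.5,
    distance: np.ndarray | None = None,
) -> TermMap:
    """Remove redundant terms by Ward clustering of term similarity.

    Pairwise distance defaults to 1 - Jaccard(gene sets); a user-supplied
    square distance matrix (term order = sorted ids) may replace it. The
    Ward tree is cut at ``cut_height``; within each cluster only the term
    with the largest gene count survives (ties: lexicographically
    smallest id).
    """
    terms = sorted(term_map.term_to_genes)
    if len(terms) <= 1:
        return TermMap(dict(term_map.term_to_genes), dict(term_map.term_name))
    if distance is None:
        sets = [term_map.term_to_genes[t] for t in terms]
        n = len(terms)
        distance = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                inter = len(sets[i] & sets[j])
                union = len(sets[i] | sets[j])
                distance[i, j] = distance[j, i] = 1.0 - inter / union
    Z = linkage(squareform(np.asarray(distance, dtype=float), checks=False), method="ward")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    kept: dict[str, set[str]] = {}
    for lab in np.unique(labels):
        members = [terms[i] for i in np.flatnonzero(labels == lab)]
        best = min(members, key=lambda t: (-len(term_map.term_to_genes[t]), t))
        kept[best] = set(term_map.term_to_genes[best])
    logger.info("prune_terms: %d clusters from %d terms at cut %.2f", len(kept), len(terms), cut_height)
    return TermMap(kept, {t: term_map.term_name.get(t, "") for t in kept})


def term_proportion_test(
    term_genes: Iterable[str],
    gene_results: Sequence[GeneIndexResult],
    term_id: str = "",
) -> TermTestResult:
    """One-sided two-sample proportion test of significant-gene fractions.

    Compares the fraction of significant genes inside the term against
    the complement of the term among all scored genes, with a
    pooled-variance z statistic (no continuity correction); p is the
    upper normal tail. Equal proportions give z = 0, p = 0.5.
    """
    term_genes = set(term_genes)
    scored = {r.gene for r in gene_results}
    if not term_genes <= scored:
        raise ValidationError(f"term genes not scored: {sorted(term_genes - scored)[:5]}")
    in_term = [r for r in gene_results if r.gene in term_genes]
    background = [r for r in gene_results if r.gene not in term_genes]
    if not in_term or not background:
        raise ValidationError("both term and background groups must be non-empty")
    n1, n2 = len(in_term), len(background)
    k1 = sum(r.significant for r in in_term)
    k2 = sum(r.significant for r in background)
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    z = 0.0 if var == 0 else (p1 - p2) / np.sqrt(var)
    p = float(stats.norm.sf(z))
    return TermTestResult(term_id, n1, n2, k1, k2, float(z), p)


def term_scan(
    term_map: TermMap,
    gene_results: Sequence[GeneIndexResult],
) -> pd.DataFrame:
    """Proportion test for every term; sorted by ascending p."""
    rows = []
    scored = {r.gene for r in gene_results}
    for term in sorted(term_map.term_to_genes):
        genes = term_map.term_to_genes[term] & scored
        if not genes or len(genes) == len(scored):
            continue
        r = term_proportion_test(genes, gene_results, term_id=term)
        rows.append((term, r.n_term, r.k_term, r.n_background, r.k_background, r.z, r.p))
    df = pd.DataFrame(rows, columns=["term", "n_term", "k_term", "n_background", "k_background", "z", "p"])
    return df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
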