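"""The selective-sweep filter cascade.

Stages, in the order the scan applies them: LD pruning of GWAS SNPs
(greedy p-ranked clumping at r² < 0.1), intersection of upper-tail PBS
outliers across the three population triplets, a GWAS association filter
(P < 5e-3, strict), gene annotation, a top-SNP |nSL| >= 2 locus filter,
and hypergeometric gene-set enrichment with BH correction. Every stage is
a pure function: identical inputs give identical sets, and outputs shrink
monotonically as any threshold tightens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneMap, GenotypeMatrix, GwasRecord, PopulationPanel, TermMap, ValidationError
from .selection_stats import NslResult, PbsResult

logger = logging.getLogger(__name__)

__all__ = [
    "SweepScanConfig",
    "LocusResult",
    "ld_prune",
    "pbs_outlier_intersection",
    "gwas_p_filter",
    "annotate_genes",
    "top_snp_nsl_filter",
    "enrich_genesets",
]


@dataclass
class SweepScanConfig:
    """Constants of the filter cascade."""

    pbs_quantile: float = 0.99
    gwas_p_max: float = 5.0e-3
    nsl_abs_min: float = 2.0
    ld_r2_max: float = 0.1
    clump_window_kb: float = 500.0

    def __post_init__(self) -> None:
        if not (0.0 < self.pbs_quantile < 1.0):
            raise ValidationError("pbs_quantile must be in (0, 1)")
        for name in ("gwas_p_max", "nsl_abs_min", "ld_r2_max", "clump_window_kb"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass
class LocusResult:
    """A locus that passed (or not) the top-SNP nSL filter."""

    locus_id: str
    snps: list[str]
    top_snp: str
    top_nsl: float
    passed: bool
    genes: list[str]


def ld_prune(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    pops: Sequence[str],
    gwas: Mapping[str, GwasRecord],
    r2_max: float = 0.1,
    window_kb: float = 500.0,
) -> list[str]:
    """Greedy p-ranked LD clumping.

    SNPs are visited by ascending GWAS p (ties broken by position); a SNP
    is kept unless its r² — the squared Pearson correlation of haplotype
    indicator vectors over samples of ``pops`` — with an already-kept SNP
    within ``window_kb`` exceeds ``r2_max``. SNPs absent from ``gwas``
    rank last (treated as p = 1, logged).
    """
    rows = np.concatenate([
        gm.haplotype_rows(panel.sample_indices(gm.sample_ids, p)) for p in pops
    ])
    H = gm.haplotypes[np.sort(rows)].astype(float)
    H[H < 0] = np.nan
    n_missing_gwas = sum(1 for v in gm.variant_ids if v not in gwas)
    if n_missing_gwas:
        logger.info("ld_prune: %d SNPs absent from GWAS ranked last (p=1)", n_missing_gwas)
    pvals = np.array([gwas[v].p if v in gwas else 1.0 for v in gm.variant_ids])
    order = np.lexsort((gm.pos, np.asarray(gm.chrom, dtype=str), pvals))
    window = window_kb * 1000.0
    kept: list[int] = []
    for j in order:
        ok = True
        for k in kept:
            if gm.chrom[k] != gm.chrom[j] or abs(int(gm.pos[k]) - int(gm.pos[j])) > window:
                continue
            x, y = H[:, j], H[:, k]
            valid = ~(np.isnan(x) | np.isnan(y))
            xv, yv = x[valid], y[valid]
            if xv.std() == 0 or yv.std() == 0:
                continue
            r = np.corrcoef(xv, yv)[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    kept_ids = [gm.variant_ids[j] for j in sorted(kept)]
    logger.info("ld_prune: kept %d of %d SNPs", len(kept_ids), gm.n_variants)
    return kept_ids


def pbs_outlier_intersection(
    pbs_sets: Sequence[PbsResult],
    q: float = 0.99,
) -> set[str]:
    """SNPs in the upper q-tail of every PBS triplet.

    Per triplet, SNPs with PBS >= the empirical q-quantile (linear
    interpolation) of that triplet's finite values are retained (ties at
    the threshold kept); the intersection over triplets is returned.
    Computed on the SNPs shared by all triplets.
    """
    shared = set(map(str, pbs_sets[0].variant_ids))
    for r in pbs_sets[1:]:
        shared &= set(map(str, r.variant_ids))
    retained: set[str] | None = None
    for r in pbs_sets:
        mask = np.array([str(v) in shared for v in r.variant_ids])
        vals = r.pbs[mask]
        finite = np.isfinite(vals)
        thr = np.quantile(vals[finite], q)
        ids = {str(v) for v, x in zip(r.variant_ids[mask], vals) if np.isfinite(x) and x >= thr}
        retained = ids if retained is None else (retained & ids)
    return retained or set()


def gwas_p_filter(
    ids: Iterable[str],
    gwas: Mapping[str, GwasRecord],
    p_max: float = 5.0e-3,
) -> set[str]:
    """Keep SNPs with association p strictly below ``p_max``.

    SNPs missing from the GWAS table are dropped (count logged).
    """
    ids = list(ids)
    missing = [s for s in ids if s not in gwas]
    if missing:
        logger.info("gwas_p_filter: %d SNPs absent from GWAS dropped", len(missing))
    return {s for s in ids if s in gwas and gwas[s].p < p_max}


def annotate_genes(
    ids: Iterable[str],
    gene_map: GeneMap,
) -> tuple[set[str], dict[str, set[str]]]:
    """Genes with at least one member SNP among ``ids`` (union semantics).

    Returns the deduplicated gene set and a per-gene map of hit SNPs.
    """
    ids = set(ids)
    hits = {
        g: snps & ids for g, snps in gene_map.gene_to_snps.items() if snps & ids
    }
    return set(hits), hits


def top_snp_nsl_filter(
    loci: Mapping[str, Sequence[str]],
    gwas: Mapping[str, GwasRecord],
    nsl: NslResult,
    threshold: float = 2.0,
    gene_map: GeneMap | None = None,
    positions: Mapping[str, int] | None = None,
) -> list[LocusResult]:
    """Retain loci whose top SNP has |standardized nSL| >= threshold.

    The top SNP of a locus is its minimum-GWAS-p member (ties broken by
    smaller physical position when ``positions`` is given, else by id).
    The comparison is inclusive (|z| >= threshold). Loci whose top SNP has
    no standardized score fail the filter.
    """
    if nsl.zscore is None:
        raise ValidationError("nsl scores must be normalized before the locus filter")
    zmap = dict(zip(map(str, nsl.variant_ids), nsl.zscore))
    out: list[LocusResult] = []
    for locus, snps in loci.items():
        snps = list(snps)
        if not snps:
            raise ValidationError(f"locus {locus!r} is empty")

        def rank(s: str):
            p = gwas[s].p if s in gwas else 1.0
            pos = positions.get(s, 0) if positions else 0
            return (p, pos, s)

        top = min(snps, key=rank)
        z = zmap.get(top, np.nan)
        passed = bool(np.isfinite(z) and abs(z) >= threshold)
        genes = sorted(annotate_genes(snps, gene_map)[0]) if gene_map else []
        out.append(LocusResult(locus, snps, top, float(z), passed, genes))
    return out


def enrich_genesets(
    genes: Iterable[str],
    term_map: TermMap,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric gene-set over-representation with BH correction.

    For a term with K genes in the universe (size N) and k hits among the
    n query genes, p is the upper-tail hypergeometric probability
    P(X >= k). Terms with no gene in the universe are not tested.
    """
    genes = set(genes)
    universe = set(universe)
    if not genes <= universe:
        raise ValidationError(f"query genes outside universe: {sorted(genes - universe)[:10]}")
    N, n = len(universe), len(genes)
    rows = []
    for term, tg in sorted(term_map.term_to_genes.items()):
        K = len(tg & universe)
        if K == 0:
            continue
        k = len(tg & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, term_map.term_name.get(term, ""), N, K, n, k, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "name", "N", "K", "n", "k", "p"])
    if len(df):
        df["p_bh"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        df["p_bh"] = []
    return df
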