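"""Per-SNP selection statistics: allele frequencies, Weir–Cockerham Fst,
the population branch statistic (PBS), and the nSL haplotype statistic.

PBS places the allele-frequency divergence of a focal population A against
two references B and C on the A branch of the (A, B, C) tree: each
pairwise Fst is transformed to a divergence time ``T = -ln(1 - Fst)`` and
``PBS_A = (T_AB + T_AC - T_BC) / 2``. Large positive values indicate a
frequency shift specific to A, the classic sweep signal.

nSL compares mean pairwise haplotype-identity tract lengths — counted in
number of segregating sites, which makes the score robust to recombination
-rate variation — between carriers of the ancestral and of the derived
allele at a focal SNP: ``nSL = ln(SL_A / SL_D)``. A strongly negative raw
score means unusually long homozygosity around the derived allele.
Raw scores are standardized within derived-allele-frequency bins; the
conventional outlier rule is |z| >= 2 on the standardized score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .datatypes import GenotypeMatrix, PopulationPanel, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "FstResult",
    "PbsResult",
    "NslPoint",
    "NslResult",
    "allele_frequency",
    "fst_wc",
    "pbs",
    "nsl_raw",
    "nsl_scan",
    "nsl_normalize",
]

#: Fst upper clamp inside the PBS log transform (avoids infinite branches).
FST_CLAMP_MAX = 1.0 - 1e-6


@dataclass
class FstResult:
    """Per-SNP Weir & Cockerham (1984) Fst between two populations.

    ``theta = a / (a + b + c)`` wherever the denominator is nonzero; NaN
    marks SNPs monomorphic in both populations (absent, not zero). The
    raw estimate may be negative; clamping happens only inside PBS.
    """

    variant_ids: np.ndarray
    theta: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    pops: tuple[str, str] = ("A", "B")


@dataclass
class PbsResult:
    """Per-SNP PBS for focal population A of the triplet (A, B, C)."""

    variant_ids: np.ndarray
    pbs: np.ndarray
    t_ab: np.ndarray
    t_ac: np.ndarray
    t_bc: np.ndarray
    triplet: tuple[str, str, str] = ("A", "B", "C")

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.variant_ids, self.pbs))


class NslPoint(NamedTuple):
    """Raw nSL at one focal SNP."""

    raw: float
    sl_a: float
    sl_d: float
    daf: float


@dataclass
class NslResult:
    """Raw and bin-standardized nSL scores for a set of focal SNPs."""

    variant_ids: np.ndarray
    raw: np.ndarray
    sl_a: np.ndarray
    sl_d: np.ndarray
    daf: np.ndarray
    zscore: np.ndarray | None = None
    bin_id: np.ndarray | None = None


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def allele_frequency(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    pop: str,
    allele: str = "alt",
) -> np.ndarray:
    """Per-SNP frequency of the requested allele in one population.

    ``allele`` is ``"ref"``, ``"alt"``, or a per-variant array of A1 bases
    (e.g. GWAS effect alleles), each of which must match the variant's ref
    or alt. Missing haplotype calls are excluded from the denominator;
    SNPs with no non-missing call in the population yield NaN.
    """
    rows = gm.haplotype_rows(panel.sample_indices(gm.sample_ids, pop))
    H = gm.haplotypes[rows]
    valid = H >= 0
    n = valid.sum(axis=0).astype(float)
    alt_count = np.where(valid, H, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n > 0, alt_count / n, np.nan)
    if isinstance(allele, str) and allele in ("ref", "alt"):
        return 1.0 - alt_freq if allele == "ref" else alt_freq
    spec = np.asarray(allele, dtype=object)
    if spec.shape == ():  # a single base applied to every variant
        spec = np.full(gm.n_variants, str(spec), dtype=object)
    out = np.empty(gm.n_variants)
    for j in range(gm.n_variants):
        a = str(spec[j]).upper()
        if a == gm.alt_allele[j]:
            out[j] = alt_freq[j]
        elif a == gm.ref_allele[j]:
            out[j] = 1.0 - alt_freq[j]
        else:
            raise ValidationError(
                f"allele {a!r} matches neither ref ({gm.ref_allele[j]}) nor "
                f"alt ({gm.alt_allele[j]}) at SNP {gm.variant_ids[j]}"
            )
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------

def _pop_genotype_summaries(gm: GenotypeMatrix, panel: PopulationPanel, pop: str):
    """Per-SNP (n usable diploids, alt frequency, observed het proportion)."""
    idx = panel.sample_indices(gm.sample_ids, pop)
    h0 = gm.haplotypes[2 * idx]
    h1 = gm.haplotypes[2 * idx + 1]
    usable = (h0 >= 0) & (h1 >= 0)  # pairwise-complete: both calls present
    n = usable.sum(axis=0).astype(float)
    alt = np.where(usable, h0 + h1, 0).sum(axis=0).astype(float)
    het = (usable & (h0 != h1)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def fst_wc(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    pop_a: str,
    pop_b: str,
) -> FstResult:
    """Per-SNP two-population Weir & Cockerham (1984) Fst estimator.

    Computed from diploid genotype counts; observed heterozygosity enters
    the within-individual component ``c``. Estimates may be negative.
    SNPs monomorphic in both populations, or with fewer than 2 usable
    diploids in either population, yield NaN (counts logged).
    """
    n1, p1, h1 = _pop_genotype_summaries(gm, panel, pop_a)
    n2, p2, h2 = _pop_genotype_summaries(gm, panel, pop_b)
    r = 2.0
    usable = (n1 >= 2) & (n2 >= 2)
    n_small = int((~usable).sum())
    if n_small:
        logger.info("fst_wc(%s,%s): %d SNPs with <2 usable diploids set to NaN", pop_a, pop_b, n_small)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    mono = usable & (denom == 0)
    theta = np.where(usable, theta, np.nan)
    for arr in (a, b, c):
        arr[~usable] = np.nan
    if mono.any():
        logger.info("fst_wc(%s,%s): %d SNPs monomorphic in both populations", pop_a, pop_b, int(mono.sum()))
    return FstResult(gm.variant_ids.copy(), theta, a, b, c, (pop_a, pop_b))


def pbs(fst_ab: FstResult, fst_ac: FstResult, fst_bc: FstResult) -> PbsResult:
    """PBS of focal population A from the three pairwise Fst results.

    Each Fst is clamped to [0, 1 - 1e-6] before ``T = -ln(1 - Fst)``;
    ``PBS = (T_AB + T_AC - T_BC) / 2``. NaN Fst propagates to NaN PBS.
    """
    ids = fst_ab.variant_ids
    for other in (fst_ac, fst_bc):
        if len(other.variant_ids) != len(ids) or not np.array_equal(other.variant_ids, ids):
            sym = set(map(str, ids)) ^ set(map(str, other.variant_ids))
            raise ValidationError(f"variant sets misaligned; symmetric difference: {sorted(sym)[:10]}")

    def t_of(f: np.ndarray) -> np.ndarray:
        clamped = np.clip(f, 0.0, FST_CLAMP_MAX)
        with np.errstate(invalid="ignore"):
            return -np.log1p(-clamped)

    t_ab, t_ac, t_bc = t_of(fst_ab.theta), t_of(fst_ac.theta), t_of(fst_bc.theta)
    values = (t_ab + t_ac - t_bc) / 2.0
    a = fst_ab.pops[0]
    triplet = (a, fst_ab.pops[1], fst_ac.pops[1])
    return PbsResult(ids.copy(), values, t_ab, t_ac, t_bc, triplet)


# ---------------------------------------------------------------------------
# nSL
# ---------------------------------------------------------------------------

def _mean_pairwise_tract(H: np.ndarray, focal: int, max_extend: int) -> float:
    """Mean pairwise identity-tract length (in sites, incl. focal) within
    one carrier class. Tracts are truncated at the data edge and at
    ``max_extend`` sites each side of the focal SNP."""
    c = H.shape[0]
    right = H[:, focal : focal + max_extend + 1]
    left = H[:, max(0, focal - max_extend) : focal + 1][:, ::-1]
    iu = np.triu_indices(c, 1)
    total = np.zeros(len(iu[0]))
    for side in (right, left):
        eq = side[iu[0]] == side[iu[1]]
        total += np.cumprod(eq, axis=1).sum(axis=1)
    return float(total.mean()) - 1.0  # focal site counted on both sides


def _derived_indicator(gm: GenotypeMatrix, focal: int) -> np.ndarray | None:
    """Haplotype indicator of the derived allele at ``focal`` (1=derived),
    or None when the ancestral annotation is missing/mismatched."""
    if gm.ancestral_allele is None:
        return None
    aa = str(gm.ancestral_allele[focal]).upper()
    if aa == gm.ref_allele[focal]:
        return gm.haplotypes[:, focal].astype(np.int8)
    if aa == gm.alt_allele[focal]:
        return (1 - gm.haplotypes[:, focal]).astype(np.int8)
    return None


def nsl_raw(
    gm: GenotypeMatrix,
    focal: int,
    maf_min: float = 0.05,
    max_extend: int = 100,
) -> NslPoint | None:
    """Unstandardized nSL at one focal SNP.

    Returns None (with a logged reason) when the focal SNP lacks a usable
    ancestral annotation, its derived-allele frequency lies outside
    ``[maf_min, 1 - maf_min]``, or either carrier class has < 2 members.
    Requires a complete haplotype matrix (drop missing columns first).
    """
    if (gm.haplotypes == -1).any():
        raise ValidationError("nsl_raw requires a matrix without missing calls (use drop_missing)")
    d = _derived_indicator(gm, focal)
    if d is None:
        logger.info("nsl_raw: SNP %s skipped (no usable ancestral annotation)", gm.variant_ids[focal])
        return None
    daf = float(d.mean())
    if not (maf_min <= daf <= 1.0 - maf_min):
        logger.info("nsl_raw: SNP %s skipped (daf=%.3f outside band)", gm.variant_ids[focal], daf)
        return None
    anc_rows = np.flatnonzero(d == 0)
    der_rows = np.flatnonzero(d == 1)
    if len(anc_rows) < 2 or len(der_rows) < 2:
        logger.info("nsl_raw: SNP %s skipped (carrier class < 2)", gm.variant_ids[focal])
        return None
    sl_a = _mean_pairwise_tract(gm.haplotypes[anc_rows], focal, max_extend)
    sl_d = _mean_pairwise_tract(gm.haplotypes[der_rows], focal, max_extend)
    return NslPoint(raw=float(np.log(sl_a / sl_d)), sl_a=sl_a, sl_d=sl_d, daf=daf)


def nsl_scan(
    gm: GenotypeMatrix,
    foci: Sequence[int] | None = None,
    maf_min: float = 0.05,
    max_extend: int = 100,
) -> NslResult:
    """Raw nSL over many focal SNPs of one complete haplotype matrix."""
    if foci is None:
        foci = range(gm.n_variants)
    ids, raws, slas, slds, dafs = [], [], [], [], []
    for j in foci:
        pt = nsl_raw(gm, int(j), maf_min=maf_min, max_extend=max_extend)
        if pt is None:
            continue
        ids.append(gm.variant_ids[j])
        raws.append(pt.raw)
        slas.append(pt.sl_a)
        slds.append(pt.sl_d)
        dafs.append(pt.daf)
    return NslResult(
        np.array(ids, dtype=object), np.array(raws), np.array(slas),
        np.array(slds), np.array(dafs),
    )


def combine_nsl(results: Sequence[NslResult]) -> NslResult:
    """Concatenate per-region scans before genome-wide normalization."""
    return NslResult(
        np.concatenate([r.variant_ids for r in results]),
        np.concatenate([r.raw for r in results]),
        np.concatenate([r.sl_a for r in results]),
        np.concatenate([r.sl_d for r in results]),
        np.concatenate([r.daf for r in results]),
    )


def nsl_normalize(result: NslResult, n_bins: int = 20) -> NslResult:
    """Standardize raw nSL within equal-width derived-allele-frequency bins.

    Bin of a score is ``floor(daf * n_bins)`` on (0, 1); within each bin
    ``z = (raw - bin mean) / bin sd`` (population sd). Bins with fewer
    than 2 scores yield NaN z-scores.
    """
    bins = np.minimum((result.daf * n_bins).astype(np.int64), n_bins - 1)
    z = np.full_like(result.raw, np.nan)
    for b in np.unique(bins):
        mask = bins == b
        if mask.sum() < 2:
            continue
        mu = result.raw[mask].mean()
        sd = result.raw[mask].std()
        if sd == 0:
            continue
        z[mask] = (result.raw[mask] - mu) / sd
    return NslResult(result.variant_ids, result.raw, result.sl_a, result.sl_d,
                     result.daf, zscore=z, bin_id=bins)
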