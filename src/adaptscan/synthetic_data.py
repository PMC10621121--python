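"""Synthetic inputs with the statistical structure the pipeline assumes.

Each generator produces data with a known ground truth so every downstream
stage can be tested end-to-end without external downloads:

* Balding–Nichols allele-frequency divergence across populations, with
  optional directional "spikes" in a focal population (truth for PBS and
  the polygenic selection index);
* a founder-copying haplotype mosaic with an inserted high-frequency core
  haplotype (truth for the nSL sweep statistic);
* gene architectures whose SNP-count distribution has mode 11, plus
  annotation terms with one planted selected term;
* allele frequencies correlated with an environmental variable under a
  population covariance model (truth for the Bayes-factor scan);
* exposure/outcome instrument tables with a known causal effect and
  optional directional pleiotropy (truth for Mendelian randomization).

All generators are bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import GeneMap, GenotypeMatrix, GwasRecord, PopulationPanel, TermMap, ValidationError

__all__ = [
    "SimulationConfig",
    "SweepConfig",
    "MrSimConfig",
    "simulate_frequency_table",
    "spike_selection",
    "simulate_genotypes",
    "simulate_sweep_region",
    "simulate_gene_architecture",
    "simulate_env_correlated_freqs",
    "simulate_mr_instruments",
]


@dataclass
class SimulationConfig:
    """Balding–Nichols divergence model for several populations.

    Each population's alternate-allele frequency at a SNP is drawn
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around an ancestral frequency ``p``,
    so ``E[p_pop] = p`` and ``Var[p_pop] = F p (1-p)`` — the drift
    parameter ``F`` plays the role of Fst between each population and the
    ancestral pool.
    """

    n_snps: int = 1000
    n_pops: int = 4
    drift: float | tuple[float, ...] = 0.05
    sample_sizes: int | tuple[int, ...] = 100
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        F = np.broadcast_to(np.asarray(self.drift, dtype=float), (self.n_pops,))
        if np.any(F <= 0) or np.any(F >= 1):
            raise ValidationError("drift F must lie in (0, 1)")
        n = np.broadcast_to(np.asarray(self.sample_sizes, dtype=int), (self.n_pops,))
        if np.any(n < 2):
            raise ValidationError("sample sizes must be >= 2 diploids")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("ancestral_freq_range must be within (0, 1)")

    @property
    def drift_per_pop(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.drift, dtype=float), (self.n_pops,)).copy()

    @property
    def sizes_per_pop(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.sample_sizes, dtype=int), (self.n_pops,)).copy()


@dataclass
class SweepConfig:
    """A sweep-bearing haplotype block over a neutral copying background."""

    n_haplotypes: int = 200
    n_sites: int = 201
    core_freq: float = 0.6
    core_span: int = 101
    mutation_rate: float = 0.01
    founder_count: int = 20
    switch_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_freq * self.n_haplotypes < 2:
            raise ValidationError("core must be carried by at least 2 haplotypes")
        if self.core_span > self.n_sites:
            raise ValidationError("core_span cannot exceed n_sites")


@dataclass
class MrSimConfig:
    """Two-sample MR instrument generator with a known causal effect."""

    n_instruments: int = 50
    causal_beta: float = 0.2
    pleiotropy_alpha: float = 0.0
    beta_x_range: tuple[float, float] = (0.05, 0.3)
    se_x: float = 0.01
    se_y: float = 0.05
    flip_fraction: float = 0.0
    palindromic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instruments < 3:
            raise ValidationError("need at least 3 instruments")
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValidationError("se scales must be > 0")


# ---------------------------------------------------------------------------
# allele-frequency divergence
# ---------------------------------------------------------------------------

def simulate_frequency_table(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-population alternate-allele frequencies.

    Returns ``(freqs, p_anc)`` with ``freqs`` of shape (n_pops, n_snps).
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_snps)
    F = cfg.drift_per_pop
    a = p_anc[None, :] * (1.0 - F[:, None]) / F[:, None]
    b = (1.0 - p_anc[None, :]) * (1.0 - F[:, None]) / F[:, None]
    freqs = rng.beta(a, b)
    return freqs, p_anc


def spike_selection(
    freqs: np.ndarray,
    snp_indices: np.ndarray,
    target_pop: int,
    shift: float,
) -> np.ndarray:
    """Shift the named SNPs in one population by ``shift``, clipped to [0.01, 0.99].

    Models a directional allele-frequency change (the ground truth for
    PBS outlier and selection-index power tests). All other entries are
    returned unchanged.
    """
    out = np.array(freqs, dtype=float, copy=True)
    idx = np.asarray(snp_indices, dtype=np.int64)
    out[target_pop, idx] = np.clip(out[target_pop, idx] + shift, 0.01, 0.99)
    return out


def simulate_genotypes(
    freqs: np.ndarray,
    sample_sizes: int | np.ndarray,
    seed: int = 0,
    chrom: str = "1",
    pos_step: int = 1000,
) -> tuple[GenotypeMatrix, PopulationPanel]:
    """Draw phased Bernoulli haplotypes from population frequencies.

    Populations are labelled POP0..POPk; sample ids SAMPLE0000... run in
    population order. Variant positions are ``pos_step`` apart on one
    chromosome; REF='A', ALT='G', ancestral='A' (so the derived allele is
    the alternate).
    """
    freqs = np.asarray(freqs, dtype=float)
    n_pops, n_snps = freqs.shape
    sizes = np.broadcast_to(np.asarray(sample_sizes, dtype=int), (n_pops,))
    rng = np.random.default_rng(seed)
    blocks, sample_ids, sample_to_pop = [], [], {}
    for k in range(n_pops):
        hap = (rng.random((2 * sizes[k], n_snps)) < freqs[k]).astype(np.int8)
        blocks.append(hap)
        for i in range(sizes[k]):
            sid = f"SAMPLE{len(sample_ids):04d}"
            sample_ids.append(sid)
            sample_to_pop[sid] = f"POP{k}"
    gm = GenotypeMatrix(
        variant_ids=np.array([f"snp{j}" for j in range(n_snps)], dtype=object),
        chrom=np.array([chrom] * n_snps, dtype=object),
        pos=np.arange(1, n_snps + 1, dtype=np.int64) * pos_step,
        ref_allele=np.array(["A"] * n_snps, dtype=object),
        alt_allele=np.array(["G"] * n_snps, dtype=object),
        haplotypes=np.vstack(blocks),
        sample_ids=np.array(sample_ids, dtype=object),
        ancestral_allele=np.array(["A"] * n_snps, dtype=object),
        phased=True,
    )
    panel = PopulationPanel(sample_to_pop, {f"POP{k}": "SIM" for k in range(n_pops)})
    return gm, panel


# ---------------------------------------------------------------------------
# sweep haplotypes
# ---------------------------------------------------------------------------

def _copying_mosaic(rng: np.random.Generator, n_hap: int, n_sites: int,
                    founder_count: int, switch_rate: float) -> np.ndarray:
    """Neutral background: each haplotype copies one of ``founder_count``
    founder haplotypes, re-choosing its template with probability
    ``switch_rate`` at each site (a Li–Stephens-style mosaic)."""
    founders = (rng.random((founder_count, n_sites)) < 0.5).astype(np.int8)
    choice = np.empty((n_hap, n_sites), dtype=np.int64)
    choice[:, 0] = rng.integers(0, founder_count, size=n_hap)
    switches = rng.random((n_hap, n_sites)) < switch_rate
    new = rng.integers(0, founder_count, size=(n_hap, n_sites))
    for s in range(1, n_sites):
        choice[:, s] = np.where(switches[:, s], new[:, s], choice[:, s - 1])
    return founders[choice, np.arange(n_sites)[None, :]]


def simulate_sweep_region(cfg: SweepConfig) -> tuple[np.ndarray, int, np.ndarray]:
    """Build a haplotype block carrying a partial sweep.

    Returns ``(haplotypes, focal_site, is_core)``: a (n_haplotypes,
    n_sites) 0/1 matrix (0 = ancestral), the focal site index, and a
    boolean core-membership vector. A fraction ``core_freq`` of rows are
    copies of one core haplotype across ``core_span`` sites centred on the
    focal site, each copy perturbed by private mutations at
    ``mutation_rate`` per site; the focal site's derived allele is carried
    by exactly the core rows.
    """
    rng = np.random.default_rng(cfg.seed)
    H = _copying_mosaic(rng, cfg.n_haplotypes, cfg.n_sites, cfg.founder_count, cfg.switch_rate)
    focal = cfg.n_sites // 2
    half = (cfg.core_span - 1) // 2
    lo = max(0, focal - half)
    hi = min(cfg.n_sites, lo + cfg.core_span)
    n_core = int(round(cfg.core_freq * cfg.n_haplotypes))
    core_rows = rng.choice(cfg.n_haplotypes, size=n_core, replace=False)
    is_core = np.zeros(cfg.n_haplotypes, dtype=bool)
    is_core[core_rows] = True

    core_hap = (rng.random(hi - lo) < 0.5).astype(np.int8)
    block = np.tile(core_hap, (n_core, 1))
    muts = rng.random(block.shape) < cfg.mutation_rate
    block = np.where(muts, 1 - block, block).astype(np.int8)
    H[core_rows, lo:hi] = block
    # focal column defines the swept (derived) allele: core rows exactly
    H[:, focal] = 0
    H[core_rows, focal] = 1
    return H, focal, is_core


def sweep_region_matrix(
    cfg: SweepConfig, chrom: str = "1", pos_offset: int = 0, id_prefix: str = "sw",
) -> tuple[GenotypeMatrix, int, np.ndarray]:
    """Wrap :func:`simulate_sweep_region` output as a GenotypeMatrix
    (one diploid sample per two haplotypes, ancestral = REF)."""
    H, focal, is_core = simulate_sweep_region(cfg)
    n_hap, n_sites = H.shape
    n_samples = n_hap // 2
    H = H[: 2 * n_samples]
    gm = GenotypeMatrix(
        variant_ids=np.array([f"{id_prefix}_{j}" for j in range(n_sites)], dtype=object),
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=pos_offset + np.arange(1, n_sites + 1, dtype=np.int64) * 100,
        ref_allele=np.array(["A"] * n_sites, dtype=object),
        alt_allele=np.array(["G"] * n_sites, dtype=object),
        haplotypes=H.astype(np.int8),
        sample_ids=np.array([f"{id_prefix}_s{i}" for i in range(n_samples)], dtype=object),
        ancestral_allele=np.array(["A"] * n_sites, dtype=object),
        phased=True,
    )
    return gm, focal, is_core[: 2 * n_samples]


# ---------------------------------------------------------------------------
# gene architecture
# ---------------------------------------------------------------------------

def simulate_gene_architecture(
    n_genes: int = 4000,
    n_terms: int = 50,
    planted_term_size: int = 20,
    mean_term_size: int = 25,
    seed: int = 0,
) -> tuple[GeneMap, TermMap, dict]:
    """Genes with a skewed SNP-count distribution (mode 11) plus terms.

    Gene sizes are drawn as ``1 + NegBin(r=6, p=1/3)`` — a shifted
    negative binomial whose mode is 11 and mean 13, emulating the skewed
    SNP-per-gene distribution of a GWAS annotation. Terms draw genes at
    random; term ``TERM_PLANTED`` is the designated selected term whose
    member genes are flagged for frequency spiking.

    Returns (gene_map, term_map, truth) where truth carries
    ``planted_term``, ``planted_genes`` and ``gene_order``.
    """
    rng = np.random.default_rng(seed)
    sizes = 1 + rng.negative_binomial(6, 1.0 / 3.0, size=n_genes)
    genes = [f"GENE{g:05d}" for g in range(n_genes)]
    gene_to_snps: dict[str, set[str]] = {}
    snp_counter = 0
    for g, k in zip(genes, sizes):
        gene_to_snps[g] = {f"rs{snp_counter + j}" for j in range(int(k))}
        snp_counter += int(k)
    planted = sorted(rng.choice(genes, size=planted_term_size, replace=False))
    term_to_genes: dict[str, set[str]] = {"TERM_PLANTED": set(planted)}
    for t in range(n_terms - 1):
        k = max(2, int(rng.poisson(mean_term_size)))
        term_to_genes[f"TERM{t:04d}"] = set(rng.choice(genes, size=min(k, n_genes), replace=False))
    truth = {"planted_term": "TERM_PLANTED", "planted_genes": set(planted), "gene_order": genes}
    names = {t: t.lower().replace("_", " ") for t in term_to_genes}
    return GeneMap(gene_to_snps), TermMap(term_to_genes, names), truth


# ---------------------------------------------------------------------------
# environment-correlated frequencies
# ---------------------------------------------------------------------------

def simulate_env_correlated_freqs(
    omega: np.ndarray,
    env: np.ndarray,
    beta_true: float,
    n_signal: int,
    n_null: int,
    seed: int = 0,
    anc_range: tuple[float, float] = (0.2, 0.8),
) -> tuple[np.ndarray, np.ndarray]:
    """Frequencies whose standardized form follows MVN(beta·env, omega).

    ``env`` is z-standardized internally. Signal SNPs (the first
    ``n_signal`` columns) get mean ``beta_true * env_std``; null SNPs mean
    zero. Standardized draws are mapped back through
    ``p = p_anc + y * sqrt(p_anc (1 - p_anc))`` and clipped to (0, 1).

    Returns ``(freqs, is_signal)`` with freqs of shape (L, n_signal + n_null).
    """
    rng = np.random.default_rng(seed)
    omega = np.asarray(omega, dtype=float)
    L = omega.shape[0]
    e = np.asarray(env, dtype=float)
    e = (e - e.mean()) / e.std()
    m = n_signal + n_null
    chol = np.linalg.cholesky(omega)
    y = chol @ rng.standard_normal((L, m))
    y[:, :n_signal] += beta_true * e[:, None]
    p_anc = rng.uniform(*anc_range, size=m)
    freqs = p_anc[None, :] + y * np.sqrt(p_anc * (1.0 - p_anc))[None, :]
    freqs = np.clip(freqs, 1e-3, 1.0 - 1e-3)
    is_signal = np.zeros(m, dtype=bool)
    is_signal[:n_signal] = True
    return freqs, is_signal


# ---------------------------------------------------------------------------
# MR instruments
# ---------------------------------------------------------------------------

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


def simulate_mr_instruments(
    cfg: MrSimConfig,
) -> tuple[list[GwasRecord], list[GwasRecord], dict]:
    """Exposure and outcome summary-statistic tables with known causal effect.

    ``beta_y = pleiotropy_alpha + causal_beta * beta_x + N(0, se_y)``;
    reported standard errors equal the generating scales. A fraction
    ``flip_fraction`` of outcome rows has its alleles swapped (beta
    negated) to exercise harmonization; ``palindromic_fraction`` of rows
    get A/T alleles (which harmonization must drop).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_instruments
    beta_x = rng.uniform(*cfg.beta_x_range, size=n)
    beta_x_obs = beta_x + rng.normal(0.0, cfg.se_x, size=n)
    beta_y = cfg.pleiotropy_alpha + cfg.causal_beta * beta_x + rng.normal(0.0, cfg.se_y, size=n)

    from scipy import stats

    def p_of(b, se):
        return float(np.clip(2.0 * stats.norm.sf(abs(b) / se), 1e-300, 1.0))

    flip = rng.random(n) < cfg.flip_fraction
    palin = rng.random(n) < cfg.palindromic_fraction
    exposure, outcome = [], []
    for j in range(n):
        a1, a2 = ("A", "T") if palin[j] else _NONPALINDROMIC[int(rng.integers(0, 4))]
        rsid = f"iv{j}"
        exposure.append(GwasRecord(rsid, a1, a2, float(beta_x_obs[j]), cfg.se_x, p_of(beta_x_obs[j], cfg.se_x)))
        if flip[j]:
            outcome.append(GwasRecord(rsid, a2, a1, float(-beta_y[j]), cfg.se_y, p_of(beta_y[j], cfg.se_y)))
        else:
            outcome.append(GwasRecord(rsid, a1, a2, float(beta_y[j]), cfg.se_y, p_of(beta_y[j], cfg.se_y)))
    truth = {
        "causal_beta": cfg.causal_beta,
        "pleiotropy_alpha": cfg.pleiotropy_alpha,
        "beta_x_true": beta_x,
        "flipped": flip,
        "palindromic": palin,
    }
    return exposure, outcome, truth
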