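"""Synthetic evaluation experiments for the pipeline.

Each function runs one study design end-to-end on generated data with
known ground truth and returns summary metrics: null calibration of the
selection index, power against planted polygenic and sweep signals,
specificity of the PBS outlier cascade, MR interval coverage and
pleiotropy-test size, and Bayes-factor separation of environment-
correlated SNPs. The same entry points back the test suite and the
acceptance script, so reported numbers always come from a fresh run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import gene_env, mendelian_randomization as mr, polygenic_scan, selection_stats, sweep_scan
from .datatypes import GwasRecord
from .synthetic_data import (
    MrSimConfig,
    SimulationConfig,
    SweepConfig,
    simulate_env_correlated_freqs,
    simulate_frequency_table,
    simulate_gene_architecture,
    simulate_genotypes,
    simulate_mr_instruments,
    simulate_sweep_region,
    spike_selection,
)

__all__ = [
    "simulate_pbs_values",
    "polygenic_null_run",
    "polygenic_power_run",
    "sweep_cascade_run",
    "sweep_nsl_power_run",
    "mr_coverage",
    "egger_type1_error",
    "env_bf_separation",
]


def simulate_pbs_values(
    n_snps: int,
    seed: int,
    drift: float = 0.05,
    diploids: int = 100,
) -> np.ndarray:
    """Null per-SNP PBS for a three-population Balding–Nichols design.

    Simulates genotypes for a focal population A and references B, C with
    equal drift, runs the Weir–Cockerham/PBS path of the package, and
    returns the finite PBS vector (one value per SNP).
    """
    cfg = SimulationConfig(n_snps=n_snps, n_pops=3, drift=drift,
                           sample_sizes=diploids, seed=seed)
    freqs, _ = simulate_frequency_table(cfg)
    gm, panel = simulate_genotypes(freqs, diploids, seed=seed + 1)
    f_ab = selection_stats.fst_wc(gm, panel, "POP0", "POP1")
    f_ac = selection_stats.fst_wc(gm, panel, "POP0", "POP2")
    f_bc = selection_stats.fst_wc(gm, panel, "POP1", "POP2")
    return selection_stats.pbs(f_ab, f_ac, f_bc).pbs


@dataclass
class PolygenicRun:
    frac_significant: float
    bin_indices: np.ndarray
    ks_p: float
    size_slope: float
    size_r2_adj: float
    size_p: float
    sensitivity: float = np.nan
    planted_term_rank: int = -1
    gene_results: list = field(default_factory=list)


def _polygenic_run(
    n_genes: int,
    n_perm: int,
    seed: int,
    spike_sd: float = 0.0,
) -> PolygenicRun:
    gene_map, term_map, truth = simulate_gene_architecture(n_genes=n_genes, seed=seed)
    sizes = gene_map.sizes()
    n_snps = sum(sizes.values())
    pbs_vals = simulate_pbs_values(n_snps, seed=seed + 1)
    snp_ids = [f"rs{j}" for j in range(n_snps)]
    pbs_map = dict(zip(snp_ids, pbs_vals))
    if spike_sd:
        shift = spike_sd * float(np.nanstd(pbs_vals))
        for g in truth["planted_genes"]:
            for s in gene_map.gene_to_snps[g]:
                pbs_map[s] = pbs_map[s] + shift
    positions = {s: j for j, s in enumerate(snp_ids)}
    bins = polygenic_scan.make_bins(gene_map, positions)
    pool = np.array([v for v in pbs_map.values() if np.isfinite(v)])
    bin_results = polygenic_scan.selection_index(bins, pbs_map, pool, n_perm=n_perm, seed=seed + 2)
    gene_results = polygenic_scan.gene_index(bin_results)
    frac = float(np.mean([g.significant for g in gene_results]))
    idx = np.array([r.index for r in bin_results])
    ks_p = float(stats.kstest(idx, "uniform").pvalue)
    slope, r2, p = polygenic_scan.check_size_bias(gene_results, sizes)
    run = PolygenicRun(frac, idx, ks_p, slope, r2, p, gene_results=gene_results)
    if spike_sd:
        planted = truth["planted_genes"]
        flagged = {g.gene for g in gene_results if g.significant}
        run.sensitivity = len(planted & flagged) / len(planted)
        table = polygenic_scan.term_scan(term_map, gene_results)
        ranks = table.index[table["term"] == truth["planted_term"]]
        run.planted_term_rank = int(ranks[0]) if len(ranks) else -1
    return run


def polygenic_null_run(n_genes: int = 4000, n_perm: int = 5000, seed: int = 0) -> PolygenicRun:
    """Calibration run with no planted selection."""
    return _polygenic_run(n_genes, n_perm, seed, spike_sd=0.0)


def polygenic_power_run(n_genes: int = 4000, n_perm: int = 5000, seed: int = 0,
                        spike_sd: float = 2.0) -> PolygenicRun:
    """Power run: the planted term's genes get PBS shifted by
    ``spike_sd`` pooled standard deviations."""
    return _polygenic_run(n_genes, n_perm, seed, spike_sd=spike_sd)


# ---------------------------------------------------------------------------
# sweep cascade (PBS outlier intersection + GWAS filter + genes)
# ---------------------------------------------------------------------------

@dataclass
class CascadeRun:
    snp_sensitivity: float
    snp_specificity: float
    gene_sensitivity: float
    gene_fp_rate: float


def sweep_cascade_run(
    n_snps: int = 4000,
    n_spiked: int = 20,
    shift: float = 0.5,
    seed: int = 0,
    snps_per_gene: int = 5,
    q: float = 0.99,
    gwas_p_max: float = 5.0e-3,
) -> CascadeRun:
    """PBS-outlier filter cascade against planted frequency shifts.

    Five populations (focal A, references B1-B3, outgroup C); the first
    ``n_spiked`` SNPs are shifted by ``shift`` in A only. The cascade —
    upper-tail PBS intersection over the three (A, Bi, C) triplets, then
    the strict GWAS-P filter, then gene annotation — is scored against
    the planted truth at SNP and gene level.
    """
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(n_snps=n_snps, n_pops=5, drift=0.02, sample_sizes=60, seed=seed)
    freqs, p_anc = simulate_frequency_table(cfg)
    # plant the shift on alleles with headroom: a sweep already near
    # fixation in every population is undetectable by construction
    candidates = np.flatnonzero(p_anc <= 1.0 - shift - 0.1)
    spiked_idx = candidates[:n_spiked]
    freqs = spike_selection(freqs, spiked_idx, target_pop=0, shift=shift)
    gm, panel = simulate_genotypes(freqs, 60, seed=seed + 1)
    triplets = [("POP0", f"POP{b}", "POP4") for b in (1, 2, 3)]
    pbs_sets = []
    for a, b, c in triplets:
        f_ab = selection_stats.fst_wc(gm, panel, a, b)
        f_ac = selection_stats.fst_wc(gm, panel, a, c)
        f_bc = selection_stats.fst_wc(gm, panel, b, c)
        pbs_sets.append(selection_stats.pbs(f_ab, f_ac, f_bc))
    outliers = sweep_scan.pbs_outlier_intersection(pbs_sets, q=q)

    # GWAS: planted SNPs strongly associated, null SNPs uniform p
    spiked_set = set(spiked_idx.tolist())
    gwas = {}
    for j, v in enumerate(gm.variant_ids):
        p = float(rng.uniform(1e-6, 1e-4)) if j in spiked_set else float(rng.uniform(0.0001, 1.0))
        gwas[str(v)] = GwasRecord(str(v), "G", "A", -0.01, 0.005, p)
    passed = sweep_scan.gwas_p_filter(outliers, gwas, p_max=gwas_p_max)

    from .datatypes import GeneMap
    gene_to_snps = {
        f"G{k:04d}": {f"snp{j}" for j in range(k * snps_per_gene, (k + 1) * snps_per_gene)}
        for k in range(n_snps // snps_per_gene)
    }
    gene_map = GeneMap(gene_to_snps)
    genes, _ = sweep_scan.annotate_genes(passed, gene_map)

    spiked_ids = {f"snp{j}" for j in spiked_idx}
    true_genes = {g for g, s in gene_to_snps.items() if s & spiked_ids}
    null_genes = set(gene_to_snps) - true_genes
    snp_tp = len(passed & spiked_ids)
    snp_fp = len(passed - spiked_ids)
    return CascadeRun(
        snp_sensitivity=snp_tp / n_spiked,
        snp_specificity=1.0 - snp_fp / (n_snps - n_spiked),
        gene_sensitivity=len(genes & true_genes) / len(true_genes),
        gene_fp_rate=len(genes & null_genes) / len(null_genes),
    )


# ---------------------------------------------------------------------------
# nSL locus filter power
# ---------------------------------------------------------------------------

@dataclass
class NslPowerRun:
    sensitivity: float
    false_positive_rate: float


def sweep_nsl_power_run(
    n_sweep: int = 10,
    n_neutral: int = 200,
    seed: int = 0,
    core_freq_range: tuple[float, float] = (0.25, 0.85),
    n_haplotypes: int = 200,
    threshold: float = 2.0,
    n_bins: int = 10,
) -> NslPowerRun:
    """Top-SNP |nSL| locus filter against planted sweeps.

    Each locus is one simulated haplotype region; sweep loci carry a core
    haplotype at a frequency drawn from ``core_freq_range``, neutral loci
    are pure copying mosaics. Focal-site raw nSL scores are standardized
    jointly in derived-allele-frequency bins — sweeps must stay a small
    minority of every bin, as in a genome-wide scan, or they would set
    their own bin's mean and variance. A locus passes when the |z| of its
    top SNP (its focal site, which carries the planted GWAS association)
    meets ``threshold``.
    """
    from .synthetic_data import sweep_region_matrix

    results = []
    truth = []
    focal_ids = []
    rng = np.random.default_rng(seed)
    for i in range(n_sweep + n_neutral):
        is_sweep = i < n_sweep
        cfg = SweepConfig(
            n_haplotypes=n_haplotypes,
            core_freq=float(rng.uniform(*core_freq_range)) if is_sweep else 2.0 / n_haplotypes,
            core_span=101 if is_sweep else 1,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        gm, focal, _ = sweep_region_matrix(cfg, id_prefix=f"L{i}")
        if not is_sweep:
            # neutral locus: focal alleles independent of haplotype background
            gm.haplotypes[:, focal] = _neutral_focal_column(cfg, gm.n_haplotypes)
        pt = selection_stats.nsl_raw(gm, focal, maf_min=0.05, max_extend=100)
        if pt is None:
            continue
        results.append(selection_stats.NslResult(
            np.array([gm.variant_ids[focal]], dtype=object),
            np.array([pt.raw]), np.array([pt.sl_a]), np.array([pt.sl_d]), np.array([pt.daf]),
        ))
        truth.append(is_sweep)
        focal_ids.append(str(gm.variant_ids[focal]))
    combined = selection_stats.combine_nsl(results)
    normalized = selection_stats.nsl_normalize(combined, n_bins=n_bins)
    loci = {f"locus{i}": [fid] for i, fid in enumerate(focal_ids)}
    gwas = {fid: GwasRecord(fid, "G", "A", -0.02, 0.005, 1e-8) for fid in focal_ids}
    out = sweep_scan.top_snp_nsl_filter(loci, gwas, normalized, threshold=threshold)
    passed = {r.locus_id for r in out if r.passed}
    sweep_loci = {f"locus{i}" for i, t in enumerate(truth) if t}
    neutral_loci = {f"locus{i}" for i, t in enumerate(truth) if not t}
    sens = len(passed & sweep_loci) / len(sweep_loci) if sweep_loci else np.nan
    fpr = len(passed & neutral_loci) / len(neutral_loci) if neutral_loci else np.nan
    return NslPowerRun(sens, fpr)


def _neutral_focal_column(cfg: SweepConfig, n_hap: int) -> np.ndarray:
    """A focal-site column with intermediate derived-allele frequency but
    no haplotype structure (alleles shuffled independently of rows)."""
    rng = np.random.default_rng(cfg.seed + 7)
    daf = rng.uniform(0.15, 0.85)
    col = (rng.random(n_hap) < daf).astype(np.int8)
    if col.sum() < 2 or col.sum() > n_hap - 2:
        col[:] = 0
        col[: n_hap // 2] = 1
    return col


# ---------------------------------------------------------------------------
# Mendelian randomization operating characteristics
# ---------------------------------------------------------------------------

def mr_coverage(n_reps: int = 500, seed: int = 0, causal_beta: float = 0.2,
                n_instruments: int = 50) -> float:
    """Fraction of replicates whose IVW 95% interval covers the truth."""
    hits = 0
    for r in range(n_reps):
        cfg = MrSimConfig(n_instruments=n_instruments, causal_beta=causal_beta, seed=seed + r)
        exposure, outcome, _ = simulate_mr_instruments(cfg)
        est = mr.mr_ivw(mr.harmonize(exposure, outcome))
        lo, hi = est.ci95
        hits += lo <= causal_beta <= hi
    return hits / n_reps


def egger_type1_error(n_reps: int = 500, seed: int = 0, n_instruments: int = 50,
                      alpha: float = 0.05) -> float:
    """Rejection rate of the Egger intercept test with no pleiotropy."""
    rejections = 0
    for r in range(n_reps):
        cfg = MrSimConfig(n_instruments=n_instruments, causal_beta=0.2,
                          pleiotropy_alpha=0.0, seed=seed + r)
        exposure, outcome, _ = simulate_mr_instruments(cfg)
        _, icept = mr.mr_egger(mr.harmonize(exposure, outcome))
        rejections += icept.p < alpha
    return rejections / n_reps


# ---------------------------------------------------------------------------
# gene-environment Bayes factors
# ---------------------------------------------------------------------------

def env_bf_separation(
    n_reps: int = 20,
    seed: int = 0,
    n_pops: int = 10,
    n_signal: int = 500,
    n_null: int = 500,
    beta_true: float = 0.25,
    mw_alpha: float = 0.01,
) -> float:
    """Fraction of replicates where signal and null SNPs separate by BF.

    Per replicate, frequencies for signal and null SNPs are generated
    under a diagonal covariance with a planted latitude effect, the scan
    estimates Ω from separate control SNPs and computes Bayes factors,
    and a one-sided Mann–Whitney test checks that signal BFs exceed null
    BFs at ``mw_alpha``.
    """
    from .datatypes import EnvTable

    wins = 0
    omega = 0.01 * np.eye(n_pops)
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        lat = np.sort(rng.uniform(0.0, 65.0, size=n_pops))
        env = EnvTable(["latitude"], {f"POP{i}": np.array([lat[i]]) for i in range(n_pops)})
        freqs, is_signal = simulate_env_correlated_freqs(
            omega, lat, beta_true, n_signal, n_null, seed=seed + 1000 + r)
        control, _ = simulate_env_correlated_freqs(
            omega, lat, 0.0, 0, 20 * n_pops, seed=seed + 2000 + r)
        snp_ids = [f"s{j}" for j in range(n_signal + n_null)]
        table = gene_env.env_scan(freqs, env, control,
                                  populations=[f"POP{i}" for i in range(n_pops)],
                                  snp_ids=snp_ids)
        bf = dict(zip(table["snp"], table["bf"]))
        sig = [bf[f"s{j}"] for j in range(n_signal)]
        nul = [bf[f"s{j}"] for j in range(n_signal, n_signal + n_null)]
        p = stats.mannwhitneyu(sig, nul, alternative="greater").pvalue
        wins += p < mw_alpha
    return wins / n_reps
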