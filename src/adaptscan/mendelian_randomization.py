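"""Two-sample Mendelian randomization.

Instruments are SNPs with effects on an exposure and on an outcome
estimated in separate GWAS. After harmonizing the two tables to a common
effect allele (palindromic A/T and C/G SNPs dropped), the causal effect
of exposure on outcome is estimated by:

* IVW — the fixed-effect inverse-variance-weighted slope through the
  origin, ``Σ w β_X β_Y / Σ w β_X²`` with ``w = se_Y^-2``;
* MR-Egger — weighted least squares of β_Y on β_X with an intercept,
  exposure effects oriented non-negative first; a nonzero intercept is
  the directional-pleiotropy test (t distribution, n-2 df).

Leave-one-out refits IVW excluding each instrument in turn and flags
exclusions that flip the sign or leave the full-set 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import GwasRecord, ValidationError

__all__ = [
    "Instrument",
    "InstrumentSet",
    "MrEstimate",
    "harmonize",
    "mr_ivw",
    "mr_egger",
    "leave_one_out",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class Instrument:
    rsid: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    action: str  # kept | sign-flipped | dropped-palindromic | dropped-mismatch


@dataclass
class InstrumentSet:
    """Harmonized instruments, all aligned to the exposure effect allele."""

    instruments: list[Instrument]

    @property
    def retained(self) -> list[Instrument]:
        return [i for i in self.instruments if not i.action.startswith("dropped")]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        r = self.retained
        return (
            np.array([i.beta_exposure for i in r]),
            np.array([i.se_exposure for i in r]),
            np.array([i.beta_outcome for i in r]),
            np.array([i.se_outcome for i in r]),
        )


@dataclass
class MrEstimate:
    method: str  # IVW | Egger-slope | Egger-intercept
    estimate: float
    se: float
    p: float  # two-sided
    n_instruments: int

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)


def harmonize(
    exposure: Sequence[GwasRecord],
    outcome: Sequence[GwasRecord],
) -> InstrumentSet:
    """Align outcome effects to the exposure effect allele.

    Matching alleles are kept; swapped (or strand-complementary swapped)
    alleles negate the outcome beta; palindromic SNPs are dropped (their
    strand cannot be resolved without frequencies); irreconcilable allele
    pairs are dropped as mismatches. Raises if nothing survives.
    """
    out_by_id = {r.rsid: r for r in outcome}
    instruments: list[Instrument] = []
    for ex in exposure:
        oc = out_by_id.get(ex.rsid)
        if oc is None:
            continue
        e1, e2 = ex.effect_allele, ex.other_allele
        o1, o2 = oc.effect_allele, oc.other_allele
        if frozenset((e1, e2)) in _PALINDROMIC:
            instruments.append(Instrument(ex.rsid, ex.beta, ex.se, oc.beta, oc.se, "dropped-palindromic"))
            continue
        c1, c2 = _COMPLEMENT.get(o1, "?"), _COMPLEMENT.get(o2, "?")
        if (o1, o2) == (e1, e2) or (c1, c2) == (e1, e2):
            instruments.append(Instrument(ex.rsid, ex.beta, ex.se, oc.beta, oc.se, "kept"))
        elif (o2, o1) == (e1, e2) or (c2, c1) == (e1, e2):
            instruments.append(Instrument(ex.rsid, ex.beta, ex.se, -oc.beta, oc.se, "sign-flipped"))
        else:
            instruments.append(Instrument(ex.rsid, ex.beta, ex.se, oc.beta, oc.se, "dropped-mismatch"))
    iset = InstrumentSet(instruments)
    if not iset.retained:
        raise ValidationError("no instruments survived harmonization")
    return iset


def mr_ivw(instr: InstrumentSet) -> MrEstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    ``estimate = Σ w β_X β_Y / Σ w β_X²`` with ``w = se_Y^-2``;
    ``se = (Σ w β_X²)^-1/2``; two-sided normal p.
    """
    bx, _, by, sy = instr.arrays()
    if len(bx) < 2:
        raise ValidationError("IVW needs at least 2 instruments")
    w = sy**-2.0
    denom = float((w * bx**2).sum())
    est = float((w * bx * by).sum()) / denom
    se = denom**-0.5
    p = float(2.0 * stats.norm.sf(abs(est) / se))
    return MrEstimate("IVW", est, se, p, len(bx))


def mr_egger(instr: InstrumentSet) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger regression: (slope estimate, intercept estimate).

    Exposure betas are oriented non-negative (outcome betas flipped with
    them) before the ``se_Y^-2``-weighted least-squares fit of β_Y on
    β_X with intercept. The intercept is the directional-pleiotropy
    test; p-values use the t distribution with n-2 df.
    """
    bx, _, by, sy = instr.arrays()
    n = len(bx)
    if n < 3:
        raise ValidationError("MR-Egger needs at least 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    fit = sm.WLS(by, sm.add_constant(bx), weights=sy**-2.0).fit()
    icept = MrEstimate("Egger-intercept", float(fit.params[0]), float(fit.bse[0]),
                       float(fit.pvalues[0]), n)
    slope = MrEstimate("Egger-slope", float(fit.params[1]), float(fit.bse[1]),
                       float(fit.pvalues[1]), n)
    return slope, icept


def leave_one_out(instr: InstrumentSet) -> pd.DataFrame:
    """IVW re-estimated with each instrument excluded in turn.

    The ``flagged`` column marks exclusions whose estimate changes sign
    relative to the full fit or leaves the full-set 95% interval —
    evidence the full estimate leans on a single SNP.
    """
    retained = instr.retained
    if len(retained) < 3:
        raise ValidationError("leave-one-out needs at least 3 instruments")
    full = mr_ivw(instr)
    lo, hi = full.ci95
    rows = []
    for excl in retained:
        sub = InstrumentSet([i for i in retained if i.rsid != excl.rsid])
        est = mr_ivw(sub)
        flagged = (np.sign(est.estimate) != np.sign(full.estimate)) or not (lo <= est.estimate <= hi)
        rows.append((excl.rsid, est.estimate, est.se, *est.ci95, bool(flagged)))
    return pd.DataFrame(rows, columns=["excluded", "estimate", "se", "ci_low", "ci_high", "flagged"])
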