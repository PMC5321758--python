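"""Chou-Talalay median-effect modelling and combination-index computation.

The median-effect equation fa/fu = (D/Dm)^m linearizes to
log10(fa/(1-fa)) = m*log10(D) - m*log10(Dm), so each drug's dose-response
is an ordinary least-squares line; the combination index at an observed
combined effect is CI = d1/Dx1 + d2/Dx2, with Dx the dose of each drug
alone producing that effect.  CI < 1 is synergism, CI = 1 additive and
CI > 1 antagonism.

Also here: the small closed-form assay metrics (two-sample t-test power,
population doubling time, ellipsoid tumour volume).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class SynergyError(ValueError):
    pass


@dataclass
class DoseResponse:
    drug_id: str
    doses: np.ndarray     # concentrations, strictly positive
    fa: np.ndarray        # fraction affected per dose

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        if self.doses.shape != self.fa.shape:
            raise SynergyError("doses and fa must have equal length")
        if np.any(self.doses <= 0):
            raise SynergyError("doses must be strictly positive")


@dataclass
class MedianEffectFit:
    drug_id: str
    m: float             # sigmoidicity slope
    dm: float            # median-effect dose (50% affected)
    r2: float
    n_used: int
    n_excluded: int = 0

    def predict_fa(self, dose: float | np.ndarray) -> np.ndarray:
        ratio = (np.asarray(dose, dtype=float) / self.dm) ** self.m
        return ratio / (1.0 + ratio)


@dataclass
class CombinationResult:
    d1: float
    d2: float
    fa_combo: float
    ci: float
    call: str            # synergism | additive | antagonism


def fit_median_effect(dr: DoseResponse) -> MedianEffectFit:
    """OLS fit of log10(fa/(1-fa)) on log10(D); m = slope, Dm = 10^(-b/m).

    Points with fa outside the open interval (0,1) are excluded (the logit
    is undefined there) with a logged count.
    """
    usable = (dr.fa > 0) & (dr.fa < 1)
    n_excluded = int(np.sum(~usable))
    if n_excluded:
        logger.warning("%s: %d points with fa outside (0,1) excluded", dr.drug_id, n_excluded)
    doses, fa = dr.doses[usable], dr.fa[usable]
    if len(np.unique(doses)) < 2:
        raise SynergyError(f"{dr.drug_id}: need >=2 distinct usable doses")
    x = np.log10(doses)
    y = np.log10(fa / (1.0 - fa))
    slope, intercept, r, _, _ = stats.linregress(x, y)
    if slope <= 0:
        logger.warning("%s: non-positive median-effect slope m=%.3g", dr.drug_id, slope)
    return MedianEffectFit(
        drug_id=dr.drug_id,
        m=float(slope),
        dm=float(10.0 ** (-intercept / slope)),
        r2=float(r**2),
        n_used=int(usable.sum()),
        n_excluded=n_excluded,
    )


def effective_dose(fit: MedianEffectFit, fa: float) -> float:
    """Dose producing fraction affected ``fa``: Dx = Dm*(fa/(1-fa))^(1/m)."""
    if not 0 < fa < 1:
        raise SynergyError("fa must lie strictly inside (0,1)")
    return float(fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def combination_index(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    d1: float,
    d2: float,
    fa_combo: float,
    call_tolerance: float = 0.05,
) -> CombinationResult:
    """CI = d1/Dx1(fa) + d2/Dx2(fa) at the observed combined effect.

    The call is additive when |CI-1| <= call_tolerance, synergism below,
    antagonism above (the strict thresholds are CI<1 / CI=1 / CI>1; the
    tolerance is a reporting convention for noisy assays).
    """
    if d1 < 0 or d2 < 0 or (d1 == 0 and d2 == 0):
        raise SynergyError("doses must be nonnegative and not both zero")
    if not 0 < fa_combo < 1:
        raise SynergyError("fa_combo must lie strictly inside (0,1)")
    ci = 0.0
    if d1 > 0:
        ci += d1 / effective_dose(fit1, fa_combo)
    if d2 > 0:
        ci += d2 / effective_dose(fit2, fa_combo)
    if abs(ci - 1.0) <= call_tolerance:
        call = "additive"
    elif ci < 1.0:
        call = "synergism"
    else:
        call = "antagonism"
    return CombinationResult(d1=d1, d2=d2, fa_combo=fa_combo, ci=float(ci), call=call)


def power_two_sample_t(
    n_per_group: int, true_diff: float, sd: float, alpha: float = 0.05
) -> float:
    """Power of the two-sided two-sample t-test via the noncentral t.

    ncp = (diff/sd)*sqrt(n/2) on 2n-2 df; power = P(|T'| > t_crit).
    """
    if n_per_group < 2:
        raise SynergyError("need n_per_group >= 2")
    if sd <= 0 or not 0 < alpha < 1:
        raise SynergyError("sd must be positive and alpha in (0,1)")
    df = 2 * n_per_group - 2
    ncp = (true_diff / sd) * math.sqrt(n_per_group / 2.0)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    return float(power)


def population_doubling_time(n0: float, nt: float, hours: float) -> float:
    """PD = hours * log(2) / (log(nt) - log(n0)) under exponential growth."""
    if n0 <= 0 or nt <= 0 or hours <= 0:
        raise SynergyError("cell counts and hours must be positive")
    if nt <= n0:
        raise SynergyError("no net growth: nt must exceed n0")
    return float(hours * math.log(2.0) / (math.log(nt) - math.log(n0)))


def tumour_volume(length: float, width: float) -> float:
    """Ellipsoid volume pi/6 * length * width^2 (longest dimension first)."""
    if length <= 0 or width <= 0:
        raise SynergyError("dimensions must be positive")
    if width > length:
        logger.warning("width > length; swapping so the longest dimension is length")
        length, width = width, length
    return float(math.pi / 6.0 * length * width**2)
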