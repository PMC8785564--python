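"""Lethal doses, heterogeneity-adjusted fiducial limits and resistance ratios.

The lethal dose at mortality level pi is LD_pi = 10^m with
m = (Phi^-1(pi) - a) / b on the log10-dose scale.  Confidence limits for m
come from Fieller's theorem applied to the ratio of the two (approximately
normal) coefficient estimates, with the covariance matrix inflated by the
heterogeneity factor h and a Student-t multiplier when h > 1 (Finney's
treatment of heterogeneous assays).  Finney's g = t^2 h Var(b) / b^2
indexes slope uncertainty: limits widen as g grows and cease to exist at
g >= 1; with good data g stays well below 0.4.

Resistance ratios divide a population's LD by the reference (lowest-LD)
population's LD at the same level; their CIs use the delta method on the
log10 scale (Robertson & Preisler).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AssayError, UnboundedIntervalError
from .probit import ProbitFit, probit

DEFAULT_LEVELS = (0.25, 0.50, 0.95)


@dataclass
class LDEstimate:
    population: str
    level: float
    ld: float
    ci_low: float
    ci_high: float
    conf_level: float
    g: float
    h: float


@dataclass
class RREstimate:
    population: str
    reference: str
    level: float
    rr: float
    ci_low: float
    ci_high: float
    conf_level: float


def _check_fit(fit: ProbitFit) -> None:
    if not fit.converged:
        raise AssayError(f"population {fit.population!r}: fit did not converge")
    if fit.slope <= 0:
        raise AssayError(
            f"population {fit.population!r}: slope {fit.slope:.3g} <= 0; the "
            "response must increase with dose for a lethal dose to exist"
        )


def _t_multiplier(fit: ProbitFit, conf_level: float) -> float:
    """Normal quantile, or Student-t with df_resid for heterogeneous fits.

    Heterogeneity is considered established (Finney's criterion) when the
    fit's Pearson chi-square is significant at 0.05; a dispersion ratio
    barely above 1, as half of all well-behaved binomial assays show by
    chance, does not trigger the heavier multiplier.
    """
    q = 0.5 + conf_level / 2
    if fit.h > 1 and fit.het_p < 0.05 and fit.df_resid > 0:
        return float(stats.t.ppf(q, fit.df_resid))
    return float(stats.norm.ppf(q))


def _h_vcov(fit: ProbitFit) -> np.ndarray:
    """Heterogeneity-inflated covariance: the binomial (X'WX)^-1 times h.

    ``ProbitFit.vcov`` is already scaled by the dispersion floored at 1,
    i.e. it IS h times the binomial covariance; inflating again here
    would count heterogeneity twice.
    """
    return fit.vcov


def lethal_dose_point(fit: ProbitFit, level: float) -> float:
    """Point estimate of the lethal dose at the given mortality level."""
    _check_fit(fit)
    if not 0 < level < 1:
        raise AssayError(f"level must be in (0, 1), got {level}")
    m = (probit(level) - fit.intercept) / fit.slope
    return float(10.0**m)


def g_statistic(fit: ProbitFit, conf_level: float = 0.95, use_h: bool = True) -> float:
    """Finney's g = t^2 * H * Var_binomial(slope) / slope^2 (H = h unless disabled).

    ``fit.vcov`` already carries one factor of h, so with ``use_h`` (the
    default, Finney's convention) it is used as-is; disabling ``use_h``
    divides the heterogeneity back out.
    """
    _check_fit(fit)
    t = _t_multiplier(fit, conf_level)
    var_slope = fit.vcov[1, 1] if use_h else fit.vcov[1, 1] / fit.h
    return float(t**2 * var_slope / fit.slope**2)


def fieller_ci(
    fit: ProbitFit,
    level: float,
    conf_level: float = 0.95,
    use_h: bool = True,
) -> tuple[float, float]:
    """Fieller confidence limits for the lethal dose at ``level``.

    Returns (low, high) on the dose scale.  Raises
    :class:`UnboundedIntervalError` when Finney's g >= 1, in which case
    the fiducial interval is unbounded (slope indistinguishable from 0 at
    this confidence level).
    """
    _check_fit(fit)
    if not 0 < level < 1:
        raise AssayError(f"level must be in (0, 1), got {level}")
    t = _t_multiplier(fit, conf_level)
    V = _h_vcov(fit) if use_h else fit.vcov / fit.h
    v_aa, v_ab, v_bb = V[0, 0], V[0, 1], V[1, 1]
    b = fit.slope
    m = (probit(level) - fit.intercept) / b
    g = t**2 * v_bb / b**2
    if g >= 1:
        raise UnboundedIntervalError(
            f"population {fit.population!r}: Finney's g = {g:.3f} >= 1; the "
            "slope is too uncertain at this confidence level and the fiducial "
            "interval is unbounded"
        )
    if v_bb == 0:
        half = (t / b) * np.sqrt(max(v_aa, 0.0))
        return float(10.0 ** (m - half)), float(10.0 ** (m + half))
    radicand = v_aa + 2 * m * v_ab + m**2 * v_bb - g * (v_aa - v_ab**2 / v_bb)
    half = (t / b) * np.sqrt(max(radicand, 0.0))
    center = m + g * v_ab / v_bb
    low = (center - half) / (1 - g)
    high = (center + half) / (1 - g)
    return float(10.0**low), float(10.0**high)


def estimate_ld(
    fit: ProbitFit,
    level: float,
    conf_level: float = 0.95,
    use_h_in_g: bool = True,
) -> LDEstimate:
    """Lethal dose with Fieller limits and the g, h diagnostics."""
    ld = lethal_dose_point(fit, level)
    low, high = fieller_ci(fit, level, conf_level, use_h=use_h_in_g)
    return LDEstimate(
        population=fit.population,
        level=level,
        ld=ld,
        ci_low=low,
        ci_high=high,
        conf_level=conf_level,
        g=g_statistic(fit, conf_level, use_h=use_h_in_g),
        h=fit.h,
    )


def _var_log10_ld(fit: ProbitFit, level: float) -> float:
    """Delta-method variance of log10 LD = h * (vaa + 2m vab + m^2 vbb) / b^2
    (the h factor is already inside ``fit.vcov``)."""
    V = _h_vcov(fit)
    m = (probit(level) - fit.intercept) / fit.slope
    return float(
        (V[0, 0] + 2 * m * V[0, 1] + m**2 * V[1, 1]) / fit.slope**2
    )


def resistance_ratio(
    fit_pop: ProbitFit,
    fit_ref: ProbitFit,
    level: float = 0.5,
    conf_level: float = 0.95,
) -> RREstimate:
    """Resistance ratio LD(pop) / LD(ref) with a delta-method CI.

    Var(log10 RR) is the sum of the two populations' delta-method
    variances of log10 LD; the CI is symmetric on the log scale with a
    normal multiplier.  A population compared with itself gives exactly 1.
    """
    ld_pop = lethal_dose_point(fit_pop, level)
    ld_ref = lethal_dose_point(fit_ref, level)
    rr = ld_pop / ld_ref
    if fit_pop.population == fit_ref.population:
        return RREstimate(
            fit_pop.population, fit_ref.population, level, 1.0, 1.0, 1.0, conf_level
        )
    var_log_rr = _var_log10_ld(fit_pop, level) + _var_log10_ld(fit_ref, level)
    z = float(stats.norm.ppf(0.5 + conf_level / 2))
    half = z * np.sqrt(var_log_rr)
    log_rr = np.log10(rr)
    return RREstimate(
        population=fit_pop.population,
        reference=fit_ref.population,
        level=level,
        rr=float(rr),
        ci_low=float(10.0 ** (log_rr - half)),
        ci_high=float(10.0 ** (log_rr + half)),
        conf_level=conf_level,
    )


def choose_reference(fits: Iterable[ProbitFit], level: float = 0.5) -> str:
    """Most susceptible population: smallest LD at ``level``, ties lexicographic."""
    fits = list(fits)
    if not fits:
        raise AssayError("no convergent fits to choose a reference from")
    return min(fits, key=lambda f: (lethal_dose_point(f, level), f.population)).population


def ld_table(
    fits: Sequence[ProbitFit],
    levels: Sequence[float] = DEFAULT_LEVELS,
    conf_level: float = 0.95,
    use_h_in_g: bool = True,
    reference: str | None = None,
) -> pd.DataFrame:
    """Tidy LD/RR table: one row per population x level.

    The reference defaults to the population with the lowest LD at the
    first level <= 0.5 present (else the first level).  Reference rows
    carry RR = 1.  Unbounded Fieller intervals (g >= 1) yield NaN limits
    rather than an error, so one noisy population does not sink the table.
    """
    fits = list(fits)
    ref_level = next((lv for lv in levels if lv <= 0.5), levels[0])
    if reference is None:
        reference = choose_reference(fits, ref_level)
    by_name = {f.population: f for f in fits}
    if reference not in by_name:
        raise AssayError(f"reference population {reference!r} has no fit")
    rows = []
    for fit in fits:
        for level in levels:
            ld = lethal_dose_point(fit, level)
            try:
                lo, hi = fieller_ci(fit, level, conf_level, use_h=use_h_in_g)
            except UnboundedIntervalError:
                lo, hi = float("nan"), float("nan")
            rr = resistance_ratio(fit, by_name[reference], level, conf_level)
            rows.append(
                {
                    "population": fit.population,
                    "level": level,
                    "ld": ld,
                    "ci_low": lo,
                    "ci_high": hi,
                    "g": g_statistic(fit, conf_level, use_h=use_h_in_g),
                    "h": fit.h,
                    "reference": reference,
                    "rr": rr.rr,
                    "rr_low": rr.ci_low,
                    "rr_high": rr.ci_high,
                }
            )
    return pd.DataFrame(rows)
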