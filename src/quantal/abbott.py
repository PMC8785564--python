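"""Control-mortality estimation and Abbott's correction.

Unexposed (dose-0) batches measure the mortality caused by the experiment
itself.  A shared mortality parameter is estimated across the control
replicates of each population by maximum likelihood, and when it exceeds a
threshold (default 5%) treatment mortalities are rescaled with Abbott's
formula

    corrected = 1 - s_T / s_C,

where s_T and s_C are the treatment and control survival rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AssayError, HeterogeneityWarning, SaturatedControlError
from .io import AssayTable

_EPS = 1e-9


@dataclass
class ControlCorrection:
    """Per-population control-mortality estimate and whether it is applied.

    ``applied`` is true exactly when the estimated control mortality
    exceeds ``threshold``.  ``replicate_heterogeneity_p`` is the p-value of
    a chi-square homogeneity test of mortality across control replicates
    (1.0 when fewer than two replicates exist).
    """

    population: str
    control_mortality: float
    applied: bool
    threshold: float = 0.05
    replicate_heterogeneity_p: float = 1.0
    n_control: int = 0


def _control_negloglik(c, dead: np.ndarray, total: np.ndarray) -> float:
    c = float(np.clip(np.asarray(c).reshape(-1)[0], _EPS, 1 - _EPS))
    return -float(np.sum(dead * np.log(c) + (total - dead) * np.log1p(-c)))


def estimate_control_mortality(
    controls: AssayTable,
    population: str,
    threshold: float = 0.05,
) -> ControlCorrection:
    """Estimate the shared control mortality of one population.

    The estimate maximizes the product of binomial likelihoods over the
    population's control replicates with a single mortality parameter
    (numerical L-BFGS-B optimization on [1e-9, 1-1e-9]; for the shared
    binomial this coincides with the pooled proportion).  Heterogeneity
    between replicates is reported as a chi-square homogeneity p-value and
    warned about below 0.05; it does not alter the estimate.

    With no control record the mortality is 0 and no correction applies.

    Raises
    ------
    SaturatedControlError
        If every control organism died: stimulus-free mortality is
        saturated and the correction is undefined.
    """
    if not 0 <= threshold <= 1:
        raise AssayError(f"threshold must be in [0, 1], got {threshold}")
    sub = controls.data[controls.data["population"] == population]
    if len(sub) == 0:
        return ControlCorrection(population, 0.0, False, threshold, 1.0, 0)

    dead = sub["dead"].to_numpy(float)
    total = sub["total"].to_numpy(float)
    if dead.sum() >= total.sum():
        raise SaturatedControlError(
            f"population {population!r}: all {int(total.sum())} control organisms "
            "died; stimulus-free mortality is saturated and Abbott's correction "
            "is undefined"
        )

    res = optimize.minimize(
        _control_negloglik,
        x0=[np.clip(dead.sum() / total.sum(), 0.01, 0.99)],
        args=(dead, total),
        method="L-BFGS-B",
        bounds=[(_EPS, 1 - _EPS)],
    )
    c = float(res.x[0])
    if c <= 2 * _EPS:  # boundary solution: report an exact zero
        c = 0.0

    p_het = 1.0
    if len(sub) >= 2:
        contingency = np.column_stack([dead, total - dead])
        # rows (replicates) with zero margin cannot enter the test
        keep = contingency.sum(axis=1) > 0
        if keep.sum() >= 2 and dead[keep].sum() > 0 and (total - dead)[keep].sum() > 0:
            p_het = float(
                stats.chi2_contingency(contingency[keep], correction=False).pvalue
            )
        if p_het < 0.05:
            warnings.warn(
                f"population {population!r}: control mortality differs between "
                f"replicates (chi-square homogeneity p = {p_het:.3g}); use the "
                "data with caution",
                HeterogeneityWarning,
                stacklevel=2,
            )

    return ControlCorrection(
        population=population,
        control_mortality=c,
        applied=c > threshold,
        threshold=threshold,
        replicate_heterogeneity_p=p_het,
        n_control=int(len(sub)),
    )


def abbott_correct(raw_mortality, control_mortality: float):
    """Abbott's formula, clamped to [0, 1].

    corrected = 1 - (1 - raw) / (1 - control).  Accepts scalars or arrays;
    strictly increasing in the raw mortality, identity when the control
    mortality is 0, and 0 whenever the treatment kills no more than the
    control.
    """
    raw = np.asarray(raw_mortality, dtype=float)
    if np.any(raw < 0) or np.any(raw > 1):
        raise AssayError("raw mortality outside [0, 1]")
    if not 0 <= control_mortality < 1:
        raise AssayError("control mortality must lie in [0, 1)")
    if control_mortality == 0:
        corrected = raw.copy()  # exact identity, no round trip through 1-raw
    else:
        corrected = np.clip(1 - (1 - raw) / (1 - control_mortality), 0.0, 1.0)
    return corrected if corrected.ndim else float(corrected)


def apply_correction(
    treatments: AssayTable,
    correction: ControlCorrection,
    threshold: float | None = None,
) -> pd.Series:
    """Row-wise corrected mortality for a population's treatment batches.

    Below the threshold the raw dead/total proportions pass through
    unchanged; above it Abbott's formula is applied.  The returned series
    is aligned with ``treatments.data`` and named ``"corrected"``;
    ``correction.applied`` records which branch was taken for downstream
    reports.
    """
    if threshold is None:
        threshold = correction.threshold
    if not 0 <= threshold <= 1:
        raise AssayError(f"threshold must be in [0, 1], got {threshold}")
    sub = treatments.data[treatments.data["population"] == correction.population]
    raw = sub["dead"] / sub["total"]
    correction.applied = correction.control_mortality > threshold
    if not correction.applied:
        return raw.rename("corrected")
    values = abbott_correct(raw.to_numpy(), correction.control_mortality)
    return pd.Series(values, index=sub.index, name="corrected")
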