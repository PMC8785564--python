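"""Quasi-binomial probit regression of mortality on log10 dose.

For each population the mean model is

    Phi^-1( E[Y] ) = a + b * log10(dose),

fitted by iteratively reweighted least squares (IRLS) on the (possibly
Abbott-corrected) mortality proportions with batch totals as binomial
weights.  Overdispersion is absorbed by the Pearson dispersion; the
heterogeneity factor h = max(1, Pearson chi2 / df) inflates all downstream
confidence limits.  A chi-square homogeneity test between observed and
predicted dead counts per dose screens for departures from log-dose
linearity (mixed populations, threshold effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AssayError, DesignError, NonIdentifiableError
from .io import AssayTable, aggregate_replicates

_MU_EPS = 1e-10


def probit(p):
    """Standard normal quantile Phi^-1(p), defined on the open interval (0, 1).

    Scalars or arrays; p equal to 0 or 1 raises, because those points have
    no finite probit (they are dropped from transformed displays, never
    from count-based fitting).
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise AssayError("probit is defined only on the open interval (0, 1)")
    out = stats.norm.ppf(arr)
    return out if out.ndim else float(out)


@dataclass
class ProbitFit:
    """Result of a probit-on-log10(dose) fit for one population.

    ``vcov`` is the 2x2 covariance of (intercept, slope) on the probit /
    log10-dose scale, already scaled by the dispersion floored at 1;
    ``h`` is the heterogeneity factor max(1, Pearson chi2 / df_resid).
    The per-observation arrays used in the fit are retained for the
    linearity test and plotting.
    """

    population: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    vcov: np.ndarray
    dispersion: float
    n_points: int
    df_resid: int
    h: float
    het_p: float = 1.0  # upper-tail p of Pearson chi2 on df_resid
    abbott_applied: bool = False
    converged: bool = True
    deviance: float = float("nan")
    pearson_chi2: float = float("nan")
    dose: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    total: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    observed: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    fitted: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def predict(self, dose) -> np.ndarray:
        """Fitted mortality probability at the given dose(s)."""
        eta = self.intercept + self.slope * np.log10(np.asarray(dose, dtype=float))
        return stats.norm.cdf(eta)


@dataclass
class LinearityTest:
    """Chi-square homogeneity test of observed vs predicted dead counts."""

    chi2: float
    df: int
    p_value: float
    linear: bool
    floored_points: int = 0


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> dict:
    """IRLS for a binomial-proportion GLM with probit link.

    ``y`` are proportions in [0, 1] (possibly non-integer after Abbott's
    correction), ``w`` the batch totals acting as binomial weights.
    Returns coefficients, the unscaled (X'WX)^-1, deviance and Pearson
    statistics.  Starts from a flat curve at the overall mean mortality.
    """
    n, k = X.shape
    mean0 = float(np.clip(np.average(y, weights=w), 0.01, 0.99))
    beta = np.zeros(k)
    beta[0] = stats.norm.ppf(mean0)

    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(stats.norm.cdf(eta), _MU_EPS, 1 - _MU_EPS)
        dmu = np.maximum(stats.norm.pdf(eta), 1e-300)
        weight = w * dmu**2 / (mu * (1 - mu))
        z = eta + (y - mu) / dmu
        WX = X * weight[:, None]
        xtwx = X.T @ WX
        try:
            beta_new = np.linalg.solve(xtwx, WX.T @ z)
        except np.linalg.LinAlgError as err:
            raise NonIdentifiableError(
                "singular weighted design matrix; the response does not "
                "identify the dose-response curve"
            ) from err
        delta = np.max(np.abs(beta_new - beta) / np.maximum(1.0, np.abs(beta_new)))
        beta = beta_new
        if delta < tol:
            converged = True
            break

    if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 1e6:
        raise NonIdentifiableError(
            "coefficients diverged (complete separation or degenerate response)"
        )

    eta = X @ beta
    mu = np.clip(stats.norm.cdf(eta), _MU_EPS, 1 - _MU_EPS)
    dmu = np.maximum(stats.norm.pdf(eta), 1e-300)
    weight = w * dmu**2 / (mu * (1 - mu))
    xtwx = X.T @ (X * weight[:, None])
    xtwx_inv = np.linalg.pinv(xtwx)
    pearson = float(np.sum(w * (y - mu) ** 2 / (mu * (1 - mu))))

    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        term2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    deviance = float(2 * np.sum(w * (term1 + term2)))

    return {
        "beta": beta,
        "xtwx_inv": xtwx_inv,
        "pearson": pearson,
        "deviance": deviance,
        "mu": mu,
        "converged": converged,
        "n": n,
        "k": k,
    }


def fit_probit_glm(
    treatments: AssayTable,
    population: str,
    corrected: pd.Series | np.ndarray | None = None,
    pooling: str = "replicate",
    abbott_applied: bool = False,
) -> ProbitFit:
    """Fit the probit dose-response line for one population.

    Parameters
    ----------
    treatments
        Nonzero-dose batches (controls must already be split off).
    corrected
        Mortality proportions aligned with the population's rows in
        ``treatments.data`` (e.g. from :func:`quantal.abbott.apply_correction`).
        Defaults to the raw dead/total.
    pooling
        ``"replicate"`` (default) keeps replicate rows as separate binomial
        observations; ``"pooled"`` sums counts per dose before fitting.
        With homogeneous replicates the two give identical coefficients.
    abbott_applied
        Recorded on the fit for downstream reports.

    Raises
    ------
    DesignError
        Fewer than two distinct nonzero doses.
    NonIdentifiableError
        All-0 or all-1 mortalities, or complete separation.
    """
    if pooling not in {"replicate", "pooled"}:
        raise AssayError(f"pooling must be 'replicate' or 'pooled', got {pooling!r}")
    sub = treatments.data[treatments.data["population"] == population]
    if (sub["dose"] <= 0).any():
        raise DesignError(
            f"population {population!r}: dose-0 rows present; split controls first"
        )
    if corrected is None:
        y = (sub["dead"] / sub["total"]).to_numpy(float)
    else:
        y = np.asarray(
            corrected.loc[sub.index] if isinstance(corrected, pd.Series) else corrected,
            dtype=float,
        )
    dose = sub["dose"].to_numpy(float)
    total = sub["total"].to_numpy(float)

    if pooling == "pooled":
        pooled = pd.DataFrame({"dose": dose, "total": total, "dead_eq": y * total})
        agg = pooled.groupby("dose", sort=True, as_index=False).sum()
        dose = agg["dose"].to_numpy()
        total = agg["total"].to_numpy()
        y = (agg["dead_eq"] / agg["total"]).to_numpy()

    if len(np.unique(dose)) < 2:
        raise DesignError(
            f"population {population!r}: at least 2 distinct nonzero doses are "
            f"required for a dose-response fit, got {len(np.unique(dose))}"
        )
    if np.all(y <= 0) or np.all(y >= 1):
        raise NonIdentifiableError(
            f"population {population!r}: all mortalities are "
            f"{'0' if np.all(y <= 0) else '1'}; the curve is not identifiable"
        )

    x = np.log10(dose)
    X = np.column_stack([np.ones_like(x), x])
    res = _irls(X, y, total)

    n = len(y)
    df_resid = n - 2
    dispersion = res["pearson"] / df_resid if df_resid > 0 else float("nan")
    scale = max(1.0, dispersion) if df_resid > 0 else 1.0
    vcov = res["xtwx_inv"] * scale
    h = max(1.0, dispersion) if df_resid > 0 else 1.0
    het_p = float(stats.chi2.sf(res["pearson"], df_resid)) if df_resid > 0 else 1.0

    a, b = res["beta"]
    return ProbitFit(
        population=population,
        slope=float(b),
        intercept=float(a),
        slope_se=float(np.sqrt(vcov[1, 1])),
        intercept_se=float(np.sqrt(vcov[0, 0])),
        vcov=vcov,
        dispersion=float(dispersion),
        n_points=n,
        df_resid=df_resid,
        h=float(h),
        het_p=het_p,
        abbott_applied=abbott_applied,
        converged=res["converged"],
        deviance=res["deviance"],
        pearson_chi2=res["pearson"],
        dose=dose,
        total=total,
        observed=y,
        fitted=res["mu"],
    )


def linearity_test(fit: ProbitFit, alpha: float = 0.05) -> LinearityTest:
    """Chi-square homogeneity test of the log-dose linearity.

    Observed and predicted dead counts are compared per dose point
    (replicates at the same dose pooled): chi2 = sum (O - E)^2 / E with
    df = #dose points - 2.  A predicted count of zero at some point is
    floored at 0.5 and counted in ``floored_points``.  Significant
    deviation may reflect mixed populations or a threshold effect.
    """
    df_points = pd.DataFrame(
        {
            "dose": fit.dose,
            "obs_dead": fit.observed * fit.total,
            "pred_dead": fit.fitted * fit.total,
        }
    )
    agg = df_points.groupby("dose", sort=True).sum()
    expected = agg["pred_dead"].to_numpy()
    floored = int(np.sum(expected < 1e-9))
    expected = np.where(expected < 1e-9, 0.5, expected)
    chi2 = float(np.sum((agg["obs_dead"].to_numpy() - expected) ** 2 / expected))
    df = len(agg) - 2
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LinearityTest(chi2=chi2, df=max(df, 0), p_value=p, linear=p >= alpha,
                         floored_points=floored)


def heterogeneity_factor(fit: ProbitFit) -> float:
    """Heterogeneity factor h = max(1, Pearson chi2 / df_resid)."""
    if fit.df_resid <= 0:
        raise DesignError(
            "saturated design: residual degrees of freedom are 0, "
            "heterogeneity is undefined"
        )
    return fit.h
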