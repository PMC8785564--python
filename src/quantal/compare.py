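"""Multi-population dose-response comparison.

Populations exposed to the same stimulus are compared by contrasting a
null probit GLM (log10 dose only, all data pooled) with a complete model
whose design matrix adds the population effect and its interaction with
dose.  Because the fits are quasi-binomial there is no true likelihood;
the contrast is the scaled deviance-difference F test

    F = (D_null - D_full) / (delta_df * phi_full),

with phi_full the complete model's Pearson dispersion, referred to
F(delta_df, df_resid_full).  With more than two populations a significant
global test is followed by pairwise refits with Holm-Bonferroni control
of the family-wise error.  Only populations passing the linearity screen
may enter: comparing a nonlinear dose-response is not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AssayError, DesignError
from .io import AssayTable
from .probit import _irls, fit_probit_glm, linearity_test


@dataclass
class ComparisonResult:
    populations: list[str]
    stat: float
    df_num: int
    df_den: int
    p_value: float
    deviance_null: float
    deviance_full: float
    dispersion_full: float
    alpha: float = 0.05
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm-Bonferroni step-down adjustment, returned in input order.

    Sorted ascending, the i-th smallest p is multiplied by (m - i + 1),
    a running maximum enforces monotonicity and values are capped at 1.
    """
    p = list(map(float, p_values))
    if any(q < 0 or q > 1 for q in p):
        raise AssayError("p-values must lie in [0, 1]")
    m = len(p)
    order = sorted(range(m), key=p.__getitem__)
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adjusted[idx] = running
    return adjusted


def _design_matrices(
    sub: pd.DataFrame, populations: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(null, full) design matrices: [1, x] and [1, x, dummies, x*dummies]."""
    x = np.log10(sub["dose"].to_numpy(float))
    X_null = np.column_stack([np.ones_like(x), x])
    cols = [np.ones_like(x), x]
    for pop in populations[1:]:
        d = (sub["population"] == pop).to_numpy(float)
        cols.append(d)
        cols.append(d * x)
    return X_null, np.column_stack(cols)


def _check_linearity(
    treatments: AssayTable,
    corrected: pd.Series | None,
    populations: list[str],
    alpha: float,
) -> None:
    failing = []
    for pop in populations:
        fit = fit_probit_glm(treatments, pop, corrected)
        if not linearity_test(fit, alpha).linear:
            failing.append(pop)
    if failing:
        raise DesignError(
            "population(s) failing the log-dose linearity test cannot enter a "
            f"dose-response comparison: {', '.join(failing)}"
        )


def _f_contrast(
    treatments: AssayTable,
    corrected: pd.Series | None,
    populations: list[str],
    alpha: float,
) -> ComparisonResult:
    mask = treatments.data["population"].isin(populations)
    sub = treatments.data[mask]
    if corrected is not None:
        y = np.asarray(corrected.loc[sub.index], dtype=float)
    else:
        y = (sub["dead"] / sub["total"]).to_numpy(float)
    w = sub["total"].to_numpy(float)
    X_null, X_full = _design_matrices(sub, populations)

    res_null = _irls(X_null, y, w)
    res_full = _irls(X_full, y, w)
    df_resid_full = res_full["n"] - res_full["k"]
    if df_resid_full <= 0:
        raise DesignError("complete model is saturated; add dose points or replicates")
    phi_full = res_full["pearson"] / df_resid_full
    df_num = res_full["k"] - res_null["k"]
    stat = (res_null["deviance"] - res_full["deviance"]) / (df_num * phi_full)
    stat = max(stat, 0.0)
    p = float(stats.f.sf(stat, df_num, df_resid_full))
    return ComparisonResult(
        populations=list(populations),
        stat=float(stat),
        df_num=df_num,
        df_den=df_resid_full,
        p_value=p,
        deviance_null=res_null["deviance"],
        deviance_full=res_full["deviance"],
        dispersion_full=float(phi_full),
        alpha=alpha,
    )


def global_test(
    treatments: AssayTable,
    corrected: pd.Series | None = None,
    populations: Sequence[str] | None = None,
    alpha: float = 0.05,
    check_linearity: bool = True,
    run_pairwise: bool = True,
) -> ComparisonResult:
    """Test whether populations differ in dose-response magnitude and/or slope.

    ``corrected`` is a mortality series aligned with ``treatments.data``
    (concatenate the per-population Abbott outputs); raw proportions are
    used when omitted.  When the global test is significant and more than
    two populations are involved, Holm-adjusted pairwise tests are
    attached to the result.

    Raises
    ------
    DesignError
        Fewer than two populations, or a population failing the
        linearity screen (named in the message).
    """
    pops = list(populations) if populations is not None else list(
        dict.fromkeys(treatments.data["population"])
    )
    if len(pops) < 2:
        raise DesignError("at least two populations are required for a comparison")
    if check_linearity:
        _check_linearity(treatments, corrected, pops, alpha)
    result = _f_contrast(treatments, corrected, pops, alpha)
    if run_pairwise and result.significant and len(pops) > 2:
        result.pairwise = pairwise_tests(
            treatments, corrected, pops, alpha, check_linearity=False
        )
    return result


def pairwise_tests(
    treatments: AssayTable,
    corrected: pd.Series | None = None,
    populations: Sequence[str] | None = None,
    alpha: float = 0.05,
    check_linearity: bool = True,
) -> pd.DataFrame:
    """Post hoc pairwise contrasts with Holm-adjusted p-values.

    Each unordered pair is refitted on its own data (null vs complete),
    keeping the dispersion estimate local to the pair.
    """
    pops = list(populations) if populations is not None else list(
        dict.fromkeys(treatments.data["population"])
    )
    if len(pops) < 2:
        raise DesignError("at least two populations are required")
    if check_linearity:
        _check_linearity(treatments, corrected, pops, alpha)
    rows = []
    for pop_i, pop_j in combinations(pops, 2):
        res = _f_contrast(treatments, corrected, [pop_i, pop_j], alpha)
        rows.append(
            {
                "pop_i": pop_i,
                "pop_j": pop_j,
                "stat": res.stat,
                "df_num": res.df_num,
                "df_den": res.df_den,
                "p_raw": res.p_value,
            }
        )
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p_raw"].tolist())
    return table
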