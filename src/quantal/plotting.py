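"""Probit graphs: probit-transformed mortality against log10 dose.

Populations with a linear log-dose response get their regression line and
(optionally) a confidence band; populations failing the linearity screen
are drawn as point-to-point segments only — plotting an invalid
regression would suggest a meaningless LD.  Points at exactly 0% or 100%
mortality have no finite probit and are omitted from the display (they
still enter the count-based fits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .errors import AssayError
from .io import AssayTable
from .probit import LinearityTest, ProbitFit

_DEFAULT_COLORS = ("#1f77b4", "#d62728", "#2ca02c", "#9467bd", "#ff7f0e", "#8c564b")
_DEFAULT_MARKERS = ("^", "s", "o", "D", "v", "P")


@dataclass
class PlotSpec:
    """Styling and content options for a probit graph."""

    conf_band: bool = True
    conf_level: float = 0.95
    colors: dict[str, str] = field(default_factory=dict)
    markers: dict[str, str] = field(default_factory=dict)
    segment_mode: bool = True  # draw nonlinear populations as segments
    band_alpha: float = 0.2
    dose_label: str = "dose"


def _style(spec: PlotSpec, populations: list[str]) -> dict[str, tuple[str, str]]:
    out = {}
    for i, pop in enumerate(populations):
        color = spec.colors.get(pop, _DEFAULT_COLORS[i % len(_DEFAULT_COLORS)])
        marker = spec.markers.get(pop, _DEFAULT_MARKERS[i % len(_DEFAULT_MARKERS)])
        out[pop] = (color, marker)
    return out


def probit_plot(
    fits: dict[str, ProbitFit],
    linearity: dict[str, LinearityTest] | None = None,
    spec: PlotSpec | None = None,
    path: str | None = None,
    ax: plt.Axes | None = None,
) -> plt.Figure:
    """Draw the probit graph for a set of fitted populations.

    Each fit carries its own observed (corrected) mortalities and doses.
    Artists are tagged with ``gid`` values ``points:<pop>``,
    ``regline:<pop>``, ``band:<pop>`` and ``segments:<pop>`` so the
    content is machine-checkable.  Returns the figure; writes ``path``
    when given (deterministic for fixed inputs).
    """
    spec = spec or PlotSpec()
    linearity = linearity or {}
    if ax is None:
        fig, ax = plt.subplots(figsize=(6.5, 4.5))
    else:
        fig = ax.figure

    populations = list(fits)
    styles = _style(spec, populations)
    plotted_any = False
    excluded: list[str] = []

    for pop, fit in fits.items():
        color, marker = styles[pop]
        y = np.asarray(fit.observed, dtype=float)
        x = np.log10(np.asarray(fit.dose, dtype=float))
        inside = (y > 0) & (y < 1)
        if not inside.any():
            excluded.append(pop)
        else:
            plotted_any = True
            ax.plot(
                x[inside],
                stats.norm.ppf(y[inside]),
                linestyle="none",
                marker=marker,
                color=color,
                label=pop,
                gid=f"points:{pop}",
            )
        lin = linearity.get(pop)
        is_linear = lin.linear if lin is not None else True
        if is_linear:
            grid = np.linspace(x.min(), x.max(), 100)
            line = fit.intercept + fit.slope * grid
            ax.plot(grid, line, color=color, gid=f"regline:{pop}")
            if spec.conf_band:
                t = stats.norm.ppf(0.5 + spec.conf_level / 2)
                V = fit.vcov  # already h-inflated by the fit
                se = np.sqrt(V[0, 0] + 2 * grid * V[0, 1] + grid**2 * V[1, 1])
                ax.fill_between(
                    grid,
                    line - t * se,
                    line + t * se,
                    color=color,
                    alpha=spec.band_alpha,
                    linewidth=0,
                    gid=f"band:{pop}",
                )
        elif spec.segment_mode:
            # pool replicates per dose for a readable broken line
            pooled = (
                pd.DataFrame({"x": x, "y": y, "w": fit.total})
                .groupby("x", sort=True)
                .apply(lambda g: np.average(g["y"], weights=g["w"]), include_groups=False)
            )
            py = pooled.to_numpy(float)
            ok = (py > 0) & (py < 1)
            ax.plot(
                pooled.index.to_numpy(float)[ok],
                stats.norm.ppf(py[ok]),
                linestyle="--",
                marker="",
                color=color,
                gid=f"segments:{pop}",
            )

    if not plotted_any:
        plt.close(fig)
        raise AssayError(
            "nothing to plot: no population has a point with mortality "
            "strictly between 0 and 1"
        )
    ax.set_xlabel(f"log10({spec.dose_label})")
    ax.set_ylabel("probit(corrected mortality)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
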