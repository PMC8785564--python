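"""Synthetic bioassay generator with known ground truth.

Mortality at dose d for a population with probit slope b and median
lethal dose LD50 follows the Abbott mixture

    p*(d) = c + (1 - c) * Phi( b * (log10 d - log10 LD50) ),

where c is the baseline (control) mortality.  Dead counts are binomial,
or beta-binomial with intra-class correlation rho to emulate
replicate-level overdispersion.  Control batches are generated at dose 0
with mortality c.  Identical seeds reproduce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abbott import apply_correction, estimate_control_mortality
from .doseresponse import estimate_ld, lethal_dose_point, resistance_ratio
from .errors import ConfigError, UnboundedIntervalError
from .io import AssayTable, split_controls
from .probit import fit_probit_glm


@dataclass
class SimulationConfig:
    """Ground truth and design of a simulated assay.

    ``populations`` maps each label to its probit slope (per log10 dose)
    and true LD50 in dose units.  ``overdispersion_rho`` is the
    beta-binomial intra-class correlation (0 = pure binomial).
    """

    populations: Sequence[tuple[str, float, float]]
    doses: Sequence[float]
    n_per_dose: int = 100
    replicates: int = 1
    control_mortality: float = 0.0
    control_n: int = 0
    overdispersion_rho: float = 0.0
    seed: int = 0
    stimulus: str | None = None

    def validate(self) -> None:
        if not self.populations:
            raise ConfigError("populations", "at least one population is required")
        for label, slope, ld50 in self.populations:
            if ld50 <= 0:
                raise ConfigError("populations", f"{label}: ld50 must be > 0")
        if not self.doses or any(d <= 0 for d in self.doses):
            raise ConfigError("doses", "doses must be positive (0 is reserved for controls)")
        if self.n_per_dose < 1:
            raise ConfigError("n_per_dose", "must be a positive integer")
        if self.replicates < 1:
            raise ConfigError("replicates", "must be a positive integer")
        if not 0 <= self.control_mortality < 1:
            raise ConfigError("control_mortality", "must lie in [0, 1)")
        if self.control_n < 0:
            raise ConfigError("control_n", "must be >= 0")
        if not 0 <= self.overdispersion_rho < 1:
            raise ConfigError("overdispersion_rho", "must lie in [0, 1)")


def true_mortality(
    dose, slope: float, ld50: float, control_mortality: float = 0.0
) -> np.ndarray:
    """Expected mortality p*(d) of the Abbott mixture model."""
    d = np.asarray(dose, dtype=float)
    phi = stats.norm.cdf(slope * (np.log10(d) - np.log10(ld50)))
    out = control_mortality + (1 - control_mortality) * phi
    return out if out.ndim else float(out)


def _draw_dead(rng: np.random.Generator, n: int, p: float, rho: float) -> int:
    if p <= 0:
        return 0
    if p >= 1:
        return n
    if rho == 0:
        return int(rng.binomial(n, p))
    s = (1 - rho) / rho  # beta "sample size": Var matches ICC rho
    p_batch = rng.beta(p * s, (1 - p) * s)
    return int(rng.binomial(n, p_batch))


def simulate_assay(config: SimulationConfig) -> AssayTable:
    """Generate one bioassay table under the configured ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    c = config.control_mortality
    rows = []
    for label, slope, ld50 in config.populations:
        for rep in range(1, config.replicates + 1):
            if config.control_n > 0:
                rows.append(
                    {
                        "population": label,
                        "dose": 0.0,
                        "total": config.control_n,
                        "dead": _draw_dead(
                            rng, config.control_n, c, config.overdispersion_rho
                        ),
                        "replicate": str(rep),
                    }
                )
            for dose in config.doses:
                p = float(true_mortality(dose, slope, ld50, c))
                rows.append(
                    {
                        "population": label,
                        "dose": float(dose),
                        "total": config.n_per_dose,
                        "dead": _draw_dead(
                            rng, config.n_per_dose, p, config.overdispersion_rho
                        ),
                        "replicate": str(rep),
                    }
                )
    data = pd.DataFrame(rows)
    if config.stimulus is not None:
        data["stimulus"] = config.stimulus
    return AssayTable(data)


@dataclass
class RecoverySummary:
    """Monte-Carlo parameter-recovery summary against the generative truth."""

    n_runs: int
    per_population: pd.DataFrame
    rr: pd.DataFrame = field(default_factory=pd.DataFrame)


def recovery_experiment(
    config: SimulationConfig,
    n_runs: int,
    conf_level: float = 0.95,
    abbott_threshold: float = 0.05,
) -> RecoverySummary:
    """Simulate -> correct -> fit -> LD/RR repeatedly; report bias, RMSE, coverage.

    Run r uses seed ``config.seed + r``.  Slope coverage uses the Wald
    interval slope +- z * SE; LD50 coverage uses the Fieller interval.
    When two or more populations are configured, the ratio of the first
    population's LD50 to the last's is tracked against its truth.
    """
    if n_runs < 1:
        raise ConfigError("n_runs", "must be >= 1")
    z = float(stats.norm.ppf(0.5 + conf_level / 2))
    truth = {label: (slope, ld50) for label, slope, ld50 in config.populations}
    records = {label: {"slope": [], "ld50": [], "slope_cover": [], "ld_cover": []}
               for label in truth}
    rr_est = []
    labels = [p[0] for p in config.populations]
    rr_truth = (
        truth[labels[0]][1] / truth[labels[-1]][1] if len(labels) > 1 else None
    )

    for r in range(n_runs):
        cfg = SimulationConfig(
            populations=config.populations,
            doses=config.doses,
            n_per_dose=config.n_per_dose,
            replicates=config.replicates,
            control_mortality=config.control_mortality,
            control_n=config.control_n,
            overdispersion_rho=config.overdispersion_rho,
            seed=config.seed + r,
            stimulus=config.stimulus,
        )
        table = simulate_assay(cfg)
        controls, treatments = split_controls(table)
        fits = {}
        for label in labels:
            corr = estimate_control_mortality(controls, label, abbott_threshold)
            corrected = apply_correction(treatments, corr)
            fits[label] = fit_probit_glm(
                treatments, label, corrected, abbott_applied=corr.applied
            )
        for label, fit in fits.items():
            slope_true, ld50_true = truth[label]
            rec = records[label]
            rec["slope"].append(fit.slope)
            rec["slope_cover"].append(
                abs(fit.slope - slope_true) <= z * fit.slope_se
            )
            try:
                est = estimate_ld(fit, 0.5, conf_level)
                rec["ld50"].append(est.ld)
                rec["ld_cover"].append(est.ci_low <= ld50_true <= est.ci_high)
            except UnboundedIntervalError:
                # g >= 1: the fiducial region is the whole dose axis, which
                # trivially contains the truth
                rec["ld50"].append(lethal_dose_point(fit, 0.5))
                rec["ld_cover"].append(True)
        if rr_truth is not None:
            rr_est.append(
                resistance_ratio(fits[labels[0]], fits[labels[-1]], 0.5, conf_level).rr
            )

    rows = []
    for label, rec in records.items():
        slope_true, ld50_true = truth[label]
        slopes = np.asarray(rec["slope"])
        lds = np.asarray(rec["ld50"])
        rows.append(
            {
                "population": label,
                "slope_true": slope_true,
                "slope_bias": float(slopes.mean() - slope_true),
                "slope_rmse": float(np.sqrt(np.mean((slopes - slope_true) ** 2))),
                "slope_coverage": float(np.mean(rec["slope_cover"])),
                "ld50_true": ld50_true,
                "ld50_bias": float(lds.mean() - ld50_true),
                "ld50_rmse": float(np.sqrt(np.mean((lds - ld50_true) ** 2))),
                "ld50_coverage": float(np.mean(rec["ld_cover"])),
            }
        )
    rr_frame = pd.DataFrame()
    if rr_truth is not None:
        rr_arr = np.asarray(rr_est)
        rr_frame = pd.DataFrame(
            [
                {
                    "pair": f"{labels[0]}/{labels[-1]}",
                    "rr_true": rr_truth,
                    "rr_mean": float(rr_arr.mean()),
                    "rr_bias": float(rr_arr.mean() - rr_truth),
                    "rr_rmse": float(np.sqrt(np.mean((rr_arr - rr_truth) ** 2))),
                }
            ]
        )
    return RecoverySummary(n_runs=n_runs, per_population=pd.DataFrame(rows), rr=rr_frame)
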