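"""End-to-end analysis: read -> controls -> correction -> fits -> LD/RR ->
comparison -> plot, with every decision recorded in a machine-readable
manifest.

This orchestration layer computes nothing itself; every number in the
report is reproducible by direct calls into the library modules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .abbott import ControlCorrection, apply_correction, estimate_control_mortality
from .compare import ComparisonResult, global_test
from .doseresponse import DEFAULT_LEVELS, choose_reference, ld_table
from .errors import AssayError
from .io import AssayTable, read_assay_table, split_controls
from .plotting import PlotSpec, probit_plot
from .probit import LinearityTest, ProbitFit, fit_probit_glm, linearity_test

logger = logging.getLogger("quantal")


@dataclass
class AnalysisOptions:
    ld_levels: Sequence[float] = DEFAULT_LEVELS
    conf_level: float = 0.95
    abbott_threshold: float = 0.05
    alpha: float = 0.05
    pooling: str = "replicate"
    use_h_in_g: bool = True
    conf_band: bool = True
    plot_format: str = "png"
    delimiter: str | None = None


@dataclass
class ReportBundle:
    """In-memory results plus the paths of everything written."""

    corrections: dict[str, ControlCorrection]
    fits: dict[str, ProbitFit]
    linearity: dict[str, LinearityTest]
    fit_table: pd.DataFrame
    ld_rr_table: pd.DataFrame
    comparison: ComparisonResult | None
    reference: str | None
    manifest: dict
    failures: dict[str, str] = field(default_factory=dict)
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def fit_table_frame(
    fits: dict[str, ProbitFit], linearity: dict[str, LinearityTest]
) -> pd.DataFrame:
    rows = []
    for pop, fit in fits.items():
        lin = linearity[pop]
        rows.append(
            {
                "population": pop,
                "slope": fit.slope,
                "slope_se": fit.slope_se,
                "intercept": fit.intercept,
                "intercept_se": fit.intercept_se,
                "chi2_p": lin.p_value,
                "h": fit.h,
                "n_points": fit.n_points,
                "abbott_applied": fit.abbott_applied,
            }
        )
    return pd.DataFrame(rows)


def analyze_table(table: AssayTable, options: AnalysisOptions | None = None) -> ReportBundle:
    """Run the full workflow on an in-memory table (no files written)."""
    options = options or AnalysisOptions()
    controls, treatments = split_controls(table)
    failures: dict[str, str] = {}
    corrections: dict[str, ControlCorrection] = {}
    fits: dict[str, ProbitFit] = {}
    linearity: dict[str, LinearityTest] = {}
    corrected_parts = []

    for pop in treatments.populations:
        try:
            corr = estimate_control_mortality(controls, pop, options.abbott_threshold)
            corrections[pop] = corr
            corrected = apply_correction(treatments, corr)
            corrected_parts.append(corrected)
            fit = fit_probit_glm(
                treatments, pop, corrected,
                pooling=options.pooling, abbott_applied=corr.applied,
            )
            fits[pop] = fit
            linearity[pop] = linearity_test(fit, options.alpha)
        except AssayError as err:
            failures[pop] = str(err)
            logger.warning("population %s failed: %s", pop, err)

    corrected_all = pd.concat(corrected_parts).sort_index() if corrected_parts else None
    fit_frame = fit_table_frame(fits, linearity)

    reference = None
    ld_rr = pd.DataFrame()
    if fits:
        positive = {p: f for p, f in fits.items() if f.slope > 0}
        if positive:
            reference = choose_reference(positive.values(), min(options.ld_levels))
            ld_rr = ld_table(
                list(positive.values()),
                levels=list(options.ld_levels),
                conf_level=options.conf_level,
                use_h_in_g=options.use_h_in_g,
                reference=reference,
            )
            nonlinear = {p for p, lin in linearity.items() if not lin.linear}
            ld_rr["recommended"] = ~ld_rr["population"].isin(nonlinear)

    comparison = None
    linear_pops = [p for p, lin in linearity.items() if lin.linear]
    if len(linear_pops) >= 2:
        try:
            comparison = global_test(
                treatments, corrected_all, linear_pops, alpha=options.alpha
            )
        except AssayError as err:
            failures["comparison"] = str(err)

    manifest = {
        "quantal_version": __version__,
        "populations": treatments.populations,
        "control_correction": {
            pop: {
                "control_mortality": corr.control_mortality,
                "applied": corr.applied,
                "threshold": corr.threshold,
                "replicate_heterogeneity_p": corr.replicate_heterogeneity_p,
            }
            for pop, corr in corrections.items()
        },
        "nonlinear_populations": [
            p for p, lin in linearity.items() if not lin.linear
        ],
        "reference_population": reference,
        "ld_levels": list(options.ld_levels),
        "conf_level": options.conf_level,
        "alpha": options.alpha,
        "comparison": None
        if comparison is None
        else {
            "populations": comparison.populations,
            "stat": comparison.stat,
            "df": [comparison.df_num, comparison.df_den],
            "p_value": comparison.p_value,
            "significant": comparison.significant,
        },
        "failures": failures,
    }
    return ReportBundle(
        corrections=corrections,
        fits=fits,
        linearity=linearity,
        fit_table=fit_frame,
        ld_rr_table=ld_rr,
        comparison=comparison,
        reference=reference,
        manifest=manifest,
        failures=failures,
    )


def run_analysis(
    input_path: str | Path,
    output_dir: str | Path,
    options: AnalysisOptions | None = None,
) -> ReportBundle:
    """File-to-files workflow: reads the assay table, writes the report bundle.

    Writes ``fits.csv``, ``ld_rr.csv``, ``comparison.csv`` (when a
    comparison ran), one probit plot per stimulus, ``manifest.json`` and
    ``run.log`` into ``output_dir``.  Partial results are still written
    when a population fails; the manifest lists the failures.
    """
    options = options or AnalysisOptions()
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    log_path = output_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("reading %s", input_path)
        table = read_assay_table(input_path, delimiter=options.delimiter)
        bundle = analyze_table(table, options)

        paths: dict[str, Path] = {}
        paths["fits"] = output_dir / "fits.csv"
        bundle.fit_table.to_csv(paths["fits"], index=False)
        if len(bundle.ld_rr_table):
            paths["ld_rr"] = output_dir / "ld_rr.csv"
            bundle.ld_rr_table.to_csv(paths["ld_rr"], index=False)
        if bundle.comparison is not None:
            paths["comparison"] = output_dir / "comparison.csv"
            comp = bundle.comparison
            frame = pd.DataFrame(
                [
                    {
                        "scope": "global",
                        "pop_i": "",
                        "pop_j": "",
                        "deviance_null": comp.deviance_null,
                        "deviance_full": comp.deviance_full,
                        "stat": comp.stat,
                        "df_num": comp.df_num,
                        "df_den": comp.df_den,
                        "p_raw": comp.p_value,
                        "p_holm": comp.p_value,
                    }
                ]
            )
            if len(comp.pairwise):
                pw = comp.pairwise.assign(scope="pairwise")
                frame = pd.concat([frame, pw], ignore_index=True)
            frame.to_csv(paths["comparison"], index=False)

        # one plot per stimulus when the optional column is present
        groups: list[tuple[str, list[str]]]
        if "stimulus" in table.data.columns:
            groups = [
                (str(s), list(dict.fromkeys(g["population"])))
                for s, g in table.data.groupby("stimulus", sort=False)
            ]
        else:
            groups = [("assay", list(bundle.fits))]
        for label, pops in groups:
            sub_fits = {p: bundle.fits[p] for p in pops if p in bundle.fits}
            if not sub_fits:
                continue
            spec = PlotSpec(conf_band=options.conf_band, conf_level=options.conf_level)
            plot_path = output_dir / f"probit_{label}.{options.plot_format}"
            try:
                fig = probit_plot(sub_fits, bundle.linearity, spec, path=str(plot_path))
                import matplotlib.pyplot as plt

                plt.close(fig)
                paths[f"plot:{label}"] = plot_path
            except AssayError as err:
                bundle.failures[f"plot:{label}"] = str(err)

        bundle.manifest["failures"] = bundle.failures
        paths["manifest"] = output_dir / "manifest.json"
        paths["manifest"].write_text(json.dumps(bundle.manifest, indent=2, default=str))
        bundle.paths = paths
        for pop, corr in bundle.corrections.items():
            logger.info(
                "population %s: control mortality %.4f (correction %s)",
                pop, corr.control_mortality,
                "applied" if corr.applied else "not applied",
            )
        if bundle.manifest["nonlinear_populations"]:
            logger.info(
                "nonlinear populations (segments only): %s",
                ", ".join(bundle.manifest["nonlinear_populations"]),
            )
        if bundle.reference:
            logger.info("reference population: %s", bundle.reference)
        return bundle
    finally:
        logger.removeHandler(handler)
        handler.close()
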