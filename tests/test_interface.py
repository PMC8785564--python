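import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import quantal as q
from quantal.cli import main
from quantal.errors import AssayError


def artists_with_gid(fig, prefix):
    out = []
    for ax in fig.axes:
        for artist in ax.lines + ax.collections:
            gid = artist.get_gid() or ""
            if gid.startswith(prefix):
                out.append(artist)
    return out


@pytest.fixture
def mixed_table(simulated_pair, nonlinear_table):
    """Two clean populations plus one plateau-shaped (nonlinear) one."""
    return q.AssayTable(
        pd.concat(
            [simulated_pair.data, nonlinear_table.data], ignore_index=True
        )
    )


class TestRunAnalysis:
    def test_published_subset_end_to_end(self, table1_path, tmp_path):
        bundle = q.run_analysis(table1_path, tmp_path / "out")
        assert bundle.ok
        assert set(bundle.fits) == {"KIS-ref", "DZOU"}
        # field strain LD50 lands at ~5.7e-3 dose units on this subset
        dzou = bundle.ld_rr_table.query("population == 'DZOU' and level == 0.5")
        assert 3e-3 < dzou["ld"].iloc[0] < 9e-3
        for key in ("fits", "ld_rr", "manifest"):
            assert bundle.paths[key].exists()
        assert (tmp_path / "out" / "probit_Temephos.png").exists()
        manifest = json.loads(bundle.paths["manifest"].read_text())
        assert manifest["reference_population"] == bundle.reference

    def test_single_population_has_no_comparison(self, tmp_path):
        cfg = q.SimulationConfig(
            populations=[("A", 4.0, 0.05)],
            doses=list(np.geomspace(0.0125, 0.2, 5)),
            n_per_dose=100,
            seed=3,
        )
        path = tmp_path / "single.csv"
        q.write_assay_table(q.simulate_assay(cfg), path)
        bundle = q.run_analysis(path, tmp_path / "out")
        assert bundle.comparison is None
        assert "comparison" not in bundle.paths

    def test_three_populations_rank_and_flag_resistant(self, tmp_path):
        cfg = q.SimulationConfig(
            populations=[("S1", 4.0, 0.05), ("S2", 4.0, 0.05), ("RST", 4.0, 0.5)],
            doses=list(np.geomspace(0.0125, 2.0, 6)),
            n_per_dose=200,
            seed=13,
        )
        path = tmp_path / "three.csv"
        q.write_assay_table(q.simulate_assay(cfg), path)
        bundle = q.run_analysis(path, tmp_path / "out")
        ld50 = bundle.ld_rr_table.query("level == 0.5").set_index("population")
        assert ld50["rr"].idxmax() == "RST"
        comp = bundle.comparison
        assert comp is not None and comp.significant
        pw = comp.pairwise
        flagged = pw[pw["p_holm"] < 0.05]
        # every significant pair involves the resistant strain, and both do
        assert ((flagged["pop_i"] == "RST") | (flagged["pop_j"] == "RST")).all()
        involving = pw[(pw["pop_i"] == "RST") | (pw["pop_j"] == "RST")]
        assert len(involving) == 2
        assert (involving["p_holm"] < 0.05).all()

    def test_report_numbers_match_direct_library_calls(self, table1_path, tmp_path):
        bundle = q.run_analysis(table1_path, tmp_path / "out")
        fits_csv = pd.read_csv(bundle.paths["fits"])
        table = q.read_assay_table(table1_path)
        controls, treatments = q.split_controls(table)
        for _, row in fits_csv.iterrows():
            fit = q.fit_probit_glm(treatments, row["population"])
            assert row["slope"] == pytest.approx(fit.slope, rel=1e-12)
            assert row["intercept"] == pytest.approx(fit.intercept, rel=1e-12)

    def test_partial_results_on_population_failure(self, tmp_path):
        # one population has a single dose and cannot be fitted
        good = q.simulate_assay(
            q.SimulationConfig(
                populations=[("OK", 4.0, 0.05)],
                doses=list(np.geomspace(0.0125, 0.2, 5)),
                n_per_dose=100,
                seed=1,
            )
        ).data
        bad = pd.DataFrame(
            {"population": "BAD", "dose": [0.1], "total": [50], "dead": [20],
             "replicate": "1"}
        )
        path = tmp_path / "mixed.csv"
        q.write_assay_table(
            q.AssayTable(pd.concat([good, bad], ignore_index=True)), path
        )
        bundle = q.run_analysis(path, tmp_path / "out")
        assert "BAD" in bundle.failures
        assert "OK" in bundle.fits
        manifest = json.loads(bundle.paths["manifest"].read_text())
        assert "BAD" in manifest["failures"]


class TestProbitPlot:
    def _fits(self, table):
        _, treatments = q.split_controls(table)
        fits, lins = {}, {}
        for pop in treatments.populations:
            fit = q.fit_probit_glm(treatments, pop)
            fits[pop] = fit
            lins[pop] = q.linearity_test(fit)
        return fits, lins

    def test_nonlinear_population_drawn_as_segments_only(self, mixed_table):
        import matplotlib.pyplot as plt

        fits, lins = self._fits(mixed_table)
        assert not lins["MIX"].linear
        fig = q.probit_plot(fits, lins)
        assert len(artists_with_gid(fig, "regline:MIX")) == 0
        assert len(artists_with_gid(fig, "band:MIX")) == 0
        assert len(artists_with_gid(fig, "segments:MIX")) == 1
        assert len(artists_with_gid(fig, "regline:SUS")) == 1
        plt.close(fig)

    def test_band_toggle(self, simulated_pair):
        import matplotlib.pyplot as plt

        fits, lins = self._fits(simulated_pair)
        fig_on = q.probit_plot(fits, lins, q.PlotSpec(conf_band=True))
        fig_off = q.probit_plot(fits, lins, q.PlotSpec(conf_band=False))
        assert len(artists_with_gid(fig_on, "band:")) == 2
        assert len(artists_with_gid(fig_off, "band:")) == 0
        # lines unchanged by the toggle
        for pop in fits:
            (line_on,) = artists_with_gid(fig_on, f"regline:{pop}")
            (line_off,) = artists_with_gid(fig_off, f"regline:{pop}")
            np.testing.assert_array_equal(
                line_on.get_ydata(), line_off.get_ydata()
            )
        plt.close(fig_on)
        plt.close(fig_off)

    def test_boundary_mortalities_omitted_from_display(self, simulated_pair):
        import matplotlib.pyplot as plt

        fits, lins = self._fits(simulated_pair)
        for pop, fit in fits.items():
            inside = (fit.observed > 0) & (fit.observed < 1)
            (pts,) = artists_with_gid(q.probit_plot({pop: fit}, lins), f"points:{pop}")
            assert len(pts.get_xdata()) == inside.sum()
        plt.close("all")

    def test_two_renders_are_byte_identical(self, simulated_pair, tmp_path):
        import matplotlib.pyplot as plt

        fits, lins = self._fits(simulated_pair)
        paths = [tmp_path / "a.png", tmp_path / "b.png"]
        for p in paths:
            fig = q.probit_plot(fits, lins, path=str(p))
            plt.close(fig)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_nothing_plottable_raises(self):
        fit = q.ProbitFit(
            population="X", slope=1.0, intercept=0.0, slope_se=0.1,
            intercept_se=0.1, vcov=np.eye(2) * 0.01, dispersion=1.0,
            n_points=2, df_resid=0, h=1.0,
            dose=np.array([0.1, 10.0]), total=np.array([10.0, 10.0]),
            observed=np.array([0.0, 1.0]), fitted=np.array([0.01, 0.99]),
        )
        with pytest.raises(AssayError, match="nothing to plot"):
            q.probit_plot({"X": fit})


class TestCLI:
    def test_simulate_then_analyze(self, tmp_path):
        runner = CliRunner()
        out_csv = tmp_path / "sim.csv"
        res = runner.invoke(
            main,
            [
                "simulate",
                "--populations", "SUS:4:0.05",
                "--populations", "RES:4:0.5",
                "--doses", "0.0125,0.05,0.2,0.8,2.0",
                "--n-per-dose", "150",
                "--control-mortality", "0.02",
                "--control-n", "100",
                "--seed", "5",
                "--out", str(out_csv),
            ],
        )
        assert res.exit_code == 0, res.output
        assert out_csv.exists()

        res = runner.invoke(
            main,
            ["analyze", "--input", str(out_csv),
             "--output-dir", str(tmp_path / "report")],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "report" / "fits.csv").exists()
        assert (tmp_path / "report" / "manifest.json").exists()

    def test_ld_levels_flag(self, table1_path, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            main,
            ["analyze", "--input", str(table1_path),
             "--output-dir", str(tmp_path / "r"), "--ld-levels", "10,90"],
        )
        assert res.exit_code == 0, res.output
        ld = pd.read_csv(tmp_path / "r" / "ld_rr.csv")
        assert set(ld["level"].round(2)) == {0.10, 0.90}

    def test_config_file_and_flag_precedence(self, table1_path, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("ld_levels: '50'\nconf_level: 0.9\n")
        runner = CliRunner()
        res = runner.invoke(
            main,
            ["analyze", "--input", str(table1_path),
             "--output-dir", str(tmp_path / "r"),
             "--config", str(cfg), "--ld-levels", "25"],
        )
        assert res.exit_code == 0, res.output
        ld = pd.read_csv(tmp_path / "r" / "ld_rr.csv")
        assert set(ld["level"]) == {0.25}  # flag beats config

    def test_plot_subcommand(self, table1_path, tmp_path):
        runner = CliRunner()
        out = tmp_path / "graph.png"
        res = runner.invoke(
            main, ["plot", "--input", str(table1_path), "--output", str(out)]
        )
        assert res.exit_code == 0, res.output
        assert out.exists()

    def test_compare_subcommand(self, simulated_pair, tmp_path):
        path = tmp_path / "pair.csv"
        q.write_assay_table(simulated_pair, path)
        runner = CliRunner()
        res = runner.invoke(main, ["compare", "--input", str(path)])
        assert res.exit_code == 0, res.output
        assert "global: F" in res.output

    def test_missing_column_is_clean_error(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("Strain,Dose,Total\nA,0.1,50\n")
        runner = CliRunner()
        res = runner.invoke(
            main, ["analyze", "--input", str(bad), "--output-dir", str(tmp_path / "o")]
        )
        assert res.exit_code != 0
        assert "dead" in res.output.lower()
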