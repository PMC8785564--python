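import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import quantal as q

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Published example subset: three doses of one susceptible strain and two
# replicates of a field strain exposed to temephos.
TABLE1_CSV = """Insecticide,Strain,Dose,Total,Dead,Replicate,Date
Temephos,KIS-ref,0.002,97,47,1,2011-01-26
Temephos,KIS-ref,0.003,96,68,1,2011-01-26
Temephos,KIS-ref,0.004,98,89,1,2011-01-26
Temephos,DZOU,0.001,97,4,1,2010-08-04
Temephos,DZOU,0.002,97,20,1,2010-08-04
Temephos,DZOU,0.004,100,31,1,2010-08-04
Temephos,DZOU,0.007,95,52,1,2010-08-04
Temephos,DZOU,0.002,97,24,2,2010-08-04
Temephos,DZOU,0.004,100,35,2,2010-08-04
Temephos,DZOU,0.007,95,56,2,2010-08-04
Temephos,DZOU,0.010,97,69,2,2010-08-04
"""


@pytest.fixture
def table1_path(tmp_path):
    path = tmp_path / "temephos.csv"
    path.write_text(TABLE1_CSV)
    return path


@pytest.fixture
def table1(table1_path):
    return q.read_assay_table(table1_path)


@pytest.fixture
def simulated_pair():
    """Two populations with a true LD50 ratio of 10, clean binomial data."""
    cfg = q.SimulationConfig(
        populations=[("SUS", 4.0, 0.05), ("RES", 4.0, 0.5)],
        doses=list(np.geomspace(0.0125, 2.0, 6)),
        n_per_dose=200,
        seed=20260925,
    )
    return q.simulate_assay(cfg)


@pytest.fixture
def nonlinear_table():
    """A plateau-shaped response that a straight probit line cannot fit.

    Mortality jumps to ~50% then stalls across two decades of dose before
    climbing again, the signature of a mixed (part-resistant) population.
    """
    import pandas as pd

    doses = [0.01, 0.03, 0.1, 0.3, 1.0, 3.0]
    mort = [0.02, 0.50, 0.52, 0.54, 0.56, 0.98]
    n = 400
    data = pd.DataFrame(
        {
            "population": "MIX",
            "dose": doses,
            "total": n,
            "dead": [int(round(m * n)) for m in mort],
            "replicate": "1",
        }
    )
    return q.AssayTable(data)


def make_fit(
    slope,
    intercept,
    slope_se=0.0,
    intercept_se=0.0,
    cov_ab=0.0,
    h=1.0,
    df_resid=3,
    population="POP",
):
    """Assemble a ProbitFit from summary statistics (no data attached)."""
    from scipy import stats

    vcov = np.array([[intercept_se**2, cov_ab], [cov_ab, slope_se**2]])
    het_p = (
        float(stats.chi2.sf(h * df_resid, df_resid)) if df_resid > 0 and h > 1 else 1.0
    )
    return q.ProbitFit(
        population=population,
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        intercept_se=intercept_se,
        vcov=vcov,
        dispersion=h,
        n_points=df_resid + 2,
        df_resid=df_resid,
        h=h,
        het_p=het_p,
    )
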