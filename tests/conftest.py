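import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import quadmtmm as qm
from quadmtmm.lms_quadratic import QuadraticStructural
from quadmtmm.simulate import SimulationDesign

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: application measurement model reused across tests
LOADINGS = np.array([1.0, 1.23, 1.09])
INTERCEPTS = np.array([0.0, 0.03, 0.09])


@pytest.fixture(scope="session")
def table1():
    """Published 6x6 summary statistics of the two-rater inattention data."""
    return qm.load_fixture("table1_moments")


@pytest.fixture(scope="session")
def app_fits(table1):
    """TMU + linear LD/LM fits to the published moments (shared, expensive)."""
    tmu_est, tmu_res = qm.fit_tmu(table1, I=3, K=2, error_pairs="identical")
    ld, ld_res = qm.fit_linear_ld(table1, reference=1, error_pairs="identical")
    lm, lm_res = qm.fit_linear_lm(table1, error_pairs="identical")
    return {
        "tmu": (tmu_est, tmu_res),
        "ld": (ld, ld_res),
        "lm": (lm, lm_res),
    }


def ld_quadratic_population():
    """Quadratic LD application estimates as a simulation population."""
    return QuadraticStructural(
        b0=0.24, b1=-0.33, b2=0.06, var_z=0.23, mean_x=0.95, var_x=0.69,
        variant="ld", reference=1,
    )


def lm_quadratic_population():
    return QuadraticStructural(
        b0=-0.034, b1=0.11, b2=-0.036, var_z=0.06, mean_x=0.93, var_x=0.64,
        variant="lm",
    )


@pytest.fixture()
def small_ld_table():
    """N=200 draw from the quadratic LD population, fixed seed."""
    design = SimulationDesign(
        structural=ld_quadratic_population(), n=200, replications=1,
        reliability=0.8, master_seed=11,
    )
    return qm.simulate_dataset(design, 0)
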