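"""Monte Carlo machinery: synthetic MTMM data, power and Type-I error.

The generator draws the latent predictor ``t`` from its normal
population, forms the method effect ``M = b0 + b1 t + b2 t^2 + zeta``,
maps ``(t, M)`` to the two method-specific trait scores (LD:
``T1 = t, T2 = t + M``; LM: ``T1 = t - M*, T2 = t + M*``), and emits
parcel indicators through the invariant measurement model with error
variances chosen so every indicator hits a target reliability (squared
completely standardized loading).

Default population parameters are the two-rater inattention application
estimates: measurement loadings (1, 1.23, 1.09) and intercepts
(0, 0.03, 0.09); LD predictor N(0.95, 0.69) with linear regression
(0.18, -0.16) and residual variance 0.23; LM predictor N(0.93, 0.64)
with residual variance 0.06.  Quadratic effect sizes map Cohen's
f2 = 0.02 / 0.15 / 0.35 (small / medium / large) onto ``b2`` through the
incremental variance 2 b2^2 sigma^4 explained by the squared term.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import IndicatorTable
from .lms_quadratic import QuadraticStructural, fit_quadratic_ld, fit_quadratic_lm
from .sem_core import SemError

__all__ = [
    "SimulationDesign",
    "MonteCarloResult",
    "application_population",
    "effect_size_to_beta2",
    "latent_trait_moments",
    "reliability_error_variances",
    "simulate_dataset",
    "run_power_cell",
    "run_type1_cell",
    "COHEN_F2",
]

COHEN_F2 = {"small": 0.02, "medium": 0.15, "large": 0.35}

#: application measurement model (three parcels, strong invariance)
APP_LOADINGS = np.array([1.0, 1.23, 1.09])
APP_INTERCEPTS = np.array([0.0, 0.03, 0.09])

#: application structural estimates used as simulation populations
APP_LD_LINEAR = dict(b0=0.18, b1=-0.16, var_z=0.23, mean_x=0.95, var_x=0.69)
APP_LD_QUADRATIC = dict(b0=0.24, b1=-0.33, b2=0.06, var_z=0.23, mean_x=0.95, var_x=0.69)
APP_LM_LINEAR = dict(b0=0.011, b1=0.001, var_z=0.06, mean_x=0.93, var_x=0.64)
APP_LM_QUADRATIC = dict(b0=-0.034, b1=0.11, b2=-0.036, var_z=0.06, mean_x=0.93, var_x=0.64)


@dataclass
class SimulationDesign:
    """One Monte Carlo cell."""

    structural: QuadraticStructural
    n: int
    replications: int
    reliability: float = 0.8
    alpha: float = 0.05
    master_seed: int = 20190353
    effect_size: str = "null"  # null | small | medium | large
    loadings: np.ndarray = field(default_factory=lambda: APP_LOADINGS.copy())
    intercepts: np.ndarray = field(default_factory=lambda: APP_INTERCEPTS.copy())

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("need at least one replication")
        if not 0 < self.reliability < 1:
            raise ValueError("reliability must lie in (0, 1)")
        if self.n < 50:
            raise ValueError("N per replication must be at least 50")


@dataclass
class MonteCarloResult:
    design: SimulationDesign
    rejection_rate: float
    rejection_ci: tuple
    n_converged: int
    n_rejected: int
    parameter_means: dict
    parameter_bias: dict
    parameter_rmse: dict
    seeds: list
    runtime_seconds: float
    high_nonconvergence: bool


def effect_size_to_beta2(
    label: str, mean_x: float, var_x: float, var_z: float, sign: float = 1.0
) -> tuple[float, dict]:
    """Cohen-f2 mapping: ``b2`` explaining ``f2 * Var(zeta)`` extra variance.

    For a normal predictor the squared term residualized on the linear
    term has variance ``2 sigma^4`` (independent of the mean), so the
    quadratic term's incremental explained variance is ``2 b2^2 sigma^4``
    and ``f2 = 2 b2^2 sigma^4 / Var(zeta)``.  Returns (b2, mapping log).
    """
    if label == "null":
        return 0.0, {"label": "null", "f2": 0.0, "beta2": 0.0}
    if label not in COHEN_F2:
        raise ValueError(f"unknown effect size {label!r}")
    if var_x <= 0:
        raise ValueError("predictor variance must be positive")
    f2 = COHEN_F2[label]
    b2 = float(np.copysign(np.sqrt(f2 * var_z / (2.0 * var_x**2)), sign))
    return b2, {"label": label, "f2": f2, "beta2": b2, "var_x": var_x, "var_z": var_z}


def application_population(variant: str = "ld", effect_size: str = "null") -> QuadraticStructural:
    """Population structural parameters for a simulation cell.

    Null cells use the linear application estimates with ``b2 = 0``;
    power cells keep the quadratic application intercept/slope and set
    ``b2`` from the Cohen mapping (sign matching the application fit).
    """
    if variant == "ld":
        base = APP_LD_LINEAR if effect_size == "null" else APP_LD_QUADRATIC
        sign = 1.0
    elif variant == "lm":
        base = APP_LM_LINEAR if effect_size == "null" else APP_LM_QUADRATIC
        sign = -1.0
    else:
        raise ValueError("variant must be 'ld' or 'lm'")
    b2, _ = effect_size_to_beta2(effect_size, base["mean_x"], base["var_x"], base["var_z"], sign)
    return QuadraticStructural(
        b0=base["b0"], b1=base["b1"], b2=b2, var_z=base["var_z"],
        mean_x=base["mean_x"], var_x=base["var_x"], variant=variant, reference=1,
    )


def latent_trait_moments(struct: QuadraticStructural) -> dict:
    """Exact normal-theory moments of (t, M, T1, T2) under the population."""
    mu, s2 = struct.mean_x, struct.var_x
    b0, b1, b2, vz = struct.b0, struct.b1, struct.b2, struct.var_z
    e_m = b0 + b1 * mu + b2 * (mu * mu + s2)
    var_t2_term = 2.0 * s2 * s2 + 4.0 * mu * mu * s2  # Var(t^2)
    cov_t_t2 = 2.0 * mu * s2
    var_m = b1 * b1 * s2 + b2 * b2 * var_t2_term + 2.0 * b1 * b2 * cov_t_t2 + vz
    cov_tm = b1 * s2 + b2 * cov_t_t2
    u = struct.method_signs
    var_T = np.array([s2 + u[m] ** 2 * var_m + 2.0 * u[m] * cov_tm for m in range(2)])
    mean_T = np.array([mu + u[m] * e_m for m in range(2)])
    return {"e_m": e_m, "var_m": var_m, "cov_tm": cov_tm, "mean_T": mean_T, "var_T": var_T}


def reliability_error_variances(
    loadings: np.ndarray, var_T: np.ndarray, reliability: float
) -> np.ndarray:
    """Error variances giving each indicator the target reliability.

    reliability = lam^2 Var(T_m) / (lam^2 Var(T_m) + theta), solved for
    theta; positive whenever reliability is in (0, 1).
    """
    loadings = np.asarray(loadings, float)
    theta = np.concatenate(
        [loadings**2 * var_T[m] * (1.0 - reliability) / reliability for m in range(2)]
    )
    assert np.all(theta > 0)
    return theta


def simulate_dataset(design: SimulationDesign, replication_index: int = 0,
                     return_latents: bool = False):
    """One synthetic dataset, deterministic in (master_seed, replication).

    With ``return_latents=True`` also returns the drawn latent scores
    ``{"t", "m", "T1", "T2"}`` for oracle checks.
    """
    rng = np.random.default_rng([design.master_seed, replication_index])
    struct = design.structural
    n, I = design.n, design.loadings.size
    t = struct.mean_x + np.sqrt(struct.var_x) * rng.standard_normal(n)
    zeta = np.sqrt(struct.var_z) * rng.standard_normal(n) if struct.var_z > 0 else 0.0
    m = struct.predict(t) + zeta
    u = struct.method_signs
    T = np.column_stack([t + u[0] * m, t + u[1] * m])
    moms = latent_trait_moments(struct)
    theta = reliability_error_variances(design.loadings, moms["var_T"], design.reliability)
    eps = rng.standard_normal((n, 2 * I)) * np.sqrt(theta)
    lam, nu = design.loadings, design.intercepts
    y = np.empty((n, 2 * I))
    for meth in range(2):
        y[:, meth * I:(meth + 1) * I] = nu + np.outer(T[:, meth], lam) + eps[:, meth * I:(meth + 1) * I]
    layout = [(i, meth) for meth in (1, 2) for i in range(1, I + 1)]
    table = IndicatorTable(y, layout)
    if return_latents:
        return table, {"t": t, "m": np.asarray(m), "T1": T[:, 0], "T2": T[:, 1]}
    return table


def _run_cell(design: SimulationDesign) -> MonteCarloResult:
    start = time.perf_counter()
    rejections = 0
    converged = 0
    b2_hats, b1_hats, b0_hats = [], [], []
    seeds = []
    for rep in range(design.replications):
        seeds.append((design.master_seed, rep))
        table = simulate_dataset(design, rep)
        try:
            if design.structural.variant == "ld":
                fit = fit_quadratic_ld(table, reference=design.structural.reference,
                                       compute_se=False)
            else:
                fit = fit_quadratic_lm(table, compute_se=False)
        except SemError:
            continue
        if not fit.converged or fit.heywood:
            continue
        converged += 1
        if fit.lr_p_value < design.alpha:
            rejections += 1
        b2_hats.append(fit.structural.b2)
        b1_hats.append(fit.structural.b1)
        b0_hats.append(fit.structural.b0)
    if converged == 0:
        raise SemError("no replication converged in this cell")
    rate = rejections / converged
    ci = stats.binomtest(rejections, converged).proportion_ci(0.95)
    truth = {"b0": design.structural.b0, "b1": design.structural.b1,
             "b2": design.structural.b2}
    hats = {"b0": np.array(b0_hats), "b1": np.array(b1_hats), "b2": np.array(b2_hats)}
    means = {k: float(v.mean()) for k, v in hats.items()}
    bias = {k: means[k] - truth[k] for k in means}
    rmse = {k: float(np.sqrt(np.mean((hats[k] - truth[k]) ** 2))) for k in hats}
    return MonteCarloResult(
        design=design,
        rejection_rate=float(rate),
        rejection_ci=(float(ci.low), float(ci.high)),
        n_converged=converged,
        n_rejected=rejections,
        parameter_means=means,
        parameter_bias=bias,
        parameter_rmse=rmse,
        seeds=seeds,
        runtime_seconds=time.perf_counter() - start,
        high_nonconvergence=converged < 0.8 * design.replications,
    )


def run_power_cell(design: SimulationDesign) -> MonteCarloResult:
    """Rejection rate of the quadratic LR test under a non-null population."""
    if design.effect_size == "null" or design.structural.b2 == 0:
        raise ValueError("power cells need a nonzero quadratic effect")
    return _run_cell(design)


def run_type1_cell(design: SimulationDesign) -> MonteCarloResult:
    """Empirical alpha of the quadratic LR test under the null population."""
    if design.structural.b2 != 0:
        raise ValueError("Type-I cells require b2 = 0 in the population")
    return _run_cell(design)


def make_design(
    variant: str = "ld",
    effect_size: str = "null",
    n: int = 250,
    reliability: float = 0.8,
    replications: int = 200,
    master_seed: int = 20190353,
    alpha: float = 0.05,
) -> SimulationDesign:
    """Convenience builder for an application-population cell."""
    struct = application_population(variant, effect_size)
    return SimulationDesign(
        structural=struct, n=n, replications=replications, reliability=reliability,
        alpha=alpha, master_seed=master_seed, effect_size=effect_size,
    )
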