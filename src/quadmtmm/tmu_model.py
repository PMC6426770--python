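"""Trait-method-unit (TMU) measurement models.

One trait measured by ``K`` methods, ``I`` parcel indicators per method:
each method gets its own trait factor ``T_m`` with freely estimated
means, variances and covariances.  Under strong factorial invariance the
loadings and intercepts are equated across methods, which is the
prerequisite for forming latent difference scores downstream.  Residual
covariances between identical parcels across methods can be freed to
absorb parcel-specific variance shared by raters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import IndicatorTable, MomentSummary, sample_moments
from .sem_core import FitResult, LinearModelSpec, delta_se, fit_ml, lr_test

__all__ = [
    "TmuEstimates",
    "build_tmu_spec",
    "identical_parcel_pairs",
    "fit_tmu",
    "invariance_test",
    "InvarianceComparison",
]


def identical_parcel_pairs(I: int, K: int) -> list[tuple[int, int, int]]:
    """All (indicator, method, method') pairs linking identical parcels."""
    return [(i, m, mp) for i in range(1, I + 1) for m in range(1, K + 1) for mp in range(m + 1, K + 1)]


def _check_pairs(pairs, I, K) -> None:
    for i, m, mp in pairs:
        if m == mp:
            raise ValueError(f"error pair ({i},{m},{mp}) references the same method")
        if not (1 <= i <= I and 1 <= m <= K and 1 <= mp <= K):
            raise ValueError(f"error pair ({i},{m},{mp}) out of range for I={I}, K={K}")


def build_tmu_spec(
    I: int,
    K: int,
    invariance: str = "strong",
    error_pairs: list[tuple[int, int, int]] | str | None = None,
    scaling_indicator: int = 1,
) -> LinearModelSpec:
    """Pattern spec for the basic TMU model (columns ordered method-major).

    Column ``(m-1)*I + (i-1)`` is indicator ``i`` of method ``m``.  The
    scaling indicator's loading is fixed to 1 and its intercept to 0 in
    every method, identifying the scale and mean of each trait factor.
    """
    if I < 2:
        raise ValueError("under-identified TMU: need at least 2 indicators per method")
    if K < 2:
        raise ValueError("need at least 2 methods")
    if invariance not in ("strong", "configural"):
        raise ValueError("invariance must be 'strong' or 'configural'")
    if not (1 <= scaling_indicator <= I):
        raise ValueError("scaling indicator out of range")
    if error_pairs in ("identical", True):
        error_pairs = identical_parcel_pairs(I, K)
    error_pairs = list(error_pairs or [])
    _check_pairs(error_pairs, I, K)

    p = I * K
    lam = [[0.0] * K for _ in range(p)]
    nu: list = [0.0] * p
    for m in range(1, K + 1):
        for i in range(1, I + 1):
            row = (m - 1) * I + (i - 1)
            if i == scaling_indicator:
                lam[row][m - 1] = 1.0
                nu[row] = 0.0
            else:
                suffix = f"{i}" if invariance == "strong" else f"{i}_m{m}"
                lam[row][m - 1] = f"lam_{suffix}"
                nu[row] = f"alpha_{suffix}"
    kappa = [f"mean_T{m}" for m in range(1, K + 1)]
    psi = [[None] * K for _ in range(K)]
    for m in range(K):
        for mp in range(K):
            lo, hi = sorted((m, mp))
            psi[m][mp] = f"var_T{m + 1}" if m == mp else f"cov_T{lo + 1}{hi + 1}"
    theta = [[0.0] * p for _ in range(p)]
    for m in range(1, K + 1):
        for i in range(1, I + 1):
            row = (m - 1) * I + (i - 1)
            theta[row][row] = f"theta_{i}_{m}"
    for i, m, mp in error_pairs:
        r1 = (m - 1) * I + (i - 1)
        r2 = (mp - 1) * I + (i - 1)
        theta[r1][r2] = theta[r2][r1] = f"theta_cov_{i}_{m}{mp}"
    names = [f"P{i}_M{m}" for m in range(1, K + 1) for i in range(1, I + 1)]
    return LinearModelSpec(lam=lam, nu=nu, theta=theta, kappa=kappa, psi=psi, var_names=names)


@dataclass
class TmuEstimates:
    """Table-style estimate set from a fitted TMU model."""

    I: int
    K: int
    loadings: dict
    intercepts: dict
    trait_means: np.ndarray
    trait_cov: np.ndarray
    error_vars: dict
    error_covs: dict
    phi: float
    phi_se: float
    standardized: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)

    @property
    def trait_vars(self) -> np.ndarray:
        return np.diag(self.trait_cov)


def _as_moments(data) -> MomentSummary:
    if isinstance(data, IndicatorTable):
        return sample_moments(data.sorted())
    if isinstance(data, MomentSummary):
        return data
    raise TypeError("expected an IndicatorTable or MomentSummary")


def _standardize_tmu(spec: LinearModelSpec, result: FitResult, I: int, K: int) -> dict:
    def values(x):
        lam, nu, kappa, psi, theta = spec.matrices(x)
        sigma = lam @ psi @ lam.T + theta
        sd_obs = np.sqrt(np.diag(sigma))
        sd_lat = np.sqrt(np.diag(psi))
        out = {}
        for m in range(K):
            for i in range(I):
                row = m * I + i
                out[f"std_lam_{i + 1}_m{m + 1}"] = lam[row, m] * sd_lat[m] / sd_obs[row]
                out[f"std_theta_{i + 1}_{m + 1}"] = theta[row, row] / sigma[row, row]
        for m in range(K):
            for mp in range(m + 1, K):
                out[f"corr_T{m + 1}{mp + 1}"] = psi[m, mp] / (sd_lat[m] * sd_lat[mp])
        for i, j, idx, _ in spec._entries["theta"]:
            if i < j:
                name = spec.free_names[idx]
                out[f"std_{name}"] = theta[i, j] / np.sqrt(theta[i, i] * theta[j, j])
        return out

    point = values(result.theta)
    ses = {}
    for key in point:
        ses[key] = delta_se(lambda x, k=key: values(x)[k], result)
    return {"estimates": point, "se": ses}


def fit_tmu(data, spec: LinearModelSpec | None = None, I: int | None = None,
            K: int | None = None, **build_kwargs):
    """Fit the TMU model; returns ``(TmuEstimates, FitResult)``.

    Either pass a prebuilt ``spec`` or the design size ``I``/``K`` plus
    any :func:`build_tmu_spec` keyword arguments.
    """
    moments = _as_moments(data)
    if spec is None:
        if isinstance(data, IndicatorTable):
            I, K = data.n_indicators, data.n_methods
        if I is None or K is None:
            raise ValueError("pass spec or the design size I, K")
        spec = build_tmu_spec(I, K, **build_kwargs)
    else:
        I = moments.p // len(spec.lam[0])
        K = len(spec.lam[0])
    if moments.p != I * K:
        raise ValueError("data dimensions do not match the TMU design")
    result = fit_ml(spec, moments)

    lam, nu, kappa, psi, theta = spec.matrices(result.theta)
    std = _standardize_tmu(spec, result, I, K)
    loadings = {f"lam_{i + 1}_m{m + 1}": float(lam[m * I + i, m]) for m in range(K) for i in range(I)}
    intercepts = {f"alpha_{i + 1}_m{m + 1}": float(nu[m * I + i]) for m in range(K) for i in range(I)}
    error_vars = {f"theta_{i + 1}_{m + 1}": float(theta[m * I + i, m * I + i])
                  for m in range(K) for i in range(I)}
    error_covs = {}
    for i, j, idx, _ in spec._entries["theta"]:
        if i < j:
            error_covs[spec.free_names[idx]] = float(theta[i, j])

    def phi_fun(x):
        _, _, _, psi_x, _ = spec.matrices(x)
        return psi_x[0, 1] / np.sqrt(psi_x[0, 0] * psi_x[1, 1])

    phi = float(phi_fun(result.theta)) if K >= 2 else np.nan
    phi_se = delta_se(phi_fun, result) if K >= 2 else np.nan
    estimates = TmuEstimates(
        I=I,
        K=K,
        loadings=loadings,
        intercepts=intercepts,
        trait_means=kappa.copy(),
        trait_cov=psi.copy(),
        error_vars=error_vars,
        error_covs=error_covs,
        phi=phi,
        phi_se=phi_se,
        standardized=std["estimates"],
        se={**result.se, **{k: v for k, v in std["se"].items()}},
    )
    return estimates, result


@dataclass
class InvarianceComparison:
    chi_configural: float
    df_configural: int
    chi_strong: float
    df_strong: int
    delta_chi: float
    delta_df: int
    p_value: float
    strong_retained: bool


def invariance_test(data, I: int, K: int,
                    error_pairs=None, alpha: float = 0.05) -> InvarianceComparison:
    """Configural vs strong invariance via the chi-square difference test."""
    moments = _as_moments(data)
    res_c = fit_ml(build_tmu_spec(I, K, "configural", error_pairs), moments)
    res_s = fit_ml(build_tmu_spec(I, K, "strong", error_pairs), moments)
    delta_df = res_s.stats.df - res_c.stats.df
    if delta_df <= 0:
        raise ValueError("models are not nested (strong must restrict configural)")
    stat, p = lr_test(res_s.stats.log_likelihood, res_c.stats.log_likelihood, delta_df)
    return InvarianceComparison(
        chi_configural=res_c.stats.chi_square,
        df_configural=res_c.stats.df,
        chi_strong=res_s.stats.chi_square,
        df_strong=res_s.stats.df,
        delta_chi=stat,
        delta_df=delta_df,
        p_value=p,
        strong_retained=p >= alpha,
    )
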