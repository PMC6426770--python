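"""Latent-difference (LD) and latent-means (LM) parameterizations.

Both models re-express the two-method TMU model with an explicit method
factor and are exact reparameterizations of it in the linear case:

* LD: pick a reference method ``r``; the method factor is the latent
  difference ``M = T_o - T_r`` and is regressed on the reference trait,
  ``M = b0 + b1 T_r + zeta``.
* LM: the common trait is the average ``T = (T1 + T2)/2``; the method
  factor ``M* = (T2 - T1)/2`` carries loadings -1 (method 1) and +1
  (method 2) and is regressed on ``T``.

Because ``M* = M/2``, every LM method-factor moment is a quartered or
halved version of its LD counterpart.  Fit (chi-square, log-likelihood)
is identical across TMU, linear LD, and linear LM on the same data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import IndicatorTable
from .sem_core import FitResult, LinearModelSpec, StructuralBlock, delta_se, fit_ml
from .tmu_model import TmuEstimates, _as_moments, _check_pairs, identical_parcel_pairs

logger = logging.getLogger("quadmtmm")

__all__ = [
    "LdParams",
    "LmParams",
    "build_ld_spec",
    "build_lm_spec",
    "ld_from_tmu",
    "lm_from_tmu",
    "fit_linear_ld",
    "fit_linear_lm",
    "factor_scores",
]


@dataclass
class LdParams:
    """Structural parameters of the linear LD model (two methods)."""

    reference: int
    mean_t: float
    var_t: float
    b0: float
    b1: float
    var_z: float
    e_m: float
    var_m: float
    cov_tm: float
    corr_tm: float
    r2: float
    se: dict | None = None

    def validate(self) -> None:
        assert abs(self.var_m - (self.b1**2 * self.var_t + self.var_z)) < 1e-8
        assert abs(self.e_m - (self.b0 + self.b1 * self.mean_t)) < 1e-8
        assert abs(self.corr_tm) <= 1 + 1e-10


@dataclass
class LmParams:
    """Structural parameters of the linear LM model (two methods)."""

    mean_t: float
    var_t: float
    b0: float
    b1: float
    var_z: float
    e_m: float
    var_m: float
    cov_tm: float
    corr_tm: float
    r2: float
    loading_signs: tuple = (-1.0, 1.0)
    se: dict | None = None


def _structural_derived(mean_t, var_t, b0, b1, var_z):
    e_m = b0 + b1 * mean_t
    cov_tm = b1 * var_t
    var_m = b1**2 * var_t + var_z
    corr = cov_tm / np.sqrt(var_t * var_m) if var_m > 0 else 0.0
    r2 = b1**2 * var_t / var_m if var_m > 0 else 0.0
    return e_m, var_m, cov_tm, corr, r2


def ld_from_tmu(tmu: TmuEstimates, reference_method: int, target_method: int | None = None) -> LdParams:
    """Closed-form LD mapping from fitted TMU latent moments."""
    K = tmu.K
    if K < 2:
        raise ValueError("need at least two methods")
    if not (1 <= reference_method <= K):
        raise ValueError("invalid reference method")
    if target_method is None:
        target_method = next(m for m in range(1, K + 1) if m != reference_method)
    r, o = reference_method - 1, target_method - 1
    var_r = tmu.trait_cov[r, r]
    if var_r <= 0:
        raise ValueError("reference trait variance must be positive")
    e_m = tmu.trait_means[o] - tmu.trait_means[r]
    var_m = tmu.trait_cov[r, r] + tmu.trait_cov[o, o] - 2 * tmu.trait_cov[r, o]
    cov_tm = tmu.trait_cov[r, o] - var_r
    b1 = cov_tm / var_r
    b0 = e_m - b1 * tmu.trait_means[r]
    var_z = var_m - b1**2 * var_r
    corr = cov_tm / np.sqrt(var_r * var_m) if var_m > 1e-14 else 0.0
    r2 = b1**2 * var_r / var_m if var_m > 1e-14 else 0.0
    return LdParams(
        reference=reference_method,
        mean_t=float(tmu.trait_means[r]),
        var_t=float(var_r),
        b0=float(b0),
        b1=float(b1),
        var_z=float(var_z),
        e_m=float(e_m),
        var_m=float(var_m),
        cov_tm=float(cov_tm),
        corr_tm=float(corr),
        r2=float(r2),
    )


def lm_from_tmu(tmu: TmuEstimates) -> LmParams:
    """Closed-form LM mapping; defined here for exactly two methods."""
    if tmu.K != 2:
        raise ValueError("LM mapping implemented for exactly 2 methods")
    m1, m2 = tmu.trait_means[:2]
    v1, v2 = tmu.trait_cov[0, 0], tmu.trait_cov[1, 1]
    c12 = tmu.trait_cov[0, 1]
    mean_t = (m1 + m2) / 2
    var_t = (v1 + v2 + 2 * c12) / 4
    e_m = (m2 - m1) / 2
    var_m = (v1 + v2 - 2 * c12) / 4
    cov_tm = (v2 - v1) / 4
    b1 = cov_tm / var_t
    b0 = e_m - b1 * mean_t
    var_z = var_m - b1**2 * var_t
    corr = cov_tm / np.sqrt(var_t * var_m) if var_m > 1e-14 else 0.0
    r2 = b1**2 * var_t / var_m if var_m > 1e-14 else 0.0
    return LmParams(
        mean_t=float(mean_t),
        var_t=float(var_t),
        b0=float(b0),
        b1=float(b1),
        var_z=float(var_z),
        e_m=float(e_m),
        var_m=float(var_m),
        cov_tm=float(cov_tm),
        corr_tm=float(corr),
        r2=float(r2),
    )


def _measurement_patterns(I, K, invariance, error_pairs, scaling_indicator):
    if I < 2 or K != 2:
        raise ValueError("regression parameterizations are defined for K=2 methods, I>=2")
    if error_pairs in ("identical", True):
        error_pairs = identical_parcel_pairs(I, K)
    error_pairs = list(error_pairs or [])
    _check_pairs(error_pairs, I, K)
    p = I * K
    nu: list = [0.0] * p
    lam_labels = [None] * p
    for m in range(1, K + 1):
        for i in range(1, I + 1):
            row = (m - 1) * I + (i - 1)
            if i == scaling_indicator:
                lam_labels[row] = 1.0
                nu[row] = 0.0
            else:
                suffix = f"{i}" if invariance == "strong" else f"{i}_m{m}"
                lam_labels[row] = f"lam_{suffix}"
                nu[row] = f"alpha_{suffix}"
    theta = [[0.0] * p for _ in range(p)]
    for m in range(1, K + 1):
        for i in range(1, I + 1):
            row = (m - 1) * I + (i - 1)
            theta[row][row] = f"theta_{i}_{m}"
    for i, m, mp in error_pairs:
        r1, r2 = (m - 1) * I + (i - 1), (mp - 1) * I + (i - 1)
        theta[r1][r2] = theta[r2][r1] = f"theta_cov_{i}_{m}{mp}"
    names = [f"P{i}_M{m}" for m in range(1, K + 1) for i in range(1, I + 1)]
    return lam_labels, nu, theta, names


def _signed(cell, sign):
    if sign == 0:
        return 0.0
    if isinstance(cell, (int, float)):
        return float(sign * cell)
    return (cell, float(sign)) if sign != 1 else cell


def build_ld_spec(I: int = 3, K: int = 2, reference: int = 1, invariance: str = "strong",
                  error_pairs=None, scaling_indicator: int = 1) -> LinearModelSpec:
    """LD regression parameterization over latents ``(T_ref, M)``.

    Reference-method indicators load on the trait only; the other
    method's indicators load on both (``T_o = T_r + M``).
    """
    if reference not in (1, 2):
        raise ValueError("reference must be 1 or 2 in the two-method design")
    lam_lab, nu, theta, names = _measurement_patterns(I, K, invariance, error_pairs, scaling_indicator)
    lam = []
    for m in range(1, K + 1):
        for i in range(1, I + 1):
            row = (m - 1) * I + (i - 1)
            on_m = 0 if m == reference else 1
            lam.append([lam_lab[row], _signed(lam_lab[row], on_m)])
    return LinearModelSpec(lam=lam, nu=nu, theta=theta, structural=StructuralBlock(), var_names=names)


def build_lm_spec(I: int = 3, K: int = 2, invariance: str = "strong",
                  error_pairs=None, scaling_indicator: int = 1) -> LinearModelSpec:
    """LM regression parameterization over latents ``(T, M*)``.

    Both methods load on the common trait; the method factor carries
    sign -1 for method 1 and +1 for method 2.
    """
    lam_lab, nu, theta, names = _measurement_patterns(I, K, invariance, error_pairs, scaling_indicator)
    lam = []
    for m in range(1, K + 1):
        sign = -1 if m == 1 else 1
        for i in range(1, I + 1):
            row = (m - 1) * I + (i - 1)
            lam.append([lam_lab[row], _signed(lam_lab[row], sign)])
    return LinearModelSpec(lam=lam, nu=nu, theta=theta, structural=StructuralBlock(), var_names=names)


def _extract_structural(result: FitResult, cls, **extra):
    est = result.estimates
    mean_t, var_t = est["mean_x"], est["var_x"]
    b0, b1, var_z = est["b0"], est["b1"], est["var_z"]
    e_m, var_m, cov_tm, corr, r2 = _structural_derived(mean_t, var_t, b0, b1, var_z)
    se = {k: result.se.get(k, np.nan) for k in ("mean_x", "var_x", "b0", "b1", "var_z")}

    def derived(which):
        def fun(x):
            e = dict(zip(result.spec.free_names, x))
            vals = _structural_derived(e["mean_x"], e["var_x"], e["b0"], e["b1"], e["var_z"])
            return vals[which]
        return fun

    for j, key in enumerate(["e_m", "var_m", "cov_tm", "corr_tm", "r2"]):
        se[key] = delta_se(derived(j), result)
    return cls(
        mean_t=float(mean_t), var_t=float(var_t), b0=float(b0), b1=float(b1),
        var_z=float(var_z), e_m=float(e_m), var_m=float(var_m),
        cov_tm=float(cov_tm), corr_tm=float(corr), r2=float(r2), se=se, **extra,
    )


def fit_linear_ld(data, I: int = 3, reference: int | None = None, invariance: str = "strong",
                  error_pairs=None, scaling_indicator: int = 1):
    """Directly fit the linear LD model; returns ``(LdParams, FitResult)``.

    The reference method is a required, deliberate choice.
    """
    if reference is None:
        raise ValueError("the LD model requires an explicit reference method")
    moments = _as_moments(data)
    if isinstance(data, IndicatorTable):
        I = data.n_indicators
    spec = build_ld_spec(I, 2, reference, invariance, error_pairs, scaling_indicator)
    result = fit_ml(spec, moments)
    params = _extract_structural(result, LdParams, reference=reference)
    return params, result


def fit_linear_lm(data, I: int = 3, invariance: str = "strong",
                  error_pairs=None, scaling_indicator: int = 1):
    """Directly fit the linear LM model; returns ``(LmParams, FitResult)``."""
    moments = _as_moments(data)
    if isinstance(data, IndicatorTable):
        I = data.n_indicators
    spec = build_lm_spec(I, 2, invariance, error_pairs, scaling_indicator)
    result = fit_ml(spec, moments)
    params = _extract_structural(result, LmParams)
    return params, result


def factor_scores(result, table: IndicatorTable) -> pd.DataFrame:
    """Regression-method (posterior mean) factor scores per subject.

    For a linear :class:`~quadmtmm.sem_core.FitResult` the scores are the
    Gaussian posterior means ``kappa + Psi Lambda' Sigma^-1 (y - mu)``.
    Quadratic fits are handled by quadrature in
    :func:`quadmtmm.lms_quadratic.quad_factor_scores`, to which this
    dispatches.  Rows with missing indicators are skipped.
    """
    from .lms_quadratic import QuadFitResult, quad_factor_scores

    if isinstance(result, QuadFitResult):
        return quad_factor_scores(result, table)
    if not isinstance(result, FitResult):
        raise TypeError("expected a FitResult or QuadFitResult")
    spec = result.spec
    lam, nu, kappa, psi, theta = spec.matrices(result.theta)
    sigma = lam @ psi @ lam.T + theta
    mu = nu + lam @ kappa
    weight = psi @ lam.T @ np.linalg.inv(sigma)
    values = table.sorted().values
    ok = ~np.isnan(values).any(axis=1)
    if not ok.all():
        logger.info("factor_scores: skipped %d rows with missing indicators", int((~ok).sum()))
    scores = kappa[None, :] + (values[ok] - mu) @ weight.T
    cols = ["trait_score", "method_score"] if spec.q == 2 else [f"eta{j + 1}" for j in range(spec.q)]
    frame = pd.DataFrame(scores, columns=cols)
    frame.insert(0, "subject", np.nonzero(ok)[0])
    return frame
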