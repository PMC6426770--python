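"""Marginal maximum likelihood for quadratic trait-method relationships.

With a quadratic latent regression ``M = b0 + b1 t + b2 t^2 + zeta`` the
observed indicators are no longer jointly normal: conditional on the
latent predictor ``t`` (the reference trait in the LD variant, the
common trait in the LM variant) the model is linear-Gaussian, so the
marginal density of an observation is a continuous normal mixture over
``t``.  The log-likelihood integrates ``t`` out with Gauss-Hermite
quadrature::

    l_i = int N(y_i; mu(t), Sigma_c) phi(t; mean_x, var_x) dt

where ``mu(t) = m0 + m1 t + m2 t^2`` and ``Sigma_c`` (constant in ``t``)
adds ``Var(zeta)`` through the method-factor loadings to the error
covariance.  Nodes are adaptively rescaled per subject to the Gaussian
posterior of the linearized model; with that placement the quadrature is
exact whenever ``b2 = 0`` (the integrand is then proportional to the
quadrature kernel), so the quadratic likelihood nests the linear one
exactly at any node count.

Estimation maximizes this marginal likelihood directly by quasi-Newton
iteration (same estimand as the EM-based LMS formulation; the direct
maximization is a deliberate engineering choice).  The quadratic term is
tested against the linear model with a df-1 likelihood-ratio test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_io import IndicatorTable, sample_moments
from .sem_core import FitResult, SemError
from .structural import fit_linear_ld, fit_linear_lm
from .tmu_model import _check_pairs, identical_parcel_pairs

logger = logging.getLogger("quadmtmm")

__all__ = [
    "QuadraticStructural",
    "QuadFitResult",
    "quadrature_weights",
    "marginal_loglik",
    "fit_quadratic_ld",
    "fit_quadratic_lm",
    "quad_factor_scores",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class QuadraticStructural:
    """Latent regression ``M = b0 + b1 t + b2 t^2 + zeta`` and predictor moments."""

    b0: float
    b1: float
    b2: float
    var_z: float
    mean_x: float
    var_x: float
    variant: str = "ld"  # "ld" | "lm"
    reference: int = 1

    def __post_init__(self) -> None:
        if self.variant not in ("ld", "lm"):
            raise ValueError("variant must be 'ld' or 'lm'")
        if self.var_z < 0:
            raise ValueError("Var(zeta) must be non-negative")
        if self.var_x <= 0:
            raise ValueError("predictor variance must be positive")

    @property
    def method_signs(self) -> np.ndarray:
        """Coefficients of M in (T1, T2)."""
        if self.variant == "lm":
            return np.array([-1.0, 1.0])
        return np.array([1.0, 0.0]) if self.reference == 2 else np.array([0.0, 1.0])

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.b0 + self.b1 * t + self.b2 * t * t


def quadrature_weights(n_nodes: int):
    """Normalized Gauss-Hermite nodes/weights (weights sum to one)."""
    if n_nodes < 2:
        raise ValueError("need at least 2 quadrature nodes")
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    return nodes, weights / np.sqrt(np.pi)


def _conditional_pieces(loadings, intercepts, error_cov, struct: QuadraticStructural):
    lam = np.asarray(loadings, dtype=float).ravel()
    nu = np.asarray(intercepts, dtype=float).ravel()
    I = lam.size
    lam_stack = np.concatenate([lam, lam])  # two methods, invariant loadings
    nu_stack = np.concatenate([nu, nu])
    u = struct.method_signs
    lu = np.concatenate([lam * u[0], lam * u[1]])
    m0 = nu_stack + lu * struct.b0
    m1 = lam_stack + lu * struct.b1
    m2 = lu * struct.b2
    sigma_c = struct.var_z * np.outer(lu, lu) + np.asarray(error_cov, dtype=float)
    return I, m0, m1, m2, lu, sigma_c


class _Workspace:
    """Everything the likelihood and its gradient share for one theta."""

    __slots__ = (
        "y", "struct", "p", "m0", "m1", "m2", "lu", "sigma_c", "sinv",
        "a_mat", "sinv_a", "ab", "ac", "d11", "d12", "d22",
        "per_subject", "log_terms", "t", "post", "pmom",
    )


def _marginal_core(y, loadings, intercepts, error_cov, struct, n_nodes):
    """Adaptive-quadrature marginal likelihood; returns a :class:`_Workspace`.

    The quadratic form in ``t`` expands to a degree-4 polynomial with
    per-subject coefficients, so the node evaluation is O(N * K) scalars.
    """
    ws = _Workspace()
    ws.y = y
    ws.struct = struct
    _, m0, m1, m2, lu, sigma_c = _conditional_pieces(loadings, intercepts, error_cov, struct)
    p = y.shape[1]
    try:
        chol = np.linalg.cholesky(sigma_c)
    except np.linalg.LinAlgError as exc:
        raise SemError("conditional covariance not positive definite") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    sinv = np.linalg.inv(sigma_c)
    sinv_m1 = sinv @ m1
    sinv_m2 = sinv @ m2
    a_mat = y - m0  # (N, p)
    sinv_a = a_mat @ sinv
    aa = np.einsum("ij,ij->i", a_mat, sinv_a)
    ab = a_mat @ sinv_m1
    ac = a_mat @ sinv_m2
    d11 = float(m1 @ sinv_m1)
    d12 = float(m1 @ sinv_m2)
    d22 = float(m2 @ sinv_m2)

    mx, vx = struct.mean_x, struct.var_x
    prec = 1.0 / vx + d11
    s2 = 1.0 / prec
    centre = s2 * (mx / vx + ab)  # (N,)

    x_k, w_k = quadrature_weights(n_nodes)
    s = np.sqrt(s2)
    t = centre[:, None] + np.sqrt(2.0) * s * x_k[None, :]  # (N, K)
    t2 = t * t
    quad_form = (
        aa[:, None]
        - 2.0 * ab[:, None] * t
        + (d11 - 2.0 * ac[:, None]) * t2
        + 2.0 * d12 * t2 * t
        + d22 * t2 * t2
    )
    log_g = (
        -0.5 * (p * _LOG2PI + logdet + quad_form)
        - 0.5 * (np.log(2.0 * np.pi * vx) + (t - mx) ** 2 / vx)
    )
    log_terms = np.log(w_k)[None, :] + x_k[None, :] ** 2 + log_g
    top = np.max(log_terms, axis=1)
    per_subject = top + np.log(np.exp(log_terms - top[:, None]).sum(axis=1))
    per_subject += 0.5 * np.log(2.0 * np.pi * s2)

    ws.p = p
    ws.m0, ws.m1, ws.m2, ws.lu = m0, m1, m2, lu
    ws.sigma_c, ws.sinv = sigma_c, sinv
    ws.a_mat, ws.sinv_a = a_mat, sinv_a
    ws.ab, ws.ac = ab, ac
    ws.d11, ws.d12, ws.d22 = d11, d12, d22
    ws.per_subject, ws.log_terms, ws.t = per_subject, log_terms, t
    ws.post = None
    ws.pmom = None
    return ws


def _posterior_moments(ws: _Workspace):
    """Posterior weights and E[t^d | y] (d = 1..4) on the node grid."""
    if ws.pmom is None:
        top = np.max(ws.log_terms, axis=1, keepdims=True)
        w = np.exp(ws.log_terms - top)
        w /= w.sum(axis=1, keepdims=True)
        t = ws.t
        t2 = t * t
        ws.post = w
        ws.pmom = (
            np.sum(w * t, axis=1),
            np.sum(w * t2, axis=1),
            np.sum(w * t2 * t, axis=1),
            np.sum(w * t2 * t2, axis=1),
        )
    return ws.post, ws.pmom


def _marginal_gradient(ws: _Workspace, pmap: "_QuadParameterMap", x: np.ndarray) -> np.ndarray:
    """Analytic score of the marginal log-likelihood (Fisher's identity).

    Node positions are treated as fixed: the integration is numerically
    exact at the adaptive placement, so the neglected dependence of the
    nodes on theta contributes only at quadrature-error order.
    """
    struct, sinv, lu = ws.struct, ws.sinv, ws.lu
    a_mat, m1, m2 = ws.a_mat, ws.m1, ws.m2
    _, (p1, p2, p3, p4) = _posterior_moments(ws)
    I = pmap.I

    def rsv(v):
        """(r' Sinv v) as polynomial coefficients (x0 array, x1, x2 scalars)."""
        sv = sinv @ v
        return a_mat @ sv, float(m1 @ sv), float(m2 @ sv)

    def dmu_term(v0, v1, v2):
        """E[r' Sinv dmu] for dmu(t) = v0 + v1 t + v2 t^2 (vectors or None)."""
        out = 0.0
        for power, v in enumerate((v0, v1, v2)):
            if v is None:
                continue
            x0, x1, x2 = rsv(v)
            mom = (1.0, p1, p2, p3, p4)
            out = out + x0 * mom[power] - x1 * mom[power + 1] - x2 * mom[power + 2]
        return out

    def pair_term(g, h):
        """E term for dSigma = g h' + h g'."""
        gx0, gx1, gx2 = rsv(g)
        hx0, hx1, hx2 = rsv(h)
        prod = (
            gx0 * hx0
            - (gx0 * hx1 + gx1 * hx0) * p1
            + (gx1 * hx1 - gx0 * hx2 - gx2 * hx0) * p2
            + (gx1 * hx2 + gx2 * hx1) * p3
            + gx2 * hx2 * p4
        )
        return -float(g @ sinv @ h) + prod

    mx, vx, vz = struct.mean_x, struct.var_x, struct.var_z
    u = struct.method_signs
    e = np.eye(2 * I)
    grad = np.zeros(len(pmap.names))
    for j, name in enumerate(pmap.names):
        if name.startswith("lam_"):
            i = int(name.split("_")[1]) - 1
            v_i = e[i] + e[i + I]
            w_i = u[0] * e[i] + u[1] * e[i + I]
            term = dmu_term(w_i * struct.b0, v_i + w_i * struct.b1, w_i * struct.b2)
            if vz > 0:
                term = term + vz * 0.5 * pair_term(w_i, lu) * 2.0
            grad[j] = float(np.sum(term))
        elif name.startswith("alpha_"):
            i = int(name.split("_")[1]) - 1
            grad[j] = float(np.sum(dmu_term(e[i] + e[i + I], None, None)))
        elif name.startswith("log_theta_"):
            _, i, m = name.rsplit("_", 2)
            row = (int(m) - 1) * I + (int(i) - 1)
            term = 0.5 * pair_term(e[row], e[row])
            grad[j] = float(np.sum(term)) * np.exp(x[j])  # chain rule, log scale
        elif name.startswith("theta_cov_"):
            body = name.removeprefix("theta_cov_")
            i_s, mm = body.split("_")
            i = int(i_s) - 1
            r1 = (int(mm[0]) - 1) * I + i
            r2 = (int(mm[1]) - 1) * I + i
            grad[j] = float(np.sum(pair_term(e[r1], e[r2])))
        elif name == "mean_x":
            grad[j] = float(np.sum((p1 - mx) / vx))
        elif name == "log_var_x":
            term = -0.5 / vx + (p2 - 2.0 * mx * p1 + mx * mx) / (2.0 * vx * vx)
            grad[j] = float(np.sum(term)) * vx
        elif name == "b0":
            grad[j] = float(np.sum(dmu_term(lu, None, None)))
        elif name == "b1":
            grad[j] = float(np.sum(dmu_term(None, lu, None)))
        elif name == "b2":
            grad[j] = float(np.sum(dmu_term(None, None, lu)))
        elif name == "log_var_z":
            grad[j] = float(np.sum(0.5 * pair_term(lu, lu))) * vz
    return grad


def marginal_loglik(
    loadings,
    intercepts,
    error_cov,
    structural: QuadraticStructural,
    table: IndicatorTable,
    n_nodes: int = 32,
) -> float:
    """Total marginal log-likelihood of ``table`` under the quadratic model.

    ``loadings``/``intercepts`` are the I invariant measurement
    parameters, ``error_cov`` the full 2I x 2I error covariance matrix.
    """
    y = table.sorted().values
    ws = _marginal_core(y, loadings, intercepts, error_cov, structural, n_nodes)
    return float(ws.per_subject.sum())


@dataclass
class QuadFitResult:
    variant: str
    reference: int
    loadings: np.ndarray
    intercepts: np.ndarray
    error_cov: np.ndarray
    structural: QuadraticStructural
    loglik: float
    n_nodes: int
    linear_loglik: float
    lr_statistic: float
    lr_p_value: float
    converged: bool
    heywood: bool
    n_iter: int
    se: dict = field(default_factory=dict)
    linear_result: FitResult | None = None
    param_names: list = field(default_factory=list)
    theta_full: np.ndarray | None = None

    @property
    def b2(self) -> float:
        return self.structural.b2

    @property
    def b2_se(self) -> float:
        return self.se.get("b2", np.nan)


class _QuadParameterMap:
    """Named parameter vector <-> model matrices (variances log-scaled)."""

    def __init__(self, I, variant, reference, error_pairs, scaling_indicator, fix_b2=None):
        self.I = I
        self.variant = variant
        self.reference = reference
        self.scaling = scaling_indicator
        self.pairs = error_pairs
        self.fix_b2 = fix_b2
        self.names = []
        for i in range(1, I + 1):
            if i != scaling_indicator:
                self.names.append(f"lam_{i}")
        for i in range(1, I + 1):
            if i != scaling_indicator:
                self.names.append(f"alpha_{i}")
        for m in (1, 2):
            for i in range(1, I + 1):
                self.names.append(f"log_theta_{i}_{m}")
        for i, m, mp in error_pairs:
            self.names.append(f"theta_cov_{i}_{m}{mp}")
        self.names += ["mean_x", "log_var_x", "b0", "b1"]
        if fix_b2 is None:
            self.names.append("b2")
        self.names.append("log_var_z")

    def unpack(self, x):
        d = dict(zip(self.names, x))
        I = self.I
        lam = np.ones(I)
        nu = np.zeros(I)
        for i in range(1, I + 1):
            if i != self.scaling:
                lam[i - 1] = d[f"lam_{i}"]
                nu[i - 1] = d[f"alpha_{i}"]
        theta = np.zeros((2 * I, 2 * I))
        for m in (1, 2):
            for i in range(1, I + 1):
                row = (m - 1) * I + (i - 1)
                theta[row, row] = np.exp(d[f"log_theta_{i}_{m}"])
        for i, m, mp in self.pairs:
            r1, r2 = (m - 1) * I + (i - 1), (mp - 1) * I + (i - 1)
            theta[r1, r2] = theta[r2, r1] = d[f"theta_cov_{i}_{m}{mp}"]
        b2 = self.fix_b2 if self.fix_b2 is not None else d["b2"]
        struct = QuadraticStructural(
            b0=d["b0"], b1=d["b1"], b2=b2,
            var_z=float(np.exp(d["log_var_z"])),
            mean_x=d["mean_x"], var_x=float(np.exp(d["log_var_x"])),
            variant=self.variant, reference=self.reference,
        )
        return lam, nu, theta, struct

    def pack_from_linear(self, linear_params, linear_result):
        est = linear_result.estimates
        x = []
        for name in self.names:
            if name.startswith("lam_") or name.startswith("alpha_") or name.startswith("theta_cov"):
                x.append(est.get(name, 0.0))
            elif name.startswith("log_theta_"):
                key = name.removeprefix("log_")
                x.append(np.log(max(est[key], 1e-8)))
            elif name == "mean_x":
                x.append(linear_params.mean_t)
            elif name == "log_var_x":
                x.append(np.log(max(linear_params.var_t, 1e-8)))
            elif name == "b0":
                x.append(linear_params.b0)
            elif name == "b1":
                x.append(linear_params.b1)
            elif name == "b2":
                x.append(0.0)
            elif name == "log_var_z":
                x.append(np.log(max(linear_params.var_z, 1e-8)))
        return np.array(x, dtype=float)

    def original_scale(self, x):
        """Report-scale values (variances exponentiated)."""
        out = {}
        for name, v in zip(self.names, x):
            if name.startswith("log_"):
                out[name.removeprefix("log_")] = float(np.exp(v))
            else:
                out[name] = float(v)
        return out


def _fit_quadratic(table, variant, I, reference, error_pairs, invariance,
                   scaling_indicator, n_nodes, fix_b2, compute_se, max_iter):
    if invariance != "strong":
        raise ValueError("quadratic models require strong invariance")
    if isinstance(table, IndicatorTable):
        I = table.n_indicators
        if table.n_methods != 2:
            raise ValueError("quadratic models implemented for 2 methods")
    else:
        raise TypeError("raw data required: moment summaries cannot identify quadratic terms")
    if error_pairs in ("identical", True):
        error_pairs = identical_parcel_pairs(I, 2)
    error_pairs = list(error_pairs or [])
    _check_pairs(error_pairs, I, 2)

    moments = sample_moments(table.sorted())
    if variant == "ld":
        lin_params, lin_result = fit_linear_ld(
            moments, I=I, reference=reference, invariance=invariance,
            error_pairs=error_pairs, scaling_indicator=scaling_indicator)
    else:
        lin_params, lin_result = fit_linear_lm(
            moments, I=I, invariance=invariance,
            error_pairs=error_pairs, scaling_indicator=scaling_indicator)
    ll_linear = lin_result.stats.log_likelihood

    pmap = _QuadParameterMap(I, variant, reference, error_pairs, scaling_indicator, fix_b2)
    x0 = pmap.pack_from_linear(lin_params, lin_result)
    y = table.sorted().values

    def negloglik(x):
        lam, nu, theta, struct = pmap.unpack(x)
        try:
            ws = _marginal_core(y, lam, nu, theta, struct, n_nodes)
        except (SemError, ValueError):
            return 1e10, np.zeros_like(x)
        val = -float(ws.per_subject.sum())
        if not np.isfinite(val):
            return 1e10, np.zeros_like(x)
        return val, -_marginal_gradient(ws, pmap, x)

    res = optimize.minimize(
        negloglik, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-11, "gtol": 1e-6},
    )
    x_hat = res.x
    ll_quad = -float(res.fun)
    converged = bool(res.success)
    lam, nu, theta, struct = pmap.unpack(x_hat)
    heywood = bool(
        np.min(np.diag(theta)) < 1e-6 or struct.var_z < 1e-8 or struct.var_x < 1e-8
    )

    lr = 2.0 * (ll_quad - ll_linear)
    if lr < -1e-5:
        raise SemError(f"quadratic fit worse than linear (LR = {lr:.4g}): optimizer failure")
    lr = max(lr, 0.0)
    lr_p = float(stats.chi2.sf(lr, 1)) if fix_b2 is None else np.nan

    se = {}
    if compute_se:
        se = _wald_se(lambda x: negloglik(x)[1], x_hat, pmap)

    return QuadFitResult(
        variant=variant,
        reference=reference,
        loadings=lam,
        intercepts=nu,
        error_cov=theta,
        structural=struct,
        loglik=ll_quad,
        n_nodes=n_nodes,
        linear_loglik=ll_linear,
        lr_statistic=lr,
        lr_p_value=lr_p,
        converged=converged,
        heywood=heywood,
        n_iter=int(res.nit),
        se=se,
        linear_result=lin_result,
        param_names=list(pmap.names),
        theta_full=x_hat,
    )


def _wald_se(grad_fun, x_hat, pmap):
    """Delta-method SEs on the report scale.

    The observed information is the central-difference Jacobian of the
    analytic score in the transformed parameterization.
    """
    n = x_hat.size
    h = 1e-5 * (1.0 + np.abs(x_hat))
    hess = np.zeros((n, n))
    for j in range(n):
        xp, xm = x_hat.copy(), x_hat.copy()
        xp[j] += h[j]
        xm[j] -= h[j]
        hess[:, j] = (grad_fun(xp) - grad_fun(xm)) / (2.0 * h[j])
    hess = 0.5 * (hess + hess.T)
    try:
        vcov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return {}
    diag = np.diag(vcov)
    se = {}
    for name, v, x in zip(pmap.names, diag, x_hat):
        sd = np.sqrt(v) if v > 0 else np.nan
        if name.startswith("log_"):
            se[name.removeprefix("log_")] = float(np.exp(x) * sd)  # delta method
        else:
            se[name] = float(sd)
    return se


def fit_quadratic_ld(
    table: IndicatorTable,
    reference: int | None = None,
    error_pairs=None,
    n_nodes: int = 32,
    scaling_indicator: int = 1,
    fix_b2: float | None = None,
    compute_se: bool = True,
    max_iter: int = 2000,
) -> QuadFitResult:
    """Quadratic LD model by marginal ML; warm-started from the linear fit."""
    if reference is None:
        raise ValueError("the LD model requires an explicit reference method")
    return _fit_quadratic(table, "ld", None, reference, error_pairs, "strong",
                          scaling_indicator, n_nodes, fix_b2, compute_se, max_iter)


def fit_quadratic_lm(
    table: IndicatorTable,
    error_pairs=None,
    n_nodes: int = 32,
    scaling_indicator: int = 1,
    fix_b2: float | None = None,
    compute_se: bool = True,
    max_iter: int = 2000,
) -> QuadFitResult:
    """Quadratic LM model by marginal ML; warm-started from the linear fit."""
    return _fit_quadratic(table, "lm", None, 1, error_pairs, "strong",
                          scaling_indicator, n_nodes, fix_b2, compute_se, max_iter)


def quad_factor_scores(result: QuadFitResult, table: IndicatorTable) -> pd.DataFrame:
    """Posterior-mean trait and method scores under a quadratic fit.

    ``E[t | y]`` and ``E[M | y] = E[ b0 + b1 t + b2 t^2 + E(zeta | t, y) | y ]``
    are computed on the adaptive quadrature grid.
    """
    values = table.sorted().values
    ok = ~np.isnan(values).any(axis=1)
    if not ok.all():
        logger.info("quad_factor_scores: skipped %d incomplete rows", int((~ok).sum()))
    y = values[ok]
    struct = result.structural
    ws = _marginal_core(
        y, result.loadings, result.intercepts, result.error_cov, struct, result.n_nodes
    )
    post, _ = _posterior_moments(ws)
    t = ws.t
    trait = np.sum(post * t, axis=1)
    resid = y[:, None, :] - (ws.m0[None, None, :] + ws.m1[None, None, :] * t[:, :, None]
                             + ws.m2[None, None, :] * t[:, :, None] ** 2)
    sinv_lu = ws.sinv @ ws.lu
    e_zeta = struct.var_z * np.einsum("nkp,p->nk", resid, sinv_lu)
    method = np.sum(post * (struct.predict(t) + e_zeta), axis=1)
    frame = pd.DataFrame({"trait_score": trait, "method_score": method})
    frame.insert(0, "subject", np.nonzero(ok)[0])
    return frame
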