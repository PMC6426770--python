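"""Linear structural-equation engine for mean-and-covariance structures.

A model is a set of pattern matrices over observed variables ``y`` and
latent variables ``eta``::

    y     = nu + Lambda @ eta + eps,   eps ~ N(0, Theta)
    eta   ~ N(kappa, Psi)

so the implied moments are ``mu = nu + Lambda kappa`` and
``Sigma = Lambda Psi Lambda' + Theta``.  Pattern cells are fixed numbers,
free-parameter labels, or ``(label, coef)`` pairs (the cell equals
``coef * parameter``); repeating a label imposes an equality constraint.

Instead of free latent moments, a spec may carry a two-variable
structural block ``(x, M)`` with ``M = b0 + b1 x + zeta``: the latent
mean vector and covariance matrix then become smooth functions of
``(mean_x, var_x, b0, b1, var_z)``.  This is how the latent-difference
and latent-means regression parameterizations are expressed.

Fitting minimizes the normal-theory ML discrepancy

    F = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p + (m - mu)' Sigma^-1 (m - mu)

with an analytic gradient, followed by Newton polishing so that exact
reparameterizations of the same structure agree in chi-square to well
below 1e-6.  ``chi_square = N * F_min`` (the multiplier is N, not N-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data_io import MomentSummary

__all__ = [
    "StructuralBlock",
    "LinearModelSpec",
    "FitStatistics",
    "FitResult",
    "SemError",
    "fit_ml",
    "fit_statistics",
    "lr_test",
    "baseline_chi_square",
    "delta_se",
]

_BIG = 1e10


class SemError(RuntimeError):
    """Estimation failure (non-convergence, under-identification, non-PD)."""


Cell = float | str | tuple


@dataclass
class StructuralBlock:
    """Latent regression ``M = b0 + b1 * x + zeta`` over latents (x, M)."""

    mean_x: Cell = "mean_x"
    var_x: Cell = "var_x"
    b0: Cell = "b0"
    b1: Cell = "b1"
    var_z: Cell = "var_z"

    FIELDS = ("mean_x", "var_x", "b0", "b1", "var_z")


@dataclass
class LinearModelSpec:
    """Pattern matrices defining a linear mean/covariance structure."""

    lam: list
    nu: list
    theta: list
    kappa: list | None = None
    psi: list | None = None
    structural: StructuralBlock | None = None
    start: dict = field(default_factory=dict)
    var_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lam = [list(r) for r in self.lam]
        self.theta = [list(r) for r in self.theta]
        p, q = len(self.lam), len(self.lam[0])
        if len(self.nu) != p or len(self.theta) != p:
            raise ValueError("pattern dimensions disagree")
        if self.structural is None:
            if self.kappa is None or self.psi is None:
                raise ValueError("need kappa/psi patterns or a structural block")
            if len(self.kappa) != q or len(self.psi) != q:
                raise ValueError("latent pattern dimensions disagree")
        elif q != 2:
            raise ValueError("a structural block requires exactly 2 latent variables")
        self.p, self.q = p, q
        self._compile()

    # -- compilation -------------------------------------------------
    def _compile(self) -> None:
        self._names: list[str] = []
        self._index: dict[str, int] = {}
        self._kind: dict[str, str] = {}

        def reg(cell, kind):
            if isinstance(cell, (int, float, np.floating)):
                return None
            if isinstance(cell, tuple):
                label, coef = cell
            else:
                label, coef = cell, 1.0
            if label not in self._index:
                self._index[label] = len(self._names)
                self._names.append(label)
                self._kind[label] = kind
            return self._index[label], float(coef)

        def scan(rows, kind, store):
            for i, row in enumerate(rows):
                for j, cell in enumerate(row):
                    hit = reg(cell, kind)
                    if hit is None:
                        self._fixed[store][i, j] = float(cell)
                    else:
                        self._entries[store].append((i, j, *hit))

        self._fixed = {
            "lam": np.zeros((self.p, self.q)),
            "nu": np.zeros((self.p, 1)),
            "theta": np.zeros((self.p, self.p)),
            "kappa": np.zeros((self.q, 1)),
            "psi": np.zeros((self.q, self.q)),
        }
        self._entries = {k: [] for k in self._fixed}
        scan(self.lam, "lam", "lam")
        scan([[c] for c in self.nu], "nu", "nu")
        if self.structural is None:
            scan([[c] for c in self.kappa], "kappa", "kappa")
            scan(self.psi, "psi", "psi")
            self._struct_idx = None
        else:
            self._struct_idx = {}
            for f in StructuralBlock.FIELDS:
                cell = getattr(self.structural, f)
                hit = reg(cell, f)
                self._struct_idx[f] = hit if hit is not None else float(cell)
        scan(self.theta, "theta", "theta")

    @property
    def free_names(self) -> list[str]:
        return list(self._names)

    @property
    def n_free(self) -> int:
        return len(self._names)

    def param_kind(self, name: str) -> str:
        return self._kind[name]

    # -- evaluation --------------------------------------------------
    def _struct_values(self, x: np.ndarray) -> dict[str, float]:
        out = {}
        for f, ref in self._struct_idx.items():
            out[f] = ref if isinstance(ref, float) else ref[1] * x[ref[0]]
        return out

    def matrices(self, x: np.ndarray):
        """Return (Lambda, nu, kappa, Psi, Theta) at parameter vector x."""
        mats = {k: v.copy() for k, v in self._fixed.items()}
        for store, entries in self._entries.items():
            for i, j, idx, coef in entries:
                mats[store][i, j] += coef * x[idx]
        if self._struct_idx is not None:
            s = self._struct_values(x)
            mx, vx, b0, b1, vz = (s[f] for f in StructuralBlock.FIELDS)
            mats["kappa"] = np.array([[mx], [b0 + b1 * mx]])
            mats["psi"] = np.array([[vx, b1 * vx], [b1 * vx, b1 * b1 * vx + vz]])
        return (
            mats["lam"],
            mats["nu"].ravel(),
            mats["kappa"].ravel(),
            mats["psi"],
            mats["theta"],
        )

    def implied_moments(self, x: np.ndarray, n: int = 0) -> MomentSummary:
        lam, nu, kappa, psi, theta = self.matrices(np.asarray(x, float))
        sigma = lam @ psi @ lam.T + theta
        mu = nu + lam @ kappa
        return MomentSummary(mu, 0.5 * (sigma + sigma.T), n, list(self.var_names))

    def default_start(self, moments: MomentSummary) -> np.ndarray:
        grand = float(np.mean(moments.means))
        v = float(np.mean(np.diag(moments.cov)))
        obs_var = np.diag(moments.cov)
        x = np.zeros(self.n_free)
        diag_theta = {}
        for i, j, idx, _ in self._entries["theta"]:
            if i == j:
                diag_theta[idx] = 0.5 * obs_var[i]
        for name, idx in self._index.items():
            kind = self._kind[name]
            if name in self.start:
                x[idx] = self.start[name]
            elif kind == "lam":
                x[idx] = 1.0
            elif kind == "nu":
                x[idx] = 0.0
            elif kind in ("kappa", "mean_x"):
                x[idx] = grand
            elif kind in ("var_x",):
                x[idx] = 0.5 * v
            elif kind == "psi":
                diag = any(i == j and k == idx for i, j, k, _ in self._entries["psi"])
                x[idx] = 0.5 * v if diag else 0.2 * v
            elif kind == "var_z":
                x[idx] = 0.3 * v
            elif kind in ("b0", "b1"):
                x[idx] = 0.0
            elif kind == "theta":
                x[idx] = diag_theta.get(idx, 0.0)
        return x


@dataclass
class FitStatistics:
    chi_square: float
    df: int
    p_value: float
    rmsea: float
    cfi: float
    log_likelihood: float
    n_free_parameters: int
    baseline_chi_square: float
    baseline_df: int
    aic: float = np.nan
    bic: float = np.nan
    rmsea_undefined: bool = False


@dataclass
class FitResult:
    spec: LinearModelSpec
    theta: np.ndarray
    estimates: dict
    se: dict
    vcov: np.ndarray
    implied: MomentSummary
    moments: MomentSummary
    stats: FitStatistics
    gradient_norm: float
    f_min: float

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


# ----------------------------------------------------------------------
def _discrepancy_and_grad(spec, x, mbar, S, logdet_s):
    lam, nu, kappa, psi, theta = spec.matrices(x)
    sigma = lam @ psi @ lam.T + theta
    sigma = 0.5 * (sigma + sigma.T)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return _BIG, np.zeros(spec.n_free), None
    sinv = np.linalg.inv(sigma)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    mu = nu + lam @ kappa
    d = mbar - mu
    p = S.shape[0]
    f = logdet - logdet_s + float(np.sum(sinv * S)) - p + float(d @ sinv @ d)

    # dF = tr(A dSigma) - 2 (Sinv d)' dmu, A = Sinv (Sigma - S - dd') Sinv
    a = sinv @ (sigma - S - np.outer(d, d)) @ sinv
    sinvd = sinv @ d
    b_lam = 2.0 * a @ lam @ psi            # dF wrt Lambda cells (Sigma part)
    b_psi = lam.T @ a @ lam                # dF wrt Psi cells
    lt_sinvd = lam.T @ sinvd
    grad = np.zeros(spec.n_free)
    for i, j, idx, c in spec._entries["lam"]:
        grad[idx] += c * (b_lam[i, j] - 2.0 * sinvd[i] * kappa[j])
    for i, _, idx, c in spec._entries["nu"]:
        grad[idx] += -2.0 * c * sinvd[i]
    for i, j, idx, c in spec._entries["theta"]:
        grad[idx] += c * a[i, j]
    if spec._struct_idx is None:
        for i, _, idx, c in spec._entries["kappa"]:
            grad[idx] += -2.0 * c * lt_sinvd[i]
        for i, j, idx, c in spec._entries["psi"]:
            grad[idx] += c * b_psi[i, j]
    else:
        s = spec._struct_values(x)
        mx, vx, b0, b1, vz = (s[f] for f in StructuralBlock.FIELDS)
        dkappa = {
            "mean_x": np.array([1.0, b1]),
            "var_x": np.zeros(2),
            "b0": np.array([0.0, 1.0]),
            "b1": np.array([0.0, mx]),
            "var_z": np.zeros(2),
        }
        dpsi = {
            "mean_x": np.zeros((2, 2)),
            "var_x": np.array([[1.0, b1], [b1, b1 * b1]]),
            "b0": np.zeros((2, 2)),
            "b1": np.array([[0.0, vx], [vx, 2.0 * b1 * vx]]),
            "var_z": np.array([[0.0, 0.0], [0.0, 1.0]]),
        }
        for fname, ref in spec._struct_idx.items():
            if isinstance(ref, float):
                continue
            idx, c = ref
            grad[idx] += c * (
                float(np.sum(b_psi * dpsi[fname])) - 2.0 * float(dkappa[fname] @ lt_sinvd)
            )
    return f, grad, sigma


def _numerical_hessian(fun_grad, x, rel_step=1e-6):
    n = x.size
    h = rel_step * (1.0 + np.abs(x))
    hess = np.zeros((n, n))
    for j in range(n):
        xp, xm = x.copy(), x.copy()
        xp[j] += h[j]
        xm[j] -= h[j]
        gp = fun_grad(xp)[1]
        gm = fun_grad(xm)[1]
        hess[:, j] = (gp - gm) / (2.0 * h[j])
    return 0.5 * (hess + hess.T)


def baseline_chi_square(moments: MomentSummary) -> tuple[float, int]:
    """Independence baseline (free means and variances, zero covariances)."""
    s = moments.cov
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise SemError("sample covariance matrix is singular")
    f_b = float(np.sum(np.log(np.diag(s))) - logdet_s)
    p = moments.p
    return moments.n * f_b, p * (p - 1) // 2


def fit_statistics(
    chi_square: float,
    df: int,
    n: int,
    baseline_chi: float,
    baseline_df: int,
    log_likelihood: float = np.nan,
    n_free: int = 0,
) -> FitStatistics:
    rmsea_undefined = df == 0
    if rmsea_undefined:
        warnings.warn("df = 0: RMSEA undefined, reported as 0", stacklevel=2)
        rmsea = 0.0
        p_value = 1.0 if chi_square <= 1e-12 else 0.0
    else:
        rmsea = float(np.sqrt(max(0.0, (chi_square - df) / (df * (n - 1)))))
        p_value = float(stats.chi2.sf(chi_square, df))
    denom = max(baseline_chi - baseline_df, chi_square - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi_square - df, 0.0) / denom
    aic = bic = np.nan
    if np.isfinite(log_likelihood):
        aic = -2.0 * log_likelihood + 2.0 * n_free
        bic = -2.0 * log_likelihood + np.log(n) * n_free
    return FitStatistics(
        chi_square=float(chi_square),
        df=int(df),
        p_value=p_value,
        rmsea=rmsea,
        cfi=float(cfi),
        log_likelihood=float(log_likelihood),
        n_free_parameters=int(n_free),
        baseline_chi_square=float(baseline_chi),
        baseline_df=int(baseline_df),
        aic=aic,
        bic=bic,
        rmsea_undefined=rmsea_undefined,
    )


def lr_test(loglik_restricted: float, loglik_full: float, df_diff: int):
    """Likelihood-ratio test of nested models; returns (statistic, p)."""
    if df_diff < 1:
        raise ValueError("df_diff must be >= 1")
    statistic = -2.0 * (loglik_restricted - loglik_full)
    tol = 1e-6 * max(1.0, abs(loglik_full))
    if statistic < -tol:
        raise SemError(
            f"restricted model fit better (LR = {statistic:.3g} < 0): optimizer failure"
        )
    statistic = max(statistic, 0.0)
    return statistic, float(stats.chi2.sf(statistic, df_diff))


def saturated_loglik(moments: MomentSummary) -> float:
    sign, logdet_s = np.linalg.slogdet(moments.cov)
    p = moments.p
    return -0.5 * moments.n * (logdet_s + p + p * np.log(2.0 * np.pi))


def loglik_from_f(f_value: float, moments: MomentSummary) -> float:
    return saturated_loglik(moments) - 0.5 * moments.n * f_value


def fit_ml(
    spec: LinearModelSpec,
    moments: MomentSummary,
    start: np.ndarray | None = None,
    max_iter: int = 5000,
    gtol: float = 1e-8,
    compute_se: bool = True,
) -> FitResult:
    """Minimize the ML discrepancy of ``spec`` against ``moments``."""
    if moments.n < moments.p + 1:
        raise ValueError("sample size too small for the number of variables")
    S = moments.cov
    mbar = moments.means
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise SemError("sample covariance matrix is singular")

    def fun(x):
        f, g, _ = _discrepancy_and_grad(spec, x, mbar, S, logdet_s)
        return f, g

    x0 = np.asarray(start, float) if start is not None else spec.default_start(moments)
    res = optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10, "maxcor": 30},
    )
    x = res.x
    f, g, sigma = _discrepancy_and_grad(spec, x, mbar, S, logdet_s)
    # Newton polishing: exact reparameterizations must agree to ~1e-9 in F.
    hess = None
    for _ in range(8):
        if np.max(np.abs(g)) < 1e-11:
            break
        hess = _numerical_hessian(fun, x)
        try:
            step = np.linalg.solve(hess, g)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(20):
            f_new, g_new, sig_new = _discrepancy_and_grad(
                spec, x - scale * step, mbar, S, logdet_s
            )
            if f_new <= f + 1e-14:
                x = x - scale * step
                f, g, sigma = f_new, g_new, sig_new
                break
            scale *= 0.5
        else:
            break
    gnorm = float(np.max(np.abs(g)))
    if sigma is None:
        raise SemError("implied covariance not positive definite at the solution")
    if gnorm > 1e-4:
        raise SemError(f"non-convergence: gradient infinity-norm {gnorm:.3g}")

    if hess is None:
        hess = _numerical_hessian(fun, x)
    eigvals, eigvecs = np.linalg.eigh(hess)
    if eigvals[0] < 1e-10 * max(eigvals[-1], 1.0):
        null = eigvecs[:, 0]
        names = [spec.free_names[i] for i in np.argsort(-np.abs(null))[:4]]
        raise SemError(
            "model under-identified: information matrix is rank-deficient; "
            f"null-space dominated by parameters {names}"
        )
    vcov = np.full((spec.n_free, spec.n_free), np.nan)
    se = {}
    if compute_se:
        vcov = np.linalg.inv(0.5 * moments.n * hess)
        diag = np.diag(vcov)
        se = {
            name: float(np.sqrt(v)) if v > 0 else np.nan
            for name, v in zip(spec.free_names, diag)
        }

    n = moments.n
    chi_square = n * f
    n_moments = moments.p * (moments.p + 3) // 2
    df = n_moments - spec.n_free
    if df < 0:
        raise SemError(f"negative degrees of freedom ({df})")
    loglik = loglik_from_f(f, moments)
    base_chi, base_df = baseline_chi_square(moments)
    stats_ = fit_statistics(chi_square, df, n, base_chi, base_df, loglik, spec.n_free)
    estimates = {name: float(v) for name, v in zip(spec.free_names, x)}
    return FitResult(
        spec=spec,
        theta=x,
        estimates=estimates,
        se=se,
        vcov=vcov,
        implied=spec.implied_moments(x, n),
        moments=moments,
        stats=stats_,
        gradient_norm=gnorm,
        f_min=float(f),
    )


def delta_se(fun, result: FitResult, rel_step: float = 1e-6) -> float:
    """Delta-method SE of a scalar function of the free parameters."""
    x = result.theta
    h = rel_step * (1.0 + np.abs(x))
    grad = np.zeros(x.size)
    for j in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[j] += h[j]
        xm[j] -= h[j]
        grad[j] = (fun(xp) - fun(xm)) / (2.0 * h[j])
    var = float(grad @ result.vcov @ grad)
    return float(np.sqrt(var)) if var > 0 else np.nan
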