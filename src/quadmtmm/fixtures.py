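"""Bundled numeric fixtures from the two-rater inattention application.

A published multi-rater validity study of the nine ADHD inattention
symptoms (mother and father ratings of 752 children, three item parcels
per rater on a 0-5 scale) supplies the package's worked example: its
summary-statistic table, the fitted TMU parameter table, and the fitted
quadratic curve coefficients.  ``load_fixture(name)`` returns exact
transcriptions of those printed numbers.
"""

from __future__ import annotations

import numpy as np

from .data_io import moments_from_correlations

__all__ = ["load_fixture", "FIXTURE_NAMES"]

_TABLE1_CORR = np.array(
    [
        [1.00, 0.87, 0.82, 0.77, 0.71, 0.69],
        [0.87, 1.00, 0.85, 0.74, 0.78, 0.72],
        [0.82, 0.85, 1.00, 0.72, 0.72, 0.78],
        [0.77, 0.74, 0.72, 1.00, 0.88, 0.83],
        [0.71, 0.78, 0.72, 0.88, 1.00, 0.86],
        [0.69, 0.72, 0.78, 0.83, 0.86, 1.00],
    ]
)
_TABLE1_MEANS = np.array([0.94, 1.20, 1.10, 0.96, 1.18, 1.11])
_TABLE1_SDS = np.array([0.96, 1.13, 1.05, 0.94, 1.12, 1.08])
_TABLE1_N = 752
_TABLE1_NAMES = ["P1_M1", "P2_M1", "P3_M1", "P1_M2", "P2_M2", "P3_M2"]

_TABLE2 = {
    "mean_T1": 0.954,
    "mean_T2": 0.977,
    "var_T1": 0.759,
    "var_T2": 0.761,
    "cov_T12": 0.637,
    "corr_T12": 0.84,
    "loadings": [1.0, 1.23, 1.09],
    "std_loadings_m1": [0.91, 0.95, 0.90],
    "std_loadings_m2": [0.93, 0.95, 0.90],
    "intercepts": [0.0, 0.03, 0.09],
    "error_vars_m1": [0.13, 0.10, 0.21],
    "error_vars_m2": [0.13, 0.12, 0.22],
    "error_covs": [0.06, 0.03, 0.09],
    "std_error_covs": [0.43, 0.32, 0.44],
}

_REGISTRY = {
    # 6 x 6 summary statistics of the mother/father parcel ratings
    "table1_moments": lambda: moments_from_correlations(
        _TABLE1_CORR, _TABLE1_SDS, _TABLE1_MEANS, _TABLE1_N, _TABLE1_NAMES
    ),
    # fitted TMU parameter table (strong invariance, correlated parcels)
    "table2_estimates": lambda: dict(_TABLE2),
    # fitted quadratic LD curve, mother report as reference
    "quad_ld_coeffs": lambda: (0.24, -0.33, 0.06),
    # fitted quadratic LM curve
    "quad_lm_coeffs": lambda: (-0.034, 0.11, -0.036),
    # textbook-style worked example curve
    "worked_example_coeffs": lambda: (0.6, -0.7, 0.1),
}

FIXTURE_NAMES = tuple(_REGISTRY)


def load_fixture(name: str):
    """Return a bundled fixture: a :class:`MomentSummary`, a dict, or coefficients."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}") from None
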