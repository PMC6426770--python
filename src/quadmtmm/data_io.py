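"""Indicator tables and moment summaries for multitrait-multimethod designs.

The two in-memory currencies of the package are

* :class:`IndicatorTable` — raw subject-by-indicator scores, where each
  column is one (indicator, method) cell of the MTMM design, and
* :class:`MomentSummary` — a mean vector, covariance matrix and sample
  size, which is all a linear structural model needs.

Covariances are maximum-likelihood (divisor ``N``) throughout, matching
the normal-theory fit function used downstream.  Published tables usually
report divisor ``N-1`` standard deviations; at the sample sizes these
models need, the difference is far below the rounding of such tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("quadmtmm")

__all__ = [
    "IndicatorTable",
    "MomentSummary",
    "read_indicator_table",
    "write_indicator_table",
    "default_layout",
    "moments_from_correlations",
    "sample_moments",
    "read_moment_summary",
    "write_moment_summary",
    "mean_parcels",
]


@dataclass
class IndicatorTable:
    """Raw MTMM data: ``values[n, j]`` is subject ``n`` on column ``j``.

    ``layout[j] = (i, m)`` maps column ``j`` to indicator ``i`` of method
    ``m`` (both 1-based, matching the usual subscript convention).
    """

    values: np.ndarray
    layout: list[tuple[int, int]]
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape[1] != len(self.layout):
            raise ValueError("layout length must match number of columns")
        if not self.column_names:
            self.column_names = [f"P{i}_M{m}" for i, m in self.layout]
        self._validate_design()

    def _validate_design(self) -> None:
        pairs = list(self.layout)
        if len(set(pairs)) != len(pairs):
            dupes = sorted({p for p in pairs if pairs.count(p) > 1})
            raise ValueError(f"duplicate (indicator, method) mapping: {dupes}")
        indicators = sorted({i for i, _ in pairs})
        methods = sorted({m for _, m in pairs})
        if len(indicators) < 2:
            raise ValueError("incomplete design: need at least 2 indicators per method")
        if len(methods) < 2:
            raise ValueError("incomplete design: need at least 2 methods")
        expected = {(i, m) for i in indicators for m in methods}
        missing = expected - set(pairs)
        if missing:
            raise ValueError(f"incomplete design: missing cells {sorted(missing)}")
        if self.values.shape[0] < 1:
            raise ValueError("empty table")
        self.n_indicators = len(indicators)
        self.n_methods = len(methods)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def column_order(self) -> np.ndarray:
        """Permutation sorting columns method-major: (1,1)..(I,1),(1,2).."""
        return np.array(
            sorted(range(len(self.layout)), key=lambda j: (self.layout[j][1], self.layout[j][0]))
        )

    def sorted(self) -> "IndicatorTable":
        order = self.column_order()
        return IndicatorTable(
            self.values[:, order],
            [self.layout[j] for j in order],
            [self.column_names[j] for j in order],
        )


@dataclass
class MomentSummary:
    """First and second sample (or implied) moments plus the sample size."""

    means: np.ndarray
    cov: np.ndarray
    n: int
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        p = self.means.size
        if self.cov.shape != (p, p):
            raise ValueError("covariance dimensions do not match mean vector")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")
        if np.any(np.diag(self.cov) < 0):
            raise ValueError("negative variance on the covariance diagonal")
        self.cov = 0.5 * (self.cov + self.cov.T)
        if not self.names:
            self.names = [f"y{j + 1}" for j in range(p)]

    @property
    def p(self) -> int:
        return self.means.size

    def correlations(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.cov))
        return self.cov / np.outer(sd, sd)


def default_layout(columns: list[str]) -> dict[str, tuple[int, int]]:
    """Parse column names of the form ``<anything><i>_<anything><m>``.

    The generated-file convention is ``P<i>_M<m>`` (parcel i, method m);
    any ``<stem><digits>_<stem><digits>`` pair is accepted.
    """
    import re

    layout: dict[str, tuple[int, int]] = {}
    pat = re.compile(r"^\D*(\d+)_\D*(\d+)$")
    for c in columns:
        match = pat.match(c.strip())
        if not match:
            raise ValueError(
                f"cannot infer (indicator, method) from column {c!r}; pass layout_config"
            )
        layout[c] = (int(match.group(1)), int(match.group(2)))
    return layout


def read_indicator_table(
    path, layout_config: dict[str, tuple[int, int]] | None = None, sep: str = ","
) -> IndicatorTable:
    """Read a delimited indicator file, listwise-deleting incomplete rows."""
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if frame.shape[0] == 0:
        raise ValueError("empty table")
    if layout_config is None:
        layout_config = default_layout(list(frame.columns))
    missing_cols = [c for c in layout_config if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"layout refers to absent columns: {missing_cols}")
    cols = list(layout_config)
    sub = frame[cols].apply(pd.to_numeric, errors="coerce")
    non_numeric = sub.isna() & frame[cols].notna()
    if non_numeric.to_numpy().any():
        bad = [c for c in cols if non_numeric[c].any()]
        raise ValueError(f"non-numeric cells in columns: {bad}")
    complete = sub.notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("listwise deletion dropped %d of %d rows", dropped, len(sub))
    sub = sub.loc[complete]
    if sub.shape[0] == 0:
        raise ValueError("empty table after listwise deletion")
    return IndicatorTable(sub.to_numpy(float), [layout_config[c] for c in cols], cols)


def write_indicator_table(table: IndicatorTable, path) -> None:
    pd.DataFrame(table.values, columns=table.column_names).to_csv(path, index=False)


def moments_from_correlations(corr, sds, means, n: int, names=None) -> MomentSummary:
    """Assemble a :class:`MomentSummary` from a published correlation table."""
    corr = np.asarray(corr, dtype=float)
    sds = np.asarray(sds, dtype=float).ravel()
    means = np.asarray(means, dtype=float).ravel()
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix is not symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation diagonal must be 1")
    if np.any(np.abs(corr) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(sds <= 0):
        raise ValueError("standard deviations must be positive")
    cov = corr * np.outer(sds, sds)
    return MomentSummary(means, cov, int(n), list(names) if names else [])


def sample_moments(table: IndicatorTable) -> MomentSummary:
    """ML (divisor-N) sample means and covariance of the observed columns."""
    n = table.n_subjects
    if n < 2:
        raise ValueError("need at least 2 subjects for sample moments")
    values = table.values
    means = values.mean(axis=0)
    centred = values - means
    cov = centred.T @ centred / n
    return MomentSummary(means, cov, n, list(table.column_names))


def read_moment_summary(path) -> MomentSummary:
    """Load a moment summary from YAML/JSON (keys: means, cov or corr+sd, n)."""
    text = open(path).read()
    doc = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    means = doc["means"]
    n = doc["n"]
    names = doc.get("names")
    if "cov" in doc:
        return MomentSummary(means, np.asarray(doc["cov"], float), int(n), names or [])
    return moments_from_correlations(doc["corr"], doc["sd"], means, int(n), names)


def write_moment_summary(moments: MomentSummary, path) -> None:
    doc = {
        "means": [float(x) for x in moments.means],
        "cov": [[float(x) for x in row] for row in moments.cov],
        "n": int(moments.n),
        "names": list(moments.names),
    }
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(doc, fh, indent=1)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


def mean_parcels(items: np.ndarray, assignment: list[list[int]]) -> np.ndarray:
    """Average pre-assigned item columns into parcels (plumbing helper).

    ``assignment[k]`` lists the 0-based item columns of parcel ``k``.  The
    choice of which items form a parcel is up to the caller.
    """
    items = np.asarray(items, dtype=float)
    return np.column_stack([items[:, idx].mean(axis=1) for idx in assignment])
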