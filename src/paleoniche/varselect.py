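"""Predictor screening: pairwise-correlation filtering and niche-stability GAMs.

Collinear predictors destabilize presence-background models, so candidates
are screened greedily in a stated priority order: a variable is dropped when
its absolute Pearson correlation with any already-retained variable exceeds
the threshold (default 0.7).  Categorical candidates (e.g. a biome layer)
cannot enter a Pearson matrix and are passed through on a flag.

Temporal stability of the niche is probed with small penalized-spline
regressions (k = 3) of each variable's values on time, separately for
presence and background records: a significant smooth at presences but not
backgrounds (or vice versa) indicates the occupied environments drifted
relative to the available ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .smooth import SmoothFit, fit_penalized_spline

#: greedy screening order: the headline predictors first, then the rest
DEFAULT_PRIORITY = [
    "temperature",
    "precipitation",
    "npp",
    "bio01",
    "bio12",
    "bio05",
    "bio06",
    "bio10",
    "bio11",
    "bio19",
]


@dataclass
class CorrelationReport:
    candidates: list[str]
    matrix: pd.DataFrame
    retained: list[str]
    dropped: list[tuple[str, str, float]]  # (variable, retained partner, r)
    categorical_passthrough: list[str] = field(default_factory=list)
    constant_dropped: list[str] = field(default_factory=list)


def correlation_filter(
    table: pd.DataFrame,
    candidates: Sequence[str],
    threshold: float = 0.7,
    priority: Sequence[str] | None = None,
    categorical: Sequence[str] = (),
) -> CorrelationReport:
    """Greedy correlation screen over candidate predictors.

    Candidates are visited in priority order (unlisted candidates keep their
    input order after the listed ones); each is retained unless its |Pearson
    r| with an already-retained variable exceeds ``threshold``.  Constant
    variables have undefined correlations and are dropped with a warning
    entry; categorical variables are excluded from the matrix and returned on
    the pass-through list.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate variables")
    if len(table) < 3:
        raise ValueError("need at least three records to estimate correlations")

    cat = [c for c in candidates if c in set(categorical)]
    numeric = [c for c in candidates if c not in set(categorical)]

    order = list(priority if priority is not None else DEFAULT_PRIORITY)
    ordered = [v for v in order if v in numeric] + [v for v in numeric if v not in order]

    data = table[numeric].astype(float)
    constant = [v for v in numeric if data[v].nunique() <= 1 or data[v].std() == 0]
    usable = [v for v in ordered if v not in constant]

    corr = data[usable].corr(method="pearson") if usable else pd.DataFrame()

    retained: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for v in usable:
        clash = None
        for kept in retained:
            r = float(corr.loc[v, kept])
            if abs(r) > threshold:
                clash = (v, kept, r)
                break
        if clash is None:
            retained.append(v)
        else:
            dropped.append(clash)

    return CorrelationReport(
        candidates=candidates,
        matrix=corr,
        retained=retained,
        dropped=dropped,
        categorical_passthrough=cat,
        constant_dropped=constant,
    )


def stability_smooth(
    values: np.ndarray,
    years: np.ndarray,
    k: int = 3,
    lam: float | None = None,
) -> SmoothFit:
    """Penalized spline of a variable's values on years BP (basis dimension k).

    Reports the effective degrees of freedom of the smooth (between 1, a
    straight line, and k - 1) and an approximate Wald-type p-value for any
    departure from a constant mean through time.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=float)
    n_distinct = len(np.unique(years))
    if n_distinct < k:
        raise ValueError(f"need at least {k} distinct years, got {n_distinct}")
    return fit_penalized_spline(years, values, k=k, lam=lam)


def stability_report(
    table: pd.DataFrame,
    variables: Sequence[str],
    k: int = 3,
) -> pd.DataFrame:
    """The six-smooth stability screen: each variable at presences and backgrounds."""
    rows = []
    for label, sub in table.groupby("label"):
        for v in variables:
            fit = stability_smooth(sub[v].values, sub["year_bp"].values, k=k)
            rows.append(
                {
                    "variable": v,
                    "label": label,
                    "k": k,
                    "edf": fit.edf,
                    "p_value": fit.p_value,
                    "lambda": fit.lam,
                }
            )
    return pd.DataFrame(rows)
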