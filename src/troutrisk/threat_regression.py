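"""Ordinal threat-status encoding and the risk-score ~ threat-level regression.

The national threat-classification scheme ranks species on an ordinal ladder
from Not Threatened up to Nationally Critical.  This module encodes those
labels as integers and fits the simple linear regression of trait-based risk
score on threat level by closed-form ordinary least squares, reporting R²,
adjusted R², the F statistic on (1, n-2) degrees of freedom and its p-value.

The default encoding maps seven categories onto 1..6 (Not Threatened = 1 ...
Nationally Critical = 6); Data Deficient has no ordinal position and is
excluded with a warning unless the user supplies an encoding that maps it.
The encoding is fully overridable.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["DEFAULT_ENCODING", "RegressionFit", "encode_threat_status",
           "load_status_table", "fit_linear", "regress_scores_on_status"]

#: Default ordinal encoding: ascending threat severity on 1..6.
DEFAULT_ENCODING: dict[str, int] = {
    "Not Threatened": 1,
    "Naturally Uncommon & Relict": 2,
    "Naturally Uncommon": 2,
    "Relict": 2,
    "Recovering": 3,
    "Declining": 4,
    "Nationally Vulnerable": 5,
    "Nationally Endangered": 6,
    "Nationally Critical": 6,
}


@dataclass(frozen=True)
class RegressionFit:
    """Closed-form OLS fit of y on a single regressor x."""

    slope: float
    intercept: float
    r_squared: float
    adjusted_r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    n: int

    def format_p(self, threshold: float = 0.001) -> str:
        """Report-style p-value string (``"< 0.001"`` below the threshold)."""
        if self.p_value < threshold:
            return f"< {threshold:g}"
        return f"{self.p_value:.3g}"


def encode_threat_status(
    statuses: Mapping[str, str] | Sequence[str],
    encoding: Mapping[str, int] | None = None,
    *,
    drop_unmapped: bool = False,
):
    """Encode status labels as ordinals.

    With a mapping input returns ``{species: ordinal}``; with a sequence
    returns an aligned integer array.  Unknown labels raise unless
    ``drop_unmapped`` is set, in which case they are dropped (mapping input
    only) with a warning — the default encoding deliberately leaves
    "Data Deficient" unmapped.
    """
    enc = dict(DEFAULT_ENCODING if encoding is None else encoding)

    def lookup(label: str, who: str):
        if label not in enc:
            if drop_unmapped:
                warnings.warn(
                    f"excluding {who}: status {label!r} has no ordinal encoding",
                    stacklevel=3,
                )
                return None
            raise KeyError(f"unknown threat status {label!r} for {who}; "
                           f"known: {sorted(enc)}")
        return enc[label]

    if hasattr(statuses, "keys"):
        out = {}
        for sp, label in statuses.items():
            val = lookup(label, sp)
            if val is not None:
                out[sp] = val
        return out
    vals = [lookup(label, f"position {i}") for i, label in enumerate(statuses)]
    return np.array(vals, dtype=int)


def load_status_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (species, status) comma-separated table."""
    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or not row[0].strip():
                continue
            if row[0].strip().lower() == "species":
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: row {row!r} lacks a status column")
            key = "_".join(row[0].strip().lower().split())
            out[key] = row[1].strip()
    return out


def fit_linear(x, y) -> RegressionFit:
    """Ordinary least squares of y on x, by the closed-form normal equations.

    adjusted R² = 1 - (1 - R²)(n - 1)/(n - 2); F = R²(n - 2)/(1 - R²) on
    (1, n - 2) df, p from the exact F survival function.  Requires n >= 3
    and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("x is constant: slope inference undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r2 = 1.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if r2 >= 1.0:
        f = float("inf")
        p = 0.0
    else:
        f = r2 * (n - 2) / (1.0 - r2)
        p = float(stats.f.sf(f, 1, n - 2))
    return RegressionFit(slope=slope, intercept=intercept, r_squared=r2,
                         adjusted_r_squared=adj, f_statistic=f,
                         df=(1, n - 2), p_value=p, n=n)


def regress_scores_on_status(
    scores: Mapping[str, float],
    statuses: Mapping[str, str],
    encoding: Mapping[str, int] | None = None,
) -> RegressionFit:
    """Fit risk score on encoded threat level over the shared species.

    Species missing a status, or with an unmapped status (e.g. Data
    Deficient under the default encoding), are excluded with a warning.
    """
    ordinals = encode_threat_status(statuses, encoding, drop_unmapped=True)
    shared = [sp for sp in scores if sp in ordinals]
    missing = sorted(set(scores) - set(statuses))
    if missing:
        warnings.warn(f"species without threat status excluded: {missing}",
                      stacklevel=2)
    x = [ordinals[sp] for sp in shared]
    y = [scores[sp] for sp in shared]
    return fit_linear(x, y)
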