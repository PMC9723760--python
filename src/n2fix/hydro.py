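"""Derived hydrochemical quantities and profile operations.

Covers the excess-phosphate index P* = PO4 - (NO3+NO2)/16, censoring of nutrient
and chlorophyll values against analytical limits, trapezoidal depth integration of
volumetric quantities to areal rates, threshold-criterion mixed-layer depth, the
Redfield N->C equivalence, and the nonparametric association screen (Spearman rank
correlation and Mann-Whitney U, with exact small-sample permutation nulls).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .isotope import BDL, DNQ, QUANTIFIED

__all__ = [
    "AnalyteLimits",
    "StationProfile",
    "REDFIELD_C_TO_N",
    "p_star",
    "censor_analyte",
    "depth_integrate",
    "mixed_layer_depth",
    "redfield_c_equivalent",
    "spearman_association",
    "mann_whitney",
    "association_screen",
]

#: Canonical marine plankton C:N (Redfield 106:16).
REDFIELD_C_TO_N = 106.0 / 16.0

#: Default analytical limits for the survey's analytes (units of the analyte).
DEFAULT_ANALYTE_LIMITS = {
    "no3no2": (0.01, 0.04),  # umol l^-1
    "po4": (0.01, 0.02),     # umol l^-1
    "chl": (0.002, None),    # ug l^-1, LOD only
}

#: Exact permutation nulls are enumerated up to this sample size.
_EXACT_N_MAX = 8


@dataclass(frozen=True)
class AnalyteLimits:
    """Detection (LOD) and quantitation (LOQ) limits for one analyte."""

    analyte: str
    lod: float
    loq: float | None = None

    def __post_init__(self) -> None:
        if self.loq is not None and self.lod > self.loq:
            raise ValueError("LOD must not exceed LOQ")


@dataclass(frozen=True)
class StationProfile:
    """Ordered depth profile of one station (depths strictly increasing)."""

    station: str
    cruise: str
    depth_m: tuple[float, ...]
    values: dict  # analyte name -> tuple of values aligned with depth_m

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_m, dtype=float)
        if d.size >= 2 and not np.all(np.diff(d) > 0):
            raise ValueError("depths must be strictly increasing")


def p_star(po4: float, no3no2: float) -> float:
    """Excess phosphate P* = PO4 - (NO3+NO2)/16 in umol l^-1; may be negative.

    Missing inputs (NaN) propagate to a NaN result.
    """
    return po4 - no3no2 / 16.0


def censor_analyte(value: float, limits: AnalyteLimits) -> tuple[float, str]:
    """Censor one analyte value against its limits.

    Returns ``(numeric_value, status)``. Below-LOD values get status BDL with
    numeric 0 (the raw value is the caller's to keep); between LOD and LOQ is
    DNQ with the value retained; otherwise quantified.
    """
    if math.isnan(value):
        return value, "missing"
    if value < limits.lod:
        return 0.0, BDL
    if limits.loq is not None and value < limits.loq:
        return value, DNQ
    return value, QUANTIFIED


def depth_integrate(depths, values, z_max: float | None = None,
                    extend_surface: bool = True) -> float:
    """Trapezoidal depth integral of a volumetric quantity.

    ``values`` in per-litre units integrate to per-m^2 with a unit change of
    x1000 l m^-3 folded into the metre-depth integral: nmol l^-1 d^-1 over
    metres -> umol m^-2 d^-1 (and copies l^-1 -> copies m^-2 x1e3, handled the
    same way since nmol l^-1 == umol m^-3).

    The shallowest value is extended unchanged to 0 m unless ``extend_surface``
    is False; integration runs to ``z_max`` (default: deepest sample), with the
    deepest value constant-extrapolated if ``z_max`` exceeds it.
    """
    d = np.asarray(depths, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.shape != v.shape:
        raise ValueError("depths and values must align")
    order = np.argsort(d)
    d, v = d[order], v[order]
    if d.size < 2:
        raise ValueError("need >= 2 depths to integrate")
    if np.any(np.diff(d) <= 0):
        raise ValueError("duplicate depths in profile")
    if extend_surface and d[0] > 0:
        d = np.concatenate([[0.0], d])
        v = np.concatenate([[v[0]], v])
    if z_max is not None:
        if z_max <= d[0]:
            raise ValueError("z_max must exceed the shallowest depth")
        if z_max < d[-1]:
            v_at = np.interp(z_max, d, v)
            keep = d < z_max
            d = np.concatenate([d[keep], [z_max]])
            v = np.concatenate([v[keep], [v_at]])
        elif z_max > d[-1]:
            d = np.concatenate([d, [z_max]])
            v = np.concatenate([v, [v[-1]]])
    return float(np.trapezoid(v, d))


def mixed_layer_depth(depths, values, threshold: float = 0.125,
                      criterion: str = "density") -> tuple[float, str]:
    """Mixed-layer depth by a threshold criterion from the shallowest sample.

    ``values`` is sigma-theta (kg m^-3, default criterion ``"density"``, default
    threshold 0.125) or temperature (``"temperature"``, conventional threshold
    0.2 degC, deviation taken as absolute). Returns ``(mld_m, flag)`` where flag
    is ``"ok"`` or ``"unstratified"`` when the deviation never exceeds the
    threshold (the deepest sample is then returned).

    Linear interpolation between the bracketing samples locates the crossing.
    """
    d = np.asarray(depths, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.size < 2:
        raise ValueError("need >= 2 depths")
    order = np.argsort(d)
    d, v = d[order], v[order]
    ref = v[0]
    if criterion == "density":
        dev = v - ref
    elif criterion == "temperature":
        dev = np.abs(v - ref)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    above = np.nonzero(dev > threshold)[0]
    if above.size == 0:
        return float(d[-1]), "unstratified"
    i = above[0]
    if i == 0:
        return float(d[0]), "ok"
    # interpolate the exact crossing between samples i-1 and i
    frac = (threshold - dev[i - 1]) / (dev[i] - dev[i - 1])
    return float(d[i - 1] + frac * (d[i] - d[i - 1])), "ok"


def redfield_c_equivalent(n_rate: float) -> float:
    """Carbon production supported by a nitrogen input at Redfield C:N (x106/16)."""
    if n_rate < 0:
        raise ValueError("rate must be >= 0")
    return n_rate * REDFIELD_C_TO_N


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_association(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p value.

    For n <= 8 the p value is exact, from the full permutation null of the
    observed y values (ties included); otherwise the large-sample t
    approximation via scipy. A constant variable yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d")
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 paired observations")
    rho = _spearman_rho(x, y)
    if math.isnan(rho):
        return float("nan"), float("nan")
    if n <= _EXACT_N_MAX:
        hits = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(y):
            r = _spearman_rho(x, np.asarray(perm))
            total += 1
            if abs(r) >= target:
                hits += 1
        return rho, hits / total
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p value (exact for small tie-free samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("need >= 1 observation per group")
    method = "exact" if (a.size <= _EXACT_N_MAX and b.size <= _EXACT_N_MAX
                         and np.unique(np.concatenate([a, b])).size == a.size + b.size) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def association_screen(table, pairs=None, group_tests=None):
    """Nonparametric association screen over a table of variables.

    ``table`` is a pandas DataFrame; ``pairs`` an iterable of (x, y) column
    pairs for Spearman rho; ``group_tests`` an iterable of (value_column,
    group_column) for two-group Mann-Whitney U. Rows with missing values are
    dropped pairwise. Returns a DataFrame with columns test, x, y, n, statistic,
    p_value.
    """
    import pandas as pd

    rows = []
    for xcol, ycol in (pairs or []):
        sub = table[[xcol, ycol]].dropna()
        if len(sub) < 3 or sub[xcol].nunique() < 2 or sub[ycol].nunique() < 2:
            rows.append({"test": "spearman", "x": xcol, "y": ycol,
                         "n": len(sub), "statistic": float("nan"),
                         "p_value": float("nan")})
            continue
        rho, p = spearman_association(sub[xcol].to_numpy(), sub[ycol].to_numpy())
        rows.append({"test": "spearman", "x": xcol, "y": ycol, "n": len(sub),
                     "statistic": rho, "p_value": p})
    for vcol, gcol in (group_tests or []):
        sub = table[[vcol, gcol]].dropna()
        levels = sorted(sub[gcol].unique())
        if len(levels) != 2:
            raise ValueError(f"{gcol!r} must have exactly 2 levels, got {levels}")
        a = sub.loc[sub[gcol] == levels[0], vcol].to_numpy()
        b = sub.loc[sub[gcol] == levels[1], vcol].to_numpy()
        u, p = mann_whitney(a, b)
        rows.append({"test": "mannwhitney", "x": vcol, "y": gcol,
                     "n": len(sub), "statistic": u, "p_value": p})
    return pd.DataFrame(rows)
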