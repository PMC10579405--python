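"""Derived interaction analytics: time-resolved interaction strength,
pH--total-SCFA regression and attached--planktonic linearity.

Interaction strength follows the study's definition: the log ratio of a
species' viable cell density in co-culture versus monoculture at matching
time points.  Positive values mean the partner species promotes growth,
negative values mean it suppresses it; the sign commonly flips along the
growth curve as nutrients and pH change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelError, TimeSeries

__all__ = [
    "interaction_strength",
    "fit_ph_scfa",
    "attachment_linearity",
    "LinearFit",
]

_LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0}


def _viable_series(ts, species: str, compartment: str):
    if isinstance(ts, TimeSeries):
        return ts.time, ts.viable(species, compartment)
    t, v = ts  # (time, values) pair
    return np.asarray(t, dtype=float), np.asarray(v, dtype=float)


def interaction_strength(co, mono, species: str, base: str = "e",
                         compartment: str = "planktonic",
                         match_tol_h: float = 2.0) -> pd.DataFrame:
    """Per-time log ratio of viable counts in co- versus monoculture.

    Accepts :class:`TimeSeries` objects or ``(time, viable)`` pairs.  Time
    grids are matched nearest-neighbor within ``match_tol_h`` hours;
    unmatched co-culture points are filled by linear interpolation of the
    monoculture's log density.  Points with a non-positive monoculture
    count are marked undefined rather than imputed.  Returns a DataFrame
    with columns time_h, log_ratio, defined, log_base.
    """
    if base not in _LOG_BASES:
        raise ModelError(f"unknown log base {base!r}; use one of {list(_LOG_BASES)}")
    b = _LOG_BASES[base]
    t_co, v_co = _viable_series(co, species, compartment)
    t_mono, v_mono = _viable_series(mono, species, compartment)
    rows = []
    order = np.argsort(t_mono)
    t_mono, v_mono = t_mono[order], v_mono[order]
    pos = v_mono > 0
    for t, vc in zip(t_co, v_co):
        i = int(np.argmin(np.abs(t_mono - t)))
        if abs(t_mono[i] - t) <= match_tol_h:
            vm = v_mono[i]
        elif pos.sum() >= 2 and t_mono[pos].min() <= t <= t_mono[pos].max():
            vm = float(np.exp(np.interp(t, t_mono[pos], np.log(v_mono[pos]))))
        else:
            vm = np.nan
        defined = np.isfinite(vm) and vm > 0 and vc > 0
        s = math.log(vc / vm, b) if defined else np.nan
        rows.append({"time_h": float(t), "log_ratio": s, "defined": defined})
    out = pd.DataFrame(rows)
    out["log_base"] = base
    return out


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    stderr: float
    n: int


def _ols(x: np.ndarray, y: np.ndarray, through_origin: bool = False) -> LinearFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ModelError("need at least three paired observations")
    if np.ptp(x) == 0:
        raise ModelError("degenerate regression: predictor is constant")
    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        resid = y - slope * x
        ss_tot = float(np.dot(y, y))
        r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot else 0.0
        dof = max(len(x) - 1, 1)
        se = math.sqrt(float(np.dot(resid, resid)) / dof / float(np.dot(x, x)))
        return LinearFit(slope, 0.0, r2, se, len(x))
    res = stats.linregress(x, y)
    return LinearFit(float(res.slope), float(res.intercept),
                     float(res.rvalue) ** 2, float(res.stderr), len(x))


def fit_ph_scfa(ph, scfa_sum) -> LinearFit:
    """OLS of pH on the summed SCFA concentration (slope expected < 0)."""
    return _ols(scfa_sum, ph)


def attachment_linearity(attached, planktonic,
                         through_origin: bool = False) -> LinearFit:
    """OLS of attached on planktonic viable counts.

    Under the fixed-attached-fraction assumption the slope equals
    f_att / (1 - f_att).
    """
    return _ols(planktonic, attached, through_origin=through_origin)
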