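"""Parameter calibration: fitting the kinetic model to observed (or
synthetic) time series, with recovery diagnostics.

The study tuned its parameters manually; this module automates that with a
weighted least-squares objective over three observation blocks:

* cell densities, compared as log10(viable + 1) so that residuals are
  meaningful across the four decades the trajectories span;
* metabolite concentrations (mM);
* pH.

Several scenarios (mono- and co-cultures, with and without mucin) can be
fitted jointly with a shared parameter set, mirroring the fact that a
single parameterization generates all of the study's panels.  The search
runs an optional bounded global stage (differential evolution) followed by
local least-squares refinement; free parameters are handled in log space,
which keeps them positive and makes the search scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, least_squares

from .model import ModelError, ModelParams, ScenarioConfig, TimeSeries, simulate
from .synth import grid_for

__all__ = ["FitSpec", "FitResult", "loss", "residuals", "fit"]


@dataclass
class FitSpec:
    """What to fit and how.

    ``free`` maps parameter names to (lower, upper) bounds; ``fixed`` is the
    base parameter set supplying everything else.  Weights scale the
    residual blocks.  ``global_maxiter=0`` skips the evolution stage.
    """

    free: dict = field(default_factory=dict)
    fixed: ModelParams = field(default_factory=ModelParams)
    w_counts: float = 1.0
    w_metabolites: float = 1.0
    w_ph: float = 1.0
    seed: int = 0
    max_evals: int = 2000
    global_maxiter: int = 20
    global_popsize: int = 8

    def __post_init__(self) -> None:
        if not self.free:
            raise ModelError("no free parameters specified")
        for name, (lo, hi) in self.free.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                raise ModelError(f"bounds for {name} must be finite, positive "
                                 "and ordered")
        if min(self.w_counts, self.w_metabolites, self.w_ph) < 0:
            raise ModelError("weights must be non-negative")
        if self.w_counts + self.w_metabolites + self.w_ph == 0:
            raise ModelError("at least one weight must be positive")

    @property
    def names(self) -> list[str]:
        return list(self.free)

    def params_from_vector(self, x: np.ndarray) -> ModelParams:
        updates = dict(zip(self.names, np.exp(np.asarray(x, dtype=float))))
        return self.fixed.replace(**updates)

    def vector_from_params(self, params: ModelParams) -> np.ndarray:
        return np.log([getattr(params, n) for n in self.names])

    @property
    def log_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.log([self.free[n][0] for n in self.names])
        hi = np.log([self.free[n][1] for n in self.names])
        return lo, hi


_COUNT_BLOCKS = (("bt", ("bt_fast", "bt_slow")), ("ri", ("ri_fast", "ri_slow")))
_MET_COLS = ("G", "M", "A", "Bu", "acid_other")


def _pair_residuals(sim: TimeSeries, obs: TimeSeries, spec: FitSpec) -> np.ndarray:
    """Residual vector for one scenario, simulation vs one observed table."""
    out = []
    sim_df = sim.data.set_index("time_h")
    obs_df = obs.data.set_index("time_h")
    common = sim_df.index.intersection(obs_df.index)
    if len(common) == 0:
        raise ModelError("no common time points between simulation and data")
    s, o = sim_df.loc[common], obs_df.loc[common]
    if spec.w_counts > 0:
        for _, cols in _COUNT_BLOCKS:
            have = [c for c in cols if c in o.columns]
            if not have:
                continue
            vs = s[list(cols)].sum(axis=1).to_numpy()
            vo = o[have].sum(axis=1).to_numpy()
            mask = np.isfinite(vo)
            out.append(spec.w_counts * (np.log10(vs[mask] + 1.0)
                                        - np.log10(vo[mask] + 1.0)))
    if spec.w_metabolites > 0:
        for c in _MET_COLS:
            if c in o.columns:
                vo = o[c].to_numpy()
                mask = np.isfinite(vo)
                out.append(spec.w_metabolites * (s[c].to_numpy()[mask] - vo[mask]))
    if spec.w_ph > 0 and "pH" in o.columns:
        vo = o["pH"].to_numpy()
        mask = np.isfinite(vo)
        out.append(spec.w_ph * (s["pH"].to_numpy()[mask] - vo[mask]))
    return np.concatenate(out) if out else np.zeros(0)


def residuals(params: ModelParams, observed, spec: FitSpec) -> np.ndarray:
    """Stacked residual vector over all (scenario, replicate) pairs.

    ``observed`` is a list of ``(ScenarioConfig, [TimeSeries, ...])`` pairs;
    a bare TimeSeries is accepted in place of the list.
    """
    res = []
    for scenario, tables in observed:
        if isinstance(tables, TimeSeries):
            tables = [tables]
        t_end = max(t.time.max() for t in tables)
        sim = simulate(scenario, params, grid_for(t_end))
        for obs in tables:
            res.append(_pair_residuals(sim, obs, spec))
    return np.concatenate(res)


def loss(params: ModelParams, observed, spec: FitSpec) -> float:
    """Weighted sum of squared residuals; +inf if the simulation fails."""
    try:
        r = residuals(params, observed, spec)
    except ModelError:
        return np.inf
    return float(np.dot(r, r))


@dataclass
class FitResult:
    params: ModelParams
    loss: float
    success: bool
    nfev: int
    free_values: dict
    trace: list
    message: str = ""

    def residual_table(self, observed, spec: FitSpec) -> pd.DataFrame:
        r = residuals(self.params, observed, spec)
        return pd.DataFrame({"residual": r})


def fit(observed, spec: FitSpec, seed: int | None = None,
        x0: np.ndarray | ModelParams | None = None) -> FitResult:
    """Bounded global search plus local refinement.

    ``observed`` as in :func:`residuals`.  The evolution stage (skipped when
    ``spec.global_maxiter == 0``) explores the log-bounded box; the local
    stage polishes with least squares.  Deterministic for a fixed seed.
    """
    if seed is None:
        seed = spec.seed
    lo, hi = spec.log_bounds
    trace: list = []
    nfev = 0

    def track(x):
        nonlocal nfev
        nfev += 1
        val = loss(spec.params_from_vector(x), observed, spec)
        if not trace or val < trace[-1][1]:
            trace.append((nfev, val))
        return val

    if x0 is None:
        x_start = spec.vector_from_params(spec.fixed)
    elif isinstance(x0, ModelParams):
        x_start = spec.vector_from_params(x0)
    else:
        x_start = np.asarray(x0, dtype=float)
    x_start = np.clip(x_start, lo, hi)

    if spec.global_maxiter > 0:
        de = differential_evolution(
            track, bounds=list(zip(lo, hi)), seed=seed,
            maxiter=spec.global_maxiter, popsize=spec.global_popsize,
            init="sobol", tol=1e-8, polish=False, x0=x_start,
        )
        x_start = de.x

    def resid_vec(x):
        nonlocal nfev
        nfev += 1
        try:
            return residuals(spec.params_from_vector(x), observed, spec)
        except ModelError:
            return np.full(max(1, len(trace)), 1e6)

    ls = least_squares(resid_vec, x_start, bounds=(lo, hi),
                       max_nfev=spec.max_evals, xtol=1e-12, ftol=1e-12,
                       gtol=1e-12)
    best = spec.params_from_vector(ls.x)
    final = loss(best, observed, spec)
    trace.append((nfev, final))
    if not np.isfinite(final):
        raise ModelError("fit failed: objective not finite at the optimum")
    return FitResult(params=best, loss=final, success=bool(ls.success),
                     nfev=nfev,
                     free_values=dict(zip(spec.names, np.exp(ls.x))),
                     trace=trace, message=str(ls.message))
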