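"""Kinetic ODE model of the BT/RI mucin-bead batch co-culture.

The model tracks two species -- the primary fermenter *Bacteroides
thetaiotaomicron* (BT) and the butyrate producer *Roseburia intestinalis*
(RI) -- in a closed batch bottle, optionally containing mucin beads.
Each species is split into a glucose-fed "fast" growth state, a post-glucose
"slow" growth state (mucin foraging for BT, lactate/acetate consumption for
RI) and an inviable pool.  Substrates are lumped: G = glucose + pyruvate,
M = mucin-derived sugars, A = acetate + lactate, Bu = butyrate and a pool of
other acids (succinate + formate).  The pH is not an independent state: it is
an affine function of the total acid concentration, reflecting the observed
linear pH--sum(SCFA) relationship, and feeds back on growth through a steep
Hill factor per species, with BT the more acid-sensitive of the two.

Mechanistic assumptions encoded here:

* a fixed fraction of each species' cells is attached to the beads and only
  attached viable cells release mucin sugars; the mucin polymer itself is
  inexhaustible and not a state variable;
* mucin sugars inhibit RI's growth on glucose; glucose inhibits BT's growth
  on mucin sugars (carbon-catabolite-style repression in both directions);
* RI switches to its lactate/acetate slow mode only when glucose AND mucin
  sugars are low; BT switches to mucin foraging when glucose is low;
* BT loses viability at low pH only when it has no energy source; RI instead
  persists by entering the slow mode, whose viable count slowly decays;
* RI's slow mode converts acetate/lactate to butyrate with a net loss of
  acid moles, so the pH drifts back up late in the fermentation.

Units: cell densities in cells/ul of culture, concentrations in mM,
time in hours.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.special import expit

__all__ = [
    "STATE_NAMES",
    "ModelParams",
    "ScenarioConfig",
    "SystemState",
    "TimeSeries",
    "ph_from_acids",
    "ph_growth_factor",
    "rhs",
    "simulate",
    "default_params",
    "scenario_presets",
    "EXPERIMENTAL_GRID",
]

#: State-vector layout used by :func:`rhs` and :func:`simulate`.
STATE_NAMES = (
    "bt_fast",
    "bt_slow",
    "bt_dead",
    "ri_fast",
    "ri_slow",
    "ri_dead",
    "G",
    "M",
    "A",
    "Bu",
    "acid_other",
)

#: The experimental sampling grid: every 4 h for 0-48 h, every 12 h to 120 h.
EXPERIMENTAL_GRID = tuple(float(t) for t in list(range(0, 49, 4)) + list(range(60, 121, 12)))


class ModelError(ValueError):
    """Domain or configuration error raised by the kinetic model."""


@dataclass
class ModelParams:
    """Rate constants, yields, thresholds and pH-response parameters.

    Defaults are the package's calibrated set, tuned so the six study
    scenarios (mono/co-culture, with/without mucin) reproduce the reported
    peak viable densities, peak times and pH endpoints.
    """

    # Maximum specific growth rates (1/h)
    mu_bt_G: float = 0.45      # BT fast mode on glucose+pyruvate
    mu_ri_G: float = 0.369      # RI fast mode on glucose+pyruvate
    mu_bt_M: float = 0.30      # BT slow mode on mucin sugars
    mu_ri_M: float = 0.0       # RI on mucin sugars (negligible; kept as a dial)
    mu_ri_A: float = 0.015     # RI slow mode on acetate+lactate

    # Half-saturation constants (mM)
    K_G: float = 0.25
    K_M: float = 0.03
    K_A: float = 4.0
    # Much lower mucin-sugar level sufficing for maintenance energy
    K_M_maint: float = 0.005

    # Cross-inhibition constants (mM)
    KI_M_ri: float = 0.435      # mucin sugars inhibit RI growth on G
    n_MI: float = 4.3          # Hill exponent of that inhibition (threshold-like)
    KI_G_bt: float = 2.0       # glucose inhibits BT growth on M

    # Biomass yields (cells/ul per mM substrate)
    Y_bt_G: float = 9.0e4
    Y_ri_G: float = 5.5e4
    Y_bt_M: float = 4.0e4
    Y_ri_A: float = 1.5e4

    # Acid production yields (mM acid per mM substrate consumed)
    y_A_bt: float = 1.05       # acetate+lactate from BT on G
    y_other_bt: float = 1.0    # succinate+formate from BT on G
    y_A_bt_M: float = 0.12     # acetate+lactate from BT on mucin sugars
    y_other_bt_M: float = 0.12  # succinate+formate from BT on mucin sugars
    y_A_ri: float = 0.55       # acetate+lactate from RI fast mode
    y_bu_ri: float = 0.27      # butyrate from RI fast mode
    y_other_ri: float = 0.58   # formate from RI fast mode
    y_bu_from_A: float = 0.5   # butyrate per mM A consumed in RI slow mode

    # Mucin-sugar release per attached viable cell (mM * ul / cells / h)
    r_M: float = 1.23e-6
    # Fixed attached fractions of total cells (dimensionless)
    f_att_bt: float = 0.33
    f_att_ri: float = 0.25

    # State switching fast -> slow
    k_switch_bt: float = 0.30  # 1/h
    k_switch_ri: float = 0.50  # 1/h
    theta_G: float = 0.50      # mM, low-glucose trigger
    theta_M: float = 0.30      # mM, low-mucin-sugar trigger (RI only)
    switch_eps_G: float = 0.10  # mM, smoothing width of the glucose trigger
    switch_eps_M: float = 0.10  # mM, smoothing width of the mucin trigger

    # Death rates (1/h)
    d_bt: float = 0.035        # BT, acid-driven when starved
    m_bt: float = 0.0092        # BT slow mode, pH-homeostasis maintenance cost
    d_ri: float = 0.058        # RI fast mode, starvation-driven
    d_ri_slow: float = 0.012   # RI slow mode, constant decay

    # pH coupling
    pH0: float = 6.7           # initial medium pH
    c_pH: float = 0.055        # pH drop per mM total acid
    pH_floor: float = 4.0
    pH_half_bt: float = 5.4    # BT growth half-inhibited here
    pH_half_ri: float = 4.8    # RI growth half-inhibited here (less sensitive)
    n_pH: float = 18.0         # Hill steepness of the pH response

    def __post_init__(self) -> None:
        positive = [
            "mu_bt_G", "mu_ri_G", "mu_bt_M", "mu_ri_A", "K_G", "K_M", "K_A",
            "K_M_maint", "KI_M_ri", "n_MI", "KI_G_bt", "Y_bt_G", "Y_ri_G",
            "Y_bt_M", "Y_ri_A", "r_M", "theta_G", "theta_M",
            "switch_eps_G", "switch_eps_M",
            "c_pH", "pH_half_bt", "pH_half_ri", "n_pH",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ModelError(f"parameter {name} must be strictly positive")
        # Switching, death and maintenance rates may be zeroed to obtain
        # reduced sub-models (e.g. the plain Monod batch oracle).
        for name in ("mu_ri_M", "y_A_bt", "y_other_bt", "y_A_bt_M",
                     "y_other_bt_M", "y_A_ri", "y_bu_ri",
                     "y_other_ri", "y_bu_from_A", "k_switch_bt",
                     "k_switch_ri", "d_bt", "m_bt", "d_ri", "d_ri_slow"):
            if getattr(self, name) < 0:
                raise ModelError(f"parameter {name} must be non-negative")
        for name in ("f_att_bt", "f_att_ri"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ModelError(f"{name} must lie in (0, 1)")
        if not self.pH_half_bt > self.pH_half_ri:
            raise ModelError("pH_half_bt must exceed pH_half_ri "
                             "(BT is the more acid-sensitive species)")

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ModelError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**d)


@dataclass
class ScenarioConfig:
    """A cultivation scenario: which species, mucin or not, initial medium."""

    species: str = "co"                # {"BT_mono", "RI_mono", "co"}
    mucin_present: bool = False
    t_end: float = 120.0               # h
    inoculum_bt: float = 1.2e3         # cells/ul
    inoculum_ri: float = 1.8e3         # cells/ul
    G0: float = 14.6                   # mM lumped glucose+pyruvate
    M0: float = 0.0
    A0: float = 0.0
    Bu0: float = 0.0
    acid_other0: float = 0.0
    ph_override: float | None = None   # fixed pH (pH-preference experiments)
    name: str = ""

    VALID_SPECIES = ("BT_mono", "RI_mono", "co")

    def __post_init__(self) -> None:
        if self.species not in self.VALID_SPECIES:
            raise ModelError(f"unknown scenario species {self.species!r}")
        if self.t_end <= 0:
            raise ModelError("t_end must be positive")
        if self.species == "BT_mono" and self.inoculum_ri != 0.0:
            self.inoculum_ri = 0.0
        if self.species == "RI_mono" and self.inoculum_bt != 0.0:
            self.inoculum_bt = 0.0
        if min(self.inoculum_bt, self.inoculum_ri, self.G0, self.M0, self.A0,
               self.Bu0, self.acid_other0) < 0:
            raise ModelError("initial conditions must be non-negative")
        if not self.name:
            self.name = f"{self.species}_{'mucin' if self.mucin_present else 'WC'}"

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(len(STATE_NAMES))
        y0[STATE_NAMES.index("bt_fast")] = self.inoculum_bt
        y0[STATE_NAMES.index("ri_fast")] = self.inoculum_ri
        y0[STATE_NAMES.index("G")] = self.G0
        y0[STATE_NAMES.index("M")] = self.M0 if self.mucin_present else 0.0
        y0[STATE_NAMES.index("A")] = self.A0
        y0[STATE_NAMES.index("Bu")] = self.Bu0
        y0[STATE_NAMES.index("acid_other")] = self.acid_other0
        return y0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)


@dataclass
class SystemState:
    """Named view of one instantaneous state vector (cells/ul and mM)."""

    bt_fast: float = 0.0
    bt_slow: float = 0.0
    bt_dead: float = 0.0
    ri_fast: float = 0.0
    ri_slow: float = 0.0
    ri_dead: float = 0.0
    G: float = 0.0
    M: float = 0.0
    A: float = 0.0
    Bu: float = 0.0
    acid_other: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "SystemState":
        return cls(**dict(zip(STATE_NAMES, map(float, y))))

    @property
    def bt_viable(self) -> float:
        return self.bt_fast + self.bt_slow

    @property
    def ri_viable(self) -> float:
        return self.ri_fast + self.ri_slow


def ph_from_acids(A, Bu, acid_other, params: ModelParams):
    """pH as an affine, floored function of the total acid concentration.

    pH = max(pH_floor, pH0 - c_pH * (A + Bu + acid_other)).  Accepts scalars
    or arrays; raises on negative concentrations.
    """
    A = np.asarray(A, dtype=float)
    Bu = np.asarray(Bu, dtype=float)
    acid_other = np.asarray(acid_other, dtype=float)
    if np.any(A < 0) or np.any(Bu < 0) or np.any(acid_other < 0):
        raise ModelError("acid concentrations must be non-negative")
    ph = params.pH0 - params.c_pH * (A + Bu + acid_other)
    out = np.maximum(ph, params.pH_floor)
    return float(out) if out.ndim == 0 else out


def ph_growth_factor(ph, pH_half: float, n_pH: float):
    """Sigmoidal (Hill) pH response of growth, in [0, 1].

    Equals 0.5 at ``pH_half``, approaches 1 at circumneutral pH and 0 in
    strongly acidic medium; strictly increasing in pH.
    """
    ph = np.asarray(ph, dtype=float)
    if np.any(ph < 0) or np.any(ph > 14):
        raise ModelError("pH must lie in [0, 14]")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(ph > 0, pH_half / np.maximum(ph, 1e-12), np.inf)
        out = 1.0 / (1.0 + ratio ** n_pH)
    out = np.where(ph <= 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def _smooth_step(x, eps: float):
    """Smooth logistic threshold sigma(x) = 1/(1+exp(-x/eps))."""
    return expit(np.asarray(x, dtype=float) / eps)


def rhs(t: float, y: Sequence[float], params: ModelParams,
        scenario: ScenarioConfig) -> np.ndarray:
    """Time derivative of the full state vector (order :data:`STATE_NAMES`).

    Raises :class:`ModelError` if any state component is materially negative
    (below -1e-6 in its own units); tiny negative excursions from the
    integrator are clipped to zero before evaluating the kinetics.
    """
    y = np.asarray(y, dtype=float)
    # Stiff solvers probe slightly negative trial states; clip those, but a
    # grossly negative component means the caller fed a bad state.
    if np.any(y < -1e-3 * (1.0 + np.abs(y).max())):
        raise ModelError(f"negative state component at t={t}: {y}")
    y = np.maximum(y, 0.0)
    (bt_f, bt_s, bt_d, ri_f, ri_s, ri_d, G, M, A, Bu, other) = y
    p = params

    if scenario.ph_override is not None:
        ph = scenario.ph_override
    else:
        ph = ph_from_acids(A, Bu, other, p)
    phi_bt = ph_growth_factor(ph, p.pH_half_bt, p.n_pH)
    phi_ri = ph_growth_factor(ph, p.pH_half_ri, p.n_pH)

    monod_G = G / (p.K_G + G)
    monod_M = M / (p.K_M + M)
    monod_A = A / (p.K_A + A)

    # Growth fluxes (cells/ul/h)
    inhib_M_ri = p.KI_M_ri ** p.n_MI / (p.KI_M_ri ** p.n_MI + M ** p.n_MI)
    rho_bt_f = p.mu_bt_G * monod_G * phi_bt * bt_f
    rho_bt_s = p.mu_bt_M * monod_M * p.KI_G_bt / (p.KI_G_bt + G) * phi_bt * bt_s
    rho_ri_G = p.mu_ri_G * monod_G * inhib_M_ri * phi_ri * ri_f
    rho_ri_f = rho_ri_G + p.mu_ri_M * monod_M * phi_ri * ri_f
    rho_ri_s = p.mu_ri_A * monod_A * phi_ri * ri_s

    # Substrate fluxes (mM/h)
    q_G = rho_bt_f / p.Y_bt_G + rho_ri_G / p.Y_ri_G
    q_M = rho_bt_s / p.Y_bt_M + (p.mu_ri_M * monod_M * phi_ri * ri_f) / p.Y_bt_M
    q_A = rho_ri_s / p.Y_ri_A  # RI slow-mode acetate/lactate consumption

    # State switching fast -> slow.  RI requires BOTH glucose and mucin
    # sugars to be low; BT needs only low glucose (its slow mode feeds on M).
    sw_bt = p.k_switch_bt * _smooth_step(p.theta_G - G, p.switch_eps_G) * bt_f
    sw_ri = (p.k_switch_ri * _smooth_step(p.theta_G - G, p.switch_eps_G)
             * _smooth_step(p.theta_M - M, p.switch_eps_M) * ri_f)

    # Death.  BT: acid-driven, suppressed while an energy source is available.
    # RI fast: starvation-driven; RI slow: constant slow decay.
    energy_bt = max(monod_G, M / (p.K_M_maint + M))
    death_bt_f = p.d_bt * (1.0 - phi_bt) * (1.0 - energy_bt) * bt_f
    # Mucin foraging at low pH diverts energy to pH homeostasis: the slow
    # mode pays a maintenance cost that balances growth near a pH set-point.
    death_bt_s = (p.d_bt * (1.0 - phi_bt) * (1.0 - energy_bt)
                  + p.m_bt * (1.0 - phi_bt)) * bt_s
    death_ri_f = p.d_ri * (1.0 - monod_G) * ri_f
    death_ri_s = p.d_ri_slow * ri_s

    dy = np.empty_like(y)
    dy[0] = rho_bt_f - sw_bt - death_bt_f
    dy[1] = rho_bt_s + sw_bt - death_bt_s
    dy[2] = death_bt_f + death_bt_s
    dy[3] = rho_ri_f - sw_ri - death_ri_f
    dy[4] = rho_ri_s + sw_ri - death_ri_s
    dy[5] = death_ri_f + death_ri_s

    dy[6] = -q_G
    if scenario.mucin_present:
        release = p.r_M * (p.f_att_bt * (bt_f + bt_s) + p.f_att_ri * (ri_f + ri_s))
        dy[7] = release - q_M
    else:
        dy[7] = 0.0
    bt_G_flux = rho_bt_f / p.Y_bt_G
    bt_M_flux = rho_bt_s / p.Y_bt_M
    ri_G_flux = rho_ri_G / p.Y_ri_G
    dy[8] = (p.y_A_bt * bt_G_flux + p.y_A_bt_M * bt_M_flux
             + p.y_A_ri * ri_G_flux - q_A)
    dy[9] = p.y_bu_ri * ri_G_flux + p.y_bu_from_A * q_A
    dy[10] = (p.y_other_bt * bt_G_flux + p.y_other_bt_M * bt_M_flux
              + p.y_other_ri * ri_G_flux)
    return dy


@dataclass
class TimeSeries:
    """Trajectories of densities, metabolites and pH on a time grid.

    ``data`` is a wide DataFrame with a ``time_h`` column, the state columns
    of :data:`STATE_NAMES`, derived viable/total densities and ``pH``.
    ``f_att`` maps species to the attached fraction used for the
    planktonic/attached split (empty for scenarios without beads).
    """

    data: pd.DataFrame
    f_att: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    COMPARTMENTS = ("total", "planktonic", "attached")

    @property
    def time(self) -> np.ndarray:
        return self.data["time_h"].to_numpy()

    def _split(self, species: str, values: np.ndarray,
               compartment: str) -> np.ndarray:
        if compartment not in self.COMPARTMENTS:
            raise ModelError(f"unknown compartment {compartment!r}")
        f = self.f_att.get(species, 0.0)
        if compartment == "total":
            return values
        if compartment == "attached":
            return f * values
        return (1.0 - f) * values

    def viable(self, species: str, compartment: str = "planktonic") -> np.ndarray:
        col = self.data[f"{species}_fast"] + self.data[f"{species}_slow"]
        return self._split(species, col.to_numpy(), compartment)

    def total_cells(self, species: str, compartment: str = "planktonic") -> np.ndarray:
        col = (self.data[f"{species}_fast"] + self.data[f"{species}_slow"]
               + self.data[f"{species}_dead"])
        return self._split(species, col.to_numpy(), compartment)

    def ph(self) -> np.ndarray:
        return self.data["pH"].to_numpy()

    def metabolite(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def peak(self, species: str, compartment: str = "planktonic"):
        """(time, value) of the maximum viable density for ``species``."""
        v = self.viable(species, compartment)
        i = int(np.argmax(v))
        return float(self.time[i]), float(v[i])

    def value_at(self, column: str, t: float) -> float:
        """Linearly interpolated value of a wide-format column at time t."""
        return float(np.interp(t, self.time, self.data[column].to_numpy()))

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: time_h, variable, compartment, value, units."""
        rows = []
        t = self.time
        for sp in ("bt", "ri"):
            if not (self.data[f"{sp}_fast"] + self.data[f"{sp}_slow"]
                    + self.data[f"{sp}_dead"]).abs().sum() and sp not in self.f_att:
                pass  # keep zero trajectories too; they are informative
            for comp in self.COMPARTMENTS:
                for var, vals in (
                    (f"{sp}_viable", self.viable(sp, comp)),
                    (f"{sp}_total", self.total_cells(sp, comp)),
                ):
                    rows.append(pd.DataFrame({
                        "time_h": t, "variable": var, "compartment": comp,
                        "value": vals, "units": "cells/ul"}))
            for state in ("fast", "slow", "dead"):
                rows.append(pd.DataFrame({
                    "time_h": t, "variable": f"{sp}_{state}", "compartment": "total",
                    "value": self.data[f"{sp}_{state}"].to_numpy(),
                    "units": "cells/ul"}))
        for met in ("G", "M", "A", "Bu", "acid_other"):
            rows.append(pd.DataFrame({
                "time_h": t, "variable": met, "compartment": "total",
                "value": self.data[met].to_numpy(), "units": "mM"}))
        rows.append(pd.DataFrame({
            "time_h": t, "variable": "pH", "compartment": "total",
            "value": self.ph(), "units": "pH"}))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, f_att: dict | None = None,
                  meta: dict | None = None) -> "TimeSeries":
        base = tidy[tidy["compartment"] == "total"]
        wide = base.pivot_table(index="time_h", columns="variable",
                                values="value", sort=True)
        wide = wide.reset_index()
        wide.columns.name = None
        # Reconstruct any missing state columns from zeros
        for col in STATE_NAMES:
            if col not in wide:
                wide[col] = 0.0
        if "pH" not in wide:
            raise ModelError("tidy table lacks a pH variable")
        return cls(data=wide, f_att=dict(f_att or {}), meta=dict(meta or {}))


def simulate(scenario: ScenarioConfig, params: ModelParams,
             t_grid: Iterable[float] | None = None,
             rtol: float = 1e-8, atol: float = 1e-6) -> TimeSeries:
    """Integrate the model over ``t_grid`` (default: the experimental grid).

    Uses a stiff-capable integrator (LSODA); raises :class:`ModelError` on
    integrator failure or on negative overshoot beyond tolerance.
    """
    if t_grid is None:
        t_grid = [t for t in EXPERIMENTAL_GRID if t <= scenario.t_end]
        if t_grid[-1] < scenario.t_end:
            t_grid.append(scenario.t_end)
    t_grid = np.asarray(list(t_grid), dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or t_grid[0] != 0.0 \
            or np.any(np.diff(t_grid) <= 0):
        raise ModelError("t_grid must be strictly increasing and start at 0")

    y0 = scenario.initial_state()
    sol = solve_ivp(
        rhs, (0.0, float(t_grid[-1])), y0, t_eval=t_grid,
        args=(params, scenario), method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise ModelError(f"integration failed for scenario "
                         f"{scenario.name!r}: {sol.message}")
    Y = sol.y.T
    # Allow solver-noise-level undershoot (well below one cell or one uM),
    # then clip; anything larger signals a real integration problem.
    if Y.min() < -1e-2:
        raise ModelError(f"negative overshoot beyond tolerance: min={Y.min():g}")
    Y = np.maximum(Y, 0.0)

    df = pd.DataFrame(Y, columns=list(STATE_NAMES))
    df.insert(0, "time_h", sol.t)
    if scenario.ph_override is not None:
        df["pH"] = scenario.ph_override
    else:
        df["pH"] = ph_from_acids(df["A"], df["Bu"], df["acid_other"], params)
    f_att = {}
    if scenario.mucin_present:
        f_att = {"bt": params.f_att_bt, "ri": params.f_att_ri}
    meta = {"scenario": scenario.name, "species": scenario.species,
            "mucin_present": scenario.mucin_present}
    return TimeSeries(data=df, f_att=f_att, meta=meta)


def default_params() -> ModelParams:
    """The calibrated default parameter set."""
    return ModelParams()


def scenario_presets() -> dict[str, ScenarioConfig]:
    """The six study scenarios: {BT mono, RI mono, co} x {WC, WC+mucin}."""
    out = {}
    for species in ("BT_mono", "RI_mono", "co"):
        for mucin in (False, True):
            sc = ScenarioConfig(species=species, mucin_present=mucin)
            out[sc.name] = sc
    return out
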