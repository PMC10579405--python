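"""Synthetic data generation: noisy model trajectories and labeled
flow-cytometry event mixtures.

Everything the downstream modules consume can be generated here, so the
whole pipeline is testable without the study's deposited raw data.  Two
generators are provided:

``generate_timeseries``
    integrates the kinetic model on the experimental sampling grid (every
    4 h for 0--48 h, every 12 h to 120 h) and applies replicate noise:
    multiplicative lognormal noise on cell counts (mean-preserving, given
    coefficient of variation) and additive Gaussian noise, truncated at
    zero, on metabolite concentrations and pH.  The noise model emulates
    the replicate-to-replicate scatter of biological replicates.

``generate_flow_events``
    draws per-event channel intensities (FSC, SSC, SG and PI fluorescence)
    from per-population multivariate lognormal distributions -- normal in
    log10 channel space -- for the five populations the gating pipeline
    distinguishes: live BT, live RI, inviable cells, debris and blank
    (sterile-medium background) events.  Population separations are
    parameterized in pooled-SD units so classification difficulty is
    controllable, and ground-truth labels are retained.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParams, ScenarioConfig, TimeSeries, simulate, EXPERIMENTAL_GRID

__all__ = [
    "NoiseSpec",
    "PopulationSpec",
    "EventTable",
    "CHANNELS",
    "POPULATIONS",
    "generate_timeseries",
    "generate_flow_events",
    "make_population_spec",
]

#: Measured flow-cytometry channels (arbitrary fluorescence/scatter units).
CHANNELS = ("FSC", "SSC", "FL_SG", "FL_PI")

#: Ground-truth population labels used by the generator.
POPULATIONS = ("BT_live", "RI_live", "inviable", "debris", "blank")


@dataclass
class NoiseSpec:
    """Replicate noise model for synthetic time series."""

    count_cv: float = 0.10        # multiplicative lognormal CV on densities
    metabolite_sd: float = 0.5    # mM, additive Gaussian, truncated at 0
    ph_sd: float = 0.05           # pH units, additive Gaussian
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count_cv < 0 or self.metabolite_sd < 0 or self.ph_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.replicates < 1:
            raise ValueError("at least one replicate required")


@dataclass
class EventTable:
    """Per-event channel intensities plus sample metadata.

    ``data`` holds one row per event with the columns of :data:`CHANNELS`
    and, for synthetic data, a ``truth_label`` column.
    """

    data: pd.DataFrame
    sample_id: str = "sample"
    role: str = "sample"            # {sample, blank, monoculture_reference}
    species_hint: str | None = None  # for monoculture references
    dilution: float = 200.0
    acquisition_volume_ul: float = 10.0  # 1 min at 10 ul/min

    def __post_init__(self) -> None:
        if self.dilution <= 0:
            raise ValueError("dilution must be positive")
        if self.acquisition_volume_ul <= 0:
            raise ValueError("acquisition volume must be positive")
        chan = [c for c in CHANNELS if c in self.data.columns]
        if chan and not np.isfinite(self.data[chan].to_numpy(dtype=float)).all():
            raise ValueError("channel intensities must be finite")

    @property
    def n_events(self) -> int:
        return len(self.data)

    def channels(self) -> list[str]:
        return [c for c in CHANNELS if c in self.data.columns]

    def intensities(self) -> np.ndarray:
        return self.data[self.channels()].to_numpy(dtype=float)


@dataclass
class PopulationSpec:
    """Mixture specification for synthetic flow-cytometry events.

    ``means`` and ``covs`` are given in log10 channel space; events are
    exponentiated after sampling, giving multivariate-lognormal channel
    intensities with the skew characteristic of cytometry data.
    """

    fractions: dict = field(default_factory=dict)   # population -> fraction
    means: dict = field(default_factory=dict)       # population -> (4,) log10 means
    covs: dict = field(default_factory=dict)        # population -> (4,4) log10 cov
    total_events: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValueError("no populations specified")
        fr = np.array(list(self.fractions.values()), dtype=float)
        if np.any(fr < 0) or not np.isclose(fr.sum(), 1.0, atol=1e-6):
            raise ValueError("population fractions must be >= 0 and sum to 1")
        for pop in self.fractions:
            if pop not in self.means or pop not in self.covs:
                raise ValueError(f"population {pop!r} lacks a mean or covariance")
            cov = np.asarray(self.covs[pop], dtype=float)
            if np.any(np.linalg.eigvalsh(cov) <= 0):
                raise ValueError(f"covariance for {pop!r} is not positive-definite")


def grid_for(t_end: float) -> np.ndarray:
    """Experimental sampling grid truncated at ``t_end``."""
    g = [t for t in EXPERIMENTAL_GRID if t <= t_end]
    return np.asarray(g, dtype=float)


def generate_timeseries(params: ModelParams, scenario: ScenarioConfig,
                        noise: NoiseSpec) -> tuple[TimeSeries, list[TimeSeries]]:
    """Simulate ``scenario`` on the sampling grid and emit noisy replicates.

    Returns ``(truth, replicates)``: the noise-free trajectory and
    ``noise.replicates`` independently perturbed copies.  With all noise
    magnitudes zero the replicates equal the truth exactly.
    """
    truth = simulate(scenario, params, grid_for(scenario.t_end))
    rng = np.random.default_rng(noise.seed)
    count_cols = ["bt_fast", "bt_slow", "bt_dead", "ri_fast", "ri_slow", "ri_dead"]
    met_cols = ["G", "M", "A", "Bu", "acid_other"]
    # Mean-preserving lognormal: E[exp(N(-s^2/2, s^2))] = 1.
    sigma = np.sqrt(np.log1p(noise.count_cv ** 2))
    reps = []
    for _ in range(noise.replicates):
        df = truth.data.copy()
        n = len(df)
        if sigma > 0:
            factors = np.exp(rng.normal(-0.5 * sigma ** 2, sigma,
                                        size=(n, len(count_cols))))
            df[count_cols] = df[count_cols].to_numpy() * factors
        if noise.metabolite_sd > 0:
            df[met_cols] = np.maximum(
                df[met_cols].to_numpy()
                + rng.normal(0.0, noise.metabolite_sd, size=(n, len(met_cols))),
                0.0)
        if noise.ph_sd > 0:
            df["pH"] = df["pH"].to_numpy() + rng.normal(0.0, noise.ph_sd, size=n)
        meta = dict(truth.meta, replicate=len(reps))
        reps.append(TimeSeries(data=df, f_att=dict(truth.f_att), meta=meta))
    return truth, reps


# Base log10 channel layout.  Rows follow POPULATIONS; the species pair and
# the remaining populations are separated along different channel axes.
_BASE_MEANS = {
    #            FSC   SSC   FL_SG  FL_PI
    "BT_live":  (4.15, 3.65, 4.30, 2.00),
    "RI_live":  (3.85, 3.35, 4.30, 2.00),
    "inviable": (4.00, 3.50, 3.60, 4.00),
    "debris":   (3.10, 2.70, 2.30, 2.30),
    "blank":    (2.50, 2.10, 1.80, 1.80),
}
_BASE_SD = 0.15  # log10 decades per channel


def _pairwise_min_sep(means: dict, sd: float) -> float:
    keys = list(means)
    arr = np.array([means[k] for k in keys], dtype=float)
    d = np.inf
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            d = min(d, np.linalg.norm(arr[i] - arr[j]) / sd)
    return d


def make_population_spec(separation_sd: float = 6.0,
                         fractions: dict | None = None,
                         total_events: int = 10_000,
                         channel_sd: float = _BASE_SD,
                         seed: int = 0) -> PopulationSpec:
    """Population mixture whose minimum pairwise separation is ``separation_sd``.

    The base layout (distinct scatter signatures for the two species, high
    SG/low PI for live cells, high PI for inviable, low everything for
    debris and blank) is scaled about its centroid so that the closest two
    population centers lie ``separation_sd`` pooled SDs apart.
    """
    if fractions is None:
        fractions = {"BT_live": 0.35, "RI_live": 0.25, "inviable": 0.15,
                     "debris": 0.15, "blank": 0.10}
    # Scale the FULL base layout about its centroid, then subset, so that a
    # population sits at the same coordinates in every spec sharing one
    # separation (e.g. blank-only files match the blank cluster in samples).
    arr = np.array([_BASE_MEANS[k] for k in POPULATIONS], dtype=float)
    center = arr.mean(axis=0)
    base_sep = _pairwise_min_sep(_BASE_MEANS, channel_sd)
    scale = separation_sd / base_sep
    means = {k: tuple(center + (np.asarray(_BASE_MEANS[k]) - center) * scale)
             for k in fractions}
    cov = np.eye(len(CHANNELS)) * channel_sd ** 2
    covs = {k: cov.copy() for k in fractions}
    return PopulationSpec(fractions=dict(fractions), means=means, covs=covs,
                          total_events=total_events, seed=seed)


def generate_flow_events(pop: PopulationSpec, sample_id: str = "synthetic",
                         role: str = "sample",
                         dilution: float = 200.0,
                         acquisition_volume_ul: float = 10.0) -> EventTable:
    """Draw a labeled multichannel event mixture from ``pop``.

    Population sizes are multinomial; channel intensities are multivariate
    lognormal per population.  The returned table keeps ``truth_label``.
    """
    rng = np.random.default_rng(pop.seed)
    pops = list(pop.fractions)
    counts = rng.multinomial(pop.total_events, [pop.fractions[p] for p in pops])
    frames = []
    for p, n in zip(pops, counts):
        if n == 0:
            continue
        log_x = rng.multivariate_normal(np.asarray(pop.means[p], dtype=float),
                                        np.asarray(pop.covs[p], dtype=float),
                                        size=n)
        df = pd.DataFrame(10.0 ** log_x, columns=list(CHANNELS))
        df["truth_label"] = p
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    # Shuffle so event order carries no label information.
    data = data.sample(frac=1.0, random_state=int(rng.integers(2 ** 31)))
    data = data.reset_index(drop=True)
    return EventTable(data=data, sample_id=sample_id, role=role,
                      dilution=dilution,
                      acquisition_volume_ul=acquisition_volume_ul)
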