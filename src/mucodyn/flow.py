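"""Flow-cytometry event classification: from raw channel intensities to
absolute per-species viable densities.

Pipeline stages, mirroring the study's processing of SG/PI-stained samples:

1. variance-stabilizing transform of each channel (inverse hyperbolic sine
   by default) followed by standardization to zero mean / unit variance;
2. nonlinear 3-D embedding of the events (UMAP, Euclidean metric,
   25 neighbors, 0.1 minimum distance, seeded for reproducibility);
3. four-way gating: PI-positive events are inviable, SG-positive/PI-negative
   events are live, double-negative events are debris -- except for events
   overlapping the sterile-medium blank population, which are removed first;
4. blank overlap is detected by drawing a ball around every blank event in
   embedding space whose radius is proportional to the local blank density
   (dense blank regions claim a wide area, isolated cell-carryover events
   in the blank file claim almost none);
5. in co-culture samples the live events are assigned a species by
   reprojecting them into a supervised embedding trained on labeled
   monoculture reference events, then taking a distance-weighted 50-nearest
   -neighbor vote under the Mahalanobis metric;
6. event counts become absolute densities via the acquisition volume and
   dilution factor (cells/ul = events / volume * dilution).

Thresholds for "SG positive" and "PI positive" default to the minimum-
density valley between the two largest modes of the pooled transformed
channel distribution and can be overridden with explicit values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors

from .synth import CHANNELS, EventTable

__all__ = [
    "FlowConfig",
    "ClassifiedEvents",
    "PopulationCounts",
    "normalize_events",
    "embed_events",
    "estimate_threshold",
    "remove_blank_overlap",
    "gate_categories",
    "classify_species",
    "count_populations",
    "process_sample",
]

CATEGORIES = ("live", "inviable", "debris", "blank")


class FlowError(ValueError):
    """Configuration or input error in the flow pipeline."""


@dataclass
class FlowConfig:
    """Tunable knobs of the event-classification pipeline."""

    transform: str = "asinh"          # {"asinh", "arcsin"}
    n_neighbors: int = 25             # embedding neighborhood size
    min_dist: float = 0.1
    n_components: int = 3
    density_k: int = 15               # kNN density estimate for blank balls
    density_radius_scale: float = 2.0
    sg_threshold: float | None = None  # transformed-scale override
    pi_threshold: float | None = None
    knn_neighbors: int = 50           # species vote
    n_training: int = 5000            # events drawn per monoculture replicate
    seed: int = 0


@dataclass
class ClassifiedEvents:
    """Per-event categories, optional species labels and embedding coords."""

    data: pd.DataFrame                # category, species, emb_0..emb_2, channels
    sample_id: str = "sample"
    meta: dict = field(default_factory=dict)

    def counts(self) -> dict:
        out = {c: int((self.data["category"] == c).sum()) for c in CATEGORIES}
        if "species" in self.data:
            live = self.data[self.data["category"] == "live"]
            for sp in ("BT", "RI"):
                n = int((live["species"] == sp).sum())
                if n or live["species"].notna().any():
                    out[f"live_{sp}"] = n
        return out


@dataclass
class PopulationCounts:
    """Per-sample event counts and absolute densities (cells/ul)."""

    sample_id: str
    counts: dict
    densities: dict
    dilution: float
    acquisition_volume_ul: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample_id": self.sample_id, "population": k,
                 "events": self.counts.get(k, 0), "density_cells_per_ul": v}
                for k, v in self.densities.items()]
        return pd.DataFrame(rows)


def _transform(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "asinh":
        return np.arcsinh(x)
    if kind == "arcsin":
        # Plain arcsine is only defined on [-1, 1]; rescale by the maximum.
        mx = np.nanmax(np.abs(x), axis=0, keepdims=True)
        mx[mx == 0] = 1.0
        return np.arcsin(np.clip(x / mx, -1.0, 1.0))
    raise FlowError(f"unknown transform {kind!r}")


def normalize_events(events: EventTable, config: FlowConfig | None = None
                     ) -> EventTable:
    """Variance-stabilize and standardize each channel.

    Returns a new :class:`EventTable` whose channels have zero mean and unit
    variance; zero-variance channels are dropped with a warning.  The
    per-channel transform is monotone, so within-channel event ordering is
    preserved.
    """
    config = config or FlowConfig()
    if events.n_events < 2:
        raise FlowError("need at least two events to normalize")
    chans = events.channels()
    if len(chans) < 2:
        raise FlowError("need at least two channels")
    X = _transform(events.intensities(), config.transform)
    keep, cols = [], []
    for j, c in enumerate(chans):
        sd = X[:, j].std()
        if sd <= 1e-10 * max(1.0, abs(X[:, j].mean())) or not np.isfinite(sd):
            warnings.warn(f"channel {c} has zero variance; dropped from embedding")
            continue
        keep.append((X[:, j] - X[:, j].mean()) / sd)
        cols.append(c)
    data = events.data.copy()
    data = data.drop(columns=[c for c in chans if c not in cols])
    for c, v in zip(cols, keep):
        data[c] = v
    out = EventTable(data=data, sample_id=events.sample_id, role=events.role,
                     species_hint=events.species_hint, dilution=events.dilution,
                     acquisition_volume_ul=events.acquisition_volume_ul)
    return out


def _umap(n_neighbors: int, min_dist: float, n_components: int, seed: int):
    from umap import UMAP  # deferred: numba compilation is expensive
    return UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                n_components=n_components, metric="euclidean",
                random_state=seed)


def embed_events(events: EventTable | np.ndarray, seed: int = 0,
                 config: FlowConfig | None = None) -> np.ndarray:
    """Project normalized events into 3-D with a seeded neighbor-graph
    embedding (deterministic for a fixed seed: the seed forces
    single-threaded layout optimization)."""
    config = config or FlowConfig()
    X = events if isinstance(events, np.ndarray) else events.intensities()
    n = len(X)
    n_neighbors = config.n_neighbors
    if n <= n_neighbors:
        n_neighbors = max(2, n - 1)
        warnings.warn(f"fewer events ({n}) than neighbor count; "
                      f"reduced n_neighbors to {n_neighbors}")
    reducer = _umap(n_neighbors, config.min_dist, config.n_components, seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*n_jobs value.*")
        return np.asarray(reducer.fit_transform(X), dtype=float)


def estimate_threshold(values: np.ndarray) -> float:
    """Valley between the two largest modes of a kernel-density estimate.

    Falls back to the midpoint of the value range for unimodal data.
    """
    values = np.asarray(values, dtype=float)
    grid = np.linspace(values.min(), values.max(), 512)
    if grid[0] == grid[-1]:
        raise FlowError("cannot estimate a threshold from constant values")
    dens = gaussian_kde(values)(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    if len(maxima) < 2:
        return float(0.5 * (grid[0] + grid[-1]))
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = sorted(top2)
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    return float(grid[valley])


def remove_blank_overlap(sample_emb: np.ndarray, blank_emb: np.ndarray,
                         density_radius_scale: float = 2.0,
                         k: int = 15) -> np.ndarray:
    """Flag sample events lying inside any blank-centered ball.

    Every blank event defines a ball whose radius is proportional to the
    local blank density (estimated from the distance to its k-th nearest
    blank neighbor): ``r_i = scale * r_med^2 / r_k(i)`` where ``r_med`` is
    the median k-NN distance.  Dense blank regions therefore claim wide
    neighborhoods while isolated carryover cells in the blank file claim
    almost nothing.  Returns a boolean mask over the sample events.
    """
    sample_emb = np.asarray(sample_emb, dtype=float)
    if blank_emb is None or len(blank_emb) == 0:
        return np.zeros(len(sample_emb), dtype=bool)
    blank_emb = np.asarray(blank_emb, dtype=float)
    kk = min(k, len(blank_emb) - 1)
    if kk < 1:
        radii = np.full(len(blank_emb), density_radius_scale)
    else:
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(blank_emb)
        dist, _ = nn.kneighbors(blank_emb)
        r_k = np.maximum(dist[:, -1], 1e-12)
        r_med = np.median(r_k)
        radii = density_radius_scale * r_med ** 2 / r_k
    tree = NearestNeighbors(radius=float(radii.max())).fit(sample_emb)
    flagged = np.zeros(len(sample_emb), dtype=bool)
    d_all, i_all = tree.radius_neighbors(blank_emb, radius=float(radii.max()))
    for d, idx, r in zip(d_all, i_all, radii):
        flagged[idx[d <= r]] = True
    return flagged


def gate_categories(events: EventTable, blanks: EventTable | None,
                    config: FlowConfig | None = None,
                    seed: int | None = None) -> ClassifiedEvents:
    """Assign each event one of live / inviable / debris / blank.

    Sample and blank events are normalized and embedded jointly; blank
    overlap is removed first, PI-positive events become inviable, remaining
    SG-positive events live, the rest debris.  SG/PI thresholds come from
    ``config`` or are estimated from the pooled distributions.
    """
    config = config or FlowConfig()
    if seed is None:
        seed = config.seed
    for c in ("FL_SG", "FL_PI"):
        if c not in events.data.columns:
            raise FlowError(f"missing required channel {c}")
    n_sample = events.n_events
    if blanks is not None and blanks.n_events:
        combined = pd.concat([events.data, blanks.data], ignore_index=True)
    else:
        combined = events.data.copy()
    pool = EventTable(data=combined, sample_id=events.sample_id,
                      role="pooled", dilution=events.dilution,
                      acquisition_volume_ul=events.acquisition_volume_ul)
    norm = normalize_events(pool, config)
    emb = embed_events(norm, seed=seed, config=config)
    sample_emb, blank_emb = emb[:n_sample], emb[n_sample:]

    tx = _transform(events.data[["FL_SG", "FL_PI"]].to_numpy(dtype=float),
                    config.transform)
    pool_tx = _transform(combined[["FL_SG", "FL_PI"]].to_numpy(dtype=float),
                         config.transform)
    sg_thr = (config.sg_threshold if config.sg_threshold is not None
              else estimate_threshold(pool_tx[:, 0]))
    pi_thr = (config.pi_threshold if config.pi_threshold is not None
              else estimate_threshold(pool_tx[:, 1]))

    blank_mask = remove_blank_overlap(sample_emb, blank_emb,
                                      config.density_radius_scale,
                                      config.density_k)
    category = np.full(n_sample, "debris", dtype=object)
    pi_pos = tx[:, 1] > pi_thr
    sg_pos = tx[:, 0] > sg_thr
    category[blank_mask] = "blank"
    category[~blank_mask & pi_pos] = "inviable"
    category[~blank_mask & ~pi_pos & sg_pos] = "live"

    data = events.data.copy().reset_index(drop=True)
    data["category"] = category
    data["species"] = pd.Series([pd.NA] * n_sample, dtype="object")
    for j in range(sample_emb.shape[1]):
        data[f"emb_{j}"] = sample_emb[:, j]
    meta = {"sg_threshold": float(sg_thr), "pi_threshold": float(pi_thr),
            "n_blank_events": int(blank_emb.shape[0]), "seed": seed}
    return ClassifiedEvents(data=data, sample_id=events.sample_id, meta=meta)


def select_reference(refs_by_time: dict, t: float, tol_h: float = 0.0):
    """Monoculture reference for time ``t``; nearest time point otherwise.

    ``refs_by_time`` maps sampling time (h) to a reference object.  Falls
    back to the nearest available time point with a warning when ``t`` is
    missing (beyond ``tol_h``).
    """
    if not refs_by_time:
        raise FlowError("no monoculture references available")
    times = np.asarray(sorted(refs_by_time), dtype=float)
    i = int(np.argmin(np.abs(times - t)))
    if abs(times[i] - t) > tol_h:
        warnings.warn(f"no monoculture reference at t={t} h; "
                      f"using nearest time point {times[i]} h")
    return refs_by_time[sorted(refs_by_time)[i]]


def _draw_training(mono_refs, n_training, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sample up to ``n_training`` events per monoculture replicate."""
    X, y = [], []
    for species, tables in mono_refs.items():
        if not isinstance(tables, (list, tuple)):
            tables = [tables]
        for t in tables:
            arr = t.intensities() if isinstance(t, EventTable) else np.asarray(t)
            if len(arr) > n_training:
                idx = rng.choice(len(arr), size=n_training, replace=False)
                arr = arr[idx]
            X.append(arr)
            y.extend([species] * len(arr))
    return np.concatenate(X, axis=0), np.asarray(y, dtype=object)


def classify_species(co_events: EventTable | np.ndarray, mono_refs: dict,
                     seed: int = 0, config: FlowConfig | None = None
                     ) -> np.ndarray:
    """Label live co-culture events as BT or RI.

    ``mono_refs`` maps species name to one or more monoculture reference
    event tables (ideally from the matching time point).  A supervised 3-D
    embedding is trained on up to ``config.n_training`` events per
    reference replicate; co-culture events are reprojected into that space
    and labeled by a distance-weighted k-NN vote (k=50) under the
    Mahalanobis metric.  Raw channel intensities are normalized jointly
    before embedding.
    """
    config = config or FlowConfig()
    species = sorted(mono_refs)
    if len(species) < 2:
        raise FlowError("monoculture references for both species are required")
    X_co = (co_events.intensities() if isinstance(co_events, EventTable)
            else np.asarray(co_events, dtype=float))
    if len(X_co) == 0:
        return np.asarray([], dtype=object)
    rng = np.random.default_rng(seed)
    X_train_raw, y_train = _draw_training(mono_refs, config.n_training, rng)
    for sp in species:
        if (y_train == sp).sum() < config.knn_neighbors:
            raise FlowError(f"fewer than {config.knn_neighbors} training "
                            f"events for species {sp}")
    # Joint variance-stabilization + standardization (training statistics).
    Z_train = _transform(X_train_raw, config.transform)
    mu, sd = Z_train.mean(axis=0), Z_train.std(axis=0)
    sd[sd == 0] = 1.0
    Z_train = (Z_train - mu) / sd
    Z_co = (_transform(X_co, config.transform) - mu) / sd

    n_neighbors = min(config.n_neighbors, len(Z_train) - 1)
    reducer = _umap(n_neighbors, config.min_dist, config.n_components, seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*n_jobs value.*")
        emb_train = reducer.fit_transform(Z_train, y=pd.factorize(y_train)[0])
        emb_co = reducer.transform(Z_co)

    VI = np.linalg.inv(np.cov(emb_train, rowvar=False)
                       + 1e-9 * np.eye(emb_train.shape[1]))
    k = min(config.knn_neighbors, len(emb_train))
    knn = KNeighborsClassifier(n_neighbors=k, weights="distance",
                               metric="mahalanobis", metric_params={"VI": VI},
                               algorithm="brute")
    knn.fit(emb_train, y_train)
    return knn.predict(emb_co)


def count_populations(classified: ClassifiedEvents,
                      dilution: float | None = None,
                      acquisition_volume_ul: float | None = None,
                      meta: EventTable | None = None) -> PopulationCounts:
    """Absolute densities: events / acquired volume (ul) * dilution."""
    if meta is not None:
        dilution = meta.dilution
        acquisition_volume_ul = meta.acquisition_volume_ul
    if not acquisition_volume_ul or acquisition_volume_ul <= 0:
        raise FlowError("acquisition volume must be positive")
    if not dilution or dilution <= 0:
        raise FlowError("dilution must be positive")
    counts = classified.counts()
    factor = dilution / acquisition_volume_ul
    densities = {k: v * factor for k, v in counts.items()}
    return PopulationCounts(sample_id=classified.sample_id, counts=counts,
                            densities=densities, dilution=dilution,
                            acquisition_volume_ul=acquisition_volume_ul)


def process_sample(events: EventTable, blanks: EventTable | None = None,
                   mono_refs: dict | None = None,
                   config: FlowConfig | None = None,
                   seed: int | None = None
                   ) -> tuple[ClassifiedEvents, PopulationCounts, dict]:
    """Full pipeline for one sample: gate, optionally assign species, count.

    Returns the classified events, the population counts/densities and a
    QC dictionary (thresholds used, category fractions, and -- when truth
    labels are present -- agreement with the generator).
    """
    config = config or FlowConfig()
    if seed is None:
        seed = config.seed
    classified = gate_categories(events, blanks, config=config, seed=seed)
    live_mask = classified.data["category"] == "live"
    if mono_refs and live_mask.any():
        chans = [c for c in CHANNELS if c in classified.data.columns]
        live_X = classified.data.loc[live_mask, chans].to_numpy(dtype=float)
        labels = classify_species(live_X, mono_refs, seed=seed, config=config)
        classified.data.loc[live_mask, "species"] = labels
    pops = count_populations(classified, dilution=events.dilution,
                             acquisition_volume_ul=events.acquisition_volume_ul)
    qc = {"sample_id": events.sample_id, **classified.meta}
    n = max(1, classified.data.shape[0])
    for c in CATEGORIES:
        qc[f"frac_{c}"] = float((classified.data["category"] == c).mean())
    if "truth_label" in classified.data.columns:
        truth = classified.data["truth_label"].to_numpy()
        pred_cat = classified.data["category"].to_numpy()
        cat_truth = np.where(np.isin(truth, ("BT_live", "RI_live")), "live", truth)
        qc["category_accuracy"] = float((pred_cat == cat_truth).mean())
    return classified, pops, qc
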