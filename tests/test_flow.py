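"""Tests for the flow-cytometry classification pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import silhouette_score

from mucodyn.flow import (
    FlowConfig,
    FlowError,
    classify_species,
    count_populations,
    embed_events,
    estimate_threshold,
    gate_categories,
    normalize_events,
    process_sample,
    remove_blank_overlap,
    select_reference,
)
from mucodyn.synth import (
    CHANNELS,
    EventTable,
    generate_flow_events,
    make_population_spec,
)


def _table(arr, **kw):
    return EventTable(data=pd.DataFrame(arr, columns=list(CHANNELS)), **kw)


class TestNormalizeEvents:
    def test_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        table = _table(10 ** rng.uniform(1, 5, size=(500, 4)))
        out = normalize_events(table)
        X = out.intensities()
        assert np.all(np.abs(X.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(X.var(axis=0) - 1) < 1e-9)

    def test_equal_intensities_stay_equal(self):
        arr = np.column_stack([np.full(10, 123.0),
                               np.arange(10) + 1.0,
                               np.arange(10) + 2.0,
                               np.full(10, 7.0)])
        arr[3, 1] = arr[4, 1]  # two events equal in one channel, not another
        out = normalize_events(_table(arr))
        X = out.data
        assert X.loc[3, "SSC"] == X.loc[4, "SSC"]
        assert X.loc[3, "FL_SG"] != X.loc[4, "FL_SG"]

    def test_transform_reduces_lognormal_skewness(self):
        rng = np.random.default_rng(1)
        raw = 10 ** rng.normal(3, 0.5, size=2000)
        arr = np.column_stack([raw, raw * 2, raw * 3, raw * 4])
        out = normalize_events(_table(arr))
        assert (abs(stats.skew(out.intensities()[:, 0]))
                < abs(stats.skew(raw)))

    def test_zero_variance_channel_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        arr = 10 ** rng.uniform(1, 4, size=(100, 4))
        arr[:, 3] = 50.0
        with pytest.warns(UserWarning, match="zero variance"):
            out = normalize_events(_table(arr))
        assert "FL_PI" not in out.data.columns

    def test_too_few_events_rejected(self):
        with pytest.raises(FlowError):
            normalize_events(_table(np.ones((1, 4))))


class TestEmbedEvents:
    def test_three_dimensional_and_deterministic(self):
        rng = np.random.default_rng(3)
        table = normalize_events(_table(10 ** rng.uniform(1, 4, size=(400, 4))))
        a = embed_events(table, seed=9)
        b = embed_events(table, seed=9)
        assert a.shape == (400, 3)
        assert np.array_equal(a, b)

    def test_fewer_events_than_neighbors_warns(self):
        rng = np.random.default_rng(4)
        table = normalize_events(_table(10 ** rng.uniform(1, 4, size=(15, 4))))
        with pytest.warns(UserWarning, match="fewer events"):
            emb = embed_events(table, seed=0)
        assert emb.shape == (15, 3)

    def test_separated_clusters_keep_silhouette(self):
        """Two 6-SD-separated Gaussian clusters stay cleanly separated in
        the 3-D embedding (silhouette > 0.5 against generator labels)."""
        spec = make_population_spec(
            6.0, {"BT_live": 0.5, "blank": 0.5}, total_events=600, seed=5)
        table = generate_flow_events(spec)
        labels = table.data["truth_label"].to_numpy()
        emb = embed_events(normalize_events(table), seed=1)
        assert silhouette_score(emb, labels) > 0.5


class TestBlankRemoval:
    def test_no_blanks_flags_nothing(self):
        rng = np.random.default_rng(6)
        assert not remove_blank_overlap(rng.normal(size=(50, 3)),
                                        np.zeros((0, 3))).any()

    def test_identical_distribution_mostly_flagged(self):
        rng = np.random.default_rng(7)
        blanks = rng.normal(size=(400, 3))
        sample = rng.normal(size=(500, 3))
        flagged = remove_blank_overlap(sample, blanks)
        assert flagged.mean() >= 0.95

    def test_planted_blanks_flagged_cells_spared(self):
        """10% blank-like events are caught while a distant cell cluster
        (>= 6 SD away) is left untouched."""
        rng = np.random.default_rng(8)
        blanks = rng.normal(size=(300, 3))
        cells = rng.normal(size=(450, 3)) + np.array([8.0, 0.0, 0.0])
        planted = rng.normal(size=(50, 3))
        sample = np.vstack([cells, planted])
        flagged = remove_blank_overlap(sample, blanks)
        assert flagged[len(cells):].mean() >= 0.90
        assert flagged[: len(cells)].mean() <= 0.05

    def test_carryover_cells_claim_little_area(self):
        """A few cell events carried over into the blank file sit in a
        low-density region and must not absorb the cell cluster."""
        rng = np.random.default_rng(9)
        blanks = np.vstack([rng.normal(size=(300, 3)),
                            rng.normal(size=(5, 3), scale=0.3)
                            + np.array([8.0, 0.0, 0.0])])
        cells = rng.normal(size=(400, 3)) + np.array([8.0, 0.0, 0.0])
        flagged = remove_blank_overlap(cells, blanks)
        assert flagged.mean() <= 0.25


@pytest.fixture(scope="module")
def gated():
    spec = make_population_spec(separation_sd=6.0, total_events=3000, seed=31)
    events = generate_flow_events(spec, sample_id="gate_test")
    blanks = generate_flow_events(
        make_population_spec(6.0, {"blank": 1.0}, total_events=600, seed=32),
        role="blank")
    return events, gate_categories(events, blanks, seed=17)


class TestGateCategories:
    def test_rule_application_and_partition(self, gated):
        events, classified = gated
        counts = classified.counts()
        assert sum(counts[c] for c in ("live", "inviable", "debris", "blank")) \
            == events.n_events

    def test_category_agreement_with_generator(self, gated):
        """At 6-SD separation the four-way gate matches generator truth for
        at least 99% of events."""
        _, classified = gated
        truth = classified.data["truth_label"].to_numpy()
        cat_truth = np.where(np.isin(truth, ("BT_live", "RI_live")),
                             "live", truth)
        agreement = (classified.data["category"].to_numpy() == cat_truth).mean()
        assert agreement >= 0.99

    def test_pi_positive_is_inviable_regardless_of_sg(self, gated):
        _, classified = gated
        tx = np.arcsinh(classified.data["FL_PI"].to_numpy())
        pi_pos = tx > classified.meta["pi_threshold"]
        not_blank = classified.data["category"] != "blank"
        assert (classified.data.loc[pi_pos & not_blank, "category"]
                == "inviable").all()

    def test_missing_stain_channel_rejected(self):
        rng = np.random.default_rng(33)
        df = pd.DataFrame(10 ** rng.uniform(1, 4, size=(100, 2)),
                          columns=["FSC", "SSC"])
        with pytest.raises(FlowError):
            gate_categories(EventTable(data=df), None)

    def test_threshold_estimator_finds_valley(self):
        rng = np.random.default_rng(34)
        lo = rng.normal(2.0, 0.3, 700)
        hi = rng.normal(8.0, 0.3, 300)
        thr = estimate_threshold(np.concatenate([lo, hi]))
        assert 3.5 < thr < 6.5


class TestClassifySpecies:
    CFG = FlowConfig(n_training=1000)

    def test_degenerate_mixture_labeled_as_reference(self, live_mixture_tables):
        """Co-culture events drawn from the BT reference distribution are
        labeled BT (up to ~1% boundary noise)."""
        mono_bt, mono_ri, _ = live_mixture_tables[6.0]
        co = generate_flow_events(make_population_spec(
            6.0, {"BT_live": 1.0}, total_events=400, seed=55))
        labels = classify_species(co, {"BT": mono_bt, "RI": mono_ri},
                                  seed=5, config=self.CFG)
        assert (labels == "BT").mean() >= 0.99

    def test_empty_event_set_gives_empty_labels(self, live_mixture_tables):
        mono_bt, mono_ri, _ = live_mixture_tables[4.0]
        labels = classify_species(np.zeros((0, 4)),
                                  {"BT": mono_bt, "RI": mono_ri}, seed=5,
                                  config=self.CFG)
        assert len(labels) == 0

    def test_one_species_reference_rejected(self, live_mixture_tables):
        mono_bt, _, co = live_mixture_tables[4.0]
        with pytest.raises(FlowError):
            classify_species(co, {"BT": mono_bt}, seed=5, config=self.CFG)

    def test_accuracy_nondecreasing_in_separation(self, live_mixture_tables):
        """Label stability: accuracy against generator truth does not get
        worse as the species clusters separate (2, 4, 6 SD)."""
        accs = []
        for sep in (2.0, 4.0, 6.0):
            mono_bt, mono_ri, co = live_mixture_tables[sep]
            labels = classify_species(co, {"BT": mono_bt, "RI": mono_ri},
                                      seed=5, config=self.CFG)
            truth = co.data["truth_label"].map(
                {"BT_live": "BT", "RI_live": "RI"}).to_numpy()
            accs.append((labels == truth).mean())
        assert accs[0] <= accs[1] + 0.02 <= accs[2] + 0.04
        assert accs[2] >= 0.98

    def test_reference_time_fallback_warns(self):
        refs = {4.0: "a", 8.0: "b"}
        assert select_reference(refs, 4.0, tol_h=0.1) == "a"
        with pytest.warns(UserWarning, match="nearest time point"):
            assert select_reference(refs, 11.0, tol_h=0.1) == "b"


class TestCountPopulations:
    def _classified(self, n_live, sample_id="s"):
        from mucodyn.flow import ClassifiedEvents
        df = pd.DataFrame({"category": ["live"] * n_live})
        return ClassifiedEvents(data=df, sample_id=sample_id)

    def test_density_arithmetic(self):
        pops = count_populations(self._classified(50_000), dilution=200.0,
                                 acquisition_volume_ul=10.0)
        assert pops.densities["live"] == pytest.approx(1.0e6)

    def test_zero_events_zero_density(self):
        pops = count_populations(self._classified(0), dilution=200.0,
                                 acquisition_volume_ul=10.0)
        assert pops.densities["live"] == 0.0

    def test_low_dilution_example(self):
        pops = count_populations(self._classified(123), dilution=10.0,
                                 acquisition_volume_ul=10.0)
        assert pops.densities["live"] == pytest.approx(123.0)

    def test_dilution_equivariance(self):
        a = count_populations(self._classified(777), dilution=100.0,
                              acquisition_volume_ul=10.0)
        b = count_populations(self._classified(777), dilution=200.0,
                              acquisition_volume_ul=10.0)
        assert b.densities["live"] == pytest.approx(2 * a.densities["live"])

    def test_zero_volume_rejected(self):
        with pytest.raises(FlowError):
            count_populations(self._classified(10), dilution=10.0,
                              acquisition_volume_ul=0.0)


class TestFullPipeline:
    def test_seeded_pipeline_is_bit_identical(self):
        spec = make_population_spec(6.0, total_events=700, seed=41)
        events = generate_flow_events(spec)
        blanks = generate_flow_events(
            make_population_spec(6.0, {"blank": 1.0}, total_events=200, seed=42),
            role="blank")
        a, _, _ = process_sample(events, blanks, seed=13)
        b, _, _ = process_sample(events, blanks, seed=13)
        pd.testing.assert_frame_equal(a.data, b.data)
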