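"""Spine morphometry: refinement rules, frustum/hemisphere geometry,
threshold classification, per-segment densities, and PCA/k-means clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from engramkit import (
    SPINE_CLASSES,
    RefinementConfig,
    SpineClusterer,
    SpineGenConfig,
    SpineRuleClassifier,
    classify_spines,
    cluster_class_crosstab,
    compute_feature_matrix,
    gen_spine_table,
    per_segment_counts,
    refine_spines,
    spine_geometry,
)


# --------------------------------------------------------------------------
# refinement
# --------------------------------------------------------------------------

class TestRefinement:
    @staticmethod
    def _table(**overrides):
        row = {
            "spine_id": "s0", "length": 1.0, "head_max_diameter": 0.5,
            "neck_min_diameter": 0.2, "neck_mean_diameter": 0.25,
        }
        row.update(overrides)
        return pd.DataFrame([row])

    def test_neckless_spine_removed(self):
        kept, report = refine_spines(self._table(neck_min_diameter=np.nan))
        assert len(kept) == 0 and report["neckless"] == 1

    def test_neckless_kept_when_rule_disabled(self):
        kept, _ = refine_spines(
            self._table(neck_min_diameter=np.nan), RefinementConfig(drop_neckless=False)
        )
        assert len(kept) == 1

    def test_small_head_removed(self):
        kept, report = refine_spines(self._table(head_max_diameter=0.3))
        assert len(kept) == 0 and report["below_min_diameter"] == 1

    def test_dendrite_diameter_rule_applies_when_column_present(self):
        kept, report = refine_spines(self._table(dendrite_diameter=6.0))
        assert len(kept) == 0 and report["dendrite_diameter_out_of_range"] == 1

    def test_neckless_fraction_removal_count(self):
        df = gen_spine_table(SpineGenConfig(n_spines=1000, neckless_fraction=0.2, seed=6))
        kept, report = refine_spines(df)
        assert abs(report["neckless"] - 200) < 4 * np.sqrt(1000 * 0.2 * 0.8)
        assert report["n_kept"] + report["neckless"] == 1000


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _oracle(r_a, r_t, h):
    """Solid-of-revolution integration of the frustum profile plus the
    closed-form hemisphere corrections."""
    r = lambda z: r_a + (r_t - r_a) * z / h
    vol_frustum, _ = integrate.quad(lambda z: np.pi * r(z) ** 2, 0, h)
    slope = (r_t - r_a) / h
    area_frustum, _ = integrate.quad(
        lambda z: 2 * np.pi * r(z) * np.sqrt(1 + slope**2), 0, h
    )
    vol = vol_frustum + 2 / 3 * np.pi * r_t**3 - 2 / 3 * np.pi * r_a**3
    area = area_frustum + 2 * np.pi * r_t**2 - 2 * np.pi * r_a**2
    return area, vol


class TestGeometry:
    def test_equal_radii_reduce_to_cylinder(self):
        r, length = 0.2, 1.3
        h = length - r
        area, vol = spine_geometry(length, 2 * r, 2 * r)
        assert vol == pytest.approx(np.pi * r**2 * h, rel=1e-12)
        assert area == pytest.approx(2 * np.pi * r * h, rel=1e-12)

    def test_matches_numerical_integration(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            r_a = rng.uniform(0.05, 0.4)
            r_t = rng.uniform(0.05, 0.6)
            h = rng.uniform(0.2, 3.0)
            area, vol = spine_geometry(h + r_t, 2 * r_t, 2 * r_a)
            area_ref, vol_ref = _oracle(r_a, r_t, h)
            if area_ref > 0:
                assert abs(area - area_ref) / abs(area_ref) < 1e-3
            assert abs(vol - vol_ref) / abs(vol_ref) < 1e-3

    def test_degenerate_height_gives_vanishing_cylinder(self):
        r = 0.25
        area, vol = spine_geometry(r + 1e-9, 2 * r, 2 * r)  # h floors at 1e-6
        assert vol < 1e-6 and area < 1e-5

    def test_volume_monotone_in_height_and_terminal_radius(self):
        _, v1 = spine_geometry(1.0, 0.4, 0.3)
        _, v2 = spine_geometry(1.5, 0.4, 0.3)
        assert v2 > v1
        _, v3 = spine_geometry(1.0, 0.5, 0.3)
        assert v3 > v1

    def test_negative_area_floored_at_lateral_surface(self):
        # huge attachment radius vs tiny head: hemisphere subtraction
        # exceeds lateral + terminal cap
        with pytest.warns(UserWarning, match="floored"):
            area, _ = spine_geometry(1.0, 0.1, 4.0)
        assert area > 0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            spine_geometry(1.0, 0.0, 0.2)


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

class TestClassification:
    @pytest.mark.parametrize(
        "length,head,expected",
        [
            (0.8, 0.5, "thin"),
            (1.5, 0.5, "long_thin"),
            (2.5, 0.4, "filopodia"),
            (1.0, 0.8, "mushroom"),
            (0.9, 0.6, "mushroom"),   # boundary head == 0.6 belongs to mushroom
            (0.4, 0.5, "stubby"),     # LWR = 0.8 <= 1
            (0.5, 0.62, "mushroom"),  # stubby-like but big head: head wins
        ],
    )
    def test_threshold_rules(self, length, head, expected):
        df = pd.DataFrame({"length": [length], "head_max_diameter": [head]})
        assert classify_spines(df)[0] == expected

    def test_total_and_single_valued_on_random_features(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame(
            {
                "length": rng.uniform(0.05, 5.0, 100_000),
                "head_max_diameter": rng.uniform(0.05, 2.0, 100_000),
            }
        )
        labels = classify_spines(df)
        assert set(labels) <= set(SPINE_CLASSES)
        assert len(labels) == len(df)

    @pytest.mark.parametrize("cls", SPINE_CLASSES)
    def test_recovery_per_generated_class(self, cls):
        mix = tuple(1.0 if c == cls else 0.0 for c in SPINE_CLASSES)
        df = gen_spine_table(SpineGenConfig(n_spines=2000, class_mixture=mix, seed=13))
        assert (classify_spines(df) == cls).mean() >= 0.95

    def test_missing_feature_names_the_spine(self):
        df = pd.DataFrame(
            {"length": [1.0, np.nan], "head_max_diameter": [0.5, 0.5]},
            index=["sp_ok", "sp_bad"],
        )
        with pytest.raises(ValueError, match="sp_bad"):
            classify_spines(df)

    def test_width_convention_changes_lwr(self):
        # head_mean < head_max, so LWR grows and a stubby call can flip
        df = pd.DataFrame(
            {"length": [0.55], "head_max_diameter": [0.55], "head_mean_diameter": [0.4]}
        )
        assert classify_spines(df)[0] == "stubby"
        assert classify_spines(df, width_convention="head_mean")[0] == "thin"

    def test_sklearn_params_round_trip(self):
        clf = SpineRuleClassifier(head_threshold=0.7)
        assert clf.get_params()["head_threshold"] == 0.7
        clf.set_params(width_convention="head_mean").fit()
        assert list(clf.classes_) == list(SPINE_CLASSES)


# --------------------------------------------------------------------------
# per-segment densities
# --------------------------------------------------------------------------

class TestSegmentCounts:
    @staticmethod
    def _spines(class_counts, segment="seg0"):
        rows = []
        for cls, n in class_counts.items():
            for i in range(n):
                rows.append({"neuron_id": "n0", "segment_id": segment,
                             "class_label": cls, "spine_id": f"{cls}{i}"})
        return pd.DataFrame(rows)

    def test_class_counts_sum_to_total_density(self):
        df = self._spines({"thin": 7, "long_thin": 9, "mushroom": 6, "stubby": 1,
                           "filopodia": 4})
        out = per_segment_counts(df)
        assert out["total_per_20um"].iloc[0] == sum(
            out[c].iloc[0] for c in SPINE_CLASSES
        )
        assert out["total_per_20um"].iloc[0] == 27.0

    def test_scaling_to_20um(self):
        df = self._spines({"thin": 10})
        out = per_segment_counts(df, segment_length_um=40.0)
        assert out["thin"].iloc[0] == 5.0

    def test_doubling_counts_preserves_proportions(self):
        single = self._spines({"thin": 3, "mushroom": 2})
        double = self._spines({"thin": 6, "mushroom": 4})
        a = per_segment_counts(single)
        b = per_segment_counts(double)
        assert b["total_per_20um"].iloc[0] == 2 * a["total_per_20um"].iloc[0]
        assert (
            b["thin"].iloc[0] / b["total_per_20um"].iloc[0]
            == a["thin"].iloc[0] / a["total_per_20um"].iloc[0]
        )

    def test_per_neuron_aggregation(self):
        df = pd.concat(
            [self._spines({"thin": 4}, "segA"), self._spines({"thin": 8}, "segB")]
        )
        out = per_segment_counts(df, per_neuron=True)
        assert out["thin"].iloc[0] == 6.0

    def test_unknown_segment_length_rejected(self):
        with pytest.raises(ValueError):
            per_segment_counts(self._spines({"thin": 1}), segment_length_um=np.nan)

    def test_generated_mixture_reflected_in_class_proportions(self):
        mix = (0.27, 0.33, 0.21, 0.03, 0.16)
        df = gen_spine_table(SpineGenConfig(n_spines=4000, class_mixture=mix, seed=5))
        df["class_label"] = classify_spines(df)
        out = per_segment_counts(df)
        props = out[list(SPINE_CLASSES)].sum() / out["total_per_20um"].sum()
        assert np.abs(props.to_numpy() - np.asarray(mix)).max() < 0.03


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

class TestClustering:
    def test_two_blobs_recovered_against_nearest_centroid_oracle(self):
        rng = np.random.default_rng(4)
        X = np.vstack(
            [rng.normal(0, 0.3, (300, 4)), rng.normal(5, 0.3, (300, 4))]
        )
        truth = np.repeat([0, 1], 300)
        model = SpineClusterer(n_clusters=2, random_state=0).fit(X)
        # oracle: assign each point to the nearest of the two blob means
        scores = model.transform(X)
        centroids = np.vstack([scores[truth == g].mean(axis=0) for g in (0, 1)])
        oracle = np.argmin(
            ((scores[:, None, :] - centroids[None]) ** 2).sum(-1), axis=1
        )
        agreement = max(
            (model.labels_ == oracle).mean(), (model.labels_ != oracle).mean()
        )
        assert agreement >= 0.99

    def test_identical_rows_collapse_to_zero_inertia(self):
        X = np.ones((50, 3))
        model = SpineClusterer(n_clusters=1, random_state=0).fit(X)
        assert model.inertia_ == pytest.approx(0.0, abs=1e-12)

    def test_fixed_seed_is_deterministic(self, refined_spines):
        X = compute_feature_matrix(refined_spines)
        a = SpineClusterer(n_clusters=5, random_state=3).fit(X).labels_
        b = SpineClusterer(n_clusters=5, random_state=3).fit(X).labels_
        assert (a == b).all()

    def test_fewer_points_than_clusters_rejected(self):
        with pytest.raises(ValueError):
            SpineClusterer(n_clusters=5).fit(np.ones((3, 2)) * np.arange(3)[:, None])

    def test_elbow_selects_true_blob_count(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(c, 0.2, (150, 3)) for c in (0.0, 4.0, 8.0)])
        model = SpineClusterer(n_clusters=None, random_state=0).fit(X)
        assert model.n_clusters_ == 3
        assert set(model.elbow_inertias_) >= set(range(2, 11))

    def test_feature_matrix_roster_and_standardization(self, refined_spines):
        X = compute_feature_matrix(refined_spines)
        assert X.shape[1] == 16
        model = SpineClusterer(n_clusters=5, random_state=0).fit(X)
        Z = model.scaler_.transform(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-9
        assert np.abs(Z.std(axis=0) - 1).max() < 1e-9
        assert model.explained_variance_ratio_.sum() <= 1 + 1e-9
        assert model.cluster_proportions().sum() == pytest.approx(1.0)

    def test_five_class_mixture_concentrates_in_clusters(self, refined_spines):
        X = compute_feature_matrix(refined_spines)
        model = SpineClusterer(n_clusters=5, random_state=0).fit(X)
        tab = cluster_class_crosstab(model.labels_, refined_spines["true_class"])
        majority = tab.max(axis=1) / tab.sum(axis=1)
        assert (majority >= 0.6).all()


class TestCrosstab:
    def test_aligned_labels_give_diagonal(self):
        labels = np.repeat(list(SPINE_CLASSES), 4)
        clusters = np.repeat(np.arange(5), 4)
        tab = cluster_class_crosstab(clusters, labels)
        off_diag = tab.to_numpy().sum() - np.trace(
            tab[list(SPINE_CLASSES)].to_numpy()
        )
        assert off_diag == 0

    def test_marginals_conserved(self):
        rng = np.random.default_rng(2)
        clusters = rng.integers(0, 4, 200)
        classes = rng.choice(SPINE_CLASSES, 200)
        tab = cluster_class_crosstab(clusters, classes)
        assert tab.to_numpy().sum() == 200
        for k in np.unique(clusters):
            assert tab.loc[k].sum() == (clusters == k).sum()

    def test_independent_labels_match_outer_product(self):
        rng = np.random.default_rng(8)
        n = 20_000
        clusters = rng.integers(0, 4, n)
        classes = rng.choice(SPINE_CLASSES, n)
        tab = cluster_class_crosstab(clusters, classes).to_numpy()
        chi2 = stats.chi2_contingency(tab)
        assert chi2.pvalue > 0.001

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cluster_class_crosstab([0, 1], ["thin"])
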