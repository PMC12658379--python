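"""Dendritic spine morphometry: refinement, geometry, classification, clustering.

Works on per-spine feature tables (µm units) exported from 3-D filament
reconstructions of dendrite segments.  The stages are:

1. **Refinement** — drop reconstruction artifacts: protrusions lacking a
   spine neck and spines below the minimum reconstructable diameter
   (0.4 µm by default; dendrite diameters outside 1–5 µm when a dendrite
   diameter column is present).
2. **Geometry** — closed-form surface area and volume modelling the spine
   as a truncated cone (frustum) from the attachment point to the head,
   capped by a terminal hemisphere, minus the hemisphere at the
   attachment point.
3. **Classification** — five morphological categories (thin, long thin,
   mushroom, stubby, filopodia) from length, head max diameter and the
   length-to-width ratio (LWR), via fixed-precedence threshold rules.
4. **Clustering** — z-score standardization, PCA, then k-means on the PCA
   scores, with the number of clusters chosen by the elbow method when
   not fixed; reported against the rule-based classes as a cluster-by-class
   contingency table.

Classification and clustering are exposed as scikit-learn style estimators
(:class:`SpineRuleClassifier`, :class:`SpineClusterer`) so they compose
with sklearn pipelines and model selection.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

SPINE_CLASSES = ("thin", "long_thin", "mushroom", "stubby", "filopodia")

#: The 16-feature roster used for clustering (the data dictionary).
#: Nine measured features, two ratios of the raw measurements, the two
#: closed-form geometry quantities, and three derived shape descriptors.
FEATURE_COLUMNS = (
    "length",               # attachment to tip along the spine axis, µm
    "head_max_diameter",    # µm
    "head_mean_diameter",   # µm
    "head_length",          # µm
    "neck_min_diameter",    # µm
    "neck_mean_diameter",   # µm
    "neck_length",          # µm
    "attachment_diameter",  # at the dendrite junction, µm
    "straightness",         # tip-to-base chord / path length, (0, 1]
    "lwr",                  # length / width (width convention configurable)
    "surface_area",         # µm², frustum + hemisphere model
    "volume",               # µm³
    "head_neck_ratio",      # head_max / neck_mean
    "head_length_fraction", # head_length / length
    "neck_aspect",          # neck_length / neck_mean
    "taper",                # (head_max - attachment) / length
)


# --------------------------------------------------------------------------
# refinement
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RefinementConfig:
    """Rules for removing reconstruction artifacts from spine tables."""

    dendrite_diameter_range: tuple[float, float] = (1.0, 5.0)
    min_spine_diameter: float = 0.4
    drop_neckless: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.dendrite_diameter_range
        if not lo < hi:
            raise ValueError("dendrite_diameter_range low must be < high")


def refine_spines(
    spines: pd.DataFrame, cfg: RefinementConfig = RefinementConfig()
) -> tuple[pd.DataFrame, dict]:
    """Filter artifact records; return (kept, rejection report).

    A spine is removed if it lacks a neck (NaN ``neck_min_diameter``, when
    ``drop_neckless``), if its head max diameter is below the minimum
    reconstructable spine diameter, or — when a ``dendrite_diameter``
    column is present — if its parent dendrite lies outside the allowed
    diameter range.  The report counts removals by the first failing rule.
    """
    reasons = pd.Series("", index=spines.index, dtype=object)
    if cfg.drop_neckless and "neck_min_diameter" in spines.columns:
        m = spines["neck_min_diameter"].isna() & (reasons == "")
        reasons[m] = "neckless"
    m = (spines["head_max_diameter"] < cfg.min_spine_diameter) & (reasons == "")
    reasons[m] = "below_min_diameter"
    if "dendrite_diameter" in spines.columns:
        lo, hi = cfg.dendrite_diameter_range
        m = (~spines["dendrite_diameter"].between(lo, hi)) & (reasons == "")
        reasons[m] = "dendrite_diameter_out_of_range"
    kept = spines[reasons == ""].copy()
    report = dict(Counter(reasons[reasons != ""]))
    report["n_input"] = len(spines)
    report["n_kept"] = len(kept)
    return kept, report


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def spine_geometry(
    length: float | np.ndarray,
    head_max_diameter: float | np.ndarray,
    attachment_diameter: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form spine surface area (µm²) and volume (µm³).

    The spine is a conical frustum from attachment radius
    ``r_a = attachment_diameter/2`` to terminal radius
    ``r_t = head_max_diameter/2`` over height ``h = length − r_t`` (the
    terminal hemisphere caps the frustum; h floored at 1e-6 µm), plus the
    terminal hemisphere, minus the hemisphere at the attachment point:

        V = (πh/3)(r_a² + r_a r_t + r_t²) + (2/3)π r_t³ − (2/3)π r_a³
        A = π(r_a + r_t)·√(h² + (r_a − r_t)²) + 2π r_t² − 2π r_a²

    In the equal-radius limit these reduce exactly to the cylinder volume
    π r² h and lateral surface 2π r h.  If the attachment-hemisphere
    subtraction drives A negative (possible when r_a ≫ r_t) the area is
    floored at the frustum lateral surface with a warning.
    """
    length = np.asarray(length, dtype=float)
    r_t = np.asarray(head_max_diameter, dtype=float) / 2.0
    r_a = np.asarray(attachment_diameter, dtype=float) / 2.0
    if (r_t <= 0).any() or (r_a <= 0).any() or (length <= 0).any():
        raise ValueError("lengths and diameters must be positive")
    h = np.maximum(length - r_t, 1e-6)
    volume = (
        np.pi * h / 3.0 * (r_a**2 + r_a * r_t + r_t**2)
        + 2.0 / 3.0 * np.pi * r_t**3
        - 2.0 / 3.0 * np.pi * r_a**3
    )
    lateral = np.pi * (r_a + r_t) * np.sqrt(h**2 + (r_a - r_t) ** 2)
    area = lateral + 2.0 * np.pi * r_t**2 - 2.0 * np.pi * r_a**2
    neg = area < 0
    if neg.any():
        warnings.warn(
            f"{int(np.sum(neg))} spines with negative surface area after "
            "hemisphere subtraction; floored at the frustum lateral area",
            stacklevel=2,
        )
        area = np.where(neg, lateral, area)
    return area, volume


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

class SpineRuleClassifier(ClassifierMixin, BaseEstimator):
    """Threshold classifier assigning each spine one of five categories.

    Decision rules on length (µm), head max diameter (µm), and
    length-to-width ratio LWR = length / width, applied with a fixed
    precedence so the rule set is exhaustive and mutually exclusive:

    1. mushroom   — head max diameter ≥ ``head_threshold`` (0.6 µm)
    2. stubby     — LWR ≤ 1
    3. filopodia  — length > ``filopodia_min_length`` (2 µm)
    4. long_thin  — ``thin_max_length`` (1 µm) < length ≤ 2 µm
    5. thin       — length ≤ 1 µm

    Head-size dominance (mushroom first) resolves the overlap between the
    raw criteria — e.g. a spine with LWR ≤ 1 and head ≥ 0.6 µm is
    mushroom, and the head = 0.6 µm boundary belongs to mushroom.  The
    width in LWR defaults to the head max diameter
    (``width_convention="head_max"``; ``"head_mean"`` is available).

    The estimator is stateless: ``fit`` validates parameters and records
    ``classes_``; ``predict`` accepts a DataFrame with columns ``length``,
    ``head_max_diameter`` (and ``head_mean_diameter`` if that convention
    is selected).
    """

    def __init__(
        self,
        head_threshold: float = 0.6,
        thin_max_length: float = 1.0,
        filopodia_min_length: float = 2.0,
        lwr_stubby_max: float = 1.0,
        width_convention: str = "head_max",
    ):
        self.head_threshold = head_threshold
        self.thin_max_length = thin_max_length
        self.filopodia_min_length = filopodia_min_length
        self.lwr_stubby_max = lwr_stubby_max
        self.width_convention = width_convention

    def fit(self, X=None, y=None):
        if self.width_convention not in ("head_max", "head_mean"):
            raise ValueError(f"unknown width convention {self.width_convention!r}")
        if not 0 < self.thin_max_length < self.filopodia_min_length:
            raise ValueError("length thresholds must satisfy 0 < thin < filopodia")
        self.classes_ = np.asarray(SPINE_CLASSES)
        return self

    def _width(self, X: pd.DataFrame) -> np.ndarray:
        col = {"head_max": "head_max_diameter", "head_mean": "head_mean_diameter"}[
            self.width_convention
        ]
        if col not in X.columns:
            raise ValueError(f"missing required feature column {col!r}")
        return X[col].to_numpy(dtype=float)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "classes_"):
            self.fit()
        for col in ("length", "head_max_diameter"):
            if col not in X.columns:
                raise ValueError(f"missing required feature column {col!r}")
            if X[col].isna().any():
                bad = X.index[X[col].isna()][0]
                raise ValueError(f"spine {bad!r}: missing {col}")
        length = X["length"].to_numpy(dtype=float)
        head = X["head_max_diameter"].to_numpy(dtype=float)
        lwr = length / self._width(X)
        return np.select(
            [
                head >= self.head_threshold,
                lwr <= self.lwr_stubby_max,
                length > self.filopodia_min_length,
                length > self.thin_max_length,
            ],
            ["mushroom", "stubby", "filopodia", "long_thin"],
            default="thin",
        )


def classify_spines(spines: pd.DataFrame, **params) -> np.ndarray:
    """Rule-classify a spine table; thin wrapper over :class:`SpineRuleClassifier`."""
    return SpineRuleClassifier(**params).fit().predict(spines)


def lwr(spines: pd.DataFrame, width_convention: str = "head_max") -> np.ndarray:
    """Length-to-width ratio under the configured width convention."""
    col = {"head_max": "head_max_diameter", "head_mean": "head_mean_diameter"}[width_convention]
    return spines["length"].to_numpy(dtype=float) / spines[col].to_numpy(dtype=float)


# --------------------------------------------------------------------------
# per-segment densities
# --------------------------------------------------------------------------

def per_segment_counts(
    spines: pd.DataFrame,
    segment_length_um: float = 20.0,
    class_col: str = "class_label",
    per_neuron: bool = False,
) -> pd.DataFrame:
    """Per-class spine counts per 20 µm of dendrite, plus total density.

    Counts within each traced segment are scaled by
    ``20 / segment_length_um``; the sum over the five classes equals the
    segment's total per-20-µm density exactly.  With ``per_neuron=True``
    segment rows are averaged within neuron.
    """
    if segment_length_um <= 0 or not np.isfinite(segment_length_um):
        raise ValueError("segment length must be a positive finite number of µm")
    scale = 20.0 / segment_length_um
    tab = (
        pd.crosstab(
            [spines["neuron_id"], spines["segment_id"]],
            pd.Categorical(spines[class_col], categories=SPINE_CLASSES),
            dropna=False,
        )
        * scale
    )
    tab.columns = [str(c) for c in tab.columns]
    tab["total_per_20um"] = tab[list(SPINE_CLASSES)].sum(axis=1)
    tab = tab.reset_index()
    if per_neuron:
        tab = tab.groupby("neuron_id", as_index=False)[
            list(SPINE_CLASSES) + ["total_per_20um"]
        ].mean()
    return tab


# --------------------------------------------------------------------------
# feature matrix + clustering
# --------------------------------------------------------------------------

def compute_feature_matrix(
    spines: pd.DataFrame, width_convention: str = "head_max"
) -> pd.DataFrame:
    """Assemble the 16-column morphometric feature matrix.

    Adds the derived columns (LWR, surface area, volume, and the shape
    ratios) to the nine measured features; see :data:`FEATURE_COLUMNS` for
    the roster.  Requires a refined table (no missing neck diameters).
    """
    df = spines.copy()
    df["lwr"] = lwr(df, width_convention)
    area, vol = spine_geometry(
        df["length"], df["head_max_diameter"], df["attachment_diameter"]
    )
    df["surface_area"] = area
    df["volume"] = vol
    df["head_neck_ratio"] = df["head_max_diameter"] / df["neck_mean_diameter"]
    df["head_length_fraction"] = df["head_length"] / df["length"]
    df["neck_aspect"] = df["neck_length"] / df["neck_mean_diameter"]
    df["taper"] = (df["head_max_diameter"] - df["attachment_diameter"]) / df["length"]
    X = df[list(FEATURE_COLUMNS)]
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"feature matrix has missing values in {bad}; refine first")
    return X


class SpineClusterer(ClusterMixin, BaseEstimator):
    """z-score → PCA → k-means clustering of spine feature matrices.

    Features are standardized per column (mean 0, sd 1 over the fitted
    set), projected with PCA retaining all components (the first two are
    conventionally used for display), and clustered with k-means on the
    full score matrix.  When ``n_clusters`` is None the number of clusters
    is chosen by the elbow method: the k in ``k_range`` whose point on the
    normalized inertia-vs-k curve lies farthest below the chord joining
    the curve's endpoints, ties broken toward smaller k.

    Parameters
    ----------
    n_clusters : int or None, default 5
        Fixed cluster count; None triggers elbow selection.
    k_range : (int, int), default (2, 10)
        Inclusive candidate range for elbow selection.
    n_init : int, default 10
        k-means restarts.
    random_state : int, default 0
        Seed; fixed seed gives identical assignments across runs.

    Attributes
    ----------
    scaler_, pca_, kmeans_ : fitted sklearn transformers/estimator
    labels_ : cluster assignment per fitted spine
    n_clusters_ : the cluster count actually used
    explained_variance_ratio_ : PCA explained-variance fractions
    elbow_inertias_ : dict of k → inertia (only when elbow selection ran)
    """

    def __init__(
        self,
        n_clusters: int | None = 5,
        k_range: tuple[int, int] = (2, 10),
        n_init: int = 10,
        random_state: int = 0,
        tol: float = 1e-6,
    ):
        self.n_clusters = n_clusters
        self.k_range = k_range
        self.n_init = n_init
        self.random_state = random_state
        self.tol = tol

    def _kmeans(self, k: int) -> KMeans:
        return KMeans(
            n_clusters=k, n_init=self.n_init, random_state=self.random_state, tol=self.tol
        )

    def _select_k(self, scores: np.ndarray) -> int:
        lo, hi = self.k_range
        ks = np.arange(lo - 1, hi + 2)
        inertia = np.array([self._kmeans(k).fit(scores).inertia_ for k in ks])
        self.elbow_inertias_ = dict(zip(ks.tolist(), inertia.tolist()))
        # elbow = knee of the inertia curve: the k whose (normalized) point
        # lies farthest below the chord joining the curve's endpoints;
        # ties go to the smaller k
        x = (ks - ks[0]) / (ks[-1] - ks[0])
        span = inertia[0] - inertia[-1]
        y = (inertia - inertia[-1]) / (span if span > 0 else 1.0)
        dist = (1.0 - x) * y[0] + x * y[-1] - y  # chord height minus curve
        inner = (ks >= lo) & (ks <= hi)
        best = int(ks[inner][np.argmax(np.round(dist[inner], 12))])
        return best

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        self.pca_ = PCA(random_state=self.random_state).fit(Z)
        scores = self.pca_.transform(Z)
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_
        k = self.n_clusters if self.n_clusters is not None else self._select_k(scores)
        if len(X) < k:
            raise ValueError(f"need at least {k} spines to form {k} clusters")
        self.kmeans_ = self._kmeans(k).fit(scores)
        self.n_clusters_ = k
        self.labels_ = self.kmeans_.labels_
        self.inertia_ = self.kmeans_.inertia_
        return self

    def transform(self, X) -> np.ndarray:
        """PCA scores of new data under the fitted standardization."""
        return self.pca_.transform(self.scaler_.transform(np.asarray(X, dtype=float)))

    def predict(self, X) -> np.ndarray:
        return self.kmeans_.predict(self.transform(X))

    def cluster_proportions(self) -> np.ndarray:
        """Fraction of fitted spines per cluster (sums to 1)."""
        counts = np.bincount(self.labels_, minlength=self.n_clusters_)
        return counts / counts.sum()


def cluster_spines(
    features, k: int | None = 5, random_state: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convenience wrapper: returns (assignments, proportions, explained variance)."""
    model = SpineClusterer(n_clusters=k, random_state=random_state).fit(features)
    return model.labels_, model.cluster_proportions(), model.explained_variance_ratio_


def cluster_class_crosstab(
    assignments: Sequence[int], class_labels: Sequence[str]
) -> pd.DataFrame:
    """Cluster-by-class contingency table of absolute spine counts.

    Rows are clusters, columns the five morphological categories; row and
    column marginals equal the cluster sizes and class counts.
    """
    a = np.asarray(assignments)
    c = np.asarray(class_labels)
    if len(a) != len(c):
        raise ValueError(f"length mismatch: {len(a)} assignments vs {len(c)} labels")
    tab = pd.crosstab(
        pd.Series(a, name="cluster"),
        pd.Categorical(c, categories=SPINE_CLASSES),
        dropna=False,
    )
    tab.columns = [str(col) for col in tab.columns]
    return tab
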