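"""Phenotyping stage: outlier exclusion, transforms, k-means, elbow, labels.

The feature space is (average frequency, duration, log amplitude, log
cycle count); amplitude and cycle count are log-transformed because their
distributions are right-skewed, then all four columns are z-standardized
so each feature contributes equally to the Euclidean metric.  K-means is
run with many random restarts (k-means++ initialization) and the number
of clusters is chosen at the elbow of the within-cluster sum-of-squares
(WSS) curve.  With k = 3 the clusters are relabelled canonically by
ascending duration centroid (1 = shortest, 3 = longest), matching the
published phenotype naming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .synth import FEATURE_COLUMNS  # avg_frequency_hz, duration_ms, amplitude_z, n_cycles

LOG_COLUMNS = ("amplitude_z", "n_cycles")
TRANSFORMED_COLUMNS = ["avg_frequency_hz", "duration_ms", "log_amplitude", "log_n_cycles"]

_MAD_SCALE = 1.4826  # consistency factor: MAD -> SD under normality


class ClusterError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """Transformed (and optionally standardized) event-by-feature matrix.

    Retains per-column means/SDs so centroids can be mapped back to the
    raw measurement scale.
    """

    values: np.ndarray                      # n_events x 4
    columns: list[str] = field(default_factory=lambda: list(TRANSFORMED_COLUMNS))
    standardized: bool = False
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    event_ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        """Map standardized coordinates back to the raw feature scale
        (undo z-scoring, then exponentiate the log columns)."""
        if not self.standardized:
            raise ClusterError("matrix is not standardized")
        raw = z * self.sds + self.means
        out = np.array(raw, dtype=float)
        for j, col in enumerate(self.columns):
            if col.startswith("log_"):
                out[..., j] = np.exp(raw[..., j])
        return out


def _transformed(table: pd.DataFrame) -> pd.DataFrame:
    """Apply natural logs to amplitude and cycles; keep frequency/duration."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ClusterError(f"feature table missing columns {missing}")
    bad = (table[list(LOG_COLUMNS)] <= 0).any(axis=None)
    if bad:
        raise ClusterError("amplitude and cycle count must be positive for log transform")
    out = pd.DataFrame(
        {
            "avg_frequency_hz": table["avg_frequency_hz"].to_numpy(float),
            "duration_ms": table["duration_ms"].to_numpy(float),
            "log_amplitude": np.log(table["amplitude_z"].to_numpy(float)),
            "log_n_cycles": np.log(table["n_cycles"].to_numpy(float)),
        }
    )
    return out


def exclude_outliers(
    table: pd.DataFrame, z_max: float = 3.5
) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop events with extreme values in any transformed feature.

    Extremeness is a robust z-score, |x - median| / (1.4826 x MAD) > z_max,
    computed once on the original statistics (single pass, so removal is
    order-independent).  Columns with zero MAD are skipped.
    Returns (retained table, integer positions of excluded rows).
    """
    if len(table) < 10:
        raise ClusterError("need at least 10 events for outlier screening")
    tf = _transformed(table).to_numpy()
    med = np.median(tf, axis=0)
    mad = np.median(np.abs(tf - med), axis=0) * _MAD_SCALE
    mask = np.zeros(len(table), dtype=bool)
    for j in range(tf.shape[1]):
        if mad[j] <= 0:
            import warnings

            warnings.warn(
                f"zero MAD in column {TRANSFORMED_COLUMNS[j]}; skipped in "
                "outlier screening",
                stacklevel=2,
            )
            continue
        mask |= np.abs(tf[:, j] - med[j]) / mad[j] > z_max
    if mask.all():
        raise ClusterError("outlier rule excluded every event")
    return table.loc[~mask].reset_index(drop=True), np.flatnonzero(mask)


def transform_and_standardize(table: pd.DataFrame) -> FeatureMatrix:
    """Log-transform skewed columns and z-standardize all four features."""
    tf = _transformed(table)
    vals = tf.to_numpy()
    means = vals.mean(axis=0)
    sds = vals.std(axis=0, ddof=0)
    if np.any(sds <= 0):
        raise ClusterError("constant feature column cannot be standardized")
    ids = (
        table["event_id"].to_numpy()
        if "event_id" in table.columns
        else np.arange(len(table))
    )
    return FeatureMatrix(
        values=(vals - means) / sds,
        standardized=True,
        means=means,
        sds=sds,
        event_ids=ids,
    )


@dataclass
class ClusterModel:
    """A fitted k-means solution on the standardized feature matrix."""

    k: int
    centroids: np.ndarray                 # k x 4, standardized space
    centroids_raw: np.ndarray             # k x 4, back-transformed
    assignments: np.ndarray               # 1..k per event
    total_wss: float
    n_restarts: int
    seed: int
    wss_curve: dict[int, float] = field(default_factory=dict)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k + 1)[1:]


def kmeans_fit(
    matrix: FeatureMatrix,
    k: int,
    n_restarts: int = 300,
    seed: int = 0,
) -> ClusterModel:
    """Best-of-``n_restarts`` Lloyd k-means (k-means++ starts), deterministic
    given ``seed``."""
    if not matrix.standardized:
        raise ClusterError("k-means expects a standardized matrix")
    if k >= matrix.n:
        raise ClusterError(f"k={k} must be below n={matrix.n}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=seed % (2**32),
    ).fit(matrix.values)
    centroids = km.cluster_centers_
    return ClusterModel(
        k=k,
        centroids=centroids,
        centroids_raw=matrix.inverse_transform(centroids),
        assignments=km.labels_.astype(int) + 1,
        total_wss=float(km.inertia_),
        n_restarts=n_restarts,
        seed=seed,
    )


def wss_curve(
    matrix: FeatureMatrix,
    k_max: int = 8,
    n_restarts: int = 300,
    seed: int = 0,
) -> dict[int, float]:
    """Total within-cluster sum of squares for k = 1..k_max."""
    return {
        k: kmeans_fit(matrix, k, n_restarts=n_restarts, seed=seed).total_wss
        for k in range(1, k_max + 1)
    }


def select_k_elbow(curve: dict[int, float]) -> int:
    """Elbow of the WSS curve: the k at which the rate of decrease in WSS
    changes most sharply.

    The rate of decrease is the first difference of the curve; its sharpest
    change is the maximal second difference, evaluated at the interior k
    values.  Ties break toward smaller k (argmax takes the first maximum);
    a perfectly linear curve has no elbow and yields the smallest interior
    k with a warning.
    """
    ks = sorted(curve)
    if len(ks) < 4 or ks != list(range(ks[0], ks[0] + len(ks))):
        raise ClusterError("need >= 4 consecutive k values")
    w = np.array([curve[k] for k in ks], dtype=float)
    if np.any(np.diff(w) > 1e-9 * max(abs(w[0]), 1.0)):
        raise ClusterError("WSS curve must be non-increasing in k")
    curvature = w[:-2] - 2 * w[1:-1] + w[2:]
    if np.all(curvature <= 1e-12 * max(abs(w[0]), 1.0)):
        import warnings

        warnings.warn("no elbow: WSS curve is linear", stacklevel=2)
        return ks[1]
    return ks[1 + int(np.argmax(curvature))]


def canonical_labels(model: ClusterModel) -> ClusterModel:
    """Relabel a k=3 solution by ascending raw-scale duration centroid
    (1 = shortest duration, 3 = longest), the published phenotype order."""
    if model.k != 3:
        import warnings

        warnings.warn("canonical labels defined for k=3 only; left as-is",
                      stacklevel=2)
        return model
    dur = model.centroids_raw[:, TRANSFORMED_COLUMNS.index("duration_ms")]
    order = np.argsort(dur, kind="stable")       # old index -> rank
    new_of_old = np.empty(3, dtype=int)
    new_of_old[order] = np.arange(1, 4)
    return ClusterModel(
        k=3,
        centroids=model.centroids[order],
        centroids_raw=model.centroids_raw[order],
        assignments=new_of_old[model.assignments - 1],
        total_wss=model.total_wss,
        n_restarts=model.n_restarts,
        seed=model.seed,
        wss_curve=dict(model.wss_curve),
    )


def fit_phenotypes(
    table: pd.DataFrame,
    k: int | None = None,
    k_max: int = 8,
    n_restarts: int = 300,
    seed: int = 0,
    elbow_restarts: int | None = None,
) -> tuple[ClusterModel, pd.DataFrame, np.ndarray]:
    """Full clustering stage on a raw feature table.

    Excludes outliers, transforms and standardizes, selects k at the WSS
    elbow when ``k`` is None, fits best-of-restarts k-means and applies
    canonical labels for k=3.  Returns (model, retained table with a
    ``cluster`` column, excluded row positions).
    """
    retained, excluded = exclude_outliers(table)
    matrix = transform_and_standardize(retained)
    curve = {}
    if k is None:
        curve = wss_curve(
            matrix, k_max=k_max,
            n_restarts=elbow_restarts or n_restarts, seed=seed,
        )
        k = select_k_elbow(curve)
    model = kmeans_fit(matrix, k, n_restarts=n_restarts, seed=seed)
    model.wss_curve = curve
    model = canonical_labels(model)
    labelled = retained.copy()
    labelled["cluster"] = model.assignments
    return model, labelled, excluded
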