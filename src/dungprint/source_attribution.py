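"""Ordination-based fecal source attribution.

The reference library of dung compositions is ordinated by PCA; lake-sediment
samples are then projected into the same component space as *supplementary
individuals* (using the training centering, scaling and loadings, without
influencing the fit).  Training samples are clustered in score space with
Ward's method on Euclidean distances (hierarchical clustering on principal
components, HCPC), and each sediment sample is attributed to the nearest
cluster centroid.  Shorter centroid distance means greater similarity of the
sediment's steroid signature to that species group — an indicator of the
dominant fecal contributor.

Determinism: component signs are fixed so that the largest-magnitude loading
of each component is positive, making scores and loadings reproducible across
runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import cdist

__all__ = [
    "OrdinationModel",
    "ClusterModel",
    "fit_pca",
    "project_supplementary",
    "hcpc_cluster",
    "attribute_sediments",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


@dataclass
class OrdinationModel:
    """A fitted PCA: centering/scaling vectors, loadings and training scores.

    ``loadings`` has shape (variables, components) with orthonormal columns;
    ``training_scores`` is a DataFrame (samples x components, columns
    ``PC1..PCk``); ``explained_variance`` are fractions of total variance.
    """

    variable_names: list[str]
    center_vector: np.ndarray
    scale_vector: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    training_scores: pd.DataFrame
    n_components: int

    def __post_init__(self) -> None:
        ev = self.explained_variance
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("explained variance fractions must be non-increasing")
        if ev.sum() > 1 + 1e-9:
            raise ValueError("explained variance fractions sum above 1")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("loading columns are not orthonormal")

    @property
    def component_names(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.n_components)]


@dataclass
class ClusterModel:
    """Ward dendrogram over training scores cut at ``k`` clusters.

    ``merge_history`` is a scipy linkage matrix with Euclidean ("Ward.D2"
    style, square-root form) heights.  ``centroids`` are means of member
    scores, one row per cluster id 1..k.
    """

    merge_history: np.ndarray
    k: int
    assignments: pd.Series  # sample_id -> cluster id (1-based)
    centroids: pd.DataFrame  # index cluster id, columns PC1..PCk

    def __post_init__(self) -> None:
        counts = self.assignments.value_counts()
        if set(counts.index) != set(range(1, self.k + 1)):
            raise ValueError("cluster ids must be 1..k with every cluster non-empty")


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude loading of each component positive.

    Magnitude ties are broken toward the lowest variable index (within a
    1e-9 relative tolerance) so the convention does not depend on
    floating-point noise in the solver.
    """
    flip = np.ones(loadings.shape[1])
    for j in range(loadings.shape[1]):
        mag = np.abs(loadings[:, j])
        i = int(np.flatnonzero(mag >= mag.max() * (1 - 1e-9))[0])
        if loadings[i, j] < 0:
            flip[j] = -1.0
    return loadings * flip


def fit_pca(
    profiles: pd.DataFrame,
    n_components: int | None = None,
    standardize: bool = True,
) -> OrdinationModel:
    """Principal component analysis of a profile matrix (samples x variables).

    Variables are centered, and — by default — scaled to unit (population,
    ddof=0) standard deviation, the convention of the HCPC workflow this
    mirrors.  ``n_components`` defaults to min(n_samples - 1, n_variables).
    """
    n, p = profiles.shape
    if n < 2 or p < 2:
        raise ValueError(f"need >=2 samples and >=2 variables, got {n}x{p}")
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, min(n-1, p)] = [1, {max_comp}], "
            f"got {n_components}"
        )
    X = profiles.to_numpy(dtype=float)
    center = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0, ddof=0)
        constant = scale <= 0
        if constant.any():
            names = [profiles.columns[i] for i in np.flatnonzero(constant)]
            raise ValueError(
                f"cannot standardize constant variable(s): {names}"
            )
    else:
        scale = np.ones(p)
    Z = (X - center) / scale
    # SVD of the centered/scaled matrix: right singular vectors are loadings.
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2  # proportional to component variances
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    loadings = _fix_signs(vt[:n_components].T)
    scores = Z @ loadings
    model = OrdinationModel(
        variable_names=list(profiles.columns),
        center_vector=center,
        scale_vector=scale,
        loadings=loadings,
        explained_variance=frac[:n_components],
        training_scores=pd.DataFrame(
            scores,
            index=profiles.index,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        n_components=n_components,
    )
    return model


def project_supplementary(model: OrdinationModel, profiles: pd.DataFrame) -> pd.DataFrame:
    """Project new samples into an existing ordination.

    Supplementary individuals receive scores via the training centering,
    scaling and loadings; the fit itself is untouched.
    """
    missing = [v for v in model.variable_names if v not in profiles.columns]
    extra = [v for v in profiles.columns if v not in model.variable_names]
    if missing or extra:
        raise ValueError(
            f"variable mismatch with ordination model; missing={missing}, extra={extra}"
        )
    X = profiles[model.variable_names].to_numpy(dtype=float)
    Z = (X - model.center_vector) / model.scale_vector
    scores = Z @ model.loadings
    return pd.DataFrame(scores, index=profiles.index, columns=model.component_names)


def _within_inertia(scores: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = scores[labels == lab]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def _auto_k(scores: np.ndarray, Z: np.ndarray, k_max: int) -> int:
    """Pick k by the greatest relative drop of within-cluster inertia.

    For k in 2..k_max, the candidate quality is
    (W(k-1) - W(k)) / W(k-1): the share of remaining within-cluster inertia
    removed by allowing one more cluster.  The first big structural split
    dominates this ratio.
    """
    best_k, best_gain = 2, -np.inf
    labels_prev = cut_tree(Z, n_clusters=1).ravel()
    w_prev = _within_inertia(scores, labels_prev)
    for k in range(2, k_max + 1):
        labels = cut_tree(Z, n_clusters=k).ravel()
        w = _within_inertia(scores, labels)
        gain = (w_prev - w) / w_prev if w_prev > 0 else 0.0
        if gain > best_gain:
            best_k, best_gain = k, gain
        w_prev = w
    return best_k


def hcpc_cluster(
    training_scores: pd.DataFrame,
    k: int | None = None,
    consolidate: bool = False,
) -> ClusterModel:
    """Ward clustering of samples in retained-component score space.

    ``k=None`` selects the cut in 2..min(10, n-1) with the maximal relative
    loss of within-cluster inertia between successive cuts.  ``consolidate``
    optionally refines the cut with one k-means pass seeded at the Ward
    centroids (off by default).
    """
    n = len(training_scores)
    scores = training_scores.to_numpy(dtype=float)
    if k is not None and not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n={n}, got {k}")
    Z = linkage(scores, method="ward")  # Euclidean, sqrt-form heights
    if k is None:
        k = _auto_k(scores, Z, k_max=min(10, n - 1))
    raw = cut_tree(Z, n_clusters=k).ravel()
    # Relabel clusters 1..k in order of first appearance for stable ids.
    order = {lab: i + 1 for i, lab in enumerate(pd.unique(raw))}
    labels = np.array([order[lab] for lab in raw])
    if consolidate:
        from sklearn.cluster import KMeans

        init = np.stack([scores[labels == c].mean(axis=0) for c in range(1, k + 1)])
        km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=300)
        labels = km.fit_predict(scores) + 1
    assignments = pd.Series(labels, index=training_scores.index, name="cluster")
    centroids = (
        pd.DataFrame(scores, index=training_scores.index, columns=training_scores.columns)
        .groupby(assignments)
        .mean()
    )
    return ClusterModel(merge_history=Z, k=k, assignments=assignments, centroids=centroids)


def attribute_sediments(
    model: OrdinationModel,
    clusters: ClusterModel,
    sediment_profiles: pd.DataFrame,
    age_model=None,
    depths: pd.Series | None = None,
) -> pd.DataFrame:
    """Attribute sediment samples to the nearest reference cluster centroid.

    Returns one row per sediment sample with projected scores, Euclidean
    distance to every centroid (``dist_to_cluster_<id>``), the nearest cluster
    id, and — when an age model and depths are supplied — the sample age.
    An empty sediment set yields an empty frame.  Distance ties are broken
    toward the lowest cluster id with a logged warning.
    """
    if set(clusters.centroids.columns) != set(model.component_names):
        raise ValueError("cluster model was not built from this ordination's scores")
    if len(sediment_profiles) == 0:
        cols = (
            model.component_names
            + [f"dist_to_cluster_{c}" for c in clusters.centroids.index]
            + ["nearest_cluster"]
        )
        return pd.DataFrame(columns=cols)
    scores = project_supplementary(model, sediment_profiles)
    dists = cdist(
        scores.to_numpy(), clusters.centroids[model.component_names].to_numpy()
    )
    nearest_pos = dists.argmin(axis=1)
    row_min = dists[np.arange(len(dists)), nearest_pos]
    ties = (np.isclose(dists, row_min[:, None], rtol=0, atol=1e-12).sum(axis=1)) > 1
    for sid in scores.index[ties]:
        logger.warning(
            "sample %s is equidistant to multiple centroids; assigned lowest cluster id",
            sid,
        )
    cluster_ids = clusters.centroids.index.to_numpy()
    out = scores.copy()
    for j, cid in enumerate(cluster_ids):
        out[f"dist_to_cluster_{cid}"] = dists[:, j]
    out["nearest_cluster"] = cluster_ids[nearest_pos]
    if age_model is not None and depths is not None:
        out["age_cal_BP"] = age_model.age_at(depths.reindex(scores.index).to_numpy())
    return out


# ---------------------------------------------------------------------------
# Plain-text model persistence so attribution runs are reproducible
# ---------------------------------------------------------------------------

def save_model(model: OrdinationModel, clusters: ClusterModel, path: str | Path) -> None:
    """Write ordination + clusters as a documented key/value + matrix text file."""
    lines: list[str] = ["# dungprint ordination model v1"]
    lines.append("variables\t" + "\t".join(model.variable_names))
    lines.append("n_components\t" + str(model.n_components))
    lines.append("center\t" + "\t".join(format(float(v), '.17g') for v in model.center_vector))
    lines.append("scale\t" + "\t".join(format(float(v), '.17g') for v in model.scale_vector))
    lines.append(
        "explained_variance\t" + "\t".join(format(float(v), '.17g') for v in model.explained_variance)
    )
    for i, row in enumerate(model.loadings):
        lines.append(f"loading\t{model.variable_names[i]}\t" + "\t".join(format(float(v), '.17g') for v in row))
    for sid, row in model.training_scores.iterrows():
        lines.append(f"score\t{sid}\t" + "\t".join(format(float(v), '.17g') for v in row.to_numpy()))
    lines.append("k\t" + str(clusters.k))
    for sid, cid in clusters.assignments.items():
        lines.append(f"assignment\t{sid}\t{cid}")
    for cid, row in clusters.centroids.iterrows():
        lines.append(f"centroid\t{cid}\t" + "\t".join(format(float(v), '.17g') for v in row.to_numpy()))
    for row in clusters.merge_history:
        lines.append("merge\t" + "\t".join(format(float(v), '.17g') for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> tuple[OrdinationModel, ClusterModel]:
    variables: list[str] = []
    n_components = 0
    center = scale = ev = None
    loadings: list[list[float]] = []
    score_ids: list[str] = []
    score_rows: list[list[float]] = []
    k = 0
    assign_ids: list[str] = []
    assign_vals: list[int] = []
    centroid_ids: list[int] = []
    centroid_rows: list[list[float]] = []
    merges: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        key = parts[0]
        if key == "variables":
            variables = parts[1:]
        elif key == "n_components":
            n_components = int(parts[1])
        elif key == "center":
            center = np.array([float(v) for v in parts[1:]])
        elif key == "scale":
            scale = np.array([float(v) for v in parts[1:]])
        elif key == "explained_variance":
            ev = np.array([float(v) for v in parts[1:]])
        elif key == "loading":
            loadings.append([float(v) for v in parts[2:]])
        elif key == "score":
            score_ids.append(parts[1])
            score_rows.append([float(v) for v in parts[2:]])
        elif key == "k":
            k = int(parts[1])
        elif key == "assignment":
            assign_ids.append(parts[1])
            assign_vals.append(int(parts[2]))
        elif key == "centroid":
            centroid_ids.append(int(parts[1]))
            centroid_rows.append([float(v) for v in parts[2:]])
        elif key == "merge":
            merges.append([float(v) for v in parts[1:]])
        else:
            raise ValueError(f"unknown model file record {key!r}")
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    model = OrdinationModel(
        variable_names=variables,
        center_vector=center,
        scale_vector=scale,
        loadings=np.array(loadings),
        explained_variance=ev,
        training_scores=pd.DataFrame(score_rows, index=score_ids, columns=comp_names),
        n_components=n_components,
    )
    clusters = ClusterModel(
        merge_history=np.array(merges),
        k=k,
        assignments=pd.Series(assign_vals, index=assign_ids, name="cluster"),
        centroids=pd.DataFrame(centroid_rows, index=centroid_ids, columns=comp_names),
    )
    return model, clusters
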