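"""UMAP projection of single-vessel extravasation patterns, the
UMAP-distance leakage index, hyperparameter tuning, k-means cluster
composition, and rank-based ROC diagnostics."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

DEFAULT_N_NEIGHBORS = 5
DEFAULT_MIN_DIST = 0.4
DEFAULT_SEED = 42


@dataclass
class EmbeddingResult:
    coords: np.ndarray                 # (n, 2)
    n_neighbors: int
    min_dist: float
    seed: int
    metric: str = "euclidean"
    input_matrix_hash: str = ""


@dataclass
class DiagnosticResult:
    roc_auc: float
    mann_whitney_U: float
    p_value: float
    positive_label: str
    unit: str = "per_animal"   # or "per_vessel"
    n_positive: int = 0
    n_negative: int = 0


def build_feature_matrix(
    normalized_traces: np.ndarray | list[np.ndarray],
    decimate_to: int | None = None,
) -> np.ndarray:
    """Stack baseline-normalized traces into a (vessels x frames) matrix.

    Mixed lengths are an error unless ``decimate_to`` resamples every
    row to a fixed frame count (recorded by the caller).
    """
    rows = [np.asarray(r, float) for r in normalized_traces]
    if not rows:
        return np.empty((0, 0))
    lengths = {len(r) for r in rows}
    if len(lengths) > 1 and decimate_to is None:
        raise ValueError(f"mixed trace lengths {sorted(lengths)}; enable resampling")
    if decimate_to is not None:
        out = []
        for r in rows:
            x_old = np.linspace(0, 1, len(r))
            x_new = np.linspace(0, 1, decimate_to)
            out.append(np.interp(x_new, x_old, r))
        rows = out
    return np.vstack(rows)


def embed_umap(
    matrix: np.ndarray,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
    seed: int = DEFAULT_SEED,
) -> EmbeddingResult:
    """2D UMAP embedding with Euclidean input metric and a fixed seed."""
    import umap

    matrix = np.asarray(matrix, float)
    if matrix.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} rows, got {matrix.shape[0]}"
        )
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
        metric="euclidean", random_state=seed, n_jobs=1,
    )
    coords = reducer.fit_transform(matrix)
    digest = hashlib.sha256(np.ascontiguousarray(matrix).tobytes()).hexdigest()[:16]
    return EmbeddingResult(coords=np.asarray(coords, float), n_neighbors=n_neighbors,
                           min_dist=min_dist, seed=seed, input_matrix_hash=digest)


def umap_distance(
    coords: np.ndarray,
    control_mask: np.ndarray,
    classes: np.ndarray | None = None,
) -> np.ndarray:
    """Mean Euclidean distance from each vessel to the control reference.

    The reference set is the control vessels (restricted to the same
    vascular class when ``classes`` is given); control vessels exclude
    themselves from their own reference. Raises on an empty reference.
    """
    coords = np.asarray(coords, float)
    control_mask = np.asarray(control_mask, bool)
    n = len(coords)
    if control_mask.shape != (n,):
        raise ValueError("control_mask must have one entry per vessel")
    out = np.empty(n)
    for i in range(n):
        ref = control_mask.copy()
        if classes is not None:
            ref &= np.asarray(classes) == classes[i]
        ref[i] = False
        if not ref.any():
            raise ValueError(f"empty control reference set for vessel {i}")
        diffs = coords[ref] - coords[i]
        out[i] = float(np.mean(np.sqrt((diffs**2).sum(axis=1))))
    return out


def tune_umap(
    matrix: np.ndarray,
    indices: pd.DataFrame,
    control_mask: np.ndarray,
    n_neighbors_grid: tuple[int, ...] = (5, 10, 15),
    min_dist_grid: tuple[float, ...] = (0.1, 0.4, 0.8),
    seed: int = DEFAULT_SEED,
    index_cols: tuple[str, ...] = ("auc", "dff0", "dfdt"),
) -> tuple[tuple[int, float], pd.DataFrame]:
    """Select the (n_neighbors, min_dist) cell maximizing the mean
    Spearman correlation between UMAP distance and the conventional
    indices. Returns the best cell and the full correlation table."""
    for col in index_cols:
        if np.std(indices[col].to_numpy()) == 0:
            raise ValueError(f"degenerate index {col!r}: zero variance")
    rows = []
    for nn, md in product(n_neighbors_grid, min_dist_grid):
        emb = embed_umap(matrix, n_neighbors=nn, min_dist=md, seed=seed)
        d = umap_distance(emb.coords, control_mask)
        corrs = {col: float(stats.spearmanr(d, indices[col]).statistic)
                 for col in index_cols}
        rows.append({"n_neighbors": nn, "min_dist": md,
                     **{f"spearman_{c}": v for c, v in corrs.items()},
                     "mean_spearman": float(np.mean(list(corrs.values())))})
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_spearman"].idxmax()]
    return (int(best["n_neighbors"]), float(best["min_dist"])), table


def kmeans_clusters(
    coords: np.ndarray,
    groups: np.ndarray,
    classes: np.ndarray | None = None,
    k: int = 3,
    seed: int = 0,
    n_init: int = 100,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame | None]:
    """k-means on embedding coordinates plus composition tables.

    Returns ``(labels, cluster_by_group, class_condition_by_cluster)``.
    ``cluster_by_group`` rows are clusters, columns group fractions
    (each row sums to 1); the second table gives, per (class, group)
    row, the fraction of its vessels landing in each cluster.
    """
    coords = np.asarray(coords, float)
    if k > len(coords):
        raise ValueError(f"k={k} exceeds number of points {len(coords)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(coords)

    groups = np.asarray(groups)
    comp = pd.crosstab(pd.Series(labels, name="cluster"),
                       pd.Series(groups, name="group"))
    cluster_by_group = comp.div(comp.sum(axis=1), axis=0)

    by_cluster = None
    if classes is not None:
        df = pd.DataFrame({"cluster": labels, "group": groups,
                           "vessel_class": np.asarray(classes)})
        counts = df.groupby(["vessel_class", "group"])["cluster"] \
                   .value_counts().unstack(fill_value=0)
        by_cluster = counts.div(counts.sum(axis=1), axis=0)
    return labels, cluster_by_group, by_cluster


def roc_diagnostic(
    values: np.ndarray,
    labels: np.ndarray,
    positive: str,
    unit: str = "per_animal",
    animal_ids: np.ndarray | None = None,
) -> DiagnosticResult:
    """Rank-formulation ROC-AUC with the Mann-Whitney equivalence.

    AUC = U / (n1*n2), where U counts (positive > negative) pairs with
    ties contributing one half. In ``per_animal`` mode vessel values are
    first averaged within animal, so the ranking unit matches the
    study's statistical unit. Exact Mann-Whitney p for <= 10 per group
    (ties permitting), asymptotic otherwise.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    if unit == "per_animal":
        if animal_ids is None:
            raise ValueError("per_animal ROC requires animal_ids")
        df = pd.DataFrame({"v": values, "lab": labels, "animal": np.asarray(animal_ids)})
        per = df.groupby("animal").agg(v=("v", "mean"), lab=("lab", "first"))
        values = per["v"].to_numpy()
        labels = per["lab"].to_numpy()
    elif unit != "per_vessel":
        raise ValueError("unit must be per_animal or per_vessel")

    pos = values[labels == positive]
    neg = values[labels != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")

    ranks = stats.rankdata(np.concatenate([pos, neg]))
    U = float(ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2)
    auc = U / (len(pos) * len(neg))

    has_ties = len(np.unique(values)) < len(values)
    method = "exact" if (max(len(pos), len(neg)) <= 10 and not has_ties) else "asymptotic"
    mw = stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    return DiagnosticResult(
        roc_auc=float(auc), mann_whitney_U=U, p_value=float(mw.pvalue),
        positive_label=str(positive), unit=unit,
        n_positive=len(pos), n_negative=len(neg),
    )
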