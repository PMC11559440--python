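"""k-means subtyping of patient summary statistics with silhouette model selection.

Feature sets: WD, DT, NT (Lying/Reclined/Upright/Unknown durations plus
FPT for the window; UserDefined durations are never used — their values
are ~0 for all patients and carry no signal) and combined = DT + NT
features concatenated, one row per patient.  Columns are z-scored with
the sample SD before clustering; k is chosen over 2..10 by maximizing
the average silhouette width (Euclidean, standardized space), ties
broken toward smaller k.  Reported clusters are relabeled largest-first
and centroids are mapped back to original units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples, silhouette_score

logger = logging.getLogger(__name__)

FEATURE_SETS: dict[str, list[str]] = {
    "wd": ["Lying-WD", "Reclined-WD", "Upright-WD", "Unknown-WD", "FPT-WD"],
    "dt": ["Lying-DT", "Reclined-DT", "Upright-DT", "Unknown-DT", "FPT-DT"],
    "nt": ["Lying-NT", "Reclined-NT", "Upright-NT", "Unknown-NT", "FPT-NT"],
}
FEATURE_SETS["combined"] = FEATURE_SETS["dt"] + FEATURE_SETS["nt"]

DEFAULT_K_RANGE = range(2, 11)


@dataclass
class StandardizationParams:
    mean: pd.Series
    sd: pd.Series


@dataclass
class ClusterResult:
    feature_set: str
    features: list[str]
    k: int
    labels: pd.Series  # canonical labels 0..k-1, largest cluster first
    centroids: pd.DataFrame  # original units, one row per canonical label
    sizes: pd.Series
    percentages: pd.Series
    silhouette_overall: float | None
    silhouette_per_cluster: pd.Series | None
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    inertia: float = float("nan")


def feature_matrix(summaries: pd.DataFrame, feature_set: str) -> pd.DataFrame:
    """Extract one feature set from the summary table, indexed by MRN."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; choose from {sorted(FEATURE_SETS)}")
    cols = FEATURE_SETS[feature_set]
    X = summaries.set_index("mrn")[cols].astype(float)
    if X.isna().any().any():
        n = int(X.isna().any(axis=1).sum())
        logger.warning("dropping %d patients with missing features", n)
        X = X.dropna()
    return X


def standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationParams]:
    """Column-wise z-scores with sample SD (n-1 denominator)."""
    if len(X) < 2:
        raise ValueError("standardization needs >=2 patients")
    mean = X.mean()
    sd = X.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance column(s): {list(zero.index)}")
    return (X - mean) / sd, StandardizationParams(mean=mean, sd=sd)


def destandardize(Z: pd.DataFrame | np.ndarray, params: StandardizationParams) -> pd.DataFrame:
    Z = pd.DataFrame(np.asarray(Z), columns=params.mean.index)
    return Z * params.sd + params.mean


def _canonicalize(labels: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters by descending size; ties by first patient index.

    Returns (new labels, order) where ``order[new] = old`` label.
    """
    sizes = np.bincount(labels, minlength=k)
    first = np.full(k, len(labels))
    for old in range(k):
        idx = np.flatnonzero(labels == old)
        if len(idx):
            first[old] = idx[0]
    order = sorted(range(k), key=lambda old: (-sizes[old], first[old]))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    return remap[labels], np.asarray(order)


def fit_kmeans_select(
    X: pd.DataFrame,
    k_range: range | list[int] = DEFAULT_K_RANGE,
    restarts: int = 50,
    max_iter: int = 100,
    seed: int = 0,
    feature_set: str = "custom",
    force_k: int | None = None,
) -> ClusterResult:
    """Standardize, run k-means over a k grid, and keep the silhouette winner.

    For each k, Lloyd's algorithm with k-means++ seeding is restarted
    ``restarts`` times and the best within-cluster sum of squares kept.
    ``force_k`` bypasses selection (debug; k=1 yields no silhouette).
    """
    Z, params = standardize(X)
    Zv = Z.to_numpy()
    n = len(Z)
    rng = np.random.RandomState(seed)

    ks = [force_k] if force_k is not None else list(k_range)
    best = None
    curve: dict[int, float] = {}
    for k in ks:
        if k > 1 and n <= k:
            warnings.warn(f"skipping k={k}: only {n} patients")
            continue
        km = KMeans(
            n_clusters=k,
            n_init=restarts,
            max_iter=max_iter,
            algorithm="lloyd",
            random_state=rng.randint(0, 2**31 - 1),
        )
        labels = km.fit_predict(Zv)
        sil = silhouette_score(Zv, labels, metric="euclidean") if k > 1 else None
        if k > 1:
            curve[k] = float(sil)
        # strict > keeps the smaller k on silhouette ties
        if force_k is not None or best is None or (sil is not None and sil > best[0]):
            best = (sil if sil is not None else -np.inf, k, km, labels)
    if best is None:
        raise ValueError("no feasible k in range")

    _, k_star, km, labels = best
    canon, order = _canonicalize(labels, k_star)
    centroids = destandardize(km.cluster_centers_[order], params)
    centroids.index.name = "cluster"
    sizes = pd.Series(np.bincount(canon, minlength=k_star), name="n")
    percentages = (100.0 * sizes / n).rename("pct")

    if k_star > 1:
        samples = silhouette_samples(Zv, canon, metric="euclidean")
        sil_overall = float(np.mean(samples))
        per_cluster = pd.Series(
            [float(samples[canon == c].mean()) for c in range(k_star)], name="silhouette"
        )
    else:
        sil_overall, per_cluster = None, None

    return ClusterResult(
        feature_set=feature_set,
        features=list(X.columns),
        k=k_star,
        labels=pd.Series(canon, index=X.index, name="cluster"),
        centroids=centroids,
        sizes=sizes,
        percentages=percentages,
        silhouette_overall=sil_overall,
        silhouette_per_cluster=per_cluster,
        silhouette_by_k=curve,
        inertia=float(km.inertia_),
    )


def cluster_table(result: ClusterResult, X: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster original-unit feature means, sizes and a grand-average row.

    The size-weighted mean of the cluster means reconstructs the grand
    mean (asserted to 1e-9): the table is internally consistent.
    """
    X = X.loc[result.labels.index]
    rows = []
    for c in range(result.k):
        members = X.loc[result.labels == c]
        row = members.mean()
        row["n"] = len(members)
        row["pct"] = 100.0 * len(members) / len(X)
        rows.append(row.rename(f"C{c + 1}"))
    grand = X.mean()
    grand["n"] = len(X)
    grand["pct"] = 100.0
    rows.append(grand.rename("Average"))
    table = pd.DataFrame(rows)

    weights = table["n"].iloc[:-1].to_numpy()
    recon = (table[X.columns].iloc[:-1].to_numpy() * weights[:, None]).sum(axis=0) / weights.sum()
    if not np.allclose(recon, grand[X.columns].to_numpy(dtype=float), atol=1e-9):
        raise AssertionError("weighted cluster means do not reconstruct the grand mean")
    return table
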