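"""Ensemble clustering of model activity outputs.

The strategy mirrors a virtual-trial mechanistic-clustering workflow:
per-arm feature centering (removing the direct dose/concentration effect),
dimensionality reduction (PCA or classical MDS, on Euclidean or Spearman
distance, into 2/3/5 dimensions), a grid of clustering algorithms (k-means,
1-D SOM, spectral, Gaussian mixture, hierarchical), per-setting optimal-k
selection by Calinski-Harabasz, Davies-Bouldin, gap and silhouette indices
(silhouette prioritized), and three solution-quality indicators: Hopkins
(clustering tendency), Dunn (compactness/separation) and a Jaccard bootstrap
stability index.  Selected clusters are then characterized demographically
and molecularly (differential and classifier proteins).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterConfig",
    "ClusterSolution",
    "QualityReport",
    "normalize_by_arm",
    "reduce_dimensions",
    "spearman_distance",
    "classical_mds",
    "fit_labels",
    "cluster_grid",
    "quality",
    "hopkins_statistic",
    "dunn_index",
    "jaccard_bootstrap",
    "select_best",
    "intercluster_distances",
    "characterize_clusters",
    "differential_proteins",
    "classifier_proteins",
    "default_grid",
]

ALGORITHMS = ("kmeans", "som", "spectral", "gmm", "hierarchical")
REDUCTIONS = ("pca", "mds")
ALLOWED_DIMS = (2, 3, 5)


@dataclass(frozen=True)
class ClusterConfig:
    reduction: str = "mds"
    dims: int = 5
    distance: str = "spearman"  # euclidean | spearman (spearman requires mds)
    algorithm: str = "hierarchical"
    linkage: str = "average"  # hierarchical only: average | complete | ward
    k_range: tuple = (2, 6)

    def __post_init__(self) -> None:
        if self.reduction not in REDUCTIONS:
            raise ValueError(f"unknown reduction {self.reduction!r}")
        if self.dims not in ALLOWED_DIMS:
            raise ValueError(f"dims must be one of {ALLOWED_DIMS}")
        if self.distance not in ("euclidean", "spearman"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.distance == "spearman" and self.reduction != "mds":
            raise ValueError("spearman distance is only available with mds")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.k_range[0] < 2:
            raise ValueError("k range must start at 2 (indices undefined at k=1)")

    @property
    def embedding_key(self) -> tuple:
        return (self.reduction, self.dims, self.distance)

    def describe(self) -> str:
        tail = f"-{self.linkage}" if self.algorithm == "hierarchical" else ""
        return f"{self.reduction}{self.dims}-{self.distance}-{self.algorithm}{tail}"


@dataclass
class ClusterSolution:
    config: ClusterConfig
    k: int  # silhouette-selected k
    labels: np.ndarray  # 1..k at the selected k
    index_table: pd.DataFrame  # one row per candidate k
    best_k: dict  # index name -> optimal k under that index
    embedding: np.ndarray
    converged: bool = True

    def refit(self, data: np.ndarray, seed: int = 0) -> np.ndarray:
        return fit_labels(data, self.k, self.config, seed=seed)


@dataclass(frozen=True)
class QualityReport:
    hopkins: float
    dunn: float
    jaccard_bootstrap: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.hopkins <= 1.0:
            raise ValueError("hopkins must lie in [0, 1]")
        if self.dunn < 0:
            raise ValueError("dunn must be >= 0")
        if not 0.0 <= self.jaccard_bootstrap <= 1.0:
            raise ValueError("jaccard bootstrap must lie in [0, 1]")


# ---------------------------------------------------------------------------
# normalization & reduction
# ---------------------------------------------------------------------------

def normalize_by_arm(values: pd.DataFrame, arms: pd.Series) -> pd.DataFrame:
    """Center each protein within each arm (subtract the per-arm per-protein
    mean), removing the direct exposure offset between dosing arms while
    preserving within-arm variability."""
    arms = arms.reindex(values.index)
    if arms.isna().any():
        raise ValueError("every row needs an arm label")
    out = values.copy()
    for arm, rows in values.groupby(arms).groups.items():
        block = values.loc[rows]
        if len(block) == 1:
            warnings.warn(f"arm {arm!r} has a single row; centered to zero")
        out.loc[rows] = block - block.mean(axis=0)
    return out


def spearman_distance(values: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Spearman rank correlation between row profiles."""
    X = np.asarray(values, dtype=float)
    const = np.ptp(X, axis=1) == 0
    if const.any():
        raise ValueError(
            f"constant rows have undefined rank correlation: {np.flatnonzero(const).tolist()}"
    )
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    corr = np.corrcoef(ranks)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def classical_mds(dist: np.ndarray, dims: int):
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distance matrix and embeds on the top
    eigenvectors; exact for distances that are Euclidean in ``dims``
    dimensions.  Returns (embedding, eigenvalue fractions).
    """
    D2 = np.asarray(dist, dtype=float) ** 2
    n = len(D2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = np.clip(w, 0.0, None)
    emb = V[:, :dims] * np.sqrt(pos[:dims])
    total = pos.sum()
    frac = pos[:dims] / total if total > 0 else np.zeros(dims)
    return emb, frac


def reduce_dimensions(values: pd.DataFrame, config: ClusterConfig):
    """Embed rows into ``config.dims`` dimensions.

    PCA returns principal-component scores with explained-variance fractions;
    MDS is classical scaling on the chosen row distance (Euclidean or
    1 - Spearman).
    """
    X = values.to_numpy(dtype=float)
    if X.shape[0] < config.dims + 1:
        raise ValueError("need at least dims + 1 rows")
    if config.reduction == "pca":
        p = PCA(n_components=config.dims, svd_solver="full")
        emb = p.fit_transform(X)
        return emb, p.explained_variance_ratio_
    if config.distance == "spearman":
        d = spearman_distance(X)
    else:
        d = squareform(pdist(X))
    return classical_mds(d, config.dims)


# ---------------------------------------------------------------------------
# algorithms
# ---------------------------------------------------------------------------

def _som_1d(X: np.ndarray, k: int, seed: int, epochs: int = 40) -> np.ndarray:
    """Self-organizing map on a 1-D chain of k nodes (node == cluster).

    Nodes are initialized along the first principal axis and trained with a
    shrinking Gaussian neighborhood; samples are assigned to their best
    matching node.
    """
    rng = np.random.default_rng(seed)
    n = len(X)
    center = X.mean(axis=0)
    Xc = X - center
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    axis = vt[0]
    lo, hi = np.quantile(Xc @ axis, [0.05, 0.95])
    nodes = center + np.linspace(lo, hi, k)[:, None] * axis
    positions = np.arange(k, dtype=float)
    for epoch in range(epochs):
        lr = 0.5 * (1 - epoch / epochs) + 0.01
        sigma = max(k / 2.0 * (1 - epoch / epochs), 0.5)
        for i in rng.permutation(n):
            x = X[i]
            bmu = int(np.argmin(np.sum((nodes - x) ** 2, axis=1)))
            h = np.exp(-((positions - bmu) ** 2) / (2 * sigma**2))
            nodes += lr * h[:, None] * (x - nodes)
    d = cdist(X, nodes)
    return np.argmin(d, axis=1)


def fit_labels(X: np.ndarray, k: int, config: ClusterConfig, seed: int = 0) -> np.ndarray:
    """Fit the configured algorithm at ``k`` clusters; labels are 1-based."""
    algo = config.algorithm
    if algo == "kmeans":
        raw = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    elif algo == "som":
        raw = _som_1d(X, k, seed)
    elif algo == "spectral":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = SpectralClustering(
                n_clusters=k, random_state=seed, assign_labels="kmeans",
                n_init=10,
            ).fit_predict(X)
    elif algo == "gmm":
        raw = GaussianMixture(n_components=k, random_state=seed,
                              n_init=3).fit_predict(X)
    elif algo == "hierarchical":
        raw = AgglomerativeClustering(
            n_clusters=k, linkage=config.linkage, metric="euclidean"
        ).fit_predict(X)
    else:  # pragma: no cover - guarded by ClusterConfig
        raise ValueError(algo)
    # relabel to 1..k' preserving first-appearance order
    _, relabeled = np.unique(raw, return_inverse=True)
    return relabeled + 1


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        w += float(np.sum((pts - pts.mean(axis=0)) ** 2))
    return w


def gap_statistic(X: np.ndarray, config: ClusterConfig, ks, seed: int = 0,
                  n_references: int = 20):
    """Gap statistic with a uniform bounding-box null.

    Returns (gap values per k, optimal k by the one-standard-error rule,
    falling back to argmax when the rule never fires).
    """
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w_ref = np.empty((n_references, len(ks)))
    for b in range(n_references):
        ref = rng.uniform(lo, hi, size=X.shape)
        for j, k in enumerate(ks):
            lab = fit_labels(ref, k, config, seed=seed + b + 1)
            log_w_ref[b, j] = np.log(max(_within_dispersion(ref, lab), 1e-300))
    gaps, sks = [], []
    for j, k in enumerate(ks):
        lab = fit_labels(X, k, config, seed=seed)
        log_w = np.log(max(_within_dispersion(X, lab), 1e-300))
        gaps.append(float(log_w_ref[:, j].mean() - log_w))
        sks.append(float(log_w_ref[:, j].std(ddof=0) * np.sqrt(1 + 1 / n_references)))
    best = None
    for j in range(len(ks) - 1):
        if gaps[j] >= gaps[j + 1] - sks[j + 1]:
            best = ks[j]
            break
    if best is None:
        best = ks[int(np.argmax(gaps))]
    return np.array(gaps), best


def cluster_grid(values: pd.DataFrame, configs, seed: int = 0,
                 gap_references: int = 20) -> list:
    """Fit every (config, k) combination and choose each config's optimal k.

    Per config, every index nominates its own k; the silhouette choice is the
    config's k (silhouette is prioritized over the other indices).
    """
    embeddings: dict = {}
    solutions = []
    for config in configs:
        if config.embedding_key not in embeddings:
            embeddings[config.embedding_key] = reduce_dimensions(values, config)[0]
        X = embeddings[config.embedding_key]
        ks = list(range(config.k_range[0], config.k_range[1] + 1))
        if ks[-1] > len(X) - 1:
            raise ValueError("k_max must be <= rows - 1")
        rows, labels_by_k, converged = [], {}, True
        for k in ks:
            try:
                lab = fit_labels(X, k, config, seed=seed)
            except Exception as exc:  # non-convergence is flagged, not fatal
                warnings.warn(f"{config.describe()} failed at k={k}: {exc}")
                converged = False
                continue
            labels_by_k[k] = lab
            k_eff = len(np.unique(lab))
            if k_eff < 2:
                rows.append({"k": k, "silhouette": np.nan,
                             "calinski_harabasz": np.nan,
                             "davies_bouldin": np.nan})
                continue
            rows.append({
                "k": k,
                "silhouette": float(silhouette_score(X, lab)),
                "calinski_harabasz": float(calinski_harabasz_score(X, lab)),
                "davies_bouldin": float(davies_bouldin_score(X, lab)),
            })
        table = pd.DataFrame(rows).set_index("k")
        gaps, gap_k = gap_statistic(X, config, list(table.index), seed=seed,
                                    n_references=gap_references)
        table["gap"] = gaps
        best_k = {
            "silhouette": int(table["silhouette"].idxmax()),
            "calinski_harabasz": int(table["calinski_harabasz"].idxmax()),
            "davies_bouldin": int(table["davies_bouldin"].idxmin()),
            "gap": int(gap_k),
        }
        k_star = best_k["silhouette"]
        solutions.append(
            ClusterSolution(
                config=config,
                k=k_star,
                labels=labels_by_k[k_star],
                index_table=table,
                best_k=best_k,
                embedding=X,
                converged=converged,
            )
        )
    return solutions


def default_grid(algorithms=ALGORITHMS, k_range=(2, 6)) -> list:
    """The full reduction x dimension x distance x algorithm grid."""
    configs = []
    for red, dims in itertools.product(REDUCTIONS, ALLOWED_DIMS):
        distances = ("euclidean", "spearman") if red == "mds" else ("euclidean",)
        for dist_name, algo in itertools.product(distances, algorithms):
            linkages = ("average", "complete", "ward") if algo == "hierarchical" else ("average",)
            for lk in linkages:
                configs.append(ClusterConfig(red, dims, dist_name, algo, lk, k_range))
    return configs


# ---------------------------------------------------------------------------
# quality indicators
# ---------------------------------------------------------------------------

def hopkins_statistic(X: np.ndarray, sample_fraction: float = 0.1,
                      seed: int = 0) -> float:
    """Hopkins clustering-tendency statistic with a uniform hyper-rectangle
    null: ~0.5 for spatially random data, -> 1 for clustered data."""
    rng = np.random.default_rng(seed)
    n = len(X)
    m = max(1, int(round(sample_fraction * n)))
    idx = rng.choice(n, size=m, replace=False)
    lo, hi = X.min(axis=0), X.max(axis=0)
    U = rng.uniform(lo, hi, size=(m, X.shape[1]))
    du = cdist(U, X).min(axis=1)
    dw = np.empty(m)
    for j, i in enumerate(idx):
        d = np.linalg.norm(X - X[i], axis=1)
        d[i] = np.inf
        dw[j] = d.min()
    denom = du.sum() + dw.sum()
    return float(du.sum() / denom) if denom > 0 else 0.5


def dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    """min inter-cluster point distance / max intra-cluster diameter.

    Singleton clusters have diameter 0; if every cluster is a singleton the
    index is infinite by convention.
    """
    clusters = [X[labels == c] for c in np.unique(labels)]
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    inter = min(
        cdist(a, b).min()
        for a, b in itertools.combinations(clusters, 2)
    )
    diameters = [pdist(c).max() if len(c) > 1 else 0.0 for c in clusters]
    max_diam = max(diameters)
    if max_diam == 0:
        return float("inf") if inter > 0 else 0.0
    return float(inter / max_diam)


def _best_match_jaccard(orig_sets, new_sets) -> float:
    vals = []
    for a in orig_sets:
        if not a:
            continue
        best = 0.0
        for b in new_sets:
            if not b:
                continue
            inter = len(a & b)
            union = len(a | b)
            if union:
                best = max(best, inter / union)
        vals.append(best)
    return float(np.mean(vals)) if vals else 0.0


def jaccard_bootstrap(X: np.ndarray, solution: ClusterSolution,
                      n_bootstrap: int = 100, seed: int = 0) -> float:
    """Mean best-match Jaccard similarity between original clusters and
    clusters re-derived on bootstrap resamples (cluster stability)."""
    rng = np.random.default_rng(seed)
    n = len(X)
    scores = []
    for b in range(n_bootstrap):
        take = np.unique(rng.integers(0, n, size=n))
        if len(take) <= solution.k:
            continue
        lab_b = solution.refit(X[take], seed=seed + b + 1)
        orig_sets = [
            set(take[solution.labels[take] == c])
            for c in np.unique(solution.labels[take])
        ]
        new_sets = [set(take[lab_b == c]) for c in np.unique(lab_b)]
        scores.append(_best_match_jaccard(orig_sets, new_sets))
    return float(np.mean(scores)) if scores else 0.0


def quality(X: np.ndarray, solution: ClusterSolution, n_bootstrap: int = 100,
            seed: int = 0) -> QualityReport:
    return QualityReport(
        hopkins=hopkins_statistic(X, seed=seed),
        dunn=min(dunn_index(X, solution.labels), np.finfo(float).max),
        jaccard_bootstrap=jaccard_bootstrap(X, solution, n_bootstrap, seed),
    )


def select_best(solutions, reports) -> ClusterSolution:
    """Rank candidate solutions lexicographically on (jaccard bootstrap,
    hopkins, dunn), each rounded to 2 decimals; deterministic first-wins
    tie-break in input order."""
    if not solutions:
        raise ValueError("no solutions to select from")
    best_i, best_key = 0, None
    for i, (sol, rep) in enumerate(zip(solutions, reports)):
        key = (round(rep.jaccard_bootstrap, 2), round(rep.hopkins, 2),
               round(rep.dunn, 2))
        if best_key is None or key > best_key:
            best_i, best_key = i, key
    return solutions[best_i]


def intercluster_distances(X: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Euclidean distances between cluster centroids."""
    cs = np.unique(labels)
    if len(cs) < 2:
        raise ValueError("need at least 2 clusters")
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in cs])
    d = cdist(centroids, centroids)
    return pd.DataFrame(d, index=cs, columns=cs)


# ---------------------------------------------------------------------------
# characterization
# ---------------------------------------------------------------------------

CONTINUOUS_VARS = ("age", "height_cm", "weight_kg", "bmi")


def characterize_clusters(labels: np.ndarray, patient_rows: pd.DataFrame,
                          arms: pd.Series) -> pd.DataFrame:
    """Per-cluster demographic characterization against the rest.

    ``patient_rows`` has one row per patient-arm model (covariates repeated
    across arms) with the patient-table columns.  Continuous variables use a
    cluster-vs-rest two-sided t-test, sex a chi-squared contingency test,
    comorbidity tags Fisher's exact test; all p-values are BH-adjusted across
    the table.  Arm incidence per cluster is reported without a test.
    """
    labels = np.asarray(labels)
    if len(labels) != len(patient_rows):
        raise ValueError("labels must align with patient rows")
    arms = arms.reset_index(drop=True)
    pr = patient_rows.reset_index(drop=True)
    tags = sorted({
        t for s in pr["comorbidities"] for t in str(s).split(";") if t and t != "nan"
    })
    rows = []
    for c in np.unique(labels):
        mask = labels == c
        if mask.sum() == 0:
            warnings.warn(f"cluster {c} is empty; excluded")
            continue
        rest = ~mask
        for var in CONTINUOUS_VARS:
            x, yv = pr.loc[mask, var], pr.loc[rest, var]
            if rest.sum() and x.std(ddof=1) + yv.std(ddof=1) > 0:
                t, p = stats.ttest_ind(x, yv, equal_var=False)
            else:
                t, p = np.nan, np.nan
            rows.append({"cluster": int(c), "variable": var, "kind": "continuous",
                         "value": float(x.mean()), "sd": float(x.std(ddof=1)),
                         "statistic": float(t), "p_value": float(p),
                         "test": "t-test"})
        n_m = int((pr.loc[mask, "sex"] == "male").sum())
        n_f = int((pr.loc[mask, "sex"] == "female").sum())
        table = np.array([
            [n_m, n_f],
            [int((pr.loc[rest, "sex"] == "male").sum()),
             int((pr.loc[rest, "sex"] == "female").sum())],
        ])
        if table.sum(axis=0).min() > 0 and rest.sum():
            chi2, p, _, _ = stats.chi2_contingency(table)
        else:
            chi2, p = np.nan, np.nan
        rows.append({"cluster": int(c), "variable": "sex", "kind": "categorical",
                     "value": n_m / max(n_f, 1), "sd": np.nan,
                     "statistic": float(chi2), "p_value": float(p),
                     "test": "chi-squared", "detail": f"{n_m}:{n_f}"})
        for tag in tags:
            has = pr["comorbidities"].astype(str).str.split(";").apply(lambda s: tag in s)
            t2 = np.array([
                [int((has & mask).sum()), int((~has & mask).sum())],
                [int((has & rest).sum()), int((~has & rest).sum())],
            ])
            _, p = stats.fisher_exact(t2)
            rows.append({"cluster": int(c), "variable": tag, "kind": "comorbidity",
                         "value": float(has[mask].mean()), "sd": np.nan,
                         "statistic": np.nan, "p_value": float(p),
                         "test": "fisher-exact"})
        for arm in sorted(arms.unique()):
            rows.append({"cluster": int(c), "variable": f"arm_{arm}",
                         "kind": "arm", "value": float((arms[mask] == arm).mean()),
                         "sd": np.nan, "statistic": np.nan, "p_value": np.nan,
                         "test": "none"})
    out = pd.DataFrame(rows)
    tested = out["p_value"].notna()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = multipletests(out.loc[tested, "p_value"],
                                             method="fdr_bh")[1]
    out["q_value"] = q
    return out


def differential_proteins(values: pd.DataFrame, labels: np.ndarray,
                          mean_threshold: float = 0.1,
                          q_threshold: float = 1e-4) -> pd.DataFrame:
    """Per-cluster UP/DOWN protein screen.

    A protein marks a cluster when its cluster mean differs from the overall
    mean by more than ``mean_threshold`` AND the cluster-vs-rest Wilcoxon
    rank-sum test survives BH correction at ``q_threshold``.
    """
    labels = np.asarray(labels)
    overall = values.mean(axis=0)
    recs = []
    for c in np.unique(labels):
        mask = labels == c
        sub, rest = values.loc[mask], values.loc[~mask]
        diffs = sub.mean(axis=0) - overall
        for prot in values.columns:
            x, yv = sub[prot].to_numpy(), rest[prot].to_numpy()
            if np.ptp(np.concatenate([x, yv])) == 0:
                p = 1.0
            else:
                p = float(stats.ranksums(x, yv).pvalue)
            recs.append({"cluster": int(c), "protein": prot,
                         "mean_diff": float(diffs[prot]), "p_value": p})
    out = pd.DataFrame(recs)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["selected"] = (out["mean_diff"].abs() > mean_threshold) & \
        (out["q_value"] < q_threshold)
    out["direction"] = np.where(out["mean_diff"] > 0, "UP", "DOWN")
    return out


# ---------------------------------------------------------------------------
# single-feature classifier screen
# ---------------------------------------------------------------------------

def _threshold_classifier_fit(x: np.ndarray, y: np.ndarray):
    """Best (threshold, direction) by training balanced accuracy for the rule
    'predict 1 when x > threshold' (direction=+1) or its flip."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n1 = max(int((y == 1).sum()), 1)
    n0 = max(int((y == 0).sum()), 1)
    cum1 = np.concatenate([[0], np.cumsum(ys == 1)])
    cum0 = np.concatenate([[0], np.cumsum(ys == 0)])
    # cut i: left = first i samples; predicting 1 on the right side
    sens = (n1 - cum1) / n1
    spec = cum0 / n0
    bacc = (sens + spec) / 2.0
    best, thr, direction = -1.0, 0.0, 1
    for i in range(len(bacc)):
        b = bacc[i]
        if i == 0:
            t = xs[0] - 1.0
        elif i == len(xs):
            t = xs[-1] + 1.0
        else:
            t = 0.5 * (xs[i - 1] + xs[i])
        for b_dir, d in ((b, 1), (1.0 - b, -1)):
            if b_dir > best:
                best, thr, direction = float(b_dir), float(t), d
    return thr, direction


def _threshold_classifier_bacc(x_tr, y_tr, x_te, y_te) -> float:
    thr, direction = _threshold_classifier_fit(x_tr, y_tr)
    pred = (x_te > thr).astype(int) if direction == 1 else (x_te <= thr).astype(int)
    n1, n0 = max((y_te == 1).sum(), 1), max((y_te == 0).sum(), 1)
    sens = ((pred == 1) & (y_te == 1)).sum() / n1
    spec = ((pred == 0) & (y_te == 0)).sum() / n0
    return float((sens + spec) / 2.0)


def _cv_bacc(x: np.ndarray, y: np.ndarray, k_folds: int, seed: int) -> float:
    n_min = min(int((y == 1).sum()), int((y == 0).sum()))
    k = min(k_folds, n_min)
    if k < 2:
        return float("nan")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = [
        _threshold_classifier_bacc(x[tr], y[tr], x[te], y[te])
        for tr, te in cv.split(x.reshape(-1, 1), y)
    ]
    return float(np.mean(scores))


def classifier_proteins(values: pd.DataFrame, labels: np.ndarray,
                        k_folds: int = 10, bacc_threshold: float = 0.8,
                        n_permutations: int = 200, seed: int = 0) -> pd.DataFrame:
    """Single-feature cluster-pair classifier screen.

    For every protein and cluster pair, a threshold classifier on that
    protein alone is scored by stratified k-fold cross-validated balanced
    accuracy (BACC).  Pairs with BACC above the threshold get a
    cross-validated permutation p-value (labels shuffled, CV repeated).
    """
    labels = np.asarray(labels)
    cs = np.unique(labels)
    if len(cs) < 2:
        raise ValueError("need at least 2 clusters")
    rng = np.random.default_rng(seed)
    recs = []
    for ca, cb in itertools.combinations(cs, 2):
        mask = (labels == ca) | (labels == cb)
        y = (labels[mask] == cb).astype(int)
        n_min = min(int((y == 1).sum()), int((y == 0).sum()))
        if n_min < k_folds:
            warnings.warn(
                f"cluster pair ({ca}, {cb}): smallest class has {n_min} "
                f"members, folds reduced to {min(k_folds, n_min)}"
            )
        block = values.loc[mask]
        for prot in values.columns:
            x = block[prot].to_numpy(dtype=float)
            bacc = _cv_bacc(x, y, k_folds, seed)
            p_perm = np.nan
            if np.isfinite(bacc) and bacc > bacc_threshold and n_permutations > 0:
                null = np.empty(n_permutations)
                for b in range(n_permutations):
                    null[b] = _cv_bacc(x, rng.permutation(y), k_folds, seed + b + 1)
                p_perm = (1.0 + float((null >= bacc).sum())) / (n_permutations + 1.0)
            recs.append({"protein": prot, "cluster_a": int(ca), "cluster_b": int(cb),
                         "bacc": bacc, "p_permutation": p_perm,
                         "passes": bool(np.isfinite(bacc) and bacc > bacc_threshold)})
    return pd.DataFrame(recs)
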