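import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import rand_score

from psorqsp import cluster
from psorqsp.cluster import ClusterConfig, QualityReport


def _frame(X, prefix="p"):
    return pd.DataFrame(X, columns=[f"{prefix}{j}" for j in range(X.shape[1])])


# ---------------------------------------------------------------------------
# normalization & reduction
# ---------------------------------------------------------------------------

def test_per_arm_centering_zeroes_means_and_keeps_variance():
    rng = np.random.default_rng(0)
    values = _frame(rng.uniform(-1, 1, (40, 6)))
    arms = pd.Series(["a"] * 25 + ["b"] * 15, index=values.index)
    centered = cluster.normalize_by_arm(values, arms)
    for arm in ("a", "b"):
        block = centered[arms == arm]
        assert np.all(np.abs(block.mean(axis=0)) < 1e-12)
        raw = values[arms == arm]
        assert np.allclose(block.var(axis=0), raw.var(axis=0))


def test_single_arm_centering_equals_global_centering():
    rng = np.random.default_rng(1)
    values = _frame(rng.normal(size=(20, 4)))
    arms = pd.Series(["only"] * 20, index=values.index)
    centered = cluster.normalize_by_arm(values, arms)
    assert np.allclose(centered, values - values.mean(axis=0))


def test_pca_on_rank_two_data_explains_everything():
    rng = np.random.default_rng(2)
    basis = rng.normal(size=(2, 8))
    X = rng.normal(size=(30, 2)) @ basis
    emb, ratio = cluster.reduce_dimensions(_frame(X), ClusterConfig(
        reduction="pca", dims=2, distance="euclidean"))
    assert emb.shape == (30, 2)
    assert ratio.sum() == pytest.approx(1.0, abs=1e-9)


def test_classical_mds_recovers_planar_configuration():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(25, 2))
    d = squareform(pdist(pts))
    emb, _ = cluster.classical_mds(d, 2)
    a = pts - pts.mean(axis=0)
    b = emb - emb.mean(axis=0)
    R, _ = orthogonal_procrustes(b, a)
    assert np.max(np.abs(b @ R - a)) < 1e-6


def test_mds_five_dims_spearman_is_accepted():
    rng = np.random.default_rng(4)
    values = _frame(rng.uniform(-1, 1, (12, 9)))
    emb, _ = cluster.reduce_dimensions(values, ClusterConfig(
        reduction="mds", dims=5, distance="spearman"))
    assert emb.shape == (12, 5)


def test_spearman_distance_rejects_constant_rows():
    X = np.ones((5, 4))
    with pytest.raises(ValueError, match="constant"):
        cluster.spearman_distance(X)


def test_config_validation():
    with pytest.raises(ValueError):
        ClusterConfig(reduction="pca", distance="spearman")
    with pytest.raises(ValueError):
        ClusterConfig(dims=4)
    with pytest.raises(ValueError):
        ClusterConfig(k_range=(1, 4))


# ---------------------------------------------------------------------------
# grid & index-based k selection
# ---------------------------------------------------------------------------

def _blobs(seed=0, n_per=20, sep=10.0, d=2, k=3):
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=sep, size=(k, d))
    X = np.vstack([c + rng.normal(size=(n_per, d)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return X, labels


@pytest.mark.parametrize("algorithm", cluster.ALGORITHMS)
def test_silhouette_selects_three_for_separated_blobs(algorithm):
    X, truth = _blobs(seed=5, sep=10.0)
    cfg = ClusterConfig(reduction="pca", dims=2, distance="euclidean",
                        algorithm=algorithm, k_range=(2, 5))
    sol = cluster.cluster_grid(_frame(X), [cfg], seed=1, gap_references=5)[0]
    assert sol.k == 3
    assert rand_score(truth, sol.labels) > 0.99


def test_selected_k_is_always_silhouettes_choice():
    X, _ = _blobs(seed=6, sep=3.0)
    cfg = ClusterConfig(reduction="pca", dims=2, distance="euclidean",
                        algorithm="kmeans", k_range=(2, 6))
    sol = cluster.cluster_grid(_frame(X), [cfg], seed=2, gap_references=5)[0]
    assert sol.k == sol.best_k["silhouette"]
    assert set(sol.best_k) == {"silhouette", "calinski_harabasz",
                               "davies_bouldin", "gap"}
    assert sol.index_table.index.min() == 2  # k=1 never considered


def test_indices_match_textbook_recomputation():
    """Silhouette, Calinski-Harabasz and Davies-Bouldin against direct
    formula implementations on random 50-point data, to 1e-9."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(50, 3))
    labels = rng.integers(1, 4, size=50)
    D = cdist(X, X)
    # silhouette
    sil = []
    for i in range(50):
        same = (labels == labels[i]) & (np.arange(50) != i)
        a = D[i, same].mean() if same.any() else 0.0
        b = min(D[i, labels == c].mean() for c in np.unique(labels)
                if c != labels[i])
        sil.append(0.0 if not same.any() else (b - a) / max(a, b))
    from sklearn.metrics import (
        calinski_harabasz_score,
        davies_bouldin_score,
        silhouette_score,
    )
    assert silhouette_score(X, labels) == pytest.approx(np.mean(sil), abs=1e-9)
    # calinski-harabasz
    overall = X.mean(axis=0)
    ks = np.unique(labels)
    bg = sum((labels == c).sum() * np.sum((X[labels == c].mean(0) - overall) ** 2)
             for c in ks)
    wg = sum(np.sum((X[labels == c] - X[labels == c].mean(0)) ** 2) for c in ks)
    ch = (bg / (len(ks) - 1)) / (wg / (50 - len(ks)))
    assert calinski_harabasz_score(X, labels) == pytest.approx(ch, abs=1e-9)
    # davies-bouldin
    cents = {c: X[labels == c].mean(0) for c in ks}
    scat = {c: np.mean(np.linalg.norm(X[labels == c] - cents[c], axis=1)) for c in ks}
    db = np.mean([
        max((scat[a] + scat[b]) / np.linalg.norm(cents[a] - cents[b])
            for b in ks if b != a)
        for a in ks
    ])
    assert davies_bouldin_score(X, labels) == pytest.approx(db, abs=1e-9)


# ---------------------------------------------------------------------------
# quality indicators
# ---------------------------------------------------------------------------

def test_hopkins_near_half_for_uniform_noise():
    vals = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, (200, 2))
        # statistic seeded independently of the data stream
        vals.append(cluster.hopkins_statistic(X, seed=1000 + seed))
    assert abs(np.mean(vals) - 0.5) < 0.1
    assert all(0.0 <= v <= 1.0 for v in vals)


def test_hopkins_high_for_clustered_data():
    X, _ = _blobs(seed=8, sep=20.0)
    assert cluster.hopkins_statistic(X, seed=1) > 0.7


def test_dunn_index_hand_cases():
    X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
    labels = np.array([1, 1, 2, 2])
    # min inter-cluster point distance 10, max intra-cluster diameter 1
    assert cluster.dunn_index(X, labels) == pytest.approx(10.0)
    singletons = np.array([1, 2, 3, 4])
    assert cluster.dunn_index(X, singletons) == np.inf


def test_two_tight_blobs_are_stable_and_compact():
    X, truth = _blobs(seed=9, n_per=30, sep=50.0, k=2)
    cfg = ClusterConfig(reduction="pca", dims=2, distance="euclidean",
                        algorithm="kmeans", k_range=(2, 4))
    sol = cluster.cluster_grid(_frame(X), [cfg], seed=3, gap_references=5)[0]
    rep = cluster.quality(sol.embedding, sol, n_bootstrap=30, seed=4)
    assert rep.jaccard_bootstrap > 0.95
    assert rep.dunn > 1.0
    assert set(rep.__dataclass_fields__) == {"hopkins", "dunn", "jaccard_bootstrap"}


def test_select_best_rules():
    X, _ = _blobs(seed=10)
    cfg = ClusterConfig(reduction="pca", dims=2, distance="euclidean",
                        algorithm="kmeans")
    sol = cluster.cluster_grid(_frame(X), [cfg], seed=1, gap_references=3)[0]
    only = cluster.select_best([sol], [QualityReport(0.5, 0.1, 0.5)])
    assert only is sol
    sols = [sol, sol, sol]
    reports = [QualityReport(0.6, 0.2, 0.7), QualityReport(0.9, 0.9, 0.9),
               QualityReport(0.7, 0.3, 0.8)]
    assert cluster.select_best(sols, reports) is sols[1]
    for perm in itertools.permutations(range(3)):
        chosen = cluster.select_best([sols[i] for i in perm],
                                     [reports[i] for i in perm])
        assert chosen is sol  # same object; dominance invariant to order


def test_intercluster_distances_three_four_five():
    X = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0], [3.0, 4.0]])
    labels = np.array([1, 1, 2, 2])
    d = cluster.intercluster_distances(X, labels)
    assert d.loc[1, 2] == pytest.approx(5.0)
    assert d.loc[2, 1] == pytest.approx(5.0)
    assert d.loc[1, 1] == 0.0
    # brute-force centroid recomputation
    rng = np.random.default_rng(11)
    X2 = rng.normal(size=(30, 3))
    lab2 = rng.integers(1, 4, 30)
    d2 = cluster.intercluster_distances(X2, lab2)
    for a in np.unique(lab2):
        for b in np.unique(lab2):
            expected = np.linalg.norm(X2[lab2 == a].mean(0) - X2[lab2 == b].mean(0))
            assert d2.loc[a, b] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# characterization & protein screens
# ---------------------------------------------------------------------------

def _patient_rows(n, rng, weight_shift=None, cluster_labels=None):
    rows = pd.DataFrame({
        "id": [f"P{i}" for i in range(n)],
        "sex": rng.choice(["male", "female"], n),
        "age": rng.normal(45, 12, n),
        "height_cm": rng.normal(172, 8, n),
        "weight_kg": rng.normal(90, 20, n),
        "bmi": rng.normal(30, 6, n),
        "comorbidities": rng.choice(["", "diabetes_t2"], n),
    })
    if weight_shift is not None and cluster_labels is not None:
        rows.loc[cluster_labels == 1, "weight_kg"] += weight_shift
    return rows


def test_characterization_false_positive_rate_under_the_null():
    """Identical covariate distributions across clusters: after BH at 0.05
    the fraction of rejected tests stays at or below 0.05 over 100 seeds."""
    rejections, tests = 0, 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        labels = rng.integers(1, 4, 60)
        rows = _patient_rows(60, rng)
        arms = pd.Series(rng.choice(["czp200", "czp400"], 60))
        out = cluster.characterize_clusters(labels, rows, arms)
        tested = out["q_value"].notna()
        rejections += int((out.loc[tested, "q_value"] < 0.05).sum())
        tests += int(tested.sum())
    assert rejections / tests <= 0.05


def test_characterization_detects_planted_weight_shift():
    rng = np.random.default_rng(5)
    labels = np.repeat([1, 2, 3], 60)
    rows = _patient_rows(180, rng, weight_shift=2 * 20.0, cluster_labels=labels)
    arms = pd.Series(["czp200"] * 180)
    out = cluster.characterize_clusters(labels, rows, arms)
    row = out[(out["cluster"] == 1) & (out["variable"] == "weight_kg")].iloc[0]
    assert row["q_value"] < 0.001


def test_characterization_reports_sex_ratio_detail():
    rng = np.random.default_rng(6)
    labels = np.repeat([1, 2], 30)
    rows = _patient_rows(60, rng)
    out = cluster.characterize_clusters(labels, rows, pd.Series(["a"] * 60))
    sex_rows = out[out["variable"] == "sex"]
    assert sex_rows["detail"].str.match(r"\d+:\d+").all()


def test_differential_protein_screen_thresholds():
    rng = np.random.default_rng(7)
    n_per = 300
    labels = np.repeat([1, 2], n_per)
    values = pd.DataFrame({
        "planted": rng.normal(0, 0.05, 2 * n_per),
        "constant": np.zeros(2 * n_per),
        "subthreshold": rng.normal(0, 0.02, 2 * n_per),
    })
    values.loc[labels == 1, "planted"] += 0.3
    values.loc[labels == 1, "subthreshold"] += 0.09  # tiny q but |diff| < 0.1
    out = cluster.differential_proteins(values, labels)
    planted = out[(out["cluster"] == 1) & (out["protein"] == "planted")].iloc[0]
    assert planted["selected"] and planted["direction"] == "UP"
    const = out[(out["cluster"] == 1) & (out["protein"] == "constant")].iloc[0]
    assert not const["selected"]
    sub = out[(out["cluster"] == 1) & (out["protein"] == "subthreshold")].iloc[0]
    assert sub["q_value"] < 1e-4 and not sub["selected"]


def test_classifier_bacc_chance_level_for_identical_distributions():
    rng = np.random.default_rng(8)
    labels = np.repeat([1, 2], 500)
    values = pd.DataFrame({"null": rng.normal(size=1000)})
    out = cluster.classifier_proteins(values, labels, n_permutations=0)
    assert abs(out.iloc[0]["bacc"] - 0.5) < 0.05
    assert not out.iloc[0]["passes"]


def test_classifier_bacc_one_for_disjoint_supports():
    labels = np.repeat([1, 2], 50)
    values = pd.DataFrame({"sep": np.concatenate([
        np.random.default_rng(9).uniform(0, 1, 50),
        np.random.default_rng(10).uniform(2, 3, 50),
    ])})
    out = cluster.classifier_proteins(values, labels, n_permutations=20)
    row = out.iloc[0]
    assert row["bacc"] == pytest.approx(1.0)
    assert row["passes"]
    assert row["p_permutation"] < 0.05


def test_label_permuted_feature_concentrates_at_chance():
    rng = np.random.default_rng(11)
    labels = np.repeat([0, 1], 250)
    x = rng.normal(size=500)
    baccs = [cluster._cv_bacc(x, rng.permutation(labels), 10, seed=b)
             for b in range(200)]
    assert abs(np.mean(baccs) - 0.5) < 0.02
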