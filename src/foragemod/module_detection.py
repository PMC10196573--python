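"""Behavioral-module discovery: partition, PCA, clustering, and validation.

The detection procedure mirrors a train/test reproducibility design:

1. Mice are split 50/50 into training and test partitions, stratified by
   genotype and sex, so every stratum contributes to both sides.
2. PCA is fit on the training excursions' scaled features; the number of
   retained components is the one (in a scan range) that maximizes the
   cluster count found by the hybrid dynamic tree cut on a Ward dendrogram,
   ties broken toward fewer components.
3. Cluster *existence* is tested against a column-permutation null: each
   iteration independently shuffles every feature column, re-runs
   PCA + clustering, and counts clusters; genuinely structured data yields
   far fewer clusters than the shuffled null (lower-tail p).
4. Cluster *reproducibility* is tested with the distance-based in-group
   proportion (IGP): test-partition excursions are assigned to the nearest
   training-cluster centroid, and IGP_c is the fraction of points assigned
   to c whose nearest test-partition neighbor is also assigned to c. The
   permutation null reassigns training points to clusters at random (sizes
   preserved), recomputes centroids, and re-evaluates IGP; q < 0.1 clusters
   are certified as modules.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .excursions import parse_cimar
from .features import FeatureMatrix
from .qvalue import qvalues
from .treecut import (CutParams, cut_tree_hybrid, merge_close_clusters,
                      pam_assign, ward_linkage)

__all__ = ["PartitionSpec", "PCModel", "ClusterAssignment",
           "ReproducibilityResult", "ModuleCatalog", "PartitionError",
           "balanced_partition", "select_principal_components",
           "cluster_and_cut", "null_cluster_count_test", "igp_statistic",
           "igp_permutation_test", "build_module_catalog", "detect_modules"]


class PartitionError(ValueError):
    pass


@dataclass
class PartitionSpec:
    train_mice: tuple[int, ...]
    test_mice: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.train_mice) & set(self.test_mice):
            raise PartitionError("train and test mice overlap")


def balanced_partition(manifest: pd.DataFrame, seed: int) -> PartitionSpec:
    """Mouse-level 50/50 split stratified by genotype x sex.

    ``manifest`` needs columns mouse_id, sex, genotype (mouse_id integer
    or integer-like). Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    mice = manifest.drop_duplicates("mouse_id")
    train: list[int] = []
    test: list[int] = []
    for _, grp in mice.groupby(["genotype", "sex"], sort=True):
        ids = sorted(int(m) for m in grp["mouse_id"])
        if len(ids) < 2:
            raise PartitionError("each genotype x sex stratum needs >= 2 mice")
        perm = rng.permutation(len(ids))
        half = len(ids) // 2
        extra = rng.integers(0, 2) if len(ids) % 2 else 0
        cut = half + extra
        train += [ids[i] for i in perm[:cut]]
        test += [ids[i] for i in perm[cut:]]
    return PartitionSpec(tuple(sorted(train)), tuple(sorted(test)))


@dataclass
class PCModel:
    loadings: np.ndarray          # k x p
    mean: np.ndarray              # p
    k: int
    explained_variance: np.ndarray
    scan: dict[int, int] = field(default_factory=dict)  # k -> cluster count

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.loadings.T


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-excursion integer label, 0 = unassigned

    @property
    def cluster_ids(self) -> list[int]:
        return [int(k) for k in np.unique(self.labels) if k != 0]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def sizes(self) -> dict[int, int]:
        return {k: int((self.labels == k).sum()) for k in self.cluster_ids}


@dataclass
class ReproducibilityResult:
    cluster_ids: list[int]
    igp: dict[int, float]
    n_test_points: dict[int, int]
    p: dict[int, float]
    q: dict[int, float]
    pi0: float
    q_threshold: float = 0.1

    def is_module(self, cluster_id: int) -> bool:
        q = self.q.get(cluster_id)
        return q is not None and np.isfinite(q) and q < self.q_threshold

    @property
    def module_ids(self) -> list[int]:
        return [c for c in self.cluster_ids if self.is_module(c)]


def _count_clusters(X: np.ndarray, k: int, cut: CutParams) -> int:
    pca = PCA(n_components=k, svd_solver="full").fit(X)
    scores = pca.transform(X)
    labels = cut_tree_hybrid(ward_linkage(scores), cut)
    return len([c for c in np.unique(labels) if c != 0])


def select_principal_components(train: FeatureMatrix | np.ndarray,
                                k_range: range | list[int] = range(2, 13),
                                cut_params: CutParams | None = None) -> PCModel:
    """Retain the component count that maximizes tree-cut cluster detection.

    Ties break toward fewer components.
    """
    X = train.values if isinstance(train, FeatureMatrix) else np.asarray(train, float)
    cut = cut_params or CutParams()
    ks = sorted(int(k) for k in k_range)
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if ks[-1] > max_rank:
        raise ValueError(f"k_range exceeds data rank ({max_rank})")
    scan: dict[int, int] = {}
    for k in ks:
        scan[k] = _count_clusters(X, k, cut)
    best_k = max(ks, key=lambda k: (scan[k], -k))
    pca = PCA(n_components=best_k, svd_solver="full").fit(X)
    return PCModel(loadings=pca.components_.copy(), mean=pca.mean_.copy(),
                   k=best_k, explained_variance=pca.explained_variance_.copy(),
                   scan=scan)


def cluster_and_cut(scores: np.ndarray, cut_params: CutParams | None = None,
                    consolidate: bool = True) -> ClusterAssignment:
    """Ward.D2 clustering of PC scores cut by the hybrid dynamic tree cut.

    With ``consolidate`` the raw cut's adjacent fragments of one compact
    cluster are fused (no density valley between them) before the PAM-like
    reassignment of unassigned points. The cluster-existence null test
    deliberately uses the raw, unconsolidated cut (see
    :func:`null_cluster_count_test`).
    """
    cut = cut_params or CutParams()
    scores = np.asarray(scores, float)
    if scores.shape[0] < cut.min_cluster_size:
        warnings.warn("fewer points than min_cluster_size: single cluster")
        return ClusterAssignment(np.ones(scores.shape[0], dtype=int))
    labels = cut_tree_hybrid(ward_linkage(scores), cut)
    if consolidate:
        labels = merge_close_clusters(scores, labels)
        labels = _relabel_consecutive(labels)
    if cut.pam_stage:
        labels = pam_assign(scores, labels)
    return ClusterAssignment(labels)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels)
    for new, old in enumerate(sorted(set(labels) - {0}), start=1):
        out[labels == old] = new
    return out


def null_cluster_count_test(train: FeatureMatrix | np.ndarray, k: int,
                            iterations: int = 10_000, seed: int = 0,
                            cut_params: CutParams | None = None
                            ) -> tuple[int, np.ndarray, float]:
    """Observed cluster count vs a column-shuffled null; lower-tail p.

    Each iteration independently permutes every feature column (breaking
    excursion-measure relationships), reruns PCA + clustering, and counts
    clusters. The lower-tail p is the observed count's exchangeable rank
    among the null counts, with ties broken uniformly at random — the
    count statistic is discrete, and random tie-breaking is what makes
    the p-value exactly uniform when the input itself carries no
    structure; p >= 1/(iterations+1) always.
    """
    if iterations < 100:
        warnings.warn("fewer than 100 null iterations: p will be coarse")
    X = train.values if isinstance(train, FeatureMatrix) else np.asarray(train, float)
    cut = cut_params or CutParams()
    rng = np.random.default_rng(seed)
    observed = _count_clusters(X, k, cut)
    null = np.empty(iterations, dtype=int)
    Xp = X.copy()
    for it in range(iterations):
        for j in range(Xp.shape[1]):
            rng.shuffle(Xp[:, j])
        null[it] = _count_clusters(Xp, k, cut)
    below = int((null < observed).sum())
    ties = int((null == observed).sum())
    p = (1 + below + int(rng.integers(0, ties + 1))) / (1 + iterations)
    return observed, null, float(p)


def _igp(test_scores: np.ndarray, centroids: np.ndarray,
         nn_index: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-centroid IGP values and the assignment vector."""
    d = ((test_scores[:, None, :] - centroids[None]) ** 2).sum(-1)
    assign = d.argmin(axis=1)
    nn_lab = assign[nn_index]
    igp = np.full(len(centroids), np.nan)
    for c in range(len(centroids)):
        m = assign == c
        if m.any():
            igp[c] = float((nn_lab[m] == c).mean())
    return igp, assign


def igp_statistic(test_scores: np.ndarray, centroids: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Distance IGP: test points go to the nearest training centroid; the
    IGP of a cluster is the fraction of its points whose nearest test-set
    neighbor lands in the same cluster. Returns (igp, assignment);
    clusters attracting no test points have IGP NaN (flagged undefined).
    """
    test_scores = np.asarray(test_scores, float)
    nn = NearestNeighbors(n_neighbors=2).fit(test_scores)
    _, idx = nn.kneighbors(test_scores)
    return _igp(test_scores, np.asarray(centroids, float), idx[:, 1])


def igp_permutation_test(train_scores: np.ndarray, train_labels: np.ndarray,
                         test_scores: np.ndarray, n_perm: int = 10_000,
                         seed: int = 0, q_threshold: float = 0.1
                         ) -> ReproducibilityResult:
    """Certify reproducible clusters via a structure-randomizing null.

    Each permutation independently shuffles every column of the test
    scores — destroying any cluster structure while preserving the
    marginal distributions — and recomputes every cluster's IGP against
    the original training centroids. A cluster's p-value is the +1
    smoothed fraction of null IGPs at least as large as the observed one.
    q-values use the pi0-estimating FDR method; clusters with
    q < ``q_threshold`` are modules.
    """
    train_scores = np.asarray(train_scores, float)
    test_scores = np.asarray(test_scores, float)
    labels = np.asarray(train_labels)
    ids = [int(k) for k in np.unique(labels) if k != 0]
    if len(ids) < 2:
        raise ValueError("need >= 2 clusters for the reproducibility test")
    rng = np.random.default_rng(seed)
    centroids = np.array([train_scores[labels == k].mean(axis=0) for k in ids])

    nn = NearestNeighbors(n_neighbors=2).fit(test_scores)
    _, idx = nn.kneighbors(test_scores)
    nn_index = idx[:, 1]
    obs_igp, assign = _igp(test_scores, centroids, nn_index)
    n_assigned = {c: int((assign == j).sum()) for j, c in enumerate(ids)}

    null = np.full((n_perm, len(ids)), np.nan)
    tp = test_scores.copy()
    for it in range(n_perm):
        for j in range(tp.shape[1]):
            rng.shuffle(tp[:, j])
        nn_p = NearestNeighbors(n_neighbors=2).fit(tp)
        _, idx_p = nn_p.kneighbors(tp)
        null[it], _ = _igp(tp, centroids, idx_p[:, 1])

    p: dict[int, float] = {}
    for j, c in enumerate(ids):
        o = obs_igp[j]
        if not np.isfinite(o):
            p[c] = np.nan
            continue
        nj = null[:, j]
        nj = nj[np.isfinite(nj)]
        p[c] = (1 + int((nj >= o).sum())) / (1 + nj.size)
    defined = [c for c in ids if np.isfinite(p[c])]
    if defined:
        qv, pi0 = qvalues(np.array([p[c] for c in defined]))
        q = {c: float(v) for c, v in zip(defined, qv)}
    else:
        q, pi0 = {}, 1.0
    for c in ids:
        q.setdefault(c, np.nan)
    return ReproducibilityResult(
        cluster_ids=ids,
        igp={c: float(obs_igp[j]) for j, c in enumerate(ids)},
        n_test_points=n_assigned,
        p=p, q=q, pi0=pi0, q_threshold=q_threshold,
    )


@dataclass
class ModuleCatalog:
    """Validated modules plus per-excursion labels.

    ``labels`` maps CIMAR -> string label: ``"M<k>"`` for module k,
    ``"C<k>"`` for a non-modular cluster, ``"0"`` for unassigned.
    """

    module_ids: list[int]
    centroids: dict[int, list[float]]  # PC-space centroids per training cluster
    repro: ReproducibilityResult
    labels: dict[str, str]
    pc_k: int
    catalog_version: str = "fm57-1"

    def module_members(self, module_id: int) -> list[str]:
        tag = f"M{module_id}"
        return [c for c, l in self.labels.items() if l == tag]

    def label_array(self, cimars: list[str], modules_only: bool = True) -> np.ndarray:
        """Integer labels aligned to ``cimars``; non-module labels -> 0."""
        out = np.zeros(len(cimars), dtype=int)
        for i, c in enumerate(cimars):
            l = self.labels.get(c, "0")
            if l.startswith("M"):
                out[i] = int(l[1:])
            elif not modules_only and l.startswith("C"):
                out[i] = -int(l[1:])
        return out

    def to_json(self, path: str | Path) -> None:
        d = {
            "catalog_version": self.catalog_version,
            "pc_k": self.pc_k,
            "module_ids": self.module_ids,
            "pi0": self.repro.pi0,
            "clusters": [
                {
                    "id": c,
                    "igp": self.repro.igp[c],
                    "p": self.repro.p[c],
                    "q": self.repro.q[c],
                    "n_test_points": self.repro.n_test_points.get(c, 0),
                    "is_module": self.repro.is_module(c),
                    "centroid": self.centroids[c],
                }
                for c in self.repro.cluster_ids
            ],
            "labels": self.labels,
        }
        Path(path).write_text(json.dumps(d, indent=2, allow_nan=True))

    def labels_csv(self, path: str | Path) -> None:
        pd.DataFrame({"cimar": list(self.labels), "label": list(self.labels.values())}
                     ).to_csv(path, index=False)


def build_module_catalog(train_cimars: list[str], train_labels: np.ndarray,
                         test_cimars: list[str], test_assign_ids: np.ndarray,
                         repro: ReproducibilityResult, centroids: dict[int, np.ndarray],
                         pc_k: int) -> ModuleCatalog:
    """Label every excursion with a module id, non-modular cluster id, or 0."""
    for c in set(int(k) for k in np.unique(train_labels) if k != 0):
        if c not in repro.p:
            raise ValueError(f"reproducibility result missing cluster {c}")
    labels: dict[str, str] = {}
    for cimar, lab in zip(train_cimars, train_labels):
        lab = int(lab)
        if lab == 0:
            labels[cimar] = "0"
        elif repro.is_module(lab):
            labels[cimar] = f"M{lab}"
        else:
            labels[cimar] = f"C{lab}"
    for cimar, lab in zip(test_cimars, test_assign_ids):
        lab = int(lab)
        if lab == 0:
            labels[cimar] = "0"
        elif repro.is_module(lab):
            labels[cimar] = f"M{lab}"
        else:
            labels[cimar] = f"C{lab}"
    return ModuleCatalog(
        module_ids=repro.module_ids,
        centroids={c: list(map(float, centroids[c])) for c in centroids},
        repro=repro,
        labels=labels,
        pc_k=pc_k,
    )


def detect_modules(matrix: FeatureMatrix, manifest: pd.DataFrame, seed: int = 0,
                   k_range: range | list[int] = range(2, 13),
                   cut_params: CutParams | None = None,
                   n_perm: int = 10_000, q_threshold: float = 0.1
                   ) -> tuple[ModuleCatalog, PCModel, PartitionSpec]:
    """End-to-end module detection on a scaled feature matrix."""
    cut = cut_params or CutParams()
    part = balanced_partition(manifest, seed)
    mouse_of = np.array([parse_cimar(c).mouse_number for c in matrix.cimars])
    in_train = np.isin(mouse_of, part.train_mice)
    cimars = np.array(matrix.cimars)
    X = matrix.values
    Xtr, Xte = X[in_train], X[~in_train]
    tr_cimars = list(cimars[in_train])
    te_cimars = list(cimars[~in_train])
    if len(Xtr) < 2 * cut.min_cluster_size or len(Xte) < 2:
        raise ValueError("not enough excursions in a partition")

    pcm = select_principal_components(Xtr, k_range=k_range, cut_params=cut)
    tr_scores = pcm.transform(Xtr)
    te_scores = pcm.transform(Xte)
    assignment = cluster_and_cut(tr_scores, cut)
    repro = igp_permutation_test(tr_scores, assignment.labels, te_scores,
                                 n_perm=n_perm, seed=seed + 1,
                                 q_threshold=q_threshold)
    ids = repro.cluster_ids
    centroids = {c: tr_scores[assignment.labels == c].mean(axis=0) for c in ids}
    cents_arr = np.array([centroids[c] for c in ids])
    d = ((te_scores[:, None, :] - cents_arr[None]) ** 2).sum(-1)
    te_assign = np.array([ids[j] for j in d.argmin(axis=1)])
    catalog = build_module_catalog(tr_cimars, assignment.labels, te_cimars,
                                   te_assign, repro, centroids, pcm.k)
    return catalog, pcm, part
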