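"""Partitioning, PC selection, IGP statistics and module certification."""

import numpy as np
import pandas as pd
import pytest

from foragemod.module_detection import (PartitionError, balanced_partition,
                                        build_module_catalog, cluster_and_cut,
                                        igp_permutation_test, igp_statistic,
                                        select_principal_components)
from foragemod.treecut import CutParams


def manifest_of(n_per_stratum=15):
    rows = []
    mid = 0
    for geno in ("WT", "KO"):
        for sex in ("M", "F"):
            for _ in range(n_per_stratum):
                mid += 1
                for phase in ("Exploration", "Foraging"):
                    rows.append({"mouse_id": mid, "sex": sex,
                                 "genotype": geno, "phase": phase})
    return pd.DataFrame(rows)


class TestPartition:
    def test_sixty_mice_split_eight_seven_per_stratum(self):
        man = manifest_of(15)
        part = balanced_partition(man, seed=0)
        assert len(part.train_mice) + len(part.test_mice) == 60
        for geno in ("WT", "KO"):
            for sex in ("M", "F"):
                ids = set(man[(man.genotype == geno) & (man.sex == sex)]
                          ["mouse_id"])
                n_tr = len(ids & set(part.train_mice))
                assert n_tr in (7, 8)

    def test_disjoint(self):
        part = balanced_partition(manifest_of(), seed=3)
        assert not set(part.train_mice) & set(part.test_mice)

    def test_deterministic_given_seed(self):
        man = manifest_of()
        assert balanced_partition(man, 5) == balanced_partition(man, 5)
        assert balanced_partition(man, 5) != balanced_partition(man, 6)

    def test_empty_stratum_is_error(self):
        man = manifest_of().query("genotype != 'KO' or sex != 'F'")
        man = pd.concat([man, pd.DataFrame([{"mouse_id": 999, "sex": "F",
                                             "genotype": "KO",
                                             "phase": "Foraging"}])])
        with pytest.raises(PartitionError):
            balanced_partition(man, 0)


class TestPCSelection:
    def test_recovers_planted_structure_and_matches_exhaustive_scan(self,
                                                                    blob_data):
        X, truth = blob_data
        pcm = select_principal_components(X, k_range=range(2, 7))
        # oracle: independent exhaustive scan over the same range
        from sklearn.decomposition import PCA
        from foragemod.treecut import cut_tree_hybrid, ward_linkage
        counts = {}
        for k in range(2, 7):
            s = PCA(n_components=k, svd_solver="full").fit_transform(X)
            counts[k] = len(set(cut_tree_hybrid(ward_linkage(s), CutParams()))
                            - {0})
        best = max(sorted(counts), key=lambda k: (counts[k], -k))
        assert pcm.k == best
        assert pcm.scan == counts
        assert counts[pcm.k] >= 6  # at least the planted cluster count

    def test_tie_breaks_toward_smaller_k(self):
        rng = np.random.default_rng(0)
        # two clean blobs: cluster count is 2 for every k -> smallest k wins
        X = np.vstack([rng.normal(0, 0.5, (60, 10)),
                       rng.normal(20, 0.5, (60, 10))])
        pcm = select_principal_components(X, k_range=[2, 3, 4])
        assert pcm.scan[2] == pcm.scan[3] == pcm.scan[4]
        assert pcm.k == 2

    def test_k_range_beyond_rank_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 5))
        with pytest.raises(ValueError):
            select_principal_components(X, k_range=range(2, 20))


class TestIgpStatistic:
    def test_tight_clumps_have_unit_igp(self):
        rng = np.random.default_rng(0)
        test = np.vstack([rng.normal(0, 0.1, (40, 3)),
                          rng.normal(10, 0.1, (40, 3))])
        cents = np.array([[0.0, 0, 0], [10.0, 10, 10][:3]])
        cents = np.array([[0.0, 0.0, 0.0], [10.0, 10.0, 10.0]])
        igp, assign = igp_statistic(test, cents)
        np.testing.assert_allclose(igp, 1.0)

    def test_single_point_cluster_with_foreign_neighbor_scores_zero(self):
        test = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 0.0]])
        cents = np.array([[0.0, 0.0], [4.0, 0.0]])
        igp, assign = igp_statistic(test, cents)
        # the lone point at 5.0 goes to centroid 2; its NN (0.1) is in 1
        assert igp[1] == 0.0

    def test_uniform_points_two_equidistant_centroids_match_brute_oracle(self):
        # nearest-centroid assignment splits the square at the bisector;
        # IGP equals the fraction of each side's points whose brute-force
        # nearest neighbor stays on the same side
        rng = np.random.default_rng(42)
        for _ in range(5):
            test = rng.uniform(-1, 1, (300, 2))
            cents = np.array([[-0.001, 0.0], [0.001, 0.0]])
            igp, assign = igp_statistic(test, cents)
            D = ((test[:, None] - test[None]) ** 2).sum(-1)
            np.fill_diagonal(D, np.inf)
            nn = D.argmin(1)
            for side in (0, 1):
                m = assign == side
                oracle = (assign[nn[m]] == side).mean()
                assert igp[side] == pytest.approx(oracle, abs=1e-12)

    def test_cluster_without_test_points_flagged_nan(self):
        test = np.zeros((10, 2)) + np.arange(10)[:, None] * 0.01
        cents = np.array([[0.0, 0.0], [1000.0, 1000.0]])
        igp, _ = igp_statistic(test, cents)
        assert np.isnan(igp[1])


class TestIgpPermutation:
    def test_perfectly_reproduced_clumps_hit_significance_floor(self):
        # operating regime: several clusters in enough dimensions that the
        # column-shuffled null cannot reassemble coherent clumps (with very
        # few clusters the null is deliberately conservative)
        rng = np.random.default_rng(1)
        K = 6
        mus = rng.normal(0, 6, (K, 10))
        train = np.vstack([rng.normal(mus[k], 0.5, (40, 10)) for k in range(K)])
        test = np.vstack([rng.normal(mus[k], 0.5, (40, 10)) for k in range(K)])
        labels = np.repeat(np.arange(1, K + 1), 40)
        n_perm = 200
        res = igp_permutation_test(train, labels, test, n_perm=n_perm, seed=0)
        floor = 1 / (n_perm + 1)
        at_floor = sum(res.p[c] == pytest.approx(floor) for c in res.p)
        assert at_floor >= K - 1
        for c in res.cluster_ids:
            assert res.p[c] <= 0.01
            assert res.is_module(c)

    def test_single_cluster_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        with pytest.raises(ValueError):
            igp_permutation_test(X, np.ones(50, dtype=int), X, n_perm=10)


class TestCatalog:
    def make(self, repro_q):
        rng = np.random.default_rng(0)
        train = np.vstack([rng.normal(0, 0.3, (30, 2)),
                           rng.normal(8, 0.3, (30, 2))])
        test = train + rng.normal(0, 0.05, train.shape)
        labels = np.repeat([1, 2], 30)
        res = igp_permutation_test(train, labels, test, n_perm=100, seed=0)
        for c in res.q:
            res.q[c] = repro_q
        cents = {1: train[:30].mean(0), 2: train[30:].mean(0)}
        tr = [f"m001.e{i:03d}.M.adult.WT.F" for i in range(1, 61)]
        te = [f"m002.e{i:03d}.M.adult.WT.F" for i in range(1, 11)]
        return build_module_catalog(tr, labels, te, np.ones(10, dtype=int),
                                    res, cents, pc_k=2)

    def test_all_reproducible_means_all_module_labels(self):
        cat = self.make(repro_q=0.01)
        assert set(cat.module_ids) == {1, 2}
        assert all(l.startswith("M") for l in cat.labels.values())

    def test_none_reproducible_means_all_nonmodular(self):
        cat = self.make(repro_q=0.5)
        assert cat.module_ids == []
        assert all(l.startswith("C") for l in cat.labels.values())

    def test_catalog_roundtrips_to_json(self, tmp_path):
        cat = self.make(repro_q=0.01)
        cat.to_json(tmp_path / "cat.json")
        import json
        d = json.loads((tmp_path / "cat.json").read_text())
        assert d["module_ids"] == [1, 2]
        assert len(d["labels"]) == 70
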