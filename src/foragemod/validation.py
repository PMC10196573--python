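"""Planted-truth benchmarks for the whole pipeline.

Every function here generates its own inputs from the synthetic module (or
closed-form constructions), runs the corresponding analysis stage, and
measures recovery, calibration, or power against the planted ground truth.
They are the package's acceptance surface: the test suite asserts on their
outputs and the reproduction script reports them.

Problem sizes are scaled for a single CPU: module recovery runs the full
default cohort (~1,600 excursions) with 2,000 reproducibility permutations
per seed; the calibration suites use a few hundred small simulated
datasets each.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kstest
from sklearn.metrics import adjusted_rand_score

from .geometry import ArenaGeometry
from .synthetic import (default_config, epoch_benchmark_config,
                        generate_cohort)
from .tracking import KinematicsConfig, annotate_zones
from .features import FEATURE_NAMES, extract_features
from .module_detection import (balanced_partition, cluster_and_cut,
                               detect_modules, igp_permutation_test,
                               null_cluster_count_test,
                               select_principal_components)
from .treecut import CutParams
from .excursions import parse_cimar
from .epochs import segment_epochs, sliding_window_pot_bias
from .expression import per_module_posttests
from .transitions import genotype_distance_permutation_test

__all__ = ["truth_ari", "module_recovery", "igp_calibration",
           "null_count_benchmark", "feature_timing", "posttest_benchmark",
           "epoch_benchmark", "transition_benchmark", "poisson_irls_deviance"]


def _prep_cohort(seed: int, geometry: ArenaGeometry | None = None):
    from .pipeline import process_cohort

    geometry = geometry or ArenaGeometry()
    trajs, manifest, truth = generate_cohort(default_config(), geometry,
                                             seed=seed)
    excursions, matrix, processed = process_cohort(
        trajs, geometry, KinematicsConfig(), analysis_window_min=None)
    return matrix, manifest, truth, excursions, processed


def truth_ari(catalog, matrix, truth) -> float:
    """ARI between module labels and planted archetypes (noise and all
    non-module labels collapse to one class)."""
    pred = catalog.label_array(matrix.cimars)
    tl = [truth.labels[c] for c in matrix.cimars]
    names = sorted(set(tl) - {"noise"})
    tmap = {n: i + 1 for i, n in enumerate(names)}
    tmap["noise"] = 0
    ti = np.array([tmap[l] for l in tl])
    return float(adjusted_rand_score(ti, pred))


@dataclass
class RecoveryResult:
    seeds: list[int]
    n_excursions: list[int]
    module_counts: list[int]
    aris: list[float]
    count_lo: int = 5
    count_hi: int = 8
    ari_min: float = 0.8

    @property
    def success(self) -> np.ndarray:
        return np.array([(self.count_lo <= m <= self.count_hi) and a >= self.ari_min
                         for m, a in zip(self.module_counts, self.aris)])

    @property
    def success_rate(self) -> float:
        return float(self.success.mean())


def module_recovery(seeds=range(1, 21), n_perm: int = 2000) -> RecoveryResult:
    """Full-pipeline module recovery on the default planted cohort."""
    counts, aris, ns = [], [], []
    seeds = list(seeds)
    for seed in seeds:
        matrix, manifest, truth, *_ = _prep_cohort(seed)
        catalog, pcm, part = detect_modules(matrix, manifest, seed=seed,
                                            n_perm=n_perm)
        counts.append(len(catalog.module_ids))
        aris.append(truth_ari(catalog, matrix, truth))
        ns.append(len(matrix.cimars))
    return RecoveryResult(seeds=seeds, n_excursions=ns,
                          module_counts=counts, aris=aris)


def igp_calibration(n_datasets: int = 200, n_points: int = 300, dims: int = 6,
                    n_perm: int = 200, seed: int = 11, alpha: float = 0.05
                    ) -> tuple[float, int]:
    """Cluster-level type-I error of the IGP test on structureless data.

    Uses the raw (unconsolidated) cut: consolidation correctly collapses a
    structureless cloud to one cluster, which would leave nothing to test.
    Returns (type-I rate, number of cluster-level tests).
    """
    rng = np.random.default_rng(seed)
    rej = tot = 0
    for _ in range(n_datasets):
        train = rng.normal(size=(n_points, dims))
        test = rng.normal(size=(n_points, dims))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            asg = cluster_and_cut(train, CutParams(), consolidate=False)
        if asg.n_clusters < 2:
            continue
        res = igp_permutation_test(train, asg.labels, test, n_perm=n_perm,
                                   seed=int(rng.integers(2 ** 31)))
        for c in res.cluster_ids:
            p = res.p[c]
            if np.isfinite(p):
                tot += 1
                rej += p < alpha
    return rej / tot, tot


def null_count_benchmark(seed: int = 1, iterations: int = 1000,
                         n_uniform_runs: int = 100, uniform_points: int = 250,
                         uniform_iterations: int = 99
                         ) -> dict[str, float]:
    """Existence test: power on planted structure, calibration when shuffled."""
    matrix, manifest, *_ = _prep_cohort(seed)
    part = balanced_partition(manifest, seed)
    mouse_of = np.array([parse_cimar(c).mouse_number for c in matrix.cimars])
    Xtr = matrix.values[np.isin(mouse_of, part.train_mice)]
    pcm = select_principal_components(Xtr)
    obs, null, p_planted = null_cluster_count_test(Xtr, pcm.k,
                                                   iterations=iterations,
                                                   seed=seed)
    rng = np.random.default_rng(seed + 1)
    Xs = matrix.values[rng.choice(matrix.values.shape[0], uniform_points,
                                  replace=False)]
    ps = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_uniform_runs):
            Xp = Xs.copy()
            for j in range(Xp.shape[1]):
                rng.shuffle(Xp[:, j])
            _, _, pv = null_cluster_count_test(Xp, 6,
                                               iterations=uniform_iterations,
                                               seed=seed + 100 + r)
            ps.append(pv)
    ks = kstest(ps, "uniform")
    return {"observed_clusters": int(obs), "null_mean": float(null.mean()),
            "p_planted": float(p_planted), "uniformity_ks_p": float(ks.pvalue)}


def feature_timing(seed: int = 1, n_target: int = 1000) -> tuple[float, int]:
    """Seconds to featurize ``n_target`` excursions (57-measure contract)."""
    geometry = ArenaGeometry()
    matrix, manifest, truth, excursions, processed = _prep_cohort(seed, geometry)
    subset = excursions[:n_target]
    t0 = time.time()
    for e in subset:
        v = extract_features(e, geometry)
        assert v.shape == (len(FEATURE_NAMES),)
    return time.time() - t0, len(subset)


def simulate_count_table(rng: np.random.Generator, n_modules: int = 24,
                         n_affected: int = 6, n_per_cell: int = 15,
                         base_rate: float = 5.0, rate_ratio: float = 2.0
                         ) -> tuple[pd.DataFrame, list[str]]:
    """Per-mouse Poisson module-count table with planted genotype effects."""
    mods = [f"mod{j:02d}" for j in range(n_modules)]
    affected = mods[:n_affected]
    rows = []
    mid = 0
    for geno in ("WT", "KO"):
        for sex in ("M", "F"):
            for _ in range(n_per_cell):
                mid += 1
                row = {"mouse_id": mid, "sex": sex, "genotype": geno,
                       "phase": "Foraging"}
                for m in mods:
                    lam = base_rate * (rate_ratio if (geno == "KO" and
                                                      m in affected) else 1.0)
                    row[m] = rng.poisson(lam)
                rows.append(row)
    return pd.DataFrame(rows), affected


def posttest_benchmark(n_sims: int = 50, seed: int = 42) -> dict[str, float]:
    """Recall and observed FDR of the two-step per-module tests."""
    rng = np.random.default_rng(seed)
    recalls, fdrs = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_sims):
            table, affected = simulate_count_table(rng)
            post = per_module_posttests(table)
            sig = set(post.significant)
            recalls.append(len(sig & set(affected)) / len(affected))
            fdrs.append(len(sig - set(affected)) / max(1, len(sig)))
    return {"recall": float(np.mean(recalls)), "fdr": float(np.mean(fdrs)),
            "n_sims": n_sims}


def poisson_irls_deviance(table: pd.DataFrame) -> tuple[float, float]:
    """Deviance of ``count ~ sex + genotype`` by hand-rolled IRLS.

    Independent of statsmodels: builds the design matrix explicitly and
    iterates weighted least squares to convergence. Returns
    (deviance, log-likelihood-free residual check) for oracle comparison.
    """
    y = table["count"].to_numpy(float)
    X = np.column_stack([
        np.ones(len(table)),
        (table["sex"] == sorted(table["sex"].unique())[1]).astype(float),
        (table["genotype"] == sorted(table["genotype"].unique())[1]).astype(float),
    ])
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    for _ in range(100):
        eta = X @ beta
        mu = np.exp(eta)
        W = mu
        z = eta + (y - mu) / mu
        WX = X * W[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    mu = np.exp(X @ beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    deviance = 2.0 * np.sum(term - (y - mu))
    return float(deviance), float(np.abs(X.T @ (y - mu)).max())


def epoch_benchmark(n_sims: int = 20, seed0: int = 1,
                    planted_onsets=(0, 12, 19)) -> dict[str, float]:
    """Sliding-window epoch-onset recovery on the planted two-gap cohort."""
    geo = ArenaGeometry()
    cfg = epoch_benchmark_config()
    hits = 0
    for s in range(n_sims):
        trajs, _, _ = generate_cohort(cfg, geo, seed=seed0 + s)
        trajs = [annotate_zones(t, geo) for t in trajs]
        series = sliding_window_pot_bias(trajs, trial_min=30.0)
        ep = segment_epochs(series, trial_min=30.0)
        onsets = [series.windows[i][0] for i in ep.onsets]
        ok = (len(onsets) == len(planted_onsets)
              and all(abs(a - b) <= 1 for a, b in zip(onsets, planted_onsets)))
        hits += ok
    return {"recovery_rate": hits / n_sims, "n_sims": n_sims}


def _markov_sequences(n_mice: int, P: np.ndarray, rng: np.random.Generator,
                      length: int = 20, offset: int = 0) -> dict[int, list[str]]:
    states = [f"M{i + 1}" for i in range(P.shape[0])]
    out = {}
    for m in range(n_mice):
        s = int(rng.integers(0, P.shape[0]))
        seq = []
        for _ in range(length):
            seq.append(states[s])
            s = int(rng.choice(P.shape[0], p=P[s]))
        out[m + offset] = seq
    return out


def transition_benchmark(n_power: int = 30, n_calib: int = 100,
                         n_perm: int = 300, seed: int = 0) -> dict[str, float]:
    """Power against planted distinct dynamics; calibration when exchangeable.

    The planted contrast mirrors a knockout group favoring the direct
    food-dart module about 3:1 over the baseline mix.
    """
    P_base = np.array([[0.4, 0.3, 0.3], [0.3, 0.4, 0.3], [0.3, 0.3, 0.4]])
    P_alt = np.array([[0.6, 0.2, 0.2], [0.6, 0.2, 0.2], [0.5, 0.25, 0.25]])
    rej = 0
    for s in range(n_power):
        rng = np.random.default_rng(seed + 100 + s)
        a = _markov_sequences(15, P_base, rng)
        b = _markov_sequences(15, P_alt, rng, offset=100)
        _, p = genotype_distance_permutation_test(a, b, n_perm=n_perm,
                                                  seed=seed + s)
        rej += p < 0.05
    ps = []
    for s in range(n_calib):
        rng = np.random.default_rng(seed + 500 + s)
        a = _markov_sequences(15, P_base, rng)
        b = _markov_sequences(15, P_base, rng, offset=100)
        _, p = genotype_distance_permutation_test(a, b, n_perm=200,
                                                  seed=seed + 1000 + s)
        ps.append(p)
    ks = kstest(ps, "uniform")
    return {"power": rej / n_power, "calibration_ks_p": float(ks.pvalue),
            "n_power": n_power, "n_calib": n_calib}
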