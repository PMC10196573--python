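"""End-to-end orchestration: ingest -> excursions -> features -> modules ->
expression/epoch/transition statistics -> embedding.

A run is configured by a :class:`RunConfig` (YAML-serializable), executes
stage by stage into a run directory, and records a manifest with every
seed and version needed to reproduce it bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import ArenaGeometry
from .tracking import (KinematicsConfig, Trajectory, annotate_zones,
                       compute_kinematics, procrustes_align,
                       read_tracking_table)
from .excursions import Excursion, export_excursion_index, segment_excursions
from .features import (CATALOG_VERSION, build_feature_matrix, catalog_schema,
                       extract_features, FeatureMatrix)
from .module_detection import detect_modules, null_cluster_count_test
from .treecut import CutParams
from .expression import (epoch_contingency_test, interaction_glm_test,
                         per_module_posttests, tally_module_expression)
from .epochs import segment_epochs, sliding_window_pot_bias
from .transitions import (build_transition_matrix,
                          genotype_distance_permutation_test,
                          sequences_from_labels, transition_dependence_test)
from .cartography import embed_excursions, plot_embedding

log = logging.getLogger("foragemod")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "process_cohort"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a run needs; defaults follow the study conditions."""

    data_dir: str | None = None          # cohort dir (manifest.csv + tracks)
    simulate: bool = True                # generate a synthetic cohort instead
    seed: int = 0
    module_window_min: float | None = 25.0
    epoch_window_min: float = 30.0
    k_range: tuple[int, int] = (2, 12)   # inclusive PC scan bounds
    deep_split: int = 4
    min_cluster_size: int = 20
    n_perm_igp: int = 10_000
    n_iter_null: int = 10_000
    n_perm_transitions: int = 10_000
    q_module: float = 0.1
    q_posttest: float = 0.05
    variance_quantile: float = 0.1
    embed_dims: int = 2
    kinematics: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("q_module", "q_posttest", "variance_quantile"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.data_dir is not None and not Path(self.data_dir).exists():
            raise FileNotFoundError(self.data_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        Path(path).write_text(yaml.safe_dump(d))


def load_cohort(data_dir: str | Path, geometry: ArenaGeometry
                ) -> tuple[list[Trajectory], pd.DataFrame]:
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    trajs = []
    for _, row in manifest.iterrows():
        traj = read_tracking_table(
            data_dir / row["file"],
            mouse_id=f"m{int(row['mouse_id']):03d}",
            phase=row["phase"], sex=row["sex"], genotype=row["genotype"])
        trajs.append(traj)
    return trajs, manifest


def process_cohort(trajs: list[Trajectory], geometry: ArenaGeometry,
                   kcfg: KinematicsConfig,
                   analysis_window_min: float | None = None
                   ) -> tuple[list[Excursion], FeatureMatrix, list[Trajectory]]:
    """Align, annotate, segment and featurize a cohort of trials."""
    processed = []
    excursions: list[Excursion] = []
    for traj in trajs:
        t = procrustes_align(traj, geometry)
        t = compute_kinematics(t, kcfg)
        t = annotate_zones(t, geometry)
        processed.append(t)
        excursions.extend(segment_excursions(t, analysis_window_min))
    vecs = [extract_features(e, geometry) for e in excursions]
    matrix = build_feature_matrix(vecs, [e.cimar for e in excursions])
    return excursions, matrix, processed


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage; outputs land in ``outdir``.

    Re-running with the same config and seeds reproduces all outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__,
                      "catalog_version": CATALOG_VERSION,
                      "seed": config.seed, "stages": []}
    geometry = ArenaGeometry.from_dict(config.geometry) if config.geometry \
        else ArenaGeometry()
    kcfg = KinematicsConfig(**config.kinematics)

    def stage(name):
        log.info(json.dumps({"stage": name, "status": "start"}))
        manifest["stages"].append(name)

    try:
        stage("ingest")
        if config.simulate:
            from .synthetic import default_config, export_truth, generate_cohort

            trajs, cohort_manifest, truth = generate_cohort(
                default_config(), geometry, seed=config.seed)
            export_truth(truth, outdir / "truth.json")
        else:
            if config.data_dir is None:
                raise PipelineError("ingest", "data_dir required when not simulating")
            trajs, cohort_manifest = load_cohort(config.data_dir, geometry)
        cohort_manifest.to_csv(outdir / "cohort_manifest.csv", index=False)

        stage("excursions")
        excursions, matrix, processed = process_cohort(
            trajs, geometry, kcfg, config.module_window_min)
        exc_index = export_excursion_index(excursions, outdir / "excursions.csv")
        matrix.to_csv(outdir / "features.csv")
        (outdir / "feature_catalog.json").write_text(
            json.dumps(catalog_schema(), indent=2))

        stage("detect")
        if config.n_perm_igp < 10_000:
            warnings.warn("IGP permutations below 10,000")
        if config.n_iter_null < 10_000:
            warnings.warn("null cluster-count iterations below 10,000")
        cut = CutParams(deep_split=config.deep_split,
                        min_cluster_size=config.min_cluster_size)
        catalog, pcm, part = detect_modules(
            matrix, cohort_manifest, seed=config.seed,
            k_range=range(config.k_range[0], config.k_range[1] + 1),
            cut_params=cut, n_perm=config.n_perm_igp,
            q_threshold=config.q_module)
        catalog.to_json(outdir / "module_catalog.json")
        catalog.labels_csv(outdir / "module_labels.csv")
        mouse_of = np.array([int(c.split(".")[0][1:]) for c in matrix.cimars])
        train_mask = np.isin(mouse_of, part.train_mice)
        obs_count, _, null_p = null_cluster_count_test(
            matrix.values[train_mask], pcm.k, iterations=config.n_iter_null,
            seed=config.seed, cut_params=cut)

        stage("stats")
        counts = tally_module_expression(catalog, exc_index)
        counts.to_csv(outdir / "expression_counts.csv", index=False)
        inter = interaction_glm_test(counts)
        post = per_module_posttests(counts,
                                    variance_quantile=config.variance_quantile,
                                    q_threshold=config.q_posttest)
        post.per_module.to_csv(outdir / "posttests.csv", index=False)

        stage("epochs")
        foraging = [t for t in processed if t.phase == "Foraging"] or processed
        series = sliding_window_pot_bias(foraging,
                                         trial_min=config.epoch_window_min)
        epochs = segment_epochs(series, trial_min=config.epoch_window_min)
        pd.DataFrame({
            "win_start_min": [w[0] for w in series.windows],
            "win_end_min": [w[1] for w in series.windows],
            "p": series.p, "coef": series.coef,
            "significant": series.significant,
        }).to_csv(outdir / "window_bias.csv", index=False)

        # epoch-resolved module-expression heatmaps + dependence tests
        epoch_counts = tally_module_expression(catalog, exc_index,
                                               epochs=epochs.intervals,
                                               include_nonmodular=False)
        contingency: dict = {}
        mod_cols = [c for c in epoch_counts.columns
                    if c not in ("mouse_id", "sex", "genotype", "phase",
                                 "epoch")]
        for e, grp in epoch_counts.groupby("epoch"):
            if e == 0:
                continue
            agg = (grp.assign(group=grp["genotype"] + "_" + grp["sex"])
                      .groupby("group")[mod_cols].sum().T)
            if (agg.to_numpy().sum(axis=0) == 0).any() or agg.shape[0] < 2:
                continue
            res = epoch_contingency_test(agg, seed=config.seed)
            res.scaled.to_csv(outdir / f"epoch{e}_heatmap.csv")
            contingency[f"epoch{e}"] = {"p": res.p, "method": res.method,
                                        "column_order": res.column_order}

        stage("transitions")
        seqs = sequences_from_labels(catalog.labels, exc_index)
        genos = {g: {m for m in cohort_manifest.loc[
            cohort_manifest["genotype"] == g, "mouse_id"]}
            for g in cohort_manifest["genotype"].unique()}
        trans_out: dict = {}
        model = build_transition_matrix(seqs)
        model.counts.to_csv(outdir / "transition_counts.csv")
        model.P.to_csv(outdir / "transition_probs.csv")
        model.pi.rename("pi").to_csv(outdir / "stationary.csv")
        trans_out["dependence_p"] = transition_dependence_test(
            model.counts, seed=config.seed)
        if len(genos) == 2:
            (ga, ma), (gb, mb) = genos.items()
            d_obs, p = genotype_distance_permutation_test(
                {k: v for k, v in seqs.items() if k in ma},
                {k: v for k, v in seqs.items() if k in mb},
                n_perm=config.n_perm_transitions, seed=config.seed)
            trans_out["groups"] = [ga, gb]
            trans_out["stationary_distance"] = d_obs
            trans_out["permutation_p"] = p

        stage("cartography")
        emb = embed_excursions(matrix, dims=config.embed_dims,
                               seed=config.seed)
        emb.to_csv(outdir / "embedding.csv")
        plot_embedding(emb, catalog, outdir / "landscape.png")

        manifest.update({
            "n_trials": len(trajs),
            "n_excursions": len(excursions),
            "pc_k": pcm.k,
            "pc_scan": {str(k): v for k, v in pcm.scan.items()},
            "train_mice": list(part.train_mice),
            "test_mice": list(part.test_mice),
            "n_modules": len(catalog.module_ids),
            "null_count_observed": int(obs_count),
            "null_count_p": null_p,
            "interaction_p": inter.p,
            "significant_modules": post.significant,
            "epoch_onsets_min": [series.windows[i][0] for i in epochs.onsets],
            "epochs_min": epochs.intervals,
            "epoch_contingency": contingency,
            "transitions": trans_out,
            "embedding_backend": emb.backend,
        })
    except PipelineError:
        (outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
        raise
    except Exception as e:  # halt with stage-tagged error + partial manifest
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "?"
        (outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
        raise PipelineError(manifest.get("failed_stage", "?"), str(e)) from e

    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return outdir
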