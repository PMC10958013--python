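"""End-to-end experiment orchestration: simulate, train, embed, analyze.

``run_experiment`` executes the whole reproduction — episode simulation,
Siamese action-prediction training, embedding of a balanced 0..30 test set,
number-category clustering, embedding-line calibration, psychophysics — and
writes every intermediate artifact plus a machine-readable ``summary.json``
into one output directory.  Identical configs and seeds produce identical
summaries.

Two profiles bundle coherent defaults: ``desk`` (64 px scenes, small
network, lr 1e-3, 120 epochs — minutes on one CPU core) and ``full``
(244 px scenes, the reference schedule: lr 1e-4, 30 epochs x 30
mini-batches x 180 actions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import analysis, model, psychophys, scenes


@dataclass
class ExperimentConfig:
    """Everything one reproduction run depends on, resolved from a profile."""

    profile: str = "desk"
    regime: str = "A"
    seed: int = 0
    replicates: int = 1
    scene: scenes.SceneConfig | None = None
    model: model.ModelConfig | None = None
    training: model.TrainingConfig | None = None
    min_cluster_size: int = 90
    purity_threshold: float = 0.95
    test_counts: tuple[int, ...] = tuple(range(31))
    n_per_count: int = 300
    reference_count: int = 16
    psychophys_trials: int = 200
    action_test_episodes: int = 20

    def __post_init__(self) -> None:
        if self.profile not in ("desk", "full"):
            raise ValueError("profile must be 'desk' or 'full'")
        if self.scene is None:
            self.scene = (scenes.desk_config(self.regime) if self.profile == "desk"
                          else (scenes.regime_a() if self.regime == "A"
                                else scenes.regime_b()))
        if self.model is None:
            self.model = model.ModelConfig(profile=self.profile)
        if self.training is None:
            self.training = (model.desk_schedule()
                             if self.profile == "desk" else model.TrainingConfig())
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.reference_count not in self.test_counts:
            raise ValueError("reference_count must be among test_counts")
        if self.scene.regime != self.regime:
            raise ValueError("scene config regime disagrees with experiment regime")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _run_single(config: ExperimentConfig, seed: int, out: Path, log) -> dict:
    rng = np.random.default_rng(seed)
    stages: dict[str, float] = {}

    def stage(name):
        t0 = time.time()
        log(f"[stage] {name}")
        return lambda: stages.__setitem__(name, round(time.time() - t0, 2))

    done = stage("train")
    net = model.build_model(config.model, rng)
    stream = scenes.sequence_stream(config.scene, config.training.actions_per_minibatch, rng)
    history = model.train(net, stream, config.training, rng)
    net.save(out / "model.npz")
    history.to_frame().to_csv(out / "training_history.csv", index=False)
    done()

    done = stage("action-test")
    episodes = [scenes.generate_training_sequence(
        config.scene, config.training.actions_per_minibatch, rng)
        for _ in range(config.action_test_episodes)]
    err_df = model.evaluate_action_error_by_count(net, episodes)
    err_df.to_csv(out / "action_error_by_count.csv")
    trained_max = config.scene.max_objects
    in_range = err_df[err_df.index <= trained_max]
    action_error_pct = 100.0 * in_range["errors"].sum() / in_range["n"].sum()
    done()

    done = stage("embed")
    test_set = scenes.generate_balanced_test_set(
        config.scene, config.test_counts, config.n_per_count, rng)
    z = net.embed(test_set.images)
    done()

    done = stage("analyze")
    labeling = analysis.cluster_embeddings(z, min_cluster_size=config.min_cluster_size)
    confusion = analysis.number_confusion(labeling, test_set.counts,
                                          purity_threshold=config.purity_threshold)
    confusion.matrix.to_csv(out / "confusion_matrix.csv")
    line = analysis.calibrate_line(z, labeling)
    with open(out / "line_model.json", "w") as fh:
        json.dump(line.to_json(), fh, indent=1)
    perceived = analysis.perceived_numerosity(line, z)
    import pandas as pd
    emb_df = pd.DataFrame(z, columns=[f"z{i}" for i in range(z.shape[1])])
    emb_df.insert(0, "true_count", test_set.counts)
    emb_df["cluster"] = labeling.labels
    emb_df["perceived"] = perceived
    emb_df.to_csv(out / "embeddings.csv", index=False)
    from scipy.stats import spearmanr
    rho = float(spearmanr(perceived, test_set.counts).statistic)
    rank1 = analysis.linear_approximation_error(z)
    big = analysis.cluster_embeddings(z, min_cluster_size=96)
    done()

    done = stage("psychophys")
    curve = psychophys.relative_comparison_curve(
        line, z, test_set.counts, rng, reference_count=config.reference_count,
        n_trials=config.psychophys_trials)
    curve.table.to_csv(out / "psychometric_curve.csv", index=False)
    report = psychophys.absolute_estimation_report(line, z, test_set.counts)
    report.table.to_csv(out / "estimation_report.csv")
    done()

    at_ref = curve.table.loc[curve.table["test_count"] == config.reference_count,
                             "proportion_more"].iloc[0]
    summary = {
        "seed": seed,
        "pairs_consumed": history.pairs_consumed,
        "final_train_accuracy": history.epoch_accuracy[-1],
        "action_error_pct_trained_range": action_error_pct,
        "action_error_by_count": {int(c): float(r) for c, r in
                                  err_df["error_rate"].items()},
        "n_clusters": labeling.n_clusters,
        "n_outliers": int(labeling.outlier_mask.sum()),
        "subitization_limit": confusion.subitization_limit,
        "n_clusters_min_size_96": big.n_clusters,
        "spearman_perceived_vs_count": rho,
        "linear_approximation_error": rank1,
        "mean_abs_relative_error": report.mean_abs_relative_error,
        "power_law_exponent": report.power_law.exponent,
        "power_law_coefficient": report.power_law.coefficient,
        "proportion_more_at_reference": float(at_ref),
    }
    # wall-times live outside the summary so reruns stay byte-identical
    with open(out / "timings.json", "w") as fh:
        json.dump(stages, fh, indent=1)
    return summary


def run_experiment(config: ExperimentConfig, out_dir: str | Path,
                   log=print) -> dict:
    """Run the full pipeline (possibly replicated) and write artifacts.

    Returns the summary dict that is also written to ``summary.json``.
    With ``replicates > 1`` each replicate runs with its own derived seed in
    its own subdirectory, and the top-level summary aggregates the per-
    replicate power-law fits (the multi-initialization exponent spread).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": 1,
        "config": config.to_jsonable(),
        "config_hash": _config_hash(config),
        "versions": _library_versions(),
    }
    if config.replicates == 1:
        summary = _run_single(config, config.seed, out, log)
    else:
        child_seeds = np.random.SeedSequence(config.seed).generate_state(
            config.replicates) % (2 ** 31)
        reps = []
        for i, s in enumerate(child_seeds):
            sub = out / f"replicate_{i:02d}"
            sub.mkdir(exist_ok=True)
            reps.append(_run_single(config, int(s), sub, log))
        exps = [r["power_law_exponent"] for r in reps]
        summary = {
            "replicates": reps,
            "power_law_exponent_mean": float(np.mean(exps)),
            "power_law_exponent_std": float(np.std(exps)),
        }
    summary = {**meta, **summary}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _library_versions() -> dict:
    import pandas
    import scipy
    import sklearn

    from . import __version__
    return {"numerosense": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__,
            "scikit-learn": sklearn.__version__}
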