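"""End-to-end orchestration: simulate -> preprocess -> train -> threshold -> evaluate.

`run_experiment` executes the full pipeline for one imbalance strategy and
returns an EvalReport (optionally writing all artifacts to a run directory);
`compare_strategies` runs several strategies on the *same* corpus, split and
seeds and tabulates them.

Strategies
----------
baseline            plain cross-entropy, default threshold 0.5
class_weight        inverse-frequency class-weighted cross-entropy, threshold 0.5
smote               SMOTE-balanced train split, threshold 0.5
smote_threshold     SMOTE plus the closed-form moved threshold
focal               focal loss, threshold 0.5
threshold_moving    plain cross-entropy plus the closed-form moved threshold
empirical_threshold plain cross-entropy; threshold fitted on the validation
                    posteriors (never the test split)

Leakage rules enforced here: SMOTE augments the train split only; the
empirical threshold is fitted on validation posteriors only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imbalance, metrics, model, preprocess, simulate

logger = logging.getLogger("imbfall")

STRATEGIES = (
    "baseline",
    "class_weight",
    "smote",
    "smote_threshold",
    "focal",
    "threshold_moving",
    "empirical_threshold",
)

#: Table-style display names for the comparison report.
STRATEGY_DISPLAY = {
    "baseline": "Baseline (ResNet10)",
    "class_weight": "Class-Weight",
    "smote": "SMOTE",
    "smote_threshold": "SMOTE + Threshold",
    "focal": "Focal Loss",
    "threshold_moving": "Threshold Moving",
    "empirical_threshold": "Empirical Threshold",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one experiment needs, with every seed explicit."""

    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    width_s: float = 1.0
    stride_s: float = 0.5
    fall_span_s: float = 3.0
    split_ratio: tuple[float, float, float] = (6.0, 2.0, 2.0)
    split_seed: int = 0
    network: model.NetworkConfig | None = None
    strategy: str = "baseline"
    beta: float = 0.5
    k: float = 0.5
    focal_gamma: float = 2.0
    focal_alpha: float = 0.75
    smote_k_neighbors: int = 5
    smote_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise PipelineError(f"unknown strategy {self.strategy!r}; known: {STRATEGIES}")

    def resolved_network(self) -> model.NetworkConfig:
        if self.network is not None:
            return self.network
        timesteps = round(self.width_s * self.simulation.fs)
        return model.NetworkConfig(input_shape=(timesteps, 3))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@dataclass
class RunResult:
    report: metrics.EvalReport
    policy: imbalance.ThresholdPolicy
    split: preprocess.SplitCorpus
    history: pd.DataFrame
    classifier: model.Classifier
    rho_train: float


def prepare_split(config: RunConfig) -> tuple[preprocess.SplitCorpus, pd.DataFrame]:
    """Simulate the corpus and produce the stratified window split."""
    trials, manifest = simulate.generate_corpus(config.simulation)
    windows = preprocess.windows_from_trials(
        trials,
        manifest["label"].tolist(),
        width_s=config.width_s,
        stride_s=config.stride_s,
        fall_span_s=config.fall_span_s,
    )
    split = preprocess.split_corpus(windows, config.split_ratio, config.split_seed)
    return split, manifest


def train_with_strategy(
    config: RunConfig, split: preprocess.SplitCorpus
) -> tuple[model.Classifier, pd.DataFrame, preprocess.SplitCorpus]:
    """Train under the configured strategy; returns the classifier, the
    history and the (possibly SMOTE-augmented) split actually trained on."""
    net_cfg = config.resolved_network()
    clf = model.build_network(net_cfg)
    train_split = split
    loss = model.LossSpec()
    if config.strategy == "class_weight":
        loss = model.LossSpec(class_weights=imbalance.class_weights(split))
    elif config.strategy == "focal":
        loss = model.LossSpec(name="focal", gamma=config.focal_gamma, alpha=config.focal_alpha)
    elif config.strategy in ("smote", "smote_threshold"):
        counts = split.class_counts("train")
        n_new = counts[0] - counts[1]
        minority = [w for w in split.train if w.label == 1]
        synthetic = imbalance.smote_windows(
            minority, n_new, config.smote_k_neighbors, config.smote_seed
        )
        train_split = preprocess.SplitCorpus(
            train=list(split.train) + synthetic,
            validation=split.validation,
            test=split.test,
            ratio=split.ratio,
            seed=split.seed,
        )
        logger.info("SMOTE: added %d synthetic minority windows to train only", len(synthetic))
    clf, history = model.train(clf, train_split, net_cfg, loss)
    return clf, history, train_split


def choose_policy(
    config: RunConfig, split: preprocess.SplitCorpus, clf: model.Classifier, rho_train: float
) -> imbalance.ThresholdPolicy:
    """Decision threshold per strategy. The moved threshold always derives
    from the original train imbalance ratio (deployment distribution), even
    after SMOTE balancing."""
    if config.strategy in ("threshold_moving", "smote_threshold"):
        return imbalance.closed_form_threshold(rho_train, config.k)
    if config.strategy == "empirical_threshold":
        f = imbalance.minority_frequency(split)
        val_posteriors = model.predict_proba(clf, split.validation)[:, 1]
        return imbalance.empirical_threshold(val_posteriors, f)
    return imbalance.ThresholdPolicy(lam=config.k, k=config.k, provenance="default")


def run_experiment(
    config: RunConfig,
    split: preprocess.SplitCorpus | None = None,
    manifest: pd.DataFrame | None = None,
) -> RunResult:
    """Execute the full pipeline and (optionally) write artifacts to out_dir.

    A pre-built split/manifest may be passed to share one corpus across
    several strategy runs.
    """
    if split is None:
        split, manifest = _stage("simulate+preprocess")(prepare_split)(config)
    counts = split.class_counts("train")
    if counts[1] == 0:
        raise PipelineError("stage 'preprocess' failed: no minority windows in train split")
    rho_train = preprocess.imbalance_ratio(counts[0], counts[1])
    logger.info("train windows: %d ADL / %d fall (rho=%.2f)", counts[0], counts[1], rho_train)

    clf, history, train_split = _stage("train")(train_with_strategy)(config, split)
    policy = _stage("threshold")(choose_policy)(config, split, clf, rho_train)

    posteriors = _stage("predict")(model.predict_proba)(clf, split.test)
    pred = imbalance.apply_threshold(posteriors, policy)
    y_test = np.array([w.label for w in split.test])
    report = _stage("evaluate")(metrics.evaluate)(y_test, pred, posteriors[:, 1], config.beta)

    if config.out_dir is not None:
        _write_artifacts(config, manifest, split, clf, history, policy, report)
    return RunResult(report, policy, split, history, clf, rho_train)


def _split_index(split: preprocess.SplitCorpus) -> pd.DataFrame:
    rows = []
    for name in ("train", "validation", "test"):
        for w in getattr(split, name):
            rows.append((name, w.source_trial, w.offset, w.label))
    return pd.DataFrame(rows, columns=["split", "trial_id", "offset", "label"])


def _write_artifacts(config, manifest, split, clf, history, policy, report) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if manifest is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    _split_index(split).to_csv(out / "split_index.csv", index=False)
    history.to_csv(out / "history.csv", index=False)
    (out / "policy.txt").write_text(policy.to_text())
    report.to_frame().to_csv(out / "report.csv", index=False)
    (out / "report.txt").write_text(report.to_text())
    model.save_checkpoint(clf, out / "checkpoint")
    cfg = dataclasses.asdict(config)
    cfg["network"] = dataclasses.asdict(config.resolved_network())
    (out / "run_config.json").write_text(json.dumps(cfg, indent=2, default=str))
    logger.info("artifacts written to %s", out)


def compare_strategies(base_config: RunConfig, strategies: list[str]) -> pd.DataFrame:
    """One EvalReport row per strategy, same corpus/split/network seeds."""
    if not strategies:
        raise PipelineError("stage 'compare' failed: need at least one strategy")
    split, manifest = prepare_split(base_config)
    rows = []
    for strategy in strategies:
        cfg = dataclasses.replace(base_config, strategy=strategy, out_dir=None)
        result = run_experiment(cfg, split=split, manifest=manifest)
        r = result.report
        rows.append(
            {
                "method": STRATEGY_DISPLAY.get(strategy, strategy),
                "strategy": strategy,
                "lambda": result.policy.lam,
                "sensitivity_pct": r.sensitivity,
                "specificity_pct": r.specificity,
                "f_score_pct": r.f_score,
                "auc_pct": r.auc,
                "accuracy_pct": r.accuracy,
            }
        )
    table = pd.DataFrame(rows)
    if base_config.out_dir is not None:
        out = Path(base_config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "comparison.csv", index=False)
    return table
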