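"""Configuration-driven experiment orchestration.

``run_experiment`` ties the stages together: load or simulate trials, run
nested cross-validation per estimator on *shared* fold assignments (so
estimator comparisons are paired), classify the attended talker on decoding
segments of every requested length, and evaluate accuracy / ROC / ITR.  The
result bundle is written to the output directory as plain text (JSON + CSV)
together with a copy of the configuration and the seed, so any number in the
outputs is traceable to a config + seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crossval import CVReport, Trial, cross_validate_multi, make_folds
from .datamodel import LagSpec
from .decoding import (
    DecisionRecord,
    accuracy_from_records,
    apply_forward_classifier,
    classify_argmax,
    nykopp_itr,
    roc_from_decisions,
    segment_correlation_features,
    train_forward_classifier,
)
from .estimators import ESTIMATOR_NAMES, default_path, sweep_geometric_lambdas, sweep_logsigmoid_lambdas
from .exceptions import ConfigError
from .synthetic import SyntheticScenario, generate_dataset, read_dataset

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "compare_estimators",
    "fisher_z_mean",
    "arcsine_mean",
]

DEFAULT_SEGMENTS = (1.0, 3.0, 5.0, 7.0, 10.0, 15.0, 20.0, 30.0)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    direction: str = "backward"
    estimators: list[str] = field(default_factory=lambda: ["ridge"])
    scenario: SyntheticScenario | None = None
    data_dir: str | None = None          # alternative to scenario: saved bundle
    kernel_s: float = 0.5
    n_folds: int = 10
    seed: int = 0
    alpha: float = 0.25                  # elastic-net L1/L2 balance
    segment_lengths_s: tuple[float, ...] = DEFAULT_SEGMENTS
    step_s: float = 1.0
    lambda_path: dict | None = None      # {"family", "lam0", "ratio"/"step", "n_steps"}
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ConfigError(f"unknown direction {self.direction!r}")
        for est in self.estimators:
            if est not in ESTIMATOR_NAMES:
                raise ConfigError(f"unknown estimator {est!r}")
        if self.scenario is None and self.data_dir is None:
            self.scenario = SyntheticScenario(seed=self.seed)
        if not self.segment_lengths_s:
            raise ConfigError("at least one segment length is required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        scen = d.pop("scenario", None)
        if scen is not None:
            scen = SyntheticScenario(**scen)
        segs = d.pop("segment_lengths_s", DEFAULT_SEGMENTS)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(scenario=scen, segment_lengths_s=tuple(segs), **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def resolved_path(self, estimator: str):
        if estimator == "ols":
            return None
        if self.lambda_path is None:
            return default_path(estimator)
        p = dict(self.lambda_path)
        family = p.pop("family", "geometric")
        if family == "geometric":
            path = sweep_geometric_lambdas(**p)
        elif family == "logsigmoid":
            path = sweep_logsigmoid_lambdas(**p)
        else:
            raise ConfigError(f"unknown path family {family!r}")
        # schemes whose parameter lives on (0, 1] cannot take a geometric
        # sweep into the hundreds; fall back to their natural path
        if estimator in ("lra", "shrinkage") and path.lambdas[-1] >= 1:
            return default_path(estimator)
        return path


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    reports: dict[str, CVReport]
    records: dict[tuple[str, float], list[DecisionRecord]]
    metrics: pd.DataFrame

    def result_hash(self) -> str:
        """Digest of the numeric outputs (idempotence checks)."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.metrics.round(12).to_csv().encode())
        for name in sorted(self.reports):
            for m in self.reports[name].models:
                h.update(np.ascontiguousarray(m.weights).round(12).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _load_trials(config: ExperimentConfig) -> list[Trial]:
    if config.data_dir is not None:
        ds = read_dataset(config.data_dir)
    else:
        ds = generate_dataset(config.scenario)
    return [Trial(t.eeg, t.attended_env, t.unattended_env, t.attended)
            for t in ds.trials]


def run_experiment(config: ExperimentConfig,
                   trials: list[Trial] | None = None) -> ExperimentResult:
    """Run the full pipeline for one configuration (see module docstring)."""
    if trials is None:
        trials = _load_trials(config)
    fs = trials[0].eeg.fs
    lag_spec = LagSpec.for_direction(config.kernel_s, fs, config.direction)
    folds = make_folds(len(trials), config.n_folds, config.seed)
    paths = {est: config.resolved_path(est) for est in config.estimators}
    reports = cross_validate_multi(trials, config.direction, paths, lag_spec,
                                   seed=config.seed, alpha=config.alpha,
                                   folds=folds)

    records: dict[tuple[str, float], list[DecisionRecord]] = {}
    rows = []
    for name, rep in reports.items():
        for seg_s in config.segment_lengths_s:
            recs = decode_segments(rep, trials, seg_s, config.step_s,
                                   config.kernel_s)
            records[(name, seg_s)] = recs
            acc = accuracy_from_records(recs)
            roc = roc_from_decisions(recs)
            itr = nykopp_itr(recs, v=60.0 / seg_s, segment_s=seg_s)
            rows.append({
                "estimator": name,
                "direction": config.direction,
                "segment_s": seg_s,
                "n_segments": len(recs),
                "accuracy": acc,
                "auc": roc.auc,
                "wolpaw_bits_per_min": itr.wolpaw_bits_per_min,
                "nykopp_bits_per_min": itr.nykopp_bits_per_min,
                "r_attended": rep.mean_r_attended,
            })
    metrics = pd.DataFrame(rows)
    result = ExperimentResult(config, reports, records, metrics)
    if config.outdir:
        _write_bundle(result, Path(config.outdir))
    return result


def decode_segments(rep: CVReport, trials: list[Trial], seg_len_s: float,
                    step_s: float = 1.0, kernel_s: float = 0.5,
                    ) -> list[DecisionRecord]:
    """Classify every decoding segment of every held-out trial.

    Backward models use the argmax (correlation-difference) rule directly.
    Forward models additionally need a trained classifier: for each outer
    fold a linear SVM is fit on segment features computed over that fold's
    *training* trials with the averaged fold model, then applied to the
    held-out segments — test data never touches classifier training.
    """
    all_records: list[DecisionRecord] = []
    sid = 0
    for o, model in enumerate(rep.models):
        mu_x, sd_x, mu_y, sd_y = rep.fold_norms[o]
        test_idx = rep.folds.trials_in(o)

        def _features(trial_indices):
            nonlocal sid
            recs = []
            for ti in trial_indices:
                tr = trials[ti]
                if rep.direction == "backward":
                    eeg = tr.eeg.copy_with((tr.eeg.samples - mu_x) / sd_x)
                    env_pair = (tr.attended_env, tr.unattended_env)
                else:
                    eeg = tr.eeg.copy_with((tr.eeg.samples - mu_y) / sd_y)
                    env_pair = (
                        tr.attended_env.copy_with(
                            (tr.attended_env.samples - mu_x) / sd_x),
                        tr.unattended_env.copy_with(
                            (tr.unattended_env.samples - mu_x) / sd_x),
                    )
                env_a, env_b = ((env_pair[0], env_pair[1])
                                if tr.label == "A" else (env_pair[1], env_pair[0]))
                recs.extend(segment_correlation_features(
                    model, eeg, env_a, env_b, tr.label, seg_len_s, step_s,
                    kernel_s, start_id=sid))
                sid = recs[-1].segment_id + 1 if recs else sid
            return recs

        test_records = _features(test_idx)
        if rep.direction == "backward":
            for r in test_records:
                classify_argmax(r)
        else:
            train_idx = [i for i in range(len(trials))
                         if rep.folds.fold_of[i] != o]
            train_records = _features(train_idx)
            clf = train_forward_classifier(train_records)
            apply_forward_classifier(clf, test_records)
        all_records.extend(test_records)
    return all_records


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def fisher_z_mean(rs) -> float:
    """Mean of correlations through the Fisher z-transform (variance stabilized)."""
    rs = np.clip(np.asarray(rs, dtype=float), -0.999999, 0.999999)
    return float(np.tanh(np.arctanh(rs).mean()))


def arcsine_mean(accs) -> float:
    """Mean of proportions through the arcsine-square-root transform."""
    accs = np.clip(np.asarray(accs, dtype=float), 0.0, 1.0)
    return float(np.sin(np.arcsin(np.sqrt(accs)).mean()) ** 2)


def compare_estimators(results: list[ExperimentResult]) -> pd.DataFrame:
    """Descriptive per-estimator summary over shared folds and data.

    One row per estimator and segment length: transformed-mean r_attended
    (Fisher z over folds) and accuracy (arcsine), with plain SDs.  Refuses to
    compare bundles with different fold assignments — the comparison must be
    paired.
    """
    ref = results[0].reports[next(iter(results[0].reports))].folds
    for res in results:
        for rep in res.reports.values():
            if (rep.folds.n_folds != ref.n_folds
                    or not np.array_equal(rep.folds.fold_of, ref.fold_of)):
                raise ConfigError(
                    "cannot compare results with different fold assignments")
    rows = []
    for res in results:
        for name, rep in res.reports.items():
            for seg_s in res.config.segment_lengths_s:
                recs = res.records[(name, seg_s)]
                accs = [accuracy_from_records(recs)]
                rows.append({
                    "estimator": name,
                    "direction": rep.direction,
                    "segment_s": seg_s,
                    "r_attended_mean": fisher_z_mean(rep.r_attended),
                    "r_attended_sd": float(np.std(rep.r_attended, ddof=1))
                    if len(rep.r_attended) > 1 else 0.0,
                    "accuracy_mean": arcsine_mean(accs),
                })
    df = pd.DataFrame(rows).sort_values(["estimator", "segment_s"])
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Bundle output
# ---------------------------------------------------------------------------

def _write_bundle(result: ExperimentResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config.to_dict()
    (outdir / "config.json").write_text(json.dumps(cfg, indent=1, default=str))
    result.metrics.to_csv(outdir / "metrics.csv", index=False)
    for name, rep in result.reports.items():
        rep.to_json(outdir / f"cv_{name}.json")
    rec_rows = []
    for (name, seg_s), recs in result.records.items():
        for r in recs:
            rec_rows.append({
                "estimator": name, "segment_s": seg_s, "segment_id": r.segment_id,
                "true_label": r.true_label, "predicted_label": r.predicted_label,
                "decision_value": r.decision_value,
                "r_a": float(np.asarray(r.features_a).ravel()[0]),
                "r_b": float(np.asarray(r.features_b).ravel()[0]),
                "tie": r.tie,
            })
    pd.DataFrame(rec_rows).to_csv(outdir / "decisions.csv", index=False)
    roc_rows = []
    for (name, seg_s), recs in result.records.items():
        roc = roc_from_decisions(recs)
        for t, tp, fp, fr in zip(roc.thresholds, roc.tpr, roc.fpr,
                                 roc.fraction_at_or_above):
            roc_rows.append({"estimator": name, "segment_s": seg_s,
                             "threshold": t, "tpr": tp, "fpr": fp,
                             "fraction_evaluated": fr})
    pd.DataFrame(roc_rows).to_csv(outdir / "roc.csv", index=False)
    (outdir / "itr.json").write_text(result.metrics[
        ["estimator", "segment_s", "accuracy",
         "wolpaw_bits_per_min", "nykopp_bits_per_min"]
    ].to_json(orient="records", indent=1))
    (outdir / "result_hash.txt").write_text(result.result_hash() + "\n")
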