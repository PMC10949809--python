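"""End-to-end study orchestration.

``run_experiment`` drives the four model families (clinical, hippocampal,
freesurfer, deep learning) through every (outer fold, inner fold) training
run of a double cross-validation plan, evaluating each trained model on its
outer fold's held-out test set.  It returns fold-level metric tables, outer-
fold means, percentile-bootstrap confidence intervals on pooled test-set
predictions, and pairwise Mann-Whitney model comparisons — one results table
per task.

All randomness descends from the experiment seed, so identical seeds yield
byte-identical written tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import baselines
from .cnn import ImagingDataset, LossSpec, MultiTaskCNN, NetworkConfig, train
from .errors import ConfigurationError
from .evaluation import (MetricReport, auc, bootstrap_ci, compare_models,
                         mcc, r_squared)
from .outcomes import derive_outcomes
from .preprocessing import (FeatureScaler, conform_shape,
                            global_intensity_max, rescale_mri)
from .splits import SplitPlan, iterate_plan, make_split_plan
from .synthetic import (GeneratorConfig, VolumePair, cohort_to_frame,
                        generate_cohort, generate_volumes)

ALL_MODELS = ("clinical", "hippocampal", "freesurfer", "deep_learning")


@dataclass(frozen=True)
class ExperimentConfig:
    generator: GeneratorConfig = GeneratorConfig()
    n_outer: int = 5
    n_inner: int = 10
    alpha: float = 0.05
    models: tuple[str, ...] = ALL_MODELS
    net: NetworkConfig | None = None          # derived from generator if None
    loss_spec: LossSpec = LossSpec(1.0, 0.025, 0.025)
    bootstrap_reps: int = 1000
    global_max_scope: str = "train"           # "train" | "all"
    mcc_threshold: float = 0.5
    seed: int = 0

    def resolved_net(self) -> NetworkConfig:
        if self.net is not None:
            return self.net
        return NetworkConfig(input_shape=self.generator.jd_shape,
                             clinical_dim=len(baselines.CLINICAL_FEATURES),
                             seed=self.seed)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    plan: SplitPlan
    metrics: pd.DataFrame                     # long fold-level table
    reports: dict[tuple[str, str], MetricReport]
    summaries: dict[str, pd.DataFrame]        # per task
    comparisons: dict[str, pd.DataFrame]      # per metric
    failures: list[dict] = field(default_factory=list)


def _conform(volume: np.ndarray, target: tuple[int, int, int]) -> np.ndarray:
    """Crop axes that are too large, zero-pad axes that are too small."""
    inter = tuple(min(s, t) for s, t in zip(volume.shape, target))
    out = conform_shape(volume, inter, "crop")
    return conform_shape(out, target, "zero_pad")


def build_imaging_dataset(cohort_df: pd.DataFrame,
                          outcomes_df: pd.DataFrame,
                          volumes: dict[str, VolumePair],
                          ids: Sequence[str],
                          clinical_scaler: FeatureScaler,
                          mri_global_max: float,
                          input_shape: tuple[int, int, int]) -> ImagingDataset:
    """Assemble preprocessed network inputs for a list of subjects.

    Clinical features are min-max scaled with the supplied (training-set)
    scaler; MRIs are rescaled to [-1, 1] with the supplied global max and
    cropped; JDs pass through unscaled and are zero-padded.
    """
    df = cohort_df.set_index("subject_id", drop=False).loc[list(ids)]
    out = outcomes_df.set_index("subject_id").loc[list(ids)]
    X_raw, _ = baselines.feature_matrix(df, "clinical")
    clin = clinical_scaler.transform(X_raw)
    mri = np.stack([
        rescale_mri(_conform(volumes[i].mri, input_shape), mri_global_max)
        for i in ids])[:, None]
    jd = np.stack([_conform(np.asarray(volumes[i].jd, np.float32),
                            input_shape) for i in ids])[:, None]
    return ImagingDataset(
        subject_ids=list(ids),
        mri=mri.astype(np.float64), jd=jd.astype(np.float64),
        clinical=clin,
        labels=out["progressed_4y"].to_numpy().astype(int),
        slopes=out["mmse_slope_4y"].to_numpy(float),
        hippo=df["hippocampus_mm3"].to_numpy(float))


def _plan_signature(plan: SplitPlan) -> str:
    return hashlib.sha256(plan.to_json().encode()).hexdigest()[:16]


def run_experiment(config: ExperimentConfig,
                   cohort_df: pd.DataFrame | None = None,
                   outcomes_df: pd.DataFrame | None = None,
                   volumes: dict[str, VolumePair] | None = None,
                   ) -> ExperimentResult:
    """Run the full four-model comparison on a (synthetic) cohort."""
    gen = config.generator
    if cohort_df is None:
        cohort = generate_cohort(gen)
        cohort_df = cohort_to_frame(cohort)
        outcomes_df = derive_outcomes(cohort)
        if "deep_learning" in config.models:
            volumes = generate_volumes(cohort, gen)
    if outcomes_df is None:
        raise ConfigurationError(
            "outcomes_df is required when a cohort is supplied")
    if "deep_learning" in config.models and volumes is None:
        raise ConfigurationError(
            "volumes are required for the deep_learning model")

    merged = cohort_df.merge(outcomes_df, on="subject_id")
    plan = make_split_plan(merged, config.n_outer, config.n_inner,
                           alpha=config.alpha, seed=config.seed)
    signature = _plan_signature(plan)
    net_cfg = config.resolved_net()
    by_id = merged.set_index("subject_id", drop=False)

    rows: list[dict] = []
    failures: list[dict] = []
    # pooled test-set scores for bootstrap CIs: model -> id -> list of scores
    pooled: dict[tuple[str, str], dict[str, list[float]]] = {
        (m, t): {} for m in config.models
        for t in ("progression", "slope")}

    for triple in iterate_plan(plan):
        tri_seed = (config.seed * 1009 + triple.outer_fold * 101
                    + triple.inner_fold) % (2 ** 31)
        train_df = by_id.loc[triple.train_ids]
        test_df = by_id.loc[triple.test_ids]
        y_test = test_df["progressed_4y"].to_numpy().astype(int)
        s_test = test_df["mmse_slope_4y"].to_numpy(float)

        def record(model: str, task: str, metric: str, value: float) -> None:
            rows.append({
                "model": model, "task": task,
                "outer_fold": triple.outer_fold,
                "inner_fold": triple.inner_fold,
                "metric": metric, "value": value})

        def pool(model: str, task: str, scores: np.ndarray) -> None:
            store = pooled[(model, task)]
            for sid, sc in zip(triple.test_ids, scores):
                store.setdefault(sid, []).append(float(sc))

        for name in config.models:
            if name == "deep_learning":
                continue
            try:
                m_prog = baselines.fit(
                    name, "progression", train_df,
                    train_df["progressed_4y"].to_numpy().astype(int),
                    seed=tri_seed)
                p = baselines.predict(m_prog, test_df)
                record(name, "progression", "auc", auc(p, y_test))
                record(name, "progression", "mcc",
                       mcc(p, y_test, config.mcc_threshold))
                pool(name, "progression", p)
                m_slope = baselines.fit(
                    name, "slope", train_df,
                    train_df["mmse_slope_4y"].to_numpy(float),
                    seed=tri_seed)
                s = baselines.predict(m_slope, test_df)
                record(name, "slope", "r2", r_squared(s, s_test))
                pool(name, "slope", s)
            except Exception as exc:   # partial failures: record, continue
                failures.append({
                    "model": name, "outer_fold": triple.outer_fold,
                    "inner_fold": triple.inner_fold, "error": repr(exc)})

        if "deep_learning" in config.models:
            try:
                X_train_raw, _ = baselines.feature_matrix(
                    train_df, "clinical")
                clin_scaler = FeatureScaler("minmax").fit(X_train_raw)
                if config.global_max_scope == "all":
                    gmax_ids = list(by_id.index)
                else:
                    gmax_ids = triple.train_ids
                gmax = global_intensity_max(
                    _conform(volumes[i].mri, net_cfg.input_shape)
                    for i in gmax_ids)
                mk = lambda ids: build_imaging_dataset(
                    cohort_df, outcomes_df, volumes, ids, clin_scaler,
                    gmax, net_cfg.input_shape)
                ds_train = mk(triple.train_ids)
                ds_val = mk(triple.val_ids)
                ds_test = mk(triple.test_ids)
                model = MultiTaskCNN(replace(net_cfg, seed=tri_seed))
                train(model, ds_train, ds_val, config.loss_spec)
                pred = model.predict(ds_test)
                p = pred["p_progression"].to_numpy()
                s = pred["pred_slope"].to_numpy()
                record("deep_learning", "progression", "auc", auc(p, y_test))
                record("deep_learning", "progression", "mcc",
                       mcc(p, y_test, config.mcc_threshold))
                record("deep_learning", "slope", "r2", r_squared(s, s_test))
                pool("deep_learning", "progression", p)
                pool("deep_learning", "slope", s)
            except Exception as exc:
                failures.append({
                    "model": "deep_learning",
                    "outer_fold": triple.outer_fold,
                    "inner_fold": triple.inner_fold, "error": repr(exc)})

    metrics = pd.DataFrame(
        rows, columns=["model", "task", "outer_fold", "inner_fold",
                       "metric", "value"])

    reports: dict[tuple[str, str], MetricReport] = {}
    labels_by_id = by_id["progressed_4y"].astype(int)
    slopes_by_id = by_id["mmse_slope_4y"].astype(float)
    for name in config.models:
        for task in ("progression", "slope"):
            sel = metrics[(metrics["model"] == name)
                          & (metrics["task"] == task)]
            rep = MetricReport(model=name, task=task,
                               fold_values=sel.reset_index(drop=True),
                               plan_signature=signature)
            store = pooled[(name, task)]
            if store:
                ids = sorted(store)
                mean_scores = np.array(
                    [float(np.mean(store[i])) for i in ids])
                if task == "progression":
                    y = labels_by_id.loc[ids].to_numpy()
                    rep.ci["auc"] = bootstrap_ci(
                        auc, mean_scores, y, reps=config.bootstrap_reps,
                        seed=config.seed)
                    rep.ci["mcc"] = bootstrap_ci(
                        lambda s, l: mcc(s, l, config.mcc_threshold),
                        mean_scores, y, reps=config.bootstrap_reps,
                        seed=config.seed)
                else:
                    t = slopes_by_id.loc[ids].to_numpy()
                    rep.ci["r2"] = bootstrap_ci(
                        r_squared, mean_scores, t,
                        reps=config.bootstrap_reps, seed=config.seed)
            reports[(name, task)] = rep

    summaries = {}
    for task, metric_names in (("progression", ("auc", "mcc")),
                               ("slope", ("r2",))):
        srows = []
        for name in config.models:
            rep = reports[(name, task)]
            row: dict = {"model": name}
            for met in metric_names:
                vals = rep.values(met)
                row[f"{met}_mean"] = (float(np.mean(vals)) if vals.size
                                      else np.nan)
                lo, hi = rep.ci.get(met, (np.nan, np.nan))
                row[f"{met}_ci_low"], row[f"{met}_ci_high"] = lo, hi
            srows.append(row)
        summaries[task] = pd.DataFrame(srows)

    comparisons = {}
    for task, met in (("progression", "auc"), ("slope", "r2")):
        reps_with_values = [reports[(m, task)] for m in config.models
                            if reports[(m, task)].values(met).size > 0]
        if len(reps_with_values) >= 2:
            comparisons[met] = compare_models(reps_with_values, met,
                                              config.alpha)
    return ExperimentResult(config=config, plan=plan, metrics=metrics,
                            reports=reports, summaries=summaries,
                            comparisons=comparisons, failures=failures)


def write_results(result: ExperimentResult, directory: str | Path) -> None:
    """Write deterministic CSV/JSON artifacts for an experiment run."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fmt = "%.12g"
    result.metrics.to_csv(directory / "fold_metrics.csv", index=False,
                          float_format=fmt)
    for task, table in result.summaries.items():
        table.to_csv(directory / f"summary_{task}.csv", index=False,
                     float_format=fmt)
    for met, table in result.comparisons.items():
        table.to_csv(directory / f"comparison_{met}.csv",
                     float_format=fmt)
    result.plan.to_json(directory / "split_plan.json")
    (directory / "provenance.json").write_text(json.dumps({
        "seed": result.config.seed,
        "n_outer": result.config.n_outer,
        "n_inner": result.config.n_inner,
        "models": list(result.config.models),
        "n_failures": len(result.failures),
    }, indent=1, sort_keys=True))
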