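"""Feature-table prognostic models.

Three predictor sets of increasing richness:

* ``clinical`` — age, sex, education, baseline MMSE, ADAS delayed recall,
  APOE ε4 (logistic regression for progression, linear regression for the
  MMSE slope);
* ``hippocampal`` — clinical plus hippocampal and intracranial volume (same
  model families);
* ``freesurfer`` — clinical plus the 68 regional gray-matter volumes and
  intracranial volume (random forest classifier / regressor, 100 trees,
  unlimited depth, seeded).

All features are z-scored with training-set statistics before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression

from .errors import DegenerateLabelsError, SchemaError
from .preprocessing import FeatureScaler
from .synthetic import N_REGIONS

CLINICAL_FEATURES = [
    "age", "sex_female", "education_years", "mmse_baseline", "adas_delayed",
    "apoe_e4",
]
HIPPOCAMPAL_FEATURES = CLINICAL_FEATURES + ["hippocampus_mm3", "icv_cm3"]
FREESURFER_FEATURES = (CLINICAL_FEATURES
                       + [f"region_{i + 1:03d}" for i in range(N_REGIONS)]
                       + ["icv_cm3"])

PREDICTOR_SETS: dict[str, list[str]] = {
    "clinical": CLINICAL_FEATURES,
    "hippocampal": HIPPOCAMPAL_FEATURES,
    "freesurfer": FREESURFER_FEATURES,
}

Task = Literal["progression", "slope"]


def feature_matrix(cohort: pd.DataFrame, predictor_set: str,
                   apoe_encoding: Literal["count", "carrier"] = "count"
                   ) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix for a predictor set.

    Sex enters as a female indicator; APOE as allele count (default) or a
    binary carrier flag.
    """
    if predictor_set not in PREDICTOR_SETS:
        raise SchemaError(f"unknown predictor set {predictor_set!r}")
    df = cohort.copy()
    df["sex_female"] = (df["sex"] == "F").astype(float)
    if apoe_encoding == "carrier":
        df["apoe_e4"] = (df["apoe_e4"] > 0).astype(float)
    features = PREDICTOR_SETS[predictor_set]
    missing = [f for f in features if f not in df.columns]
    if missing:
        raise SchemaError(f"missing feature column(s): {missing}")
    return df[features].to_numpy(float), list(features)


@dataclass
class FittedModel:
    """A trained tabular model plus the scaler it was fitted with."""

    predictor_set: str
    task: Task
    family: Literal["logistic", "linear", "random_forest"]
    estimator: object
    scaler: FeatureScaler
    feature_names: list[str]
    apoe_encoding: Literal["count", "carrier"] = "count"


def _family_for(predictor_set: str, task: Task) -> str:
    if predictor_set == "freesurfer":
        return "random_forest"
    return "logistic" if task == "progression" else "linear"


def fit(predictor_set: str, task: Task, train_subjects: pd.DataFrame,
        train_targets: np.ndarray, seed: int = 0,
        apoe_encoding: Literal["count", "carrier"] = "count") -> FittedModel:
    """Fit one model family on z-scored training features.

    ``train_targets`` is the binary progression label or the MMSE slope,
    aligned with ``train_subjects`` rows.
    """
    X_raw, names = feature_matrix(train_subjects, predictor_set, apoe_encoding)
    y = np.asarray(train_targets)
    scaler = FeatureScaler("zscore").fit(X_raw, names)
    X = scaler.transform(X_raw)
    family = _family_for(predictor_set, task)
    if task == "progression":
        if len(np.unique(y.astype(int))) < 2:
            raise DegenerateLabelsError(
                "training labels contain a single class")
        if family == "logistic":
            est = LogisticRegression(max_iter=5000, random_state=seed)
        else:
            est = RandomForestClassifier(n_estimators=100, random_state=seed)
        est.fit(X, y.astype(int))
    else:
        if family == "linear":
            est = LinearRegression()
        else:
            est = RandomForestRegressor(n_estimators=100, random_state=seed)
        est.fit(X, y.astype(float))
    return FittedModel(predictor_set, task, family, est, scaler, names,
                       apoe_encoding)


def predict(model: FittedModel, subjects: pd.DataFrame) -> np.ndarray:
    """Scores for new subjects: P(progression) or predicted points/year."""
    X_raw, _ = feature_matrix(subjects, model.predictor_set,
                              model.apoe_encoding)
    X = model.scaler.transform(X_raw)
    if model.task == "progression":
        return model.estimator.predict_proba(X)[:, 1]
    return model.estimator.predict(X)
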