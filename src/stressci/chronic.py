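"""Chronic-stress stage: depression classification and the SSCI3 index.

Feature vectors combine the temporally retro-adjusted biomarker panel
(cortisol and glucose mapped to the 08:00 benchmark via the fitted
circadian baselines; skin temperature and heart rate raw) with
demographic covariates (gender, age, height, weight, mean blood
pressure) — nine features in total. Labels come from the weighted
addition of three min-max-normalized depression scales (SCL-90, SDS,
SAS), thresholded into four groups (ND / DR / MD / SD); MD and SD form
the binary "patient" class, ND and DR the "healthy" class.

Five classifiers (random forest, SVM, Gaussian naive Bayes,
gradient-boosted trees, and a small neural network) are trained on
min-max-normalized features — normalization parameters estimated on the
training partition only — and compared on held-out subjects. The
quantitative SSCI3 index is the output of a linear regression on the
same features. Splitting is at the subject level so that no subject
contributes rows to both partitions; with the default 49-subject,
3-repeat cohort and 10 held-out subjects the partition sizes are
exactly 117 and 30 rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LinearRegression
from sklearn.metrics import (accuracy_score, auc, confusion_matrix,
                             precision_recall_curve, roc_curve)
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .baseline import BaselineModel, retro_adjust
from .cohort import scale_normalize
from .errors import (CollinearityError, ConfigError, InvalidParameterError,
                     MissingDataError)

FEATURE_NAMES = ("cortisol_adj", "glucose_adj", "st", "hr",
                 "gender", "age", "height", "weight", "mean_bp")
DEMOGRAPHICS = ("gender", "age", "height", "weight", "mean_bp")
CLASS4 = ("ND", "DR", "MD", "SD")
PATIENT_GROUPS = frozenset({"MD", "SD"})

#: Equal-thirds weights over the three min-max-normalized scales and the
#: composite thresholds anchoring the four label groups. With the scale
#: anchors of the synthetic generator, latent levels 0/1/2/3 map to
#: composites near 0 / 0.16 / 0.32 / 0.49, so the thresholds sit between
#: adjacent levels.
DEFAULT_SCALE_WEIGHTS = {"SCL90": 1.0 / 3.0, "SDS": 1.0 / 3.0, "SAS": 1.0 / 3.0}
DEFAULT_CLASS_THRESHOLDS = (0.08, 0.24, 0.40)


@dataclass(frozen=True)
class DepressionLabel:
    composite_score: float
    class4: str
    class2: str


def class2_of(class4: str) -> str:
    return "patient" if class4 in PATIENT_GROUPS else "healthy"


def label_from_scales(scl90: float, sds: float, sas: float,
                      weights: dict | None = None,
                      thresholds=DEFAULT_CLASS_THRESHOLDS) -> DepressionLabel:
    """Composite chronic-stress label from the three scale scores.

    Each scale is min-max normalized over its admissible range, then
    combined by weighted addition. The composite is cut at three
    thresholds into ND / DR / MD / SD; a composite exactly at a
    threshold goes to the higher class.
    """
    weights = weights or DEFAULT_SCALE_WEIGHTS
    if sorted(weights) != ["SAS", "SCL90", "SDS"]:
        raise ConfigError(f"scale weights must cover SCL90/SDS/SAS, got {sorted(weights)}")
    if not (len(thresholds) == 3 and thresholds[0] < thresholds[1] < thresholds[2]):
        raise ConfigError("thresholds must be three increasing values")
    scores = {"SCL90": scl90, "SDS": sds, "SAS": sas}
    composite = 0.0
    for kind, score in scores.items():
        normed = float(scale_normalize(score, kind))
        if not (0.0 <= normed <= 1.0):
            raise InvalidParameterError(
                f"{kind} score {score} outside its admissible range")
        composite += weights[kind] * normed
    idx = int(np.searchsorted(np.asarray(thresholds), composite, side="right"))
    class4 = CLASS4[idx]
    return DepressionLabel(composite_score=composite, class4=class4,
                           class2=class2_of(class4))


def make_labels(table: pd.DataFrame, weights: dict | None = None,
                thresholds=DEFAULT_CLASS_THRESHOLDS) -> pd.DataFrame:
    """Row-wise labels for a cohort table with scl90/sds/sas columns."""
    labels = [label_from_scales(r.scl90, r.sds, r.sas, weights, thresholds)
              for r in table.itertuples()]
    return pd.DataFrame({
        "composite_score": [l.composite_score for l in labels],
        "class4": [l.class4 for l in labels],
        "class2": [l.class2 for l in labels],
    }, index=table.index)


def assemble_features(table: pd.DataFrame, models: dict[str, BaselineModel],
                      temporal: bool = True) -> pd.DataFrame:
    """Nine-column feature matrix from a cohort table.

    With ``temporal=True`` cortisol and glucose are retro-adjusted to
    the benchmark time using the fitted baselines; otherwise the raw
    values pass through. Rows measured exactly at the benchmark time
    are unchanged by adjustment.
    """
    for col in ("time", "cortisol", "glucose", "st", "hr"):
        if col not in table.columns:
            raise MissingDataError(f"cohort table missing column {col!r}")
    for col in DEMOGRAPHICS:
        if col not in table.columns:
            raise MissingDataError(f"missing demographic column {col!r}")
        if table[col].isna().any():
            raise MissingDataError(f"demographic column {col!r} has missing values")
    if temporal:
        for b in ("cortisol", "glucose"):
            if b not in models:
                raise MissingDataError(f"no baseline model for {b!r}")
        cort = np.array([retro_adjust(v, t, models["cortisol"])
                         for v, t in zip(table["cortisol"], table["time"])])
        glu = np.array([retro_adjust(v, t, models["glucose"])
                        for v, t in zip(table["glucose"], table["time"])])
    else:
        cort = table["cortisol"].to_numpy(dtype=float)
        glu = table["glucose"].to_numpy(dtype=float)
    gender = table["gender"].map({"M": 1.0, "F": 0.0})
    if gender.isna().any():
        raise MissingDataError("gender column must contain only 'M'/'F'")
    out = pd.DataFrame({
        "cortisol_adj": cort, "glucose_adj": glu,
        "st": table["st"].to_numpy(dtype=float),
        "hr": table["hr"].to_numpy(dtype=float),
        "gender": gender.to_numpy(dtype=float),
        "age": table["age"].to_numpy(dtype=float),
        "height": table["height"].to_numpy(dtype=float),
        "weight": table["weight"].to_numpy(dtype=float),
        "mean_bp": table["mean_bp"].to_numpy(dtype=float),
    }, index=table.index)
    return out[list(FEATURE_NAMES)]


def split_cohort(table: pd.DataFrame, test_subjects: int = 10,
                 seed: int = 0):
    """Subject-level train/test split; no subject straddles partitions."""
    subjects = np.asarray(sorted(table["subject_id"].unique()))
    if test_subjects >= subjects.size:
        raise InvalidParameterError(
            f"test_subjects={test_subjects} must be < number of subjects ({subjects.size})")
    rng = np.random.default_rng(seed)
    test_ids = set(rng.choice(subjects, size=test_subjects, replace=False))
    is_test = table["subject_id"].isin(test_ids)
    return table.loc[~is_test].copy(), table.loc[is_test].copy()


# ---------------------------------------------------------------------------
# Normalization and classifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MinMaxNorm:
    """Min-max normalization fitted on the training partition only."""

    mins: pd.Series
    maxs: pd.Series

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "MinMaxNorm":
        return cls(mins=X.min(axis=0), maxs=X.max(axis=0))

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        span = (self.maxs - self.mins).replace(0.0, 1.0)
        return (X - self.mins) / span


def default_algorithms(seed: int) -> dict:
    """The five compared classifiers, each seeded for determinism."""
    return {
        "RF": RandomForestClassifier(n_estimators=300, random_state=seed),
        "SVM": CalibratedClassifierCV(SVC(kernel="rbf", C=10.0,
                                          random_state=seed), ensemble=False),
        "NaiveBayes": GaussianNB(),
        "GradientBoostedTrees": GradientBoostingClassifier(random_state=seed),
        "ANN": MLPClassifier(hidden_layer_sizes=(16,), max_iter=3000,
                             random_state=seed),
    }


@dataclass
class ClassifierBundle:
    norm: MinMaxNorm
    models: dict
    classes: tuple

    def predict(self, name: str, X: pd.DataFrame) -> np.ndarray:
        return self.models[name].predict(self.norm.transform(X))

    def predict_proba_patient(self, name: str, X: pd.DataFrame) -> np.ndarray:
        model = self.models[name]
        proba = model.predict_proba(self.norm.transform(X))
        patient_cols = [i for i, c in enumerate(model.classes_)
                        if class2_of(c) == "patient"]
        return proba[:, patient_cols].sum(axis=1)


def train_classifiers(X_train: pd.DataFrame, y_train, seed: int = 0,
                      algorithms: dict | None = None) -> ClassifierBundle:
    """Fit the classifier panel on min-max-normalized training features."""
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    if classes.size < 2:
        raise InvalidParameterError("training labels contain a single class")
    norm = MinMaxNorm.fit(X_train)
    Xn = norm.transform(X_train)
    algorithms = algorithms or default_algorithms(seed)
    fitted = {name: est.fit(Xn, y_train) for name, est in algorithms.items()}
    return ClassifierBundle(norm=norm, models=fitted, classes=tuple(classes))


def evaluate(bundle: ClassifierBundle, X_test: pd.DataFrame,
             y4_test, y2_test=None) -> dict:
    """Per-algorithm four-class and binary test metrics.

    Returns, per algorithm: the 4-class accuracy and confusion matrix
    (rows = true ND/DR/MD/SD), and on the healthy/patient collapse the
    ROC curve/AUC and precision-recall curve/AUC from the predicted
    patient probability.
    """
    if len(X_test) == 0:
        raise InvalidParameterError("test partition is empty")
    y4_test = np.asarray(y4_test)
    if y2_test is None:
        y2_test = np.array([class2_of(c) for c in y4_test])
    y2_bin = (np.asarray(y2_test) == "patient").astype(int)
    out = {}
    for name in bundle.models:
        pred4 = bundle.predict(name, X_test)
        labels = [c for c in CLASS4 if c in set(y4_test) | set(pred4)]
        cm = confusion_matrix(y4_test, pred4, labels=labels)
        metrics = {
            "accuracy4": float(accuracy_score(y4_test, pred4)),
            "confusion_labels": labels,
            "confusion": cm,
            "accuracy2": float(np.mean(
                np.array([class2_of(c) for c in pred4]) == y2_test)),
        }
        if len(np.unique(y2_bin)) == 2:
            score = bundle.predict_proba_patient(name, X_test)
            fpr, tpr, _ = roc_curve(y2_bin, score)
            prec, rec, _ = precision_recall_curve(y2_bin, score)
            metrics["roc"] = (fpr, tpr)
            metrics["roc_auc"] = float(auc(fpr, tpr))
            metrics["pr"] = (rec, prec)
            metrics["pr_auc"] = float(auc(rec, prec))
        out[name] = metrics
    return out


# ---------------------------------------------------------------------------
# SSCI3 regression
# ---------------------------------------------------------------------------

@dataclass
class Ssci3Regressor:
    norm: MinMaxNorm
    model: LinearRegression

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(self.norm.transform(X))


def _pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def regress_ssci3(X_train: pd.DataFrame, y_train,
                  X_test: pd.DataFrame | None = None, y_test=None) -> dict:
    """Linear-regression SSCI3: composite score predicted from features.

    Returns the fitted regressor plus train R^2 and, when a test
    partition is given, the test predictions and Pearson correlation
    with the true composite scores.
    """
    norm = MinMaxNorm.fit(X_train)
    Xn = norm.transform(X_train)
    informative = Xn.to_numpy().std(axis=0) > 0
    if np.linalg.matrix_rank(Xn.to_numpy()[:, informative]) < int(informative.sum()):
        raise CollinearityError("feature matrix is rank deficient")
    model = LinearRegression().fit(Xn, np.asarray(y_train, dtype=float))
    reg = Ssci3Regressor(norm=norm, model=model)
    out = {"regressor": reg,
           "train_r2": float(model.score(Xn, np.asarray(y_train, dtype=float)))}
    if X_test is not None:
        pred = reg.predict(X_test)
        out["test_pred"] = pred
        if y_test is not None:
            out["test_corr"] = _pearson(pred, y_test)
    return out


# ---------------------------------------------------------------------------
# Temporal-stability comparison
# ---------------------------------------------------------------------------

def _rsd_percent(x) -> float:
    x = np.asarray(x, dtype=float)
    m = float(np.mean(x))
    if m == 0.0:
        return 0.0
    return 100.0 * float(np.std(x, ddof=1)) / abs(m)


def stability_comparison(day_table: pd.DataFrame,
                         models: dict[str, BaselineModel],
                         regressor: Ssci3Regressor,
                         bundle: ClassifierBundle | None = None,
                         classifier: str = "RF") -> dict:
    """SSCI3 stability for one subject tracked across the day.

    Computes SSCI3 at every within-window time point both with and
    without temporal retro-adjustment and returns the two relative
    standard deviations (percent) and, when a classifier bundle is
    given, the two predicted class sequences. Out-of-window points are
    skipped.
    """
    if day_table["subject_id"].nunique() != 1:
        raise InvalidParameterError("stability comparison expects a single subject")
    lo, hi = models["cortisol"].window
    in_window = (day_table["time"] >= lo) & (day_table["time"] <= hi)
    n_skipped = int((~in_window).sum())
    day_table = day_table.loc[in_window]
    if len(day_table) < 5:
        raise InvalidParameterError("need >= 5 within-window time points")
    X_adj = assemble_features(day_table, models, temporal=True)
    X_raw = assemble_features(day_table, models, temporal=False)
    ssci3_adj = regressor.predict(X_adj)
    ssci3_raw = regressor.predict(X_raw)
    out = {
        "times": day_table["time"].to_numpy(),
        "ssci3_adjusted": ssci3_adj, "ssci3_raw": ssci3_raw,
        "rsd_adjusted": _rsd_percent(ssci3_adj),
        "rsd_raw": _rsd_percent(ssci3_raw),
        "n_skipped": n_skipped,
    }
    if bundle is not None:
        out["class_sequence_adjusted"] = bundle.predict(classifier, X_adj)
        out["class_sequence_raw"] = bundle.predict(classifier, X_raw)
    return out
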