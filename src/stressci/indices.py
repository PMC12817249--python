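"""Composite stress indices for acute-stress assessment.

Two indices over the four-biomarker panel (sweat cortisol, sweat
glucose, skin temperature, heart rate):

* SSCI1 — the unweighted algebraic superposition of relative changes
  against a per-test control value,
  ``sum_i (measure_i - control_i) / control_i``. Suitable for
  before/after comparisons within one stress test.
* SSCI2 — the weighted sum of temporally-coupled relative deviations,
  ``sum_i w_i (measure_i(t) - B_i(t)) / B_i(t)``, where B_i is the
  fitted circadian baseline and the impact weights w_i are estimated by
  multiple linear regression of STAI-S anxiety scores on the deviations.

Adding the regression intercept to the weighted sum puts SSCI2 on the
STAI-S scale, where scores of 34 and 44 separate three acute-stress
states (Non-AS / Low AS / High AS). The intercept-free sum is exposed
as the literal index value. A warning trigger fires when a streamed
SSCI1 crosses a configurable fraction (default 80%) of a reference
maximum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .baseline import BaselineModel, baseline_at, _positivity_floor
from .cohort import BIOMARKERS
from .errors import (CollinearityError, DegenerateBaselineError,
                     DegenerateControlError, InsufficientDataError,
                     InvalidParameterError)

#: STAI-S cutpoints separating Non-AS / Low AS / High AS.
AS_CUTPOINT_LOW = 34.0
AS_CUTPOINT_HIGH = 44.0
#: Fraction of the reference maximum SSCI1 that triggers a warning.
DEFAULT_WARNING_FRACTION = 0.8


@dataclass(frozen=True)
class ControlValues:
    """Per-biomarker control levels for SSCI1 (pre-test or stable period)."""

    values: dict
    source: str = "pre_test"

    def __post_init__(self):
        if self.source not in ("pre_test", "stable_period"):
            raise InvalidParameterError(f"unknown control source {self.source!r}")
        for k, v in self.values.items():
            if k not in BIOMARKERS:
                raise KeyError(f"unknown biomarker {k!r} in control values")
            if not np.isfinite(v) or v <= 0:
                raise DegenerateControlError(
                    f"control value for {k} must be positive, got {v!r}")

    def __getitem__(self, key):
        return self.values[key]


@dataclass(frozen=True)
class WeightVector:
    """Impact weights of the biomarker deviations on the STAI-S scale."""

    weights: dict
    intercept: float
    fit_r2: float | None = None
    n_fit: int | None = None
    stderr: dict | None = field(default=None, compare=False)
    conf_int: dict | None = field(default=None, compare=False)

    @property
    def included_biomarkers(self):
        return set(self.weights)

    def to_dict(self) -> dict:
        return {"weights": dict(self.weights), "intercept": self.intercept,
                "fit_r2": self.fit_r2, "n_fit": self.n_fit,
                "stderr": self.stderr,
                "conf_int": None if self.conf_int is None else
                {k: list(v) for k, v in self.conf_int.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "WeightVector":
        ci = d.get("conf_int")
        return cls(weights=dict(d["weights"]), intercept=float(d["intercept"]),
                   fit_r2=d.get("fit_r2"), n_fit=d.get("n_fit"),
                   stderr=d.get("stderr"),
                   conf_int=None if ci is None else {k: tuple(v) for k, v in ci.items()})

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "WeightVector":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def compute_ssci1(measure: dict, control: ControlValues,
                  included=BIOMARKERS) -> float:
    """Unweighted sum of relative changes against the control values."""
    total = 0.0
    for b in included:
        if b not in control.values:
            raise KeyError(f"control missing biomarker {b!r}")
        if b not in measure:
            raise KeyError(f"measurement missing biomarker {b!r}")
        c = control[b]
        if c <= 0:
            raise DegenerateControlError(f"control for {b} must be positive")
        total += (measure[b] - c) / c
    return total


def relative_deviation_t(value: float, t: float, model: BaselineModel) -> float:
    """Temporally-coupled relative deviation (v - B(t)) / B(t)."""
    bt = baseline_at(model, t)
    if bt <= _positivity_floor(model):
        raise DegenerateBaselineError(f"baseline at t={t} is degenerate ({bt!r})")
    return (float(value) - bt) / bt


def estimate_weights_mlr(deviations, stais_scores, biomarker_names=None,
                         alpha: float = 0.05) -> WeightVector:
    """Impact weights by ordinary least squares with intercept.

    Regresses STAI-S scores on the deviation matrix (n observations x k
    biomarkers). Returns the weights with standard errors, the
    (1-alpha) confidence intervals and the fit R^2.
    """
    X = np.asarray(deviations, dtype=float)
    y = np.asarray(stais_scores, dtype=float)
    if X.ndim != 2:
        raise InvalidParameterError("deviations must be a 2-D matrix")
    n, k = X.shape
    if biomarker_names is None:
        biomarker_names = [f"x{i + 1}" for i in range(k)]
    if len(biomarker_names) != k:
        raise InvalidParameterError("biomarker_names length must match columns")
    if n <= k + 1:
        raise InsufficientDataError(f"need n > k + 1 observations, got n={n}, k={k}")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=alpha)
    return WeightVector(
        weights={name: float(res.params[i + 1]) for i, name in enumerate(biomarker_names)},
        intercept=float(res.params[0]),
        fit_r2=float(res.rsquared), n_fit=n,
        stderr={name: float(res.bse[i + 1]) for i, name in enumerate(biomarker_names)},
        conf_int={name: (float(ci[i + 1, 0]), float(ci[i + 1, 1]))
                  for i, name in enumerate(biomarker_names)},
    )


def compute_ssci2(deviations: dict, weights: WeightVector,
                  with_intercept: bool = False) -> float:
    """Weighted sum of relative deviations; optionally on the STAI-S scale.

    Without the intercept this is the literal index value; with it, the
    result is a predicted STAI-S score suitable for the 34/44 cutpoints.
    """
    total = 0.0
    for b, w in weights.weights.items():
        if b not in deviations:
            raise KeyError(f"deviations missing included biomarker {b!r}")
        total += w * deviations[b]
    if with_intercept:
        total += weights.intercept
    return total


@dataclass(frozen=True)
class AsState:
    state: str  # "NonAS" | "LowAS" | "HighAS"
    score: float


def classify_as_state(score: float, cutpoint_low: float = AS_CUTPOINT_LOW,
                      cutpoint_high: float = AS_CUTPOINT_HIGH) -> AsState:
    """Three-way acute-stress state from a STAI-S-scale score.

    Left-closed intervals: score < low -> NonAS, low <= score < high ->
    LowAS, score >= high -> HighAS.
    """
    if not math.isfinite(score):
        raise InvalidParameterError(f"score must be finite, got {score!r}")
    if cutpoint_low >= cutpoint_high:
        raise InvalidParameterError("cutpoint_low must be < cutpoint_high")
    if score < cutpoint_low:
        state = "NonAS"
    elif score < cutpoint_high:
        state = "LowAS"
    else:
        state = "HighAS"
    return AsState(state=state, score=float(score))


def warning_trigger(times, ssci1_values, reference_max: float,
                    fraction: float = DEFAULT_WARNING_FRACTION):
    """Earliest time at which SSCI1 reaches ``fraction * reference_max``.

    ``reference_max`` comes from a prior calibration session. Returns
    the trigger time, or ``None`` if the threshold is never reached.
    """
    if reference_max <= 0:
        raise InvalidParameterError("reference_max must be positive")
    if not (0.0 < fraction <= 1.0):
        raise InvalidParameterError("fraction must lie in (0, 1]")
    times = np.asarray(times, dtype=float)
    values = np.asarray(ssci1_values, dtype=float)
    hits = np.nonzero(values >= fraction * reference_max)[0]
    return float(times[hits[0]]) if hits.size else None


def running_max_warning(times, ssci1_values,
                        fraction: float = DEFAULT_WARNING_FRACTION):
    """Online variant: threshold tracks the running maximum of the stream.

    Provided for streaming deployments; differs from the calibrated-
    reference rule above, which matches the published protocol.
    """
    if not (0.0 < fraction <= 1.0):
        raise InvalidParameterError("fraction must lie in (0, 1]")
    times = np.asarray(times, dtype=float)
    values = np.asarray(ssci1_values, dtype=float)
    run_max = -np.inf
    for t, v in zip(times, values):
        if run_max > 0 and v >= fraction * run_max:
            return float(t)
        run_max = max(run_max, v)
    return None
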