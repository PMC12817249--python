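"""Per-biomarker circadian baseline curves and temporal retro-adjustment.

Cortisol and glucose carry strong within-day structure (circadian rhythm
and meal responses respectively), so a measurement's meaning depends on
its clock time. This module fits a dynamic day-curve B(t) over the
08:00-22:00 window from a small set of candidate families, selects among
them by leave-one-out cross-validation on mean squared prediction error,
and uses the fitted curve to (a) evaluate the temporally-coupled relative
deviation (v - B(t)) / B(t) and (b) retro-adjust a measurement to a
benchmark clock time (08:00 by default).

Retro-adjustment is multiplicative — adjusted = v * B(benchmark) / B(t) —
because the downstream composite indices are built on relative
deviations, which a ratio-preserving map leaves exactly invariant.
Skin temperature and heart rate show no clear day pattern and use
constant baselines (the 08:00 measurement).

Nonlinear fits use bounded least squares with at most 5000 function
evaluations and a deterministic initialization rule (mesor = data mean,
amplitude = half the data range, acrophase = time of the data maximum),
so a fit is reproducible from the data alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from statsmodels.tsa.seasonal import STL

from . import cohort as _cohort
from .cohort import DAY_WINDOW, DEFAULT_MEAL_TIMES, glucose_pulse_kernel
from .errors import (ConvergenceError, DegenerateBaselineError,
                     InsufficientDataError, InvalidParameterError,
                     ModelSelectionError, OutOfWindowError)

MAX_EVALS = 5000
BENCHMARK_TIME = 8.0
POSITIVITY_FLOOR_FRACTION = 1e-6

#: Candidate families and their parameter names.
FAMILY_PARAMS = {
    "constant": ("level",),
    "cosinor": ("mesor", "amplitude", "acrophase"),
    "harmonic2": ("mesor", "amp1", "phase1", "amp2", "phase2"),
    "skewed_peak": ("basal", "amplitude", "acrophase", "kappa", "skew"),
    "meal_pulse": ("basal", "amp1", "amp2", "amp3", "rise"),
}


def _f_constant(t, level):
    return np.full_like(np.asarray(t, dtype=float), level)


def _f_cosinor(t, mesor, amplitude, acrophase):
    t = np.asarray(t, dtype=float)
    return mesor + amplitude * np.cos(2.0 * np.pi * (t - acrophase) / 24.0)


def _f_harmonic2(t, mesor, amp1, phase1, amp2, phase2):
    t = np.asarray(t, dtype=float)
    return (mesor
            + amp1 * np.cos(2.0 * np.pi * (t - phase1) / 24.0)
            + amp2 * np.cos(4.0 * np.pi * (t - phase2) / 24.0))


def _f_skewed_peak(t, basal, amplitude, acrophase, kappa, skew):
    t = np.asarray(t, dtype=float)
    phase = 2.0 * np.pi * (t - acrophase) / 24.0
    return basal + amplitude * np.exp(kappa * (np.cos(phase - skew * np.sin(phase)) - 1.0))


def _make_meal_pulse(meal_times):
    meal_times = tuple(meal_times)

    def _f_meal_pulse(t, basal, amp1, amp2, amp3, rise):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, basal)
        for amp, m in zip((amp1, amp2, amp3), meal_times):
            out = out + amp * glucose_pulse_kernel(t - m, rise=rise)
        return out

    return _f_meal_pulse


def family_function(family: str, meal_times=DEFAULT_MEAL_TIMES):
    if family == "constant":
        return _f_constant
    if family == "cosinor":
        return _f_cosinor
    if family == "harmonic2":
        return _f_harmonic2
    if family == "skewed_peak":
        return _f_skewed_peak
    if family == "meal_pulse":
        return _make_meal_pulse(meal_times)
    raise InvalidParameterError(f"unknown baseline family {family!r}")


@dataclass(frozen=True)
class BaselineModel:
    """A fitted per-biomarker day curve B(t)."""

    biomarker: str
    family: str
    params: tuple
    window: tuple = DAY_WINDOW
    loocv_loss: float | None = None
    benchmark_time: float = BENCHMARK_TIME
    data_mean: float = 1.0
    meal_times: tuple = DEFAULT_MEAL_TIMES
    residual_mse: float | None = None
    bounds: tuple | None = field(default=None, compare=False)

    def to_dict(self) -> dict:
        return {
            "biomarker": self.biomarker, "family": self.family,
            "params": list(self.params), "window": list(self.window),
            "loocv_loss": self.loocv_loss, "benchmark_time": self.benchmark_time,
            "data_mean": self.data_mean, "meal_times": list(self.meal_times),
            "residual_mse": self.residual_mse,
            "bounds": None if self.bounds is None else [list(self.bounds[0]),
                                                        list(self.bounds[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaselineModel":
        bounds = d.get("bounds")
        return cls(
            biomarker=d["biomarker"], family=d["family"],
            params=tuple(d["params"]), window=tuple(d["window"]),
            loocv_loss=d.get("loocv_loss"),
            benchmark_time=d.get("benchmark_time", BENCHMARK_TIME),
            data_mean=d.get("data_mean", 1.0),
            meal_times=tuple(d.get("meal_times", DEFAULT_MEAL_TIMES)),
            residual_mse=d.get("residual_mse"),
            bounds=None if bounds is None else (tuple(bounds[0]), tuple(bounds[1])),
        )

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "BaselineModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def constant_baseline(biomarker: str, level: float,
                      window=DAY_WINDOW, benchmark_time=BENCHMARK_TIME) -> BaselineModel:
    """Constant baseline at a measured level (used for ST and HR)."""
    if level <= 0:
        raise InvalidParameterError("constant baseline level must be positive")
    return BaselineModel(biomarker=biomarker, family="constant",
                         params=(float(level),), window=tuple(window),
                         benchmark_time=benchmark_time, data_mean=float(level))


# ---------------------------------------------------------------------------
# STL characterization
# ---------------------------------------------------------------------------

def stl_characterize(times, values, period: float = 24.0,
                     samples_per_period: int = 24) -> dict:
    """Additive seasonal/trend/residual decomposition of a biomarker series.

    The series is linearly resampled onto a uniform grid and decomposed
    with seasonal-trend decomposition by loess. Requires a span of at
    least two periods. Returns the resampled grid together with the
    three components; their sum reconstructs the resampled series.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size or times.size < 4:
        raise InsufficientDataError("need matching time/value arrays with >= 4 points")
    order = np.argsort(times)
    times, values = times[order], values[order]
    span = times[-1] - times[0]
    if span < 2.0 * period:
        raise InsufficientDataError(
            f"series spans {span:.2f} h; need >= 2 periods ({2 * period:.2f} h)")
    dt = period / samples_per_period
    grid = np.arange(times[0], times[-1] + 0.5 * dt, dt)
    resampled = np.interp(grid, times, values)
    res = STL(resampled, period=samples_per_period).fit()
    return {
        "grid": grid, "resampled": resampled,
        "trend": np.asarray(res.trend), "seasonal": np.asarray(res.seasonal),
        "residual": np.asarray(res.resid),
    }


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _default_bounds(family: str, times, values):
    t_lo, t_hi = float(np.min(times)), float(np.max(times))
    v_lo, v_hi = float(np.min(values)), float(np.max(values))
    rng = max(v_hi - v_lo, 1e-9)
    if family == "constant":
        return ([min(v_lo, 0.0)], [v_hi + rng + 1e-9])
    if family == "cosinor":
        return ([0.0, 0.0, 0.0], [v_hi + rng, 2.0 * rng + 1e-9, 24.0])
    if family == "harmonic2":
        return ([0.0, 0.0, 0.0, 0.0, 0.0],
                [v_hi + rng, 2.0 * rng + 1e-9, 24.0, 2.0 * rng + 1e-9, 24.0])
    if family == "skewed_peak":
        return ([0.0, 0.0, 0.0, 0.1, -1.0],
                [v_hi + rng, 4.0 * rng + 1e-9, 24.0, 10.0, 1.0])
    if family == "meal_pulse":
        return ([0.0, 0.0, 0.0, 0.0, 0.1],
                [v_hi + rng] + [4.0 * rng + 1e-9] * 3 + [4.0])
    raise InvalidParameterError(f"unknown baseline family {family!r}")


def _initial_params(family: str, times, values):
    mean = float(np.mean(values))
    half_range = max(float(np.ptp(values)) / 2.0, 1e-9)
    t_argmax = float(np.asarray(times)[int(np.argmax(values))]) % 24.0
    v_min = float(np.min(values))
    if family == "constant":
        return [mean]
    if family == "cosinor":
        return [mean, half_range, t_argmax]
    if family == "harmonic2":
        return [mean, half_range, t_argmax, half_range / 4.0, t_argmax % 12.0]
    if family == "skewed_peak":
        return [max(v_min, 1e-6), 2.0 * half_range, t_argmax, 2.0, 0.0]
    if family == "meal_pulse":
        return [max(v_min, 1e-6)] + [half_range] * 3 + [0.75]
    raise InvalidParameterError(f"unknown baseline family {family!r}")


def _clip_to_bounds(p0, bounds):
    lo, hi = np.asarray(bounds[0], dtype=float), np.asarray(bounds[1], dtype=float)
    eps = 1e-9 * np.maximum(np.abs(hi - lo), 1.0)
    return np.clip(np.asarray(p0, dtype=float), lo + eps, hi - eps)


def fit_baseline(times, values, family: str, bounds=None,
                 max_evals: int = MAX_EVALS, biomarker: str = "cortisol",
                 window=DAY_WINDOW, benchmark_time: float = BENCHMARK_TIME,
                 meal_times=DEFAULT_MEAL_TIMES) -> BaselineModel:
    """Bounded nonlinear least-squares fit of one candidate family.

    Deterministic given the data: the initialization rule is closed-form
    and no random restarts are used. Raises ``InsufficientDataError``
    when there are fewer than ``n_params + 2`` points and
    ``ConvergenceError`` (carrying the best parameters found) when the
    optimizer exhausts its evaluation budget.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if family not in FAMILY_PARAMS:
        raise InvalidParameterError(f"unknown baseline family {family!r}")
    n_params = len(FAMILY_PARAMS[family])
    if times.size < n_params + 2 and family != "constant":
        raise InsufficientDataError(
            f"{family} needs >= {n_params + 2} points, got {times.size}")
    if family == "constant":
        level = float(np.mean(values))
        resid = float(np.mean((values - level) ** 2))
        return BaselineModel(biomarker=biomarker, family="constant",
                             params=(level,), window=tuple(window),
                             benchmark_time=benchmark_time,
                             data_mean=float(np.mean(values)),
                             residual_mse=resid)
    if bounds is None:
        bounds = _default_bounds(family, times, values)
    func = family_function(family, meal_times)
    p0 = _clip_to_bounds(_initial_params(family, times, values), bounds)
    try:
        popt, _ = curve_fit(func, times, values, p0=p0, bounds=bounds,
                            max_nfev=max_evals)
    except RuntimeError as exc:
        raise ConvergenceError(f"{family} fit did not converge: {exc}",
                               best_params=tuple(p0)) from exc
    resid = float(np.mean((values - func(times, *popt)) ** 2))
    return BaselineModel(biomarker=biomarker, family=family,
                         params=tuple(float(p) for p in popt),
                         window=tuple(window), benchmark_time=benchmark_time,
                         data_mean=float(np.mean(values)), residual_mse=resid,
                         bounds=(tuple(bounds[0]), tuple(bounds[1])),
                         meal_times=tuple(meal_times))


def loocv_loss(times, values, family: str, **fit_kwargs) -> float:
    """Mean squared leave-one-out prediction error for one family."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    errs = []
    for i in range(times.size):
        mask = np.ones(times.size, dtype=bool)
        mask[i] = False
        model = fit_baseline(times[mask], values[mask], family, **fit_kwargs)
        func = family_function(model.family, model.meal_times)
        pred = float(func(np.array([times[i]]), *model.params)[0])
        errs.append((values[i] - pred) ** 2)
    return float(np.mean(errs))


def select_model_loocv(times, values, candidate_families,
                       biomarker: str = "cortisol", **fit_kwargs) -> BaselineModel:
    """Pick the candidate family with minimal leave-one-out loss.

    Each family's average squared prediction error over leave-one-out
    folds is computed; the winner is refit on all the data and returned
    with its LOOCV loss recorded. Families that cannot be fitted (too
    few points, non-convergence) are skipped; if none survives, a
    ``ModelSelectionError`` is raised.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    candidate_families = list(candidate_families)
    if times.size < 5:
        raise InsufficientDataError("model selection needs >= 5 points")
    if not candidate_families:
        raise InvalidParameterError("candidate_families must be non-empty")
    losses = {}
    for family in candidate_families:
        try:
            losses[family] = loocv_loss(times, values, family,
                                        biomarker=biomarker, **fit_kwargs)
        except (InsufficientDataError, ConvergenceError):
            continue
    if not losses:
        raise ModelSelectionError(
            f"no candidate family could be fitted out of {candidate_families}")
    best = min(losses, key=losses.get)
    model = fit_baseline(times, values, best, biomarker=biomarker, **fit_kwargs)
    return dataclasses.replace(model, loocv_loss=losses[best])


# ---------------------------------------------------------------------------
# Evaluation and retro-adjustment
# ---------------------------------------------------------------------------

def baseline_at(model: BaselineModel, t) -> float | np.ndarray:
    """Evaluate the fitted day curve B(t) inside its window."""
    t_arr = np.asarray(t, dtype=float)
    lo, hi = model.window
    if np.any((t_arr < lo) | (t_arr > hi)):
        raise OutOfWindowError(f"t={t!r} outside baseline window [{lo}, {hi}]")
    func = family_function(model.family, model.meal_times)
    out = func(np.atleast_1d(t_arr), *model.params)
    return float(out[0]) if np.isscalar(t) or t_arr.ndim == 0 else out


def _positivity_floor(model: BaselineModel) -> float:
    return POSITIVITY_FLOOR_FRACTION * abs(model.data_mean)


def retro_adjust(value, t, model: BaselineModel):
    """Map a measurement taken at clock time t to the benchmark time.

    Multiplicative rule: adjusted = value * B(benchmark) / B(t). The
    relative deviation (v - B(t)) / B(t) is exactly preserved, and the
    map is the identity at the benchmark time.
    """
    bt = baseline_at(model, t)
    floor = _positivity_floor(model)
    if np.any(np.asarray(bt) <= floor):
        raise DegenerateBaselineError(
            f"baseline at t={t!r} is {bt!r}, below positivity floor {floor:.3g}")
    out = np.asarray(value, dtype=float) * baseline_at(model, model.benchmark_time) / bt
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Reference (pretraining) baselines
# ---------------------------------------------------------------------------

def fit_reference_baselines(seed: int = 0, n_volunteers: int = 11,
                            samples_per_day: int = 15,
                            use_loocv: bool = False) -> dict:
    """Fit pooled cortisol and glucose day curves from a volunteer panel.

    Emulates pretraining the temporal models on a small volunteer cohort
    before applying them to study subjects: each volunteer contributes
    one day of within-window samples; the pooled data are fitted with
    the rhythm-appropriate family (single skewed peak for cortisol,
    meal-pulse sum for glucose), or model-selected by LOOCV over the
    full candidate set when ``use_loocv`` is set.
    """
    rng = np.random.default_rng(seed)
    lo, hi = DAY_WINDOW
    times = np.linspace(lo, hi, samples_per_day)
    all_t, all_cort, all_glu = [], [], []
    for i in range(n_volunteers):
        profile = _cohort.draw_profile(rng, f"V{i + 1:02d}")
        all_t.append(times)
        all_cort.append(_cohort.simulate_cortisol_diurnal(
            profile, times, 3.0, int(rng.integers(2 ** 31))))
        all_glu.append(_cohort.simulate_glucose(
            profile, times, noise_sd=3.0, seed=int(rng.integers(2 ** 31))))
    t = np.concatenate(all_t)
    cort = np.concatenate(all_cort)
    glu = np.concatenate(all_glu)
    if use_loocv:
        families = ("cosinor", "harmonic2", "skewed_peak", "constant")
        cort_model = select_model_loocv(t, cort, families, biomarker="cortisol")
        glu_model = select_model_loocv(t, glu, ("meal_pulse", "harmonic2", "constant"),
                                       biomarker="glucose")
    else:
        cort_model = fit_baseline(t, cort, "skewed_peak", biomarker="cortisol")
        glu_model = fit_baseline(t, glu, "meal_pulse", biomarker="glucose")
    return {"cortisol": cort_model, "glucose": glu_model}
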