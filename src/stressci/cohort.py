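"""Seeded synthetic cohorts of wearable stress-biomarker data.

Generates everything the downstream stages consume: per-subject circadian
cortisol, meal-pulsed sweat glucose, near-constant skin temperature and
heart rate, acute-stress perturbations with biomarker-specific lags, raw
pulse waveforms with percussion/tidal/dicrotic sub-peaks, psychometric
scale scores affinely coupled to a latent stress level, and a depression
cohort table (subjects x repeated panel measurements with demographics
and three scale scores).

All generators are deterministic given their integer seed. Biomarker
series are strictly positive: additive Gaussian noise is truncated at a
small positive floor.

Units: cortisol nM, glucose uM, skin temperature (st) degC, heart rate
(hr) bpm, clock time in decimal hours (8.25 = 08:15).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidParameterError

BIOMARKERS = ("cortisol", "glucose", "st", "hr")

#: Day window used by the baseline-fitting stages, decimal clock hours.
DAY_WINDOW = (8.0, 22.0)

#: Default peak time of the normal-schedule cortisol day curve. A morning
#: acrophase; an inverted sleep schedule shifts it by 12 h.
DEFAULT_ACROPHASE = 8.0

#: Sharpness of the single-peak circadian bump (dimensionless).
CORTISOL_KAPPA = 2.0
#: Skew of the circadian bump; 0 gives a plain cosinor-like shape. The
#: skew term vanishes at the peak and trough, so the acrophase is exact.
CORTISOL_SKEW = 0.3
#: Relative cortisol uplift for habitual coffee drinkers.
COFFEE_CORTISOL_UPLIFT = 0.15
#: Resting-HR reduction (bpm) for subjects with an exercise habit.
EXERCISE_HR_OFFSET = 8.0

#: Default meal clock times and the glucose pulse rise time (hours).
DEFAULT_MEAL_TIMES = (8.0, 12.5, 18.5)
GLUCOSE_PULSE_RISE_H = 0.75

#: Pulse-waveform morphology: relative amplitudes and intra-beat offsets /
#: widths as fractions of the beat period for the percussion, tidal and
#: dicrotic components.
PULSE_AMPLITUDES = (1.0, 0.5, 0.25)
PULSE_OFFSETS = (0.0, 0.22, 0.45)
PULSE_WIDTHS = (0.045, 0.08, 0.08)
#: Highest harmonic the waveform synthesis meaningfully contains (Hz);
#: the sampling rate must exceed twice this.
PULSE_MAX_HARMONIC_HZ = 20.0

#: Acute-stress kernel: delay from end of stressor to peak deviation (h).
STRESS_PEAK_DELAY_H = 5.0 / 60.0

#: Psychometric scales: (minimum, maximum, anchor intercept, slope per
#: unit latent stress). Score = clip(intercept + slope * latent + noise).
#: STAI-S anchors place latent levels 1/2/3 at 29/39/49, straddling the
#: 34 and 44 acute-stress cutpoints.
SCALES = {
    "STAIS": (20.0, 80.0, 19.0, 10.0),
    "SCL90": (90.0, 450.0, 88.0, 60.0),
    "SDS": (25.0, 100.0, 24.0, 12.0),
    "SAS": (25.0, 100.0, 24.0, 12.0),
}

_POSITIVITY_FLOOR = 1e-6


@dataclass(frozen=True)
class SubjectProfile:
    """Static per-subject parameters driving the biomarker generators."""

    subject_id: str
    group: str = "healthy"
    schedule: str = "normal"
    exercise_habit: bool = False
    coffee_habit: bool = False
    gender: str = "F"
    age: float = 30.0
    height: float = 168.0
    weight: float = 65.0
    mean_bp: float = 92.0
    acrophase: float = DEFAULT_ACROPHASE
    amplitude_cortisol: float = 60.0
    basal_cortisol: float = 100.0
    basal_glucose: float = 80.0
    basal_st: float = 34.5
    basal_hr: float = 72.0

    def __post_init__(self):
        for name in ("age", "height", "weight", "mean_bp", "basal_cortisol",
                     "basal_glucose", "basal_st", "basal_hr"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be finite and positive, got {v!r}")
        if not np.isfinite(self.amplitude_cortisol) or self.amplitude_cortisol < 0:
            raise InvalidParameterError("amplitude_cortisol must be finite and >= 0")
        if not (0.0 <= self.acrophase < 24.0):
            raise InvalidParameterError(f"acrophase must lie in [0, 24), got {self.acrophase}")
        if self.schedule not in ("normal", "inverted"):
            raise InvalidParameterError(f"unknown schedule {self.schedule!r}")

    def with_inverted_schedule(self) -> "SubjectProfile":
        """Return the same subject on an inverted sleep schedule (12 h shift)."""
        return replace(self, schedule="inverted",
                       acrophase=(self.acrophase + 12.0) % 24.0)


@dataclass(frozen=True)
class StressEvent:
    """An acute stressor: onset, duration and per-biomarker gain and lag.

    The glucose response lags the cortisol response by default, matching
    the delayed glycaemic reaction seen during psychosocial stress tests.
    """

    onset: float
    duration: float = 15.0          # minutes
    intensity: float = 1.0          # dimensionless, 0 = no effect
    gain: dict = field(default_factory=lambda: {
        "cortisol": 0.8, "glucose": 0.3, "st": 0.02, "hr": 0.15})
    lag: dict = field(default_factory=lambda: {
        "cortisol": 3.0, "glucose": 15.0, "st": 1.0, "hr": 0.0})  # minutes
    decay_halflife: float = 15.0    # minutes

    def __post_init__(self):
        if self.intensity < 0 or not np.isfinite(self.intensity):
            raise InvalidParameterError("intensity must be finite and >= 0")
        if self.duration <= 0 or self.decay_halflife <= 0:
            raise InvalidParameterError("duration and decay_halflife must be positive")


@dataclass(frozen=True)
class PulseTrace:
    """A raw pulse waveform plus simulation ground truth."""

    sample_rate: float
    values: np.ndarray
    true_beat_times: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sample_rate


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _truncated_noise(clean: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise truncated so the series stays positive."""
    if sd < 0 or not np.isfinite(sd):
        raise InvalidParameterError("noise sd must be finite and >= 0")
    if sd == 0:
        return np.asarray(clean, dtype=float).copy()
    out = clean + rng.normal(0.0, sd, size=np.shape(clean))
    return np.maximum(out, _POSITIVITY_FLOOR)


def _circadian_bump(t: np.ndarray, acrophase: float,
                    kappa: float = CORTISOL_KAPPA,
                    skew: float = CORTISOL_SKEW) -> np.ndarray:
    """Unit-peak single-bump 24 h periodic shape, peak at ``acrophase``.

    A von-Mises-style bump with a phase-skew term. The skew vanishes at
    the peak and at the trough 12 h later, so both are located exactly.
    """
    phase = 2.0 * np.pi * (np.asarray(t, dtype=float) - acrophase) / 24.0
    return np.exp(kappa * (np.cos(phase - skew * np.sin(phase)) - 1.0))


def cortisol_day_curve(profile: SubjectProfile, times) -> np.ndarray:
    """Noiseless cortisol day curve (nM) for a subject."""
    base = profile.basal_cortisol + profile.amplitude_cortisol * _circadian_bump(
        times, profile.acrophase)
    if profile.coffee_habit:
        base = base * (1.0 + COFFEE_CORTISOL_UPLIFT)
    return base


def simulate_cortisol_diurnal(profile: SubjectProfile, times, noise_sd: float,
                              seed: int) -> np.ndarray:
    """Simulate a circadian cortisol series (nM) at the given clock times."""
    times = np.asarray(times, dtype=float)
    if np.any((times < 0) | (times >= 24.0)):
        raise InvalidParameterError("times must lie in [0, 24)")
    return _truncated_noise(cortisol_day_curve(profile, times), noise_sd, _rng(seed))


def glucose_pulse_kernel(x_hours: np.ndarray,
                         rise: float = GLUCOSE_PULSE_RISE_H) -> np.ndarray:
    """Unit-peak meal-response kernel: linear-times-exponential rise/decay.

    Peaks exactly ``rise`` hours after the meal; zero before the meal.
    """
    x = np.asarray(x_hours, dtype=float)
    out = np.where(x > 0, (x / rise) * np.exp(1.0 - x / rise), 0.0)
    return out


def glucose_day_curve(profile: SubjectProfile, times, meal_times,
                      meal_amplitude: float) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    g = np.full_like(times, profile.basal_glucose, dtype=float)
    for m in meal_times:
        g = g + meal_amplitude * glucose_pulse_kernel(times - m)
    return g


def simulate_glucose(profile: SubjectProfile, times, meal_times=DEFAULT_MEAL_TIMES,
                     meal_amplitude: float = 40.0, noise_sd: float = 0.0,
                     seed: int = 0) -> np.ndarray:
    """Simulate sweat glucose (uM): basal level plus one pulse per meal."""
    if meal_amplitude < 0:
        raise InvalidParameterError("meal_amplitude must be >= 0")
    meal_times = np.asarray(meal_times, dtype=float)
    if meal_times.size and np.any((meal_times < 0) | (meal_times >= 24.0)):
        raise InvalidParameterError("meal_times must lie in [0, 24)")
    clean = glucose_day_curve(profile, times, meal_times, meal_amplitude)
    return _truncated_noise(clean, noise_sd, _rng(seed))


def simulate_st_hr(profile: SubjectProfile, times, noise_sd_st: float = 0.0,
                   noise_sd_hr: float = 0.0, seed: int = 0):
    """Simulate skin temperature (degC) and heart rate (bpm).

    Both are stationary around the subject's basal values; an exercise
    habit lowers the HR baseline by :data:`EXERCISE_HR_OFFSET`.
    """
    times = np.asarray(times, dtype=float)
    rng = _rng(seed)
    st_clean = np.full_like(times, profile.basal_st, dtype=float)
    hr_base = profile.basal_hr - (EXERCISE_HR_OFFSET if profile.exercise_habit else 0.0)
    if hr_base <= 0:
        raise InvalidParameterError("basal_hr minus exercise offset must stay positive")
    hr_clean = np.full_like(times, hr_base, dtype=float)
    st = _truncated_noise(st_clean, noise_sd_st, rng)
    hr = _truncated_noise(hr_clean, noise_sd_hr, rng)
    return st, hr


def stress_kernel(x_hours: np.ndarray, duration_min: float,
                  decay_halflife_min: float) -> np.ndarray:
    """Unit-peak rise-and-decay acute-stress kernel.

    Smooth rise from the (lag-shifted) onset to a peak shortly after the
    stressor ends, then exponential decay with the given half-life.
    Identically zero for x <= 0, so there is no anticipatory effect.
    """
    x = np.asarray(x_hours, dtype=float)
    t_peak = duration_min / 60.0 + STRESS_PEAK_DELAY_H
    halflife_h = decay_halflife_min / 60.0
    u = np.clip(x / t_peak, 0.0, 1.0)
    rise = u * u * (3.0 - 2.0 * u)           # smoothstep, unit at the peak
    decay = np.where(x > t_peak,
                     np.exp(-np.log(2.0) * (x - t_peak) / halflife_h), 1.0)
    return np.where(x > 0, rise * decay, 0.0)


def inject_stress_response(times, series_map: dict, event: StressEvent) -> dict:
    """Apply an acute-stress perturbation to a map of biomarker series.

    Each series is multiplied by ``1 + intensity * gain_b * k(t - onset -
    lag_b)`` where ``k`` is the unit-peak :func:`stress_kernel`. Values
    before ``onset + lag`` are conserved exactly.
    """
    times = np.asarray(times, dtype=float)
    for key in set(event.gain) | set(event.lag):
        if key not in BIOMARKERS:
            raise KeyError(f"unknown biomarker {key!r} in stress event gain/lag")
    if not (times.min() <= event.onset <= times.max()):
        raise InvalidParameterError("event onset outside the series time span")
    out = {}
    for name, series in series_map.items():
        series = np.asarray(series, dtype=float)
        gain = event.gain.get(name, 0.0)
        lag_h = event.lag.get(name, 0.0) / 60.0
        k = stress_kernel(times - event.onset - lag_h,
                          event.duration, event.decay_halflife)
        out[name] = series * (1.0 + event.intensity * gain * k)
    return out


def simulate_pulse_trace(hr: float, duration: float = 30.0,
                         sample_rate: float = 1000.0,
                         snr_db: float = np.inf, seed: int = 0) -> PulseTrace:
    """Synthesize a raw pulse waveform at a given heart rate.

    Each beat is the sum of three Gaussian bumps — percussion, tidal and
    dicrotic waves in decreasing amplitude at fixed intra-beat offsets —
    repeated at the beat period 60/hr, plus white noise at the requested
    signal-to-noise ratio (``snr_db = inf`` for a noiseless trace).
    ``true_beat_times`` records the percussion-peak times as ground truth.
    """
    if not (30.0 <= hr <= 200.0):
        raise InvalidParameterError(f"hr must lie in [30, 200] bpm, got {hr}")
    if duration < 10.0:
        raise InvalidParameterError("duration must be >= 10 s")
    if sample_rate <= 2.0 * PULSE_MAX_HARMONIC_HZ:
        raise InvalidParameterError(
            f"sample_rate {sample_rate} Hz below Nyquist for pulse harmonics "
            f"(need > {2 * PULSE_MAX_HARMONIC_HZ} Hz)")
    period = 60.0 / hr
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    beat_times = np.arange(0.5 * period, duration - 0.25 * period, period)
    clean = np.zeros_like(t)
    for amp, off, width in zip(PULSE_AMPLITUDES, PULSE_OFFSETS, PULSE_WIDTHS):
        centers = beat_times[:, None] + off * period
        clean += amp * np.exp(-0.5 * ((t[None, :] - centers) / (width * period)) ** 2).sum(axis=0)
    if np.isfinite(snr_db):
        signal_power = float(np.var(clean))
        noise_sd = np.sqrt(signal_power / 10.0 ** (snr_db / 10.0))
        values = clean + _rng(seed).normal(0.0, noise_sd, size=clean.shape)
    else:
        values = clean
    return PulseTrace(sample_rate=sample_rate, values=values,
                      true_beat_times=beat_times)


def scale_bounds(kind: str):
    if kind not in SCALES:
        raise InvalidParameterError(f"unknown scale kind {kind!r}; expected one of {sorted(SCALES)}")
    lo, hi, _, _ = SCALES[kind]
    return lo, hi


def scale_normalize(score, kind: str):
    """Map a raw scale score onto [0, 1] over its admissible range."""
    lo, hi = scale_bounds(kind)
    return (np.asarray(score, dtype=float) - lo) / (hi - lo)


def generate_scale_scores(latent_stress, kind: str, noise_sd: float = 0.0,
                          seed: int = 0):
    """Psychometric score as an affine map of latent stress, clipped to range."""
    if np.any(np.asarray(latent_stress) < 0):
        raise InvalidParameterError("latent_stress must be >= 0")
    lo, hi, intercept, slope = SCALES[kind] if kind in SCALES else (None,) * 4
    if lo is None:
        raise InvalidParameterError(f"unknown scale kind {kind!r}")
    raw = intercept + slope * np.asarray(latent_stress, dtype=float)
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if noise_sd > 0:
        raw = raw + _rng(seed).normal(0.0, noise_sd, size=np.shape(raw))
    return np.clip(raw, lo, hi)


# ---------------------------------------------------------------------------
# Cohort designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Design of the synthetic depression cohort.

    The default reproduces the study layout: 26 healthy-side subjects
    (14 non-depressed + 12 at depression risk) and 23 patient-side
    subjects (13 mild + 10 severe), each measured three times at random
    clock times in the 08:00-22:00 window, giving 147 rows.

    ``biomarker_effects`` are per-unit-latent-level effects: relative for
    cortisol and glucose, absolute for skin temperature (degC) and heart
    rate (bpm). The defaults realize a deliberately separable design:
    the cortisol effect of 0.35 per level puts adjacent groups roughly
    three between-subject standard deviations apart on the adjusted
    scale (gap ~56 nM vs spread ~20 nM), so a competent classifier
    should resolve the four groups. Setting every effect to zero
    decouples the biomarkers from the labels, which downstream
    classifiers must then fail on.
    """

    group_counts: dict = field(default_factory=lambda: {
        "ND": 14, "DR": 12, "MD": 13, "SD": 10})
    group_levels: dict = field(default_factory=lambda: {
        "ND": 0.0, "DR": 1.0, "MD": 2.0, "SD": 3.0})
    repeats: int = 3
    biomarker_effects: dict = field(default_factory=lambda: {
        "cortisol": 0.35, "glucose": 0.15, "st": 0.3, "hr": 8.0})
    latent_sd: float = 0.15
    scale_noise_sd: dict = field(default_factory=lambda: {
        "SCL90": 6.0, "SDS": 2.0, "SAS": 2.0})
    measurement_noise: dict = field(default_factory=lambda: {
        "cortisol": 4.0, "glucose": 3.0, "st": 0.1, "hr": 2.0})
    meal_amplitude: float = 30.0
    window: tuple = DAY_WINDOW

    def __post_init__(self):
        missing = set(self.group_counts) - set(self.group_levels)
        if missing:
            raise ConfigError(f"group_levels missing groups: {sorted(missing)}")
        missing_fx = set(BIOMARKERS) - set(self.biomarker_effects)
        if missing_fx:
            raise ConfigError(f"biomarker_effects missing biomarkers: {sorted(missing_fx)}")
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")


def draw_profile(rng: np.random.Generator, subject_id: str,
                 group: str = "healthy") -> SubjectProfile:
    """Draw a random subject profile with realistic between-subject spread."""
    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        gender=("M" if rng.random() < 0.5 else "F"),
        age=float(rng.integers(27, 72)),
        height=float(rng.normal(168.0, 8.0)),
        weight=float(rng.normal(68.0, 10.0)),
        mean_bp=float(rng.normal(92.0, 8.0)),
        acrophase=DEFAULT_ACROPHASE,
        amplitude_cortisol=float(max(rng.normal(60.0, 8.0), 20.0)),
        basal_cortisol=float(max(rng.normal(100.0, 6.0), 40.0)),
        basal_glucose=float(max(rng.normal(80.0, 5.0), 30.0)),
        basal_st=float(rng.normal(34.5, 0.2)),
        basal_hr=float(max(rng.normal(72.0, 4.0), 45.0)),
    )


def generate_depression_cohort(design: CohortDesign | None = None,
                               seed: int = 0) -> pd.DataFrame:
    """Generate the synthetic depression cohort table.

    One row per (subject, repeat): biomarker panel at the measurement
    time, demographics, three chronic-stress scale scores (SCL-90, SDS,
    SAS), the group label and the simulation-truth latent stress level.
    """
    design = design or CohortDesign()
    rng = _rng(seed)
    rows = []
    sid = 0
    for group in sorted(design.group_counts):
        level = design.group_levels[group]
        fx = design.biomarker_effects
        for _ in range(design.group_counts[group]):
            sid += 1
            subject_id = f"S{sid:03d}"
            profile = draw_profile(rng, subject_id, group=group)
            latent = max(level + rng.normal(0.0, design.latent_sd), 0.0)
            scl90 = float(generate_scale_scores(
                latent, "SCL90", design.scale_noise_sd["SCL90"],
                seed=rng.integers(2 ** 31)))
            sds = float(generate_scale_scores(
                latent, "SDS", design.scale_noise_sd["SDS"],
                seed=rng.integers(2 ** 31)))
            sas = float(generate_scale_scores(
                latent, "SAS", design.scale_noise_sd["SAS"],
                seed=rng.integers(2 ** 31)))
            lo, hi = design.window
            times = rng.uniform(lo, hi, size=design.repeats)
            noise = design.measurement_noise
            cort = cortisol_day_curve(profile, times) * (1.0 + fx["cortisol"] * level)
            glu = glucose_day_curve(profile, times, DEFAULT_MEAL_TIMES,
                                    design.meal_amplitude) * (1.0 + fx["glucose"] * level)
            st = np.full(design.repeats, profile.basal_st + fx["st"] * level)
            hr = np.full(design.repeats, profile.basal_hr + fx["hr"] * level)
            cort = _truncated_noise(cort, noise["cortisol"], rng)
            glu = _truncated_noise(glu, noise["glucose"], rng)
            st = _truncated_noise(st, noise["st"], rng)
            hr = _truncated_noise(hr, noise["hr"], rng)
            for r in range(design.repeats):
                rows.append({
                    "subject_id": subject_id, "group": group,
                    "repeat": r, "time": float(times[r]),
                    "cortisol": float(cort[r]), "glucose": float(glu[r]),
                    "st": float(st[r]), "hr": float(hr[r]),
                    "gender": profile.gender, "age": profile.age,
                    "height": profile.height, "weight": profile.weight,
                    "mean_bp": profile.mean_bp,
                    "scl90": scl90, "sds": sds, "sas": sas,
                    "latent_stress": latent,
                })
    return pd.DataFrame(rows)


def generate_weight_recovery_data(n: int, weights, intercept: float,
                                  noise_sd: float, seed: int):
    """Acute-stress calibration data: relative deviations and STAI-S scores.

    Deviations are drawn independently per biomarker; the score is the
    affine combination ``intercept + weights . deviations`` plus Gaussian
    noise — the generating model the multiple-linear-regression stage is
    supposed to recover.
    """
    weights = np.asarray(weights, dtype=float)
    rng = _rng(seed)
    deviations = rng.uniform(-0.2, 0.6, size=(n, weights.size))
    scores = intercept + deviations @ weights + rng.normal(0.0, noise_sd, size=n)
    return deviations, scores


def generate_as_cohort(n_per_level: int = 20, dev_noise_sd: float = 0.02,
                       score_noise_sd: float = 2.0, seed: int = 0) -> pd.DataFrame:
    """Acute-stress cohort with well-separated low/mid/high latent levels.

    Latent levels 1/2/3 map through the STAI-S anchors to scores around
    29/39/49, straddling the 34 and 44 cutpoints. Per-biomarker relative
    deviations (cortisol, glucose, hr; skin temperature excluded as in a
    cold-pressor setting) are proportional to the latent level.
    """
    rng = _rng(seed)
    dev_slopes = {"cortisol": 0.20, "glucose": 0.10, "hr": 0.05}
    rows = []
    for level_name, level in (("low", 1.0), ("mid", 2.0), ("high", 3.0)):
        for i in range(n_per_level):
            latent = level
            devs = {b: s * latent + rng.normal(0.0, dev_noise_sd)
                    for b, s in dev_slopes.items()}
            score = float(generate_scale_scores(
                latent, "STAIS", score_noise_sd, seed=rng.integers(2 ** 31)))
            rows.append({"level": level_name, "latent": latent,
                         "stais": score, **{f"dev_{b}": v for b, v in devs.items()}})
    return pd.DataFrame(rows)


def simulate_tsst_panel(profile: SubjectProfile, seed: int = 0,
                        start: float = 15.0, end: float = 18.0,
                        step_min: float = 2.0,
                        event: StressEvent | None = None) -> pd.DataFrame:
    """Panel time series around a psychosocial stress-test session.

    Simulates the four biomarkers on a regular grid across the session
    and injects one acute-stress event (default onset 30 min after the
    recording starts). Returns a tidy frame with a ``time`` column in
    clock hours.
    """
    times = np.arange(start, end, step_min / 60.0)
    event = event or StressEvent(onset=start + 0.5, duration=30.0,
                                 intensity=1.0, decay_halflife=15.0)
    rng = _rng(seed)
    series = {
        "cortisol": simulate_cortisol_diurnal(profile, times, 2.0, rng.integers(2 ** 31)),
        "glucose": simulate_glucose(profile, times, noise_sd=2.0,
                                    seed=rng.integers(2 ** 31)),
    }
    st, hr = simulate_st_hr(profile, times, 0.05, 1.0, rng.integers(2 ** 31))
    series["st"], series["hr"] = st, hr
    series = inject_stress_response(times, series, event)
    out = pd.DataFrame({"subject_id": profile.subject_id, "time": times, **series})
    return out
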