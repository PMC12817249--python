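"""End-to-end scenario pipelines: simulate -> fit -> index -> classify.

Each scenario reproduces one of the study designs on synthetic data:

* ``circadian`` — full-day cortisol/glucose/ST/HR tracking for a
  normal-schedule and an inverted-schedule subject, plus an STL
  characterization of the pooled cortisol series.
* ``tsst`` — a psychosocial stress-test session: SSCI1 stream against a
  pre-test control and the 80%-of-reference-maximum warning trigger.
* ``cpt`` — a cold-pressor-style acute-stress cohort: impact weights by
  multiple linear regression of STAI-S on biomarker deviations (skin
  temperature excluded), SSCI2 scoring and the 34/44 three-state
  classification.
* ``depression`` — the chronic-stress cohort: reference baseline
  fitting, temporally-adjusted features, subject-level 117:30 split,
  the five-classifier comparison, the SSCI3 regression and the
  with/without-temporal-processing stability comparison.
* ``fatloss`` — two weeks of twice-daily tracking during an exercise and
  diet intervention; evening samples retro-adjusted to the 08:00
  benchmark and scored with the depression-trained SSCI3 regressor.

``run_pipeline`` writes every stage output under the configured
directory along with a manifest (config hash, seed, library versions,
stage timings) sufficient to re-run deterministic stages bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import baseline, chronic, cohort, indices, io
from .errors import ConfigError

SCENARIOS = ("circadian", "tsst", "cpt", "depression", "fatloss")


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    seed: int = 0
    scenario: str = "depression"
    include_st: bool = True
    cutpoint_low: float = indices.AS_CUTPOINT_LOW
    cutpoint_high: float = indices.AS_CUTPOINT_HIGH
    warning_fraction: float = indices.DEFAULT_WARNING_FRACTION
    benchmark_time: float = baseline.BENCHMARK_TIME
    candidate_families: tuple = ("cosinor", "harmonic2", "skewed_peak", "constant")
    test_subjects: int = 10
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; "
                              f"expected one of {SCENARIOS}")
        if not self.cutpoint_low < self.cutpoint_high:
            raise ConfigError("cutpoint_low must be < cutpoint_high")
        if not (0.0 < self.warning_fraction <= 1.0):
            raise ConfigError("warning_fraction must lie in (0, 1]")
        for fam in self.candidate_families:
            if fam not in baseline.FAMILY_PARAMS:
                raise ConfigError(f"unknown candidate family {fam!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _subseed(seed: int, k: int) -> int:
    return int(np.random.default_rng([seed, k]).integers(2 ** 31))


# ---------------------------------------------------------------------------
# Scenario stages (pure computation; writing happens in run_pipeline)
# ---------------------------------------------------------------------------

def run_circadian(config: PipelineConfig) -> dict:
    rng = np.random.default_rng(config.seed)
    normal = cohort.draw_profile(rng, "C01")
    inverted = cohort.draw_profile(rng, "C02").with_inverted_schedule()
    times = np.arange(0.0, 72.0, 0.5) % 24.0  # three days, 30-min grid
    days = np.arange(0.0, 72.0, 0.5)
    frames = []
    for profile in (normal, inverted):
        cort = cohort.simulate_cortisol_diurnal(profile, times, 3.0,
                                                _subseed(config.seed, 1))
        glu = cohort.simulate_glucose(profile, times, noise_sd=3.0,
                                      seed=_subseed(config.seed, 2))
        st, hr = cohort.simulate_st_hr(profile, times, 0.1, 2.0,
                                       _subseed(config.seed, 3))
        frames.append(pd.DataFrame({
            "subject_id": profile.subject_id, "schedule": profile.schedule,
            "elapsed_h": days, "time": times, "cortisol": cort,
            "glucose": glu, "st": st, "hr": hr}))
    panel = pd.concat(frames, ignore_index=True)
    one = frames[0]
    stl = baseline.stl_characterize(one["elapsed_h"], one["cortisol"], period=24.0)
    seasonal_share = float(np.var(stl["seasonal"])
                           / max(np.var(stl["resampled"]), 1e-12))
    return {"panel": panel, "stl": stl, "seasonal_variance_share": seasonal_share,
            "profiles": {"normal": normal, "inverted": inverted}}


def run_tsst(config: PipelineConfig) -> dict:
    rng = np.random.default_rng(config.seed)
    profile = cohort.draw_profile(rng, "T01")
    panel = cohort.simulate_tsst_panel(profile, seed=_subseed(config.seed, 1))
    # control: mean of the pre-stress stable period (first 15 minutes)
    pre = panel[panel["time"] < panel["time"].iloc[0] + 0.25]
    control = indices.ControlValues(
        values={b: float(pre[b].mean()) for b in cohort.BIOMARKERS},
        source="stable_period")
    ssci1 = np.array([
        indices.compute_ssci1({b: row[b] for b in cohort.BIOMARKERS}, control)
        for _, row in panel.iterrows()])
    reference_max = float(ssci1.max())
    trigger = indices.warning_trigger(panel["time"].to_numpy(), ssci1,
                                      reference_max,
                                      fraction=config.warning_fraction)
    return {"panel": panel, "control": control, "ssci1": ssci1,
            "reference_max": reference_max, "trigger_time": trigger}


def run_cpt(config: PipelineConfig, n_per_level: int = 20) -> dict:
    table = cohort.generate_as_cohort(n_per_level=n_per_level,
                                      seed=_subseed(config.seed, 1))
    dev_cols = ["dev_cortisol", "dev_glucose", "dev_hr"]
    if config.include_st and "dev_st" in table.columns:
        dev_cols.append("dev_st")
    weights = indices.estimate_weights_mlr(
        table[dev_cols].to_numpy(), table["stais"].to_numpy(),
        biomarker_names=[c.removeprefix("dev_") for c in dev_cols])
    predicted = np.array([
        indices.compute_ssci2(
            {c.removeprefix("dev_"): row[c] for c in dev_cols},
            weights, with_intercept=True)
        for _, row in table.iterrows()])
    truth = [indices.classify_as_state(s, config.cutpoint_low,
                                       config.cutpoint_high).state
             for s in table["stais"]]
    pred = [indices.classify_as_state(s, config.cutpoint_low,
                                      config.cutpoint_high).state
            for s in predicted]
    accuracy = float(np.mean(np.asarray(truth) == np.asarray(pred)))
    corr = float(np.corrcoef(predicted, table["stais"])[0, 1])
    return {"table": table, "weights": weights, "predicted_scores": predicted,
            "true_states": truth, "predicted_states": pred,
            "accuracy": accuracy, "score_correlation": corr}


def run_depression(config: PipelineConfig,
                   design: cohort.CohortDesign | None = None) -> dict:
    table = cohort.generate_depression_cohort(design,
                                              seed=_subseed(config.seed, 1))
    models = baseline.fit_reference_baselines(seed=_subseed(config.seed, 2))
    labels = chronic.make_labels(table)
    table = pd.concat([table, labels], axis=1)
    train, test = chronic.split_cohort(table, config.test_subjects,
                                       seed=_subseed(config.seed, 3))
    X_train = chronic.assemble_features(train, models, temporal=True)
    X_test = chronic.assemble_features(test, models, temporal=True)
    bundle = chronic.train_classifiers(X_train, train["class4"],
                                       seed=_subseed(config.seed, 4))
    metrics = chronic.evaluate(bundle, X_test, test["class4"], test["class2"])
    reg = chronic.regress_ssci3(X_train, train["composite_score"],
                                X_test, test["composite_score"])
    # one mild-depression-level subject tracked across the day: their
    # composite sits well away from zero, so relative SDs are meaningful
    rng = np.random.default_rng(_subseed(config.seed, 5))
    profile = cohort.draw_profile(rng, "D_track", group="MD")
    dsn = design or cohort.CohortDesign()
    level = dsn.group_levels["MD"]
    fx = dsn.biomarker_effects
    t_track = np.linspace(8.0, 22.0, 8)
    day = pd.DataFrame({
        "subject_id": profile.subject_id, "time": t_track,
        "cortisol": cohort.simulate_cortisol_diurnal(
            profile, t_track, 3.0, _subseed(config.seed, 6))
        * (1.0 + fx["cortisol"] * level),
        "glucose": cohort.simulate_glucose(
            profile, t_track, noise_sd=3.0, seed=_subseed(config.seed, 7))
        * (1.0 + fx["glucose"] * level),
        "st": profile.basal_st + fx["st"] * level,
        "hr": profile.basal_hr + fx["hr"] * level,
        "gender": profile.gender, "age": profile.age,
        "height": profile.height, "weight": profile.weight,
        "mean_bp": profile.mean_bp})
    stability = chronic.stability_comparison(day, models, reg["regressor"],
                                             bundle)
    return {"table": table, "models": models, "train": train, "test": test,
            "bundle": bundle, "metrics": metrics, "regression": reg,
            "stability": stability}


def run_fatloss(config: PipelineConfig, n_days: int = 14) -> dict:
    dep = run_depression(config)
    rng = np.random.default_rng(_subseed(config.seed, 10))
    profile = cohort.draw_profile(rng, "F01")
    rows = []
    for day in range(n_days):
        # training stress accumulates until the mid-regimen break day
        load = min(day, 9) / 9.0 * (0.25 if day < 10 else 0.15)
        for t in (8.0, 20.0):
            cort = float(cohort.simulate_cortisol_diurnal(
                profile, [t], 3.0, _subseed(config.seed, 100 + 2 * day))[0] * (1 + load))
            glu = float(cohort.simulate_glucose(
                profile, [t], noise_sd=3.0,
                seed=_subseed(config.seed, 101 + 2 * day))[0])
            rows.append({
                "subject_id": profile.subject_id, "day": day + 1, "time": t,
                "cortisol": cort, "glucose": glu,
                "st": profile.basal_st, "hr": profile.basal_hr,
                "gender": profile.gender, "age": profile.age,
                "height": profile.height,
                "weight": profile.weight - 0.15 * min(day, 10),
                "mean_bp": profile.mean_bp})
    table = pd.DataFrame(rows)
    X = chronic.assemble_features(table, dep["models"], temporal=True)
    table["ssci3"] = dep["regression"]["regressor"].predict(X)
    return {"table": table, "models": dep["models"]}


_RUNNERS = {"circadian": run_circadian, "tsst": run_tsst, "cpt": run_cpt,
            "depression": run_depression, "fatloss": run_fatloss}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run one scenario end to end and write its outputs and manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = _time.perf_counter()
    result = _RUNNERS[config.scenario](config)
    elapsed = _time.perf_counter() - t0
    _write_outputs(config, result, out_dir)
    import scipy
    import sklearn
    import statsmodels
    manifest = {
        "scenario": config.scenario, "seed": config.seed,
        "config": asdict(config), "config_hash": config.config_hash(),
        "elapsed_s": round(elapsed, 3),
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__,
                     "statsmodels": statsmodels.__version__,
                     "sklearn": sklearn.__version__},
    }
    io.dump_json(manifest, out_dir / "manifest.json")
    result["manifest"] = manifest
    return result


def _write_outputs(config: PipelineConfig, result: dict, out_dir: Path) -> None:
    s = config.scenario
    if s == "circadian":
        io.write_table(result["panel"], out_dir / "circadian_panel.csv")
        io.dump_json({"seasonal_variance_share": result["seasonal_variance_share"]},
                     out_dir / "circadian_stl.json")
    elif s == "tsst":
        df = result["panel"].copy()
        df["ssci1"] = result["ssci1"]
        io.write_table(df, out_dir / "tsst_ssci1.csv")
        io.dump_json({"reference_max": result["reference_max"],
                      "warning_fraction": config.warning_fraction,
                      "trigger_time": result["trigger_time"]},
                     out_dir / "tsst_warning.json")
    elif s == "cpt":
        io.write_table(result["table"], out_dir / "cpt_cohort.csv")
        result["weights"].save(out_dir / "cpt_weights.json")
        io.dump_json({"accuracy": result["accuracy"],
                      "score_correlation": result["score_correlation"]},
                     out_dir / "cpt_metrics.json")
    elif s == "depression":
        io.write_table(result["table"], out_dir / "depression_cohort.csv")
        for b, model in result["models"].items():
            model.save(out_dir / f"baseline_{b}.json")
        summary = {name: {"accuracy4": m["accuracy4"],
                          "accuracy2": m["accuracy2"],
                          "roc_auc": m.get("roc_auc"),
                          "pr_auc": m.get("pr_auc")}
                   for name, m in result["metrics"].items()}
        summary["ssci3_test_corr"] = result["regression"].get("test_corr")
        summary["stability"] = {
            "rsd_adjusted": result["stability"]["rsd_adjusted"],
            "rsd_raw": result["stability"]["rsd_raw"]}
        io.dump_json(summary, out_dir / "depression_metrics.json")
    elif s == "fatloss":
        io.write_table(result["table"], out_dir / "fatloss_tracking.csv")
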