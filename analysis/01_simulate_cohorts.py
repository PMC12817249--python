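#!/usr/bin/env python
"""Generate the synthetic study datasets every later stage consumes.

Writes, under results/: the two-subject circadian tracking panel
(normal vs inverted sleep schedule), the stress-test session panel, the
acute-stress calibration cohort, and the 147-row depression cohort.
"""

from pathlib import Path

import numpy as np

from stressci import cohort, pipeline

SEED = 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for scenario in ("circadian", "tsst", "cpt", "depression"):
        config = pipeline.PipelineConfig(out_dir=str(OUT), seed=SEED,
                                         scenario=scenario)
        pipeline.run_pipeline(config)
        print(f"[01] wrote {scenario} outputs")

    table = cohort.generate_depression_cohort(seed=SEED)
    subjects = table.drop_duplicates("subject_id")
    patient = subjects["group"].isin(["MD", "SD"]).sum()
    print(f"[01] depression cohort: {len(table)} rows, "
          f"{len(subjects)} subjects ({patient} patient-side, "
          f"{len(subjects) - patient} healthy-side), "
          f"{table.groupby('subject_id').size().iloc[0]} repeats each")
    grid = np.arange(0.0, 24.0, 1.0 / 60.0)
    prof = cohort.draw_profile(np.random.default_rng(SEED), "demo")
    curve = cohort.cortisol_day_curve(prof, grid)
    print(f"[01] demo subject cortisol peaks at "
          f"{grid[np.argmax(curve)]:.2f} h (acrophase {prof.acrophase})")


if __name__ == "__main__":
    main()
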