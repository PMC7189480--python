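"""Simulated feedback intensities of the classical and time-to-target models.

The classical model probes one fitted movement per condition with a virtual
2 cm target jump at every time step.  The time-to-target model re-plans the
post-perturbation movement with the behaviorally observed time-to-target as
its horizon (taken here from the synthetic ground-truth tables) at the five
experimental perturbation locations.
"""

from pathlib import Path

import pandas as pd

from reachofc.finite_horizon import (
    classical_intensity_profile,
    fit_kinematic_condition,
    ttt_intensity_at_location,
)
from reachofc.plant import PlantParams, build_plant
from reachofc.synthetic import GroundTruth

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

system = build_plant(PlantParams())
truth = GroundTruth()
LOCATIONS_CM = truth.geometry.perturbation_locations_cm

CONDS = {
    "baseline": (50.0, "baseline"),
    "late-peak": (66.0, "matched-cursor-late"),
    "early-peak": (33.0, "matched-cursor-early"),
}

classical_rows, ttt_rows = [], []
for label, (peak_loc, truth_cond) in CONDS.items():
    fit = fit_kinematic_condition(system, 0.5, peak_loc, seed=61)
    prof = classical_intensity_profile(system, fit, condition=label)
    for step, t, v in zip(prof.onset_steps, prof.onset_times, prof.intensities):
        classical_rows.append(
            {"condition": label, "onset_step": step, "onset_s": t, "intensity_N": v}
        )
    peak_step = prof.intensities.argmax()
    print(f"classical {label}: N={fit.n_steps * 10} ms, peak intensity "
          f"{prof.intensities.max():.2f} N at {peak_step * 10} ms")
    for loc in LOCATIONS_CM:
        ttt = truth.time_to_target_ms(truth_cond, loc)
        v = ttt_intensity_at_location(system, fit, loc / 100.0, ttt)
        ttt_rows.append(
            {"condition": label, "location_cm": loc, "time_to_target_ms": ttt,
             "intensity_N": v}
        )

pd.DataFrame(classical_rows).to_csv(OUT / "classical_intensities.csv", index=False)
ttt_df = pd.DataFrame(ttt_rows)
ttt_df.to_csv(OUT / "ttt_intensities.csv", index=False)

pv = ttt_df.pivot(index="location_cm", columns="condition", values="intensity_N")
print("\ntime-to-target model intensities (N):")
print(pv.round(3).to_string())
print("\ncondition ordering early < baseline < late at every location:",
      bool((pv["early-peak"] < pv["baseline"]).all()
           and (pv["baseline"] < pv["late-peak"]).all()))
print(f"wrote {OUT / 'classical_intensities.csv'} and {OUT / 'ttt_intensities.csv'}")
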