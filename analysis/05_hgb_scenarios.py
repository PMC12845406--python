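#!/usr/bin/env python
"""Haemoglobin exposure scenarios.

Simulates the four scenario cohorts (low HGB 73 vs normal HGB 120 g/L,
two occasions each, 100 virtual patients weighing Normal(43.03, 9.89) kg,
5 mg/kg per administration every 12 h) and summarises steady-state AUC,
Cmin and Cmax, plus the relative Cmin gap between the haemoglobin groups.
"""

import argparse
from pathlib import Path

import pandas as pd

from cyclopk import FixedEffects, RandomEffectsSpec, simulate_scenario
from cyclopk.scenario import ScenarioSpec, scenario_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    fe, re = FixedEffects(), RandomEffectsSpec()
    tabs = {
        "low HGB": simulate_scenario(ScenarioSpec(hgb_gL=73.0, seed=args.seed), fe, re),
        "normal HGB": simulate_scenario(ScenarioSpec(hgb_gL=120.0, seed=args.seed + 1), fe, re),
    }
    table = scenario_table(tabs)
    table.to_csv(RESULTS / "scenario_summary.csv")
    records = pd.concat(
        [t.records.assign(scenario=n) for n, t in tabs.items()], ignore_index=True
    )
    records.to_csv(RESULTS / "scenario_records.csv", index=False)
    print(table.to_string())

    for occ in (1, 2):
        lo = tabs["low HGB"].median("CMIN", occ)
        hi = tabs["normal HGB"].median("CMIN", occ)
        print(f"occasion {occ}: median Cmin {hi:.0f} vs {lo:.0f} ng/mL -> "
              f"{100*(hi-lo)/lo:.1f}% higher at normal HGB")
    print("\nLower haemoglobin raises CL/F and depresses the trough far more "
          "than the peak or AUC; anaemic patients are the ones most at risk "
          "of sub-target troughs at the same mg/kg dose.")


if __name__ == "__main__":
    main()
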