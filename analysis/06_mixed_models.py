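#!/usr/bin/env python
"""Mixed-effects models on the simulated battery.

Fits the logistic random-intercept rejection model (group and dissociality
variants) and the quadratic fairness-rating model, prints the coefficient
tables with odds ratios, and exponentiates the published rejection-model
coefficients as an arithmetic cross-check.
"""

import argparse
import json
from pathlib import Path

from coopbattery import battery_io as bio
from coopbattery import mixed_models as mm
from coopbattery.battery_io import _glmm_json
from coopbattery.reference_tables import UG_GLMM_COEFS


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--trials", type=Path, default=Path("results/trials.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    trials = bio.load_trials(args.trials)
    ug = trials[trials["task"] == "ug"]
    fair = trials[trials["task"] == "fairness"]

    report = {}
    res = mm.fit_ug_glmm(ug, predictor="group")
    report["ug_group"] = _glmm_json(res)
    print("== rejection model (group) ==")
    print(res.to_frame()[["b", "se", "t", "p", "odds_ratio"]].round(3))
    print("random-intercept SD:", round(res.random_intercept_sd, 3))

    res_d = mm.fit_ug_glmm(ug, predictor="dissociality")
    report["ug_dissociality"] = _glmm_json(res_d)
    print("\n== rejection model (dissociality) ==")
    print(res_d.to_frame()[["b", "se", "t", "p", "odds_ratio"]].round(3))

    res_f = mm.fit_fairness_lmm(fair)
    report["fairness"] = _glmm_json(res_f)
    print("\n== fairness model (linear + quadratic offer) ==")
    print(res_f.to_frame()[["b", "se", "t", "p"]].round(3))

    print("\n== published coefficients exponentiated ==")
    for name in ("offer", "group"):
        b = UG_GLMM_COEFS[name]
        print(f"  {name}: b = {b} -> OR = {mm.or_from_coef(b):.3f}")

    args.out.mkdir(parents=True, exist_ok=True)
    with open(args.out / "glmm_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    print(f"\nwrote {args.out}/glmm_report.json")


if __name__ == "__main__":
    main()
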