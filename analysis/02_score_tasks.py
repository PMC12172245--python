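#!/usr/bin/env python
"""Score the SVO slider for every simulated participant.

Reports the angle and category distribution per group, the
prosocial-motivation index among consistently prosocial responders, and the
reduced sample sizes the consistency screen produces.
"""

import argparse
from pathlib import Path

import pandas as pd

from coopbattery import battery_io as bio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--trials", type=Path, default=Path("results/trials.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    trials = bio.load_trials(args.trials)
    res = bio.score_svo_table(trials)
    args.out.mkdir(parents=True, exist_ok=True)
    res.to_csv(args.out / "svo_results.csv", index=False)

    print("category distribution (%):")
    print((res.groupby("group")["svo_category"].value_counts(normalize=True) * 100).round(1))
    kept = res[res["consistent_primary"] & (res["consistent_secondary"] == True)]  # noqa: E712
    print("\nconsistency screen kept (PM analysis Ns):")
    print(kept.groupby("group").size())
    if len(kept):
        print("\nPM index among consistent responders:")
        print(kept.groupby("group")["pm_index"].agg(["mean", "std"]).round(3))
    print(f"\nwrote {args.out}/svo_results.csv")


if __name__ == "__main__":
    main()
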