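#!/usr/bin/env python
"""Run the dual-timescale estimation model over the full behavioral design
and compute the psychometric summaries: performance and reaction times by
change size and change time, instantaneous false-alarm rate, time-resolved
d', Erlang-CDF dynamics fit, and reaction-time AUROC.

Writes results/dual/{responses.csv, psychometrics.csv, dprime.csv,
fa_rate.csv, fits.json} via the experiment runner and prints the headline
numbers.
"""

import argparse
import json
from pathlib import Path

from tonecloud import behavior as bh
from tonecloud import experiment


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=str, default="results/dual")
    args = ap.parse_args()

    cfg = experiment.ExperimentConfig(seed=args.seed, model="dual",
                                      n_boot=200, out_dir=args.out)
    out = experiment.run_experiment(cfg)

    import pandas as pd
    rec = pd.read_csv(out / "responses.csv")
    n = len(rec)
    fa = (rec.outcome == "false_alarm").mean()
    print(f"{n} trials simulated at the published parameters "
          f"(tau_f=0.2, tau_s=1.1, tau_a=0.65 s, T=0.40): "
          f"{(rec.outcome == 'hit').mean():.0%} hits, {fa:.0%} false alarms")

    table = pd.read_csv(out / "psychometrics.csv")
    piv = table.pivot_table(index="size", columns="time_bin", values="performance")
    print("\nPerformance (hits / (hits+misses)), localized changes, by "
          "change size x change-time bin:")
    print(piv.round(2).to_string())
    print("Performance rises with both change size and change time, saturating "
          "for late changes - the signature of baseline-statistics estimation.")

    dist = pd.read_csv(out / "distance_performance.csv")
    print("\n110% changes by spectral separation of the incremented bins:")
    print(dist.round(2).to_string(index=False))
    print("Spreading the change across channels reduces detectability.")

    with open(out / "fits.json") as fh:
        fits = json.load(fh)
    if "erlang" in fits and "per_size" in fits["erlang"]:
        taus = {s: v["tau"] for s, v in fits["erlang"]["per_size"].items()}
        print(f"\nErlang-CDF dynamics (shared shape k={fits['erlang']['k']}): "
              f"time constants tau by size: "
              + ", ".join(f"{s}%: {t:.2f} s" for s, t in sorted(taus.items(), key=lambda kv: float(kv[0]))))
        print("The smallest change carries the slowest dynamics; adjacent sizes "
              "can swap at ~20 trials/cell (k and tau trade off).")

    hits = rec[(rec.outcome == "hit") & (rec.distance == 1)]
    med = hits.groupby("size").reaction_time.median()
    print("\nMedian reaction time by change size: "
          + ", ".join(f"{s}%: {v:.2f} s" for s, v in med.items()))

    far = pd.read_csv(out / "fa_rate.csv")
    early = far.fa_rate[far.t < 1].mean()
    late = far.fa_rate[(far.t >= 2) & (far.t < 6)].mean()
    print(f"\nInstantaneous FA rate: {early:.3f}/s in the first second "
          f"(initial hesitation), ~{late:.3f}/s thereafter (flat hazard)")

    auc = bh.auroc_by_change_size(bh.classify_frame(rec))
    print("\nReaction-time AUROC vs false-alarm pseudo-RTs by size:")
    print(auc.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
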