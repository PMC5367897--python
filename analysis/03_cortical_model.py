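#!/usr/bin/env python
"""Cortical-model analyses: change-locked average responses of the selected
modulation filter (0.72 Hz, 0.54 cyc/oct) versus the unselective summed
readout, and the collapsing-bound decision stage on a trial batch.

Writes results/cortical/{curves.csv, summed_curve.csv, responses.csv,
psychometrics.csv} and prints what the curves show.  Trial counts are kept
at 40/curve here for a quick look; the test suite runs the same analyses at
120/curve.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from tonecloud import cortical as cx
from tonecloud import dual_model as dm
from tonecloud import stimulus as st


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/cortical"))
    ap.add_argument("--n-trials", type=int, default=40)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    grid = st.build_frequency_grid()
    n = args.n_trials

    conditions = {"140% at 4.0 s": (140, 4.0), "140% at 0.5 s": (140, 0.5),
                  "50% at 4.0 s": (50, 4.0), "110% at 4.0 s": (110, 4.0)}
    rows = []
    ens = {}
    specs140 = None
    for label, (size, tc) in conditions.items():
        traces, specs = cx.condition_ensemble(size, tc, n, seed=args.seed * 1000 + size,
                                              grid=grid, keep_specs=(size == 140 and tc == 4.0))
        ens[label] = traces
        if specs:
            specs140 = specs
        m = traces.mean(axis=0)
        for k, v in enumerate(m):
            rows.append({"condition": label, "t": k / 100.0, "mean_trace": v})
    pd.DataFrame(rows).to_csv(args.out / "curves.csv", index=False)

    scale = ens["140% at 4.0 s"][:, 250:390].mean()
    for label in conditions:
        m = ens[label].mean(axis=0) / scale
        tc = conditions[label][1]
        k0 = int(tc * 100)
        peak = m[k0 + 5:k0 + 190].max() if m.size > k0 + 190 else np.nan
        print(f"{label}: onset peak {m[:min(250, k0 + 200)].max():.2f}, "
              f"post-change max {peak:.2f} (plateau = 1)")
    print("The change-locked peak grows with change size and is absent as a "
          "separate event for the early change (fused with the onset response).")

    summed = np.array([cx.summed_filterbank_trace(s)[:600] for s in specs140])
    ms = summed.mean(axis=0)
    pd.DataFrame({"t": np.arange(ms.size) / 100.0, "summed": ms}).to_csv(
        args.out / "summed_curve.csv", index=False)
    plat = ms[250:390].mean()
    print(f"\nSummed (EEG-like) readout: onset deviation "
          f"{np.abs(ms[:200] - plat).max():.2f} vs change-window deviation "
          f"{np.abs(ms[405:585] - plat).max():.2f} - the change is diluted in "
          "the unselective sum while the onset is not.")

    # decision stage on a mixed batch
    trials = [st.make_trial(args.seed * 10_000 + i, size, st.LOCALIZED_PAIRS[i % 4], trial=i)
              for i, size in enumerate(sum(([s] * 24 for s in (50, 80, 110, 140)), []))]
    rec = cx.simulate_cortical_experiment(trials, grid=grid)
    rec.to_csv(args.out / "responses.csv", index=False)
    summ = dm.summarize_conditions(rec, 2)
    summ.to_csv(args.out / "psychometrics.csv", index=False)
    fa = (rec.outcome == "false_alarm").mean()
    perf = rec[rec.outcome != "false_alarm"].groupby("size").apply(
        lambda g: (g.outcome == "hit").mean(), include_groups=False)
    print(f"\nDecision stage (collapsing bound, {len(trials)} trials): "
          f"{fa:.0%} false alarms; hit rate by size: "
          + ", ".join(f"{s}%: {v:.2f}" for s, v in perf.items()))
    print("Single-trial sensitivity of the frequency-averaged readout is modest "
          "(see docs/methods.md); the qualitative size ordering is the result "
          "to look at here.")


if __name__ == "__main__":
    main()
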