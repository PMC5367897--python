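#!/usr/bin/env python
"""Self-consistency of the fitting machinery: generate psychometric targets
from each model at known parameters, then let the exhaustive searches recover
them.  Writes results/fits/fit_reports.json.
"""

import argparse
import dataclasses
import json
from pathlib import Path

from tonecloud import cortical as cx
from tonecloud import dual_model as dm
from tonecloud import stimulus as st


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=777)
    ap.add_argument("--out", type=Path, default=Path("results/fits"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    grid = st.build_frequency_grid()
    report = {}

    # dual model: grid around the published values
    trials = st.generate_trial_batch(args.seed, repetitions=10, sizes=(50, 140),
                                     include_nonlocalized=False)
    truth = dm.DualParams()
    targets = dm.summarize_conditions(dm.simulate_experiment(trials, truth, grid=grid), 2)
    fit = dm.fit_to_behavior(
        targets, trials,
        grid_spec=dict(tau_f=[0.15, 0.2, 0.25], tau_s=[1.0, 1.1, 1.2],
                       tau_a=[0.6, 0.65, 0.7], T=[0.35, 0.4, 0.45]),
        n_time_bins=2, grid=grid)
    print(f"Dual model: truth (0.20, 1.10, 0.65, 0.40) -> recovered "
          f"({fit.params.tau_f:.2f}, {fit.params.tau_s:.2f}, "
          f"{fit.params.tau_a:.2f}, {fit.params.T:.2f}), MSE {fit.mse:.2e}, "
          f"boundary minimum: {fit.on_boundary}")
    report["dual"] = {"params": dataclasses.asdict(fit.params), "mse": fit.mse,
                      "mse_by_family": fit.mse_by_family,
                      "on_boundary": fit.on_boundary}

    # cortical model: reduced five-parameter search
    ctrials = [st.make_trial(args.seed * 100 + i, size, st.LOCALIZED_PAIRS[i % 4], trial=i)
               for i, size in enumerate([80] * 24 + [140] * 24)]
    ctruth = cx.CorticalParams()
    ctargets = dm.summarize_conditions(
        cx.simulate_cortical_experiment(ctrials, ctruth, grid=grid), 2)
    cfit = cx.simulate_and_fit(
        ctrials, ctargets,
        omega_grid=(0.6, 0.72, 0.9), Omega_grid=(0.45, 0.54, 0.65),
        lam_grid=(1.0, 1.14, 1.3), a_grid=(1.0, 1.1, 1.2),
        b_grid=(1.5, 2.0, 2.5), grid=grid, n_time_bins=2)
    p = cfit.params
    print(f"Cortical model: truth (omega=0.72, Omega=0.54, lam=1.14, a=1.10, b=2.0) "
          f"-> recovered (omega={p.omega}, Omega={p.Omega}, lam={p.lam}, "
          f"a={p.a}, b={p.b}), MSE {cfit.mse:.2e}, boundary: {cfit.on_boundary}")
    report["cortical"] = {"params": dataclasses.asdict(p), "mse": cfit.mse,
                          "on_boundary": cfit.on_boundary}

    with open(args.out / "fit_reports.json", "w") as fh:
        json.dump(report, fh, indent=1)


if __name__ == "__main__":
    main()
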