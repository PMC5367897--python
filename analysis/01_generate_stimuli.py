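#!/usr/bin/env python
"""Generate the stimulus set: the full trial batch of the behavioral design,
a rendered example trial, and summary statistics of the texture.

Writes results/stimuli/{trials.csv, trials.json, example_trial.wav,
stimulus_summary.json} and prints what it found.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from tonecloud import stimulus as st


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/stimuli"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    grid = st.build_frequency_grid()
    print(f"Tone grid: {grid.n_tones} semitone-spaced tones from "
          f"{grid.tone_freqs[0]:.0f} to {grid.tone_freqs[-1]:.0f} Hz, "
          f"{grid.n_bins} bins of width {grid.bin_width_st:.1f} st "
          f"(localized change spans {grid.localized_span_oct():.2f} oct)")

    trials = st.generate_trial_batch(args.seed)
    df = st.trials_to_frame(trials)
    df.to_csv(args.out / "trials.csv", index=False)
    st.trials_to_json(trials, args.out / "trials.json")
    print(f"Trial batch: {len(trials)} trials "
          f"({(df.distance == 1).sum()} localized, {(df.distance > 1).sum()} non-localized); "
          f"mean change time {df.change_time.mean():.2f} s")

    # long texture: empirical tone rate
    rng = np.random.default_rng([args.seed, 99])
    base = st.sample_baseline_marginal(rng)
    seq = st.generate_chords(grid, base, base, 0.0, 100.0, rng)
    rate = seq.tone_count() / seq.duration
    print(f"100 s baseline texture: {seq.tone_count()} tones -> {rate:.1f} tones/s "
          f"(expected 2 tones/oct x 2.2 oct / 30 ms = 146.7)")

    # one audible example (16 kHz keeps the file small; tones top out at 1.8 kHz)
    example = trials[0]
    wav = st.render_waveform(st.realize_trial(example, grid), grid,
                             level_db=example.level_db, sample_rate=16_000)
    st.save_wav(args.out / "example_trial.wav", wav, 16_000)
    print(f"Example trial rendered: change size {example.change.size}% in bins "
          f"{example.change.bins} at {example.change.time:.2f} s "
          f"-> {args.out / 'example_trial.wav'}")

    with open(args.out / "stimulus_summary.json", "w") as fh:
        json.dump({"n_trials": len(trials), "tone_rate_per_s": rate,
                   "bin_width_st": grid.bin_width_st,
                   "localized_span_oct": grid.localized_span_oct()}, fh, indent=1)


if __name__ == "__main__":
    main()
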