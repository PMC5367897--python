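"""Tone-cloud texture stimuli with a mid-trial change in the marginal frequency
distribution.

A texture is a train of 30 ms chords.  Each chord contains a Poisson number of
simultaneous pure tones (mean 2 tones/octave over the stimulus span); every
tone is placed by first drawing one of eight spectral bins from a *marginal
distribution* and then drawing one of the 3-4 semitone-spaced frequencies that
make up the bin.  At an exponentially distributed change time the probability
of two bins is incremented and the marginal renormalized, which changes the
spectral statistics while leaving the expected tone rate (and hence the
level) untouched.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

# Stimulus constants (package defaults).
F_MIN = 400.0                     # Hz, lowest tone
SPAN_OCTAVES = 2.2                # total spectral span
SEMITONES_PER_OCTAVE = 12         # tone grid resolution
N_BINS = 8
N_TONES = 26                      # tones kept on the grid (see build_frequency_grid)
CHORD_DUR = 0.030                 # s
TONES_PER_OCTAVE = 2.0            # Poisson mean per octave and chord
CHANGE_TIME_MEAN = 3.2            # s, exponential mean
CHANGE_TIME_CAP = 8.0             # s, redraw beyond this
RESPONSE_WINDOW = 2.0             # s after the change
CHANGE_SIZES = (30, 50, 80, 110, 140)          # percent of uniform bin probability
MARGINAL_LEVELS = (0.083, 0.125, 0.188)        # nominal per-bin probability values
MARGINAL_LEVEL_COUNTS = (3, 2, 3)              # bins assigned to each level
LOCALIZED_PAIRS = ((1, 2), (3, 4), (5, 6), (7, 8))   # 1-based bin pairs
NONLOCALIZED_DISTANCES = (2, 3, 5, 7)          # bins between pair centers
LEVEL_ROVE_DB = (60.0, 80.0)
EVENT_DT = 0.010                  # s, sampling step of the binary event series


@dataclass(frozen=True)
class ToneGrid:
    """Semitone-spaced tone frequencies partitioned into contiguous spectral bins."""

    f_min: float
    span: float
    resolution: int
    n_bins: int
    tone_freqs: np.ndarray          # Hz, strictly increasing
    bin_membership: np.ndarray      # bin index (0-based) per tone

    @property
    def n_tones(self) -> int:
        return self.tone_freqs.size

    @property
    def bin_width_st(self) -> float:
        """Nominal bin width in semitones on the log-frequency axis."""
        return self.span * self.resolution / self.n_bins

    @property
    def bin_sizes(self) -> np.ndarray:
        return np.bincount(self.bin_membership, minlength=self.n_bins)

    def bin_slices(self) -> list[slice]:
        starts = np.concatenate([[0], np.cumsum(self.bin_sizes)])
        return [slice(int(starts[b]), int(starts[b + 1])) for b in range(self.n_bins)]

    def pair_distance_st(self, bins: tuple[int, int]) -> float:
        """Distance between bin centers in semitones (bins are 1-based)."""
        return abs(bins[1] - bins[0]) * self.bin_width_st

    def localized_span_oct(self) -> float:
        """Octave span of a localized (adjacent-bin) change region."""
        return 2 * self.bin_width_st / self.resolution


def build_frequency_grid(
    f_min: float = F_MIN,
    span: float = SPAN_OCTAVES,
    resolution: int = SEMITONES_PER_OCTAVE,
    n_bins: int = N_BINS,
    n_tones: int | None = N_TONES,
) -> ToneGrid:
    """Construct the semitone tone grid and its partition into spectral bins.

    Tones are log-spaced at exactly one semitone from ``f_min`` up to
    ``f_min * 2**span``.  Enumerating inclusively yields 27 tones over 2.2
    octaves; the conventional grid keeps the lower 26 (``n_tones=26``), the
    inclusive grid is selected with ``n_tones=None``.  Tone ``k`` belongs to
    bin ``floor(k * n_bins / n_tones)``, producing contiguous bins of 3-4
    tones (4/3/3/3/4/3/3/3 for the default grid).
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if n_bins < 1 or resolution < 1:
        raise ValueError("n_bins and resolution must be >= 1")
    f_max = f_min * 2.0 ** span
    ks = []
    k = 0
    while f_min * 2.0 ** (k / resolution) <= f_max * (1 + 1e-12):
        ks.append(k)
        k += 1
    if n_tones is not None:
        if n_tones > len(ks):
            raise ValueError(f"grid supports at most {len(ks)} tones, asked for {n_tones}")
        ks = ks[:n_tones]
    ks = np.asarray(ks)
    if len(ks) < n_bins:
        raise ValueError("fewer tones than bins")
    freqs = f_min * 2.0 ** (ks / resolution)
    membership = (np.arange(len(ks)) * n_bins) // len(ks)
    return ToneGrid(f_min, span, resolution, n_bins, freqs, membership.astype(int))


@dataclass(frozen=True)
class MarginalDistribution:
    """Probability of a tone falling in each spectral bin (sums to 1)."""

    p: np.ndarray
    levels: tuple[float, ...] = MARGINAL_LEVELS

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if np.any(p <= 0):
            raise ValueError("marginal probabilities must be positive")
        object.__setattr__(self, "p", p / p.sum())

    @property
    def n_bins(self) -> int:
        return self.p.size


def sample_baseline_marginal(
    rng: np.random.Generator,
    n_bins: int = N_BINS,
    levels: Sequence[float] = MARGINAL_LEVELS,
    counts: Sequence[int] = MARGINAL_LEVEL_COUNTS,
) -> MarginalDistribution:
    """Random permutation of the fixed level multiset, renormalized to sum 1.

    The nominal values (three bins at 0.083, two at 0.125, three at 0.188) sum
    to 1.063; they are treated as rounded and renormalized after assignment.
    """
    if sum(counts) != n_bins:
        raise ValueError("level counts must sum to n_bins")
    values = np.repeat(levels, counts)
    return MarginalDistribution(rng.permutation(values), levels=tuple(levels))


def tone_draw_probability_range(
    levels: Sequence[float] = MARGINAL_LEVELS,
    bin_sizes: Sequence[int] = (3, 4),
) -> tuple[float, float]:
    """Extreme per-chord probabilities of drawing one specific tone frequency.

    A tone's draw probability is its bin's nominal probability divided by the
    number of tones in the bin; the extremes combine the smallest level with
    the largest bin and vice versa (0.021-0.063 for the default design).
    """
    return min(levels) / max(bin_sizes), max(levels) / min(bin_sizes)


def sample_change_time(
    rng: np.random.Generator,
    mean: float = CHANGE_TIME_MEAN,
    cap: float = CHANGE_TIME_CAP,
) -> float:
    """Exponential change time restricted to [0, cap] by redraw.

    Rejection (rather than clipping) keeps the density exponential on the
    whole interval, so the probability of a change per unit time stays
    constant and listeners/models cannot exploit a timing strategy.
    """
    if mean <= 0 or cap <= 0:
        raise ValueError("mean and cap must be positive")
    while True:
        t = rng.exponential(mean)
        if t <= cap:
            return float(t)


@dataclass(frozen=True)
class ChangeSpec:
    """What changes: increment size, the two incremented bins, and when."""

    size: float                     # percent of the uniform bin probability
    bins: tuple[int, int]           # 1-based bin indices
    time: float                     # s from stimulus onset

    def __post_init__(self):
        b1, b2 = self.bins
        if b1 == b2:
            raise ValueError("changed bins must differ")
        if not (0 <= self.time <= CHANGE_TIME_CAP):
            raise ValueError("change time outside [0, cap]")
        object.__setattr__(self, "bins", (min(b1, b2), max(b1, b2)))

    @property
    def distance(self) -> int:
        """Separation of the changed bins in bins (1 = localized/adjacent)."""
        return self.bins[1] - self.bins[0]


def apply_change(base: MarginalDistribution, change: ChangeSpec) -> MarginalDistribution:
    """Increment the two changed bins by size% of the uniform bin probability
    (1/n_bins), then renormalize.

    Renormalization keeps the expected tone rate - and hence the overall
    level - identical before and after the change.
    """
    n = base.n_bins
    for b in change.bins:
        if not 1 <= b <= n:
            raise ValueError(f"bin {b} out of range 1..{n}")
    inc = change.size / 100.0 * (1.0 / n)
    p = base.p.copy()
    for b in change.bins:
        p[b - 1] += inc
    return MarginalDistribution(p, levels=base.levels)


def change_increment(size: float, n_bins: int = N_BINS) -> float:
    """Per-bin probability increment before renormalization."""
    return size / 100.0 * (1.0 / n_bins)


@dataclass(frozen=True)
class TrialSpec:
    """Everything needed to regenerate one trial exactly."""

    baseline: MarginalDistribution
    change: ChangeSpec
    post: MarginalDistribution
    level_db: float
    max_duration: float             # change time + response window
    seed: int
    trial: int = 0

    def __post_init__(self):
        if not LEVEL_ROVE_DB[0] <= self.level_db <= LEVEL_ROVE_DB[1]:
            raise ValueError("presentation level outside the roving range")
        if self.max_duration < self.change.time:
            raise ValueError("trial shorter than its change time")


def make_trial(
    seed: int,
    size: float,
    bins: tuple[int, int],
    trial: int = 0,
    change_time: float | None = None,
    window: float = RESPONSE_WINDOW,
) -> TrialSpec:
    """Sample one trial: baseline marginal, change time and level rove all come
    from the trial's own seeded generator, so a trial is reproducible from
    (seed, size, bins) alone."""
    rng = np.random.default_rng(seed)
    base = sample_baseline_marginal(rng)
    if change_time is None:
        change_time = sample_change_time(rng)
    level = float(rng.uniform(*LEVEL_ROVE_DB))
    change = ChangeSpec(size=size, bins=bins, time=change_time)
    return TrialSpec(
        baseline=base,
        change=change,
        post=apply_change(base, change),
        level_db=level,
        max_duration=change_time + window,
        seed=int(seed),
        trial=trial,
    )


def nonlocalized_pairs(n_bins: int = N_BINS,
                       distances: Sequence[int] = NONLOCALIZED_DISTANCES) -> list[tuple[int, int]]:
    """All bin pairs at the tested non-adjacent distances (6/5/3/1 pairs for
    D = 2/3/5/7 on the 8-bin grid)."""
    return [(lo, lo + d) for d in distances for lo in range(1, n_bins - d + 1)]


def generate_trial_batch(
    seed: int,
    repetitions: int = 30,
    sizes: Sequence[float] = (50, 80, 110, 140),
    localized_pairs: Sequence[tuple[int, int]] = LOCALIZED_PAIRS,
    include_nonlocalized: bool = True,
    nonlocalized_size: float = 110,
    change_time: float | None = None,
) -> list[TrialSpec]:
    """The full condition grid of the behavioral design.

    Defaults give 930 trials: 4 sizes x 4 localized pairs x 30 repetitions
    (480) plus the 110% change over the 15 non-adjacent pairs x 30 (450).
    Per-trial seeds derive from the top-level seed with a counter so any
    subset of trials can be regenerated in isolation.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    conditions: list[tuple[float, tuple[int, int]]] = [
        (s, p) for s in sizes for p in localized_pairs
    ]
    if include_nonlocalized:
        conditions += [(nonlocalized_size, p) for p in nonlocalized_pairs()]
    trials = []
    idx = 0
    for rep in range(repetitions):
        for size, pair in conditions:
            tseed = int(np.random.SeedSequence([int(seed), idx]).generate_state(1)[0] % (2**31))
            trials.append(make_trial(tseed, size, pair, trial=idx, change_time=change_time))
            idx += 1
    return trials


@dataclass
class ChordSequence:
    """The realized stimulus: tone indices sounding in each 30 ms chord."""

    chords: list[np.ndarray]        # per-chord tone indices into the grid
    chord_dur: float = CHORD_DUR

    @property
    def n_chords(self) -> int:
        return len(self.chords)

    @property
    def duration(self) -> float:
        return self.n_chords * self.chord_dur

    def tone_count(self) -> int:
        return int(sum(len(c) for c in self.chords))

    def bin_counts(self, grid: ToneGrid) -> np.ndarray:
        """(n_chords, n_bins) matrix of tones per bin per chord."""
        out = np.zeros((self.n_chords, grid.n_bins), dtype=int)
        for i, c in enumerate(self.chords):
            if len(c):
                out[i] = np.bincount(grid.bin_membership[c], minlength=grid.n_bins)
        return out


def generate_chords(
    grid: ToneGrid,
    pre: MarginalDistribution,
    post: MarginalDistribution,
    change_time: float,
    duration: float,
    rng: np.random.Generator,
    chord_dur: float = CHORD_DUR,
    tones_per_octave: float = TONES_PER_OCTAVE,
) -> ChordSequence:
    """Draw the chord train: Poisson tone counts, bin by marginal, tone uniform
    within bin; chords whose onset is at or after the change time use the
    post-change marginal.  Chords are mutually independent."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration < change_time:
        raise ValueError("duration shorter than change time")
    n_chords = int(math.ceil(duration / chord_dur - 1e-9))
    lam = tones_per_octave * grid.span
    counts = rng.poisson(lam, size=n_chords)
    first_post = int(math.ceil(change_time / chord_dur - 1e-9))

    sizes = grid.bin_sizes
    starts = np.concatenate([[0], np.cumsum(sizes)])[:-1]

    def draw(total: int, marg: MarginalDistribution) -> np.ndarray:
        if total == 0:
            return np.empty(0, dtype=int)
        bins = rng.choice(grid.n_bins, size=total, p=marg.p)
        offs = rng.integers(0, sizes[bins])
        return starts[bins] + offs

    n_pre = int(counts[:first_post].sum())
    n_post = int(counts[first_post:].sum())
    tones = np.concatenate([draw(n_pre, pre), draw(n_post, post)])
    chords = np.split(tones, np.cumsum(counts)[:-1])
    return ChordSequence([np.asarray(c, dtype=int) for c in chords], chord_dur)


def render_waveform(
    seq: ChordSequence,
    grid: ToneGrid,
    level_db: float = 70.0,
    sample_rate: int = 100_000,
    ramp: float = 0.005,
    reference_db: float = 106.0,
) -> np.ndarray:
    """Sum of gated sinusoids: one 30 ms tone per drawn frequency per chord,
    with raised-cosine on/off ramps against spectral splatter.

    Levels are relative full scale (amplitude ``10**((level_db-reference_db)/20)``
    per tone); absolute SPL calibration is a hardware property and out of
    scope.
    """
    f_nyq = sample_rate / 2.0
    if grid.tone_freqs.max() >= f_nyq:
        raise ValueError("sample rate violates Nyquist for the tone grid")
    ns = int(round(seq.chord_dur * sample_rate))
    n_total = seq.n_chords * ns
    wave = np.zeros(n_total)
    t = np.arange(ns) / sample_rate
    env = np.ones(ns)
    nr = int(round(ramp * sample_rate))
    if nr > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] = r
        env[-nr:] = r[::-1]
    amp = 10.0 ** ((level_db - reference_db) / 20.0)
    for i, chord in enumerate(seq.chords):
        if len(chord) == 0:
            continue
        seg = np.sin(2 * np.pi * grid.tone_freqs[chord][:, None] * t[None, :]).sum(axis=0)
        wave[i * ns:(i + 1) * ns] = amp * env * seg
    return wave


def save_wav(path, wave: np.ndarray, sample_rate: int) -> None:
    wavfile.write(path, sample_rate, wave.astype(np.float32))


def load_wav(path) -> tuple[int, np.ndarray]:
    rate, data = wavfile.read(path)
    return rate, np.asarray(data, dtype=float)


def bin_event_series(
    seq: ChordSequence,
    grid: ToneGrid,
    channel_pairs: Sequence[tuple[int, int]] = LOCALIZED_PAIRS,
    dt: float = EVENT_DT,
) -> np.ndarray:
    """Binary tone-presence series per channel, sampled at 1/dt.

    Channel i reads 1 throughout any chord containing at least one tone in
    either bin of pair i.  dt must divide the chord duration (default 10 ms,
    three samples per 30 ms chord), and the value is held constant across a
    chord.
    """
    ratio = seq.chord_dur / dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("dt must divide the chord duration")
    per_chord = int(round(ratio))
    counts = seq.bin_counts(grid)                      # (n_chords, n_bins)
    out = np.empty((len(channel_pairs), seq.n_chords * per_chord), dtype=np.uint8)
    for i, (b1, b2) in enumerate(channel_pairs):
        present = (counts[:, b1 - 1] + counts[:, b2 - 1]) > 0
        out[i] = np.repeat(present.astype(np.uint8), per_chord)
    return out


def bin_count_series(
    seq: ChordSequence,
    grid: ToneGrid,
    channel_pairs: Sequence[tuple[int, int]] = LOCALIZED_PAIRS,
    dt: float = EVENT_DT,
) -> np.ndarray:
    """Per-bin tone occupancy per channel, sampled at 1/dt.

    Channel i reads the number of tones the current chord placed in pair i's
    two bins, divided by two (tones per bin): the quantity the marginal
    distribution controls directly.  Unlike the binary presence series it is
    not bounded by 1, and at the design's tone rates its mean (~0.3-0.8)
    approximates the per-bin presence probability.
    """
    ratio = seq.chord_dur / dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("dt must divide the chord duration")
    per_chord = int(round(ratio))
    counts = seq.bin_counts(grid)
    out = np.empty((len(channel_pairs), seq.n_chords * per_chord))
    for i, (b1, b2) in enumerate(channel_pairs):
        occ = (counts[:, b1 - 1] + counts[:, b2 - 1]) / 2.0
        out[i] = np.repeat(occ, per_chord)
    return out


# -- Serialization -----------------------------------------------------------

def trials_to_frame(trials: Sequence[TrialSpec]) -> pd.DataFrame:
    """One row per trial; baseline probabilities are stored so the symbolic
    stimulus can be regenerated exactly."""
    rows = []
    for ts in trials:
        row = {
            "trial": ts.trial,
            "seed": ts.seed,
            "change_time": ts.change.time,
            "size": ts.change.size,
            "bin_lo": ts.change.bins[0],
            "bin_hi": ts.change.bins[1],
            "distance": ts.change.distance,
            "level_db": ts.level_db,
            "max_duration": ts.max_duration,
        }
        for b in range(ts.baseline.n_bins):
            row[f"p{b + 1}"] = ts.baseline.p[b]
        rows.append(row)
    return pd.DataFrame(rows)


def trials_from_frame(df: pd.DataFrame) -> list[TrialSpec]:
    trials = []
    pcols = [c for c in df.columns if c.startswith("p") and c[1:].isdigit()]
    pcols.sort(key=lambda c: int(c[1:]))
    for _, r in df.iterrows():
        base = MarginalDistribution(np.array([r[c] for c in pcols]))
        change = ChangeSpec(size=float(r["size"]),
                            bins=(int(r["bin_lo"]), int(r["bin_hi"])),
                            time=float(r["change_time"]))
        trials.append(TrialSpec(
            baseline=base,
            change=change,
            post=apply_change(base, change),
            level_db=float(r["level_db"]),
            max_duration=float(r["max_duration"]),
            seed=int(r["seed"]),
            trial=int(r["trial"]),
        ))
    return trials


def trials_to_json(trials: Sequence[TrialSpec], path) -> None:
    payload = trials_to_frame(trials).to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def realize_trial(ts: TrialSpec, grid: ToneGrid, rng: np.random.Generator | None = None) -> ChordSequence:
    """Regenerate the chord train of a trial from its spec.

    The chord draw uses a generator derived from (but distinct from) the
    trial seed, so the trial-level samples (marginal, change time, level)
    stay reproducible independently of how many chords are consumed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([ts.seed, 7_777]))
    return generate_chords(grid, ts.baseline, ts.post, ts.change.time, ts.max_duration, rng)
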