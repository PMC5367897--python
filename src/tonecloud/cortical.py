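"""Simplified multiresolution model of auditory cortical processing with a
collapsing-bound decision stage.

The pipeline mirrors the classical two-stage cortical analysis:

1. *Cochleogram*: a bank of constant-Q bandpass filters log-spaced over 5.3
   octaves (128 channels), envelope extraction, short-term leaky integration
   (4 ms), compressive nonlinearity, and spectral sharpening by a lateral
   inhibitory first difference across channels, sampled at 100 Hz frames.
2. *Modulation filtering*: separable spectrotemporal convolution of the
   cochleogram with a temporal kernel (gamma envelope modulated at rate
   omega, Hz) and a spectral Gabor (scale Omega, cycles/octave).  Upward and
   downward drifting components are averaged, which for zero-phase (real)
   filters reduces exactly to the product of the two real kernels.  The
   magnitude is averaged across frequency to a single decision trace.

The decision stage normalizes the trace to baseline-plateau units, smooths
single trials with a matched template (the trial-averaged change response,
length 1/(2 omega) s), and reports the first local peak exceeding a
collapsing threshold T(t) = b e^(-t/lambda) + a, plus a 250 ms motor delay.
The initially elevated threshold implements the instruction not to respond to
the (salient) stimulus onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy import signal

from . import stimulus
from .behavior import classify_frame
from .dual_model import summarize_conditions
from .stimulus import ToneGrid, TrialSpec

#: Spectral-kernel envelope width in modulation cycles.  Pinned so the
#: magnitude profile of the Omega = 0.54 cyc/oct kernel has a full width at
#: half maximum of ~0.56 octave, the width of a localized change region.
SIGMA_CYCLES = 0.275

#: Modulation filter grid covering the physiologically observed range.
RATE_GRID = (1.0, 2.0, 4.0, 8.0, 16.0, 30.0)       # Hz
SCALE_GRID = (0.5, 1.0, 2.0, 4.0, 8.0)             # cycles/octave


@dataclass(frozen=True)
class CorticalParams:
    omega: float = 0.72     # Hz, temporal modulation rate of the read-out filter
    Omega: float = 0.54     # cyc/oct, spectral modulation scale
    a: float = 1.10         # threshold asymptote, plateau units
    b: float = 2.0          # initial threshold elevation above a, plateau units
    lam: float = 1.14       # s, threshold decay constant
    Tm: float = 0.250       # s, motor delay

    def __post_init__(self):
        if self.a <= 0 or self.b < 0 or self.lam <= 0:
            raise ValueError("need a > 0, b >= 0, lam > 0")


@dataclass
class AuditorySpectrogram:
    data: np.ndarray        # (n_frames, n_channels), nonnegative
    frame_rate: float       # Hz
    cfs: np.ndarray         # channel center frequencies, Hz

    @property
    def channel_spacing_oct(self) -> float:
        return float(np.log2(self.cfs[1] / self.cfs[0]))

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) / self.frame_rate


def auditory_spectrogram(wave: np.ndarray,
                         sample_rate: int,
                         n_channels: int = 128,
                         span_oct: float = 5.3,
                         f_min: float = 180.0,
                         frame_rate: float = 100.0,
                         tau: float = 0.004,
                         bw_oct: float = 0.16,
                         compression: float = 0.6,
                         lateral_inhibition: bool = True) -> AuditorySpectrogram:
    """Cochleogram: constant-Q filterbank -> envelope -> 4 ms integration ->
    compression -> half-wave-rectified channel difference (lateral inhibition).

    Channels are log-spaced over ``span_oct`` octaves starting at ``f_min``;
    each is a second-order Butterworth bandpass of constant relative bandwidth
    ``bw_oct``.  Frames are sampled at ``frame_rate`` (>= 100 Hz so the
    modulation stage can resolve rates up to tens of Hz).
    """
    wave = np.asarray(wave, dtype=float)
    if wave.size == 0:
        raise ValueError("empty waveform")
    if np.abs(wave).max() > 0.999:
        warnings.warn("waveform at or above full scale; possible clipping")
    step = sample_rate / frame_rate
    if abs(step - round(step)) > 1e-9:
        raise ValueError("frame_rate must divide sample_rate")
    step = int(round(step))
    cfs = f_min * 2.0 ** (np.linspace(0.0, span_oct, n_channels))
    if cfs[-1] * 2 ** (bw_oct / 2) >= sample_rate / 2:
        raise ValueError("top channel exceeds Nyquist; raise sample_rate or lower span")
    alpha = np.exp(-1.0 / (sample_rate * tau))
    smooth_b = np.array([1 - alpha])
    smooth_a = np.array([1.0, -alpha])
    n_frames = wave.size // step
    env = np.empty((n_channels, n_frames))
    for i, cf in enumerate(cfs):
        sos = signal.butter(2, [cf * 2 ** (-bw_oct / 2), cf * 2 ** (bw_oct / 2)],
                            "bandpass", fs=sample_rate, output="sos")
        y = signal.sosfilt(sos, wave)
        e = signal.lfilter(smooth_b, smooth_a, np.abs(y))
        env[i] = e[:n_frames * step:step]
    env = env ** compression
    if lateral_inhibition:
        # spectral sharpening: half-wave-rectified first difference across
        # channels; moves energy to spectral edges, so the per-bin energy sum
        # no longer tracks the marginal (the envelope stage does)
        env = np.maximum(np.diff(env, axis=0, prepend=env[:1]), 0.0)
    return AuditorySpectrogram(env.T.copy(), frame_rate, cfs)


def gain_normalize(spec: AuditorySpectrogram) -> AuditorySpectrogram:
    """Divisive gain normalization: scale the cochleogram to unit mean.

    The texture's expected tone rate is constant throughout a trial (the
    marginal is renormalized at the change), so the trial's own mean energy
    is a change-invariant estimate of its roved presentation level.  This is
    the adaptation step that makes a fixed decision threshold meaningful
    across the 60-80 dB level rove.
    """
    m = spec.data.mean()
    if m <= 0:
        raise ValueError("cannot gain-normalize an all-zero spectrogram")
    return AuditorySpectrogram(spec.data / m, spec.frame_rate, spec.cfs)


# -- Modulation filtering ------------------------------------------------------

def temporal_kernel(omega: float, frame_rate: float) -> np.ndarray:
    """Causal rate filter: gamma envelope t^2 e^(-3.5 omega t) modulated at
    omega (zero phase), unit energy.  Q ~ 1: bandwidth comparable to the
    center rate."""
    if omega <= 0:
        raise ValueError("omega must be positive")
    if omega >= frame_rate / 2:
        raise ValueError("omega above the Nyquist rate of the frame grid")
    t = np.arange(1, int(np.ceil(3.0 / omega * frame_rate))) / frame_rate
    h = t ** 2 * np.exp(-3.5 * omega * t) * np.cos(2 * np.pi * omega * t)
    return h / np.linalg.norm(h)


def spectral_kernel(Omega: float,
                    spacing_oct: float,
                    sigma_cycles: float = SIGMA_CYCLES) -> np.ndarray:
    """Zero-phase scale filter: Gabor at Omega cycles/octave with Gaussian
    envelope sigma = sigma_cycles / Omega octaves, unit energy."""
    if Omega <= 0:
        raise ValueError("Omega must be positive")
    sigma = sigma_cycles / Omega
    half = max(1, int(np.ceil(3.5 * sigma / spacing_oct)))
    x = np.arange(-half, half + 1) * spacing_oct
    g = np.cos(2 * np.pi * Omega * x) * np.exp(-x ** 2 / (2 * sigma ** 2))
    return g / np.linalg.norm(g)


def spectral_kernel_fwhm(Omega: float,
                         sigma_cycles: float = SIGMA_CYCLES,
                         dx: float = 1e-4) -> float:
    """Full width at half maximum (octaves) of the kernel's magnitude profile,
    measured numerically on a fine log-frequency grid."""
    sigma = sigma_cycles / Omega
    x = np.arange(0.0, 5 * sigma, dx)
    g = np.abs(np.cos(2 * np.pi * Omega * x) * np.exp(-x ** 2 / (2 * sigma ** 2)))
    peak = g[0]
    below = np.nonzero(g < peak / 2)[0]
    i = below[0]
    # linear interpolation between the straddling samples
    x_half = x[i - 1] + dx * (peak / 2 - g[i - 1]) / (g[i] - g[i - 1])
    return 2 * float(x_half)


@dataclass
class ModulationResponse:
    trace: np.ndarray       # frequency-averaged magnitude, one value per frame
    frame_rate: float
    omega: float
    Omega: float
    r: np.ndarray | None = None     # (n_frames, n_channels) filtered output

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.trace.size) / self.frame_rate


def modulation_filter(spec: AuditorySpectrogram,
                      omega: float,
                      Omega: float,
                      sigma_cycles: float = SIGMA_CYCLES,
                      readout: str = "rms",
                      band: tuple[float, float] | None = None,
                      keep_2d: bool = False) -> ModulationResponse:
    """Separable spectrotemporal modulation filtering of the cochleogram.

    The temporal convolution is causal, the spectral convolution zero-phase;
    averaging the upward and downward drifting quadrants of a separable
    filter equals the product of its real kernels, so that average is what is
    computed.  The output magnitude is then averaged across channels into a
    single trace: ``readout='rms'`` (default) takes the root mean square over
    the tonotopic axis, which weights the spectrally localized change
    response less dilutively than the plain mean (``readout='mean_abs'``).
    ``band=(f_lo, f_hi)`` restricts the average to channels with center
    frequencies inside the band (default: all channels).
    """
    ht = temporal_kernel(omega, spec.frame_rate)
    hs = spectral_kernel(Omega, spec.channel_spacing_oct, sigma_cycles)
    n = spec.data.shape[0]
    r = signal.fftconvolve(spec.data, ht[:, None], mode="full", axes=0)[:n]
    r = signal.fftconvolve(r, hs[None, :], mode="same", axes=1)
    sel = r if band is None else r[:, (spec.cfs >= band[0]) & (spec.cfs <= band[1])]
    if readout == "rms":
        trace = np.sqrt((sel ** 2).mean(axis=1))
    elif readout == "mean_abs":
        trace = np.abs(sel).mean(axis=1)
    else:
        raise ValueError(f"unknown readout {readout!r}")
    return ModulationResponse(trace, spec.frame_rate, omega, Omega,
                              r=r if keep_2d else None)


def summed_filterbank_trace(spec: AuditorySpectrogram,
                            rates=RATE_GRID,
                            scales=SCALE_GRID,
                            lowpass_hz: float | None = 10.0) -> np.ndarray:
    """Signed sum over the whole modulation filter grid and all channels - an
    EEG-like readout (spatial summation of signed sources with no filter
    selectivity).

    Onset and offset transients drive all channels coherently and survive
    the summation; the statistical change conserves the total tone rate, so
    its locked response largely cancels.  The trace is smoothed below
    ``lowpass_hz`` (zero-phase), the display convention for slow potentials,
    which also removes the chord-locked ripple.
    """
    tot = None
    n = spec.data.shape[0]
    for w in rates:
        for s in scales:
            ht = temporal_kernel(w, spec.frame_rate)
            hs = spectral_kernel(s, spec.channel_spacing_oct)
            r = signal.fftconvolve(spec.data, ht[:, None], mode="full", axes=0)[:n]
            r = signal.fftconvolve(r, hs[None, :], mode="same", axes=1)
            m = r.mean(axis=1)
            tot = m if tot is None else tot + m
    tot /= len(rates) * len(scales)
    if lowpass_hz is not None:
        b, a = signal.butter(4, lowpass_hz, fs=spec.frame_rate)
        tot = signal.filtfilt(b, a, tot)
    return tot


def condition_ensemble(size: float,
                       change_time: float,
                       n_trials: int,
                       seed: int,
                       grid: ToneGrid | None = None,
                       base: "stimulus.MarginalDistribution | None" = None,
                       pair: tuple[int, int] = (3, 4),
                       omega: float = 0.72,
                       Omega: float = 0.54,
                       sample_rate: int = 16_000,
                       band: tuple[float, float] | None = (380.0, 1900.0),
                       level_db: float = 70.0,
                       keep_specs: bool = False):
    """Trial ensemble of selected-filter traces for one fixed change condition.

    The baseline marginal and the changed bins are held fixed across trials,
    so across-trial variability reflects the random tone cloud alone - the
    convention for change-locked average response curves.  Returns
    (traces, specs): traces is (n_trials, n_frames); specs the per-trial
    cochleograms when ``keep_specs``.
    """
    grid = grid or stimulus.build_frequency_grid()
    if base is None:
        base = stimulus.MarginalDistribution(
            np.array([0.188, 0.083, 0.125, 0.125, 0.188, 0.083, 0.188, 0.083]))
    change = stimulus.ChangeSpec(size, pair, change_time)
    post = stimulus.apply_change(base, change)
    traces, specs = [], []
    for i in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        seq = stimulus.generate_chords(grid, base, post, change_time,
                                       change_time + stimulus.RESPONSE_WINDOW, rng)
        wave = stimulus.render_waveform(seq, grid, level_db=level_db,
                                        sample_rate=sample_rate)
        s = gain_normalize(auditory_spectrogram(wave, sample_rate))
        traces.append(modulation_filter(s, omega, Omega, band=band).trace)
        if keep_specs:
            specs.append(s)
    return np.array(traces), specs


# -- Decision stage ------------------------------------------------------------

def template_length(omega: float) -> float:
    """Matched-template duration in seconds: half a modulation period."""
    return 1.0 / (2.0 * omega)


def build_change_template(traces: list[np.ndarray],
                          change_times: np.ndarray,
                          omega: float,
                          frame_rate: float) -> np.ndarray:
    """Trial-averaged change-aligned response, the matched-filter template.

    Segments of length 1/(2 omega) starting at each trial's change time are
    averaged across trials; trials too short for a full segment are skipped.
    """
    n_seg = max(2, int(round(template_length(omega) * frame_rate)))
    segs = []
    for trace, tc in zip(traces, change_times):
        k0 = int(round(tc * frame_rate))
        if k0 + n_seg <= trace.size:
            segs.append(trace[k0:k0 + n_seg])
    if not segs:
        raise ValueError("no trial long enough to cut a template segment")
    return np.mean(segs, axis=0)


def matched_postfilter(trace: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Cross-correlate a single-trial trace with the unit-energy template.

    Output has the trace's length and is rescaled so a constant trace is
    preserved, keeping plateau units meaningful for the threshold.
    """
    template = np.asarray(template, dtype=float)
    energy = np.linalg.norm(template)
    if energy == 0:
        raise ValueError("template has zero energy")
    template = template / energy
    s = template.sum()
    if abs(s) < 1e-12:
        raise ValueError("template integrates to zero; cannot preserve plateau units")
    # edge-pad so the window running off the trace ends does not fabricate
    # deviations (and hence spurious peaks) near the boundaries
    pad = template.size
    padded = np.pad(np.asarray(trace, dtype=float), pad, mode="edge")
    return signal.fftconvolve(padded, template[::-1], mode="same")[pad:-pad] / s


def collapsing_threshold(t: np.ndarray | float, params: CorticalParams) -> np.ndarray | float:
    """T(t) = b e^(-t/lambda) + a: strictly decreasing to the asymptote a,
    identical across all conditions."""
    t = np.asarray(t, dtype=float)
    out = params.b * np.exp(-t / params.lam) + params.a
    return float(out) if out.ndim == 0 else out


def detect_first_peak(trace: np.ndarray,
                      threshold: np.ndarray,
                      frame_rate: float,
                      Tm: float = 0.250) -> float:
    """Earliest local maximum (3-sample neighborhood, ties broken earliest)
    strictly above the threshold at its time, plus the motor delay.  NaN when
    no peak crosses."""
    y = np.asarray(trace, dtype=float)
    is_peak = np.zeros(y.size, dtype=bool)
    is_peak[1:-1] = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])
    above = y > np.asarray(threshold, dtype=float)
    idx = np.nonzero(is_peak & above)[0]
    if idx.size == 0:
        return float("nan")
    return idx[0] / frame_rate + Tm


# -- Whole-experiment simulation and fitting -----------------------------------

def trial_traces(trials: list[TrialSpec],
                 grid: ToneGrid | None = None,
                 sample_rate: int = 16_000,
                 omega: float | None = None,
                 Omega: float | None = None,
                 specs: list[AuditorySpectrogram] | None = None,
                 **spec_kwargs) -> tuple[list[np.ndarray], list[AuditorySpectrogram]]:
    """Render each trial to audio, compute its cochleogram and the modulation
    trace for one (omega, Omega) filter.  Precomputed cochleograms can be
    passed to sweep filters cheaply."""
    grid = grid or stimulus.build_frequency_grid()
    p = CorticalParams()
    omega = p.omega if omega is None else omega
    Omega = p.Omega if Omega is None else Omega
    if specs is None:
        specs = []
        for ts in trials:
            seq = stimulus.realize_trial(ts, grid)
            wave = stimulus.render_waveform(seq, grid, level_db=ts.level_db,
                                            sample_rate=sample_rate)
            specs.append(gain_normalize(
                auditory_spectrogram(wave, sample_rate, **spec_kwargs)))
    traces = [modulation_filter(s, omega, Omega).trace for s in specs]
    return traces, specs


def plateau_scale(traces: list[np.ndarray],
                  change_times: np.ndarray,
                  frame_rate: float = 100.0,
                  settle: float = 1.5) -> float:
    """Normalization constant: pooled mean trace value over pre-change windows
    (after the onset transient has settled), so that the baseline plateau of
    a normalized trace is ~1."""
    vals = []
    for trace, tc in zip(traces, change_times):
        k0 = int(settle * frame_rate)
        k1 = int(tc * frame_rate)
        if k1 - k0 >= int(0.3 * frame_rate):
            vals.append(trace[k0:k1])
    if not vals:
        raise ValueError("no trial has a long enough pre-change window to calibrate")
    return float(np.concatenate(vals).mean())


def simulate_cortical_experiment(trials: list[TrialSpec],
                                 params: CorticalParams = CorticalParams(),
                                 grid: ToneGrid | None = None,
                                 sample_rate: int = 16_000,
                                 frame_rate: float = 100.0,
                                 specs: list[AuditorySpectrogram] | None = None,
                                 traces: list[np.ndarray] | None = None) -> pd.DataFrame:
    """Full decision pipeline over a trial batch -> classified response table.

    The threshold and template are shared across all conditions; the only
    across-trial variability is the stochastic tone cloud itself.
    """
    grid = grid or stimulus.build_frequency_grid()
    if traces is None:
        traces, specs = trial_traces(trials, grid, sample_rate,
                                     omega=params.omega, Omega=params.Omega, specs=specs)
    cts = np.array([ts.change.time for ts in trials])
    scale = plateau_scale(traces, cts, frame_rate)
    normed = [tr / scale for tr in traces]
    template = build_change_template(normed, cts, params.omega, frame_rate)
    resp = np.empty(len(trials))
    for i, (trace, ts) in enumerate(zip(normed, trials)):
        filt = matched_postfilter(trace, template)
        t = np.arange(filt.size) / frame_rate
        r = detect_first_peak(filt, collapsing_threshold(t, params), frame_rate, params.Tm)
        resp[i] = r if (np.isfinite(r) and r <= ts.max_duration) else np.nan
    df = pd.DataFrame({
        "trial": [ts.trial for ts in trials],
        "size": [ts.change.size for ts in trials],
        "distance": [ts.change.distance for ts in trials],
        "change_time": cts,
        "response_time": resp,
    })
    return classify_frame(df)


@dataclass
class CorticalFitReport:
    params: CorticalParams
    mse: float
    mse_by_family: dict
    on_boundary: bool
    responses: pd.DataFrame


def simulate_and_fit(trials: list[TrialSpec],
                     targets: pd.DataFrame,
                     omega_grid=(0.5, 0.72, 1.0),
                     Omega_grid=(0.35, 0.54, 0.8),
                     lam_grid=(0.8, 1.14, 1.5),
                     a_grid=(1.0, 1.1, 1.2),
                     b_grid=(1.5, 2.0, 2.5),
                     grid: ToneGrid | None = None,
                     sample_rate: int = 16_000,
                     frame_rate: float = 100.0,
                     n_time_bins: int = 3) -> CorticalFitReport:
    """Five-parameter search (Omega, omega, lambda, a, b) minimizing squared
    error of the performance and false-alarm curves against ``targets``
    (a summary table from :func:`summarize_conditions`).

    Cochleograms are computed once and reused across the filter grid;
    reaction times are produced but never enter the objective.
    """
    grid = grid or stimulus.build_frequency_grid()
    _, specs = trial_traces(trials, grid, sample_rate)      # cochleograms only
    tkey = ["size", "time_bin"]
    tgt = targets.set_index(tkey)[["performance", "fa_fraction"]]
    best = None
    for omega, Omega in product(omega_grid, Omega_grid):
        traces, _ = trial_traces(trials, grid, sample_rate,
                                 omega=omega, Omega=Omega, specs=specs)
        for lam, a, b in product(lam_grid, a_grid, b_grid):
            p = CorticalParams(omega=omega, Omega=Omega, a=a, b=b, lam=lam)
            rec = simulate_cortical_experiment(trials, p, grid, traces=traces,
                                               frame_rate=frame_rate)
            summ = summarize_conditions(rec, n_time_bins).set_index(tkey)
            joined = tgt.join(summ, how="inner", lsuffix="_tgt", rsuffix="_mod").dropna()
            fam_mse = {
                fam: float(np.mean((joined[f"{fam}_tgt"] - joined[f"{fam}_mod"]) ** 2))
                for fam in ["performance", "fa_fraction"]
            }
            mse = float(np.mean(list(fam_mse.values())))
            if best is None or mse < best[0]:
                best = (mse, p, fam_mse, rec)
    mse, p, fam_mse, rec = best
    axes = dict(omega=omega_grid, Omega=Omega_grid, lam=lam_grid, a=a_grid, b=b_grid)
    boundary = any(
        len(ax) > 1 and (np.isclose(getattr(p, k), ax[0]) or np.isclose(getattr(p, k), ax[-1]))
        for k, ax in axes.items()
    )
    return CorticalFitReport(params=p, mse=mse, mse_by_family=fam_mse,
                             on_boundary=boundary, responses=rec)
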