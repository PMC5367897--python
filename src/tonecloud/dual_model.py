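"""Dual-timescale statistical estimation model of change detection.

Four independent modules - one per pair of spectral bins - each track the
probability that a tone is currently present in their frequency range with
two leaky estimators relaxing toward the binary input S_i(t):

    dPfast/dt = (S_i - Pfast) / tau_f
    dPslow/dt = (S_i - Pslow) / theta(t),   theta(t) = tau_s - (tau_s - tau_f) e^(-t/tau_a)

At stimulus onset both estimators operate on the fast timescale
(theta(0) = tau_f); theta relaxes to tau_s with time constant tau_a, letting
the slow estimator settle into a long-term baseline while the fast one keeps
tracking.  A change is detected the first time |Pfast - Pslow| > T in any
channel; the overt response follows after a fixed motor delay Tm.

The stationary mean of each estimator equals the input's presence
probability, so a stationary texture eventually produces no detections beyond
chance crossings driven by estimator noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd

from . import stimulus
from .behavior import bin_change_times, classify_frame
from .stimulus import EVENT_DT, TrialSpec, ToneGrid

#: Parameter values that best matched the pooled human data.
PUBLISHED = dict(tau_f=0.2, tau_s=1.1, tau_a=0.65, T=0.40)

#: Default exhaustive-search grid (start, stop, step) per parameter.
DEFAULT_GRID = dict(
    tau_f=(0.05, 0.5, 0.05),
    tau_s=(0.4, 2.0, 0.1),
    tau_a=(0.1, 1.5, 0.05),
    T=(0.1, 0.8, 0.05),
)


@dataclass(frozen=True)
class DualParams:
    tau_f: float = 0.2      # s, fast estimator time constant
    tau_s: float = 1.1      # s, slow estimator asymptotic time constant
    tau_a: float = 0.65     # s, relaxation of theta from tau_f to tau_s
    T: float = 0.40         # detection threshold, units of probability
    Tm: float = 0.250       # s, motor delay
    dt: float = EVENT_DT    # s, integration step

    def __post_init__(self):
        if not (self.tau_s > self.tau_f > 0):
            raise ValueError("need tau_s > tau_f > 0")
        if self.tau_a <= 0 or self.T <= 0:
            raise ValueError("tau_a and T must be positive")
        if self.dt >= self.tau_f:
            raise ValueError("integration step must be smaller than tau_f")


def theta_schedule(t: np.ndarray | float, params: DualParams) -> np.ndarray | float:
    """Effective slow time constant: tau_f at onset, tau_s asymptotically."""
    t = np.asarray(t, dtype=float)
    out = params.tau_s - (params.tau_s - params.tau_f) * np.exp(-t / params.tau_a)
    return float(out) if out.ndim == 0 else out


def integrate_channels(S: np.ndarray,
                       params: DualParams,
                       method: str = "euler",
                       p0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the estimator pair over a binary input.

    ``S`` has shape (..., n_steps) (any leading trial/channel axes); sample k
    holds over [k dt, (k+1) dt).  Returns (Pfast, Pslow) sampled at the same
    instants: trace[..., k] is the state at time k dt before the k-th input
    is applied, trace[..., 0] = p0.

    ``method='euler'`` is the forward-Euler update; ``method='exact'``
    applies the exact exponential relaxation over each step (zero-order hold),
    which is unconditionally stable and step-size exact for constant inputs.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[-1]
    t = np.arange(n) * params.dt
    theta = theta_schedule(t, params)
    pf = np.empty_like(S)
    ps = np.empty_like(S)
    pf[..., 0] = p0
    ps[..., 0] = p0
    if method == "euler":
        af = params.dt / params.tau_f
        aslow = params.dt / theta
        for k in range(n - 1):
            pf[..., k + 1] = pf[..., k] + af * (S[..., k] - pf[..., k])
            ps[..., k + 1] = ps[..., k] + aslow[k] * (S[..., k] - ps[..., k])
    elif method == "exact":
        ef = np.exp(-params.dt / params.tau_f)
        eslow = np.exp(-params.dt / theta)
        for k in range(n - 1):
            pf[..., k + 1] = S[..., k] + (pf[..., k] - S[..., k]) * ef
            ps[..., k + 1] = S[..., k] + (ps[..., k] - S[..., k]) * eslow[k]
    else:
        raise ValueError(f"unknown method {method!r}")
    return pf, ps


def detect_change(pfast: np.ndarray,
                  pslow: np.ndarray,
                  params: DualParams,
                  n_valid: np.ndarray | int | None = None) -> np.ndarray:
    """First time |Pfast - Pslow| > T in any channel, plus the motor delay.

    Inputs have shape (n_trials, n_channels, n_steps) (leading axes optional).
    ``n_valid`` restricts detection to the first n_valid[i] samples of trial i
    (trials shorter than the padded array).  Returns response times in
    seconds, NaN where no crossing occurs.
    """
    diff = np.abs(pfast - pslow) > params.T
    if diff.ndim == 1:
        diff = diff[None, None, :]
    elif diff.ndim == 2:
        diff = diff[None, :, :]
    n_tr, _, n_steps = diff.shape
    if n_valid is not None:
        mask = np.arange(n_steps)[None, :] >= np.asarray(n_valid).reshape(-1, 1)
        diff = diff & ~mask[:, None, :]
    any_ch = diff.any(axis=1)
    first = np.argmax(any_ch, axis=1)
    hit = any_ch[np.arange(n_tr), first]
    return np.where(hit, first * params.dt + params.Tm, np.nan)


def stationary_prior(input_mode: str = "count",
                     grid: ToneGrid | None = None) -> float:
    """Stationary channel-input mean under the average (uniform) texture.

    Used as the estimators' initial state: a trained listener enters the
    trial with a converged estimate of the typical texture, so the silence ->
    stimulus onset does not itself register as a change.
    """
    grid = grid or stimulus.build_frequency_grid()
    tones_per_chord = stimulus.TONES_PER_OCTAVE * grid.span
    if input_mode == "count":
        return tones_per_chord / grid.n_bins
    if input_mode == "presence":
        pairs_frac = 2.0 / grid.n_bins
        return 1.0 - float(np.exp(-tones_per_chord * pairs_frac))
    raise ValueError(f"unknown input_mode {input_mode!r}")


def trial_event_series(trials: list[TrialSpec],
                       grid: ToneGrid,
                       dt: float = EVENT_DT,
                       input_mode: str = "count") -> tuple[np.ndarray, np.ndarray]:
    """Channel inputs for a trial batch, padded to a common length.

    ``input_mode='count'`` (default) uses the per-bin tone occupancy
    (:func:`tonecloud.stimulus.bin_count_series`); ``'presence'`` the binary
    tone-presence series.  Returns (S, n_valid): S has shape
    (n_trials, 4, max_steps) and n_valid[i] is the number of live samples of
    trial i (padding beyond a trial's end is masked out during detection).
    """
    series = []
    for ts in trials:
        seq = stimulus.realize_trial(ts, grid)
        if input_mode == "count":
            series.append(stimulus.bin_count_series(seq, grid, dt=dt))
        elif input_mode == "presence":
            series.append(stimulus.bin_event_series(seq, grid, dt=dt))
        else:
            raise ValueError(f"unknown input_mode {input_mode!r}")
    n_valid = np.array([s.shape[1] for s in series])
    n_max = int(n_valid.max())
    S = np.zeros((len(series), series[0].shape[0], n_max), dtype=np.float32)
    for i, s in enumerate(series):
        S[i, :, :s.shape[1]] = s
    return S, n_valid


def simulate_experiment(trials: list[TrialSpec],
                        params: DualParams,
                        grid: ToneGrid | None = None,
                        method: str = "euler",
                        input_mode: str = "count",
                        p0: float | None = None,
                        chunk: int = 2000,
                        precomputed: tuple[np.ndarray, np.ndarray] | None = None) -> pd.DataFrame:
    """Run the model over a trial batch and classify its responses.

    The model is deterministic given the stimulus, so all randomness comes
    from the trial seeds.  Estimators start at the stationary occupancy of
    the average texture unless ``p0`` overrides it.  Responses later than a
    trial's end are discarded (miss), mirroring the behavioral response
    window.  ``precomputed`` takes (S, n_valid) from
    :func:`trial_event_series` to reuse stimuli across parameter sets (used
    by the fitting routine).
    """
    grid = grid or stimulus.build_frequency_grid()
    if p0 is None:
        p0 = stationary_prior(input_mode, grid)
    if precomputed is None:
        precomputed = trial_event_series(trials, grid, dt=params.dt, input_mode=input_mode)
    S, n_valid = precomputed
    resp = np.empty(len(trials))
    for lo in range(0, len(trials), chunk):
        sl = slice(lo, min(lo + chunk, len(trials)))
        pf, ps = integrate_channels(S[sl], params, method=method, p0=p0)
        resp[sl] = detect_change(pf, ps, params, n_valid=np.atleast_1d(n_valid[sl]))
    durations = np.array([ts.max_duration for ts in trials])
    resp = np.where(resp <= durations, resp, np.nan)
    df = pd.DataFrame({
        "trial": [ts.trial for ts in trials],
        "size": [ts.change.size for ts in trials],
        "distance": [ts.change.distance for ts in trials],
        "change_time": [ts.change.time for ts in trials],
        "response_time": resp,
    })
    return classify_frame(df)


# -- Fitting -------------------------------------------------------------------

def summarize_conditions(records: pd.DataFrame,
                         n_time_bins: int = 4) -> pd.DataFrame:
    """Performance, false-alarm and miss fractions per (size x change-time bin),
    the curve families the model is fitted against."""
    df = records if "outcome" in records.columns else classify_frame(records)
    edges, assignment = bin_change_times(df["change_time"].to_numpy(), n_time_bins)
    df = df.assign(time_bin=assignment)
    rows = []
    for (size, tb), g in df.groupby(["size", "time_bin"]):
        n = len(g)
        hits = (g["outcome"] == "hit").sum()
        misses = (g["outcome"] == "miss").sum()
        fas = (g["outcome"] == "false_alarm").sum()
        rows.append({
            "size": size, "time_bin": int(tb),
            "t": 0.5 * (edges[tb] + edges[tb + 1]), "n_trials": n,
            "performance": hits / (hits + misses) if hits + misses else np.nan,
            "fa_fraction": fas / n,
            "miss_fraction": misses / n,
        })
    return pd.DataFrame(rows).sort_values(["size", "time_bin"]).reset_index(drop=True)


def _grid_axis(spec) -> np.ndarray:
    """A tuple (start, stop, step) describes a range; a list or array holds
    explicit grid values."""
    if isinstance(spec, tuple) and len(spec) == 3:
        start, stop, step = spec
        return np.round(np.arange(start, stop + step / 2, step), 10)
    return np.asarray(spec, dtype=float)


@dataclass
class FitReport:
    params: DualParams
    mse: float
    mse_by_family: dict
    correlation_by_family: dict
    on_boundary: bool
    grid_shape: tuple


def fit_to_behavior(targets: pd.DataFrame,
                    trials: list[TrialSpec],
                    grid_spec: dict | None = None,
                    base_params: DualParams = DualParams(),
                    n_time_bins: int = 4,
                    grid: ToneGrid | None = None,
                    method: str = "euler",
                    input_mode: str = "count") -> FitReport:
    """Exhaustive grid search for (tau_f, tau_s, tau_a, T) minimizing the mean
    squared error pooled over the performance, false-alarm and miss curves.

    ``targets`` is a summary table from :func:`summarize_conditions` (human or
    model-generated).  The search is exhaustive - no local minima, no
    dependence on starting values - and the stimulus set is realized once and
    reused at every grid point.  A minimum on the edge of the grid is flagged
    (``on_boundary``), signalling that the grid is too coarse or too narrow.
    """
    grid = grid or stimulus.build_frequency_grid()
    spec = {**DEFAULT_GRID, **(grid_spec or {})}
    axes = {k: _grid_axis(v) for k, v in spec.items()}
    pre = trial_event_series(trials, grid, dt=base_params.dt, input_mode=input_mode)

    tkey = ["size", "time_bin"]
    tgt = targets.set_index(tkey)[["performance", "fa_fraction", "miss_fraction"]]

    best = None
    combos = list(product(*axes.values()))
    names = list(axes.keys())
    for values in combos:
        kw = dict(zip(names, values))
        if kw["tau_s"] <= kw["tau_f"]:
            continue
        p = replace(base_params, **kw)
        rec = simulate_experiment(trials, p, grid=grid, method=method,
                                  input_mode=input_mode, precomputed=pre)
        summ = summarize_conditions(rec, n_time_bins).set_index(tkey)
        joined = tgt.join(summ, how="inner", lsuffix="_tgt", rsuffix="_mod").dropna()
        fam_mse = {}
        fam_corr = {}
        for fam in ["performance", "fa_fraction", "miss_fraction"]:
            a = joined[f"{fam}_tgt"].to_numpy()
            b = joined[f"{fam}_mod"].to_numpy()
            fam_mse[fam] = float(np.mean((a - b) ** 2))
            fam_corr[fam] = float(np.corrcoef(a, b)[0, 1]) if a.std() > 0 and b.std() > 0 else np.nan
        mse = float(np.mean(list(fam_mse.values())))
        if best is None or mse < best[0]:
            best = (mse, kw, fam_mse, fam_corr)

    mse, kw, fam_mse, fam_corr = best
    boundary = any(
        np.isclose(kw[k], axes[k][0]) or np.isclose(kw[k], axes[k][-1])
        for k in names if axes[k].size > 1
    )
    return FitReport(
        params=replace(base_params, **kw),
        mse=mse,
        mse_by_family=fam_mse,
        correlation_by_family=fam_corr,
        on_boundary=boundary,
        grid_shape=tuple(axes[k].size for k in names),
    )
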