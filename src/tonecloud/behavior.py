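"""Behavioral statistics for the change-detection task.

All functions operate on a tidy response table (one row per trial) with at
least the columns ``change_time`` (s from stimulus onset) and
``response_time`` (s from onset, NaN when no button press occurred), so
human-format and model-generated responses are analyzed identically.

Outcome semantics: a press at or before the change time is a false alarm, a
press within the 2 s window after the change is a hit, anything else
(including no press) is a miss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import norm

from .stimulus import CHANGE_TIME_CAP, CHANGE_TIME_MEAN, RESPONSE_WINDOW

DPRIME_DT = 0.25      # s, default analysis grid for time-resolved d' and FA rate


def classify_trial(change_time: float,
                   response_time: float | None,
                   window: float = RESPONSE_WINDOW) -> tuple[str, float | None]:
    """Classify one trial; returns (outcome, reaction_time).

    Reaction time (response - change) is defined for hits only.
    """
    if change_time < 0:
        raise ValueError("change_time must be nonnegative")
    if response_time is None or (isinstance(response_time, float) and np.isnan(response_time)):
        return "miss", None
    if response_time < 0:
        raise ValueError("response_time must be nonnegative")
    if response_time <= change_time:
        return "false_alarm", None
    if response_time <= change_time + window:
        return "hit", float(response_time - change_time)
    return "miss", None


def classify_frame(df: pd.DataFrame, window: float = RESPONSE_WINDOW) -> pd.DataFrame:
    """Vectorized classification; adds ``outcome`` and ``reaction_time`` columns."""
    ct = df["change_time"].to_numpy(float)
    rt = df["response_time"].to_numpy(float)
    if np.any(ct < 0) or np.any(rt[~np.isnan(rt)] < 0):
        raise ValueError("negative times")
    pressed = ~np.isnan(rt)
    fa = pressed & (rt <= ct)
    hit = pressed & (rt > ct) & (rt <= ct + window)
    outcome = np.where(fa, "false_alarm", np.where(hit, "hit", "miss"))
    reaction = np.where(hit, rt - ct, np.nan)
    out = df.copy()
    out["outcome"] = outcome
    out["reaction_time"] = reaction
    return out


def bin_change_times(change_times: np.ndarray,
                     n_bins: int,
                     mean: float = CHANGE_TIME_MEAN,
                     cap: float = CHANGE_TIME_CAP,
                     method: str = "exponential") -> tuple[np.ndarray, np.ndarray]:
    """Bin change times into ``n_bins`` bins of exponentially increasing width.

    ``method='exponential'`` places the edges at the quantiles of the capped
    exponential change-time law, which equalizes expected per-bin counts;
    ``method='quantile'`` uses empirical equal-count quantiles (the convention
    used for the four EEG analysis bins).  Returns (edges, assignment).
    """
    change_times = np.asarray(change_times, dtype=float)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if change_times.size < n_bins:
        raise ValueError("fewer trials than bins")
    if method == "exponential":
        q = np.linspace(0, 1, n_bins + 1)
        mass = 1 - np.exp(-cap / mean)
        edges = -mean * np.log1p(-q * mass)
        edges[0], edges[-1] = 0.0, cap
    elif method == "quantile":
        edges = np.quantile(change_times, np.linspace(0, 1, n_bins + 1))
        edges[0], edges[-1] = 0.0, max(cap, edges[-1])
    else:
        raise ValueError(f"unknown method {method!r}")
    assignment = np.clip(np.searchsorted(edges, change_times, side="right") - 1, 0, n_bins - 1)
    return edges, assignment


def performance_table(records: pd.DataFrame,
                      n_time_bins: int = 6,
                      edges: np.ndarray | None = None) -> pd.DataFrame:
    """Per (change size x change-time bin) trial counts and performance.

    Performance = hits / (hits + misses): trials in which the change occurred
    before any response; false alarms are excluded (they carry no information
    about the post-change stimulus).
    """
    df = records if "outcome" in records.columns else classify_frame(records)
    if edges is None:
        edges, _ = bin_change_times(df["change_time"].to_numpy(), n_time_bins)
    ct = df["change_time"].to_numpy(float)
    assignment = np.clip(np.searchsorted(edges, ct, side="right") - 1, 0, len(edges) - 2)
    df = df.assign(time_bin=assignment)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for (size, tb), g in df.groupby(["size", "time_bin"]):
        hits = int((g["outcome"] == "hit").sum())
        misses = int((g["outcome"] == "miss").sum())
        fas = int((g["outcome"] == "false_alarm").sum())
        perf = hits / (hits + misses) if hits + misses else np.nan
        rows.append({"size": size, "time_bin": int(tb), "t": centers[int(tb)],
                     "n_trials": len(g), "hits": hits, "misses": misses,
                     "false_alarms": fas, "performance": perf})
    return pd.DataFrame(rows).sort_values(["size", "time_bin"]).reset_index(drop=True)


def instantaneous_fa_rate(records: pd.DataFrame,
                          dt: float = DPRIME_DT,
                          t_max: float = CHANGE_TIME_CAP) -> pd.DataFrame:
    """False alarms per second per at-risk trial, over time in the trial.

    The risk set at bin [t, t+dt) contains trials whose change has not yet
    occurred (change_time > t) and that have not yet been responded to.  An
    empty risk set yields NaN (missing), never zero.
    """
    if len(records) == 0:
        raise ValueError("no records")
    ct = records["change_time"].to_numpy(float)
    rt = records["response_time"].to_numpy(float)
    edges = np.arange(0.0, t_max + dt / 2, dt)
    rates = np.full(edges.size - 1, np.nan)
    for k, t in enumerate(edges[:-1]):
        risk = (ct > t) & (np.isnan(rt) | (rt >= t))
        n_risk = int(risk.sum())
        if n_risk == 0:
            continue
        fa = risk & ~np.isnan(rt) & (rt < t + dt) & (rt <= ct)
        rates[k] = fa.sum() / (n_risk * dt)
    return pd.DataFrame({"t": edges[:-1], "fa_rate": rates})


@dataclass
class DPrimeCurve:
    t: np.ndarray
    hr: np.ndarray
    far: np.ndarray
    dprime: np.ndarray
    n_hr: np.ndarray | None = None
    n_far: np.ndarray | None = None
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None


def _clip_rate(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Keep rates away from {0, 1} before the inverse normal (1/(2N) rule)."""
    n = np.maximum(n, 1)
    return np.clip(p, 1.0 / (2 * n), 1 - 1.0 / (2 * n))


def _dprime_rates(ct, rt, t_edges, window, min_count=1):
    """HR(t) from trials changing within each bin; FAR(t) from 2 s no-change
    windows starting at the bin's left edge (windows advance at the grid step,
    hence overlap).  Cells with fewer than ``min_count`` trials are missing."""
    nt = t_edges.size - 1
    hr = np.full(nt, np.nan)
    far = np.full(nt, np.nan)
    n_hr = np.zeros(nt)
    n_far = np.zeros(nt)
    pressed = ~np.isnan(rt)
    hit = pressed & (rt > ct) & (rt <= ct + window)
    miss_or_hit = hit | ~(pressed & (rt <= ct))        # change occurred before response
    for k in range(nt):
        t0, t1 = t_edges[k], t_edges[k + 1]
        in_bin = (ct >= t0) & (ct < t1)
        n = int((in_bin & miss_or_hit).sum())
        if n >= min_count:
            hr[k] = (in_bin & hit).sum() / n
            n_hr[k] = n
        # no-change windows: change strictly after the window, trial still at risk
        at_risk = (ct > t0 + window) & (np.isnan(rt) | (rt > t0))
        m = int(at_risk.sum())
        if m >= min_count:
            far[k] = (at_risk & pressed & (rt <= t0 + window)).sum() / m
            n_far[k] = m
    return hr, far, n_hr, n_far


def time_dependent_dprime(records: pd.DataFrame,
                          window: float = RESPONSE_WINDOW,
                          dt: float = DPRIME_DT,
                          t_max: float = CHANGE_TIME_CAP,
                          min_count: int = 50,
                          n_boot: int = 0,
                          rng: np.random.Generator | None = None) -> DPrimeCurve:
    """Time-resolved sensitivity d'(t) = Z(HR(t)) - Z(FAR(t)) on pooled trials.

    Long trials act as catch trials before their change: the false-alarm rate
    at t is the fraction of still-at-risk, no-change 2 s windows starting at t
    that contain a press.  Rates are clipped by the 1/(2N) rule before the
    inverse Gaussian CDF, and cells with fewer than ``min_count`` trials are
    reported missing rather than fed through Z (rates from a handful of
    trials produce wild sensitivity estimates).  With ``n_boot`` > 0, 95%
    percentile bootstrap bounds over trial resampling are attached.
    """
    ct = records["change_time"].to_numpy(float)
    rt = records["response_time"].to_numpy(float)
    t_edges = np.arange(0.0, t_max + dt / 2, dt)

    def curve(ct, rt):
        hr, far, n_hr, n_far = _dprime_rates(ct, rt, t_edges, window, min_count)
        with np.errstate(invalid="ignore"):
            d = norm.ppf(_clip_rate(hr, n_hr)) - norm.ppf(_clip_rate(far, n_far))
        d[np.isnan(hr) | np.isnan(far)] = np.nan
        return hr, far, d, n_hr, n_far

    hr, far, d, n_hr, n_far = curve(ct, rt)
    lo = hi = None
    if n_boot > 0:
        rng = rng or np.random.default_rng()
        boots = np.empty((n_boot, d.size))
        n = ct.size
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            boots[b] = curve(ct[idx], rt[idx])[2]
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)
    return DPrimeCurve(t_edges[:-1], hr, far, d, n_hr, n_far, lo, hi)


def mean_dprime(curve: DPrimeCurve, weighted: bool = True) -> float:
    """Average sensitivity over the time grid.

    With ``weighted=True`` (default) grid points are pooled by inverse
    delta-method variance of d' (cells backed by more trials count more),
    the usual stabilization when late cells hold few trials; ``False`` gives
    the plain mean over defined grid points.
    """
    ok = ~np.isnan(curve.dprime)
    d = curve.dprime[ok]
    if not weighted or curve.n_hr is None:
        return float(d.mean())
    hr = _clip_rate(curve.hr[ok], curve.n_hr[ok])
    far = _clip_rate(curve.far[ok], curve.n_far[ok])
    var = (hr * (1 - hr) / (curve.n_hr[ok] * norm.pdf(norm.ppf(hr)) ** 2)
           + far * (1 - far) / (curve.n_far[ok] * norm.pdf(norm.ppf(far)) ** 2))
    w = 1.0 / var
    return float(np.sum(w * d) / np.sum(w))


# -- Performance dynamics (Erlang CDF) ----------------------------------------

def erlang_cdf(tc: np.ndarray, p0: float, pmax: float, tau: float, k: int) -> np.ndarray:
    """Sigmoidal performance curve P(tc) = P0 + Pmax * gamma(k, tc/tau)/(k-1)!.

    The regularized lower incomplete gamma with integer shape k is the CDF of
    an Erlang distribution; it rises from P0 at tc=0 to P0+Pmax.
    """
    return p0 + pmax * special.gammainc(k, np.asarray(tc, dtype=float) / tau)


@dataclass
class ErlangFit:
    k: int
    params: dict            # size -> (p0, pmax, tau)
    residual: float         # summed squared residual at the chosen k
    per_size_residual: dict
    success: bool

    def tau(self, size) -> float:
        return self.params[size][2]

    def predict(self, size, tc):
        p0, pmax, tau = self.params[size]
        return erlang_cdf(tc, p0, pmax, tau, self.k)


def _fit_one_size(t, y, k, weights=None):
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)

    def resid(x):
        p0, pmax, tau = x
        r = w * (erlang_cdf(t, p0, pmax, tau, k) - y)
        # soft ceiling: asymptote may not exceed 1
        return np.append(r, 10.0 * max(0.0, p0 + pmax - 1.0))

    x0 = np.array([max(min(y), 1e-3), min(max(y) - min(y) + 1e-3, 1.0), max(t.mean() / k, 0.1)])
    res = optimize.least_squares(resid, x0, bounds=([0, 0, 1e-3], [1, 1, 50]))
    return res.x, float(np.sum(res.fun ** 2)), res.success


def fit_erlang_cdf(table: pd.DataFrame,
                   k_range=range(1, 7),
                   weights: str | None = None) -> ErlangFit:
    """Fit the Erlang-CDF dynamics to a performance table (columns ``size``,
    ``t``, ``performance``), with per-size (P0, Pmax, tau) and one integer
    shape k shared across sizes, chosen by global least squares.

    Raises ValueError with diagnostics when any size has fewer than 4 bins.
    """
    best = None
    for size, g in table.groupby("size"):
        if g["performance"].notna().sum() < 4:
            raise ValueError(f"size {size}: need >= 4 change-time bins to fit")
    for k in k_range:
        params, residual, per_size, ok = {}, 0.0, {}, True
        for size, g in table.groupby("size"):
            g = g.dropna(subset=["performance"])
            w = np.sqrt(g["n_trials"].to_numpy(float)) if weights == "trials" else None
            x, sse, success = _fit_one_size(g["t"].to_numpy(float),
                                            g["performance"].to_numpy(float), k, w)
            params[size] = tuple(x)
            per_size[size] = sse
            residual += sse
            ok = ok and success
        if best is None or residual < best.residual:
            best = ErlangFit(k=k, params=params, residual=residual,
                             per_size_residual=per_size, success=ok)
    if not best.success:
        raise RuntimeError(f"Erlang fit did not converge (k={best.k}, residual={best.residual:.4g})")
    return best


def bootstrap_erlang_fit(records: pd.DataFrame,
                         n_boot: int = 200,
                         n_time_bins: int = 6,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Percentile bootstrap (over trials) of the per-size Erlang parameters."""
    rng = rng or np.random.default_rng()
    df = records if "outcome" in records.columns else classify_frame(records)
    rows = []
    n = len(df)
    for b in range(n_boot):
        samp = df.iloc[rng.integers(0, n, n)]
        try:
            fit = fit_erlang_cdf(performance_table(samp, n_time_bins))
        except (ValueError, RuntimeError):
            continue
        for size, (p0, pmax, tau) in fit.params.items():
            rows.append({"boot": b, "size": size, "p0": p0, "pmax": pmax,
                         "tau": tau, "k": fit.k})
    return pd.DataFrame(rows)


# -- ROC analysis over reaction-time distributions ----------------------------

def fa_pseudo_reaction_times(records: pd.DataFrame,
                             window: float = RESPONSE_WINDOW,
                             step: float = DPRIME_DT,
                             t_max: float = CHANGE_TIME_CAP) -> np.ndarray:
    """Artificial reaction times for false alarms: for every no-change window
    [t, t+2) on the analysis grid that contains the trial's press, the pseudo
    reaction time is press - t."""
    ct = records["change_time"].to_numpy(float)
    rt = records["response_time"].to_numpy(float)
    fa = ~np.isnan(rt) & (rt <= ct)
    out = []
    for t in np.arange(0.0, t_max, step):
        sel = fa & (ct > t + window) & (rt > t) & (rt <= t + window)
        out.extend(rt[sel] - t)
    return np.asarray(out)


def auroc(hit_rts: np.ndarray,
          fa_rts: np.ndarray,
          t_grid: np.ndarray | None = None) -> tuple[float, np.ndarray, np.ndarray]:
    """Area under the ROC built from the two reaction-time distributions.

    At each grid time the hit and false-alarm probabilities are the fractions
    of each distribution at or below that time; the curve is closed at (0,0)
    and (1,1) and integrated by the trapezoid rule.  Default grid: 0.2-2 s in
    0.2 s steps.
    """
    hit_rts = np.asarray(hit_rts, float)
    fa_rts = np.asarray(fa_rts, float)
    if hit_rts.size == 0 or fa_rts.size == 0:
        raise ValueError("both reaction-time samples must be nonempty")
    if t_grid is None:
        t_grid = np.arange(0.2, 2.0001, 0.2)
    hp = np.array([(hit_rts <= t).mean() for t in t_grid])
    fp = np.array([(fa_rts <= t).mean() for t in t_grid])
    fp_full = np.concatenate([[0.0], fp, [1.0]])
    hp_full = np.concatenate([[0.0], hp, [1.0]])
    if np.unique(fp_full).size < 3:
        raise ValueError("degenerate ROC: too few distinct false-alarm probabilities")
    area = float(np.trapezoid(hp_full, fp_full))
    return area, hp, fp


def auroc_by_change_size(records: pd.DataFrame,
                         t_grid: np.ndarray | None = None,
                         window: float = RESPONSE_WINDOW) -> pd.DataFrame:
    """AUROC of hit reaction times against pooled false-alarm pseudo reaction
    times, per change size."""
    df = records if "outcome" in records.columns else classify_frame(records)
    fa_rts = fa_pseudo_reaction_times(df, window=window)
    rows = []
    for size, g in df.groupby("size"):
        hit_rts = g.loc[g["outcome"] == "hit", "reaction_time"].dropna().to_numpy()
        if hit_rts.size == 0:
            rows.append({"size": size, "auroc": np.nan, "n_hits": 0})
            continue
        area, _, _ = auroc(hit_rts, fa_rts, t_grid)
        rows.append({"size": size, "auroc": area, "n_hits": int(hit_rts.size)})
    return pd.DataFrame(rows)
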