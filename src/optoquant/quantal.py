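"""Optical quantal analysis of low-frequency trial trains.

At 0.1 Hz the inter-stimulus interval is long compared with the sensor
off-rate, so each stimulus yields an independent trial.  Trial peak
amplitudes form a mixture of failures and quantized successes at integer
multiples of the single-vesicle quantal size q; an equal-spacing Gaussian
mixture fitted by grid search plus constrained EM recovers q, and counting
failures gives the release probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QuantalFit",
    "QuantalSummary",
    "extract_trial_amplitudes",
    "classify_failures",
    "fit_quantal_peaks",
    "summarize_quantal",
]


@dataclass
class QuantalFit:
    q: float                      # quantal size, ΔF/F0 per vesicle
    n_peaks: int                  # K: components at 0, q, ..., K*q
    weights: np.ndarray
    sigma0: float                 # failure-noise SD
    sigma1: float                 # per-quantum SD increment (sigma_k^2 = s0^2 + k*s1^2)
    loglik: float
    bic: float
    n: int


@dataclass
class QuantalSummary:
    release_prob: float
    mean_quanta_per_success: float
    max_quanta: int
    quantal_content_per_stimulus: float
    q: float
    n_trials: int
    n_failures: int


def extract_trial_amplitudes(trace, frame_times, stim_times,
                             peak_window: tuple[float, float] = (0.0, 2.0),
                             base_window: tuple[float, float] = (-2.0, 0.0)
                             ) -> pd.DataFrame:
    """Per-stimulus peak ΔF/F0 amplitudes from a hotspot trace.

    Amplitude = max of the trace in ``peak_window`` after the stimulus minus
    the mean in ``base_window`` before it.  Because the maximum of a noisy
    window is positively biased even without any release, the same max
    statistic is evaluated on every trial's baseline segment; its pooled mean
    is subtracted from the amplitudes (a matched-null debias that shifts all
    trials equally, leaving the quantal spacing untouched) and its pooled SD
    is reported as the trial noise.  Windows that would overlap a neighbouring
    stimulus raise.
    """
    trace = np.asarray(trace, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size == 0:
        raise ValueError("no stimuli")
    isi = np.diff(stim_times).min() if stim_times.size > 1 else np.inf
    if peak_window[1] - base_window[0] > isi:
        raise ValueError("peak/base windows overlap the adjacent stimulus")
    rows = []
    null_amps = []
    for t_s in stim_times:
        pk = (frame_times >= t_s + peak_window[0]) & (frame_times <= t_s + peak_window[1])
        bs = (frame_times >= t_s + base_window[0]) & (frame_times < t_s + base_window[1])
        if not pk.any() or not bs.any():
            raise ValueError("window contains no frames")
        b = trace[bs]
        rows.append((t_s, float(trace[pk].max() - b.mean())))
        null_amps.append(float(b.max() - b.mean()))
    null_amps = np.asarray(null_amps)
    null_mean = float(null_amps.mean())
    noise_sd = float(null_amps.std(ddof=1)) if null_amps.size > 1 else np.nan
    df = pd.DataFrame(rows, columns=["time", "amplitude"])
    df["amplitude"] -= null_mean
    df.insert(0, "stimulus", np.arange(1, len(rows) + 1))
    df["noise_sd"] = noise_sd
    return df


def classify_failures(table: pd.DataFrame, noise_sd: float | None = None,
                      q: float | None = None) -> pd.DataFrame:
    """Two-pass failure classification.

    Pass 1 (noise-based): amplitude below twice the trial-noise SD is a
    failure.  Pass 2 (quantal, once q is known): amplitude below q/2 is a
    failure.  Both flags are recorded; the final ``failure`` column uses pass
    2 when available, else pass 1.
    """
    out = table.copy()
    if noise_sd is None:
        noise_sd = float(out["noise_sd"].iloc[0])
    if noise_sd is None or not np.isfinite(noise_sd):
        raise ValueError("noise SD unavailable")
    amp = out["amplitude"].to_numpy()
    out["failure_pass1"] = amp < 2.0 * noise_sd
    if q is not None:
        out["failure_pass2"] = amp < q / 2.0
        out["failure"] = out["failure_pass2"]
    else:
        out["failure"] = out["failure_pass1"]
    return out


def _mixture_loglik(amps, q, weights, s0, s1):
    k = np.arange(weights.size)
    var = s0 * s0 + k * s1 * s1
    var = np.clip(var, 1e-18, None)
    # (n, K+1) component densities
    z = amps[:, None] - k[None, :] * q
    log_comp = -0.5 * z * z / var[None, :] - 0.5 * np.log(2 * np.pi * var)[None, :]
    with np.errstate(divide="ignore"):
        log_w = np.log(np.clip(weights, 1e-300, None))
    m = log_comp + log_w[None, :]
    mmax = m.max(axis=1, keepdims=True)
    return float((mmax[:, 0] + np.log(np.exp(m - mmax).sum(axis=1))).sum()), m


def fit_quantal_peaks(amplitudes, k_max: int = 5, grid_resolution: float = 0.01,
                      fit_sigma1: bool = True, n_em: int = 200,
                      tol: float = 1e-10) -> QuantalFit:
    """Equal-spacing Gaussian-mixture fit of a trial-amplitude sample.

    Component means are constrained to ``{0, q, 2q, ..., Kq}``; component
    variances follow ``sigma_k^2 = sigma0^2 + k sigma1^2`` (failure noise plus
    an optional per-quantum variance).  For each K in 1..``k_max`` the quantal
    size q is first located on a grid with resolution ``grid_resolution`` of
    the amplitude range, then refined by EM with the spacing constraint; K is
    selected by BIC, ties going to the smallest K.  Fitting uses the raw
    amplitudes, never a histogram.
    """
    amps = np.asarray(amplitudes, dtype=float)
    amps = amps[np.isfinite(amps)]
    n = amps.size
    if n < 20:
        raise ValueError("need at least 20 amplitudes")
    a_max = amps.max()
    if a_max <= 0:
        raise ValueError("all failures")
    rng_amp = max(np.ptp(amps), a_max)
    step = grid_resolution * rng_amp
    scale_floor = 1e-9 * rng_amp

    best = None
    for K in range(1, k_max + 1):
        q_lo = max(a_max / (K + 0.49), 2 * step)
        q_grid = np.arange(q_lo, a_max * 1.05 + step, step)
        if q_grid.size == 0:
            continue
        # grid scoring: hard-assignment SSE
        sse = np.empty(q_grid.size)
        for i, q in enumerate(q_grid):
            k_hat = np.clip(np.round(amps / q), 0, K)
            sse[i] = ((amps - k_hat * q) ** 2).sum()
        q = float(q_grid[np.argmin(sse)])
        # EM refinement with spacing constraint
        k_hat = np.clip(np.round(amps / q), 0, K).astype(int)
        weights = np.bincount(k_hat, minlength=K + 1).astype(float) / n
        s0 = max(float(np.sqrt(sse.min() / n)), scale_floor)
        s1 = s0 / 2.0 if fit_sigma1 else 0.0
        prev = -np.inf
        for _ in range(n_em):
            ll, m = _mixture_loglik(amps, q, weights, s0, s1)
            mmax = m.max(axis=1, keepdims=True)
            g = np.exp(m - mmax)
            g /= g.sum(axis=1, keepdims=True)
            weights = g.mean(axis=0)
            ks = np.arange(K + 1)
            var = np.clip(s0 * s0 + ks * s1 * s1, 1e-18, None)
            wk = g / var[None, :]
            num = (wk * ks[None, :] * amps[:, None]).sum()
            den = (wk * (ks * ks)[None, :]).sum()
            if den > 0:
                q = max(num / den, 2 * scale_floor)
            # variance model: per-component second moments, regressed on k
            z2 = (amps[:, None] - ks[None, :] * q) ** 2
            gk = g.sum(axis=0)
            s_k = (g * z2).sum(axis=0) / np.clip(gk, 1e-12, None)
            if fit_sigma1 and K >= 1 and gk[1:].sum() > 0:
                # weighted LS of s_k = s0^2 + k*s1^2 with nonneg coefficients
                A = np.stack([np.ones_like(ks, dtype=float), ks.astype(float)], axis=1)
                w = np.sqrt(np.clip(gk, 0, None))
                coef, *_ = np.linalg.lstsq(A * w[:, None], s_k * w, rcond=None)
                v0, v1 = max(coef[0], scale_floor ** 2), max(coef[1], 0.0)
            else:
                v0 = (g * z2).sum() / n
                v0, v1 = max(v0, scale_floor ** 2), 0.0
            s0, s1 = math.sqrt(v0), math.sqrt(v1)
            if abs(ll - prev) < tol * max(abs(ll), 1.0):
                break
            prev = ll
        ll, _ = _mixture_loglik(amps, q, weights, s0, s1)
        n_par = K + 2 + (1 if fit_sigma1 else 0)   # weights(K) + q + s0 (+ s1)
        bic = -2.0 * ll + n_par * math.log(n)
        fit = QuantalFit(q=q, n_peaks=K, weights=weights, sigma0=s0, sigma1=s1,
                         loglik=ll, bic=bic, n=n)
        if best is None or bic < best.bic - 1e-9:
            best = fit
    return best


def summarize_quantal(table: pd.DataFrame, fit: QuantalFit) -> QuantalSummary:
    """Release probability and quantal content from classified trials.

    Pr = 1 - failures/trials.  Quanta per successful response =
    ``round(amplitude / q)`` clipped to >= 1; reported both per success (mean
    and max) and per stimulus (Pr x mean, the quantal content).
    """
    if "failure" not in table.columns:
        raise ValueError("run classify_failures first")
    n = len(table)
    failures = int(table["failure"].sum())
    pr = 1.0 - failures / n
    succ = table.loc[~table["failure"], "amplitude"].to_numpy()
    if succ.size:
        quanta = np.clip(np.round(succ / fit.q), 1, None).astype(int)
        mean_q = float(quanta.mean())
        max_q = int(quanta.max())
    else:
        mean_q, max_q = 0.0, 0
    return QuantalSummary(
        release_prob=pr,
        mean_quanta_per_success=mean_q,
        max_quanta=max_q,
        quantal_content_per_stimulus=pr * mean_q,
        q=fit.q,
        n_trials=n,
        n_failures=failures,
    )
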