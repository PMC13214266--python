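"""Parameter-recovery studies: simulate at known ground truth, run the full
analysis chain, and compare what comes back.

Because no raw imaging data accompany the published group values, the
pipeline is validated by recovery: synthetic fixtures are generated with the
published values as ground truth and each stage must return them within its
documented tolerance.  These functions are also exposed through the
``optoquant recover`` CLI subcommand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import hotspots, pool, preprocess, quantal
from .simulate import (HotspotSpec, SimulationConfig, impulse_response,
                       render_movie, render_trace, simulate_release_train)

__all__ = [
    "spread_recovery",
    "quantal_recovery",
    "pool_recovery",
    "SPREAD_PROTOCOL",
]

# 20-pulse 16 Hz conditioning train used for the spread fixtures
SPREAD_PROTOCOL = dict(n_pulses=20, freq_hz=16.0, start_s=1.0)


def _rng_seed(base_seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(base_seed), *tags]))


# ------------------------------------------------------------------ spread

def spread_recovery(lambda_true: float, n_hotspots: int = 20,
                    base_seed: int = 1, seed_offset: int = 0,
                    pixel_size_um: float = 0.1625,
                    psf_sigma_um: float = 0.25,
                    peak_snr: float = 10.0,
                    peak_dff: float = 0.15,
                    n_iter: int = 50,
                    image_shape=(48, 48),
                    frame_rate: float = 10.0) -> pd.DataFrame:
    """Recover the spread length constant through the full imaging pipeline.

    Each fixture movie contains one release site with radial profile
    ``A exp(-r/lambda_true)``, PSF-blurred (Gaussian ``psf_sigma_um``) and
    Poisson-noisy with a basal-fluorescence level chosen so the peak ΔF/F0
    has the requested photon-shot SNR.  The movie runs through alignment and
    Landweber deconvolution (``n_iter`` iterations); spatial analysis then
    uses the ΔF/F0 map at the frame of maximal response (a one-frame
    max-map window, which avoids the per-pixel max-of-noise offset that a
    wide window would add to the profile tail), followed by radial profiling
    and the single-exponential spread fit.

    Returns one row per fixture: seed, recovered lambda, fit R², relative
    error.
    """
    p = SPREAD_PROTOCOL
    stim_times = p["start_s"] + np.arange(p["n_pulses"]) / p["freq_hz"]
    n_frames = int(frame_rate * (p["start_s"] + p["n_pulses"] / p["freq_hz"] + 1.0))
    tau_rise, tau_off = 0.1, 8.96
    # quantal size such that the summed train response peaks at peak_dff
    t = np.arange(n_frames) / frame_rate
    kernel_sum = np.zeros_like(t)
    for ts in stim_times:
        kernel_sum += impulse_response(t - ts, tau_off, tau_rise)
    q = peak_dff / kernel_sum.max()
    f0_mean = (peak_snr / peak_dff) ** 2

    fov = (image_shape[0] * pixel_size_um, image_shape[1] * pixel_size_um)
    rows = []
    for i in range(n_hotspots):
        seed = base_seed * 100000 + seed_offset + i
        rng = _rng_seed(seed, 0)
        center = (fov[0] / 2 + rng.uniform(-0.3, 0.3),
                  fov[1] / 2 + rng.uniform(-0.3, 0.3))
        spec = HotspotSpec(center_um=center, lambda_um=lambda_true,
                           quantal_size=q, release_prob=1.0,
                           quanta_weights=(1.0,))
        config = SimulationConfig(
            image_shape=image_shape, pixel_size_um=pixel_size_um,
            frame_rate=frame_rate, n_frames=n_frames,
            stim_times=tuple(stim_times), hotspots=[spec],
            f0_mean=f0_mean, f0_cv=0.0, tau_rise=tau_rise, tau_off=tau_off,
            psf_sigma_um=psf_sigma_um, read_noise=2.0, seed=seed)
        events = simulate_release_train(spec, stim_times, seed=seed + 7)
        movie, _ = render_movie([events], config)

        psf = preprocess.gaussian_psf(psf_sigma_um / pixel_size_um)
        pre_frames = int(p["start_s"] * frame_rate)
        reg = preprocess.register_translation(movie)
        aligned = reg.aligned
        # frame of maximal response (from the raw ΔF/F0 estimate)
        raw_dff = preprocess.compute_dff(aligned, (0, pre_frames))
        frame_sum = np.nansum(raw_dff.dff, axis=(1, 2))
        f_peak = int(np.argmax(frame_sum[pre_frames:])) + pre_frames
        # deconvolve the temporal average of a short window around the peak
        # (the slow sensor holds the spatial pattern steady there; averaging
        # cuts shot noise without touching the profile shape)
        lo, hi = max(pre_frames, f_peak - 2), min(n_frames, f_peak + 3)
        peak_avg = aligned[lo:hi].mean(axis=0)
        sub = np.concatenate([aligned[:pre_frames], peak_avg[None]])
        dec = preprocess.landweber_deconvolve(sub, psf, n_iter=n_iter)
        dff = preprocess.compute_dff(dec.stack, (0, pre_frames))
        mp = hotspots.max_dff_map(dff.dff, (pre_frames, pre_frames + 1))
        mp.pixel_size_um = pixel_size_um
        center_px = hotspots.find_center(mp.values)
        prof = hotspots.radial_profile(mp, center_px, max_radius_um=2.0)
        fit = hotspots.fit_spread(prof, r_min_um=2.0 * pixel_size_um)
        rows.append({"seed": seed, "lambda_true": lambda_true,
                     "lambda_hat": fit.lambda_um, "r2": fit.r2,
                     "rel_error": abs(fit.lambda_um - lambda_true) / lambda_true})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ quantal

def quantal_recovery(q_true: float = 0.40, pr_true: float = 0.79,
                     quanta_weights=(0.75, 0.20, 0.05),
                     n_hotspots: int = 10, n_trials: int = 100,
                     noise_frac: float = 0.2,
                     base_seed: int = 1) -> pd.DataFrame:
    """Recover quantal size, release probability and quantal content from
    simulated 0.1 Hz trial-amplitude tables.

    Per trial: success with probability ``pr_true``; on success k vesicles
    drawn from ``quanta_weights`` give amplitude k*q_true; Gaussian trial
    noise with SD ``noise_frac * q_true`` is added throughout.  Failures are
    classified with the two-pass rule, the equal-spacing mixture is fitted on
    the raw amplitudes, and the summary statistics are computed per hotspot.
    """
    weights = np.asarray(quanta_weights, dtype=float)
    weights = weights / weights.sum()
    kvals = np.arange(1, weights.size + 1)
    noise_sd = noise_frac * q_true
    rows = []
    for i in range(n_hotspots):
        rng = _rng_seed(base_seed, 1, i)
        success = rng.random(n_trials) < pr_true
        k = np.where(success, rng.choice(kvals, size=n_trials, p=weights), 0)
        amps = k * q_true + rng.normal(0.0, noise_sd, n_trials)
        table = pd.DataFrame({
            "stimulus": np.arange(1, n_trials + 1),
            "time": np.arange(n_trials) * 10.0,
            "amplitude": amps,
            "noise_sd": noise_sd,
        })
        table = quantal.classify_failures(table, noise_sd=noise_sd)
        fit = quantal.fit_quantal_peaks(table["amplitude"].to_numpy())
        table = quantal.classify_failures(table, noise_sd=noise_sd, q=fit.q)
        summ = quantal.summarize_quantal(table, fit)
        rows.append({
            "hotspot": i, "q_true": q_true, "q_hat": fit.q,
            "n_peaks": fit.n_peaks,
            "pr_true": pr_true, "pr_hat": summ.release_prob,
            "mean_quanta_true": float((weights * kvals).sum()),
            "mean_quanta_hat": summ.mean_quanta_per_success,
            "max_quanta_hat": summ.max_quanta,
            "quantal_content_per_stim": summ.quantal_content_per_stimulus,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- pool

def pool_recovery(rrp_whole: float = 19.93, refill_per_1000_whole: float = 22.0,
                  pr: float = 0.8, q: float = 0.4, tau_off: float = 8.96,
                  quanta_weights=(0.75, 0.20, 0.05),
                  n_cells: int = 13, n_hotspots_per_cell: int = 10,
                  n_stim: int = 1920, stim_hz: float = 16.0,
                  frame_hz: float = 10.0, tau_rise_gen: float = 0.1,
                  noise_frac: float = 0.2, denoise_span: int | None = 15,
                  late_frac: float = 1.0 / 3.0,
                  base_seed: int = 1) -> pd.DataFrame:
    """Recover RRP and refilling rate from simulated 16 Hz depletion trains.

    Whole-cell ground truth (``rrp_whole`` vesicles, ``refill_per_1000_whole``
    vesicles per 1,000 pulses) is split over the cell's hotspots: each hotspot
    receives an integer RRP (floor of the even share plus a Bernoulli unit for
    the fractional part, so the expected cell total equals ``rrp_whole``) and
    an even share of the refill rate.  Each
    hotspot's release train is drawn stochastically, traces are rendered with
    the full sensor kernel (including the small rise time the correction
    deliberately ignores), summed into a whole-cell ΔF/F0 trace, and Gaussian
    noise of SD ``noise_frac * q`` is added per frame.  The pool pipeline
    (optional denoising, off-rate correction, cumulative curve, late-phase
    back-extrapolation, conversion to vesicles) is then run per cell, with the
    nonnegativity noise floor measured on matched null traces and subtracted
    (scaled to each cell's pre-stimulus noise estimate).
    """
    t0 = 5.0
    stim_times = t0 + np.arange(n_stim) / stim_hz
    duration = t0 + n_stim / stim_hz + 35.0
    frame_times = np.arange(int(duration * frame_hz)) / frame_hz
    bank = pool.make_template_bank(frame_times, stim_times, tau_off, tau_rise=0.0)
    pre_frames = int(t0 * frame_hz)
    sigma_ref = noise_frac * q
    floor_ref = pool.noise_floor(bank, sigma_ref, late_frac=late_frac,
                                 denoise_span=denoise_span,
                                 seed=base_seed) if sigma_ref > 0 else (0.0, 0.0)

    rrp_share = rrp_whole / n_hotspots_per_cell
    refill_h = refill_per_1000_whole / 1000.0 / n_hotspots_per_cell
    rows = []
    for c in range(n_cells):
        rng = _rng_seed(base_seed, 2, c)
        trace = np.zeros_like(frame_times)
        total_released = 0.0
        for h in range(n_hotspots_per_cell):
            rrp_h = int(rrp_share) + (1 if rng.random() < rrp_share % 1.0 else 0)
            spec = HotspotSpec(center_um=(0.0, 0.0), lambda_um=0.7,
                               quantal_size=q, release_prob=pr,
                               quanta_weights=tuple(quanta_weights),
                               rrp=rrp_h, refill_rate=refill_h)
            events = simulate_release_train(
                spec, stim_times, seed=int(rng.integers(0, 2**31 - 1)))
            trace += render_trace(events, frame_times, tau_off, tau_rise_gen)
            total_released += events["amplitude"].sum()
        trace = trace + rng.normal(0.0, noise_frac * q, trace.size)
        # noise estimated from the pre-stimulus segment; the floor is linear
        # in sigma so one calibration per protocol is rescaled per cell
        sigma_hat = float(trace[:pre_frames].std(ddof=1))
        if denoise_span is not None:
            trace = preprocess.denoise_traces(
                trace[:, None, None], span=denoise_span)[:, 0, 0]
        scale = sigma_hat / sigma_ref if sigma_ref > 0 else 0.0
        floor = (floor_ref[0] * scale, floor_ref[1] * scale)
        est = pool.analyze_pool_trace(trace, frame_times, stim_times, tau_off,
                                      q=q, late_frac=late_frac, bank=bank,
                                      floor=floor)
        rows.append({
            "cell": c,
            "rrp_true_vesicles": rrp_whole,
            "refill_true_per_1000": refill_per_1000_whole,
            "rrp_hat_vesicles": est.rrp_vesicles,
            "refill_hat_per_1000": est.refill_per_1000,
            "r2": est.r2,
            "flags": ";".join(est.flags),
            "total_released_vesicles": total_released / q,
        })
    return pd.DataFrame(rows)
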