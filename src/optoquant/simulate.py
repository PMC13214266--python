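"""Synthetic fluorescence movies with known release physics.

The generator is the forward model of the whole analysis chain: stochastic
quantal release from a depleting/refilling vesicle pool at point-like release
sites, single-exponential spatial spread of transmitter (``exp(-r/lambda)``),
a slow fluorescent-sensor impulse response, heterogeneous basal fluorescence,
two-term-exponential photobleaching, Gaussian PSF blur, frame-to-frame drift,
and Poisson photon noise plus Gaussian read noise.  Every movie is written
beside a ground-truth sidecar so downstream stages can be tested by parameter
recovery without any real data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "HotspotSpec",
    "SimulationConfig",
    "impulse_response",
    "simulate_release_train",
    "render_trace",
    "render_movie",
    "make_f0_map",
    "write_fixture",
    "read_fixture",
]

SCHEMA_VERSION = 1


@dataclass
class HotspotSpec:
    """Generative parameters of one release site.

    Parameters
    ----------
    center_um : tuple of float
        (y, x) position in micrometres from the image origin.
    lambda_um : float
        Spatial spread length constant of the transmitter domain.
    quantal_size : float
        ΔF/F0 increment produced by a single released vesicle.
    release_prob : float
        Probability that a stimulus triggers release at this site.
    quanta_weights : tuple of float
        Unnormalised weights of releasing k = 1..K vesicles on a success.
    rrp : float
        Readily releasable pool size in vesicles (may be ``inf``).
    refill_rate : float
        Vesicles replenished per stimulus, capped at ``rrp``.
    """

    center_um: tuple[float, float]
    lambda_um: float
    quantal_size: float
    release_prob: float = 1.0
    quanta_weights: tuple[float, ...] = (1.0,)
    rrp: float = math.inf
    refill_rate: float = 0.0

    def validate(self) -> None:
        if self.lambda_um <= 0:
            raise ValueError("lambda_um must be > 0")
        if not 0.0 <= self.release_prob <= 1.0:
            raise ValueError("release_prob must be in [0, 1]")
        if self.quantal_size <= 0:
            raise ValueError("quantal_size must be > 0")
        if self.rrp < 0 or self.refill_rate < 0:
            raise ValueError("rrp and refill_rate must be >= 0")
        w = np.asarray(self.quanta_weights, dtype=float)
        if w.size == 0 or (w < 0).any() or w.sum() <= 0:
            raise ValueError("quanta_weights must be non-negative with positive sum")


@dataclass
class SimulationConfig:
    """Full description of one synthetic movie."""

    image_shape: tuple[int, int] = (48, 48)
    pixel_size_um: float = 0.1625
    frame_rate: float = 10.0
    n_frames: int = 100
    stim_times: tuple[float, ...] = ()
    hotspots: list[HotspotSpec] = field(default_factory=list)
    f0_mean: float = 1000.0
    f0_cv: float = 0.0
    tau_rise: float = 0.1
    tau_off: float = 8.96
    bleach: tuple[float, float, float, float] | None = None
    psf_sigma_um: float = 0.25
    gain: float = 1.0
    read_noise: float = 0.0
    drift_amp: float = 0.0
    poisson_noise: bool = True
    seed: int = 0

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.tau_rise < 0 or self.tau_off <= self.tau_rise:
            raise ValueError("need tau_off > tau_rise >= 0")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be >= 0")
        if self.f0_mean <= 0:
            raise ValueError("f0_mean must be > 0")
        st = np.asarray(self.stim_times, dtype=float)
        if st.size and (st.min() < 0 or st.max() >= self.duration):
            raise ValueError("all stim_times must lie within the movie duration")
        fov = (self.image_shape[0] * self.pixel_size_um,
               self.image_shape[1] * self.pixel_size_um)
        for h in self.hotspots:
            h.validate()
            cy, cx = h.center_um
            if not (0 <= cy < fov[0] and 0 <= cx < fov[1]):
                raise ValueError(f"hotspot center {h.center_um} outside field {fov}")


def impulse_response(t, tau_off: float, tau_rise: float = 0.0) -> np.ndarray:
    """Unit-peak sensor impulse response ``(1 - e^{-t/tau_rise}) e^{-t/tau_off}``.

    With ``tau_rise = 0`` this is a pure exponential decay with peak 1 at t=0.
    The peak occurs at ``t* = tau_rise * ln(1 + tau_off/tau_rise)``.
    """
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    m = t >= 0
    if tau_rise <= 0:
        h[m] = np.exp(-t[m] / tau_off)
        return h
    raw = (1.0 - np.exp(-t[m] / tau_rise)) * np.exp(-t[m] / tau_off)
    t_peak = tau_rise * math.log1p(tau_off / tau_rise)
    peak = (1.0 - math.exp(-t_peak / tau_rise)) * math.exp(-t_peak / tau_off)
    h[m] = raw / peak
    return h


def simulate_release_train(spec: HotspotSpec, stim_times, seed=None) -> pd.DataFrame:
    """Draw the stochastic release sequence of one hotspot over a pulse train.

    Per stimulus: release succeeds with probability ``release_prob``; on a
    success the number of released quanta k is drawn from ``quanta_weights``
    truncated to the integer part of the currently available pool.  The pool
    then refills, capped at ``rrp``: the integer part of ``refill_rate``
    arrives deterministically and the fractional part as a Bernoulli
    whole-vesicle arrival, so that a rate well below one vesicle per stimulus
    produces discrete, asynchronous replenishment events with the correct
    mean rather than a standing fractional inventory.  A success finding an
    empty pool releases nothing and is recorded as a failure.

    Returns a table with one row per stimulus: ``stimulus`` (1-based),
    ``time``, ``success``, ``quanta``, ``amplitude`` (= quanta * quantal_size)
    and ``pool_after``.
    """
    spec.validate()
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size == 0:
        raise ValueError("no stimuli")
    if stim_times.size > 1 and not (np.diff(stim_times) > 0).all():
        raise ValueError("stim_times must be strictly increasing")
    rng = np.random.default_rng(seed)
    weights = np.asarray(spec.quanta_weights, dtype=float)
    weights = weights / weights.sum()
    pool = spec.rrp
    refill_int = math.floor(spec.refill_rate)
    refill_frac = spec.refill_rate - refill_int
    rows = np.empty((stim_times.size, 4))
    for i in range(stim_times.size):
        k = 0
        if rng.random() < spec.release_prob:
            avail = int(math.floor(pool + 1e-12)) if math.isfinite(pool) else len(weights)
            avail = min(avail, len(weights))
            if avail >= 1:
                w = weights[:avail]
                k = int(rng.choice(np.arange(1, avail + 1), p=w / w.sum()))
        refill = refill_int + (1 if rng.random() < refill_frac else 0)
        pool = min(spec.rrp, pool - k + refill)
        rows[i] = (k > 0, k, k * spec.quantal_size,
                   pool if math.isfinite(pool) else np.inf)
    df = pd.DataFrame(rows, columns=["success", "quanta", "amplitude", "pool_after"])
    df.insert(0, "time", stim_times)
    df.insert(0, "stimulus", np.arange(1, stim_times.size + 1))
    df["success"] = df["success"].astype(bool)
    df["quanta"] = df["quanta"].astype(int)
    return df


def render_trace(events: pd.DataFrame, frame_times, tau_off: float,
                 tau_rise: float = 0.0) -> np.ndarray:
    """Noiseless ΔF/F0 trace at a hotspot center: sum of scaled sensor kernels."""
    frame_times = np.asarray(frame_times, dtype=float)
    trace = np.zeros_like(frame_times)
    ev = events[events["amplitude"] > 0]
    for t_e, amp in zip(ev["time"].to_numpy(), ev["amplitude"].to_numpy()):
        trace += amp * impulse_response(frame_times - t_e, tau_off, tau_rise)
    return trace


def make_f0_map(shape, mean: float, cv: float, rng, smooth_px: float = 2.0) -> np.ndarray:
    """Heterogeneous basal-fluorescence map (smoothed lognormal field)."""
    if cv <= 0:
        return np.full(shape, float(mean))
    z = rng.standard_normal(shape)
    if smooth_px > 0:
        z = ndimage.gaussian_filter(z, smooth_px)
    z = (z - z.mean()) / max(z.std(), 1e-12)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    f0 = mean * np.exp(sigma * z - 0.5 * sigma * sigma)
    return f0


def _bleach_curve(t, coefs) -> np.ndarray:
    a, b, c, d = coefs
    raw = a * np.exp(b * t) + c * np.exp(d * t)
    return raw / (a + c)


def render_movie(events_per_hotspot, config: SimulationConfig,
                 return_clean: bool = False):
    """Render a photon-count movie from release events.

    The noiseless signal is ``F(p,t) = F0(p) * (1 + sum_h a_h(t) exp(-r_ph/lambda_h))``
    with ``a_h(t)`` the sum of sensor impulse responses of hotspot h's events,
    multiplied by the bleaching curve, shifted by per-frame drift, blurred by
    the PSF, then corrupted by Poisson photon noise and Gaussian read noise.

    Parameters
    ----------
    events_per_hotspot : sequence of DataFrame
        Output of :func:`simulate_release_train`, aligned with ``config.hotspots``.
    config : SimulationConfig
    return_clean : bool
        Additionally return the noiseless, unblurred ΔF/F0 stack (oracle).

    Returns
    -------
    movie : uint16 ndarray (t, y, x)
    truth : dict
        Ground-truth sidecar (config echo, hotspot parameters, event tables).
    clean_dff : ndarray, optional
    """
    config.validate()
    if len(events_per_hotspot) != len(config.hotspots):
        raise ValueError("events_per_hotspot must align with config.hotspots")
    rng = np.random.default_rng(config.seed)
    ny, nx = config.image_shape
    t = config.frame_times
    yy, xx = np.indices((ny, nx), dtype=float)
    yy = (yy + 0.5) * config.pixel_size_um
    xx = (xx + 0.5) * config.pixel_size_um

    f0 = make_f0_map(config.image_shape, config.f0_mean, config.f0_cv, rng)
    dff = np.zeros((config.n_frames, ny, nx))
    for spec, events in zip(config.hotspots, events_per_hotspot):
        a_t = render_trace(events, t, config.tau_off, config.tau_rise)
        if not a_t.any():
            continue
        r = np.hypot(yy - spec.center_um[0], xx - spec.center_um[1])
        spatial = np.exp(-r / spec.lambda_um)
        dff += a_t[:, None, None] * spatial[None, :, :]

    clean = f0[None] * (1.0 + dff)
    if config.bleach is not None:
        clean = clean * _bleach_curve(t, config.bleach)[:, None, None]

    sigma_px = config.psf_sigma_um / config.pixel_size_um
    drift = np.zeros((config.n_frames, 2))
    if config.drift_amp > 0:
        drift = np.cumsum(rng.normal(0.0, config.drift_amp, (config.n_frames, 2)), axis=0)
        drift -= drift[0]
    movie = np.empty_like(clean)
    for i in range(config.n_frames):
        frame = clean[i]
        if config.drift_amp > 0 and drift[i].any():
            frame = ndimage.shift(frame, drift[i], order=1, mode="nearest")
        if sigma_px > 0:
            frame = ndimage.gaussian_filter(frame, sigma_px, mode="reflect")
        movie[i] = frame
    if config.poisson_noise:
        movie = rng.poisson(np.clip(movie * config.gain, 0, None)) / config.gain
    if config.read_noise > 0:
        movie = movie + rng.normal(0.0, config.read_noise, movie.shape)
    movie = np.clip(np.round(movie), 0, 65535).astype(np.uint16)

    truth = {
        "schema_version": SCHEMA_VERSION,
        "config": _config_to_dict(config),
        "hotspots": [
            {**_spec_to_dict(spec), "events": ev.to_dict(orient="list")}
            for spec, ev in zip(config.hotspots, events_per_hotspot)
        ],
        "drift": drift.tolist(),
    }
    if return_clean:
        return movie, truth, dff
    return movie, truth


def simulate_movie(config: SimulationConfig, return_clean: bool = False):
    """Draw release trains for every hotspot and render the movie."""
    rng = np.random.default_rng(config.seed)
    events = [
        simulate_release_train(spec, config.stim_times,
                               seed=int(rng.integers(0, 2**31 - 1)))
        for spec in config.hotspots
    ]
    out = render_movie(events, config, return_clean=return_clean)
    return (*out, events) if return_clean else (*out, events)


def _spec_to_dict(spec: HotspotSpec) -> dict:
    d = asdict(spec)
    d["rrp"] = None if math.isinf(spec.rrp) else spec.rrp
    d["center_um"] = list(spec.center_um)
    d["quanta_weights"] = list(spec.quanta_weights)
    return d


def _config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d.pop("hotspots")
    d["image_shape"] = list(config.image_shape)
    d["stim_times"] = list(map(float, config.stim_times))
    d["bleach"] = list(config.bleach) if config.bleach is not None else None
    return d


def truth_from_json(text: str) -> dict:
    truth = json.loads(text)
    if truth.get("schema_version") != SCHEMA_VERSION:
        raise ValueError("unsupported ground-truth schema version")
    return truth


def write_fixture(movie: np.ndarray, truth: dict, path) -> tuple[Path, Path]:
    """Write the movie as a multi-page 16-bit TIFF plus a JSON ground-truth sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tif_path = path if path.suffix in {".tif", ".tiff"} else path.with_suffix(".tif")
    tifffile.imwrite(tif_path, np.asarray(movie, dtype=np.uint16))
    truth_path = tif_path.with_suffix("").with_suffix(".truth.json")
    truth_path.write_text(json.dumps(truth, indent=1))
    return tif_path, truth_path


def read_fixture(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    movie = tifffile.imread(path)
    truth_path = path.with_suffix("").with_suffix(".truth.json")
    truth = truth_from_json(truth_path.read_text())
    return movie, truth
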