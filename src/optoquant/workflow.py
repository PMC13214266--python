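"""End-to-end orchestration: configs, stimulus files, reports.

A run takes a movie (TIFF stack), a stimulus file (JSON with explicit onset
times) and a configuration; applies the preprocessing chain; detects release
hotspots; and, depending on the protocol, runs quantal analysis (low-frequency
trains) or pool analysis (long high-frequency trains).  Every output table
carries the hash of the configuration that produced it, and reruns with the
same config and seed reproduce outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hotspots, pool, preprocess, quantal

logger = logging.getLogger("optoquant")

#: Sensor presets: fluorescence decay time constants (s) of the indicators.
SENSOR_PRESETS = {"5HT": 8.96, "OXT": 3.15}

__all__ = [
    "SENSOR_PRESETS",
    "RunConfig",
    "StimulusProtocol",
    "read_stimulus_file",
    "write_stimulus_file",
    "run_pipeline",
    "render_report",
]


@dataclass
class StimulusProtocol:
    onsets: np.ndarray
    label: str = ""

    @property
    def n_pulses(self) -> int:
        return int(self.onsets.size)

    @property
    def frequency(self) -> float:
        if self.onsets.size < 2:
            return 0.0
        return float(1.0 / np.median(np.diff(self.onsets)))


def read_stimulus_file(path) -> StimulusProtocol:
    """Load a stimulus JSON file; onsets are authoritative, derived fields
    (count, frequency) are validated against them when present."""
    data = json.loads(Path(path).read_text())
    onsets = np.asarray(data["onsets"], dtype=float)
    if onsets.size == 0:
        raise ValueError("stimulus file has no onsets")
    if not (np.diff(onsets) > 0).all():
        raise ValueError("stimulus onsets must be strictly increasing")
    if "n_pulses" in data and int(data["n_pulses"]) != onsets.size:
        raise ValueError("n_pulses inconsistent with onsets")
    if "frequency" in data and onsets.size > 1:
        freq = 1.0 / np.median(np.diff(onsets))
        if abs(freq - float(data["frequency"])) > 0.05 * freq:
            raise ValueError("frequency inconsistent with onsets")
    return StimulusProtocol(onsets=onsets, label=data.get("label", ""))


def write_stimulus_file(protocol: StimulusProtocol, path) -> Path:
    path = Path(path)
    payload = {
        "onsets": [float(t) for t in protocol.onsets],
        "n_pulses": protocol.n_pulses,
        "frequency": protocol.frequency,
        "label": protocol.label,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


@dataclass
class RunConfig:
    """Parameters of one end-to-end analysis run.

    ``protocol`` selects the analysis branch: "quantal" for low-frequency
    trial trains, "pool" for long depletion trains.  ``sensor`` picks the
    off-rate preset (tau_off seconds) unless ``tau_off`` is given explicitly.
    """

    frame_rate: float = 10.0
    pixel_size_um: float = 0.1625
    protocol: str = "quantal"
    sensor: str = "5HT"
    tau_off: float | None = None
    f0_window: tuple[int, int] = (0, 10)
    psf_sigma_um: float | None = 0.25
    landweber_iterations: int = 50
    register: bool = True
    denoise_span: int | None = None
    baseline_windows: tuple | None = None
    eps_px: float = 3.0
    min_pts: int = 5
    amp_threshold: float | None = None
    peak_window: tuple[float, float] = (0.0, 2.0)
    base_window: tuple[float, float] = (-2.0, 0.0)
    late_frac: float = 1.0 / 3.0
    quantal_size: float | None = None
    seed: int = 0

    def resolved_tau_off(self) -> float:
        if self.tau_off is not None:
            return float(self.tau_off)
        if self.sensor not in SENSOR_PRESETS:
            raise ValueError(f"unknown sensor preset {self.sensor!r}")
        return SENSOR_PRESETS[self.sensor]

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("f0_window", "baseline_windows", "peak_window", "base_window"):
            if data.get(key) is not None:
                data[key] = tuple(data[key]) if key != "baseline_windows" else \
                    tuple(tuple(w) for w in data[key])
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]


def _validate_protocol(config: RunConfig, stim: StimulusProtocol) -> None:
    freq = stim.frequency
    if config.protocol == "quantal" and freq > 1.0:
        raise ValueError(
            f"quantal analysis expects low-frequency trains (got {freq:.1f} Hz); "
            "trials are only independent when the inter-stimulus interval "
            "exceeds the sensor decay")
    if config.protocol == "pool" and freq < 1.0:
        raise ValueError(
            f"pool analysis expects a high-frequency depletion train (got "
            f"{freq:.2f} Hz); low-frequency trains cannot exhaust the pool")


def run_pipeline(movie, stim: StimulusProtocol, config: RunConfig) -> dict:
    """Run preprocess -> hotspot detection -> protocol analysis -> tables.

    Returns a bundle dict with the preprocessing result, detected hotspots,
    per-analysis DataFrames, and the config echo + hash.  Deterministic given
    the config seed.
    """
    _validate_protocol(config, stim)
    t_start = time.perf_counter()
    cfg_hash = config.digest()
    movie = np.asarray(movie, dtype=float)
    n_frames = movie.shape[0]
    frame_times = np.arange(n_frames) / config.frame_rate

    psf = None
    if config.psf_sigma_um and config.psf_sigma_um > 0:
        psf = preprocess.gaussian_psf(config.psf_sigma_um / config.pixel_size_um)
    pre = preprocess.preprocess_movie(
        movie, f0_window=config.f0_window, psf=psf,
        n_iter=config.landweber_iterations, register=config.register,
        baseline_windows=config.baseline_windows, frame_rate=config.frame_rate,
        denoise_span=config.denoise_span)
    logger.info("stage=preprocess order=%s elapsed=%.2fs", pre.order,
                time.perf_counter() - t_start)

    f0_hi = config.f0_window[1]
    noise_sd = float(np.nanstd(pre.dff.dff[:f0_hi]))
    mp = hotspots.max_dff_map(pre.dff.dff, (f0_hi, n_frames))
    mp.pixel_size_um = config.pixel_size_um
    rois = hotspots.detect_hotspots(mp, eps_px=config.eps_px,
                                    min_pts=config.min_pts,
                                    amp_threshold=config.amp_threshold,
                                    noise_sd=noise_sd)
    centers = [r.center_px for r in rois]
    spot_rows = []
    for roi in rois:
        others = [c for c in centers if c != roi.center_px]
        prof = hotspots.radial_profile(mp, roi.center_px, max_radius_um=2.0,
                                       neighbor_centers_px=others)
        row = {"hotspot_id": roi.label,
               "y_px": roi.center_px[0], "x_px": roi.center_px[1],
               "y_um": roi.center_um[0], "x_um": roi.center_um[1],
               "peak_dff": roi.peak_dff, "isolated": roi.isolated,
               "profile_truncated": prof.truncated,
               "lambda_um": np.nan, "lambda_ci_lo": np.nan,
               "lambda_ci_hi": np.nan, "r2": np.nan, "config_hash": cfg_hash}
        try:
            fit = hotspots.fit_spread(prof, r_min_um=2 * config.pixel_size_um)
            row.update({"lambda_um": fit.lambda_um,
                        "lambda_ci_lo": fit.lambda_ci[0],
                        "lambda_ci_hi": fit.lambda_ci[1], "r2": fit.r2})
        except ValueError:
            pass
        spot_rows.append(row)
    hotspot_table = pd.DataFrame(spot_rows)
    bundle = {"config": config, "config_hash": cfg_hash,
              "preprocess": pre, "max_map": mp, "hotspots": rois,
              "hotspot_table": hotspot_table, "stimulus": stim}

    if config.protocol == "quantal":
        qrows = []
        for roi in rois:
            trace = pre.dff.dff[:, roi.center_px[0], roi.center_px[1]]
            table = quantal.extract_trial_amplitudes(
                trace, frame_times, stim.onsets,
                peak_window=config.peak_window, base_window=config.base_window)
            table = quantal.classify_failures(table)
            try:
                fit = quantal.fit_quantal_peaks(table["amplitude"].to_numpy())
            except ValueError:
                continue
            table = quantal.classify_failures(table, q=fit.q)
            summ = quantal.summarize_quantal(table, fit)
            qrows.append({"hotspot_id": roi.label, "q": fit.q,
                          "n_peaks": fit.n_peaks, "pr": summ.release_prob,
                          "mean_quanta_success": summ.mean_quanta_per_success,
                          "quantal_content_per_stim": summ.quantal_content_per_stimulus,
                          "max_quanta": summ.max_quanta,
                          "n_trials": summ.n_trials,
                          "n_failures": summ.n_failures,
                          "config_hash": cfg_hash})
        bundle["quantal_table"] = pd.DataFrame(qrows)
    elif config.protocol == "pool":
        tau_off = config.resolved_tau_off()
        bank = pool.make_template_bank(frame_times, stim.onsets, tau_off)
        q = config.quantal_size
        prows = []
        cell_trace = np.zeros(n_frames)
        curves = {}
        for roi in rois:
            trace = pre.dff.dff[:, roi.center_px[0], roi.center_px[1]]
            cell_trace += np.nan_to_num(trace)
            series = pool.correct_off_rate(trace, frame_times, stim.onsets,
                                           tau_off, bank=bank)
            curve = pool.cumulative_curve(series, late_frac=config.late_frac)
            est = pool.fit_rrp_refill(curve)
            est = dataclasses.replace(est, scope="hotspot")
            if q:
                est = pool.to_vesicles(est, q)
            curves[roi.label] = curve
            prows.append(_pool_row(roi.label, est, cfg_hash))
        series = pool.correct_off_rate(cell_trace, frame_times, stim.onsets,
                                       tau_off, bank=bank)
        curve = pool.cumulative_curve(series, late_frac=config.late_frac)
        est = pool.fit_rrp_refill(curve)
        if q:
            est = pool.to_vesicles(est, q)
        curves["whole_cell"] = curve
        prows.append(_pool_row("whole_cell", est, cfg_hash))
        bundle["pool_table"] = pd.DataFrame(prows)
        bundle["cumulative_curves"] = curves
    else:
        raise ValueError(f"unknown protocol {config.protocol!r}")
    logger.info("stage=analysis protocol=%s hotspots=%d elapsed=%.2fs",
                config.protocol, len(rois), time.perf_counter() - t_start)
    return bundle


def _pool_row(scope, est: pool.PoolEstimate, cfg_hash: str) -> dict:
    return {"scope": str(scope), "rrp_dff": est.rrp_dff,
            "refill_per_stim_dff": est.refill_per_stim_dff,
            "rrp_vesicles": est.rrp_vesicles,
            "refill_per_1000": est.refill_per_1000,
            "rrp_ci_lo": est.rrp_ci[0], "rrp_ci_hi": est.rrp_ci[1],
            "r2": est.r2, "flags": ";".join(est.flags),
            "config_hash": cfg_hash}


def save_bundle(bundle: dict, outdir) -> list[Path]:
    """Write every table in the bundle as CSV plus the config echo as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("hotspot_table", "quantal_table", "pool_table"):
        if name in bundle:
            p = outdir / f"{name}.csv"
            bundle[name].to_csv(p, index=False)
            written.append(p)
    cfg = outdir / "config_echo.yaml"
    cfg.write_text(bundle["config"].to_yaml())
    written.append(cfg)
    return written


def render_report(bundle: dict, outdir) -> Path:
    """Figure-style outputs: max-ΔF/F0 heatmap, 3-D surface per hotspot,
    cumulative curves, plus a markdown summary of every parameter used."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm

    if "max_map" not in bundle:
        raise ValueError("empty bundle")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mp = bundle["max_map"]

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(mp.values, cmap="inferno")
    ax.set_title("maximal ΔF/F0")
    fig.colorbar(im, ax=ax, label="ΔF/F0")
    for roi in bundle["hotspots"]:
        ax.plot(roi.center_px[1], roi.center_px[0], "c+", ms=10)
    fig.savefig(outdir / "max_dff_heatmap.png", dpi=120)
    plt.close(fig)

    for roi in bundle["hotspots"]:
        fig = plt.figure(figsize=(5, 4))
        ax = fig.add_subplot(projection="3d")
        yy, xx = np.indices(mp.values.shape)
        ax.plot_surface(xx, yy, np.nan_to_num(mp.values), cmap=cm.inferno,
                        linewidth=0)
        ax.set_title(f"hotspot {roi.label}: 3-D max ΔF/F0")
        fig.savefig(outdir / f"hotspot_{roi.label}_surface.png", dpi=100)
        plt.close(fig)

    if "cumulative_curves" in bundle:
        fig, ax = plt.subplots(figsize=(5, 4))
        for label, curve in bundle["cumulative_curves"].items():
            ax.plot(curve.stimulus, curve.cumulative, label=str(label))
        ax.set_xlabel("stimulus number")
        ax.set_ylabel("cumulative ΔF/F0")
        ax.legend(fontsize=6)
        fig.savefig(outdir / "cumulative_release.png", dpi=120)
        plt.close(fig)

    lines = ["# Analysis report", "",
             f"config hash: `{bundle['config_hash']}`", "",
             "## Parameters", "", "```yaml",
             bundle["config"].to_yaml().rstrip(), "```", ""]
    for name in ("hotspot_table", "quantal_table", "pool_table"):
        lines.append(f"## {name}")
        lines.append("")
        if name in bundle and len(bundle[name]):
            lines.append(bundle[name].to_markdown(index=False))
        else:
            lines.append("_skipped_")
        lines.append("")
    report = outdir / "report.md"
    report.write_text("\n".join(lines))
    return report
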