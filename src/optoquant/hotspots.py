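"""Release-site detection and spatial-spread quantification.

Release hotspots are found on the pixel-wise maximal ΔF/F0 map with DBSCAN
over supra-threshold pixels; overlapping sites are separated by iteratively
removing the dominant site's fitted exponential footprint and re-clustering
the residual.  Each isolated site yields a direction-averaged radial profile
that is fitted with a single-exponential decay ``A exp(-r/lambda)``, whose
decay constant is the spatial spread length constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit
from sklearn.cluster import DBSCAN

__all__ = [
    "MaxDffMap",
    "HotspotROI",
    "RadialProfile",
    "SpreadFit",
    "max_dff_map",
    "detect_hotspots",
    "radial_profile",
    "fit_spread",
    "roi_cv",
    "dff_f0_correlation",
]


@dataclass
class MaxDffMap:
    values: np.ndarray
    window: tuple[int, int]
    pixel_size_um: float


@dataclass
class HotspotROI:
    label: int
    pixels: np.ndarray            # (n, 2) row/col indices of cluster pixels
    center_px: tuple[int, int]    # argmax pixel (centre of release)
    center_um: tuple[float, float]
    peak_dff: float
    isolated: bool = True


@dataclass
class RadialProfile:
    r_um: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    truncated: bool = False


@dataclass
class SpreadFit:
    amplitude: float
    lambda_um: float
    offset: float
    r2: float
    lambda_ci: tuple[float, float]
    ci_unbounded: bool = False


def max_dff_map(dff_stack, window) -> MaxDffMap:
    """Per-pixel maximum of the ΔF/F0 stack over an analysis window."""
    dff_stack = np.asarray(dff_stack, dtype=float)
    lo, hi = int(window[0]), int(window[1])
    if hi <= lo or lo < 0 or hi > dff_stack.shape[0]:
        raise ValueError("analysis window outside stack")
    return MaxDffMap(values=np.nanmax(dff_stack[lo:hi], axis=0),
                     window=(lo, hi), pixel_size_um=np.nan)


def _cluster_supra(values, supra_mask, eps_px, min_pts):
    coords = np.argwhere(supra_mask)
    if coords.shape[0] < min_pts:
        return []
    labels = DBSCAN(eps=eps_px, min_samples=min_pts).fit_predict(coords)
    return [coords[labels == k] for k in range(labels.max() + 1)]


def detect_hotspots(map_: MaxDffMap, eps_px: float = 3.0, min_pts: int = 5,
                    amp_threshold: float | None = None,
                    noise_sd: float | None = None,
                    max_splits: int = 20) -> list[HotspotROI]:
    """Detect release sites on a maximal-ΔF/F0 map.

    Supra-threshold pixels (default threshold: 5x the pre-stimulus pixel noise
    SD) are clustered with DBSCAN.  A cluster containing several release sites
    is split iteratively: the dominant site's fitted exponential footprint is
    subtracted and the residual re-clustered, up to ``max_splits`` times.
    Afterwards each site is flagged isolated if no other centre lies within
    3 fitted length constants.

    Returns an empty list (not an error) when nothing exceeds threshold.
    """
    if amp_threshold is None:
        if noise_sd is None:
            raise ValueError("provide amp_threshold or noise_sd")
        amp_threshold = 5.0 * noise_sd
    if amp_threshold <= 0 or eps_px <= 0 or min_pts <= 0:
        raise ValueError("thresholds must be > 0")
    values = np.nan_to_num(np.asarray(map_.values, dtype=float), nan=0.0)
    px = map_.pixel_size_um

    rois: list[HotspotROI] = []
    # queue entries: (cluster pixels, map the cluster was found on)
    queue = [(pix, values) for pix in
             _cluster_supra(values, values > amp_threshold, eps_px, min_pts)]
    splits_left = max_splits
    label = 0
    while queue:
        pixels, vmap = queue.pop(0)
        sel = tuple(pixels.T)
        vals = vmap[sel]
        imax = int(np.argmax(vals))
        cy, cx = map(int, pixels[imax])
        peak = float(vals[imax])
        if peak <= amp_threshold:
            continue
        rois.append(HotspotROI(
            label=label, pixels=pixels, center_px=(cy, cx),
            center_um=((cy + 0.5) * px, (cx + 0.5) * px), peak_dff=peak))
        label += 1
        if splits_left <= 0:
            continue
        # remove the dominant site's fitted footprint; re-cluster the residual.
        # the footprint is fitted on pixels near the dominant centre, where
        # any second site contaminates the decay estimate least
        rr = np.hypot(pixels[:, 0] - cy, pixels[:, 1] - cx) * px
        near = rr <= max(1.0, 4 * px)
        lam = _quick_lambda(rr[near], vals[near], px)
        residual = np.zeros_like(vmap)
        residual[sel] = vals - peak * np.exp(-rr / max(lam, 1e-6))
        residual = np.clip(residual, 0.0, None)
        for cluster in _cluster_supra(residual, residual > amp_threshold,
                                      eps_px, min_pts):
            sub_sel = tuple(cluster.T)
            jmax = int(np.argmax(residual[sub_sel]))
            d = np.hypot(cluster[jmax, 0] - cy, cluster[jmax, 1] - cx)
            if d > eps_px:
                queue.append((cluster, residual))
                splits_left -= 1
    # isolation flags
    for roi in rois:
        rr = np.hypot(roi.pixels[:, 0] - roi.center_px[0],
                      roi.pixels[:, 1] - roi.center_px[1]) * px
        lam = _quick_lambda(rr, values[tuple(roi.pixels.T)], px)
        for other in rois:
            if other is roi:
                continue
            d = np.hypot(other.center_px[0] - roi.center_px[0],
                         other.center_px[1] - roi.center_px[1]) * px
            if d < 3.0 * lam:
                roi.isolated = False
    return rois


def _quick_lambda(r_um, vals, px, default: float = 0.7) -> float:
    """Crude log-linear spread estimate used for footprints and isolation."""
    good = (vals > 0) & (r_um > 0)
    if good.sum() < 3:
        return default
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        slope = np.polyfit(r_um[good], np.log(vals[good]), 1)[0]
    if slope >= -1e-9:
        return default
    return float(np.clip(-1.0 / slope, 0.05, 10.0))


def find_center(values, smooth_px: float = 2.0) -> tuple[int, int]:
    """Argmax of a lightly smoothed map; robust to single-pixel noise spikes."""
    sm = gaussian_filter(np.nan_to_num(values, nan=0.0), smooth_px)
    return tuple(int(i) for i in np.unravel_index(np.argmax(sm), sm.shape))


def radial_profile(map_: MaxDffMap, center_px, max_radius_um: float,
                   bin_width_px: float = 1.0,
                   neighbor_centers_px=None) -> RadialProfile:
    """Direction-averaged (annular) radial profile around a release centre.

    Distances are binned in multiples of the pixel size; each bin reports the
    mean, SEM and pixel count.  If another detected centre lies within
    ``max_radius_um`` the profile is truncated at half the inter-centre
    distance and flagged.
    """
    values = np.asarray(map_.values, dtype=float)
    px = map_.pixel_size_um
    cy, cx = center_px
    truncated = False
    if neighbor_centers_px:
        dists = [np.hypot(oy - cy, ox - cx) * px for oy, ox in neighbor_centers_px]
        dmin = min(dists) if dists else np.inf
        if dmin < 2 * max_radius_um:
            max_radius_um = min(max_radius_um, dmin / 2.0)
            truncated = True
    yy, xx = np.indices(values.shape)
    r = np.hypot(yy - cy, xx - cx) * px
    width = bin_width_px * px
    n_bins = int(np.floor(max_radius_um / width)) + 1
    r_c, mean, sem, n = [], [], [], []
    for i in range(n_bins):
        m = (r >= i * width - width / 2) & (r < i * width + width / 2)
        m &= np.isfinite(values)
        cnt = int(m.sum())
        if cnt == 0:
            continue
        v = values[m]
        # mean pixel distance, not the nominal bin centre: annulus bins mix
        # radii (axial vs diagonal neighbours), which would bias the fit
        r_c.append(float(r[m].mean()))
        mean.append(v.mean())
        sem.append(v.std(ddof=1) / np.sqrt(cnt) if cnt > 1 else np.nan)
        n.append(cnt)
    return RadialProfile(r_um=np.array(r_c), mean=np.array(mean),
                         sem=np.array(sem), n=np.array(n, dtype=int),
                         truncated=truncated)


def fit_spread(profile: RadialProfile, r_min_um: float = 0.0,
               free_offset: bool = False) -> SpreadFit:
    """Single-exponential fit ``A exp(-r/lambda) (+ offset)`` to a radial profile.

    ``r_min_um`` excludes the innermost bins from the fit; after
    finite-iteration deconvolution the exponential tail is unbiased while the
    core retains residual blur, so pipelines pass ``r_min_um`` of about two
    pixels.  The offset is fixed to 0 by default.  The CI on lambda comes from
    the fit covariance.
    """
    keep = profile.r_um >= r_min_um
    r = profile.r_um[keep]
    y = profile.mean[keep]
    if r.size < 5:
        raise ValueError("need at least 5 distance bins to fit a spread constant")
    third = max(1, r.size // 3)
    if y[-third:].mean() >= y[:third].mean():
        raise ValueError("no decay")
    lam0 = _quick_lambda(r, y, 1.0)
    try:
        if free_offset:
            popt, pcov = curve_fit(
                lambda r, A, lam, c: A * np.exp(-r / lam) + c, r, y,
                p0=[max(y.max(), 1e-6), lam0, 0.0], maxfev=10000)
            amp, lam, off = popt
            var = pcov[1, 1]
        else:
            popt, pcov = curve_fit(
                lambda r, A, lam: A * np.exp(-r / lam), r, y,
                p0=[max(y.max(), 1e-6), lam0], maxfev=10000)
            amp, lam = popt
            off = 0.0
            var = pcov[1, 1]
    except RuntimeError as err:
        raise ValueError(f"spread fit did not converge: {err}") from err
    if lam <= 0:
        raise ValueError("no decay")
    pred = amp * np.exp(-r / lam) + off
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if np.isfinite(var) and var >= 0:
        half = 1.96 * np.sqrt(var)
        ci = (lam - half, lam + half)
        unbounded = False
    else:
        ci = (0.0, np.inf)
        unbounded = True
    return SpreadFit(amplitude=float(amp), lambda_um=float(lam),
                     offset=float(off), r2=r2, lambda_ci=ci,
                     ci_unbounded=unbounded)


def roi_cv(values) -> float:
    """Coefficient of variation (sample SD / mean) of ROI pixel values."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 pixels")
    mean = v.mean()
    if mean == 0:
        raise ValueError("mean is zero; CV undefined")
    return float(v.std(ddof=1) / mean)


def dff_f0_correlation(max_map, f0_map, roi_mask=None, n_boot: int = 1000,
                       seed: int | None = None):
    """Rank correlation between maximal ΔF/F0 and basal fluorescence F0.

    Returns ``(rho, (ci_lo, ci_hi))`` from a Spearman correlation over ROI
    pixels with a bootstrap percentile CI.  A weak correlation indicates that
    response localization reflects release, not sensor-expression level.
    """
    a = np.asarray(max_map, dtype=float).ravel()
    b = np.asarray(f0_map, dtype=float).ravel()
    if roi_mask is not None:
        m = np.asarray(roi_mask, dtype=bool).ravel()
        a, b = a[m], b[m]
    good = np.isfinite(a) & np.isfinite(b)
    a, b = a[good], b[good]
    if a.size < 10:
        raise ValueError("need at least 10 pixels")
    if np.ptp(b) == 0:
        raise ValueError("constant F0; correlation undefined")
    rho = float(sps.spearmanr(a, b).statistic)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, a.size, a.size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            boots[i] = sps.spearmanr(a[idx], b[idx]).statistic
    boots = boots[np.isfinite(boots)]
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return rho, ci
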