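"""Image-processing chain applied before any transmission-property analysis.

Five procedures, applied in this order: translational alignment, Landweber
deconvolution with a measured PSF, per-pixel baseline (photobleaching)
adjustment, per-pixel temporal denoising, and uniform background subtraction.
ΔF/F0 computation and motion diagnostics (movement score / AMMS) live here as
well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve
from skimage.registration import optical_flow_ilk, phase_cross_correlation
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "RegistrationResult",
    "MovementDiagnostics",
    "DeconvolutionResult",
    "BaselineModel",
    "gaussian_psf",
    "register_translation",
    "movement_scores",
    "landweber_deconvolve",
    "fit_baseline",
    "denoise_traces",
    "subtract_background",
    "compute_dff",
    "preprocess_movie",
]


# ---------------------------------------------------------------- registration

@dataclass
class RegistrationResult:
    aligned: np.ndarray
    shifts: np.ndarray          # (n_frames, 2) pixels, reference frame = (0, 0)
    similarity: np.ndarray      # per-frame normalized cross-correlation with reference
    flagged: np.ndarray         # frames whose similarity fell below threshold
    iterations: int = 1


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def register_translation(stack, reference_index: int = 0, upsample: int = 20,
                         max_iter: int = 200, flag_threshold: float = 0.2,
                         max_shift_frac: float = 0.25) -> RegistrationResult:
    """Subpixel translational alignment of every frame to a reference frame.

    Shifts are estimated by phase cross-correlation and applied with
    interpolation.  Two guards keep the stage safe on poorly conditioned
    frames (flat fields, pure noise): a frame whose estimated shift exceeds
    ``max_shift_frac`` of the field, or whose similarity to the reference is
    not improved by the shift, keeps its original position with shift (0, 0)
    and is flagged; frames whose post-alignment correlation stays below
    ``flag_threshold`` are flagged as well.  Flagged frames never fail the
    pipeline.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (t, y, x) stack with at least 2 frames")
    ref = stack[reference_index]
    n = stack.shape[0]
    max_shift = max_shift_frac * min(stack.shape[1:])
    # Hann taper suppresses the FFT wrap-around artefacts that otherwise
    # dominate the correlation of smooth, non-periodic images
    wy = np.hanning(stack.shape[1])[:, None]
    wx = np.hanning(stack.shape[2])[None, :]
    win = wy * wx
    ref_w = (ref - ref.mean()) * win

    shifts = np.zeros((n, 2))
    aligned = stack.copy()
    sim = np.zeros(n)
    flagged = np.zeros(n, dtype=bool)
    iters_used = 1
    for i in range(n):
        if i == reference_index:
            sim[i] = 1.0
            continue
        total = np.zeros(2)
        moved = stack[i]
        for it in range(max_iter):
            step, _, _ = phase_cross_correlation(
                ref_w, (moved - moved.mean()) * win,
                upsample_factor=upsample, normalization=None)
            total += step
            if np.abs(total).max() > max_shift:
                break
            moved = ndimage.shift(stack[i], total, order=3, mode="nearest")
            iters_used = max(iters_used, it + 1)
            if np.abs(step).max() < 0.02:   # diminishing returns
                break
        sim_raw = _ncc(ref, stack[i])
        if np.abs(total).max() > max_shift:
            sim[i] = sim_raw
            flagged[i] = True
            continue
        sim_moved = _ncc(ref, moved)
        # small shifts are accepted whenever they do not hurt; a large shift
        # must improve the similarity by more than the sampling noise of the
        # correlation itself, otherwise it is almost certainly a spurious
        # estimate from a featureless frame
        small = np.abs(total).max() < 0.75
        margin = max(0.01, 3.0 * (1.0 - max(sim_raw, 0.0) ** 2)
                     / np.sqrt(ref.size))
        if np.abs(total).max() < 1e-6 or \
                (small and sim_moved >= sim_raw) or \
                sim_moved >= sim_raw + margin:
            shifts[i] = total
            aligned[i] = moved
            sim[i] = sim_moved
        else:
            sim[i] = sim_raw
            flagged[i] = True
    flagged |= sim < flag_threshold
    return RegistrationResult(aligned, shifts, sim, flagged,
                              iterations=iters_used)


# ----------------------------------------------------------- motion diagnostics

@dataclass
class MovementDiagnostics:
    scores: np.ndarray   # per-frame mean per-pixel displacement magnitude (px)
    amms: float          # adjusted maximum movement displacement score (px)


def movement_scores(stack, stim_window, reference_index: int = 0,
                    radius: int = 7) -> MovementDiagnostics:
    """Per-frame movement score from a dense displacement field.

    The score of a frame is the mean magnitude of the pixel displacement field
    to the reference frame (iterative Lucas-Kanade optical flow, a dense
    non-parametric registration).  AMMS is the maximum over the stimulation
    window of the absolute deviation of the score from its pre-stimulus mean.
    """
    stack = np.asarray(stack, dtype=float)
    lo, hi = int(stim_window[0]), int(stim_window[1])
    if hi <= lo:
        raise ValueError("stim_window is empty")
    if lo < 0 or hi > stack.shape[0]:
        raise ValueError("stim_window outside stack")
    ref = stack[reference_index]
    n = stack.shape[0]
    scores = np.zeros(n)
    for i in range(n):
        if i == reference_index or np.array_equal(stack[i], ref):
            continue
        v, u = optical_flow_ilk(ref, stack[i], radius=radius)
        scores[i] = float(np.hypot(v, u).mean())
    pre = scores[:lo]
    pre_mean = pre.mean() if pre.size else 0.0
    amms = float(np.abs(scores[lo:hi] - pre_mean).max())
    return MovementDiagnostics(scores=scores, amms=amms)


# ------------------------------------------------------------- deconvolution

@dataclass
class DeconvolutionResult:
    stack: np.ndarray
    residual_mse: np.ndarray      # per-iteration mean residual MSE
    snr_db: np.ndarray            # per-iteration signal-to-residual ratio (dB)
    iterations: int
    step: float


def gaussian_psf(sigma_px: float, radius: int | None = None) -> np.ndarray:
    """Isotropic 2-D Gaussian PSF kernel, normalized to unit sum."""
    if sigma_px <= 0:
        return np.ones((1, 1))
    if radius is None:
        radius = max(1, int(np.ceil(4 * sigma_px)))
    y, x = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    p = np.exp(-(x * x + y * y) / (2.0 * sigma_px * sigma_px))
    return p / p.sum()


def _conv_reflect(img: np.ndarray, psf: np.ndarray) -> np.ndarray:
    # reflective padding keeps the operator well behaved at the field edge
    ry, rx = psf.shape[0] // 2, psf.shape[1] // 2
    if ry == 0 and rx == 0:
        return img * psf[0, 0]
    pad = np.pad(img, ((ry, ry), (rx, rx)), mode="reflect")
    out = fftconvolve(pad, psf, mode="same")
    return out[ry:-ry if ry else None, rx:-rx if rx else None]


def _operator_norm(psf: np.ndarray, shape, n_iter: int = 30, seed: int = 0) -> float:
    """Largest eigenvalue of H^T H estimated by power iteration."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(shape)
    v /= np.linalg.norm(v)
    psf_t = psf[::-1, ::-1]
    lam = 1.0
    for _ in range(n_iter):
        w = _conv_reflect(_conv_reflect(v, psf), psf_t)
        lam = np.linalg.norm(w)
        v = w / max(lam, 1e-300)
    return float(lam)


def landweber_deconvolve(stack_or_frame, psf, n_iter: int = 50,
                         step: float | None = None) -> DeconvolutionResult:
    """Landweber deconvolution with a non-negativity constraint.

    Iterates ``x_{k+1} = max(0, x_k + alpha * H^T (y - H x_k))`` where H is
    convolution with the PSF (reflective boundary).  The default step
    ``alpha = 1/L`` (L = largest eigenvalue of H^T H, estimated by power
    iteration) makes the residual non-increasing.  Fifty iterations are the
    default operating point; the residual-MSE and SNR traces let callers check
    convergence.

    Accepts a single frame (y, x) or a stack (t, y, x); the constraint and the
    step size are shared across frames.
    """
    arr = np.asarray(stack_or_frame, dtype=float)
    single = arr.ndim == 2
    stack = arr[None] if single else arr
    psf = np.asarray(psf, dtype=float)
    if psf.ndim != 2 or psf.sum() <= 0:
        raise ValueError("psf must be a 2-D kernel with positive sum")
    psf = psf / psf.sum()
    L = _operator_norm(psf, stack.shape[1:])
    if step is None:
        alpha = 1.0 / L
    else:
        if not 0 < step < 2.0 / L:
            raise ValueError(f"step must lie in (0, {2.0 / L:.3g}) for stability")
        alpha = step
    psf_t = psf[::-1, ::-1]
    out = np.empty_like(stack)
    mse = np.zeros((stack.shape[0], n_iter))
    snr = np.zeros((stack.shape[0], n_iter))
    for f in range(stack.shape[0]):
        y = stack[f]
        x = np.clip(y, 0.0, None)
        for k in range(n_iter):
            hx = _conv_reflect(x, psf)
            resid = y - hx
            x = np.clip(x + alpha * _conv_reflect(resid, psf_t), 0.0, None)
            mse[f, k] = float((resid * resid).mean())
            p_sig = float((hx * hx).mean())
            snr[f, k] = 10.0 * np.log10(p_sig / max(mse[f, k], 1e-300))
        out[f] = x
    return DeconvolutionResult(
        stack=out[0] if single else out,
        residual_mse=mse.mean(axis=0),
        snr_db=snr.mean(axis=0),
        iterations=n_iter,
        step=alpha,
    )


# ------------------------------------------------------------------ baseline

@dataclass
class BaselineModel:
    coefs: np.ndarray      # (y, x, 4) two-term exponential (a, b, c, d)
    factors: np.ndarray    # (t, y, x) multiplicative flattening factors
    fallback: np.ndarray   # (y, x) 0 = two-term, 1 = single-exp, 2 = flat


def _two_term(t, a, b, c, d):
    return a * np.exp(b * t) + c * np.exp(d * t)


def fit_baseline(stack, pre_window, post_window, frame_rate: float = 10.0
                 ) -> BaselineModel:
    """Per-pixel two-term exponential baseline fit on the control windows.

    ``F_base(t) = a e^{bt} + c e^{dt}`` is fitted independently at each pixel
    on the concatenated pre- and post-control frames.  Multiplication factors
    ``F_base(t_ref) / F_base(t)`` (t_ref = centre of the pre window) flatten
    the baseline over the whole sequence.  Pixels where the two-term fit
    diverges fall back to a single exponential, then to a flat baseline.
    """
    stack = np.asarray(stack, dtype=float)
    n, ny, nx = stack.shape
    pre = np.arange(*pre_window)
    post = np.arange(*post_window)
    if pre.size == 0 or post.size == 0:
        raise ValueError("control windows must be non-empty")
    if pre[-1] >= post[0]:
        raise ValueError("control windows must not overlap")
    idx = np.concatenate([pre, post])
    t_all = np.arange(n) / frame_rate
    t_ctl = idx / frame_rate
    t_ref = float(pre.mean() / frame_rate)

    coefs = np.zeros((ny, nx, 4))
    fallback = np.full((ny, nx), 2, dtype=np.int8)
    factors = np.ones((n, ny, nx))
    traces = stack[idx]
    for iy in range(ny):
        for ix in range(nx):
            yv = traces[:, iy, ix]
            mean = yv.mean()
            if mean <= 0:
                coefs[iy, ix] = (max(mean, 0.0), 0.0, 0.0, 0.0)
                continue
            # initial slope from log-linear regression on the control samples
            with np.errstate(divide="ignore", invalid="ignore"):
                logy = np.log(np.clip(yv, 1e-12, None))
            b0 = np.polyfit(t_ctl, logy, 1)[0]
            b0 = min(b0, 0.0)
            params = None
            try:
                params, _ = curve_fit(
                    _two_term, t_ctl, yv,
                    p0=[0.7 * mean, b0, 0.3 * mean, b0 / 10.0],
                    bounds=([0, -np.inf, 0, -np.inf], [np.inf, 0, np.inf, 0]),
                    maxfev=2000)
                fallback[iy, ix] = 0
            except (RuntimeError, ValueError):
                try:
                    p1, _ = curve_fit(
                        lambda t, a, b: a * np.exp(b * t), t_ctl, yv,
                        p0=[mean, b0],
                        bounds=([0, -np.inf], [np.inf, 0]), maxfev=1000)
                    params = [p1[0], p1[1], 0.0, 0.0]
                    fallback[iy, ix] = 1
                except (RuntimeError, ValueError):
                    params = [mean, 0.0, 0.0, 0.0]
            coefs[iy, ix] = params
            base = _two_term(t_all, *params)
            ref = _two_term(np.array([t_ref]), *params)[0]
            good = base > 1e-12 * max(ref, 1e-12)
            factors[good, iy, ix] = ref / base[good]
    return BaselineModel(coefs=coefs, factors=factors, fallback=fallback)


def apply_baseline(stack, model: BaselineModel) -> np.ndarray:
    return np.asarray(stack, dtype=float) * model.factors


# ------------------------------------------------------------------ denoising

def denoise_traces(stack, span: int = 15, model: str = "auto") -> np.ndarray:
    """Pixel-by-pixel temporal smoothing with locally weighted regression.

    A LOWESS (tricube-weighted local linear) smoother runs along the time axis
    of every pixel; with ``model="auto"`` a local-exponential variant (LOWESS
    on the log trace) is also computed for strictly positive traces and the
    variant with the lower residual is kept per pixel.
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    if span < 3:
        raise ValueError("span too small for a local window (need >= 3 frames)")
    if span >= n:
        raise ValueError("span must be smaller than the number of frames")
    frac = span / n
    t = np.arange(n, dtype=float)
    out = np.empty_like(stack)
    flat = stack.reshape(n, -1)
    res = out.reshape(n, -1)
    for j in range(flat.shape[1]):
        yv = flat[:, j]
        if np.ptp(yv) == 0:
            res[:, j] = yv
            continue
        lin = lowess(yv, t, frac=frac, return_sorted=False)
        best = lin
        if model in ("auto", "exponential") and (yv > 0).all():
            exp_s = np.exp(lowess(np.log(yv), t, frac=frac, return_sorted=False))
            if model == "exponential" or \
                    ((yv - exp_s) ** 2).sum() < ((yv - lin) ** 2).sum():
                best = exp_s
        res[:, j] = best
    return out


# ----------------------------------------------------------------- background

def subtract_background(stack, background_mask) -> np.ndarray:
    """Subtract the per-frame mean over a non-responsive background ROI."""
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(background_mask, dtype=bool)
    if mask.shape != stack.shape[1:]:
        raise ValueError("background mask shape must match the frame shape")
    if not mask.any():
        raise ValueError("background ROI is empty")
    bg = stack[:, mask].mean(axis=1)
    return stack - bg[:, None, None]


# ------------------------------------------------------------------- ΔF/F0

@dataclass
class DffResult:
    dff: np.ndarray
    f0: np.ndarray
    mask: np.ndarray   # True where F0 was above the floor and ΔF/F0 is defined


def compute_dff(stack, f0_window, floor_frac: float = 0.05) -> DffResult:
    """Pixel-wise ΔF/F0 with F0 the mean over a pre-stimulus window.

    Pixels whose F0 falls below ``floor_frac`` of the median F0 are masked
    (set to NaN) to avoid exploding ratios at empty pixels.
    """
    stack = np.asarray(stack, dtype=float)
    lo, hi = int(f0_window[0]), int(f0_window[1])
    if hi <= lo or lo < 0 or hi > stack.shape[0]:
        raise ValueError("invalid f0_window")
    f0 = stack[lo:hi].mean(axis=0)
    med = np.median(f0)
    if med <= 0:
        raise ValueError("F0 is zero; cannot form ΔF/F0")
    mask = f0 > floor_frac * med
    dff = np.full_like(stack, np.nan)
    dff[:, mask] = stack[:, mask] / f0[mask] - 1.0
    return DffResult(dff=dff, f0=f0, mask=mask)


# ------------------------------------------------------------------- pipeline

@dataclass
class PreprocessResult:
    dff: DffResult
    stack: np.ndarray                  # corrected fluorescence stack
    order: list = field(default_factory=list)
    registration: RegistrationResult | None = None
    deconvolution: DeconvolutionResult | None = None
    baseline: BaselineModel | None = None


def preprocess_movie(movie, f0_window, psf=None, n_iter: int = 50,
                     register: bool = True,
                     baseline_windows=None, frame_rate: float = 10.0,
                     denoise_span: int | None = None,
                     background_mask=None) -> PreprocessResult:
    """Apply the correction chain in its canonical order and compute ΔF/F0.

    Order: alignment -> deconvolution -> baseline adjustment -> denoising ->
    background correction.  Each stage is optional; the applied order is
    recorded in the result.
    """
    stack = np.asarray(movie, dtype=float)
    order = []
    reg = dec = base = None
    if register:
        reg = register_translation(stack)
        stack = reg.aligned
        order.append("align")
    if psf is not None:
        dec = landweber_deconvolve(stack, psf, n_iter=n_iter)
        stack = dec.stack
        order.append("deconvolve")
    if baseline_windows is not None:
        base = fit_baseline(stack, *baseline_windows, frame_rate=frame_rate)
        stack = apply_baseline(stack, base)
        order.append("baseline")
    if denoise_span is not None:
        stack = denoise_traces(stack, span=denoise_span)
        order.append("denoise")
    if background_mask is not None:
        stack = subtract_background(stack, background_mask)
        order.append("background")
    dff = compute_dff(stack, f0_window)
    order.append("dff")
    return PreprocessResult(dff=dff, stack=stack, order=order,
                            registration=reg, deconvolution=dec, baseline=base)
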