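"""Channel registration, deinterleaving, leakage and background corrections.

The raw experiment records two EMCCD cameras ("green" and "red") under
alternating blue/olive laser excitation.  Preprocessing turns the two raw
camera stacks into four logical channels:

* ``venus``     -- green camera, blue excitation (the tagged molecule)
* ``mixed``     -- red camera, blue excitation (spectral leakage + FRET)
* ``rhodamine`` -- red camera, olive excitation (the labeled ligand)
* ``blank``     -- green camera, olive excitation (discarded)

and then corrects the mixed channel for green->red spectral leakage,
flattens uneven illumination, and subtracts the decaying autofluorescent
background.  All corrections are linear per frame, so they commute with
summation of movies and preserve frame count and timing metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from scipy import ndimage
from skimage.restoration import rolling_ball

__all__ = [
    "MovieStack",
    "RegistrationParams",
    "register",
    "deinterleave",
    "interleave",
    "estimate_leakage",
    "correct_leakage",
    "correct_uneven_field",
    "correct_autofluorescence",
    "BackgroundFit",
]

CHANNEL_TAGS = {"green_cam", "red_cam", "venus", "rhodamine", "mixed", "fret", "blank"}


@dataclass
class MovieStack:
    """A timed 3-D image stack (time x rows x cols) with channel metadata.

    Intensities are stored as float64; after background/leakage subtraction
    pixel values may legitimately be negative, and downstream code must
    tolerate that.  ``mask`` marks pixels that are invalid in every frame
    (e.g. pushed outside the field by registration).
    """

    frames: np.ndarray
    frame_interval_s: float
    channel_tag: str = "green_cam"
    mask: Optional[np.ndarray] = None  # True where INVALID

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time, rows, cols) array")
        if self.channel_tag not in CHANNEL_TAGS:
            raise ValueError(f"unknown channel_tag {self.channel_tag!r}")
        if not np.isfinite(self.frame_interval_s) or self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive and finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def frame_times(self) -> np.ndarray:
        """Frame start times, 0-based: t_i = i * frame_interval_s."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def with_frames(self, frames: np.ndarray, **kw) -> "MovieStack":
        return MovieStack(
            frames=frames,
            frame_interval_s=kw.pop("frame_interval_s", self.frame_interval_s),
            channel_tag=kw.pop("channel_tag", self.channel_tag),
            mask=kw.pop("mask", self.mask),
        )


@dataclass(frozen=True)
class RegistrationParams:
    """Rigid (optionally scaled) transform aligning one camera to the other.

    Parameters come from a bead calibration and are inputs here, not fitted.
    """

    rotation_deg: float = 0.0
    translation_px: tuple = (0.0, 0.0)  # (rows, cols)
    scale: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.rotation_deg, *self.translation_px, self.scale)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("registration parameters must be finite")
        if self.scale == 0:
            raise ValueError("scale must be nonzero (transform must be invertible)")

    @property
    def is_identity(self) -> bool:
        return (
            self.rotation_deg == 0.0
            and tuple(self.translation_px) == (0.0, 0.0)
            and self.scale == 1.0
        )

    def inverse(self) -> "RegistrationParams":
        # Pure inverses compose only for rotation-about-center followed by
        # translation; sufficient for round-trip tests at scale == 1.
        if self.scale != 1.0:
            raise NotImplementedError("inverse only defined for scale == 1")
        th = np.deg2rad(-self.rotation_deg)
        dr, dc = self.translation_px
        # inverse translation expressed in the unrotated frame
        inv_dr = -(np.cos(th) * dr - np.sin(th) * dc)
        inv_dc = -(np.sin(th) * dr + np.cos(th) * dc)
        return RegistrationParams(-self.rotation_deg, (inv_dr, inv_dc), 1.0)


def _transform_matrix(params: RegistrationParams, shape: tuple) -> tuple:
    """Affine (matrix, offset) for scipy.ndimage.affine_transform (output->input)."""
    th = np.deg2rad(params.rotation_deg)
    c, s = np.cos(th), np.sin(th)
    rot = np.array([[c, -s], [s, c]]) * params.scale
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    shift = np.asarray(params.translation_px, dtype=float)
    # forward: y = R (x - center) + center + shift; affine_transform needs inverse
    rinv = np.linalg.inv(rot)
    offset = center - rinv @ (center + shift)
    return rinv, offset


def register(moving: MovieStack, params: RegistrationParams) -> MovieStack:
    """Apply a pre-calibrated rotation+translation to every frame.

    Bilinear interpolation; pixels mapped from outside the field are filled
    with 0 and marked in the output mask.
    """
    if params.is_identity:
        return moving.with_frames(moving.frames.copy())
    matrix, offset = _transform_matrix(params, moving.frames.shape[1:])
    out = np.empty_like(moving.frames)
    for i, frame in enumerate(moving.frames):
        out[i] = ndimage.affine_transform(
            frame, matrix, offset=offset, order=1, mode="constant", cval=0.0
        )
    valid = np.ones(moving.frames.shape[1:])
    valid_t = ndimage.affine_transform(
        valid, matrix, offset=offset, order=1, mode="constant", cval=0.0
    )
    mask = valid_t < 0.999
    if moving.mask is not None:
        mask |= moving.mask
    return moving.with_frames(out, mask=mask)


def deinterleave(
    green_cam: MovieStack, red_cam: MovieStack, parity: str = "even"
) -> dict:
    """Split interleaved two-camera stacks into the four logical channels.

    ``parity`` names which recorded frames ("even" or "odd", 0-based) were
    blue-excited.  Each output stack has the frame interval doubled.  The
    green-camera/olive-excitation record carries no fluorescence and is
    returned under ``blank`` only so bookkeeping stays lossless.
    """
    if green_cam.n_frames != red_cam.n_frames:
        raise ValueError("camera stacks must have equal frame counts")
    if parity not in ("even", "odd"):
        raise ValueError("parity must be 'even' or 'odd'")
    blue = slice(0, None, 2) if parity == "even" else slice(1, None, 2)
    olive = slice(1, None, 2) if parity == "even" else slice(0, None, 2)
    dt2 = green_cam.frame_interval_s * 2
    return {
        "venus": MovieStack(green_cam.frames[blue].copy(), dt2, "venus", green_cam.mask),
        "mixed": MovieStack(red_cam.frames[blue].copy(), dt2, "mixed", red_cam.mask),
        "rhodamine": MovieStack(red_cam.frames[olive].copy(), dt2, "rhodamine", red_cam.mask),
        "blank": MovieStack(green_cam.frames[olive].copy(), dt2, "blank", green_cam.mask),
    }


def interleave(channels: dict, parity: str = "even") -> tuple:
    """Inverse of :func:`deinterleave`; returns (green_cam, red_cam)."""
    venus, mixed = channels["venus"], channels["mixed"]
    rhod, blank = channels["rhodamine"], channels["blank"]
    n = venus.n_frames + blank.n_frames
    shape = (n,) + venus.frames.shape[1:]
    green = np.empty(shape)
    red = np.empty(shape)
    blue = slice(0, None, 2) if parity == "even" else slice(1, None, 2)
    olive = slice(1, None, 2) if parity == "even" else slice(0, None, 2)
    green[blue], green[olive] = venus.frames, blank.frames
    red[blue], red[olive] = mixed.frames, rhod.frames
    dt = venus.frame_interval_s / 2
    return (
        MovieStack(green, dt, "green_cam", venus.mask),
        MovieStack(red, dt, "red_cam", mixed.mask),
    )


def estimate_leakage(
    venus: MovieStack, mixed: MovieStack, roi_set, local_background: bool = True
) -> float:
    """Estimate green->mixed spectral bleed-through from a ligand-free record.

    For every spot ROI and frame, the ratio of ROI-integrated mixed to venus
    intensity is formed; the estimate is the median over spots x frames,
    which is robust to occasional dim frames and scale-invariant.  With
    ``local_background`` (default) each ROI sum is corrected by the median
    pixel value of the surrounding annulus (9x9 minus the 5x5 core), so
    camera baseline and autofluorescence do not bias the ratio.
    """
    if venus.shape != mixed.shape:
        raise ValueError("venus and mixed stacks must share geometry")
    ratios = []
    nrows, ncols = venus.frames.shape[1:]
    for roi in roi_set:
        rows, cols = _roi_slices(roi)
        v = venus.frames[:, rows, cols].sum(axis=(1, 2))
        m = mixed.frames[:, rows, cols].sum(axis=(1, 2))
        if local_background:
            r0 = (rows.start + rows.stop - 1) // 2
            c0 = (cols.start + cols.stop - 1) // 2
            ring_r = slice(max(r0 - 4, 0), min(r0 + 5, nrows))
            ring_c = slice(max(c0 - 4, 0), min(c0 + 5, ncols))
            core = np.zeros((nrows, ncols), dtype=bool)
            core[rows, cols] = True
            ring = np.zeros((nrows, ncols), dtype=bool)
            ring[ring_r, ring_c] = True
            ring &= ~core
            n_px = core.sum()
            # mean, not median: EMCCD pixel noise is right-skewed, so the
            # median under-subtracts background; spots are sparse enough
            # that annulus contamination is rare
            v = v - n_px * venus.frames[:, ring].mean(axis=1)
            m = m - n_px * mixed.frames[:, ring].mean(axis=1)
        ok = np.abs(v) > 1e-12
        if not ok.any():
            continue
        ratios.append(m[ok] / v[ok])
    if not ratios:
        raise ValueError("no ROI with nonzero venus intensity; leakage undefined")
    return float(np.median(np.concatenate(ratios)))


def _roi_slices(roi) -> tuple:
    """Accept a SpotROI-like object or a (row, col, half) tuple."""
    if hasattr(roi, "row_slice"):
        return roi.row_slice, roi.col_slice
    r, c = int(roi[0]), int(roi[1])
    half = int(roi[2]) if len(roi) > 2 else 2
    return slice(r - half, r + half + 1), slice(c - half, c + half + 1)


def correct_leakage(
    mixed: MovieStack, venus: MovieStack, leak_fraction: float = 0.10
) -> MovieStack:
    """FRET channel = mixed - leak_fraction * venus, frame by frame."""
    if mixed.shape != venus.shape:
        raise ValueError("mixed and venus stacks must share geometry")
    out = mixed.frames - leak_fraction * venus.frames
    return MovieStack(out, mixed.frame_interval_s, "fret", mixed.mask)


def correct_uneven_field(
    image: np.ndarray, radius_px: int = 100, downsample: int = 4
) -> np.ndarray:
    """Remove low-spatial-frequency illumination variation.

    Morphological rolling-ball background (default radius 100 px) subtracted
    from a 2-D average image.  Diffraction-limited spots are far smaller than
    the ball, so their integrals are preserved.  Because the background is by
    construction smooth, it is estimated on a block-averaged image with the
    radius scaled accordingly and resampled up, which is orders of magnitude
    faster at the default 100 px radius; set ``downsample=1`` for the exact
    full-resolution ball.
    """
    from skimage.transform import resize

    image = np.asarray(image, dtype=float)
    ds = max(int(downsample), 1)
    if ds > 1 and min(image.shape) >= 4 * ds and radius_px >= 2 * ds:
        small = image[: image.shape[0] // ds * ds, : image.shape[1] // ds * ds]
        small = small.reshape(
            small.shape[0] // ds, ds, small.shape[1] // ds, ds
        ).mean(axis=(1, 3))
        bg_small = rolling_ball(small, radius=radius_px / ds)
        bg = resize(bg_small, image.shape, order=1, mode="edge",
                    anti_aliasing=False)
    else:
        bg = rolling_ball(image, radius=radius_px)
    return image - bg


def _dual_exp(t, a1, k1, a2, k2, c):
    return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t) + c


@dataclass
class BackgroundFit:
    a1: float
    k1: float
    a2: float
    k2: float
    c: float
    residual_rms: float
    model: str = "dual_exponential"  # or "single_exponential" fallback

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return _dual_exp(np.asarray(t, dtype=float), self.a1, self.k1, self.a2, self.k2, self.c)


def _init_dual_exp(t, y):
    """Crude starting values from log-linear fits to early/late thirds."""
    c0 = float(np.min(y))
    span = max(float(np.ptp(y)), 1e-9)
    yp = np.clip(y - c0 + 0.05 * span, 1e-12, None)
    n = len(t)
    third = max(n // 3, 2)
    k_fast = _loglin_rate(t[:third], yp[:third])
    k_slow = _loglin_rate(t[-third:], yp[-third:])
    k_fast = max(k_fast, 1e-6)
    k_slow = max(min(k_slow, k_fast / 2), 1e-8)
    a = span / 2
    return [a, k_fast, a, k_slow, c0]


def _loglin_rate(t, y):
    b = np.polyfit(t, np.log(y), 1)[0]
    return float(max(-b, 0.0))


def correct_autofluorescence(
    stack: MovieStack, roi_mask: Optional[np.ndarray] = None
) -> tuple:
    """Fit and subtract the decaying autofluorescent background.

    The per-frame mean intensity over non-ROI pixels is fitted to a
    dual-exponential with a constant offset, A1*exp(-k1 t) + A2*exp(-k2 t) + C;
    the fitted per-pixel background is then subtracted from every pixel of
    every frame (ROI pixels included).  Falls back to a single exponential +
    offset if the dual-exponential fit does not converge.

    Returns (corrected stack, :class:`BackgroundFit`).
    """
    if stack.n_frames < 10:
        raise ValueError("need at least 10 frames to fit the background decay")
    frames = stack.frames
    if roi_mask is None:
        sel = np.ones(frames.shape[1:], dtype=bool)
    else:
        sel = ~np.asarray(roi_mask, dtype=bool)
    if stack.mask is not None:
        sel &= ~stack.mask
    if not sel.any():
        raise ValueError("ROI mask excludes every pixel")
    t = stack.frame_times
    y = frames[:, sel].mean(axis=1)

    fit = None
    try:
        p0 = _init_dual_exp(t, y)
        bounds = ([-np.inf, 0, -np.inf, 0, -np.inf], [np.inf] * 5)
        popt, _ = curve_fit(_dual_exp, t, y, p0=p0, bounds=bounds, maxfev=20000)
        resid = y - _dual_exp(t, *popt)
        fit = BackgroundFit(*popt, residual_rms=float(np.sqrt(np.mean(resid**2))))
    except (RuntimeError, ValueError):
        pass
    if fit is None:
        def single(tt, a, k, c):
            return a * np.exp(-k * tt) + c
        try:
            p0 = [max(float(y[0] - y[-1]), 1e-9), 0.1, float(y[-1])]
            popt, _ = curve_fit(
                single, t, y, p0=p0, bounds=([-np.inf, 0, -np.inf], [np.inf] * 3),
                maxfev=20000,
            )
            a, k, c = popt
        except (RuntimeError, ValueError):
            a, k, c = 0.0, 0.0, float(np.mean(y))
        resid = y - (a * np.exp(-k * t) + c)
        fit = BackgroundFit(a, k, 0.0, 0.0, c,
                            residual_rms=float(np.sqrt(np.mean(resid**2))),
                            model="single_exponential")

    bg_per_pixel = fit.evaluate(t)
    out = frames - bg_per_pixel[:, None, None]
    return stack.with_frames(out), fit
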