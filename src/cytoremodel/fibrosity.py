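"""Fibrosity: a band-pass spectral statistic for stress-fiber content.

The fibrosity of a fluorescence image is the fraction of its (non-DC) spectral
power that falls in an annulus of radial spatial frequencies corresponding to
features of stress-fiber thickness.  Because a line-like feature of width
``w`` concentrates power near the half-period frequency ``1/(2w)``, the
band-pass power scales with the total contour length of fiber-thickness
features, which is what makes the statistic useful as a remodeling readout.

The module also provides the supporting image operations used around the
statistic: maximum-intensity z-stack collapse, luminosity normalization
(compensating focal-plane and expression changes so the statistic responds to
structure rather than brightness), integer-pixel translational alignment, and
signed image subtraction for gain/loss maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy import fft as sp_fft
from scipy.signal import windows

__all__ = [
    "Image",
    "FiberBand",
    "FibrosityTrace",
    "collapse_zstack",
    "normalize_luminosity",
    "fibrosity_value",
    "fibrosity_trace",
    "align_translate",
    "subtract",
    "read_stack",
    "write_trace_csv",
]


@dataclass(frozen=True)
class Image:
    """A 2-D intensity grid with physical pixel size (µm/pixel)."""

    pixels: np.ndarray
    pixel_size: float = 0.5

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("image must be 2-D")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class FiberBand:
    """Feature-thickness band (µm) defining the fibrosity annulus.

    A fiber of width ``w`` contributes power near radial frequency
    ``1/(2w)`` cycles/µm, so the band maps to frequencies
    ``[1/(2*w_max), 1/(2*w_min)]``.
    """

    w_min: float = 0.3
    w_max: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.w_min < self.w_max):
            raise ValueError("require 0 < w_min < w_max")

    @property
    def f_lo(self) -> float:
        return 1.0 / (2.0 * self.w_max)

    @property
    def f_hi(self) -> float:
        return 1.0 / (2.0 * self.w_min)


@dataclass(frozen=True)
class FibrosityTrace:
    """Normalized fibrosity time series; value 1 at the reference frame."""

    times: np.ndarray
    values: np.ndarray
    reference_index: int = 0


def collapse_zstack(stack) -> Image:
    """Maximum-intensity projection of a z-stack (list of Image or 3-D array)."""
    if isinstance(stack, np.ndarray):
        if stack.ndim != 3 or stack.shape[0] == 0:
            raise ValueError("stack array must be (z, y, x) and non-empty")
        return Image(stack.max(axis=0))
    imgs = list(stack)
    if not imgs:
        raise ValueError("empty stack")
    shapes = {im.pixels.shape for im in imgs}
    if len(shapes) != 1:
        raise ValueError("stack slices differ in shape")
    px = np.max([im.pixels for im in imgs], axis=0)
    return Image(px, imgs[0].pixel_size)


def sum_project(stack) -> Image:
    """Sum projection, the alternative collapse for photometric bookkeeping."""
    imgs = list(stack)
    if not imgs:
        raise ValueError("empty stack")
    px = np.sum([im.pixels for im in imgs], axis=0)
    return Image(px, imgs[0].pixel_size)


def normalize_luminosity(img: Image) -> Image:
    """Scale an image to unit mean intensity.

    Compensates total-luminosity changes (z-motion of the cell, expression
    level) so that fibrosity compares structure, not brightness.
    """
    mean = float(img.pixels.mean())
    if mean <= 0:
        raise ValueError("cannot normalize an all-zero image")
    return Image(img.pixels / mean, img.pixel_size)


def _radial_frequency_grid(shape, pixel_size: float) -> np.ndarray:
    fy = sp_fft.fftfreq(shape[0], d=pixel_size)
    fx = sp_fft.fftfreq(shape[1], d=pixel_size)
    return np.hypot.outer(fy, fx)


def fibrosity_value(img: Image, band: FiberBand = FiberBand()) -> float:
    """Band-pass power of the 2-D periodogram of the luminosity-scaled image.

    The image is scaled to unit mean (so the statistic compares structure,
    not brightness), demeaned, Hann-windowed to suppress edge leakage, and
    the periodogram is summed over the annulus of radial frequencies
    ``[1/(2 w_max), 1/(2 w_min)]``.  The sum is normalized by the window
    energy and pixel count, making the value independent of image size for
    stationary content.  For non-overlapping fiber-thickness features the
    band power adds incoherently, so the statistic grows in proportion to
    the total contour length of such features — the property that makes it a
    remodeling readout.  Deterministic; 0 for a constant image.  Raises if
    the band lies outside the resolvable frequencies (Nyquist or image
    extent).
    """
    px = img.pixels
    nyquist = 1.0 / (2.0 * img.pixel_size)
    f_fundamental = 1.0 / (min(px.shape) * img.pixel_size)
    if band.f_hi > nyquist:
        raise ValueError(
            f"band upper frequency {band.f_hi:.3f} exceeds Nyquist {nyquist:.3f} "
            "cycles/um at this pixel size"
        )
    if band.f_lo < f_fundamental:
        raise ValueError("band lower frequency below the image's fundamental")
    mean = float(px.mean())
    if mean <= 0:
        return 0.0
    scaled = px / mean
    win = np.outer(windows.hann(px.shape[0]), windows.hann(px.shape[1]))
    tapered = (scaled - scaled.mean()) * win
    power = np.abs(sp_fft.fft2(tapered)) ** 2
    freq = _radial_frequency_grid(px.shape, img.pixel_size)
    in_band = (freq >= band.f_lo) & (freq <= band.f_hi)
    norm = float(np.sum(win ** 2)) * px.size
    return float(power[in_band].sum() / norm)


def fibrosity_trace(images, band: FiberBand = FiberBand(),
                    reference_index: int = 0, times=None) -> FibrosityTrace:
    """Per-frame fibrosity normalized to the value at ``reference_index``.

    Frames are luminosity-normalized first.  Requires at least two frames and
    a nonzero reference value.
    """
    imgs = list(images)
    if len(imgs) < 2:
        raise ValueError("need at least two frames")
    vals = np.array([fibrosity_value(normalize_luminosity(im), band)
                     for im in imgs])
    ref = vals[reference_index]
    if ref == 0:
        raise ValueError("reference frame has zero fibrosity")
    if times is None:
        times = np.arange(len(imgs), dtype=float) * 5.0  # default 5-min cadence
    return FibrosityTrace(np.asarray(times, dtype=float), vals / ref,
                          reference_index)


def align_translate(moving: Image, fixed: Image):
    """Integer-pixel shift maximizing cross-correlation, plus the shifted image.

    Returns ``((dy, dx), aligned)`` such that rolling ``moving`` by
    ``(dy, dx)`` best matches ``fixed``; vacated borders are zero-padded.
    """
    if moving.pixels.shape != fixed.pixels.shape:
        raise ValueError("images must share dimensions")
    a = fixed.pixels - fixed.pixels.mean()
    b = moving.pixels - moving.pixels.mean()
    corr = np.real(sp_fft.ifft2(sp_fft.fft2(a) * np.conj(sp_fft.fft2(b))))
    dy, dx = np.unravel_index(int(np.argmax(corr)), corr.shape)
    shape = moving.pixels.shape
    if dy > shape[0] // 2:
        dy -= shape[0]
    if dx > shape[1] // 2:
        dx -= shape[1]
    aligned = np.zeros_like(moving.pixels)
    src_y = slice(max(0, -dy), min(shape[0], shape[0] - dy))
    src_x = slice(max(0, -dx), min(shape[1], shape[1] - dx))
    dst_y = slice(max(0, dy), min(shape[0], shape[0] + dy))
    dst_x = slice(max(0, dx), min(shape[1], shape[1] + dx))
    aligned[dst_y, dst_x] = moving.pixels[src_y, src_x]
    return (int(dy), int(dx)), Image(aligned, moving.pixel_size)


def subtract(later: Image, earlier: Image) -> np.ndarray:
    """Signed per-pixel difference ``later - earlier`` (positive = gain)."""
    if later.pixels.shape != earlier.pixels.shape:
        raise ValueError("images must share dimensions")
    return later.pixels - earlier.pixels


def read_stack(path, pixel_size: float = 0.5) -> list[Image]:
    """Read a single- or multi-page TIFF as a list of frames."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return [Image(frame.astype(float), pixel_size) for frame in arr]


def write_trace_csv(trace: FibrosityTrace, path) -> None:
    pd.DataFrame({"time_min": trace.times,
                  "fibrosity": trace.values}).to_csv(path, index=False)
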