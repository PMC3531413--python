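"""Synthetic inputs for every pipeline stage: rendered fibrous-cell images,
bead displacement fields, and force-relaxation traces.

Each generator is a pure function of its spec and seed, and each carries a
recoverable ground truth (total contour length, deformation gradient, force
decrement, per-sector densities), so the package's parameter-recovery suite
can exercise the real analysis path with no external data.  Rendering is
deliberately simple — Gaussian-profile line segments for stress fibers,
isotropic Gaussian blobs for F-actin reservoirs, additive noise — emulating
collapsed confocal stacks at 20x scale, not a full optical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .fibrosity import Image
from .kinematics import BeadField
from .remodel_sim import CellModel, SimOutput

__all__ = [
    "RenderSpec",
    "Segment",
    "Blob",
    "SegmentList",
    "ForceTraceSpec",
    "render_fibers",
    "render_cell_series",
    "gen_beads",
    "gen_force_trace",
    "write_bead_csv",
    "read_bead_csv",
    "write_force_csv",
]


@dataclass(frozen=True)
class RenderSpec:
    """Rendering geometry and noise for synthetic fluorescence images."""

    size: tuple[int, int] = (256, 256)   # pixels (rows, cols)
    pixel_size: float = 0.25             # um/pixel; keeps a 0.5 um fiber at
                                         # 2 px FWHM and the default band
                                         # below Nyquist
    fiber_width: float = 0.5             # um, Gaussian FWHM of the cross-section
    fiber_intensity: float = 40.0        # peak above the diffuse background
    background: float = 50.0             # diffuse cytoplasmic fluorescence
    noise_model: str = "gaussian"        # or "poisson"
    noise_sigma: float = 1.0             # gaussian sigma (ignored for poisson)
    quantize_10bit: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fiber_width < 2.0 * self.pixel_size:
            raise ValueError(
                "fiber width under 2 pixels FWHM is not resolvable at this "
                "pixel size"
            )
        if self.fiber_intensity < 0 or self.background < 0:
            raise ValueError("intensities must be non-negative")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")


@dataclass(frozen=True)
class Segment:
    """A straight fiber segment in µm coordinates."""

    x1: float
    y1: float
    x2: float
    y2: float
    width: float = 0.5       # um
    intensity: float = 100.0

    @property
    def length(self) -> float:
        return float(np.hypot(self.x2 - self.x1, self.y2 - self.y1))


@dataclass(frozen=True)
class Blob:
    """An isotropic Gaussian blob (F-actin reservoir) in µm coordinates."""

    x: float
    y: float
    radius: float = 2.0      # um, Gaussian sigma
    intensity: float = 100.0


@dataclass
class SegmentList:
    segments: list = field(default_factory=list)
    blobs: list = field(default_factory=list)

    @property
    def total_length(self) -> float:
        return float(sum(s.length for s in self.segments))


def _paint_segment(canvas: np.ndarray, seg: Segment, pixel_size: float) -> None:
    """Add a Gaussian-cross-section line segment to the canvas (in place)."""
    ny, nx = canvas.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    xs, ys = xx * pixel_size, yy * pixel_size
    px, py = seg.x2 - seg.x1, seg.y2 - seg.y1
    length2 = px * px + py * py
    if length2 == 0:
        dist = np.hypot(xs - seg.x1, ys - seg.y1)
    else:
        t = np.clip(((xs - seg.x1) * px + (ys - seg.y1) * py) / length2, 0, 1)
        dist = np.hypot(xs - (seg.x1 + t * px), ys - (seg.y1 + t * py))
    sigma = seg.width / 2.355  # FWHM -> sigma
    canvas += seg.intensity * np.exp(-0.5 * (dist / sigma) ** 2)


def _paint_blob(canvas: np.ndarray, blob: Blob, pixel_size: float) -> None:
    ny, nx = canvas.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    dist = np.hypot(xx * pixel_size - blob.x, yy * pixel_size - blob.y)
    canvas += blob.intensity * np.exp(-0.5 * (dist / blob.radius) ** 2)


def _finalize(canvas: np.ndarray, spec: RenderSpec,
              rng: np.random.Generator) -> np.ndarray:
    canvas = canvas + spec.background
    if spec.noise_model == "gaussian":
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, canvas.shape)
    else:
        canvas = rng.poisson(np.maximum(canvas, 0)).astype(float)
    canvas = np.maximum(canvas, 0.0)
    if spec.quantize_10bit:
        canvas = np.clip(np.round(canvas), 0, 1023)
    return canvas


def render_fibers(segs: SegmentList, spec: RenderSpec) -> tuple[Image, float]:
    """Rasterize segments and blobs; returns the image and exact total length.

    Deterministic under ``spec.seed``; an empty list yields background plus
    noise with ground-truth length 0.
    """
    rng = np.random.default_rng(spec.seed)
    canvas = np.zeros(spec.size, dtype=float)
    for seg in segs.segments:
        _paint_segment(canvas, seg, spec.pixel_size)
    for blob in segs.blobs:
        _paint_blob(canvas, blob, spec.pixel_size)
    return (Image(_finalize(canvas, spec, rng), spec.pixel_size),
            segs.total_length)


def _sector_segments(cell: CellModel, rho: np.ndarray, spec: RenderSpec,
                     fibers_per_density: float,
                     jitter: np.ndarray, offsets: np.ndarray) -> list[Segment]:
    """Segments along each sector's orientation, count proportional to density.

    Fibers within a sector share its orientation (small angular jitter) but
    are displaced laterally so added fibers add contour length rather than
    merging into one thick bundle; positions are frozen per (sector, fiber)
    so frames differ only through the density-driven counts.
    """
    ny, nx = spec.size
    cx = nx * spec.pixel_size / 2.0
    cy = ny * spec.pixel_size / 2.0
    half_len = 0.35 * min(cx, cy)
    segs: list[Segment] = []
    for i in range(len(cell.theta)):
        n_fibers = int(round(fibers_per_density * rho[i]))
        for k in range(min(n_fibers, jitter.shape[1])):
            ang = cell.theta[i] + jitter[i, k]
            ux, uy = np.cos(ang), np.sin(ang)
            # lateral displacement perpendicular to the fiber direction
            mx = cx - uy * offsets[i, k]
            my = cy + ux * offsets[i, k]
            segs.append(Segment(
                x1=mx - half_len * ux, y1=my - half_len * uy,
                x2=mx + half_len * ux, y2=my + half_len * uy,
                width=spec.fiber_width, intensity=spec.fiber_intensity,
            ))
    return segs


def render_cell_series(sim: SimOutput, cell: CellModel, spec: RenderSpec,
                       fibers_per_density: float = 2.0,
                       n_frames: int | None = None) -> list[Image]:
    """Render a simulated run as a time series of cell images.

    Each intact sector is drawn as radial segments whose count rounds
    ``fibers_per_density * rho`` (monotone in density); the F-actin reservoir
    appears as a central blob whose intensity is proportional to the pool.
    Frames subsample the simulation at roughly the 5-minute imaging cadence
    unless ``n_frames`` is given.  Deterministic under ``spec.seed``.
    """
    n_times = sim.per_sector_density.shape[0]
    if n_frames is None:
        stride = max(1, int(round(5.0 / max(sim.params.dt, 1e-9))))
        idx = list(range(0, n_times, stride))
        if idx[-1] != n_times - 1:
            idx.append(n_times - 1)
    else:
        idx = list(np.linspace(0, n_times - 1, n_frames).astype(int))
    rng = np.random.default_rng(spec.seed)
    max_fibers = int(round(fibers_per_density * sim.params.rho_max)) + 1
    jitter = rng.normal(0.0, 0.02, (len(cell.theta), max_fibers))
    ny, nx = spec.size
    cx = nx * spec.pixel_size / 2.0
    cy = ny * spec.pixel_size / 2.0
    spread = 0.5 * min(cx, cy)
    offsets = rng.uniform(-spread, spread, (len(cell.theta), max_fibers))
    frames = []
    for j, t_idx in enumerate(idx):
        canvas = np.zeros(spec.size, dtype=float)
        segs = _sector_segments(cell, sim.per_sector_density[t_idx], spec,
                                fibers_per_density, jitter, offsets)
        for seg in segs:
            _paint_segment(canvas, seg, spec.pixel_size)
        # reservoir blob grows as fibers depolymerize (pool bookkeeping is
        # meaningful mainly in finite-pool mode but rendered regardless)
        lost = sim.params.rho0 * len(cell.theta) - sim.per_sector_density[t_idx].sum()
        pool_intensity = spec.fiber_intensity * max(lost, 0.0) / max(len(cell.theta), 1)
        if pool_intensity > 0:
            _paint_blob(canvas, Blob(cx, cy, 2.0, pool_intensity),
                        spec.pixel_size)
        frame_rng = np.random.default_rng(spec.seed + 7919 * (j + 1))
        frames.append(Image(_finalize(canvas, spec, frame_rng),
                            spec.pixel_size))
    return frames


def gen_beads(n: int, F, noise_sigma: float = 0.0, seed: int = 0,
              field_of_view: float = 200.0) -> BeadField:
    """Bead positions uniform in a square field, displaced by ``F`` plus noise.

    ``after = F @ before + N(0, noise_sigma)`` per coordinate (µm).
    """
    if n < 3:
        raise ValueError("need at least 3 beads for strain estimation")
    rng = np.random.default_rng(seed)
    before = rng.uniform(0.0, field_of_view, (n, 2))
    F = np.asarray(F, dtype=float)
    after = before @ F.T + rng.normal(0.0, noise_sigma, (n, 2))
    return BeadField(before, after)


@dataclass(frozen=True)
class ForceTraceSpec:
    """Step-plus-relaxation isometric force trace with optional drug decrement.

    Emulates the force response of a construct to a rapid stretch: a step
    above baseline relaxing exponentially (one or two time constants) toward
    a plateau above baseline, with an optional later step-down when a
    contractility inhibitor is added.
    """

    baseline: float = 50.0            # uN
    step_amplitude: float = 40.0      # uN above baseline at the stretch
    tau: tuple[float, ...] = (5.0,)   # min; one or two exponentials
    tau_weights: tuple[float, ...] = (1.0,)
    plateau_fraction: float = 0.15    # fraction of step remaining as t -> inf
    noise_sigma: float = 0.5          # uN
    drug_decrement: float = 0.0       # uN
    drug_onset: float | None = None   # min
    drug_tau: float = 1.0             # min, decrement settling time
    sampling_rate: float = 2.0        # samples/min
    duration: float = 30.0            # min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.step_amplitude < 0 or self.drug_decrement < 0:
            raise ValueError("amplitudes must be non-negative")
        if any(t <= 0 for t in self.tau) or self.drug_tau <= 0:
            raise ValueError("time constants must be positive")
        if len(self.tau) != len(self.tau_weights):
            raise ValueError("tau and tau_weights must match in length")


def gen_force_trace(spec: ForceTraceSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(times_min, force)`` for the configured trace.

    Noise-free output is the analytic curve exactly; noise is additive
    Gaussian, deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + 1e-9, 1.0 / spec.sampling_rate)
    w = np.asarray(spec.tau_weights, dtype=float)
    w = w / w.sum()
    decay = sum(wi * np.exp(-t / ti) for wi, ti in zip(w, spec.tau))
    relaxing = spec.plateau_fraction + (1.0 - spec.plateau_fraction) * decay
    force = spec.baseline + spec.step_amplitude * relaxing
    if spec.drug_decrement > 0 and spec.drug_onset is not None:
        after = t >= spec.drug_onset
        force = force - spec.drug_decrement * after * (
            1.0 - np.exp(-(t - spec.drug_onset) / spec.drug_tau) * after
        )
    force = force + rng.normal(0.0, spec.noise_sigma, t.shape)
    return t, force


def write_bead_csv(beads: BeadField, path) -> None:
    pd.DataFrame({
        "x_before": beads.positions_before[:, 0],
        "y_before": beads.positions_before[:, 1],
        "x_after": beads.positions_after[:, 0],
        "y_after": beads.positions_after[:, 1],
    }).to_csv(path, index=False)


def read_bead_csv(path) -> BeadField:
    df = pd.read_csv(path)
    return BeadField(df[["x_before", "y_before"]].to_numpy(),
                     df[["x_after", "y_after"]].to_numpy())


def write_force_csv(times, force, path) -> None:
    pd.DataFrame({"time_min": times, "force_uN": force}).to_csv(path, index=False)


def write_stack(frames: list[Image], path) -> None:
    """Write frames as a multi-page float32 TIFF."""
    arr = np.stack([f.pixels for f in frames]).astype(np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")
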