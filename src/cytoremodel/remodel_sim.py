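"""Sector model of stretch-induced stress-fiber remodeling.

A cell is idealized as angular sectors of stress fibers, each carrying a
density ``rho`` and a random pre-stretch ``lambda_pre`` drawn from a truncated
normal on the allowable stretch window.  A single rapid construct stretch
multiplies each sector's stretch by ``1 + eps(theta)`` (orientation-resolved
strain from :mod:`cytoremodel.kinematics`).  Two rules then drive dynamics:

1. **Depolymerization** — a sector whose total stretch leaves the allowable
   window ``[lambda_min, lambda_max]`` loses its fibers at once (tensile
   rupture above, compressive buckling below).  Released F-actin is credited
   to a reservoir pool.
2. **Stress-driven polymerization** — intact sectors whose adhesion-site
   stress lies in an intermediate band ``[s_low, s_high]`` grow first-order
   toward a saturating density ``rho_max``.  Adhesion stress is scaled by a
   load-sharing factor fixed at the stretch event: rupture of fibers under
   tension releases stress in the surrounding matrix, and the stress felt by
   the survivors drops in proportion to the tension lost.  When enough
   tensile fibers rupture, no survivor reaches the polymerization threshold
   and reinforcement is eliminated.

The summed density (weighted by sector width) is an in-silico analog of the
fibrosity image statistic, normalized to its pre-stretch value.  Depending on
the pre-stretch spread ``sigma_pre``, runs reproduce the three observed
temporal classes: monotonic reinforcement, retraction followed by
reinforcement, and monotonic retraction — and never the reverse ordering,
because depolymerization is confined to the stretch event while growth is
monotone afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy import stats

from .kinematics import fiber_strain

__all__ = [
    "SimParams",
    "CellModel",
    "SimOutput",
    "CellShape",
    "init_cell",
    "apply_stretch",
    "event_load_share",
    "adhesion_stress",
    "step",
    "simulate",
    "sweep",
]


class CellShape(str, Enum):
    circular = "circular"
    spindle = "spindle"


#: Canonical demonstration conditions for the pre-stretch-variability sweep:
#: three standard deviations at which the three temporal classes dominate in
#: turn, at the 10% local strain of the strongest stretch protocol.
SWEEP_SIGMAS = (0.02, 0.08, 0.25)
SWEEP_EPS = 0.10
#: Angular resolution used when reproducing the depolymerization-by-
#: orientation histograms (finer than the 36-sector dynamics default so the
#: pooled histogram is well populated at low pre-stretch spread).
HISTOGRAM_SECTORS = 720


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters.

    The allowable window ``[lambda_min, lambda_max]`` and the pre-stretch
    moments are literature-scale placeholders for the stretch-ratio range over
    which a stress fiber persists; every value is config-exposed.
    ``share_mode`` selects how ruptured fibers release matrix stress:
    ``"stress"`` weights each lost fiber by the tension it carried (default),
    ``"density"`` by its density alone.
    """

    lambda_min: float = 0.96
    lambda_max: float = 1.28
    mu_pre: float = 1.12
    sigma_pre: float = 0.05
    n_sectors: int = 36
    rho0: float = 1.0
    rho_max: float = 1.8
    k_poly: float = 0.15  # 1/min
    s_low: float = 0.14
    s_high: float = 1.0
    k_fiber: float = 1.0
    dt: float = 0.1  # min
    duration: float = 30.0  # min
    seed: int = 0
    rock_inhibited: bool = False
    reservoir_finite: bool = False
    reservoir_capacity: float = 50.0
    share_mode: str = "stress"
    spindle_kappa: float = 8.0  # orientation concentration for spindle cells

    def __post_init__(self) -> None:
        if not (self.lambda_min < self.mu_pre < self.lambda_max):
            raise ValueError("require lambda_min < mu_pre < lambda_max")
        if not (0 < self.rho0 <= self.rho_max):
            raise ValueError("require 0 < rho0 <= rho_max")
        if not (0 <= self.s_low < self.s_high):
            raise ValueError("require 0 <= s_low < s_high")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sigma_pre < 0:
            raise ValueError("sigma_pre must be non-negative")
        if self.n_sectors < 1:
            raise ValueError("need at least one sector")
        if self.share_mode not in ("stress", "density"):
            raise ValueError("share_mode must be 'stress' or 'density'")


@dataclass
class CellModel:
    """Cell state: per-sector orientation, pre-stretch, stretch, density."""

    shape: CellShape
    theta: np.ndarray          # sector orientations, radians in [0, pi)
    width: np.ndarray          # sector angular widths, radians
    lambda_pre: np.ndarray
    lambda_total: np.ndarray
    rho: np.ndarray
    intact: np.ndarray         # boolean; False = depolymerized
    reservoir: float = 0.0
    spindle_axis: float = 0.0

    def copy(self) -> "CellModel":
        return CellModel(
            shape=self.shape,
            theta=self.theta.copy(),
            width=self.width.copy(),
            lambda_pre=self.lambda_pre.copy(),
            lambda_total=self.lambda_total.copy(),
            rho=self.rho.copy(),
            intact=self.intact.copy(),
            reservoir=self.reservoir,
            spindle_axis=self.spindle_axis,
        )

    @property
    def total_weighted_density(self) -> float:
        return float(np.sum(self.rho * self.width))


@dataclass
class SimOutput:
    """Time series produced by :func:`simulate`."""

    times: np.ndarray
    model_fibrosity: np.ndarray
    per_sector_density: np.ndarray  # (n_times, n_sectors)
    depolymerized_mask: np.ndarray  # boolean per sector
    theta: np.ndarray
    response_class: str
    load_share: float
    params: SimParams


def _truncated_normal(mu: float, sigma: float, lo: float, hi: float,
                      n: int, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return np.full(n, mu)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def init_cell(shape: CellShape | str, params: SimParams) -> CellModel:
    """Initialize a cell with uniform (circular) or axis-concentrated (spindle)
    sector orientations and i.i.d. truncated-normal pre-stretches.

    Deterministic under ``params.seed``.
    """
    shape = CellShape(shape)
    rng = np.random.default_rng(params.seed)
    n = params.n_sectors
    width = np.full(n, np.pi / n)
    if shape is CellShape.circular:
        theta = (np.arange(n) + 0.5) * np.pi / n
        axis = 0.0
    else:
        # spindle: orientations wrapped-normal about the spindle axis, folded
        # into [0, pi); sector widths stay equal so density stays comparable
        axis = 0.0
        theta = np.mod(rng.normal(axis, 1.0 / np.sqrt(params.spindle_kappa), n), np.pi)
        theta.sort()
    lam = _truncated_normal(params.mu_pre, params.sigma_pre,
                            params.lambda_min, params.lambda_max, n, rng)
    return CellModel(
        shape=shape,
        theta=theta,
        width=width,
        lambda_pre=lam,
        lambda_total=lam.copy(),
        rho=np.full(n, params.rho0),
        intact=np.ones(n, dtype=bool),
        reservoir=0.0,
        spindle_axis=axis,
    )


def apply_stretch(cell: CellModel, eps_o: float, nu: float, params: SimParams,
                  axis_angle: float = 0.0) -> CellModel:
    """Apply a single construct stretch of local amplitude ``eps_o``.

    Each sector's stretch becomes ``lambda_total * (1 + eps(theta - axis))``;
    sectors leaving the allowable window depolymerize instantaneously, their
    F-actin credited to the reservoir.  Returns a new cell state.
    """
    out = cell.copy()
    eps = fiber_strain(eps_o, out.theta - axis_angle, nu)
    out.lambda_total = out.lambda_total * (1.0 + eps)
    ruptured = out.intact & (
        (out.lambda_total < params.lambda_min) | (out.lambda_total > params.lambda_max)
    )
    out.reservoir += float(np.sum(out.rho[ruptured] * out.width[ruptured]))
    out.rho[ruptured] = 0.0
    out.intact[ruptured] = False
    return out


def event_load_share(pre: CellModel, post: CellModel, params: SimParams) -> float:
    """Load-sharing factor fixed at the stretch event.

    The pool is the part of the cell loaded in tension by the stretch
    (sectors whose stretch increased, i.e. fiber strain > 0); the factor is
    the ratio of the tensile quantity those sectors still carry after rupture
    to what they carried immediately after stretch, clipped to [0, 1].  With
    ``share_mode="stress"`` the quantity is ``rho * width * (lambda - 1)``
    (tension actually borne, so losing the most-distended fibers releases the
    most matrix stress); with ``"density"`` it is ``rho * width``.  Rupture of
    these fibers releases stress in the surrounding matrix; newly polymerized
    fibers assemble at rest length and do not re-tension the matrix within
    the isometric hold, so the factor keeps its event value.  With no stretch
    the pool is empty and the factor is 0: no stress rise, no growth signal.
    """
    stretched = post.lambda_total > pre.lambda_total
    tension = np.maximum(post.lambda_total - 1.0, 0.0)
    if params.share_mode == "stress":
        weight = np.where(stretched, tension, 0.0)
    else:
        weight = (stretched & (tension > 0)).astype(float)
    before = float(np.sum(pre.rho * pre.width * weight))
    if before <= 0:
        return 0.0
    after = float(np.sum(post.rho * post.width * weight))
    return float(np.clip(after / before, 0.0, 1.0))


def adhesion_stress(cell: CellModel, params: SimParams,
                    load_share: float = 1.0) -> np.ndarray:
    """Per-sector adhesion-site stress ``k_fiber * rho * max(lambda-1, 0) * share``.

    Compressed fibers bear no adhesion tension; depolymerized sectors
    contribute zero.
    """
    s = (params.k_fiber * cell.rho
         * np.maximum(cell.lambda_total - 1.0, 0.0) * load_share)
    s[~cell.intact] = 0.0
    return s


def step(cell: CellModel, dt: float, params: SimParams,
         load_share: float = 1.0) -> CellModel:
    """One forward-Euler polymerization step.

    Intact sectors with adhesion stress in ``[s_low, s_high]`` grow toward
    ``rho_max`` at rate ``k_poly``, drawing monomer from the reservoir when
    the finite-pool option is on.  With ``rock_inhibited`` polymerization is
    disabled entirely (ROCK-inhibitor switch).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = cell.copy()
    if params.rock_inhibited:
        return out
    s = adhesion_stress(out, params, load_share=load_share)
    grow = out.intact & (s >= params.s_low) & (s <= params.s_high)
    d_rho = np.zeros_like(out.rho)
    d_rho[grow] = dt * params.k_poly * (params.rho_max - out.rho[grow])
    if params.reservoir_finite:
        demand = float(np.sum(d_rho * out.width))
        if demand > 0:
            avail = max(out.reservoir, 0.0)
            if demand > avail:
                d_rho *= avail / demand
            out.reservoir -= float(np.sum(d_rho * out.width))
    out.rho = np.minimum(out.rho + d_rho, params.rho_max)
    return out


def simulate(params: SimParams, shape: CellShape | str = CellShape.circular,
             eps_o: float = 0.05, nu: float = 1.0,
             cell: CellModel | None = None) -> SimOutput:
    """Run the full virtual stretch experiment for one cell.

    Initializes (unless ``cell`` is given, allowing chained stretch
    protocols), applies the stretch, then steps polymerization over
    ``duration``.  The model fibrosity is the width-weighted total density
    normalized to its pre-stretch value, so ``model_fibrosity[0] = 1``.
    """
    from .analysis import classify_trace  # analysis does not import back

    if cell is None:
        cell = init_cell(shape, params)
    pre = cell
    pre_stretch_density = pre.total_weighted_density
    if pre_stretch_density <= 0:
        raise ValueError("cell has no fibers before stretch")

    cell = apply_stretch(pre, eps_o, nu, params)
    share = event_load_share(pre, cell, params)

    n_steps = int(round(params.duration / params.dt))
    times = np.empty(n_steps + 1)
    dens = np.empty((n_steps + 1, params.n_sectors))
    fib = np.empty(n_steps + 1)
    # index 0 is the pre-stretch reference (fibrosity normalized to 1 there);
    # the stretch event happens between indices 0 and 1
    times[0], fib[0] = 0.0, 1.0
    dens[0] = pre.rho
    cur = cell
    for k in range(1, n_steps + 1):
        cur = step(cur, params.dt, params, load_share=share)
        times[k] = k * params.dt
        dens[k] = cur.rho
        fib[k] = cur.total_weighted_density / pre_stretch_density
    return SimOutput(
        times=times,
        model_fibrosity=fib,
        per_sector_density=dens,
        depolymerized_mask=~cur.intact,
        theta=cell.theta,
        response_class=classify_trace(fib),
        load_share=share,
        params=params,
    )


def sweep(sigma_values, n_reps: int, base_params: SimParams, eps_o: float = 0.05,
          shape: CellShape | str = CellShape.circular, nu: float = 1.0):
    """Class-frequency table over a grid of pre-stretch standard deviations.

    Returns ``(freq, rupture_angles)``: ``freq`` maps each sigma to a dict of
    response-class counts over ``n_reps`` seeded replicates;
    ``rupture_angles`` maps each sigma to the pooled orientations (radians) of
    depolymerized sectors together with the pooled surviving-sector final
    densities, for orientation histograms.  The orientation-dependence of
    rupture weakens as sigma grows.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    freq: dict[float, dict[str, int]] = {}
    angles: dict[float, np.ndarray] = {}
    outputs: dict[float, list[SimOutput]] = {}
    for sigma in sigma_values:
        counts: dict[str, int] = {}
        depol = []
        runs = []
        for rep in range(n_reps):
            p = replace(base_params, sigma_pre=float(sigma),
                        seed=int(base_params.seed + 1000 * rep + 1))
            out = simulate(p, shape=shape, eps_o=eps_o, nu=nu)
            counts[out.response_class] = counts.get(out.response_class, 0) + 1
            depol.append(out.theta[out.depolymerized_mask])
            runs.append(out)
        freq[float(sigma)] = counts
        angles[float(sigma)] = (np.concatenate(depol) if depol
                                else np.array([]))
        outputs[float(sigma)] = runs
    return freq, angles, outputs
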