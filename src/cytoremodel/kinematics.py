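"""Strain-field kinematics for uniaxially stretched engineered tissue constructs.

A ring-shaped engineered tissue construct (ETC) mounted on loading bars is far
more compliant radially than circumferentially, so a nominal grip-to-grip
stretch is only partially transmitted to cells in the planar flanks.  This
module provides

* the nominal-to-local strain calibration (piecewise linear through measured
  knots),
* the orientation-resolved strain felt by a stress fiber at angle ``theta`` to
  the stretch axis under an effective Poisson ratio ``nu``,
* least-squares affine estimation of the local deformation gradient from
  tracked fluorescent-bead displacements, and the effective Poisson ratio and
  first-order area change derived from it.

Strains are dimensionless engineering (small) strains throughout; angles are
radians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StrainCalibration",
    "StrainState",
    "BeadField",
    "DEFAULT_CALIBRATION",
    "local_strain",
    "fiber_strain",
    "estimate_affine",
    "poisson_ratio",
    "area_change",
]


class CalibrationRangeError(ValueError):
    """Nominal strain outside the calibrated range (no extrapolation rule)."""


class DegenerateBeadsError(ValueError):
    """Bead configuration too degenerate for an affine fit."""


@dataclass(frozen=True)
class StrainCalibration:
    """Piecewise-linear map from nominal ETC strain to local (cell-scale) strain.

    Parameters
    ----------
    pairs
        ``(nominal, local)`` knots as dimensionless fractions.  Nominal values
        must be strictly increasing, ``(0, 0)`` must be present, and the local
        strain may not exceed the nominal strain at any knot (the construct
        attenuates, never amplifies, the applied stretch).
    """

    pairs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pairs = tuple(sorted((float(n), float(l)) for n, l in self.pairs))
        object.__setattr__(self, "pairs", pairs)
        noms = np.array([p[0] for p in pairs])
        locs = np.array([p[1] for p in pairs])
        if len(pairs) < 2:
            raise ValueError("calibration needs at least two knots")
        if not np.all(np.diff(noms) > 0):
            raise ValueError("nominal strains must be strictly increasing")
        if (0.0, 0.0) not in pairs:
            raise ValueError("calibration must include the (0, 0) knot")
        if np.any(locs > noms + 1e-12):
            raise ValueError("local strain cannot exceed nominal strain")

    @property
    def nominal(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs])

    @property
    def local(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs])


#: Measured calibration: 10% and 30% nominal ETC stretches produce ~5% and
#: ~10% local stretches in the planar flanks.
DEFAULT_CALIBRATION = StrainCalibration(((0.0, 0.0), (0.10, 0.05), (0.30, 0.10)))


@dataclass(frozen=True)
class StrainState:
    """Local strain state at a cell: axial strain, Poisson ratio, stretch axis."""

    eps_o: float
    nu: float = 1.0
    axis_angle: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.nu <= 1.0):
            warnings.warn(
                f"effective Poisson ratio {self.nu} outside [0, 1] "
                "(thermodynamic bounds for transverse isotropy)",
                stacklevel=2,
            )


@dataclass
class BeadField:
    """Index-matched bead coordinates (µm) before and after stretch."""

    positions_before: np.ndarray
    positions_after: np.ndarray

    def __post_init__(self) -> None:
        self.positions_before = np.asarray(self.positions_before, dtype=float)
        self.positions_after = np.asarray(self.positions_after, dtype=float)
        if self.positions_before.shape != self.positions_after.shape:
            raise ValueError("before/after bead arrays must be index-matched")
        if self.positions_before.ndim != 2 or self.positions_before.shape[1] != 2:
            raise ValueError("bead positions must be (n, 2) arrays")

    def __len__(self) -> int:
        return self.positions_before.shape[0]


def local_strain(nominal: float, cal: StrainCalibration = DEFAULT_CALIBRATION) -> float:
    """Map a nominal ETC strain to the local strain near cells.

    Piecewise-linear interpolation through the calibration knots; exact at
    knots.  Raises :class:`CalibrationRangeError` outside the calibrated
    range, since no extrapolation rule is defensible from two measured points.
    """
    nominal = float(nominal)
    if nominal < 0 or nominal > cal.nominal[-1]:
        raise CalibrationRangeError(
            f"nominal strain {nominal} outside calibrated range "
            f"[0, {cal.nominal[-1]}]"
        )
    return float(np.interp(nominal, cal.nominal, cal.local))


def fiber_strain(eps_o: float, theta, nu: float = 1.0):
    """Strain along a fiber at angle ``theta`` (radians) to the stretch axis.

    Uniaxial strain transformation ``eps_o * (cos^2(theta) - nu sin^2(theta))``.
    At ``nu = 1`` this reduces to ``eps_o * cos(2 theta)``: tension along the
    axis, compression of equal magnitude transverse to it, and zero strain at
    45 degrees — the geometric origin of direction-dependent fiber rupture and
    buckling in these constructs.
    """
    theta = np.asarray(theta, dtype=float)
    out = eps_o * (np.cos(theta) ** 2 - nu * np.sin(theta) ** 2)
    return float(out) if out.ndim == 0 else out


def estimate_affine(beads: BeadField) -> tuple[np.ndarray, float, float]:
    """Least-squares affine fit ``after = F @ before + t`` from bead tracks.

    Returns ``(F, axial_strain, transverse_strain)`` where strains are the
    small-strain diagonal extraction ``diag(F) - 1``.  Requires at least three
    non-collinear beads; a rank-deficient design raises
    :class:`DegenerateBeadsError`.
    """
    n = len(beads)
    if n < 3:
        raise DegenerateBeadsError("affine fit needs >= 3 beads")
    X = np.hstack([beads.positions_before, np.ones((n, 1))])
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateBeadsError("beads are collinear; affine fit is singular")
    coef, *_ = np.linalg.lstsq(X, beads.positions_after, rcond=None)
    F = coef[:2, :].T
    return F, float(F[0, 0] - 1.0), float(F[1, 1] - 1.0)


def poisson_ratio(axial: float, transverse: float) -> float:
    """Effective Poisson ratio ``-transverse/axial``. Undefined at zero axial strain."""
    if axial == 0:
        raise ZeroDivisionError("Poisson ratio undefined for zero axial strain")
    return -transverse / axial


def area_change(eps_o: float, nu: float = 1.0) -> float:
    """Fractional passive area change ``(1 + eps)(1 - nu*eps) - 1``.

    At ``nu = 1`` the first-order terms cancel and the change is ``-eps**2``:
    passive area changes are negligible for constructs with Poisson ratio 1,
    so fibrosity changes reflect remodeling rather than geometry.
    """
    return (1.0 + eps_o) * (1.0 - nu * eps_o) - 1.0
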