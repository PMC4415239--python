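"""Thick-walled-cylinder mechanics of the silicone vessel phantom.

The vessel is modelled as an incompressible thick-walled elastic tube under
internal pressure ``q1`` and external pressure ``q2``.  Circumferential (hoop)
stress follows the classical Lamé solution; the loaded geometry is obtained
from an empirical quartic pressure--diameter fit combined with wall-volume
conservation under a fixed longitudinal stretch.

Sign convention: positive hoop stress is circumferential tension.  Stresses
come out in the same unit as the input pressures (mmHg throughout this
package); :func:`mmhg_to_kpa` converts if SI output is wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Union

import numpy as np

__all__ = [
    "TubeGeometry",
    "PressureDiameterFit",
    "PressurePair",
    "LoadedState",
    "CollapsedWallError",
    "DEFAULT_GEOMETRY",
    "DEFAULT_FIT",
    "external_diameter",
    "internal_radius",
    "hoop_stress_general",
    "hoop_stress_inner",
    "loaded_state",
    "mmhg_to_kpa",
]

ArrayLike = Union[float, np.ndarray]

#: kPa per mmHg
MMHG_TO_KPA = 0.133322


class CollapsedWallError(ValueError):
    """Loaded external radius too small for the wall volume: r0^2 <= k.

    Signals a physically impossible (fully collapsed) wall state where the
    incompressibility relation has no real internal radius.
    """


@dataclass(frozen=True)
class TubeGeometry:
    """Unloaded tube geometry and longitudinal stretch.

    Parameters
    ----------
    R0_mm : float
        Unloaded external radius (mm).
    Ri_mm : float
        Unloaded internal radius (mm).
    lambda_z : float
        Longitudinal stretch ratio of the mounted tube (dimensionless).
    """

    R0_mm: float
    Ri_mm: float
    lambda_z: float

    def __post_init__(self) -> None:
        if not (self.R0_mm > self.Ri_mm > 0):
            raise ValueError(
                f"require R0_mm > Ri_mm > 0, got R0_mm={self.R0_mm}, Ri_mm={self.Ri_mm}"
            )
        if not self.lambda_z > 0:
            raise ValueError(f"lambda_z must be positive, got {self.lambda_z}")

    @property
    def k_mm2(self) -> float:
        """Incompressibility constant (R0^2 - Ri^2)/lambda_z in mm^2.

        For every loaded state, r0^2 - ri^2 equals this constant.
        """
        return (self.R0_mm**2 - self.Ri_mm**2) / self.lambda_z


@dataclass(frozen=True)
class PressureDiameterFit:
    """Quartic pressure--diameter compliance fit of the mounted tube.

    Loaded external diameter as a function of transmural pressure
    ``p = q1 - q2``::

        d0(p) = a + b*p + c*p^2 - d*p^3 + e*p^4

    Note the *subtracted* cubic term: ``d`` is stored positive and enters
    with a minus sign, matching the convention in which the coefficients
    were reported.

    The fit is empirical; ``validity_range`` declares the transmural
    pressure interval over which it is trusted.  Evaluation outside the
    range warns but does not fail (quartics extrapolate poorly).
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    pressure_unit: str = "mmHg"
    validity_range: tuple[float, float] = (-20.0, 160.0)

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"unloaded diameter a must be positive, got {self.a}")
        lo, hi = self.validity_range
        if not lo < hi:
            raise ValueError(f"invalid validity_range {self.validity_range}")


class PressurePair(NamedTuple):
    """Internal (q1) and external (q2) wall pressures, scalar or array."""

    q1: ArrayLike
    q2: ArrayLike


@dataclass(frozen=True)
class LoadedState:
    """Loaded radii of the tube under one transmural pressure."""

    r0_mm: float
    ri_mm: float

    def __post_init__(self) -> None:
        if not (self.r0_mm > self.ri_mm > 0):
            raise ValueError(
                f"require r0_mm > ri_mm > 0, got r0_mm={self.r0_mm}, ri_mm={self.ri_mm}"
            )


#: Geometry of the silicone phantom: 2.465/2.165 mm unloaded radii, 1.2 axial stretch.
DEFAULT_GEOMETRY = TubeGeometry(R0_mm=2.465, Ri_mm=2.165, lambda_z=1.2)

#: Fitted compliance coefficients of the phantom (p in mmHg, d0 in mm).
DEFAULT_FIT = PressureDiameterFit(
    a=4.91, b=3.17e-3, c=1.18e-5, d=4.81e-7, e=2.39e-9
)


def mmhg_to_kpa(value: ArrayLike) -> ArrayLike:
    """Convert a pressure or stress from mmHg to kPa (1 mmHg = 0.133322 kPa)."""
    return np.multiply(value, MMHG_TO_KPA)


def external_diameter(p: ArrayLike, fit: PressureDiameterFit = DEFAULT_FIT) -> ArrayLike:
    """Loaded external diameter d0 (mm) at transmural pressure ``p = q1 - q2``.

    Evaluates the quartic compliance fit.  ``p`` may be a scalar or array in
    the fit's pressure unit.  Values outside ``fit.validity_range`` raise a
    ``UserWarning`` (the empirical polynomial is extrapolating) but are still
    evaluated.
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("transmural pressure p must be finite")
    lo, hi = fit.validity_range
    if np.any((p < lo) | (p > hi)):
        warnings.warn(
            f"transmural pressure outside fit validity range [{lo}, {hi}] "
            f"{fit.pressure_unit}; the compliance quartic is extrapolating",
            UserWarning,
            stacklevel=2,
        )
    # Horner form of a + b p + c p^2 - d p^3 + e p^4
    d0 = fit.a + p * (fit.b + p * (fit.c + p * (-fit.d + p * fit.e)))
    return d0 if d0.ndim else float(d0)


def internal_radius(r0: ArrayLike, geometry: TubeGeometry = DEFAULT_GEOMETRY) -> ArrayLike:
    """Loaded internal radius ri (mm) from loaded external radius via incompressibility.

    ri = sqrt(r0^2 - k) with k = (R0^2 - Ri^2)/lambda_z.

    Raises
    ------
    CollapsedWallError
        If any ``r0**2 <= k``: the wall volume cannot fit inside ``r0``.
    """
    r0 = np.asarray(r0, dtype=float)
    k = geometry.k_mm2
    arg = r0**2 - k
    if np.any(arg <= 0):
        bad = float(np.min(r0))
        raise CollapsedWallError(
            f"r0^2 <= k_mm2 ({k:.6g} mm^2): wall fully collapsed at r0={bad:.6g} mm"
        )
    ri = np.sqrt(arg)
    return ri if ri.ndim else float(ri)


def hoop_stress_general(
    r: ArrayLike,
    r0: ArrayLike,
    ri: ArrayLike,
    pressures: PressurePair,
) -> ArrayLike:
    """Lamé hoop stress at radius ``r`` inside a thick-walled cylinder.

    sigma_theta = (r0^2/r^2 + 1)/(r0^2/ri^2 - 1) * q1
                - (1 + ri^2/r^2)/(1 - ri^2/r0^2) * q2

    Tension positive; output in the unit of the input pressures.

    Raises
    ------
    ValueError
        If ``r`` lies outside ``[ri, r0]`` or ``ri >= r0``.
    """
    r = np.asarray(r, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    ri = np.asarray(ri, dtype=float)
    if np.any(ri >= r0) or np.any(ri <= 0):
        raise ValueError("require 0 < ri < r0")
    if np.any(r < ri) or np.any(r > r0):
        raise ValueError("radius r must lie within the wall, ri <= r <= r0")
    q1, q2 = pressures
    term1 = (r0**2 / r**2 + 1.0) / (r0**2 / ri**2 - 1.0)
    term2 = (1.0 + ri**2 / r**2) / (1.0 - ri**2 / r0**2)
    sigma = term1 * np.asarray(q1, dtype=float) - term2 * np.asarray(q2, dtype=float)
    return sigma if sigma.ndim else float(sigma)


def hoop_stress_inner(
    r0: ArrayLike,
    pressures: PressurePair,
    geometry: TubeGeometry = DEFAULT_GEOMETRY,
) -> ArrayLike:
    """Inner-wall hoop stress from the loaded external radius alone.

    Specializes the Lamé solution at r = ri and eliminates ri through the
    incompressibility constant k = (R0^2 - Ri^2)/lambda_z:

        sigma_theta = (2 r0^2 - k)/k * q1 - 2 r0^2 / k * q2

    Identical to :func:`hoop_stress_general` evaluated at the inner wall.

    Raises
    ------
    CollapsedWallError
        If any ``r0**2 <= k``.
    """
    r0 = np.asarray(r0, dtype=float)
    k = geometry.k_mm2
    if np.any(r0**2 <= k):
        raise CollapsedWallError(
            f"r0^2 <= k_mm2 ({k:.6g} mm^2): inner-wall stress undefined"
        )
    q1, q2 = pressures
    r0sq = r0**2
    sigma = (2.0 * r0sq - k) / k * np.asarray(q1, dtype=float) - (
        2.0 * r0sq / k
    ) * np.asarray(q2, dtype=float)
    return sigma if sigma.ndim else float(sigma)


def loaded_state(
    pressures: PressurePair,
    fit: PressureDiameterFit = DEFAULT_FIT,
    geometry: TubeGeometry = DEFAULT_GEOMETRY,
) -> LoadedState:
    """Loaded geometry under a pressure pair: compliance fit then incompressibility.

    r0 = d0(q1 - q2)/2, ri = sqrt(r0^2 - k).  Scalar pressures only; for time
    series use the vectorized pieces directly (see ``stress_pipeline``).
    """
    q1, q2 = pressures
    r0 = float(external_diameter(float(q1) - float(q2), fit)) / 2.0
    ri = float(internal_radius(r0, geometry))
    return LoadedState(r0_mm=r0, ri_mm=ri)
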