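"""Continuum clot model: eight-chain coupling of the fiber network curve.

A cylindrical clot under uniaxial extension is treated as an
incompressible eight-chain network: fibers run from the corners of a unit
cube to its center, so a principal stretch ``lambda1`` (with
``lambda2 = lambda3 = 1/sqrt(lambda1)``) strains every internal fiber by

    lambda_fiber = sqrt((lambda1^2 + 2/lambda1) / 3) >= 1,

with equality only in the undeformed state (AM-GM).  The clot force is

    F_clot = (lambda1 - 1/lambda1^2) * (pi D^2 v L / 24) * F_fiber(lambda_fiber) / lambda_fiber,

where D is the clot diameter, v the fiber number density and L the fiber
length; with D, L in um and v in um^-3 the prefactor pi*D^2*v*L/24 is a
dimensionless effective fiber count.  ``F_fiber`` is the force-controlled
network curve of the fiber model, inverted to stretch control by
shape-preserving monotone (PCHIP) interpolation.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

from .network import ForceExtensionCurve, fiber_curve
from .params import ClotParameters, FiberGeometry, FibrinParameterSet, SimulationControls

__all__ = [
    "eight_chain_fiber_stretch",
    "effective_fiber_count",
    "fiber_force_interpolator",
    "clot_force",
    "clot_curve",
]

PN_PER_MN = 1.0e9


def eight_chain_fiber_stretch(lambda1):
    """Internal fiber stretch of the incompressible eight-chain cube."""
    lam = np.asarray(lambda1, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("principal stretch must be > 0")
    return np.sqrt((lam**2 + 2.0 / lam) / 3.0)


def effective_fiber_count(cp: ClotParameters) -> float:
    """Dimensionless fiber count pi*D^2*v*L/24 (D, L in um, v in um^-3)."""
    d_um = cp.clot_diameter_mm * 1000.0
    return math.pi * d_um**2 * cp.fiber_density_per_um3 * cp.fiber_length_um / 24.0


def fiber_force_interpolator(fiber: ForceExtensionCurve) -> PchipInterpolator:
    """Monotone stretch -> fiber force (pN) interpolant of a fiber curve.

    PCHIP is shape-preserving: it passes through every sample and cannot
    overshoot, so the inverted force-controlled curve stays monotone.
    Evaluation beyond the sampled stretch range returns NaN (fiber break).
    """
    if fiber.scale != "fiber":
        raise ValueError(f"need a fiber-scale curve, got {fiber.scale!r}")
    x = np.asarray(fiber.x, dtype=float)
    f = np.asarray(fiber.force, dtype=float)
    keep = np.concatenate(([True], np.diff(x) > 0))
    return PchipInterpolator(x[keep], f[keep], extrapolate=False)


def clot_force(lambda1, cp: ClotParameters, fiber: ForceExtensionCurve):
    """Clot tensile force (pN) at principal stretch lambda1.

    Returns NaN where the required fiber stretch lies beyond the fiber
    curve's last (break) sample; :func:`clot_curve` truncates there.
    """
    lam = np.asarray(lambda1, dtype=float)
    lam_f = eight_chain_fiber_stretch(lam)
    interp = fiber_force_interpolator(fiber)
    f_fiber = interp(lam_f)
    return (lam - 1.0 / lam**2) * effective_fiber_count(cp) * f_fiber / lam_f


def clot_curve(
    p: FibrinParameterSet,
    g: FiberGeometry,
    cp: ClotParameters,
    c: Optional[SimulationControls] = None,
    lambda_max: float = 2.5,
    n_points: int = 200,
    fiber: Optional[ForceExtensionCurve] = None,
) -> ForceExtensionCurve:
    """Clot force-stretch curve on a uniform lambda1 grid in [1, lambda_max].

    Output forces are reported in mN (clot-scale forces are macroscopic);
    all internal arithmetic stays in pN/nm.  A precomputed fiber curve may
    be passed to avoid re-solving the network.
    """
    if lambda_max <= 1:
        raise ValueError("lambda_max must be > 1")
    if fiber is None:
        fiber = fiber_curve(p, g, c)

    lam1 = np.linspace(1.0, lambda_max, n_points)
    lam_f = eight_chain_fiber_stretch(lam1)
    force_pn = np.asarray(clot_force(lam1, cp, fiber), dtype=float)
    force_pn[0] = 0.0  # prefactor vanishes identically at lambda1 = 1

    bad = np.nonzero(~np.isfinite(force_pn))[0]
    break_index = int(bad[0]) if bad.size else None
    stop = break_index if break_index is not None else n_points

    return ForceExtensionCurve(
        scale="clot",
        x=lam1[:stop],
        force=force_pn[:stop] / PN_PER_MN,
        x_label="lambda1",
        force_label="clot_force_mN",
        extra={"lambda_fiber": lam_f[:stop]},
        metadata={
            "effective_fiber_count": effective_fiber_count(cp),
            "clot": cp.as_dict(),
            "fiber_metadata": dict(fiber.metadata),
            "force_unit_conversion": "1 mN = 1e9 pN",
            "break_lambda1": float(lam1[break_index]) if break_index is not None else None,
        },
        break_index=break_index,
    )
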