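"""Scalar force-extension laws of the fibrin spring network.

Four laws appear in the model:

* the fibrinogen monomer: linear + Heaviside-gated cubic,
  ``F(x) = k1*x + k2*H[x - d2]*(x - d2)^3``;
* the knob-hole (D-E, A-a) bond: saturating error function,
  ``F(x) = k3*erf(x/d3)``;
* the gamma-gamma (D-D) crosslink: ``F(x) = k4*erf(x/d4)``;
* the lumped inter-protofibril binding force: same shape as the monomer
  law with ``(k5, k6, d5)`` acting on the elongation of a whole element.

Compression convention: the laws are applied as written -- the cubic term
is active only beyond its onset, while the linear term provides a
symmetric restoring force for x < 0; the erf laws are odd exactly.  The
simulations are tension-driven, so the compressive branch only stabilises
the solver.  The Heaviside step takes H(0) = 1 (immaterial, since the
cubic factor vanishes at the onset).

Each law has an antiderivative (``spring_energy``) with energy(0) = 0 and
a tangent stiffness (``spring_stiffness``); equilibrium of the network is
the stationary point of the summed energies, which the tests use as an
independent oracle.  All functions are numpy-vectorised in ``x``.
"""

from __future__ import annotations

import enum
import math

import numpy as np
from scipy import special

from .params import FibrinParameterSet

__all__ = [
    "SpringKind",
    "fibrinogen_force",
    "knob_hole_force",
    "gamma_gamma_force",
    "binding_force",
    "spring_force",
    "spring_energy",
    "spring_stiffness",
    "TIE_STIFFNESS",
]

#: Nominal stiffness reported for rigid ties; ties are implemented as exact
#: displacement constraints, so this value only labels the kind.
TIE_STIFFNESS = math.inf


class SpringKind(enum.Enum):
    """Spring roles in the protofibril element."""

    MONOMER_HALF = "monomer_half"  # half of a fibrinogen molecule
    KNOB_HOLE = "knob_hole"  # D-E coupling
    GAMMA_GAMMA = "gamma_gamma"  # D-D crosslink
    BINDING = "binding"  # lumped inter-protofibril force
    RIGID_TIE = "rigid_tie"  # dummy-node attachment (exact constraint)


# -- primitive shapes -------------------------------------------------------


def _cubic_force(x, k_lin, k_cub, onset):
    x = np.asarray(x, dtype=float)
    dx = x - onset
    return k_lin * x + k_cub * np.where(dx >= 0.0, dx, 0.0) ** 3


def _cubic_energy(x, k_lin, k_cub, onset):
    x = np.asarray(x, dtype=float)
    dx = x - onset
    return 0.5 * k_lin * x**2 + 0.25 * k_cub * np.where(dx >= 0.0, dx, 0.0) ** 4


def _cubic_stiffness(x, k_lin, k_cub, onset):
    x = np.asarray(x, dtype=float)
    dx = x - onset
    return k_lin + 3.0 * k_cub * np.where(dx >= 0.0, dx, 0.0) ** 2


def _erf_force(x, k_sat, scale):
    x = np.asarray(x, dtype=float)
    return k_sat * special.erf(x / scale)


def _erf_energy(x, k_sat, scale):
    # antiderivative of k*erf(x/d):  k*[x*erf(x/d) + d/sqrt(pi)*(e^{-(x/d)^2} - 1)]
    x = np.asarray(x, dtype=float)
    t = x / scale
    return k_sat * (
        x * special.erf(t) + scale / math.sqrt(math.pi) * (np.exp(-(t**2)) - 1.0)
    )


def _erf_stiffness(x, k_sat, scale):
    x = np.asarray(x, dtype=float)
    t = x / scale
    return k_sat * 2.0 / (scale * math.sqrt(math.pi)) * np.exp(-(t**2))


# -- public force laws ------------------------------------------------------


def fibrinogen_force(x, p: FibrinParameterSet):
    """Monomer force (pN) at end-to-end extension x (nm)."""
    return _cubic_force(x, p.k1, p.k2, p.d2)


def knob_hole_force(x, p: FibrinParameterSet):
    """D-E knob-hole bond force (pN); odd, saturating at +-k3."""
    return _erf_force(x, p.k3, p.d3)


def gamma_gamma_force(x, p: FibrinParameterSet):
    """D-D crosslink force (pN); odd, saturating at +-k4."""
    return _erf_force(x, p.k4, p.d4)


def binding_force(x_elem, p: FibrinParameterSet):
    """Lumped binding force (pN) at element elongation x_elem (nm)."""
    return _cubic_force(x_elem, p.k5, p.k6, p.d5)


def _monomer_half_constants(p: FibrinParameterSet) -> tuple[float, float, float]:
    # Two identical halves in series must reproduce the full monomer law:
    # each half at extension x/2 must carry the full-molecule force at x.
    return 2.0 * p.k1, 8.0 * p.k2, p.d2 / 2.0


def spring_force(kind: SpringKind, x, p: FibrinParameterSet):
    """Force (pN) of a spring of the given kind at extension x (nm)."""
    if kind is SpringKind.MONOMER_HALF:
        return _cubic_force(x, *_monomer_half_constants(p))
    if kind is SpringKind.KNOB_HOLE:
        return _erf_force(x, p.k3, p.d3)
    if kind is SpringKind.GAMMA_GAMMA:
        return _erf_force(x, p.k4, p.d4)
    if kind is SpringKind.BINDING:
        return _cubic_force(x, p.k5, p.k6, p.d5)
    if kind is SpringKind.RIGID_TIE:
        # ties are exact constraints; their constraint force is resolved by
        # the network assembly, never through this law
        return np.zeros_like(np.asarray(x, dtype=float))
    raise ValueError(f"unknown spring kind: {kind!r}")


def spring_energy(kind: SpringKind, x, p: FibrinParameterSet):
    """Stored energy (pN.nm) with energy(0) = 0; d(energy)/dx = force."""
    if kind is SpringKind.MONOMER_HALF:
        return _cubic_energy(x, *_monomer_half_constants(p))
    if kind is SpringKind.KNOB_HOLE:
        return _erf_energy(x, p.k3, p.d3)
    if kind is SpringKind.GAMMA_GAMMA:
        return _erf_energy(x, p.k4, p.d4)
    if kind is SpringKind.BINDING:
        return _cubic_energy(x, p.k5, p.k6, p.d5)
    if kind is SpringKind.RIGID_TIE:
        return np.zeros_like(np.asarray(x, dtype=float))
    raise ValueError(f"unknown spring kind: {kind!r}")


def spring_stiffness(kind: SpringKind, x, p: FibrinParameterSet):
    """Tangent stiffness dF/dx (pN/nm); strictly positive for physical kinds."""
    if kind is SpringKind.MONOMER_HALF:
        return _cubic_stiffness(x, *_monomer_half_constants(p))
    if kind is SpringKind.KNOB_HOLE:
        return _erf_stiffness(x, p.k3, p.d3)
    if kind is SpringKind.GAMMA_GAMMA:
        return _erf_stiffness(x, p.k4, p.d4)
    if kind is SpringKind.BINDING:
        return _cubic_stiffness(x, p.k5, p.k6, p.d5)
    if kind is SpringKind.RIGID_TIE:
        return np.zeros_like(np.asarray(x, dtype=float))
    raise ValueError(f"unknown spring kind: {kind!r}")


def invert_fibrinogen_force(force: float, p: FibrinParameterSet) -> float:
    """Extension x (nm) at which the monomer law carries ``force`` (pN).

    Closed-form in the linear regime; bracketed root otherwise.  Used by
    the series-spring closed-form oracle.
    """
    if force < 0:
        raise ValueError("tension-only inversion")
    if p.k1 <= 0 and p.k2 <= 0:
        raise ValueError("degenerate monomer law")
    if p.k2 == 0 or force <= p.k1 * p.d2:
        return force / p.k1
    from scipy.optimize import brentq

    hi = p.d2 + (force / p.k2) ** (1.0 / 3.0) + force / p.k1
    return brentq(
        lambda x: fibrinogen_force(x, p) - force, p.d2, hi, xtol=1e-12, rtol=1e-14
    )
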