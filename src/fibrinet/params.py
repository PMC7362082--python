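"""Model parameters, fiber/clot geometry, and configuration handling.

Canonical internal units are nanometres (length) and piconewtons (force),
so stiffnesses are pN/nm (linear) and pN/nm^3 (cubic) and energies pN.nm.
Clot-scale inputs are specified in mm / um, the units in which they are
naturally measured, and converted where they enter the force relations.

The default parameter set is the calibrated monomer / protofibril set used
throughout: a fibrinogen monomer behaves as a linear spring (k1) with a
cubic stiffening term (k2) switching on at the molecule length d2; the
knob-hole (A-a) coupling between D- and E-regions saturates at k3 over an
extension scale d3; the gamma-gamma (D-D) crosslink saturates at k4 over
d4 (ten times weaker and twice as spread as the knob-hole bond); and the
lumped inter-protofibril binding force is a second linear+cubic spring
(k5, k6 = k5/500, onset d5 = one quarter of the element rest length).
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

__all__ = [
    "FibrinParameterSet",
    "FiberGeometry",
    "ClotParameters",
    "SimulationControls",
    "ConfigError",
    "ValidationError",
    "validate_parameters",
    "validate_geometry",
    "validate_clot",
    "validate_controls",
    "load_config",
    "save_config",
    "binding_onset",
]

#: coupling factor between the linear and cubic binding stiffness, k6 = k5 / 500
K6_COUPLING = 500.0


class ConfigError(ValueError):
    """Raised when a config file cannot be parsed or violates the schema."""


class ValidationError(ValueError):
    """Raised when a parameter set violates a physical bound."""


@dataclass
class FibrinParameterSet:
    """All spring and bond constants of the monomer/protofibril force laws."""

    k1: float = 1.5  # linear monomer stiffness, pN/nm
    k2: float = 3.0e-4  # cubic monomer stiffness, pN/nm^3
    d2: float = 46.0  # cubic-onset extension = fibrinogen length, nm
    k3: float = 130.0  # D-E (knob-hole) saturation force, pN
    d3: float = 10.0  # D-E extension scale, nm
    k4: float = 13.0  # D-D (gamma-gamma) saturation force, pN
    d4: float = 20.0  # D-D extension scale, nm
    k5: float = 0.1  # binding linear stiffness, pN/nm
    k6: float = 2.0e-4  # binding cubic stiffness, pN/nm^3
    d5: float = 11.5  # binding cubic-onset extension, nm

    def replace(self, **changes) -> "FibrinParameterSet":
        return dataclasses.replace(self, **changes)

    def without_binding(self) -> "FibrinParameterSet":
        """Copy with the inter-protofibril binding force switched off."""
        return self.replace(k5=0.0, k6=0.0)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class FiberGeometry:
    """Single-fiber geometry; all lengths in nm."""

    fiber_length: float = 12_000.0
    fiber_diameter: float = 330.0
    protein_fraction: float = 0.30
    monomer_radius: float = 2.25
    element_rest_length: float = 46.0

    @property
    def fiber_radius(self) -> float:
        return self.fiber_diameter / 2.0

    def replace(self, **changes) -> "FiberGeometry":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ClotParameters:
    """Macroscopic clot geometry (mm / um scale)."""

    clot_diameter_mm: float = 2.0
    fiber_density_per_um3: float = 0.5
    fiber_length_um: float = 12.0

    def replace(self, **changes) -> "ClotParameters":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulationControls:
    """Force-continuation and solver controls.

    ``random_seed`` is reserved for future stochastic fiber arrangements;
    the present model is fully deterministic.
    """

    force_max: float = 200.0  # maximum per-monomer force, pN
    n_steps: int = 500  # continuation samples from 0 to force_max
    solver_tolerance: float = 1.0e-8  # residual norm bound, pN
    break_extension_factor: Optional[float] = None  # optional stretch cap
    random_seed: int = 0

    def replace(self, **changes) -> "SimulationControls":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def binding_onset(element_rest_length: float) -> float:
    """Binding cubic-onset distance d5 = element rest length / 4 (nm)."""
    return element_rest_length / 4.0


# ---------------------------------------------------------------------------
# validation


def validate_parameters(p: FibrinParameterSet) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    v: list[str] = []
    for name in ("k1", "k2", "k3", "k4", "k5", "k6"):
        if getattr(p, name) < 0:
            v.append(f"{name} must be >= 0 (got {getattr(p, name)!r})")
    for name in ("d2", "d5"):
        if getattr(p, name) < 0:
            v.append(f"{name} must be >= 0 (got {getattr(p, name)!r})")
    for name in ("d3", "d4"):
        if getattr(p, name) <= 0:
            v.append(f"{name} must be > 0 (got {getattr(p, name)!r})")
    for name in dataclasses.asdict(p):
        val = getattr(p, name)
        if not math.isfinite(val):
            v.append(f"{name} must be finite (got {val!r})")
    return v


def validate_geometry(g: FiberGeometry) -> list[str]:
    v: list[str] = []
    for name in ("fiber_length", "fiber_diameter", "monomer_radius", "element_rest_length"):
        if getattr(g, name) <= 0:
            v.append(f"{name} must be > 0 (got {getattr(g, name)!r})")
    if not (0.0 < g.protein_fraction <= 1.0):
        v.append(f"protein_fraction must be in (0, 1] (got {g.protein_fraction!r})")
    if g.fiber_length < g.element_rest_length:
        v.append(
            "fiber_length must be >= element_rest_length "
            f"(got {g.fiber_length!r} < {g.element_rest_length!r})"
        )
    return v


def validate_clot(cp: ClotParameters) -> list[str]:
    v: list[str] = []
    for name in ("clot_diameter_mm", "fiber_density_per_um3", "fiber_length_um"):
        if getattr(cp, name) <= 0:
            v.append(f"{name} must be > 0 (got {getattr(cp, name)!r})")
    return v


def validate_controls(c: SimulationControls) -> list[str]:
    v: list[str] = []
    if c.n_steps < 2:
        v.append(f"n_steps must be >= 2 (got {c.n_steps!r})")
    if c.force_max <= 0:
        v.append(f"force_max must be > 0 (got {c.force_max!r})")
    if c.solver_tolerance <= 0:
        v.append(f"solver_tolerance must be > 0 (got {c.solver_tolerance!r})")
    if c.break_extension_factor is not None and c.break_extension_factor <= 1:
        v.append(
            f"break_extension_factor must be > 1 (got {c.break_extension_factor!r})"
        )
    return v


def _check_k6_coupling(p: FibrinParameterSet) -> None:
    expected = p.k5 / K6_COUPLING
    if abs(p.k6 - expected) > 1e-12 * max(1.0, abs(p.k6)):
        warnings.warn(
            f"k6 = {p.k6!r} breaks the coupling k6 = k5/{K6_COUPLING:g} "
            f"(expected {expected!r}); proceeding with the given value",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# config file round-tripping (TOML schema, sections
# [parameters] [fiber] [clot] [simulation])

_PARAM_KEYS = ("k1", "k2", "d2", "k3", "d3", "k4", "d4", "k5", "k6", "d5")

_FIBER_KEYS = {
    "length_nm": "fiber_length",
    "diameter_nm": "fiber_diameter",
    "protein_fraction": "protein_fraction",
    "monomer_radius_nm": "monomer_radius",
    "element_rest_length_nm": "element_rest_length",
}

_CLOT_KEYS = {
    "diameter_mm": "clot_diameter_mm",
    "fiber_density_per_um3": "fiber_density_per_um3",
    "fiber_length_um": "fiber_length_um",
}

_SIM_KEYS = {
    "force_max_pn": "force_max",
    "n_steps": "n_steps",
    "solver_tolerance_pn": "solver_tolerance",
    "break_extension_factor": "break_extension_factor",
    "random_seed": "random_seed",
}


def _take_section(raw: dict, section: str, keymap: dict, cls, warn_unknown: list[str]):
    data = raw.get(section, {})
    kwargs = {}
    for key, value in data.items():
        if key not in keymap:
            warn_unknown.append(f"[{section}] {key}")
            continue
        kwargs[keymap[key]] = value
    return kwargs


def load_config(
    path: Optional[str | Path],
) -> tuple[FibrinParameterSet, FiberGeometry, ClotParameters, SimulationControls]:
    """Load a config file; missing keys fall back to the defaults.

    ``path=None`` returns the full default set.  Unknown keys are reported
    as warnings; invariant violations raise :class:`ValidationError`.
    """
    raw: dict = {}
    if path is not None:
        path = Path(path)
        try:
            raw = tomllib.loads(path.read_text())
        except FileNotFoundError:
            raise ConfigError(f"config file not found: {path}")
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"malformed config {path}: {exc}") from exc

    unknown: list[str] = []
    for section in raw:
        if section not in ("parameters", "fiber", "clot", "simulation"):
            unknown.append(f"[{section}]")

    pdata = raw.get("parameters", {})
    pkwargs = {}
    for key, value in pdata.items():
        if key not in _PARAM_KEYS:
            unknown.append(f"[parameters] {key}")
            continue
        pkwargs[key] = value
    # k6 is defined through the coupling k6 = k5/500; an explicit k6 wins.
    if "k5" in pkwargs and "k6" not in pkwargs:
        pkwargs["k6"] = pkwargs["k5"] / K6_COUPLING
    params = FibrinParameterSet(**pkwargs)

    geometry = FiberGeometry(
        **_take_section(raw, "fiber", _FIBER_KEYS, FiberGeometry, unknown)
    )
    clot = ClotParameters(
        **_take_section(raw, "clot", _CLOT_KEYS, ClotParameters, unknown)
    )
    controls = SimulationControls(
        **_take_section(raw, "simulation", _SIM_KEYS, SimulationControls, unknown)
    )

    if unknown:
        warnings.warn(
            "ignoring unknown config keys: " + ", ".join(unknown), stacklevel=2
        )

    problems = (
        validate_parameters(params)
        + validate_geometry(geometry)
        + validate_clot(clot)
        + validate_controls(controls)
    )
    if problems:
        raise ValidationError("; ".join(problems))
    _check_k6_coupling(params)
    return params, geometry, clot, controls


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, int):
        return str(value)
    return repr(float(value))


def save_config(
    path: str | Path,
    params: FibrinParameterSet | None = None,
    geometry: FiberGeometry | None = None,
    clot: ClotParameters | None = None,
    controls: SimulationControls | None = None,
) -> Path:
    """Write a TOML config reproducing the given objects bit-exactly."""
    params = params or FibrinParameterSet()
    geometry = geometry or FiberGeometry()
    clot = clot or ClotParameters()
    controls = controls or SimulationControls()

    lines = ["[parameters]"]
    for key in _PARAM_KEYS:
        lines.append(f"{key} = {_fmt(getattr(params, key))}")
    lines.append("")
    lines.append("[fiber]")
    for key, fieldname in _FIBER_KEYS.items():
        lines.append(f"{key} = {_fmt(getattr(geometry, fieldname))}")
    lines.append("")
    lines.append("[clot]")
    for key, fieldname in _CLOT_KEYS.items():
        lines.append(f"{key} = {_fmt(getattr(clot, fieldname))}")
    lines.append("")
    lines.append("[simulation]")
    for key, fieldname in _SIM_KEYS.items():
        value = getattr(controls, fieldname)
        if value is None:
            continue  # optional key, omitted when unset
        lines.append(f"{key} = {_fmt(value)}")
    lines.append("")

    path = Path(path)
    path.write_text("\n".join(lines))
    return path
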