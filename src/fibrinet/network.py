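"""Protofibril spring-network element and the single-fiber force-stretch curve.

The repeating element of a double-stranded, half-staggered protofibril is a
one-dimensional spring network (all forces act along the fiber axis).  Per
element of rest length ``L_e`` (one monomer length, 46 nm):

* strand B contributes a whole monomer as two MONOMER_HALF springs,
  D(0) -- E(L_e/2) -- D(L_e);
* strand A is half-staggered: E-regions sit at the element boundaries and
  two coincident D-region nodes at the element center form the D-D
  junction, joined by one GAMMA_GAMMA spring; each boundary E contributes
  one MONOMER_HALF spring to the nearest central D node;
* KNOB_HOLE springs join every E-region to the opposite strand's D
  node(s) at the same rest coordinate: two at the element center (E_B to
  each central D_A), one at each element boundary (E_A to D_B);
* one BINDING spring spans the element end-to-end, in parallel with the
  rest of the network.

Consecutive elements share their boundary nodes.  The leftmost strand-end
nodes are fixed; the applied per-monomer force F enters through two dummy
nodes at the right end, rigidly tied to the strand ends and to each other
(a rigid loading yoke, as an AFM probe attachment), so each protofibril
carries 2F -- consistent with F_fiber = (monomers per cross-section) x F,
since a cross-section holds two monomers per protofibril.

Rigid ties are exact constraints: tied nodes share a single degree of
freedom.  Equilibrium at each load step is the root of the nodal force
balance (equivalently the minimiser of the total energy, which is strictly
convex), solved by trust-region dogleg continuation with warm starts.

Because every element is identical and the end yoke mirrors the periodic
interior, the full-chain solution is an exact replication of the
single-element solution; ``fiber_curve`` therefore solves one element by
default and the full chain on request.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from ._solver import dogleg_root
from .force_laws import SpringKind, spring_energy, spring_force, spring_stiffness
from .params import (
    FiberGeometry,
    FibrinParameterSet,
    SimulationControls,
    ValidationError,
    validate_geometry,
)

__all__ = [
    "NodeRole",
    "NetworkNode",
    "NetworkSpring",
    "NetworkTopology",
    "EquilibriumState",
    "ForceExtensionCurve",
    "derive_cross_section_count",
    "derive_element_count",
    "build_element_topology",
    "assemble_residual",
    "total_energy",
    "jacobian",
    "solve_equilibrium",
    "fiber_curve",
    "molecule_curve",
]

#: counts within 1e-9 of an integer are taken as that integer before ceiling
_CEIL_FUZZ = 1.0e-9

#: systems larger than this use sparse factorisation in the solver
_SPARSE_THRESHOLD = 64


class NodeRole(enum.Enum):
    D_REGION = "D"
    E_REGION = "E"
    DUMMY = "dummy"


@dataclass
class NetworkNode:
    node_id: int
    role: NodeRole
    strand: str  # "A" | "B"
    rest_position: float  # axial coordinate, nm
    fixed: bool = False


@dataclass
class NetworkSpring:
    spring_id: int
    kind: SpringKind
    endpoints: tuple[int, int]
    rest_separation: float  # signed, nm (coordinate of b minus coordinate of a)


@dataclass
class ForceExtensionCurve:
    """Ordered force-extension samples at one of the three model scales."""

    scale: str  # "molecule" | "fiber" | "clot"
    x: np.ndarray  # stretch (fiber/clot) or extension nm (molecule)
    force: np.ndarray
    x_label: str = "stretch"
    force_label: str = "force_pN"
    extra: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    break_index: Optional[int] = None

    @property
    def n_samples(self) -> int:
        return int(len(self.x))


@dataclass
class EquilibriumState:
    """Nodal equilibrium at one applied per-monomer force."""

    applied_force_per_monomer: float
    displacements: np.ndarray  # per node, nm; fixed nodes exactly 0
    residual_norm: float
    converged: bool
    dofs: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# derived counts


def _fuzzy_ceil(value: float) -> int:
    return int(math.ceil(value - _CEIL_FUZZ))


def derive_cross_section_count(g: FiberGeometry) -> int:
    """Monomers per fiber cross-section.

    The protein-occupied area fraction of the fiber cross-section divided
    by the monomer cross-section; the pi factors cancel, leaving
    ceil(protein_fraction * (D/2)^2 / r_monomer^2).
    """
    problems = validate_geometry(g)
    if problems:
        raise ValidationError("; ".join(problems))
    ratio = g.protein_fraction * g.fiber_radius**2 / g.monomer_radius**2
    return _fuzzy_ceil(ratio)


def derive_element_count(g: FiberGeometry) -> int:
    """Protofibril elements along the fiber: ceil(length / element rest length)."""
    problems = validate_geometry(g)
    if problems:
        raise ValidationError("; ".join(problems))
    return _fuzzy_ceil(g.fiber_length / g.element_rest_length)


# ---------------------------------------------------------------------------
# topology


class NetworkTopology:
    """Nodes and springs of an n-element protofibril chain, compiled for
    vectorised assembly.

    Rigid ties merge their endpoints into one degree of freedom; fixed
    nodes carry no degree of freedom.  ``dof_of_node[i] == -1`` marks a
    fixed node.
    """

    def __init__(
        self,
        nodes: Sequence[NetworkNode],
        springs: Sequence[NetworkSpring],
        n_elements: int,
        monomers_per_cross_section: Optional[int] = None,
        loaded_nodes: Sequence[int] = (),
        element_rest_length: float = 46.0,
    ):
        self.nodes = list(nodes)
        self.springs = list(springs)
        self.n_elements = int(n_elements)
        self.monomers_per_cross_section = monomers_per_cross_section
        self.loaded_nodes = tuple(loaded_nodes)
        self.element_rest_length = float(element_rest_length)
        self._compile()

    # -- structure ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def rest_span(self) -> float:
        return self.n_elements * self.element_rest_length

    def _compile(self) -> None:
        n = self.n_nodes
        ids = [nd.node_id for nd in self.nodes]
        if len(set(ids)) != n:
            raise ValueError("node ids must be unique")
        index_of = {nid: i for i, nid in enumerate(ids)}
        self._index_of = index_of

        # union-find over rigid ties
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for s in self.springs:
            if s.kind is SpringKind.RIGID_TIE:
                a, b = (index_of[e] for e in s.endpoints)
                parent[find(a)] = find(b)

        fixed_groups = {find(index_of[nd.node_id]) for nd in self.nodes if nd.fixed}
        dof_of_group: dict[int, int] = {}
        dof_of_node = np.empty(n, dtype=np.int64)
        next_dof = 0
        for i in range(n):
            g = find(i)
            if g in fixed_groups:
                dof_of_node[i] = -1
                continue
            if g not in dof_of_group:
                dof_of_group[g] = next_dof
                next_dof += 1
            dof_of_node[i] = dof_of_group[g]
        self.dof_of_node = dof_of_node
        self.n_dof = next_dof

        # elastic springs (ties excluded: exact constraints, no force law)
        elastic = [s for s in self.springs if s.kind is not SpringKind.RIGID_TIE]
        self._elastic_a = np.array(
            [index_of[s.endpoints[0]] for s in elastic], dtype=np.int64
        )
        self._elastic_b = np.array(
            [index_of[s.endpoints[1]] for s in elastic], dtype=np.int64
        )
        self._kind_groups: dict[SpringKind, np.ndarray] = {}
        kinds = [s.kind for s in elastic]
        for kind in SpringKind:
            idx = np.array([i for i, k in enumerate(kinds) if k is kind], dtype=np.int64)
            if idx.size:
                self._kind_groups[kind] = idx

        # external load pattern: per-monomer force F enters once per loaded node
        load_nodes = np.zeros(n)
        for nid in self.loaded_nodes:
            load_nodes[index_of[nid]] += 1.0
        self._load_per_node = load_nodes
        load_dof = np.zeros(self.n_dof)
        for i in range(n):
            d = dof_of_node[i]
            if d >= 0:
                load_dof[d] += load_nodes[i]
        self.load_per_dof = load_dof

        # scatter pattern for residual and Jacobian assembly
        da = dof_of_node[self._elastic_a]
        db = dof_of_node[self._elastic_b]
        self._dof_a = da
        self._dof_b = db
        self._mask_a = da >= 0
        self._mask_b = db >= 0

        rows, cols, sidx, sign = [], [], [], []
        for i in range(len(elastic)):
            a, b = da[i], db[i]
            if a >= 0:
                rows.append(a), cols.append(a), sidx.append(i), sign.append(-1.0)
            if b >= 0:
                rows.append(b), cols.append(b), sidx.append(i), sign.append(-1.0)
            if a >= 0 and b >= 0:
                rows.append(a), cols.append(b), sidx.append(i), sign.append(1.0)
                rows.append(b), cols.append(a), sidx.append(i), sign.append(1.0)
        self._jac_rows = np.array(rows, dtype=np.int64)
        self._jac_cols = np.array(cols, dtype=np.int64)
        self._jac_sidx = np.array(sidx, dtype=np.int64)
        self._jac_sign = np.array(sign)

        if self.n_dof and not np.any(dof_of_node < 0):
            raise ValueError("network needs at least one fixed node")

    # -- state conversion ----------------------------------------------------

    def expand_dofs(self, dofs: np.ndarray) -> np.ndarray:
        """Per-dof vector -> per-node displacements (fixed nodes at 0)."""
        dofs = np.asarray(dofs, dtype=float)
        if dofs.shape != (self.n_dof,):
            raise ValueError(f"expected {self.n_dof} dofs, got shape {dofs.shape}")
        u = np.zeros(self.n_nodes)
        mask = self.dof_of_node >= 0
        u[mask] = dofs[self.dof_of_node[mask]]
        return u

    def reduce_nodes(self, u: np.ndarray) -> np.ndarray:
        """Per-node displacements -> per-dof vector (first node of each group)."""
        u = np.asarray(u, dtype=float)
        if u.shape != (self.n_nodes,):
            raise ValueError(f"expected {self.n_nodes} node values, got {u.shape}")
        dofs = np.zeros(self.n_dof)
        seen = np.zeros(self.n_dof, dtype=bool)
        for i in range(self.n_nodes):
            d = self.dof_of_node[i]
            if d >= 0 and not seen[d]:
                dofs[d] = u[i]
                seen[d] = True
        return dofs

    def spring_extensions(self, u: np.ndarray) -> np.ndarray:
        """Extension of each elastic spring: change of endpoint separation."""
        return u[self._elastic_b] - u[self._elastic_a]

    def end_displacement(self, u: np.ndarray) -> float:
        """Axial displacement of the loaded end (the rigid yoke)."""
        i = self._index_of[self.loaded_nodes[0]]
        return float(u[i])


def build_element_topology(g: FiberGeometry, n_elements: int) -> NetworkTopology:
    """Construct the n-element protofibril chain with shared boundary nodes."""
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    L = g.element_rest_length
    half = L / 2.0

    nodes: list[NetworkNode] = []
    springs: list[NetworkSpring] = []
    nid = iter(range(10**9))
    sid = iter(range(10**9))

    def add_node(role, strand, pos, fixed=False) -> int:
        i = next(nid)
        nodes.append(NetworkNode(i, role, strand, pos, fixed))
        return i

    def add_spring(kind, a, b, rest) -> int:
        i = next(sid)
        springs.append(NetworkSpring(i, kind, (a, b), rest))
        return i

    # boundary nodes j = 0..n  (E on strand A, D on strand B), fixed at j=0
    e_a = []
    d_b = []
    centers = []  # (d_a_left, e_b, d_a_right) per element
    for j in range(n_elements + 1):
        pos = j * L
        fixed = j == 0
        e_a.append(add_node(NodeRole.E_REGION, "A", pos, fixed))
        d_b.append(add_node(NodeRole.D_REGION, "B", pos, fixed))
        if j < n_elements:
            c = pos + half
            centers.append(
                (
                    add_node(NodeRole.D_REGION, "A", c),
                    add_node(NodeRole.E_REGION, "B", c),
                    add_node(NodeRole.D_REGION, "A", c),
                )
            )

    for i in range(n_elements):
        da_l, eb, da_r = centers[i]
        # strand B monomer: two halves
        add_spring(SpringKind.MONOMER_HALF, d_b[i], eb, half)
        add_spring(SpringKind.MONOMER_HALF, eb, d_b[i + 1], half)
        # strand A half-staggered monomer halves
        add_spring(SpringKind.MONOMER_HALF, e_a[i], da_l, half)
        add_spring(SpringKind.MONOMER_HALF, da_r, e_a[i + 1], half)
        # center knob-hole pair (E_B against both central D_A nodes)
        add_spring(SpringKind.KNOB_HOLE, da_l, eb, 0.0)
        add_spring(SpringKind.KNOB_HOLE, eb, da_r, 0.0)
        # gamma-gamma junction across the coincident D_A pair
        add_spring(SpringKind.GAMMA_GAMMA, da_l, da_r, 0.0)
        # binding force spanning the element end-to-end
        add_spring(SpringKind.BINDING, d_b[i], d_b[i + 1], L)

    # boundary knob-holes, one per junction
    for j in range(n_elements + 1):
        add_spring(SpringKind.KNOB_HOLE, e_a[j], d_b[j], 0.0)

    # loading yoke: dummy nodes rigidly tied to the strand ends and each other
    end = n_elements * L
    dum_b = add_node(NodeRole.DUMMY, "B", end)
    dum_a = add_node(NodeRole.DUMMY, "A", end)
    add_spring(SpringKind.RIGID_TIE, d_b[n_elements], dum_b, 0.0)
    add_spring(SpringKind.RIGID_TIE, e_a[n_elements], dum_a, 0.0)
    add_spring(SpringKind.RIGID_TIE, dum_b, dum_a, 0.0)

    return NetworkTopology(
        nodes,
        springs,
        n_elements=n_elements,
        loaded_nodes=(dum_b, dum_a),
        element_rest_length=L,
    )


# ---------------------------------------------------------------------------
# assembly


def _spring_forces(t: NetworkTopology, ext: np.ndarray, p: FibrinParameterSet):
    f = np.zeros_like(ext)
    for kind, idx in t._kind_groups.items():
        f[idx] = spring_force(kind, ext[idx], p)
    return f


def _spring_stiffnesses(t: NetworkTopology, ext: np.ndarray, p: FibrinParameterSet):
    s = np.zeros_like(ext)
    for kind, idx in t._kind_groups.items():
        s[idx] = spring_stiffness(kind, ext[idx], p)
    return s


def assemble_residual(
    t: NetworkTopology, u: np.ndarray, F: float, p: FibrinParameterSet
) -> np.ndarray:
    """Net axial force (pN) on each degree of freedom.

    Equals minus the gradient of :func:`total_energy` with respect to the
    free displacements; zero at equilibrium.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (t.n_nodes,):
        raise ValueError(f"expected {t.n_nodes} node displacements, got {u.shape}")
    ext = t.spring_extensions(u)
    f = _spring_forces(t, ext, p)
    r = np.zeros(t.n_dof)
    np.add.at(r, t._dof_a[t._mask_a], f[t._mask_a])
    np.add.at(r, t._dof_b[t._mask_b], -f[t._mask_b])
    r += F * t.load_per_dof
    return r


def total_energy(
    t: NetworkTopology, u: np.ndarray, F: float, p: FibrinParameterSet
) -> float:
    """Total potential energy (pN.nm): stored spring energy minus load work."""
    u = np.asarray(u, dtype=float)
    if u.shape != (t.n_nodes,):
        raise ValueError(f"expected {t.n_nodes} node displacements, got {u.shape}")
    ext = t.spring_extensions(u)
    e = 0.0
    for kind, idx in t._kind_groups.items():
        e += float(np.sum(spring_energy(kind, ext[idx], p)))
    e -= F * float(np.dot(t._load_per_node, u))
    return e


def jacobian(t: NetworkTopology, u: np.ndarray, p: FibrinParameterSet, sparse=None):
    """d(residual)/d(dofs); the negative tangent stiffness matrix."""
    if sparse is None:
        sparse = t.n_dof > _SPARSE_THRESHOLD
    ext = t.spring_extensions(np.asarray(u, dtype=float))
    s = _spring_stiffnesses(t, ext, p)
    vals = t._jac_sign * s[t._jac_sidx]
    if sparse:
        return sp.coo_matrix(
            (vals, (t._jac_rows, t._jac_cols)), shape=(t.n_dof, t.n_dof)
        ).tocsc()
    J = np.zeros((t.n_dof, t.n_dof))
    np.add.at(J, (t._jac_rows, t._jac_cols), vals)
    return J


# ---------------------------------------------------------------------------
# equilibrium and continuation


def solve_equilibrium(
    t: NetworkTopology,
    F: float,
    p: FibrinParameterSet,
    init: Optional[np.ndarray] = None,
    controls: Optional[SimulationControls] = None,
) -> EquilibriumState:
    """Equilibrate the network at per-monomer force F (pN).

    ``init`` is a per-dof warm start (typically the previous continuation
    step).  Non-convergence is reported via ``converged=False`` -- never
    raised -- and is interpreted downstream as fiber break.
    """
    controls = controls or SimulationControls()
    if init is None:
        dofs0 = np.zeros(t.n_dof)
    else:
        init = np.asarray(init, dtype=float)
        if init.shape == (t.n_dof,):
            dofs0 = init.copy()
        elif init.shape == (t.n_nodes,):
            dofs0 = t.reduce_nodes(init)
        else:
            raise ValueError(
                f"init must have {t.n_dof} dofs or {t.n_nodes} node values"
            )

    sparse = t.n_dof > _SPARSE_THRESHOLD

    def fun(x):
        return assemble_residual(t, t.expand_dofs(x), F, p)

    def jac(x):
        return jacobian(t, t.expand_dofs(x), p, sparse=sparse)

    res = dogleg_root(fun, jac, dofs0, tol=controls.solver_tolerance)
    return EquilibriumState(
        applied_force_per_monomer=float(F),
        displacements=t.expand_dofs(res.x),
        residual_norm=res.residual_norm,
        converged=res.converged,
        dofs=res.x,
    )


def _parameter_hash(p: FibrinParameterSet) -> str:
    payload = json.dumps(p.as_dict(), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def fiber_curve(
    p: FibrinParameterSet,
    g: FiberGeometry,
    c: Optional[SimulationControls] = None,
    full_chain: bool = False,
) -> ForceExtensionCurve:
    """Single-fiber force-stretch curve under quasi-static force continuation.

    Per continuation step the per-monomer force is raised on an even grid
    from 0 to ``force_max``; each solve is warm-started from the previous
    step, with a 10x finer sub-stepped retry before a step is declared
    non-converged (mechanical failure, recorded as the break index).

    By default one element is solved and replicated -- exact for this
    topology, since all elements are identical and the loading yoke
    reproduces the periodic interior conditions; ``full_chain=True`` solves
    every element explicitly.
    """
    c = c or SimulationControls()
    m = derive_cross_section_count(g)
    n_el = derive_element_count(g)
    topo = build_element_topology(g, n_el if full_chain else 1)
    span = topo.rest_span

    forces = np.linspace(0.0, c.force_max, c.n_steps)
    stretches = np.empty_like(forces)
    converged = np.ones_like(forces, dtype=bool)
    break_index: Optional[int] = None

    dofs = np.zeros(topo.n_dof)
    last_F = 0.0
    for j, F in enumerate(forces):
        state = solve_equilibrium(topo, F, p, init=dofs, controls=c)
        if not state.converged:
            # retry from the last good state with 10x smaller sub-steps
            sub = np.linspace(last_F, F, 11)[1:]
            trial = dofs.copy()
            ok = True
            for Fs in sub:
                st = solve_equilibrium(topo, Fs, p, init=trial, controls=c)
                if not st.converged:
                    ok = False
                    break
                trial = st.dofs
            if ok:
                state = solve_equilibrium(topo, F, p, init=trial, controls=c)
            if not state.converged:
                break_index = j
                converged[j:] = False
                break
        dofs = state.dofs
        last_F = F
        lam = (span + topo.end_displacement(state.displacements)) / span
        stretches[j] = lam
        if (
            c.break_extension_factor is not None
            and lam > c.break_extension_factor
            and j > 0
        ):
            break_index = j + 1
            break

    stop = break_index if break_index is not None else c.n_steps
    metadata = {
        "monomers_per_cross_section": m,
        "n_elements": n_el,
        "n_elements_solved": topo.n_elements,
        "full_chain": bool(full_chain),
        "parameter_hash": _parameter_hash(p),
        "geometry": g.as_dict(),
        "break_step": break_index,
    }
    return ForceExtensionCurve(
        scale="fiber",
        x=stretches[:stop],
        force=m * forces[:stop],
        x_label="stretch",
        force_label="force_pN",
        extra={
            "per_monomer_force_pN": forces[:stop].copy(),
            "converged": converged[:stop].copy(),
        },
        metadata=metadata,
        break_index=break_index,
    )


def molecule_curve(
    p: FibrinParameterSet, x_max: float = 120.0, n_points: int = 500
) -> ForceExtensionCurve:
    """Single-fibrinogen force-extension curve (the monomer law sampled)."""
    x = np.linspace(0.0, x_max, n_points)
    from .force_laws import fibrinogen_force

    return ForceExtensionCurve(
        scale="molecule",
        x=x,
        force=np.asarray(fibrinogen_force(x, p), dtype=float),
        x_label="extension_nm",
        force_label="force_pN",
        metadata={"parameter_hash": _parameter_hash(p)},
    )
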