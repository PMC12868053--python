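"""Discretisation of the arterial tree for the 1-D solver.

Each artery gets a uniform grid with target spacing 5 mm (at least
three nodes); the reference area A0(x) comes from linear interpolation
of the proximal/distal radii.  All arteries are concatenated into flat
arrays; the root artery is always block 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import TopologyError, ValidationError
from ..parameters.types import ArteryRecord, BloodProperties

DX_TARGET = 0.005  # m


@dataclass
class ArterialSystem:
    """Geometry, wall properties and connectivity of the discretised tree."""

    blood: BloodProperties
    sigma: float
    ids: list[int]                       # artery ids in block order (root first)
    starts: np.ndarray
    counts: np.ndarray
    dxs: np.ndarray
    betas: np.ndarray
    A0: np.ndarray
    dA0dx: np.ndarray
    H: np.ndarray
    jn_parent: np.ndarray
    jn_d1: np.ndarray
    jn_d2: np.ndarray
    term_ends: np.ndarray
    term_art: np.ndarray
    index_of: dict[int, int] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return int(self.A0.shape[0])

    @property
    def gravity(self) -> float:
        return 9.81

    @property
    def friction_coeff(self) -> float:
        """2 pi nu / delta of the boundary-layer friction model."""
        return 2.0 * math.pi * self.blood.kinematic_viscosity / self.blood.boundary_layer

    def node_slice(self, artery_id: int) -> slice:
        a = self.index_of[artery_id]
        return slice(int(self.starts[a]), int(self.starts[a] + self.counts[a]))

    def mid_node(self, artery_id: int) -> int:
        a = self.index_of[artery_id]
        return int(self.starts[a] + self.counts[a] // 2)

    def wave_speed_ref(self, artery_id: int) -> float:
        """Linearised (Moens-Korteweg) wave speed at the reference area."""
        a = self.index_of[artery_id]
        return math.sqrt(self.betas[a] / (2.0 * self.blood.density))

    def volume(self, A: np.ndarray) -> float:
        """Trapezoidal lumen volume of the whole tree [m3]."""
        total = 0.0
        for a in range(len(self.ids)):
            s, n, dx = int(self.starts[a]), int(self.counts[a]), float(self.dxs[a])
            seg = A[s:s + n]
            total += dx * (np.sum(seg) - 0.5 * (seg[0] + seg[-1]))
        return total


@dataclass
class ArterialState1D:
    """Per-node cross-sectional areas and flows of the whole tree."""

    A: np.ndarray
    Q: np.ndarray
    time: float = 0.0

    def copy(self) -> "ArterialState1D":
        return ArterialState1D(self.A.copy(), self.Q.copy(), self.time)


def build_system(
    records: dict[int, ArteryRecord],
    blood: BloodProperties,
    sigma: float,
    root_id: int,
    dx_target: float = DX_TARGET,
) -> ArterialSystem:
    """Assemble the flat-array representation of the arterial tree."""
    order = [root_id] + [i for i in records if i != root_id]
    index_of = {aid: k for k, aid in enumerate(order)}

    starts, counts, dxs, betas = [], [], [], []
    A0_parts, dA0_parts, H_parts = [], [], []
    pos = 0
    for aid in order:
        rec = records[aid]
        n = max(3, int(math.ceil(rec.length / dx_target)) + 1)
        dx = rec.length / (n - 1)
        x = np.linspace(0.0, rec.length, n)
        r = rec.r_prox + (rec.r_dist - rec.r_prox) * x / rec.length
        a0 = math.pi * r**2
        drdx = (rec.r_dist - rec.r_prox) / rec.length
        da0dx = 2.0 * math.pi * r * drdx
        beta = rec.youngs_modulus * rec.h_rel / (1.0 - sigma**2)
        h = rec.elevation_prox + (rec.elevation_dist - rec.elevation_prox) * x / rec.length

        starts.append(pos)
        counts.append(n)
        dxs.append(dx)
        betas.append(beta)
        A0_parts.append(a0)
        dA0_parts.append(da0dx)
        H_parts.append(h)
        pos += n

    jn_parent, jn_d1, jn_d2 = [], [], []
    term_ends, term_art = [], []
    for aid in order:
        rec = records[aid]
        a = index_of[aid]
        if rec.is_terminal:
            term_ends.append(starts[a] + counts[a] - 1)
            term_art.append(a)
        else:
            if len(rec.daughters) > 2:
                raise TopologyError(f"artery {aid}: more than two daughters not supported")
            jn_parent.append(a)
            jn_d1.append(index_of[rec.daughters[0]])
            jn_d2.append(index_of[rec.daughters[1]] if len(rec.daughters) == 2 else -1)

    system = ArterialSystem(
        blood=blood,
        sigma=sigma,
        ids=order,
        starts=np.asarray(starts, dtype=np.int64),
        counts=np.asarray(counts, dtype=np.int64),
        dxs=np.asarray(dxs, dtype=np.float64),
        betas=np.asarray(betas, dtype=np.float64),
        A0=np.concatenate(A0_parts),
        dA0dx=np.concatenate(dA0_parts),
        H=np.concatenate(H_parts),
        jn_parent=np.asarray(jn_parent, dtype=np.int64),
        jn_d1=np.asarray(jn_d1, dtype=np.int64),
        jn_d2=np.asarray(jn_d2, dtype=np.int64),
        term_ends=np.asarray(term_ends, dtype=np.int64),
        term_art=np.asarray(term_art, dtype=np.int64),
        index_of=index_of,
    )
    if blood.boundary_layer >= math.sqrt(float(np.min(system.A0)) / math.pi):
        raise ValidationError("boundary layer exceeds the smallest reference radius")
    return system


def initial_state(system: ArterialSystem, pressure: float = 0.0) -> ArterialState1D:
    """Tree at rest: uniform transmural pressure, zero flow."""
    beta_nodes = np.repeat(system.betas, system.counts)
    A = system.A0 * (1.0 + pressure / beta_nodes) ** 2
    return ArterialState1D(A=A, Q=np.zeros_like(A))
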