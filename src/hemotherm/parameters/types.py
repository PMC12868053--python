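"""Domain types describing the standard person.

All quantities are strict SI unless the field name says otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import ValidationError

ROUTES = ("core", "muscle", "fat", "skin")


@dataclass(frozen=True)
class BloodProperties:
    """Bulk blood properties used by both the thermal and flow models.

    density [kg/m3], specific_heat [J/(kg K)], kinematic_viscosity [m2/s]
    and the friction boundary-layer thickness delta [m] of the 1-D
    momentum equation.
    """

    density: float
    specific_heat: float
    kinematic_viscosity: float
    boundary_layer: float

    def __post_init__(self) -> None:
        for name in ("density", "specific_heat", "kinematic_viscosity", "boundary_layer"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"BloodProperties.{name} must be > 0")

    @property
    def rho_c(self) -> float:
        """Volumetric heat capacity rho*c [J/(m3 K)]."""
        return self.density * self.specific_heat


@dataclass(frozen=True)
class ThermalNode:
    """One node of the thermal network (a tissue compartment or a vessel pool).

    heat_capacity [J/K] is None for artery/vein/superficial-vein nodes,
    whose energy balance is quasi-steady.  radius is the node outer radius
    of the simplified concentric geometry; vessel_area the per-segment sum
    of vessel surface area [m2] for vessel nodes.
    """

    segment: str
    node: str
    kind: str  # compartment | artery | vein | superficial_vein
    heat_capacity: float | None
    basal_met: float
    segment_length: float
    radius: float | None = None
    vessel_area: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "compartment":
            if self.heat_capacity is None or self.heat_capacity <= 0:
                raise ValidationError(
                    f"compartment node {self.segment}:{self.node} needs heat_capacity > 0"
                )
        elif self.heat_capacity is not None:
            raise ValidationError(
                f"vessel node {self.segment}:{self.node} must not carry a heat capacity"
            )
        if self.basal_met < 0:
            raise ValidationError(f"negative basal metabolic rate at {self.segment}:{self.node}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.segment, self.node)


class ConductanceMatrix:
    """Symmetric non-negative map of thermal conductances TC [W/K].

    Keys are (segment, node) pairs.  Absent entries are zero.
    """

    def __init__(self) -> None:
        self._tc: dict[frozenset, float] = {}

    @staticmethod
    def _key(a: tuple[str, str], b: tuple[str, str]) -> frozenset:
        return frozenset((a, b))

    def set(self, a: tuple[str, str], b: tuple[str, str], value: float) -> None:
        if value < 0:
            raise ValidationError(f"negative conductance between {a} and {b}")
        self._tc[self._key(a, b)] = float(value)

    def get(self, a: tuple[str, str], b: tuple[str, str]) -> float:
        return self._tc.get(self._key(a, b), 0.0)

    def items(self):
        for key, value in self._tc.items():
            a, b = tuple(key)
            yield a, b, value

    def neighbours(self, a: tuple[str, str]):
        for key, value in self._tc.items():
            if a in key and value > 0:
                pair = tuple(key)
                yield (pair[0] if pair[1] == a else pair[1]), value

    def scaled(self, factor: float) -> "ConductanceMatrix":
        out = ConductanceMatrix()
        for a, b, value in self.items():
            out.set(a, b, value * factor)
        return out


@dataclass
class ArteryRecord:
    """One artery of the 1-D tree (Westerhof/Avolio-style naming).

    Bilateral vessels appear as two records with identical properties.
    Elevation is given at the proximal and distal ends; supine baseline
    uses zeros everywhere.
    """

    id: int
    name: str
    side: str  # "R", "L" or "" for midline vessels
    length: float
    r_prox: float
    r_dist: float
    h_rel: float
    youngs_modulus: float
    parent: int | None
    daughters: list[int] = field(default_factory=list)
    elevation_prox: float = 0.0
    elevation_dist: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"artery {self.id} ({self.name}): length must be > 0")
        for nm in ("r_prox", "r_dist", "h_rel", "youngs_modulus"):
            if getattr(self, nm) <= 0:
                raise ValidationError(f"artery {self.id} ({self.name}): {nm} must be > 0")
        if self.r_dist > self.r_prox + 1e-12:
            raise ValidationError(
                f"artery {self.id} ({self.name}): distal radius exceeds proximal radius"
            )

    @property
    def is_terminal(self) -> bool:
        return not self.daughters

    @property
    def label(self) -> str:
        return f"{self.name}_{self.side.lower()}" if self.side else self.name


@dataclass(frozen=True)
class CircuitElement:
    """A lumped R-L-C element of the 0-D circulation.

    C is None where the element references a shared compliance (the four
    arteriole branches share one).
    """

    id: str
    role: str
    R: float
    L: float = 0.0
    C: float | None = None
    elevation: float = 0.0

    def __post_init__(self) -> None:
        if self.R < 0 or self.L < 0:
            raise ValidationError(f"element {self.id}: R and L must be >= 0")
        if self.C is not None and self.C <= 0:
            raise ValidationError(f"element {self.id}: C must be > 0")


@dataclass(frozen=True)
class HeartChamberParams:
    """Time-varying elastance chamber: P = (E_A e(t) + E_B) V + S dV/dt."""

    name: str
    kind: str  # atrium | ventricle
    E_A: float
    E_B: float
    S: float
    T_cs: float
    T_cp: float
    T_rp: float

    def __post_init__(self) -> None:
        for nm in ("T_cs", "T_cp", "T_rp"):
            value = getattr(self, nm)
            if not 0.0 < value < 1.0:
                raise ValidationError(f"chamber {self.name}: {nm} must lie in (0, 1)")
        total = self.T_cs + self.T_cp + self.T_rp
        if self.kind == "ventricle" and total > 1.0:
            raise ValidationError(
                f"ventricle {self.name}: activation phases must fit within one cycle"
            )
        if self.kind == "atrium" and total <= 1.0:
            raise ValidationError(
                f"atrium {self.name}: activation is expected to wrap across the cycle"
            )
        if self.E_A < 0 or self.E_B <= 0 or self.S < 0:
            raise ValidationError(f"chamber {self.name}: elastances must be positive")


@dataclass(frozen=True)
class ValveParams:
    """Heart valve momentum parameters: P_up - P_dw = Q R + Q^2 B + L dQ/dt."""

    name: str
    R: float
    B: float
    L: float

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValidationError(f"valve {self.name}: L must be > 0")
        if self.R < 0 or self.B < 0:
            raise ValidationError(f"valve {self.name}: R and B must be >= 0")


@dataclass(frozen=True)
class PulmonaryParams:
    """Exponential pulmonary compartment: P = E0 Phi exp(V/Phi) + S dV/dt."""

    name: str
    E0: float
    Phi: float
    S: float

    def __post_init__(self) -> None:
        if self.E0 <= 0 or self.Phi <= 0:
            raise ValidationError(f"pulmonary {self.name}: E0 and Phi must be > 0")


@dataclass
class RouteSpec:
    """Mapping of one peripheral route onto the thermal network."""

    group: str
    weight: float
    tnw_node: str


@dataclass
class PeripheralCircuit:
    """Four-route peripheral circulation attached to one terminal artery.

    Shared elements: distal arterial end resistance R_da, single arteriole
    compliance C_al, collecting vein (R_v, L_v, C_v).  Per-route chains
    (indexed core, muscle, fat, skin): arteriole R/L, capillary R/L/C,
    venule R/L/C.  R_T_route holds each route's total viscous resistance.
    """

    artery_id: int
    tnw_segment: str
    vena_cava: str
    R_T_route: dict[str, float]
    routes: dict[str, RouteSpec]
    # derived element values, populated by build_peripheral_circuit
    R_da: float = 0.0
    C_al: float = 0.0
    R_al: dict[str, float] = field(default_factory=dict)
    L_al: dict[str, float] = field(default_factory=dict)
    R_cp: dict[str, float] = field(default_factory=dict)
    L_cp: dict[str, float] = field(default_factory=dict)
    C_cp: dict[str, float] = field(default_factory=dict)
    R_vn: dict[str, float] = field(default_factory=dict)
    L_vn: dict[str, float] = field(default_factory=dict)
    C_vn: dict[str, float] = field(default_factory=dict)
    R_v: float = 0.0
    L_v: float = 0.0
    C_v: float = 0.0

    @property
    def R_T(self) -> float:
        """Aggregate total viscous resistance (parallel routes)."""
        return 1.0 / sum(1.0 / self.R_T_route[r] for r in ROUTES)


@dataclass
class ParameterSet:
    """The complete standard-person description."""

    blood: BloodProperties
    thermal_nodes: dict[tuple[str, str], ThermalNode]
    conductances: ConductanceMatrix
    arteries: dict[int, ArteryRecord]
    root_id: int
    chambers: dict[str, HeartChamberParams]
    valves: dict[str, ValveParams]
    pulmonary: dict[str, PulmonaryParams]
    pulmonary_links: dict[str, dict[str, float]]
    vena_cavae: dict[str, dict[str, float]]
    peripherals: dict[int, PeripheralCircuit]
    heart_rate: float
    poisson_ratio: float
    env_defaults: dict
    circuit_defaults: dict
    flow_targets: "object"  # pandas.DataFrame, layout mirrors the printed table

    @property
    def heart_period(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def segments(self) -> list[str]:
        seen: list[str] = []
        for seg, _ in self.thermal_nodes:
            if seg not in seen:
                seen.append(seg)
        return seen

    def terminal_ids(self) -> list[int]:
        return [a.id for a in self.arteries.values() if a.is_terminal]
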