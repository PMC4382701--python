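"""Model parameter containers.

All quantities are in dimensionless model units.  The defaults are the
parameter set used for the headline hollow/ridge simulations; they are the
single source of truth for every module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class MechanicsParams:
    """Vertex-mechanics constants.

    Attributes
    ----------
    eta : float
        Viscosity coefficient of the medium the vertices move in
        (overdamped dynamics, ``eta * dx/dt = F``).
    K_S : float
        Area-elasticity constant (quadratic penalty about the target area).
    K_B, K_R : float
        Edge tension and short-range repulsion constants.  Their combined
        term ``K_B*L + K_R/L`` has a minimum at ``L* = sqrt(K_R/K_B)``, the
        edge target length, and diverges as ``L -> 0`` so neighbouring
        vertices cannot collapse onto each other.
    K_E, L_E : float
        Elastic constant and target length of the outermost (cuticle-
        stiffened) cell edges.
    dt : float
        Time step of the fourth-order Runge-Kutta integrator.
    """

    eta: float = 1.0
    K_S: float = 1.0
    K_B: float = 0.1
    K_R: float = 0.001
    K_E: float = 0.005
    L_E: float = 1.3
    dt: float = 0.005

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")


@dataclass
class MorphogenParams:
    """Synthesis (A), degradation (B) and diffusion (D) rates of the three
    morphogens: ``u`` (division-promoting, sourced at the adaxial-abaxial
    epidermal boundary), ``v`` (epidermal, orients longitudinal divisions)
    and ``w`` (adaxial-epidermal, orients periclinal divisions)."""

    A_u: float = 2.0
    B_u: float = 1.0
    D_u: float = 1.0
    A_v: float = 1.0
    B_v: float = 1.0
    D_v: float = 0.2
    A_w: float = 1.0
    B_w: float = 1.0
    D_w: float = 0.2

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def species(self, z: str) -> tuple[float, float, float]:
        """Return ``(A, B, D)`` for species ``z`` in {'u','v','w'}."""
        if z not in ("u", "v", "w"):
            raise ValueError(f"unknown species {z!r}")
        return (
            getattr(self, f"A_{z}"),
            getattr(self, f"B_{z}"),
            getattr(self, f"D_{z}"),
        )


@dataclass
class ClockParams:
    """Division-clock constants.

    The clock of a non-epidermal cell advances at rate
    ``P0 + P * Hill(u; u0, n) * Hill(S; S0, m)`` and the cell divides when
    the clock exceeds its threshold ``C_i``, drawn per cell at birth from
    a uniform distribution on ``[ (1-fluct)*C, (1+fluct)*C ]``.
    """

    P0: float = 1.0
    P: float = 20.0
    u0: float = 0.03
    S0: float = 1.2
    n: float = 2.0
    m: float = 8.0
    C: float = 10_000.0
    threshold_fluctuation: float = 0.10

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if not 0 <= self.threshold_fluctuation < 1:
            raise ValueError("threshold_fluctuation must be in [0, 1)")


@dataclass
class ModelParams:
    """Bundle of all model constants."""

    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    morphogens: MorphogenParams = field(default_factory=MorphogenParams)
    clock: ClockParams = field(default_factory=ClockParams)

    @property
    def dt(self) -> float:
        return self.mechanics.dt
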