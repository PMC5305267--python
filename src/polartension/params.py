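"""Model parameters for the mechano-chemical cell-polarity model.

The model couples wave-pinning Rac-GTP/Rac-GDP kinetics to F-actin and a
spatially homogeneous membrane tension that acts as a fast global inhibitor
of actin polymerization.  All concentrations are surface densities in
``μm⁻²``, rates in ``1/s``, lengths in ``μm`` and tensions in ``pN/μm``.

Default values reproduce the calibration documented in ``docs/methods.md``:
initial homogeneous state (u0=2, v0=6, f0=0), bistable well-mixed kinetics at
the background Rac-GDP level, and the steady polarized state of the reference
disk cell (radius 10 μm in a 40 μm periodic box).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict, replace
from typing import Any


@dataclass
class ModelParams:
    # diffusion coefficients, μm²/s  (D_u < D_f ≪ D_v)
    D_u: float = 0.1
    D_v: float = 50.0
    D_f: float = 0.25

    # Rac interconversion, 1/s
    b: float = 0.007     # basal GDP→GTP conversion
    r: float = 1.0       # GTP→GDP deactivation

    # Hill activation terms: c = max rate, K = dissociation constant (μm⁻²)
    c1: float = 0.07     # Rac self-activation
    K1: float = 0.40
    c2: float = 0.0420   # F-actin → Rac activation
    K2: float = 1.20
    c3: float = 0.125    # Rac → F-actin polymerization
    K3: float = 0.40

    d_f: float = 0.01    # F-actin depolymerization, 1/s

    # membrane tension feedback
    mt0: float = 0.2     # basal tension, pN/μm
    lam: float = 0.046   # tension sensitivity to total F-actin (λ)
    K_F: float = 2.0     # tension scaling factor, pN/μm

    # geometry / numerics
    R: float = 10.0      # cell radius, μm
    eps: float = 1.0     # phase-field interface width ε, μm
    L: float = 40.0      # periodic domain edge, μm
    N: int = 128         # grid points per axis
    dt: float = 0.01     # time step, s

    # initial homogeneous concentrations, μm⁻²
    u0: float = 2.0
    v0: float = 6.0
    f0: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending key on invariant violation."""
        positive = ("D_u", "D_v", "D_f", "b", "r", "c1", "K1", "c2", "K2",
                    "c3", "K3", "d_f", "mt0", "K_F", "R", "eps", "L", "dt")
        for key in positive:
            if not getattr(self, key) > 0:
                raise ValueError(f"parameter {key!r} must be strictly positive")
        if self.lam < 0:
            raise ValueError("parameter 'lam' must be non-negative")
        for key in ("u0", "v0", "f0"):
            if getattr(self, key) < 0:
                raise ValueError(f"parameter {key!r} must be non-negative")
        if not (self.D_u < self.D_f < self.D_v):
            raise ValueError("diffusion ordering violated: require D_u < D_f < D_v")
        if not self.R < self.L / 2:
            raise ValueError("parameter 'R': cell must fit inside the domain (R < L/2)")
        if self.N < 16:
            raise ValueError("parameter 'N' too small to resolve the interface")
        if self.eps < 2 * self.L / self.N:
            raise ValueError(
                "parameter 'eps': interface unresolved (eps < 2 grid spacings)")

    # -- convenience -------------------------------------------------------

    @property
    def dx(self) -> float:
        return self.L / self.N

    def with_updates(self, **kwargs: Any) -> "ModelParams":
        """Return a validated copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


DEFAULTS = ModelParams()
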