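"""Semi-implicit Fourier-spectral time stepping of the phase-field model.

The coupled equations evolve Rac-GTP (u, membrane, weight B(φ)), Rac-GDP
(v, cytosol, weight φ) and F-actin (f, cytosol, weight φ) on a periodic
grid.  Dividing the conservative form ∂(w·c)/∂t = D∇·(w∇c) + S by the
static weight gives the concentration-level dynamics integrated here:

    ∂u/∂t = D_u ∇·(B∇u)/B̃  + φ·[(b + c1H₁(u) + c2H₂(f) + k_s)·v − r·u]
    ∂v/∂t = D_v ∇·(φ∇v)/φ̃  − (|∇φ|/φ̃)·[(b + c1H₁(u) + c2H₂(f) + k_s)·v − r·u]
    ∂f/∂t = D_f ∇·(φ∇f)/φ̃  + (|∇φ|/φ̃)·c3H₃(u)·K_F/(K_F+mt) − d_f·f

where B̃, φ̃ are the weights floored at delta_phi·max(w) to keep the update
well-conditioned where the weight degenerates.  Note the u-reaction acts at
concentration level throughout the cell support (the B-weighting of the
production and decay terms cancels against the B on the left-hand side),
while Rac conversion drains/feeds the cytosolic pool only across the
membrane layer |∇φ|.  Membrane tension is recomputed from f every step
(mechanical equilibrium is instantaneous on the chemical time scale).

Time stepping: for each field the stiff diffusion is stabilized by an
add–subtract split — σD∇² treated implicitly in Fourier space, the
variable-coefficient remainder and all reactions explicit.  The explicit
divergence uses conservative centered fluxes on the periodic grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Optional

import numpy as np
from scipy import fft as sfft

from .geometry import PhaseFieldGeometry
from .kinetics import hill, membrane_tension, production_rate, tension_factor
from .params import ModelParams


@dataclass
class CellState:
    """Concentration fields and elapsed time for one cell."""

    u: np.ndarray      # Rac-GTP, μm⁻²
    v: np.ndarray      # Rac-GDP, μm⁻²
    f: np.ndarray      # F-actin, μm⁻²
    t: float = 0.0     # s
    mt: float = 0.0    # effective membrane tension, pN/μm

    def copy(self) -> "CellState":
        return CellState(self.u.copy(), self.v.copy(), self.f.copy(),
                         self.t, self.mt)


def homogeneous_state(geometry: PhaseFieldGeometry,
                      params: ModelParams) -> CellState:
    """Uniform concentrations (u0, v0, f0) over the whole domain.

    Concentration fields extend at full value through the diffuse interface
    (all physical masses are φ- or B(φ)-weighted, so the exterior carries no
    material); initializing the exterior at the same level avoids a spurious
    early outflow through the interface tails.
    """
    shape = geometry.phi.shape
    st = CellState(u=np.full(shape, float(params.u0)),
                   v=np.full(shape, float(params.v0)),
                   f=np.full(shape, float(params.f0)))
    st.mt = membrane_tension(st.f, geometry, params)
    return st


@dataclass
class SolverConfig:
    dt: float = 0.01                  # s
    t_end: float = 100.0              # s
    stabilization_coeff: float = 2.0  # σ ≥ max mobility ratio of the split
    delta_phi: float = 0.05           # relative floor for degenerate weights
    snapshot_every: int = 100         # steps between trace rows
    store_fields: bool = False        # keep full field snapshots in the trace
    conversion_measure: str = "area"  # "area" (mass-conserving) | "interface"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.0 < self.delta_phi <= 0.1):
            raise ValueError("delta_phi must lie in (0, 0.1]")
        if self.stabilization_coeff < 1.0:
            raise ValueError("stabilization_coeff must be >= 1")
        if self.conversion_measure not in ("area", "interface"):
            raise ValueError("conversion_measure must be 'area' or 'interface'")


class Stepper:
    """Pre-computed operators for repeated stepping on one geometry."""

    def __init__(self, geometry: PhaseFieldGeometry, params: ModelParams,
                 config: SolverConfig, uniform_weights: bool = False):
        self.geometry = geometry
        self.params = params
        self.config = config
        N, dx = geometry.N, geometry.dx
        k = 2.0 * np.pi * np.fft.fftfreq(N, d=dx)
        kx2 = k[:, None] ** 2
        ky2 = k[None, :N // 2 + 1] ** 2
        self.k2 = kx2 + ky2                      # rfft2 layout
        dt, sig = config.dt, config.stabilization_coeff
        self.uniform = uniform_weights
        self.D = {"u": params.D_u, "v": params.D_v, "f": params.D_f}
        if uniform_weights:
            # constant-coefficient limit: exact exponential propagator
            self.prop = {n: np.exp(-dt * D * self.k2) for n, D in self.D.items()}
        else:
            self.denom = {n: 1.0 + dt * sig * D * self.k2
                          for n, D in self.D.items()}
        delta = config.delta_phi
        phi = geometry.phi
        # membrane mobility: B(φ) normalized to 1 at the interface midline so
        # the lateral (along-membrane) diffusivity of u is D_u itself
        B = geometry.Bphi / max(geometry.Bphi.max(), 1e-30)
        ones = np.ones_like(phi)
        # capacity measure is φ for all fields: u is stored cell-wide (its
        # reaction acts at concentration level throughout the support) but
        # transported only where the membrane mobility B(φ) is non-zero
        self.wt_u = ones if uniform_weights else np.maximum(phi, delta)
        self.wt_c = ones if uniform_weights else np.maximum(phi, delta)
        # |∇φ|/φ membrane coupling, Tikhonov-regularized: equals |∇φ|/φ on
        # the interior side but vanishes with φ on the exterior tail, so
        # conversion cannot drain the cytosolic pool outside the cell
        self.mem = geometry.grad_phi_mag * phi / (phi * phi + delta * delta)
        # weight of the GDP→GTP conversion in the v equation: φ ("area",
        # default) pairs exactly with the u equation's concentration-level
        # reaction so total Rac ∫φ(u+v) is conserved by conversion; the
        # "interface" option keeps the |∇φ|/φ weighting of the conservative
        # form as printed, at the cost of a mass defect during transients
        self.conv_w_v = phi if config.conversion_measure == "area" else self.mem
        self.gate = ones if uniform_weights else phi   # cell-support gate for u
        self.n_clipped = 0                             # negative-value clips
        # static face weights (arithmetic mean) for the conservative fluxes
        self._faces = {}
        for key, w in (("u", ones if uniform_weights else B),
                       ("c", ones if uniform_weights else phi)):
            self._faces[key] = tuple(
                (0.5 * (w + np.roll(w, -1, axis=ax)),
                 0.5 * (w + np.roll(w, 1, axis=ax))) for ax in (0, 1))

    # -- spatial operators -------------------------------------------------

    def _div_w_grad(self, c: np.ndarray, key: str) -> np.ndarray:
        """Conservative centered discretization of ∇·(w∇c), periodic."""
        dx2 = self.geometry.dx ** 2
        out = np.zeros_like(c)
        for ax in (0, 1):
            wp, wm = self._faces[key][ax]
            cp = np.roll(c, -1, axis=ax)
            cm = np.roll(c, 1, axis=ax)
            out += wp * (cp - c) - wm * (c - cm)
        out /= dx2
        return out

    def reaction_terms(self, st: CellState, k_s) -> tuple[np.ndarray, ...]:
        """Non-diffusive right-hand sides (reaction + membrane coupling)."""
        p = self.params
        prod = production_rate(st.u, st.f, p, k_s)
        conv = prod * st.v - p.r * st.u           # GDP→GTP net conversion
        Gu = self.gate * conv
        Gv = -(self.gate if self.uniform else self.conv_w_v) * conv
        Gf = self.mem * hill(st.u, p.c3, p.K3) * tension_factor(st.mt, p) \
            - p.d_f * st.f
        return Gu, Gv, Gf

    def step(self, st: CellState, k_s=0.0,
             mt_policy: Optional[Callable[[float, float], float]] = None
             ) -> CellState:
        """Advance one time step; returns a new state with t += dt."""
        p, cfg = self.params, self.config
        dt = cfg.dt
        Gu, Gv, Gf = self.reaction_terms(st, k_s)
        new = {}
        for name, c, G, wkey, wt in (("u", st.u, Gu, "u", self.wt_u),
                                     ("v", st.v, Gv, "c", self.wt_c),
                                     ("f", st.f, Gf, "c", self.wt_c)):
            if self.uniform:
                # exact exponential propagator for constant-coefficient
                # diffusion; reaction explicit
                ch = sfft.rfft2(c + dt * G)
                ch *= self.prop[name]
                cn = sfft.irfft2(ch, s=c.shape)
            else:
                # stabilized semi-implicit: the full explicit RHS is filtered
                # by (1 + dtσDk²)⁻¹, equivalent to treating σD∇² implicitly
                # with the add–subtract splitting
                R = self.D[name] * self._div_w_grad(c, wkey) / wt + G
                rh = sfft.rfft2(R)
                rh /= self.denom[name]
                cn = c + dt * sfft.irfft2(rh, s=c.shape)
            neg = cn < 0.0
            nneg = int(np.count_nonzero(neg))
            if nneg:
                self.n_clipped += nneg
                cn[neg] = 0.0
            if not np.all(np.isfinite(cn)):
                raise FloatingPointError(
                    f"non-finite values in field {name!r} at t={st.t + dt:.4f}")
            new[name] = cn
        t_new = st.t + dt
        mt = membrane_tension(new["f"], self.geometry, p)
        if mt_policy is not None:
            mt = mt_policy(t_new, mt)
        return CellState(new["u"], new["v"], new["f"], t_new, mt)


def step(state: CellState, geometry: PhaseFieldGeometry, params: ModelParams,
         k_s_field=0.0, config: SolverConfig | None = None) -> CellState:
    """Single-step convenience wrapper (builds a fresh Stepper)."""
    cfg = config or SolverConfig()
    if state.mt <= 0:
        state = replace_mt(state, geometry, params)
    return Stepper(geometry, params, cfg).step(state, k_s_field)


def replace_mt(state: CellState, geometry, params) -> CellState:
    st = state.copy()
    st.mt = membrane_tension(st.f, geometry, params)
    return st


# ---------------------------------------------------------------------------
# trace container and simulation driver

@dataclass
class SimulationTrace:
    """Per-snapshot polarity metrics, optional field snapshots, event marks."""

    times: list = field(default_factory=list)
    max_u: list = field(default_factory=list)
    total_u: list = field(default_factory=list)
    total_f: list = field(default_factory=list)
    mt_series: list = field(default_factory=list)
    polarity_angle: list = field(default_factory=list)   # deg or nan
    events: list = field(default_factory=list)           # (t, label)
    snapshots: list = field(default_factory=list)        # (t, CellState)
    final_state: Any = None

    def record(self, st: CellState, geometry: PhaseFieldGeometry,
               store_fields: bool = False) -> None:
        phi = geometry.phi
        inside = phi > 0.5
        self.times.append(st.t)
        self.max_u.append(float(np.max(st.u[inside])) if inside.any() else 0.0)
        self.total_u.append(float(np.sum(phi * st.u)) * geometry.dA)
        self.total_f.append(float(np.sum(phi * st.f)) * geometry.dA)
        self.mt_series.append(st.mt)
        self.polarity_angle.append(weighted_polarity_angle(st.u, geometry))
        if store_fields:
            self.snapshots.append((st.t, st.copy()))

    def asarrays(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(getattr(self, k if k != "mt" else "mt_series"))
                for k in ("times", "max_u", "total_u", "total_f",
                          "mt_series", "polarity_angle")}


def weighted_polarity_angle(u_field: np.ndarray, geometry: PhaseFieldGeometry,
                            noise_floor: float = 1e-3) -> float:
    """Angle (deg, [0,360)) of the B(φ)-weighted first circular moment of u.

    NaN when the moment magnitude (normalized by the weighted mean of u) is
    below ``noise_floor`` — an unpolarized cell has no direction.
    """
    X, Y = geometry.meshgrid()
    w = geometry.Bphi * u_field
    tot = float(np.sum(w))
    if tot <= 0:
        return float("nan")
    mx = float(np.sum(w * X)) / tot
    my = float(np.sum(w * Y)) / tot
    R_eff = math.sqrt(max(geometry.area, geometry.dA) / math.pi)
    if math.hypot(mx, my) / R_eff < noise_floor:
        return float("nan")
    return float(np.degrees(np.arctan2(my, mx)) % 360.0)


def simulate(initial: CellState, geometry: PhaseFieldGeometry,
             params: ModelParams,
             ks_fn: Optional[Callable[[float], np.ndarray | float]] = None,
             config: SolverConfig | None = None,
             mt_policy: Optional[Callable[[float, float], float]] = None,
             trace: SimulationTrace | None = None,
             stepper: Stepper | None = None) -> SimulationTrace:
    """Run the model from ``initial`` until ``config.t_end``.

    ``ks_fn(t)`` supplies the stimulus rate field (0 for none); ``mt_policy``
    may override the computed tension (aspiration, unreleased severing).
    Passing an existing ``trace`` appends to it (used by experiment drivers
    that chain phases).  Deterministic given the stimulus seed.
    """
    cfg = config or SolverConfig()
    stp = stepper or Stepper(geometry, params, cfg)
    st = initial if initial.mt > 0 else replace_mt(initial, geometry, params)
    tr = trace if trace is not None else SimulationTrace()
    if not tr.times:
        tr.record(st, geometry, cfg.store_fields)
    n_steps = int(round((cfg.t_end - st.t) / cfg.dt))
    for i in range(n_steps):
        ks = ks_fn(st.t) if ks_fn is not None else 0.0
        st = stp.step(st, ks, mt_policy)
        if (i + 1) % cfg.snapshot_every == 0 or i == n_steps - 1:
            tr.record(st, geometry, cfg.store_fields)
    tr.final_state = st
    return tr
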