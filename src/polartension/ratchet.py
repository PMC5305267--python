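"""Traditional 2D cell-polarity model with Brownian-ratchet tension coupling.

Cross-check formulation: the cell is a flat 2D projection in which membrane
and cytosol overlap, so u, v and f all live on the same disk mask with
zero-flux boundaries.  The reaction terms are the same wave-pinning network
as the phase-field model, except that membrane tension attenuates F-actin
polymerization through the Brownian-ratchet load factor

    exp(−mt·δ / k_B T)

(δ the elongation step added per monomer against the load, k_B T the
thermal energy) instead of the Hill-type factor K_F/(K_F+mt).  Tension
remains a global scalar, mt = mt0·(1 + λ·Σ f·ΔA over the mask).

Because membrane and cytosol coincide, conversion between u and v acts at
every interior point and total Rac Σ(u+v) over the mask is conserved
exactly; fronts pin by depleting the cytosolic pool (classic wave pinning)
with tension as the additional global inhibitor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .params import ModelParams
from .kinetics import hill, production_rate
from .solver import CellState, SimulationTrace, SolverConfig


@dataclass
class RatchetParams:
    """Kinetics as ModelParams plus the ratchet load scale.

    Defaults for δ and k_B T are the actin monomer half-size (2.7 nm) and
    thermal energy at ~300 K in pN·μm.
    """

    # the overlap geometry produces F-actin areally (no interface dilution),
    # so its maximum polymerization rate is much smaller than the
    # phase-field model's interface flux constant
    base: ModelParams = field(default_factory=lambda: ModelParams(c3=0.03))
    delta: float = 0.0027        # ratchet step, μm
    kBT: float = 0.00414         # pN·μm
    load_sites: float = 3.0      # load-bearing filaments per μm of edge

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.kBT <= 0 or self.load_sites <= 0:
            raise ValueError("delta, kBT and load_sites must be positive")


def ratchet_factor(mt, params: RatchetParams):
    """Brownian-ratchet polymerization factor exp(−mt·δ/(n·kBT)).

    The in-plane tension mt (pN/μm) is shared by ``load_sites`` filaments
    per μm of cell edge, so each filament polymerizes against the load
    mt/load_sites and its elongation rate carries the Boltzmann factor of
    the work done per added step δ.  Lies in (0, 1], equals 1 at zero
    tension, strictly decreasing in mt.
    """
    mt = np.asarray(mt, dtype=float)
    if np.any(mt < 0):
        raise ValueError("membrane tension must be non-negative")
    return np.exp(-mt * params.delta / (params.load_sites * params.kBT))


def _masked_laplacian(c: np.ndarray, mask: np.ndarray, dx: float) -> np.ndarray:
    """Five-point Laplacian with zero-flux (mirror) edges at the mask rim."""
    out = np.zeros_like(c)
    for ax in (0, 1):
        cp = np.roll(c, -1, axis=ax)
        cm = np.roll(c, 1, axis=ax)
        mp = np.roll(mask, -1, axis=ax)
        mm = np.roll(mask, 1, axis=ax)
        # flux only across faces with both cells inside the mask
        out += np.where(mp, cp - c, 0.0) + np.where(mm, cm - c, 0.0)
    return np.where(mask, out, 0.0) / dx ** 2


@dataclass
class RatchetModel:
    """Disk-mask integrator for the traditional (overlapping) 2D model."""

    params: RatchetParams

    def __post_init__(self) -> None:
        p = self.params.base
        N, L = p.N, p.L
        coords = np.arange(N) * (L / N) - L / 2.0
        X, Y = np.meshgrid(coords, coords, indexing="ij")
        self.X, self.Y = X, Y
        self.mask = np.hypot(X, Y) <= p.R
        self.dx = L / N
        self.dA = self.dx ** 2

    def homogeneous_state(self) -> CellState:
        p = self.params.base
        m = self.mask.astype(float)
        st = CellState(u=p.u0 * m, v=p.v0 * m, f=p.f0 * m)
        st.mt = self.membrane_tension(st.f)
        return st

    def membrane_tension(self, f: np.ndarray) -> float:
        p = self.params.base
        return p.mt0 * (1.0 + p.lam * float(np.sum(f[self.mask])) * self.dA)

    def step(self, st: CellState, k_s=0.0,
             mt_policy: Optional[Callable[[float, float], float]] = None
             ) -> CellState:
        """One explicit step; the cytosolic pool is treated as well mixed.

        D_v exceeds the explicit diffusion stability limit by orders of
        magnitude while making v essentially flat across a 10-μm cell, so v
        is integrated in its fast-diffusion limit: a spatially uniform pool
        drained/filled by the mask-average conversion.  u and f diffuse
        explicitly (their CFL limits are comfortably met at the default dt).
        """
        p = self.params.base
        dt, m = p.dt, self.mask
        prod = production_rate(st.u, st.f, p, k_s)
        conv = np.where(m, prod * st.v - p.r * st.u, 0.0)
        growth = hill(st.u, p.c3, p.K3) * ratchet_factor(st.mt, self.params)
        du = p.D_u * _masked_laplacian(st.u, m, self.dx) + conv
        df = p.D_f * _masked_laplacian(st.f, m, self.dx) \
            + np.where(m, growth - p.d_f * st.f, 0.0)
        u = np.clip(st.u + dt * du, 0.0, None)
        v_mean = float(st.v[m].mean()) - dt * float(conv[m].mean())
        v = max(v_mean, 0.0) * m.astype(float)
        f = np.clip(st.f + dt * df, 0.0, None)
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))
                and np.all(np.isfinite(f))):
            raise FloatingPointError(f"non-finite field at t={st.t + dt:.4f}")
        t_new = st.t + dt
        mt = self.membrane_tension(f)
        if mt_policy is not None:
            mt = mt_policy(t_new, mt)
        return CellState(u, v, f, t_new, mt)

    def total_rac(self, st: CellState) -> float:
        return float(np.sum((st.u + st.v)[self.mask])) * self.dA

    def simulate(self, initial: CellState,
                 ks_fn: Optional[Callable[[float], np.ndarray | float]] = None,
                 config: SolverConfig | None = None,
                 mt_policy: Optional[Callable[[float, float], float]] = None
                 ) -> SimulationTrace:
        """Explicit integration to config.t_end with trace recording."""
        p = self.params.base
        cfg = config or SolverConfig(dt=p.dt, t_end=100.0)
        st = initial
        tr = SimulationTrace()
        self._record(tr, st)
        n_steps = int(round((cfg.t_end - st.t) / p.dt))
        for i in range(n_steps):
            ks = ks_fn(st.t) if ks_fn is not None else 0.0
            st = self.step(st, ks, mt_policy)
            if (i + 1) % cfg.snapshot_every == 0 or i == n_steps - 1:
                self._record(tr, st)
        tr.final_state = st
        return tr

    def _record(self, tr: SimulationTrace, st: CellState) -> None:
        m = self.mask
        tr.times.append(st.t)
        tr.max_u.append(float(st.u[m].max()))
        tr.total_u.append(float(np.sum(st.u[m])) * self.dA)
        tr.total_f.append(float(np.sum(st.f[m])) * self.dA)
        tr.mt_series.append(st.mt)
        w = st.u * m
        tot = float(w.sum())
        if tot > 0:
            mx = float((w * self.X).sum()) / tot
            my = float((w * self.Y).sum()) / tot
            import math
            R_eff = math.sqrt(m.sum() * self.dA / math.pi)
            ang = (math.degrees(math.atan2(my, mx)) % 360.0
                   if math.hypot(mx, my) / R_eff > 1e-3 else float("nan"))
        else:
            ang = float("nan")
        tr.polarity_angle.append(ang)


def ratchet_aspiration_release(params: RatchetParams | None = None, *,
                               tension_multiplier: float = 10.0,
                               warm_amp: float = 0.01, warm_dur: float = 40.0,
                               t_aspirate: float = 250.0,
                               t_release: float = 330.0,
                               t_end: float = 700.0,
                               config: SolverConfig | None = None):
    """Aspiration–release assay on the traditional model.

    The cell is activated by a graded stimulus, tension is multiplied at
    ``t_aspirate`` and restored at ``t_release``; returns the trace.  The
    recovery is slower than in the phase-field formulation because the
    areal F-actin pool must be rebuilt everywhere rather than only on the
    interface layer.
    """
    rp = params or RatchetParams()
    model = RatchetModel(rp)
    p = rp.base
    pat = warm_amp * np.clip(p.R + model.X, 0.0, None) * model.mask

    def ks(t):
        return pat if 0 < t <= warm_dur else 0.0

    def mt_policy(t, mt_from_f):
        if t_aspirate < t <= t_release:
            return mt_from_f * tension_multiplier
        return mt_from_f

    cfg = config or SolverConfig(dt=p.dt, t_end=t_end,
                                 snapshot_every=max(1, int(2.0 / p.dt)))
    from dataclasses import replace
    cfg = replace(cfg, t_end=t_end)
    tr = model.simulate(model.homogeneous_state(), ks, cfg, mt_policy)
    tr.events.append((t_aspirate, "aspirate"))
    tr.events.append((t_release, "release"))
    return tr


def simulate_traditional(initial: CellState | None = None,
                         ks_fn: Optional[Callable] = None,
                         params: RatchetParams | None = None,
                         config: SolverConfig | None = None,
                         mt_policy: Optional[Callable] = None
                         ) -> SimulationTrace:
    """Convenience driver: integrate the traditional overlap model.

    Builds a :class:`RatchetModel` from ``params`` (defaults otherwise),
    starts from ``initial`` (homogeneous state otherwise) and returns the
    trace; mirrors :func:`polartension.solver.simulate` for the phase-field
    model.
    """
    model = RatchetModel(params or RatchetParams())
    st = initial if initial is not None else model.homogeneous_state()
    return model.simulate(st, ks_fn, config, mt_policy)
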