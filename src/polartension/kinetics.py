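"""Local (non-diffusive) kinetics of the Rac/F-actin/tension network.

The reaction terms implement the bistable wave-pinning interconversion of
membrane Rac-GTP (u) and cytosolic Rac-GDP (v), positive feedback between
Rac-GTP and F-actin (f), and the inhibition of actin polymerization by
membrane tension through the factor K_F/(K_F + mt).  Membrane tension is a
single scalar, mt = mt0·(1 + λ·∫φ f dA): mechanical equilibration is assumed
instantaneous relative to the reaction–diffusion dynamics.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams


def hill(x, c, K):
    """Hill activation ``c·x²/(x²+K²)``; bounded in [0, c), half-max at x=K."""
    x = np.asarray(x, dtype=float)
    if K <= 0:
        raise ValueError("Hill constant K must be positive")
    if np.any(x < 0):
        raise ValueError("Hill input must be non-negative")
    x2 = x * x
    return c * x2 / (x2 + K * K)


def tension_factor(mt, params: ModelParams):
    """Down-regulation of F-actin polymerization by tension: K_F/(K_F+mt)."""
    return params.K_F / (params.K_F + mt)


def membrane_tension(f, geometry, params: ModelParams) -> float:
    """Spatially homogeneous tension ``mt0·(1 + λ·F_tot)``.

    ``F_tot`` is the φ-weighted integral of f over the domain (the cytosolic
    total, discretized as Σ φ·f·ΔA — the smooth phase-field indicator, not a
    hard mask).
    """
    f = np.asarray(f, dtype=float)
    if f.shape != geometry.phi.shape:
        raise ValueError(
            f"field shape {f.shape} does not match grid {geometry.phi.shape}")
    F_tot = float(np.sum(geometry.phi * f)) * geometry.dA
    return params.mt0 * (1.0 + params.lam * F_tot)


class Rates(NamedTuple):
    R_u: np.ndarray
    R_v: np.ndarray
    R_f: np.ndarray


def production_rate(u, f, params: ModelParams, k_s=0.0):
    """Total GDP→GTP activation rate b + c1·H(u;K1) + c2·H(f;K2) + k_s."""
    return params.b + hill(u, params.c1, params.K1) + hill(f, params.c2, params.K2) + k_s


def reaction_rates(u, v, f, mt, k_s, params: ModelParams) -> Rates:
    """Pointwise reaction rates (R_u, R_v, R_f).

    R_u = (b + c1·H(u;K1) + c2·H(f;K2) + k_s)·v − r·u
    R_v = −R_u                     (local Rac conservation)
    R_f = c3·H(u;K3)·K_F/(K_F+mt) − d_f·f
    """
    if mt is not None and np.any(np.asarray(mt) <= 0):
        raise ValueError("membrane tension must be positive")
    R_u = production_rate(u, f, params, k_s) * np.asarray(v, dtype=float) \
        - params.r * np.asarray(u, dtype=float)
    R_f = hill(u, params.c3, params.K3) * tension_factor(mt, params) \
        - params.d_f * np.asarray(f, dtype=float)
    return Rates(R_u, -R_u, R_f)


def f_quasi_steady(u, mt, params: ModelParams):
    """F-actin level with polymerization and decay balanced at fixed u, mt."""
    return hill(u, params.c3, params.K3) * tension_factor(mt, params) / params.d_f


def f_membrane_level(u, mt, params: ModelParams):
    """Steady F-actin concentration at the membrane for membrane u and tension mt.

    F-actin is produced on the interface layer and decays while diffusing
    into the cytosol; the source is one-sided (no outward flux through the
    cell boundary), so the 1D balance D_f f'' = d_f f with boundary flux
    c3·H(u;K3)·K_F/(K_F+mt) gives the interface value

        f_mem = c3·H(u;K3)·K_F/(K_F+mt) / √(D_f·d_f).

    This closure — not the well-mixed ``f_quasi_steady`` — is what sets the
    F-actin level felt by the Rac kinetics at the cell front, and is used as
    the default f-closure when locating the bistable levels u_L, u_H.
    """
    flux = hill(u, params.c3, params.K3) * tension_factor(mt, params)
    return flux / np.sqrt(params.D_f * params.d_f)


class FixedPoints(NamedTuple):
    roots: list        # ascending steady u values
    stable: list       # parallel stability flags (sign test on R_u)


def well_mixed_fixed_points(v0: float, params: ModelParams, *,
                            f_level: float | None = None,
                            mt: float | None = None,
                            u_max_factor: float = 10.0,
                            n_scan: int = 4000) -> FixedPoints:
    """Steady u values of the well-mixed kinetics at fixed Rac-GDP level v0.

    By default F-actin is slaved to u through the membrane surface-source
    closure ``f_membrane_level`` under tension ``mt`` (basal mt0 unless
    given); passing ``f_level`` instead freezes f at that value.  Roots are
    found by a dense sign-change scan of R_u on [0, u_max_factor·u0] with
    Brent refinement of each bracket; in the bistable regime this returns
    three roots (u_L, u_mid, u_H) with the outer pair stable.
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    mt_val = params.mt0 if mt is None else mt

    def R_u(u: float) -> float:
        f = f_level if f_level is not None else f_membrane_level(u, mt_val, params)
        return float(production_rate(u, f, params) * v0 - params.r * u)

    u_hi = u_max_factor * max(params.u0, 1.0)
    grid = np.linspace(0.0, u_hi, n_scan)
    vals = np.array([R_u(u) for u in grid])
    roots: list[float] = []
    for i in range(n_scan - 1):
        a, fa = grid[i], vals[i]
        b_, fb = grid[i + 1], vals[i + 1]
        if fa == 0.0:
            roots.append(float(a))
        elif fa * fb < 0:
            roots.append(float(brentq(R_u, a, b_, xtol=1e-12)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    if not roots:
        raise RuntimeError(
            f"no steady state found on [0, {u_hi}]; R_u range "
            f"[{vals.min():.3g}, {vals.max():.3g}]")
    # dedupe near-identical roots
    uniq: list[float] = []
    for rt in sorted(roots):
        if not uniq or rt - uniq[-1] > 1e-9 * (1 + u_hi):
            uniq.append(rt)
    h = 1e-6 * (1 + u_hi)
    stable = [R_u(rt + h) < 0 < R_u(max(rt - h, 0.0) + (0.0 if rt > h else -1))
              if rt > h else R_u(rt + h) < 0
              for rt in uniq]
    # recompute cleanly: stable iff R_u decreasing through the root
    stable = [(R_u(rt + h) < 0) and (rt <= h or R_u(rt - h) > 0) for rt in uniq]
    return FixedPoints(uniq, stable)


def bistable_levels(params: ModelParams, *, mt: float | None = None) -> tuple[float, float]:
    """(u_L, u_H): outer stable fixed points at the background Rac-GDP v0."""
    fp = well_mixed_fixed_points(params.v0, params, mt=mt)
    stable_roots = [rt for rt, s in zip(fp.roots, fp.stable) if s]
    if len(stable_roots) < 2:
        raise RuntimeError(
            f"kinetics not bistable at v0={params.v0}: roots={fp.roots}")
    return stable_roots[0], stable_roots[-1]
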