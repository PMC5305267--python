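"""Synthetic inputs and analytic reference cases for testing.

Everything here is generated programmatically from a name and a seed; no
external data is required anywhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .params import ModelParams
from .geometry import PhaseFieldGeometry, make_disk
from .solver import CellState, homogeneous_state
from .experiments import noisy_initial_state, threshold_search


@dataclass
class Fixture:
    name: str
    params: ModelParams
    geometry: Optional[PhaseFieldGeometry] = None
    initial: Optional[CellState] = None
    protocol: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)
    seed: int = 0


def make_diffusion_fixture(D: float, mode_index: int, L: float = 40.0,
                           N: int = 64) -> Fixture:
    """Single Fourier cosine mode with analytic decay rate D·(2π·mode/L)².

    Used against the solver in its uniform-weight (constant-coefficient)
    configuration, where the spectral propagator is exact.
    """
    if mode_index <= 0 or mode_index >= N // 2:
        raise ValueError("mode aliased or non-positive on this grid")
    params = ModelParams(D_u=D if D > 0 else 1e-12, L=L, N=N,
                         D_f=max(2 * D, 1e-6), D_v=max(400 * D, 1e-3),
                         eps=max(1.0, 2 * L / N))
    # unit background plus the test mode: keeps the field non-negative (the
    # k=0 background is preserved exactly; the mode amplitude is read off as
    # half the peak-to-trough range)
    x = np.arange(N) * (L / N)
    field_u = 1.0 + np.cos(2 * np.pi * mode_index * x / L)[:, None] \
        * np.ones(N)[None, :]
    phi = np.ones((N, N))
    geom = PhaseFieldGeometry(L=L, N=N, eps=params.eps, phi=phi,
                              center=(L / 2, L / 2))
    st = CellState(u=field_u.copy(), v=np.zeros((N, N)), f=np.zeros((N, N)),
                   mt=params.mt0)
    decay = D * (2 * np.pi * mode_index / L) ** 2
    return Fixture(name=f"diffusion-D{D}-m{mode_index}", params=params,
                   geometry=geom, initial=st,
                   expected={"decay_rate": decay,
                             "amplitude_ratio_t1": math.exp(-decay)})


def make_polarization_fixture(mt0: float, supra: bool, params: ModelParams
                              | None = None, *, ks_dur: float = 25.0,
                              threshold: float | None = None,
                              factor_supra: float = 1.2,
                              factor_sub: float = 0.8, **search_kw) -> Fixture:
    """Graded-stimulus fixture at 1.2× (supra) or 0.8× (sub) the threshold
    amplitude for the given basal tension; expected outcome attached."""
    p = (params or ModelParams()).with_updates(mt0=mt0)
    if threshold is None:
        threshold = threshold_search(p, ks_dur, **search_kw)
    amp = threshold * (factor_supra if supra else factor_sub)
    return Fixture(name=f"polarization-mt{mt0}-{'supra' if supra else 'sub'}",
                   params=p,
                   protocol={"kind": "graded", "ks_amp": amp,
                             "ks_dur": ks_dur, "direction": 0},
                   expected={"polarized": supra, "threshold": threshold})


def make_noise_initial_state(seed: int, noise_var: float,
                             params: ModelParams,
                             geometry: PhaseFieldGeometry | None = None
                             ) -> CellState:
    """Homogeneous initial state with Gaussian noise of variance
    ``noise_var`` added independently to u and v (clipped at zero)."""
    if noise_var < 0:
        raise ValueError("noise variance must be non-negative")
    g = geometry if geometry is not None else make_disk(params)
    if noise_var == 0.0:
        return homogeneous_state(g, params)
    return noisy_initial_state(g, params, seed=seed,
                               noise_sd=math.sqrt(noise_var))
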