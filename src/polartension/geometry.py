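"""Phase-field representations of cell shapes on a periodic grid.

A shape is encoded by a smooth indicator φ ∈ [0,1] whose diffuse layer of
width ε is the membrane.  Membrane-localized quantities are weighted by
B(φ) = φ²(1−φ)² or by |∇φ|; both vanish away from the interface.  For the
reference disk,

    φ(x, y) = ½·(tanh((R − ρ)/ε) + 1),   ρ = distance to the cell center.

Coordinates used by stimuli are cell-centered (x = y = 0 at the center).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams


def _spectral_gradient_mag(phi: np.ndarray, L: float) -> np.ndarray:
    """|∇φ| by spectral differentiation on the periodic grid."""
    N = phi.shape[0]
    k = 2.0 * np.pi * np.fft.fftfreq(N, d=L / N)
    kx = k[:, None]
    ky = k[None, :]
    ph = np.fft.fft2(phi)
    gx = np.real(np.fft.ifft2(1j * kx * ph))
    gy = np.real(np.fft.ifft2(1j * ky * ph))
    return np.hypot(gx, gy)


def membrane_measures(phi: np.ndarray, L: float | None = None):
    """Return (B(φ), |∇φ|).  ``L`` is needed for the spectral gradient."""
    if np.any(phi < -1e-9) or np.any(phi > 1 + 1e-9):
        raise ValueError("phi must lie in [0, 1]")
    Bphi = phi ** 2 * (1.0 - phi) ** 2
    if L is None:
        return Bphi, None
    return Bphi, _spectral_gradient_mag(phi, L)


@dataclass
class PhaseFieldGeometry:
    """Grid, phase field and derived membrane/cytosol weights for one shape."""

    L: float
    N: int
    eps: float
    phi: np.ndarray
    center: tuple[float, float]
    Bphi: np.ndarray = field(init=False)
    grad_phi_mag: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        phi = np.clip(self.phi, 0.0, 1.0)
        self.phi = phi
        self.Bphi, self.grad_phi_mag = membrane_measures(phi, self.L)
        # spectral differentiation of a clipped field can produce tiny
        # negative overshoots; |∇φ| is non-negative by construction
        np.maximum(self.grad_phi_mag, 0.0, out=self.grad_phi_mag)

    @property
    def dx(self) -> float:
        return self.L / self.N

    @property
    def dA(self) -> float:
        return self.dx ** 2

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centered coordinate arrays (x along axis 0, y along axis 1)."""
        coords = np.arange(self.N) * self.dx
        return coords - self.center[0], coords - self.center[1]

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        cached = getattr(self, "_mesh_cache", None)
        if cached is None:
            x, y = self.axes()
            cached = np.meshgrid(x, y, indexing="ij")
            object.__setattr__(self, "_mesh_cache", cached)
        return cached

    @property
    def area(self) -> float:
        """φ-weighted area Σ φ·ΔA (cytosolic area)."""
        return float(np.sum(self.phi)) * self.dA

    def interior_mask(self, level: float = 0.5) -> np.ndarray:
        return self.phi > level


def _check_resolution(params: ModelParams) -> None:
    if params.eps < 2 * params.L / params.N:
        raise ValueError("interface unresolved: eps < 2 grid spacings")


def make_disk(params: ModelParams) -> PhaseFieldGeometry:
    """Disk of radius R centered in the periodic domain."""
    _check_resolution(params)
    if params.R + 3 * params.eps >= params.L / 2:
        raise ValueError("disk too large: R + 3·eps must be < L/2")
    N, L = params.N, params.L
    c = (L / 2.0, L / 2.0)
    coords = np.arange(N) * (L / N)
    X, Y = np.meshgrid(coords - c[0], coords - c[1], indexing="ij")
    rho = np.hypot(X, Y)
    phi = 0.5 * (np.tanh((params.R - rho) / params.eps) + 1.0)
    return PhaseFieldGeometry(L=L, N=N, eps=params.eps, phi=phi, center=c)


def _smooth_indicator(signed_dist: np.ndarray, eps: float) -> np.ndarray:
    """tanh-smoothed indicator of {signed_dist > 0} with layer width eps."""
    return 0.5 * (np.tanh(signed_dist / eps) + 1.0)


def make_tethered(params: ModelParams, *,
                  body_radius: float = 6.0,
                  neck_length: float = 10.0,
                  neck_halfwidth: float = 1.0,
                  pseudopod_radius: float = 3.5) -> PhaseFieldGeometry:
    """Pseudopod–neck–body shape: two disks joined by a thin rectangular neck.

    The pseudopod sits at positive x, the body at negative x, joined by a
    neck of length ``neck_length`` (between the disk rims) and half-width
    ``neck_halfwidth`` along the x axis.  The neck must be wide enough to
    resolve (≥ 2 grid spacings) so diffusion is restricted but not cut.
    φ is the tanh smoothing of the signed distance to the union.
    """
    _check_resolution(params)
    for name, val in [("body_radius", body_radius), ("neck_length", neck_length),
                      ("neck_halfwidth", neck_halfwidth),
                      ("pseudopod_radius", pseudopod_radius)]:
        if val <= 0:
            raise ValueError(f"{name} must be positive")
    dx = params.L / params.N
    if neck_halfwidth < dx:
        raise ValueError("neck narrower than 2 grid spacings")
    extent = 2 * body_radius + neck_length + 2 * pseudopod_radius
    if extent + 3 * params.eps >= params.L:
        raise ValueError("tethered shape does not fit in the domain")

    N, L = params.N, params.L
    c = (L / 2.0, L / 2.0)
    coords = np.arange(N) * (L / N)
    X, Y = np.meshgrid(coords - c[0], coords - c[1], indexing="ij")

    # place body center and pseudopod center so the whole shape is centered
    x_body = -(extent / 2.0 - body_radius)
    x_pod = extent / 2.0 - pseudopod_radius
    d_body = body_radius - np.hypot(X - x_body, Y)
    d_pod = pseudopod_radius - np.hypot(X - x_pod, Y)
    # rectangle spanning the two centers
    dx_rect = np.minimum(X - x_body, x_pod - X)
    d_neck = np.minimum(dx_rect, neck_halfwidth - np.abs(Y))
    signed = np.maximum(np.maximum(d_body, d_pod), d_neck)
    phi = _smooth_indicator(signed, params.eps)
    return PhaseFieldGeometry(L=L, N=N, eps=params.eps, phi=phi, center=c)


def sever(geometry: PhaseFieldGeometry, cut_x: float, *,
          eps: float | None = None):
    """Split a shape by the plane x = cut_x (cell-centered coordinate).

    Returns ``(front, body)`` geometries whose φ fields are the original φ
    multiplied by tanh-smoothed half-space indicators on either side of the
    cut; supports are disjoint and no material support is created.
    """
    eps = geometry.eps if eps is None else eps
    X, _ = geometry.meshgrid()
    # half-width of the cut gap: half the interface width, so the two pieces
    # separate cleanly within ~eps of the plane
    ind_front = _smooth_indicator(X - cut_x, eps)
    ind_body = 1.0 - ind_front
    col = int(round((cut_x + geometry.center[0]) / geometry.dx))
    if not (0 < col < geometry.N - 1) or geometry.phi[col, :].max() < 0.5:
        raise ValueError("cut plane does not cross the cell")
    front = PhaseFieldGeometry(L=geometry.L, N=geometry.N, eps=geometry.eps,
                               phi=geometry.phi * ind_front, center=geometry.center)
    body = PhaseFieldGeometry(L=geometry.L, N=geometry.N, eps=geometry.eps,
                              phi=geometry.phi * ind_body, center=geometry.center)
    return front, body
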