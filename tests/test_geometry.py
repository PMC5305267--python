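"""Phase-field shapes: disk, tethered morphology, severing, measures."""

import numpy as np
import pytest

from polartension import ModelParams, make_disk, make_tethered, sever
from polartension.geometry import membrane_measures


class TestDisk:
    def test_phi_center_and_rim(self, params_small, disk_small):
        g, p = disk_small, params_small
        c = g.N // 2
        assert g.phi[c, c] == pytest.approx(
            0.5 * (np.tanh(p.R / p.eps) + 1.0), abs=1e-9)
        # at distance R from the center phi = 1/2
        i = int(round((p.L / 2 + p.R) / g.dx))
        X, Y = g.meshgrid()
        rho = np.hypot(X[i, c], Y[i, c])
        expected = 0.5 * (np.tanh((p.R - rho) / p.eps) + 1.0)
        assert g.phi[i, c] == pytest.approx(expected, abs=1e-9)
        assert abs(expected - 0.5) < 0.2  # grid point near the rim

    def test_area_matches_disk(self):
        p = ModelParams(N=128, L=40.0, R=10.0, eps=1.0)
        g = make_disk(p)
        assert g.area == pytest.approx(np.pi * p.R ** 2, rel=0.02)

    def test_area_convergence_structure(self):
        """Grid refinement at fixed ε is already converged (the tanh profile
        is smooth), and the residual offset from πR² is the O(ε²) smoothing
        bias: halving ε shrinks it about fourfold."""
        target = np.pi * 100.0
        a96 = make_disk(ModelParams(N=96, eps=1.0)).area
        a192 = make_disk(ModelParams(N=192, eps=1.0)).area
        assert abs(a192 - a96) < 1e-6 * target
        e_full = abs(a192 - target)
        e_half = abs(make_disk(ModelParams(N=192, eps=0.5)).area - target)
        assert e_half == pytest.approx(e_full / 4.0, rel=0.3)

    def test_unresolved_interface_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(N=32, eps=1.0)


class TestMembraneMeasures:
    def test_B_values(self):
        B, _ = membrane_measures(np.array([[0.0, 0.5, 1.0]]))
        assert B[0, 0] == 0.0
        assert B[0, 1] == pytest.approx(0.0625)
        assert B[0, 2] == 0.0

    def test_gradient_peak_matches_analytic(self):
        # d/dρ of ½(tanh((R−ρ)/ε)+1) has maximum magnitude 1/(2ε)
        p = ModelParams(N=256, eps=1.0)
        g = make_disk(p)
        assert g.grad_phi_mag.max() == pytest.approx(1.0 / (2 * p.eps),
                                                     rel=0.05)

    def test_measures_vanish_away_from_interface(self, disk_small):
        g = disk_small
        X, Y = g.meshgrid()
        rho = np.hypot(X, Y)
        far = (rho < g.eps) | (rho > 18.0)
        assert g.Bphi[far].max() < 1e-6
        assert g.grad_phi_mag[far].max() < 1e-4

    def test_interface_measure_scales_with_eps(self):
        # ∫B(φ) along a normal section is proportional to ε
        totals = []
        for eps, N in [(1.0, 128), (2.0, 128)]:
            g = make_disk(ModelParams(N=N, eps=eps))
            totals.append(g.Bphi.sum() * g.dA)
        assert totals[1] / totals[0] == pytest.approx(2.0, rel=0.05)


class TestTethered:
    def test_body_and_neck_interior(self, params_small):
        p = params_small
        g = make_tethered(p, body_radius=6.0, neck_length=10.0,
                          neck_halfwidth=2.0, pseudopod_radius=3.5)
        X, Y = g.meshgrid()
        extent = 2 * 6.0 + 10.0 + 2 * 3.5
        x_body = -(extent / 2 - 6.0)
        i = int(round((x_body + p.L / 2) / g.dx))
        j = g.N // 2
        assert g.phi[i, j] > 0.99                      # body center
        i_mid = g.N // 2                               # neck midline (x≈0)
        assert g.phi[i_mid, j] > 0.9
        j_off = j + int(round((2.0 + 3 * p.eps) / g.dx))
        assert g.phi[i_mid, j_off] < 0.1               # off the neck

    def test_zero_neck_equals_disk_union_area(self):
        p = ModelParams(N=128, eps=1.0)
        r = 5.0
        g = make_tethered(p, body_radius=r, neck_length=1e-9,
                          neck_halfwidth=p.L / p.N + 1e-6, pseudopod_radius=r)
        # Monte-Carlo oracle for the union of the two analytic (tangent) disks
        rng = np.random.default_rng(7)
        extent = 4 * r + 1e-9
        xc = extent / 2 - r
        pts = rng.uniform(-p.L / 2, p.L / 2, size=(200000, 2))
        inside = (np.hypot(pts[:, 0] + xc, pts[:, 1]) <= r) | \
                 (np.hypot(pts[:, 0] - xc, pts[:, 1]) <= r)
        mc_area = inside.mean() * p.L ** 2
        # the diffuse interface carries an O(ε²) smoothing bias on top of the
        # Monte-Carlo sharp-union area
        assert g.area == pytest.approx(mc_area, rel=0.05)

    def test_narrow_neck_rejected(self, params_small):
        with pytest.raises(ValueError):
            make_tethered(params_small, neck_halfwidth=1e-3)


class TestSever:
    def test_partition_of_support(self, params_small):
        g = make_tethered(params_small, neck_halfwidth=1.5)
        front, body = sever(g, cut_x=2.0)
        assert np.all(front.phi + body.phi <= g.phi + 1e-9)
        # pieces live on opposite sides of the cut
        X, _ = g.meshgrid()
        assert front.phi[X < -2.0].max() < 0.05
        assert body.phi[X > 6.0].max() < 0.05

    def test_mass_preserved_at_cut(self, params_small, rng):
        g = make_tethered(params_small, neck_halfwidth=1.5)
        v = 6.0 * np.ones_like(g.phi)
        total = (g.phi * v).sum() * g.dA
        front, body = sever(g, cut_x=2.0)
        split = ((front.phi * v).sum() + (body.phi * v).sum()) * g.dA
        assert split == pytest.approx(total, rel=0.01)

    def test_disk_center_cut_gives_half_areas(self, params_small, disk_small):
        front, body = sever(disk_small, cut_x=0.0)
        assert front.area == pytest.approx(body.area, rel=0.02)
        assert front.area + body.area == pytest.approx(disk_small.area,
                                                       rel=0.02)

    def test_cut_outside_cell_rejected(self, disk_small):
        with pytest.raises(ValueError):
            sever(disk_small, cut_x=15.0)
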