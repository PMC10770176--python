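"""Transport operators: masked diffusion, upwind advection, uptake kinetics,
steady-state oxygen, activation, drug/sensitizer steps, vessel boundary."""

import numpy as np
import pytest

import hapsim as hs
from hapsim.transport import StabilityError, make_fields
from conftest import masked_domain, uniform_flow


def field(name, values, d, decay=0.0):
    return hs.ScalarField(name, np.asarray(values, dtype=float), d, decay)


class TestMaskedDiffusion:
    def test_uniform_field_unchanged(self, small_domain, params):
        f = field("oxygen", np.full(small_domain.grid.shape, 7.0), 100.0)
        f.values[small_domain.interior_mask] = 0.0
        out = hs.masked_diffusion_step(f, small_domain, dt=1e-3)
        interstitial = ~small_domain.interior_mask
        np.testing.assert_allclose(out.values[interstitial], 7.0)

    def test_hand_oracle_one_masked_neighbor(self):
        """Single hot node with one in-cell neighbor: the 3-neighbor update
        gives c·(1 − 3ν) with the masked direction omitted entirely."""
        grid = hs.GridSpec(0, 8, 0, 8, 2.0)
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True                      # neighbor above center is in-cell
        dom = masked_domain(grid, mask)
        c = np.zeros((5, 5))
        c[2, 2] = 4.0
        nu = 0.1
        dt = nu * 4.0 / 50.0                   # D=50: dt·D/h² = nu
        out = hs.masked_diffusion_step(field("x", c, 50.0), dom, dt)
        assert out.values[2, 2] == pytest.approx(4.0 * (1 - 3 * nu))
        assert out.values[2, 3] == 0.0         # mass never enters the cell
        assert out.values[2, 1] == pytest.approx(4.0 * nu)

    def test_exhaustive_5x5_stencil_oracle(self):
        """One full masked step on a random 5×5 grid equals an independently
        coded omit-in-cell-neighbors update, node by node."""
        rng = np.random.default_rng(12)
        grid = hs.GridSpec(0, 8, 0, 8, 2.0)
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 1] = mask[3, 2] = True
        dom = masked_domain(grid, mask)
        c = rng.uniform(0, 10, (5, 5))
        c[mask] = 0.0
        nu = 0.2
        out = hs.masked_diffusion_step(field("x", c, 50.0), dom, nu * 4 / 50.0)
        expected = c.copy()
        for i in range(5):
            for j in range(5):
                if mask[i, j]:
                    expected[i, j] = 0.0
                    continue
                acc = 0.0
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < 5 and 0 <= jj < 5 and not mask[ii, jj]:
                        acc += c[ii, jj] - c[i, j]
                expected[i, j] += nu * acc
        np.testing.assert_allclose(out.values, expected, atol=1e-14)

    def test_mass_conserved_under_reflecting_boundaries(self, small_domain):
        rng = np.random.default_rng(5)
        c = rng.uniform(0, 3, small_domain.grid.shape)
        c[small_domain.interior_mask] = 0.0
        f = field("x", c, 400.0)
        total0 = f.values.sum()
        for _ in range(20):
            f = hs.masked_diffusion_step(f, small_domain, dt=1e-3)
            assert f.values.sum() == pytest.approx(total0, rel=1e-12)

    def test_substepping_keeps_maximum_principle(self, small_domain):
        """dt·D/h² = 0.375 (the model default for oxygen) produces no new
        extrema thanks to internal substepping."""
        rng = np.random.default_rng(8)
        c = rng.uniform(0, 60, small_domain.grid.shape)
        c[small_domain.interior_mask] = 0.0
        f = field("oxygen", c.copy(), 1000.0)
        out = hs.masked_diffusion_step(f, small_domain, dt=1.5e-3)
        free = ~small_domain.interior_mask
        assert out.values[free].max() <= c[free].max() + 1e-12
        assert out.values[free].min() >= c[free].min() - 1e-12

    def test_stability_contract_violation(self, small_domain):
        f = field("x", np.zeros(small_domain.grid.shape), 1000.0)
        with pytest.raises(StabilityError, match="0.5"):
            hs.masked_diffusion_step(f, small_domain, dt=3e-3)


class TestUpwindAdvection:
    def test_zero_velocity_identity(self, small_domain, zero_flow):
        rng = np.random.default_rng(3)
        c = rng.uniform(0, 5, small_domain.grid.shape)
        c[small_domain.interior_mask] = 0.0
        out = hs.upwind_advection_step(field("x", c, 1.0), zero_flow,
                                       small_domain, dt=1e-3)
        np.testing.assert_array_equal(out.values, c)

    def test_front_advances_and_tv_nonincreasing(self, empty_domain):
        g = empty_domain.grid
        c = np.zeros(g.shape)
        c[:5, :] = 1.0
        flow = uniform_flow(g, 40.0)
        f = field("x", c, 1.0)
        dt = 0.01                               # CFL 0.2

        def tv(a):
            return np.abs(np.diff(a[:, 0])).sum()

        tv0 = tv(f.values)
        for _ in range(50):
            f = hs.upwind_advection_step(f, flow, empty_domain, dt)
        # front center moved right by ~u·t = 20 μm = 10 nodes
        mid = f.values[:, g.n_j // 2]
        assert mid[10] > 0.5 and mid[5] > 0.9
        assert tv(f.values) <= tv0 + 1e-12

    def test_column_against_semi_lagrangian_reference(self, empty_domain):
        """1D advection at CFL 0.1 vs an independent semi-Lagrangian
        interpolation scheme: agreement within the first-order error bound."""
        g = empty_domain.grid
        x = g.node_x()
        profile = np.exp(-((x - 20.0) ** 2) / 30.0)
        c = np.tile(profile[:, None], (1, g.n_j))
        u, dt, n = 20.0, 0.01, 100                # CFL 0.1, t = 1 min
        f = field("x", c.copy(), 1.0)
        flow = uniform_flow(g, u)
        for _ in range(n):
            f = hs.upwind_advection_step(f, flow, empty_domain, dt)
        # independent semi-Lagrangian reference on the same column
        ref = profile.copy()
        for _ in range(n):
            ref = np.interp(x - u * dt, x, ref, left=0.0)
        got = f.values[:, g.n_j // 2]
        l1 = np.abs(got - ref).sum() * g.h
        # first-order schemes at CFL 0.1: numerical diffusion u·h/2·t smears
        # the pulse; the two schemes must stay within that envelope
        assert l1 < 0.5 * np.abs(profile).sum() * g.h * 0.25

    def test_cfl_violation_rejected(self, empty_domain):
        flow = uniform_flow(empty_domain.grid, 300.0)
        f = field("x", np.zeros(empty_domain.grid.shape), 1.0)
        with pytest.raises(StabilityError, match="CFL"):
            hs.upwind_advection_step(f, flow, empty_domain, dt=0.01)


class TestUptakeKinetics:
    def test_baseline_and_tiered_rates(self, params):
        # normoxic, no sensitizer: the baseline 0.85 mmHg/min
        assert hs.oxygen_uptake_rate(60.0, 0.0, params) == pytest.approx(0.85)
        # sensitizer tier [ξ_1, ξ_2): 0.85·(7.5/3)
        assert hs.oxygen_uptake_rate(60.0, 50.0, params) == pytest.approx(2.125)
        # severe hypoxia: linear ramp to zero, continuous at the branch point
        assert hs.oxygen_uptake_rate(4.0, 0.0, params) == pytest.approx(0.68)
        assert hs.oxygen_uptake_rate(5.0, 0.0, params) == pytest.approx(0.85)

    def test_tier_boundaries_inclusive_left(self, params):
        psi = np.array(params.psi)
        for k, edge in enumerate(params.xi_tiers):
            assert hs.oxygen_uptake_rate(60.0, edge, params) == pytest.approx(
                0.85 * psi[k + 1])
            assert hs.oxygen_uptake_rate(60.0, edge - 1e-9, params) == pytest.approx(
                0.85 * psi[k])

    def test_activation_gate_values(self, params):
        assert hs.activation_rate(5.0, params) == pytest.approx(0.9)
        assert hs.activation_rate(60.0, params) == 0.0
        # the hypoxia threshold itself activates (inclusive gate)
        assert hs.activation_rate(10.0, params) == pytest.approx(0.9)

    def test_activation_continuous_rate_mode(self):
        p = hs.TransportParams(activation_mode="per_min")
        assert hs.activation_rate(5.0, p) == pytest.approx(0.9 * p.dt)


class TestSteadyStateOxygen:
    def test_linear_profile_without_cells_or_flow(self, empty_domain, params,
                                                  vessel_bc, zero_flow):
        oxy = hs.steady_state_oxygen(empty_domain, zero_flow, params, vessel_bc)
        g = empty_domain.grid
        x = g.node_x()
        expected = vessel_bc.gamma_in * (g.x_max - x) / (g.x_max - g.x_min)
        profile = oxy.values[:, g.n_j // 2]
        np.testing.assert_allclose(profile, expected, atol=1e-6)

    def test_advective_profile_matches_closed_form(self, empty_domain, params,
                                                   vessel_bc):
        """Steady advection–diffusion in an empty channel vs the exact
        two-point boundary-value solution (upwind adds u·h/2 of numerical
        diffusion, which sets the comparison tolerance)."""
        u = 30.0
        flow = uniform_flow(empty_domain.grid, u)
        oxy = hs.steady_state_oxygen(empty_domain, flow, params, vessel_bc)
        g = empty_domain.grid
        x = g.node_x()
        L = g.x_max - g.x_min

        def exact(d):
            a = np.exp(u * L / d)
            return vessel_bc.gamma_in * (a - np.exp(u * x / d)) / (a - 1.0)

        got = oxy.values[:, g.n_j // 2]
        assert np.abs(got - exact(params.d_gamma)).max() < 0.05 * vessel_bc.gamma_in
        # the modified-equation solution (D + u·h/2) is a much closer match
        assert np.abs(got - exact(params.d_gamma + u * g.h / 2)).max() \
            < 0.01 * vessel_bc.gamma_in

    def test_dense_tissue_monotone_profile_with_hypoxia(self, small_domain,
                                                        small_flow, params,
                                                        vessel_bc, small_steady):
        cols = hs.strip_average_profile(small_steady, small_domain)
        valid = ~np.isnan(cols)
        smoothed = np.convolve(cols[valid], np.ones(3) / 3, mode="valid")
        assert (np.diff(smoothed) < 1.0).all()      # decreasing up to noise
        assert np.nanmin(cols) < params.gamma_hyp   # hypoxic region exists
        border = hs.hypoxia_border(small_steady, small_domain)
        assert 0 < border < small_domain.grid.x_max


class TestDrugAndSensitizerSteps:
    def test_pure_decay_half_life(self, params):
        """Uniform active drug, no cells, no influx: the concentration far
        from the open boundary halves every 10 minutes."""
        dom = hs.generate_synthetic_tissue(hs.GridSpec(), n_cells=0, seed=1)
        flow = hs.FlowField(ux=np.zeros(dom.grid.shape),
                            uy=np.zeros(dom.grid.shape))
        fields = make_fields(dom, params)
        fields["active_drug"].values[:] = 8.0
        oxygen = field("oxygen", np.full(dom.grid.shape, 60.0), params.d_gamma)
        dt = 0.02
        for _ in range(500):                        # 10 minutes
            _, ea, _ = hs.drug_step(fields["inactive_drug"],
                                    fields["active_drug"], oxygen, flow, dom,
                                    None, params, dt)
            fields["active_drug"] = ea
        center = fields["active_drug"].values[dom.grid.n_i // 2, dom.grid.n_j // 2]
        assert center == pytest.approx(4.0, rel=5e-3)

    def test_activation_transfers_mass_exactly(self, zero_flow, small_grid):
        params = hs.TransportParams(omega_a=0.0)   # isolate the activation term
        dom = hs.generate_synthetic_tissue(small_grid, n_cells=0, seed=1)
        fields = make_fields(dom, params)
        ei = fields["inactive_drug"]
        ei.values[10:20, 5:15] = 3.0               # compact blob, away from edges
        gamma = np.full(small_grid.shape, 60.0)
        gamma[12:17, 8:12] = 5.0                   # hypoxic pocket
        oxygen = field("oxygen", gamma, params.d_gamma)
        total0 = ei.values.sum()
        ei2, ea2, book = hs.drug_step(ei, fields["active_drug"], oxygen,
                                      zero_flow, dom, None, params, params.dt)
        assert (ei2.values + ea2.values).sum() == pytest.approx(total0, rel=1e-12)
        assert ea2.values[14, 10] > 0.0
        produced_outside = ea2.values[(gamma > params.gamma_hyp)]
        assert np.all(produced_outside[np.isfinite(produced_outside)] <= 1e-15)

    def test_no_activation_above_threshold(self, params, zero_flow, small_grid):
        dom = hs.generate_synthetic_tissue(small_grid, n_cells=0, seed=1)
        fields = make_fields(dom, params)
        fields["inactive_drug"].values[:] = 5.0
        oxygen = field("oxygen", np.full(small_grid.shape, 60.0), params.d_gamma)
        for _ in range(10):
            ei, ea, _ = hs.drug_step(fields["inactive_drug"],
                                     fields["active_drug"], oxygen, zero_flow,
                                     dom, None, params, params.dt)
            fields["inactive_drug"], fields["active_drug"] = ei, ea
        assert fields["active_drug"].values.max() == 0.0

    def test_sensitizer_mass_nonincreasing_after_clearance(self, small_domain,
                                                           zero_flow, params):
        xi = field("sensitizer", np.zeros(small_domain.grid.shape), params.d_xi)
        xi.values[5:15, :] = 50.0
        xi.values[small_domain.interior_mask] = 0.0
        total = xi.values.sum()
        for _ in range(50):
            xi = hs.sensitizer_step(xi, zero_flow, small_domain, params.dt,
                                    influx=None)
            assert xi.values.sum() <= total + 1e-9
            total = xi.values.sum()

    def test_sensitizer_tracks_equal_diffusivity_tracer(self, small_domain,
                                                        small_flow, params):
        """D_ξ = D_γ: the sensitizer and a passive oxygen-like tracer released
        identically evolve identically."""
        init = np.zeros(small_domain.grid.shape)
        xi = field("sensitizer", init.copy(), params.d_xi)
        tracer = field("tracer", init.copy(), params.d_gamma)
        for _ in range(200):
            xi = hs.sensitizer_step(xi, small_flow, small_domain, params.dt,
                                    influx=101.0)
            tracer = hs.sensitizer_step(tracer, small_flow, small_domain,
                                        params.dt, influx=101.0)
        np.testing.assert_array_equal(xi.values, tracer.values)


class TestVesselBoundary:
    def make_fields(self, dom, params):
        f = make_fields(dom, params)
        for v in f.values():
            v.values[~dom.interior_mask] = 1.0
        return f

    def test_baseline_outside_all_windows(self, params, small_domain):
        bc = hs.VesselBC(boluses=[hs.Bolus("HAP", 5, 10)])
        assert hs.boundary_values(bc, 100.0) == (60.0, 0.0, 0.0, 1.0)

    def test_vasodilator_halves_oxygen_influx(self, small_domain, params):
        bc = hs.VesselBC(boluses=[hs.Bolus("Vaso", 5, 25)])
        g, ei, xi, lam = hs.boundary_values(bc, 10.0)
        assert (g, lam) == (30.0, 0.5)
        fields = self.make_fields(small_domain, params)
        hs.apply_vessel_boundary(fields, bc, 10.0, small_domain)
        free0 = ~small_domain.interior_mask[0]
        assert np.all(fields["oxygen"].values[0, free0] == 30.0)

    def test_hap_bolus_overlapping_vasodilator(self, small_domain, params):
        bc = hs.VesselBC(boluses=[hs.Bolus("HAP", 5, 10),
                                  hs.Bolus("Vaso", 0, 25)])
        g, ei, xi, lam = hs.boundary_values(bc, 7.0)
        assert ei == pytest.approx(25.0)           # 0.5 · 50
        fields = self.make_fields(small_domain, params)
        hs.apply_vessel_boundary(fields, bc, 7.0, small_domain)
        free0 = ~small_domain.interior_mask[0]
        assert np.all(fields["inactive_drug"].values[0, free0] == 25.0)

    def test_cleared_compound_not_drained(self, small_domain, params):
        """After its window the vessel stops exchanging a compound: the left
        column keeps its tissue value instead of being pinned to zero."""
        bc = hs.VesselBC(boluses=[hs.Bolus("Sens", 5, 25)])
        fields = self.make_fields(small_domain, params)
        hs.apply_vessel_boundary(fields, bc, 100.0, small_domain)
        free0 = ~small_domain.interior_mask[0]
        assert np.all(fields["sensitizer"].values[0, free0] == 1.0)
        assert np.all(fields["oxygen"].values[0, free0] == 60.0)

    def test_overlapping_duplicate_boluses_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            hs.VesselBC(boluses=[hs.Bolus("HAP", 5, 10), hs.Bolus("HAP", 8, 10)])
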