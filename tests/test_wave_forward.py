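"""Forward wave model: source formulas, scaling, assembly, propagation."""

import numpy as np
import pytest

from scatterbayes.wave_forward import (
    ConfigurationError,
    DomainSpec,
    MediumFields,
    Mesh,
    ObservationGrid,
    Scales,
    SourceSpec,
    StabilityError,
    TimeGrid,
    WaveSolution,
    assemble_system,
    dimensionalize,
    emitter_profile,
    energy_history,
    forward_traces,
    nondimensionalize,
    observe,
    ricker_amplitude,
    solve_wave,
    stable_dt,
)


class TestRicker:
    def test_peak_at_origin(self):
        assert ricker_amplitude(0.0, f0=3.7, fM=12.0) == pytest.approx(3.7)
        t = np.linspace(-0.1, 0.1, 201)
        vals = ricker_amplitude(t, 1.0, 25.0)
        assert np.argmax(vals) == 100

    def test_zero_crossings(self):
        fM = 50.0
        t0 = 1.0 / (np.sqrt(2.0) * np.pi * fM)
        assert ricker_amplitude(t0, 1.0, fM) == pytest.approx(0.0, abs=1e-12)
        assert ricker_amplitude(-t0, 1.0, fM) == pytest.approx(0.0, abs=1e-12)

    def test_even_in_time(self):
        t = np.linspace(0.0, 0.05, 13)
        np.testing.assert_allclose(
            ricker_amplitude(t, 2.0, 50.0), ricker_amplitude(-t, 2.0, 50.0)
        )

    def test_against_high_precision_evaluation(self):
        # independent arbitrary-precision evaluation of the wavelet formula
        sympy = pytest.importorskip("sympy")
        t, fM = sympy.Rational(1, 100), 50
        a = sympy.pi**2 * fM**2 * t**2
        expected = float(((1 - 2 * a) * sympy.exp(-a)).evalf(30))
        assert ricker_amplitude(0.01, 1.0, 50.0) == pytest.approx(expected, rel=1e-12)


class TestEmitterProfile:
    def test_single_source_at_center(self):
        src = SourceSpec(1.0, 1.0, kappa=1.0, centers=[(0.3, 0.0)])
        assert emitter_profile(np.array([[0.3, 0.0]]), src)[0] == pytest.approx(1 / np.pi)

    def test_permutation_invariance(self, rng):
        centers = rng.uniform(-1, 1, size=(5, 2))
        centers[:, 1] = 0.0
        pts = rng.uniform(-2, 2, size=(20, 2))
        a = emitter_profile(pts, SourceSpec(1.0, 1.0, 2.0, centers))
        b = emitter_profile(pts, SourceSpec(1.0, 1.0, 2.0, centers[::-1]))
        np.testing.assert_allclose(a, b)

    def test_two_sources_term_by_term(self):
        # distances 1 and 2 from the evaluation point, kappa = 2
        src = SourceSpec(1.0, 1.0, kappa=2.0, centers=[(1.0, 0.0), (2.0, 0.0)])
        expected = (np.exp(-1.0 / 2.0) + np.exp(-4.0 / 2.0)) / (np.pi * 2.0)
        assert emitter_profile(np.array([[0.0, 0.0]]), src)[0] == pytest.approx(expected)

    def test_strictly_positive(self, rng):
        # positivity within the scale of the emitters (far away the
        # Gaussian underflows to floating-point zero)
        src = SourceSpec(1.0, 1.0, 0.5, [(0.0, 0.0)])
        pts = rng.uniform(-5, 5, size=(50, 2))
        assert np.all(emitter_profile(pts, src) > 0.0)


class TestScaling:
    def test_unit_scales_are_identity(self):
        params = {"mu": (1.69, "modulus"), "fM": (50.0, "frequency"), "x": (3.0, "length")}
        out = nondimensionalize(params, Scales())
        assert out == {"mu": 1.69, "fM": 50.0, "x": 3.0}

    def test_tissue_scales_map_printed_modulus(self):
        # L = 0.01 m, T = 0.01 s, rho0 = 1e3 kg/m^3: mu' = mu T^2/(rho0 L^2)
        scales = Scales(length=0.01, time=0.01, density=1e3)
        out = nondimensionalize({"mu": (1690.0, "modulus")}, scales)
        assert out["mu"] == pytest.approx(1690.0 * 0.01**2 / (1e3 * 0.01**2))
        assert out["mu"] == pytest.approx(1.69)

    def test_round_trip(self, rng):
        scales = Scales(length=0.01, time=0.025, density=2.3e3)
        kinds = ["length", "time", "density", "modulus", "velocity", "frequency", "source_amplitude"]
        vals = rng.uniform(0.1, 10.0, len(kinds))
        params = {k: (v, k) for k, v in zip(kinds, vals)}
        back = dimensionalize(
            {k: (v, k) for k, v in nondimensionalize(params, scales).items()}, scales
        )
        for k, v in zip(kinds, vals):
            assert back[k] == pytest.approx(v, rel=1e-12)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ConfigurationError):
            Scales(length=-1.0)


class TestAssembly:
    def test_stiffness_annihilates_constants(self, tissue_mesh, tissue_medium):
        _, K, _ = assemble_system(tissue_mesh, tissue_medium)
        ones = np.ones(tissue_mesh.n_nodes)
        assert np.abs(K @ ones).max() < 1e-12

    def test_stiffness_linear_in_mu(self, tissue_mesh, tissue_medium):
        _, K1, _ = assemble_system(tissue_mesh, tissue_medium)
        doubled = MediumFields(tissue_medium.rho, 2.0 * tissue_medium.mu)
        _, K2, _ = assemble_system(tissue_mesh, doubled)
        assert abs(K2 - 2 * K1).max() < 1e-12

    def test_p1_element_integrals_match_symbolic_quadrature(self):
        # one-cell mesh; global stiffness assembled independently with sympy
        sympy = pytest.importorskip("sympy")
        mesh = Mesh.regular(DomainSpec((0.0, 1.0), (-1.0, 0.0)), 1, 1)
        fields = MediumFields.homogeneous(mesh, 1.0, 1.0)
        _, K, _ = assemble_system(mesh, fields)

        x, y = sympy.symbols("x y")
        expected = np.zeros((4, 4))
        for tri in mesh.triangles:
            pts = [sympy.Matrix(mesh.coords[i]) for i in tri]
            A = sympy.Matrix.hstack(pts[1] - pts[0], pts[2] - pts[0])
            # P1 shape functions via barycentric coordinates
            # vandermonde rows [1, x_a, y_a]; lam_b(p_a) = delta_ab
            V = sympy.Matrix([[1, p[0], p[1]] for p in pts])
            lam = sympy.Matrix([[1, x, y]]) * V.inv()
            area = abs(A.det()) / 2
            for a in range(3):
                for b in range(3):
                    grad_a = [sympy.diff(lam[a], v) for v in (x, y)]
                    grad_b = [sympy.diff(lam[b], v) for v in (x, y)]
                    expected[tri[a], tri[b]] += float(
                        area * (grad_a[0] * grad_b[0] + grad_a[1] * grad_b[1])
                    )
        np.testing.assert_allclose(K.toarray(), expected, atol=1e-12)

    def test_lumped_mass_totals_rho_area(self, tissue_mesh):
        fields = MediumFields.homogeneous(tissue_mesh, 2.5, 1.0)
        mass, _, _ = assemble_system(tissue_mesh, fields)
        assert mass.sum() == pytest.approx(2.5 * 10.0 * 5.0)

    def test_damping_only_on_artificial_boundary(self, tissue_mesh, tissue_medium):
        _, _, damping = assemble_system(tissue_mesh, tissue_medium)
        x, y = tissue_mesh.coords.T
        on_wall = (
            np.isclose(x, -5.0) | np.isclose(x, 5.0) | np.isclose(y, -5.0)
        )
        assert np.all(damping[~on_wall] == 0.0)
        assert np.all(damping[on_wall] > 0.0)

    def test_size_mismatch_rejected(self, tissue_mesh):
        bad = MediumFields(np.ones(7), np.ones(7))
        with pytest.raises(ConfigurationError):
            assemble_system(tissue_mesh, bad)


class TestSolver:
    def test_zero_source_zero_field(self, tissue_mesh, tissue_medium):
        src = SourceSpec(0.0, 0.5, 2.0, [(0.0, 0.0)])
        tg = TimeGrid.for_duration(2.0, stable_dt(tissue_mesh, tissue_medium))
        sol = solve_wave(tissue_mesh, tissue_medium, src, tg)
        assert np.all(sol.history == 0.0)

    def test_stability_bound_enforced(self, tissue_mesh, tissue_medium, tissue_source):
        dt_bad = 10.0 * stable_dt(tissue_mesh, tissue_medium)
        with pytest.raises(StabilityError):
            solve_wave(tissue_mesh, tissue_medium, tissue_source, TimeGrid(dt_bad, 50))

    def test_field_stays_finite(self, tissue_mesh, tissue_medium, tissue_source):
        tg = TimeGrid.for_duration(4.0, stable_dt(tissue_mesh, tissue_medium))
        sol = solve_wave(tissue_mesh, tissue_medium, tissue_source, tg)
        assert np.all(np.isfinite(sol.history))

    def test_energy_non_increasing_after_source_extinction(
        self, tissue_domain, tissue_source
    ):
        mesh = Mesh.structured(tissue_domain, 0.2)
        fields = MediumFields.homogeneous(mesh, 1.0, 1.69)
        tg = TimeGrid.for_duration(9.0, stable_dt(mesh, fields))
        sol = solve_wave(mesh, fields, tissue_source, tg)
        energy = energy_history(sol, fields)
        late = energy[tg.times[1:-1] > 4.0]  # Ricker support is ~[0, 3] at fM = 0.5
        assert np.all(np.diff(late) <= 1e-6 * energy.max())

    def test_traces_self_converge(self, tissue_domain, tissue_source, surface_observation):
        prev, errs = None, []
        for h in (0.4, 0.2, 0.1):
            mesh = Mesh.structured(tissue_domain, h)
            fields = MediumFields.homogeneous(mesh, 1.0, 1.69)
            tr = forward_traces(mesh, fields, tissue_source, surface_observation).values
            if prev is not None:
                errs.append(np.linalg.norm(tr - prev) / np.linalg.norm(tr))
            prev = tr
        assert errs[1] < errs[0]
        assert np.log2(errs[0] / errs[1]) >= 1.0

    def test_reciprocity_between_source_and_receiver(self):
        # swapping one emitter and one receiver leaves the trace unchanged
        domain = DomainSpec((-6.0, 6.0), (-6.0, 0.0))
        mesh = Mesh.structured(domain, 0.1)
        fields = MediumFields.homogeneous(mesh, 1.0, 1.69)
        a, b = np.array([-2.0, 0.0]), np.array([3.0, 0.0])
        times = np.arange(1.0, 6.0 + 1e-9, 0.05)
        t_ab = forward_traces(
            mesh, fields, SourceSpec(1.0, 0.5, 2.0, [a]), ObservationGrid([b], times)
        ).values
        t_ba = forward_traces(
            mesh, fields, SourceSpec(1.0, 0.5, 2.0, [b]), ObservationGrid([a], times)
        ).values
        assert np.linalg.norm(t_ab - t_ba) / np.linalg.norm(t_ab) < 1e-3


class TestObserve:
    def test_nodal_and_step_coincidence_is_exact(self, tissue_mesh, tissue_medium, tissue_source):
        dt = stable_dt(tissue_mesh, tissue_medium)
        tg = TimeGrid(dt, 40)
        sol = solve_wave(tissue_mesh, tissue_medium, tissue_source, tg)
        node = tissue_mesh.top_nodes()[tissue_mesh.nx // 2]
        grid = ObservationGrid([tissue_mesh.coords[node]], [20 * dt])
        traces = observe(sol, grid)
        assert traces.values[0, 0] == pytest.approx(sol.history[20, node], rel=1e-12)

    def test_zero_field_zero_traces(self, tissue_mesh, tissue_medium):
        src = SourceSpec(0.0, 0.5, 2.0, [(0.0, 0.0)])
        tg = TimeGrid.for_duration(2.0, stable_dt(tissue_mesh, tissue_medium))
        sol = solve_wave(tissue_mesh, tissue_medium, src, tg)
        grid = ObservationGrid([(0.3, -0.7)], np.linspace(0.1, 1.9, 11))
        assert np.all(observe(sol, grid).values == 0.0)

    def test_linear_in_time_history_recovered_exactly(self, tissue_mesh):
        # u(x, t) = t at every node: linear time interpolation is exact
        tg = TimeGrid(0.1, 30)
        history = np.outer(tg.times, np.ones(tissue_mesh.n_nodes))
        sol = WaveSolution(tissue_mesh, tg, history=history)
        times = np.array([0.123, 1.057, 2.71])
        grid = ObservationGrid([(0.2, -1.3)], times)
        np.testing.assert_allclose(observe(sol, grid).values[0], times, rtol=1e-12)

    def test_receiver_outside_domain_rejected(self, tissue_mesh, tissue_medium, tissue_source):
        tg = TimeGrid.for_duration(1.0, stable_dt(tissue_mesh, tissue_medium))
        sol = solve_wave(tissue_mesh, tissue_medium, tissue_source, tg)
        with pytest.raises(ConfigurationError):
            observe(sol, ObservationGrid([(99.0, 0.0)], [0.5]))

    def test_observation_times_must_fit_window(self, tissue_mesh, tissue_medium, tissue_source):
        tg = TimeGrid.for_duration(1.0, stable_dt(tissue_mesh, tissue_medium))
        sol = solve_wave(tissue_mesh, tissue_medium, tissue_source, tg)
        with pytest.raises(ConfigurationError):
            observe(sol, ObservationGrid([(0.0, 0.0)], [5.0]))


class TestDomainAndGrids:
    def test_halfspace_truncation_enforced(self):
        with pytest.raises(ConfigurationError):
            DomainSpec((0.0, 1.0), (0.5, 1.0))

    def test_observation_dimension(self):
        grid = ObservationGrid(np.zeros((3, 2)), [0.1, 0.2, 0.5, 0.9])
        assert grid.dimension == 12

    def test_times_must_increase(self):
        with pytest.raises(ConfigurationError):
            ObservationGrid(np.zeros((1, 2)), [0.5, 0.5, 0.9])

    def test_mesh_covers_domain(self, tissue_mesh):
        areas = tissue_mesh.element_areas()
        assert np.all(areas > 0)
        assert areas.sum() == pytest.approx(50.0)
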