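"""Strain-gated angiogenesis, oxygen diffusion-consumption and cell
colonisation against closed-form oracles."""

import numpy as np
import pytest
from scipy.special import erfcinv

from callusim.cells import CellField, CellParams, update_cells
from callusim.diffusion import ScalarDiffusion
from callusim.fixtures import FixtureSpec, make_fixture
from callusim.transport import (
    TransportParams,
    VesselField,
    supplied_elements,
    update_oxygen,
    update_vessels,
)


@pytest.fixture(scope="module")
def strip():
    fx = make_fixture(FixtureSpec(kind="strip_1d", size=100, length=10.0))
    return fx.mesh, ScalarDiffusion(fx.mesh), fx.source_nodes


@pytest.fixture()
def params():
    return TransportParams()


class TestUnitConversions:
    def test_defaults_and_derived_units(self, params):
        assert params.G_mm2_per_day == pytest.approx(2.2e-9 * 1e6 * 86400)
        assert params.o2_cartilage_mmhg == pytest.approx(22.8)
        # Q*24*n_max / (1000*alpha): fmol/mm^3/day over fmol/(mm^3 mmHg)
        assert params.consumption_mmhg_per_day(1.0) == pytest.approx(
            98.0 * 24.0 * 5e3 / (1000.0 * 1.0268)
        )


class TestVessels:
    def test_full_gating_blocks_all_transport(self, strip, params):
        """With gamma above the 6% threshold everywhere, no vessel
        concentration escapes past the source nodes."""
        mesh, diff, src = strip
        field = VesselField(np.zeros(mesh.n_nodes), src)
        out = update_vessels(field, np.full(mesh.n_elems, 7.0), params, 5.0, diff)
        off = np.setdiff1d(np.arange(mesh.n_nodes), src)
        assert np.all(out.A[off] == 0.0)
        assert np.all(out.A[src] == 100.0)

    def test_ungated_converges_to_full_concentration(self, strip, params):
        mesh, diff, src = strip
        field = VesselField(np.zeros(mesh.n_nodes), src)
        gamma = np.zeros(mesh.n_elems)
        for _ in range(40):
            field = update_vessels(field, gamma, params, 25.0, diff, n_substeps=4)
        assert np.all(field.A > 99.0)

    def test_front_arrival_matches_erfc_solution(self, strip, params):
        """Early-time 90% front on a semi-infinite strip: the arrival time at
        a near-source element matches 100*erfc(x/(2*sqrt(H t))) = 90."""
        mesh, diff, src = strip
        field = VesselField(np.zeros(mesh.n_nodes), src)
        gamma = np.zeros(mesh.n_elems)
        target = int(np.argmin(np.abs(mesh.centroid[:, 1] - 0.55)))
        x = mesh.centroid[target, 1]
        t_analytic = (x / (2.0 * erfcinv(0.9))) ** 2 / params.H
        dt, t = 0.25, 0.0
        while t < 3.0 * t_analytic:
            field = update_vessels(field, gamma, params, dt, diff, n_substeps=5)
            t += dt
            if field.A[mesh.elems[target]].mean() > 90.0:
                break
        assert t == pytest.approx(t_analytic, rel=0.10)

    def test_bounds_and_gating_monotonicity(self, strip, params):
        """A stays in [0,100]; enlarging the gated region never increases A."""
        mesh, diff, src = strip
        rng = np.random.default_rng(7)
        gamma_small = rng.uniform(0.0, 12.0, mesh.n_elems)
        gamma_large = gamma_small.copy()
        gamma_large[rng.random(mesh.n_elems) < 0.3] = 10.0  # gate a superset
        gamma_large = np.maximum(gamma_large, gamma_small)
        fa = VesselField(np.zeros(mesh.n_nodes), src)
        fb = VesselField(np.zeros(mesh.n_nodes), src)
        for _ in range(5):
            fa = update_vessels(fa, gamma_small, params, 1.0, diff)
            fb = update_vessels(fb, gamma_large, params, 1.0, diff)
        assert np.all(fa.A >= -1e-12) and np.all(fa.A <= 100.0 + 1e-12)
        assert np.all(fb.A <= fa.A + 1e-9)

    def test_maximum_principle_pure_diffusion(self, strip, params):
        """Lumped-mass implicit diffusion keeps any initial field within its
        initial bounds when there are no sources."""
        mesh, diff, _ = strip
        rng = np.random.default_rng(3)
        phi0 = rng.uniform(10.0, 80.0, mesh.n_nodes)
        phi = diff.step(phi0, np.full(mesh.n_elems, 0.5), 1.0, n_substeps=5)
        assert phi.min() >= phi0.min() - 1e-9
        assert phi.max() <= phi0.max() + 1e-9


class TestSuppliedElements:
    @pytest.mark.parametrize(
        "values,expected",
        [
            (100.0, True),      # saturated
            (90.0, False),      # exactly at threshold: strict >
        ],
    )
    def test_uniform_thresholds(self, strip, values, expected):
        mesh, _, src = strip
        field = VesselField(np.full(mesh.n_nodes, values), src)
        out = supplied_elements(field, mesh)
        off_src = ~np.isin(mesh.elems, src).any(axis=1)
        assert np.all(out[off_src] == expected)

    def test_mixed_element_mean_rule(self, params):
        fx = make_fixture(FixtureSpec(kind="strip_1d", size=1, length=1.0))
        mesh = fx.mesh
        A = np.zeros(mesh.n_nodes)
        A[mesh.elems[0]] = [100.0, 100.0, 80.0, 80.0]  # mean exactly 90
        field = VesselField(A, np.array([], dtype=np.int64))
        assert not supplied_elements(field, mesh)[0]


class TestOxygen:
    def test_supplied_everywhere_no_consumption_holds_initial(self, strip, params):
        import dataclasses

        mesh, diff, _ = strip
        p = dataclasses.replace(params, Q=1e-12)
        o2 = np.full(mesh.n_nodes, params.o2_initial)
        supplied = np.ones(mesh.n_elems, dtype=bool)
        for _ in range(3):
            o2 = update_oxygen(o2, supplied, np.ones(mesh.n_elems), p, 1.0, diff)
        assert np.allclose(o2, params.o2_initial, atol=1e-6)

    def test_sealed_domain_linear_decay_machine_precision(self, params):
        """No supply, uniform full cell density: backward-Euler reproduces
        O2(t) = O2_init - (Q n n_max / alpha') t exactly while positive."""
        fx = make_fixture(FixtureSpec(kind="slab_2d", size=2, length=1.0))
        diff = ScalarDiffusion(fx.mesh)
        o2 = np.full(fx.mesh.n_nodes, params.o2_initial)
        dt = 1e-4
        nsteps = 5
        for _ in range(nsteps):
            o2 = update_oxygen(
                o2,
                np.zeros(fx.mesh.n_elems, dtype=bool),
                np.ones(fx.mesh.n_elems),
                params,
                dt,
                diff,
                n_substeps=2,
            )
        expected = params.o2_initial - params.consumption_mmhg_per_day(1.0) * (
            dt * nsteps
        )
        assert o2 == pytest.approx(expected, abs=1e-9)

    def test_steady_parabolic_profile(self, params):
        """Both ends supplied, uniform consumption: mid-slab depression
        equals S L^2 / (8 G) within 2%."""
        fx = make_fixture(FixtureSpec(kind="strip_1d", size=48, length=0.12))
        mesh, diff = fx.mesh, ScalarDiffusion(fx.mesh)
        n_density = np.full(mesh.n_elems, 0.2)
        supplied = np.zeros(mesh.n_elems, dtype=bool)
        supplied[[0, -1]] = True
        o2 = np.full(mesh.n_nodes, params.o2_initial)
        for _ in range(60):
            o2 = update_oxygen(o2, supplied, n_density, params, 0.01, diff,
                               n_substeps=2)
        h = 0.12 / 48
        L_eff = 0.12 - 2 * h  # Dirichlet sits on the end elements' nodes
        depression = (
            params.consumption_mmhg_per_day(0.2) * L_eff**2
            / (8.0 * params.G_mm2_per_day)
        )
        mid = np.nonzero(np.abs(mesh.nodes[:, 1] - 0.06) < 1e-9)[0]
        assert params.o2_initial - o2[mid].mean() == pytest.approx(
            depression, rel=0.02
        )

    def test_floor_and_bounds(self, strip, params):
        """Distant unsupplied tissue at full density is driven to the 0 mmHg
        floor, never below, and supplied nodes stay at the initial tension."""
        mesh, diff, _ = strip
        supplied = np.zeros(mesh.n_elems, dtype=bool)
        supplied[0] = True
        o2 = np.full(mesh.n_nodes, params.o2_initial)
        for _ in range(3):
            o2 = update_oxygen(o2, supplied, np.ones(mesh.n_elems), params,
                               1.0, diff)
        assert o2.min() >= 0.0
        assert o2.max() <= params.o2_initial + 1e-9
        assert np.any(o2 == 0.0)

    def test_rejects_invalid_density(self, strip, params):
        mesh, diff, _ = strip
        with pytest.raises(ValueError):
            update_oxygen(
                np.full(mesh.n_nodes, 74.1),
                np.zeros(mesh.n_elems, dtype=bool),
                np.full(mesh.n_elems, 1.5),
                params,
                1.0,
                diff,
            )


class TestCells:
    def test_saturated_state_is_fixed_point(self, strip):
        mesh, diff, src = strip
        field = CellField(np.ones(mesh.n_nodes), src)
        out = update_cells(field, CellParams(), 1.0, diff)
        assert np.allclose(out.n, 1.0)

    def test_empty_state_without_origins_stays_empty(self, strip):
        mesh, diff, _ = strip
        field = CellField(np.zeros(mesh.n_nodes), np.array([], dtype=np.int64))
        out = update_cells(field, CellParams(p_rate=0.0), 1.0, diff)
        assert np.allclose(out.n, 0.0)

    def test_fisher_front_speed(self):
        """Colonisation front speed approaches 2 sqrt(D p) (within 15%)."""
        fx = make_fixture(FixtureSpec(kind="strip_1d", size=150, length=30.0))
        mesh, diff = fx.mesh, ScalarDiffusion(fx.mesh)
        params = CellParams()
        field = CellField(np.zeros(mesh.n_nodes), fx.source_nodes)
        rail = np.nonzero(np.abs(mesh.nodes[:, 0] - 1000.0) < 1e-9)[0]
        rail = rail[np.argsort(mesh.nodes[rail, 1])]
        zs = mesh.nodes[rail, 1]

        def front_pos():
            vals = field.n[rail]
            above = np.nonzero(vals > 0.5)[0]
            if above.size == 0 or above[-1] + 1 >= zs.size:
                return 0.0
            i = above[-1]
            frac = (vals[i] - 0.5) / (vals[i] - vals[i + 1])
            return zs[i] + frac * (zs[i + 1] - zs[i])

        positions = []
        for _ in range(20):
            field = update_cells(field, params, 1.0, diff, n_substeps=20)
            positions.append(front_pos())
        speed = (positions[-1] - positions[9]) / 10.0
        assert speed == pytest.approx(
            2.0 * np.sqrt(params.D_cell * params.p_rate), rel=0.15
        )

    def test_bounds_and_monotone_colonisation(self, strip):
        mesh, diff, src = strip
        field = CellField(np.zeros(mesh.n_nodes), src)
        prev = field.n.copy()
        for _ in range(8):
            field = update_cells(field, CellParams(), 1.0, diff)
            assert np.all(field.n >= -1e-12) and np.all(field.n <= 1.0 + 1e-12)
            assert np.all(field.n >= prev - 1e-9)
            prev = field.n.copy()
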