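"""Engine contract: data model invariants, mock energetics, file formats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from solvtune import (
    DensityGrid,
    ExcitationSet,
    MockEngine,
    MockEngineSpec,
    Molecule,
    RSHParams,
    SolvationMode,
    SolventSpec,
    get_engine,
    mock_quantities,
    read_cube,
    read_xyz,
    write_cube,
    write_xyz,
)
from solvtune.engine import EngineError, UnsupportedElementError


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class TestMolecule:
    def test_electron_count_and_charge(self, water):
        assert water.n_electrons == 10
        cation = water.with_charge(+1)
        assert cation.n_electrons == 9
        assert cation.multiplicity == 2

    def test_parity_validation(self):
        with pytest.raises(ValueError, match="multiplicity"):
            Molecule((("O", (0, 0, 0)),), net_charge=0, multiplicity=2)

    @pytest.mark.parametrize("bad", [
        (),  # no atoms
        (("Xx", (0, 0, 0)),),  # unknown element
        (("O", (0, 0, float("nan"))),),  # non-finite
    ])
    def test_invalid_molecules_rejected(self, bad):
        with pytest.raises((ValueError, UnsupportedElementError)):
            Molecule(bad)

    def test_recenter_moves_centroid_to_origin(self, water):
        assert np.allclose(water.recentered().geometric_center(), 0.0,
                           atol=1e-12)


class TestRSHParams:
    def test_defaults_are_wpbeh(self):
        p = RSHParams()
        assert (p.alpha, p.beta, p.gamma) == (0.2, 0.8, 0.2)

    @pytest.mark.parametrize("kw", [
        {"alpha": -0.1}, {"alpha": 0.6, "beta": 0.6}, {"gamma": -0.01},
    ])
    def test_invariants(self, kw):
        with pytest.raises(ValueError):
            RSHParams(**kw)


class TestSolvationTypes:
    def test_solvent_spec_ordering(self):
        with pytest.raises(ValueError):
            SolventSpec("bad", 2.0, 3.0)  # eps_inf > eps

    def test_gas_mode_carries_no_dielectric(self):
        with pytest.raises(ValueError):
            SolvationMode("gas", eps=2.0)
        assert SolvationMode.gas().active_eps is None

    def test_nonequilibrium_without_frozen_field_is_legal(self):
        mode = SolvationMode.nonequilibrium(2.03)
        assert mode.frozen_field is None
        assert mode.active_eps == 2.03


class TestExcitationSet:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError, match="nondecreasing"):
            ExcitationSet((3.0, 2.0), (0.1, 0.1), ((0, 0, 0), (0, 0, 0)))

    def test_positive_energies(self):
        with pytest.raises(ValueError, match="positive"):
            ExcitationSet((0.0,), (0.1,), ((0, 0, 0),))


# ---------------------------------------------------------------------------
# mock quantities
# ---------------------------------------------------------------------------


class TestMockQuantities:
    def test_gas_affine_evaluation(self):
        # -eps_HOMO(N) = 6.0 + 10.16*0.15 with the default intercepts
        neg_homo, _ = mock_quantities(MockEngineSpec(), "N", 0.15,
                                      SolvationMode.gas())
        assert neg_homo == pytest.approx(6.0 + 10.16 * 0.15, abs=1e-12)

    def test_reference_solvent_shift_is_exact(self):
        spec = MockEngineSpec()
        _, ip_gas = mock_quantities(spec, "N", 0.0, SolvationMode.gas())
        _, ip_dcm = mock_quantities(spec, "N", 0.0,
                                    SolvationMode.equilibrium(8.93))
        assert ip_dcm - ip_gas == pytest.approx(-1.19, abs=1e-12)

    def test_nonequilibrium_scales_with_eps_inf(self):
        spec = MockEngineSpec()
        _, ip_gas = mock_quantities(spec, "N", 0.0, SolvationMode.gas())
        _, ip_ne = mock_quantities(spec, "N", 0.0,
                                   SolvationMode.nonequilibrium(2.03))
        expected = -1.19 * (1.03 / 2.03) / (7.93 / 8.93)
        assert ip_ne - ip_gas == pytest.approx(expected, abs=1e-12)
        assert ip_ne - ip_gas == pytest.approx(-0.68, abs=0.005)

    def test_shift_vanishes_at_unit_dielectric(self):
        spec = MockEngineSpec()
        gas = mock_quantities(spec, "N+1", 0.1, SolvationMode.gas())
        eps1 = mock_quantities(spec, "N+1", 0.1, SolvationMode.equilibrium(1.0))
        assert gas == pytest.approx(eps1, abs=1e-12)

    @given(g1=hst.floats(0.0, 0.6), g2=hst.floats(0.0, 0.6))
    @settings(max_examples=50, deadline=None)
    def test_monotonicity_in_gamma(self, g1, g2):
        """-eps_HOMO strictly increases with gamma; IP(N+1) decreases."""
        if abs(g1 - g2) < 1e-12:  # below slope*step resolution
            return
        lo, hi = min(g1, g2), max(g1, g2)
        spec = MockEngineSpec()
        mode = SolvationMode.gas()
        for state in ("N", "N+1"):
            assert (mock_quantities(spec, state, hi, mode)[0]
                    > mock_quantities(spec, state, lo, mode)[0])
        assert (mock_quantities(spec, "N+1", hi, mode)[1]
                < mock_quantities(spec, "N+1", lo, mode)[1])

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            mock_quantities(MockEngineSpec(), "N", -0.1, SolvationMode.gas())


# ---------------------------------------------------------------------------
# mock engine runs
# ---------------------------------------------------------------------------


class TestMockEngine:
    def test_determinism_bitwise(self, engine, water):
        p = RSHParams(gamma=0.17)
        mode = SolvationMode.equilibrium(8.93)
        a = engine.run_ground_state(water, p, mode)
        b = engine.run_ground_state(water, p, mode)
        assert a == b  # frozen dataclasses: field-for-field identical

    def test_gas_mode_has_no_polarization_charges(self, engine, water):
        res = engine.run_ground_state(water, RSHParams(), SolvationMode.gas())
        assert res.polarization_charges == ()

    def test_continuum_mode_returns_charges(self, engine, water):
        res = engine.run_ground_state(water, RSHParams(),
                                      SolvationMode.equilibrium(8.93))
        assert len(res.polarization_charges) > 0

    def test_homo_below_lumo_for_neutral(self, engine, water):
        res = engine.run_ground_state(water, RSHParams(gamma=0.15),
                                      SolvationMode.gas())
        assert res.eps_homo <= res.eps_lumo

    def test_energy_differences_match_mock_ips(self, engine, water):
        """DeltaSCF differences reproduce the affine IP models exactly."""
        from solvtune.engine import HARTREE_TO_EV
        p = RSHParams(gamma=0.15)
        mode = SolvationMode.gas()
        e_n = engine.run_ground_state(water, p, mode).E_total
        e_cat = engine.run_ground_state(water.with_charge(+1), p, mode).E_total
        e_an = engine.run_ground_state(water.with_charge(-1), p, mode).E_total
        _, ip_n = mock_quantities(engine.spec, "N", 0.15, mode)
        _, ip_n1 = mock_quantities(engine.spec, "N+1", 0.15, mode)
        assert (e_cat - e_n) * HARTREE_TO_EV == pytest.approx(ip_n, abs=1e-10)
        assert (e_n - e_an) * HARTREE_TO_EV == pytest.approx(ip_n1, abs=1e-10)

    def test_excited_states_passthrough_and_bounds(self, engine, water):
        mode = SolvationMode.gas()
        full = engine.run_excited_states(water, RSHParams(), mode, 10)
        assert full == engine.spec.excitations
        one = engine.run_excited_states(water, RSHParams(), mode, 1)
        assert len(one) == 1
        with pytest.raises(EngineError):
            engine.run_excited_states(water, RSHParams(), mode, 11)

    def test_registry_lookup(self):
        assert isinstance(get_engine("mock"), MockEngine)
        with pytest.raises(KeyError):
            get_engine("terachem")


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


class TestFileFormats:
    def test_xyz_round_trip(self, water, tmp_path):
        path = tmp_path / "w.xyz"
        write_xyz(water, path, comment="fixture")
        back = read_xyz(path)
        assert back.symbols == water.symbols
        assert np.allclose(back.coordinates, water.coordinates, atol=1e-7)

    def test_cube_round_trip(self, water, tmp_path):
        rng = np.random.default_rng(7)
        grid = DensityGrid(origin=(-2.0, -2.0, -2.0), steps=(0.5, 0.5, 0.5),
                           counts=(8, 9, 10), values=rng.random(8 * 9 * 10))
        path = tmp_path / "rho.cube"
        write_cube(grid, water, path)
        back, mol = read_cube(path)
        assert back.counts == grid.counts
        assert np.allclose(back.steps, grid.steps, atol=1e-6)
        assert np.allclose(back.values, grid.values, rtol=1e-4)
        assert mol.symbols == water.symbols

    def test_density_grid_invariants(self):
        with pytest.raises(ValueError):
            DensityGrid((0, 0, 0), (0.0, 0.1, 0.1), (2, 2, 2), np.zeros(8))
        with pytest.raises(ValueError):
            DensityGrid((0, 0, 0), (0.1, 0.1, 0.1), (2, 2, 2), np.zeros(7))
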