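"""Forward model: form factors, structure factors, solvent, scaling, gradients."""

import gemmi
import numpy as np
import pytest

from msxref.assessment import r_factor
from msxref.crystal_core import (AtomicState, MultiStateModel, ReflectionSet,
                                 SPACE_GROUPS, UnitCell, WeightMatrix)
from msxref.forward_model import (FormFactorTable, NuisanceParameters,
                                  SolventMaskParams, StateScattering,
                                  amplitude_coordinate_gradients,
                                  bulk_solvent_sf, compute_msf, fit_nuisance,
                                  form_factor, multi_state_sf, single_state_sf,
                                  total_amplitude)
from msxref.likelihood import quadratic_gradient_weights
from msxref.synthetic_data import density_transform, full_hkl_set, gridded_density


class TestFormFactors:
    def test_zero_angle_equals_electron_count(self):
        assert form_factor("C", 0.0) == pytest.approx(6.0, rel=0.05)
        assert form_factor("O", 0.0) == pytest.approx(8.0, rel=0.05)

    @pytest.mark.parametrize("element,stol", [("C", 0.25), ("N", 0.1), ("S", 0.4)])
    def test_matches_independent_coefficient_evaluation(self, element, stol):
        oracle = gemmi.Element(element).it92.calculate_sf(stol**2)
        assert form_factor(element, stol) == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("element", ["C", "N", "O"])
    def test_monotone_decreasing(self, element):
        stol = np.linspace(0.0, 0.6, 100)
        f = form_factor(element, stol)
        assert np.all(np.diff(f) < 0)

    def test_unknown_element_named_in_error(self):
        with pytest.raises(KeyError, match="Xx"):
            form_factor("Xx", 0.1)

    def test_table_file_round_trip(self, tmp_path):
        path = tmp_path / "ff.txt"
        path.write_text("# element a1..a4 b1..b4 c\n"
                        "Q 1.0 2.0 3.0 4.0 0.1 0.2 0.3 0.4 0.5\n")
        table = FormFactorTable.from_file(path)
        expected = sum(a * np.exp(-b * 0.04) for a, b in
                       zip([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4])) + 0.5
        assert table.f("Q", 0.2) == pytest.approx(expected, rel=1e-12)
        assert table.f("C", 0.0) == pytest.approx(form_factor("C", 0.0))


class TestSingleStateSF:
    def test_point_scatterer_at_origin(self, cubic_cell, p1):
        state = AtomicState(["C"], np.zeros((1, 3)), b_factors=np.zeros(1))
        refls = ReflectionSet(cubic_cell, p1, [(1, 0, 0), (2, 1, 0), (3, 2, 1)],
                              np.ones(3))
        f = single_state_sf(state, refls)
        assert np.allclose(f.imag, 0.0, atol=1e-12)
        assert np.allclose(f.real, form_factor("C", refls.stol), rtol=1e-12)

    def test_translation_shifts_phase_only(self, cubic_cell, p1, small_state):
        refls = ReflectionSet(cubic_cell, p1, [(1, 0, 0), (1, 2, 3)], np.ones(2))
        f0 = single_state_sf(small_state, refls)
        t_frac = np.array([0.21, 0.4, -0.13])
        shifted = AtomicState(small_state.elements,
                              small_state.coords + cubic_cell.orthogonalization @ t_frac,
                              small_state.b_factors)
        f1 = single_state_sf(shifted, refls)
        assert np.allclose(np.abs(f1), np.abs(f0), rtol=1e-10)
        expected = f0 * np.exp(2j * np.pi * (refls.hkl @ t_frac))
        assert np.allclose(f1, expected, rtol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_gridded_density_dft(self, seed, p1):
        """Direct summation vs DFT of the B-smeared density, < 0.5% mean error."""
        rng = np.random.default_rng(seed)
        cell = UnitCell(13.0, 11.0, 12.0)
        n_atoms = int(rng.integers(3, 11))
        elements = list(rng.choice(["C", "N", "O", "S"], size=n_atoms))
        state = AtomicState(elements, rng.uniform(2, 9, size=(n_atoms, 3)),
                            b_factors=rng.uniform(10, 25, size=n_atoms))
        hkl = full_hkl_set(cell, p1, 2.5)
        refls = ReflectionSet(cell, p1, hkl, np.ones(len(hkl)))
        f_direct = single_state_sf(state, refls)
        rho = gridded_density(state, cell, (40, 40, 40))
        f_dft = density_transform(rho, cell, hkl)
        rel = np.abs(f_dft - f_direct) / np.abs(f_direct)
        assert rel.mean() < 0.005

    def test_friedel_symmetry(self, small_state):
        cell = UnitCell(12.0, 12.0, 12.0)
        p1 = SPACE_GROUPS["P1"]
        hkl = np.array([(1, 2, 3), (2, -1, 0), (0, 0, 4)])
        plus = ReflectionSet(cell, p1, hkl, np.ones(3))
        minus = ReflectionSet(cell, p1, -hkl, np.ones(3))
        assert np.allclose(np.abs(single_state_sf(small_state, plus)),
                           np.abs(single_state_sf(small_state, minus)), rtol=1e-12)

    def test_symmetry_expansion_consistency(self):
        """P212121 amplitudes equal the P1 calculation on symmetry-expanded atoms."""
        cell = UnitCell(14.0, 15.0, 16.0)
        ops = SPACE_GROUPS["P212121"]
        p1 = SPACE_GROUPS["P1"]
        rng = np.random.default_rng(8)
        coords = rng.uniform(1, 6, size=(4, 3))
        elements = ["C", "N", "O", "C"]
        state = AtomicState(elements, coords, b_factors=np.full(4, 15.0))
        hkl = [(1, 2, 3), (2, 0, 1), (3, 1, 2)]
        refls = ReflectionSet(cell, ops, hkl, np.ones(3))
        f_sym = single_state_sf(state, refls)
        # expand atoms over the group, compute in P1
        frac = cell.fractionalization
        ortho = cell.orthogonalization
        exp_coords, exp_elements = [], []
        for rot, tr in ops:
            for a in range(4):
                xf = rot @ (frac @ coords[a]) + tr
                exp_coords.append(ortho @ xf)
                exp_elements.append(elements[a])
        big = AtomicState(exp_elements, np.array(exp_coords),
                          b_factors=np.full(16, 15.0))
        refls_p1 = ReflectionSet(cell, p1, hkl, np.ones(3))
        f_p1 = single_state_sf(big, refls_p1)
        assert np.allclose(f_sym, f_p1, rtol=1e-10)


class TestMultiStateSF:
    def test_single_state_identity(self):
        f = np.array([1 + 2j, 3 - 1j])
        assert np.allclose(multi_state_sf([f], [1.0]), f)

    def test_identical_states_any_weights(self):
        f = np.array([2 + 1j, -1 + 4j])
        assert np.allclose(multi_state_sf([f, f], [0.3, 0.7]), f, rtol=1e-15)

    def test_elementwise_weighted_sum(self):
        rng = np.random.default_rng(2)
        f1 = rng.normal(size=5) + 1j * rng.normal(size=5)
        f2 = rng.normal(size=5) + 1j * rng.normal(size=5)
        out = multi_state_sf([f1, f2], [0.7, 0.3])
        assert np.allclose(out, 0.7 * f1 + 0.3 * f2, rtol=1e-15)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            multi_state_sf([np.ones(3)], [0.5, 0.5])

    def test_partial_occupancy_degeneracy_bit_level(self, cubic_cell, p1):
        """A single partial-occupancy description equals the weighted sum exactly."""
        rng = np.random.default_rng(6)
        x1 = rng.uniform(1, 9, size=(3, 3))
        x2 = rng.uniform(1, 9, size=(3, 3))
        elements = ["C", "N", "O"]
        w1, w2 = 0.6, 0.4
        hkl = full_hkl_set(cubic_cell, p1, 3.0)
        refls = ReflectionSet(cubic_cell, p1, hkl, np.ones(len(hkl)))
        s1 = AtomicState(elements, x1)
        s2 = AtomicState(elements, x2)
        f_weighted = multi_state_sf([single_state_sf(s1, refls),
                                     single_state_sf(s2, refls)], [w1, w2])
        merged = AtomicState(elements * 2, np.vstack([x1, x2]),
                             occupancies=np.array([w1] * 3 + [w2] * 3),
                             b_factors=np.full(6, 15.0))
        f_merged = single_state_sf(merged, refls)
        assert np.allclose(f_merged, f_weighted, rtol=1e-12, atol=1e-12)


class TestBulkSolvent:
    def test_empty_cell_is_all_solvent(self, cubic_cell, p1):
        state = AtomicState([], np.zeros((0, 3)))
        refls = ReflectionSet(cubic_cell, p1, [(1, 0, 0), (2, 2, 0)], np.ones(2))
        f_b, frac = bulk_solvent_sf([state], [1.0], refls)
        assert frac == pytest.approx(1.0)
        assert np.allclose(np.abs(f_b), 0.0, atol=1e-8)

    def test_single_atom_volume_fraction(self, p1):
        cell = UnitCell(20.0, 20.0, 20.0)
        state = AtomicState(["C"], np.array([[10.0, 10.0, 10.0]]))
        hkl = [(1, 0, 0), (1, 1, 0)]
        refls = ReflectionSet(cell, p1, hkl, np.ones(2))
        params = SolventMaskParams(probe_radius=1.1, shrink_radius=0.0,
                                   grid_spacing=0.4)
        _, frac = bulk_solvent_sf([state], [1.0], refls, params)
        r = 1.7 + 1.1  # vdW + probe
        expected = 1.0 - (4.0 / 3.0) * np.pi * r**3 / cell.volume
        assert frac == pytest.approx(expected, abs=0.01)

    def test_grid_too_coarse_rejected(self, cubic_cell, p1, small_state):
        refls = ReflectionSet(cubic_cell, p1, [(4, 0, 0)], np.ones(1))  # d = 2.5
        with pytest.raises(ValueError, match="coarse"):
            bulk_solvent_sf([small_state], [1.0], refls,
                            SolventMaskParams(grid_spacing=2.0))


class TestTotalAmplitude:
    def test_solvent_disabled(self):
        f_c = np.array([3 + 4j, 1 + 0j])
        amp, phase = total_amplitude(f_c, np.zeros(2), NuisanceParameters())
        assert np.allclose(amp, [5.0, 1.0])
        assert np.allclose(phase, np.angle(f_c))

    def test_k_total_homogeneity(self):
        f_c = np.array([3 + 4j, 1 - 2j])
        amp1, _ = total_amplitude(f_c, np.zeros(2), NuisanceParameters(k_total=1.0))
        amp2, _ = total_amplitude(f_c, np.zeros(2), NuisanceParameters(k_total=2.0))
        assert np.allclose(amp2, 2.0 * amp1)

    def test_destructive_interference(self):
        f_c = np.array([2 + 3j])
        amp, _ = total_amplitude(f_c, -f_c, NuisanceParameters(k_total=1.0, k_mask=1.0))
        assert amp[0] == pytest.approx(0.0, abs=1e-14)


class TestFitNuisance:
    def test_exact_proportionality(self, small_state, small_refls):
        f_c = single_state_sf(small_state, small_refls)
        refls = small_refls.copy()
        refls.f_obs = 3.0 * np.abs(f_c)
        nuis = fit_nuisance(refls, f_c)
        assert nuis.k_total == pytest.approx(3.0, rel=1e-12)
        amp, _ = total_amplitude(f_c, np.zeros_like(f_c), nuis)
        assert np.allclose(amp, refls.f_obs, rtol=1e-12)

    def test_grid_search_oracle_with_solvent(self, p1):
        rng = np.random.default_rng(9)
        cell = UnitCell(15.0, 15.0, 15.0)
        hkl = full_hkl_set(cell, p1, 3.5)[:50]
        f_c = rng.normal(size=50) + 1j * rng.normal(size=50)
        f_b = 0.5 * (rng.normal(size=50) + 1j * rng.normal(size=50))
        true_kt, true_km = 2.0, 0.35
        f_obs = np.abs(true_kt * (f_c + true_km * f_b))
        refls = ReflectionSet(cell, p1, hkl, f_obs)
        nuis = fit_nuisance(refls, f_c, f_b)
        # brute-force 2-D grid search oracle
        best = (np.inf, None, None)
        for km in np.linspace(0, 1, 401):
            amp = np.abs(f_c + km * f_b)
            kt = (f_obs * amp).sum() / (amp**2).sum()
            sse = ((f_obs - kt * amp) ** 2).sum()
            if sse < best[0]:
                best = (sse, kt, km)
        assert nuis.k_mask == pytest.approx(best[2], abs=0.01 * max(best[2], 1))
        assert nuis.k_total == pytest.approx(best[1], rel=0.01)

    def test_zero_residuals_clamp_beta_to_floor(self, small_state, small_refls):
        f_c = single_state_sf(small_state, small_refls)
        refls = small_refls.copy()
        refls.f_obs = np.abs(f_c)
        nuis = fit_nuisance(refls, f_c)
        floor = 1e-3 * np.mean(refls.f_obs**2)
        assert np.all(nuis.beta >= floor * (1 - 1e-12))

    def test_all_zero_f_obs_rejected(self, small_state, small_refls):
        f_c = single_state_sf(small_state, small_refls)
        refls = small_refls.copy()
        refls.f_obs = np.zeros(len(refls))
        with pytest.raises(ValueError, match="unscalable"):
            fit_nuisance(refls, f_c)

    def test_scale_invariance_of_rwork(self, small_state, small_refls):
        f_c = single_state_sf(small_state, small_refls)
        refls = small_refls.copy()
        rng = np.random.default_rng(3)
        refls.f_obs = np.abs(f_c) * (1 + 0.05 * rng.normal(size=len(refls)))
        nuis1 = fit_nuisance(refls, f_c)
        amp1, _ = total_amplitude(f_c, np.zeros_like(f_c), nuis1)
        r1 = r_factor(refls.f_obs, amp1)
        scaled = refls.copy()
        scaled.f_obs = 7.5 * refls.f_obs
        nuis2 = fit_nuisance(scaled, f_c)
        amp2, _ = total_amplitude(f_c, np.zeros_like(f_c), nuis2)
        assert nuis2.k_total == pytest.approx(7.5 * nuis1.k_total, rel=1e-9)
        assert r_factor(scaled.f_obs, amp2) == pytest.approx(r1, rel=1e-9)


class TestCoordinateGradients:
    def _setup(self, toy_study):
        native = toy_study["native"]
        refls = toy_study["datasets"][0]
        scattering = [StateScattering(s, refls) for s in native.states]
        msf, nuis = compute_msf(native, refls, 0, scattering=scattering)
        quad = quadratic_gradient_weights(refls, msf, nuis)
        return native, refls, scattering, msf, nuis, quad

    def test_zero_weight_state_feels_no_xray_force(self, toy_study):
        native, refls, scattering, msf, nuis, quad = self._setup(toy_study)
        model = MultiStateModel([s.copy() for s in native.states],
                                WeightMatrix(np.array([[1.0, 1.0], [0.0, 0.0]])))
        msf, nuis = compute_msf(model, refls, 0, scattering=scattering)
        quad = quadratic_gradient_weights(refls, msf, nuis)
        grads = amplitude_coordinate_gradients(model, refls, nuis, quad.g0, 0,
                                               msf, scattering)
        assert np.allclose(grads[1], 0.0)
        assert not np.allclose(grads[0], 0.0)

    def test_stationary_loss_gives_zero_gradient(self, toy_study):
        native, refls, scattering, msf, nuis, _ = self._setup(toy_study)
        grads = amplitude_coordinate_gradients(native, refls, nuis,
                                               np.zeros(len(refls)), 0, msf,
                                               scattering)
        for g in grads:
            assert np.allclose(g, 0.0)

    def test_matches_finite_differences(self, toy_study):
        """Analytic d(NLL)/dx vs central differences on a 2-atom subset."""
        from msxref.likelihood import dataset_neg_log_likelihood, neg_log_p_derivative

        native, refls, scattering, msf, nuis, _ = self._setup(toy_study)
        dl = neg_log_p_derivative(refls.f_obs, msf.f_model_amp,
                                  nuis.alpha_of(refls.d), nuis.beta_of(refls.d),
                                  refls.epsilon, refls.centric)
        dl = np.where(refls.work_mask, dl, 0.0)
        grads = amplitude_coordinate_gradients(native, refls, nuis, dl, 0, msf,
                                               scattering)

        def nll(model):
            sc = [StateScattering(s, refls) for s in model.states]
            m, _ = compute_msf(model, refls, 0, nuis=nuis, scattering=sc)
            return dataset_neg_log_likelihood(refls, m, nuis)

        rng = np.random.default_rng(0)
        for _ in range(4):
            i = int(rng.integers(2))
            a = int(rng.integers(native.n_atoms))
            k = int(rng.integers(3))
            h = 1e-4
            m = native.copy()
            m.states[i].coords[a, k] += h
            fp = nll(m)
            m.states[i].coords[a, k] -= 2 * h
            fm = nll(m)
            fd = (fp - fm) / (2 * h)
            assert grads[i][a, k] == pytest.approx(fd, rel=1e-5, abs=1e-8)
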