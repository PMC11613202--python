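import numpy as np
import pytest

from fluorounmix.spectral_core import AbundanceVector, SpectrumPair
from fluorounmix.synthetic import (
    NoiseModel,
    OpticalProperties,
    generate_phantom_dataset,
    simulate_pair,
)
from fluorounmix.unmix_classical import (
    DualBandConfig,
    classical_pipeline,
    correct_dual_band,
    dual_band_factor,
    mix,
    nnls_unmix,
)


def projected_gradient_nnls(Bmat, phi, iters=4000):
    """Independent NNLS oracle: accelerated projected gradient to convergence."""
    L = np.linalg.norm(Bmat.T @ Bmat, 2)
    z = np.zeros(Bmat.shape[1])
    y, t = z.copy(), 1.0
    for _ in range(iters):
        g = Bmat.T @ (Bmat @ y - phi)
        z_new = np.clip(y - g / L, 0.0, None)
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        y = z_new + (t - 1) / t_new * (z_new - z)
        if np.dot(z_new - z, y - z_new) > 0:  # restart on non-monotone step
            y, t_new = z_new.copy(), 1.0
        z, t = z_new, t_new
    return z


def objective(Bmat, z, phi):
    r = Bmat @ z - phi
    return float(r @ r)


class TestMix:
    def test_zero_abundance_gives_zero_spectrum(self, library):
        assert np.all(mix(library, np.zeros(library.K)) == 0)

    def test_unit_vector_selects_endmember_column(self, library):
        for k in range(library.K):
            e = np.zeros(library.K)
            e[k] = 1.0
            np.testing.assert_array_equal(mix(library, e), library.B[:, k])

    def test_matches_explicit_summation_loop(self, library, rng):
        z = rng.random(library.K)
        manual = sum(z[k] * library.B[:, k] for k in range(library.K))
        np.testing.assert_allclose(mix(library, z), manual, rtol=1e-12)

    def test_dimension_mismatch_rejected(self, library):
        with pytest.raises(ValueError):
            mix(library, np.ones(library.K + 1))


class TestNnls:
    def test_noiseless_mixture_recovered(self, library, rng):
        z_true = rng.random(library.K) * np.array([2, 1, 0.5, 0.5, 0.5])
        z = nnls_unmix(mix(library, z_true), library).z
        assert np.max(np.abs(z - z_true)) < 1e-8

    def test_anticorrelated_spectrum_maps_to_zero(self, library):
        # a spectrum negatively correlated with every endmember: the
        # non-negativity constraint pins the solution at the origin
        phi = -library.B[:, 0]
        z = nnls_unmix(phi, library).z
        assert np.all(z == 0)
        z_pg = projected_gradient_nnls(library.B, phi)
        assert objective(library.B, z, phi) <= objective(library.B, z_pg, phi) + 1e-9

    def test_nonnegative_objective_at_zero_beats_negative_directions(self, library):
        # the projection of a spectrum orthogonal-negative to all endmembers is z=0
        phi = np.zeros(library.grid.n_bands)
        z = nnls_unmix(phi, library).z
        assert np.all(z == 0)

    def test_small_instance_matches_dense_grid_search(self, rng):
        from fluorounmix.spectral_core import EndmemberLibrary, WavelengthGrid

        grid = WavelengthGrid(500.0, 10.0, 5)
        B = EndmemberLibrary(rng.random((5, 2)) + 0.1, ("a", "b"), grid)
        phi = B.B @ np.array([1.2, 0.4]) + 0.05 * rng.standard_normal(5)
        phi = np.clip(phi, 0, None)
        z = nnls_unmix(phi, B).z
        # dense grid over [0, 3]^2, step 1e-3
        cand = np.arange(0, 3.0, 1e-3)
        G = B.B  # (5, 2)
        best = np.inf
        for a in cand:
            r = phi[:, None] - np.outer(G[:, 0], np.full(1, a)) - G[:, 1][:, None] * cand[None, :]
            vals = (r**2).sum(axis=0)
            best = min(best, vals.min())
        assert objective(B.B, z, phi) <= best + 1e-9

    def test_nonfinite_input_rejected(self, library):
        phi = np.full(library.grid.n_bands, np.nan)
        with pytest.raises(ValueError):
            nnls_unmix(phi, library)

    def test_objective_beats_clipped_unconstrained_solution(self, library, rng):
        # projecting the unconstrained least-squares solution onto z >= 0 is
        # feasible, so the NNLS optimum can only be better
        for _ in range(20):
            phi = rng.random(library.grid.n_bands)
            z = nnls_unmix(phi, library).z
            ls, *_ = np.linalg.lstsq(library.B, phi, rcond=None)
            clipped = np.clip(ls, 0.0, None)
            assert objective(library.B, z, phi) <= objective(library.B, clipped, phi) + 1e-9

    def test_objective_matches_projected_gradient_oracle(self, library, rng):
        for _ in range(25):
            z_true = rng.random(library.K) * (rng.random(library.K) < 0.6)
            phi = np.clip(
                mix(library, z_true) + 0.01 * rng.standard_normal(library.grid.n_bands),
                0, None,
            )
            z = nnls_unmix(phi, library).z
            z_pg = projected_gradient_nnls(library.B, phi)
            assert objective(library.B, z, phi) <= objective(library.B, z_pg, phi) + 1e-6


class TestDualBand:
    def test_flat_spectrum_closed_form(self, grid):
        cfg = DualBandConfig(band_a=(450, 480), band_b=(620, 640), exponent=1.0)
        # trapezoid over the 11 grid points in 450-480 spans 30 nm,
        # over 620-640 spans 18 nm (grid-aligned band edges)
        phi = np.ones(grid.n_bands)
        wa = grid.wavelengths[grid.band_indices(450, 480)]
        wb = grid.wavelengths[grid.band_indices(620, 640)]
        expected = (wa[-1] - wa[0]) * (wb[-1] - wb[0])
        assert dual_band_factor(phi, grid, cfg) == pytest.approx(expected, rel=1e-12)

    def test_zero_exponent_leaves_band_b_alone(self, grid, rng):
        phi = rng.random(grid.n_bands) + 0.5
        cfg0 = DualBandConfig(exponent=0.0)
        wb = grid.wavelengths[grid.band_indices(*cfg0.band_b)]
        expected = np.trapezoid(phi[grid.band_indices(*cfg0.band_b)], wb)
        assert dual_band_factor(phi, grid, cfg0) == pytest.approx(expected, rel=1e-12)

    def test_matches_fine_grid_quadrature(self, grid, rng):
        # oracle: integrate the piecewise-linear interpolant of the sampled
        # spectrum on a 100x finer grid — must agree with the native
        # trapezoid rule to high precision
        w = grid.wavelengths
        phi = rng.random(grid.n_bands) + 0.2
        cfg = DualBandConfig()
        s = dual_band_factor(phi, grid, cfg)

        def fine_integral(band):
            wa = w[grid.band_indices(*band)]  # the trapezoid's actual domain
            fine = np.linspace(wa[0], wa[-1], 100 * int(wa[-1] - wa[0]) + 1)
            return np.trapezoid(np.interp(fine, w, phi), fine)

        s_fine = fine_integral(cfg.band_a) ** 0.7 * fine_integral(cfg.band_b)
        assert s == pytest.approx(s_fine, rel=1e-6)

    def test_zero_reflectance_rejected(self, grid):
        with pytest.raises(ValueError, match="saturated or empty"):
            dual_band_factor(np.zeros(grid.n_bands), grid)

    def test_scale_equivariance_of_correction(self, grid, library, rng):
        fluo = rng.random(grid.n_bands)
        ref = rng.random(grid.n_bands) + 0.5
        p1 = SpectrumPair(fluo, ref, grid)
        p2 = SpectrumPair(3.0 * fluo, ref, grid)
        np.testing.assert_allclose(
            correct_dual_band(p2), 3.0 * correct_dual_band(p1), rtol=1e-12
        )

    def test_alpha_scaled_pairs_correct_identically(self, grid, rng):
        """Scaling fluorescence by alpha with reflectance scaled so the factor
        grows by alpha leaves the corrected spectrum unchanged."""
        fluo = rng.random(grid.n_bands) + 0.1
        ref = rng.random(grid.n_bands) + 0.5
        alpha = 2.0
        # s scales as beta^(x+1) when reflectance scales by beta
        beta = alpha ** (1.0 / 1.7)
        p1 = SpectrumPair(fluo, ref, grid)
        p2 = SpectrumPair(alpha * fluo, beta * ref, grid)
        np.testing.assert_allclose(
            correct_dual_band(p2), correct_dual_band(p1), rtol=1e-10
        )

    def test_constant_concentration_vials_variance_halved(self, library):
        grid = library.grid
        pairs = [
            p for p in generate_phantom_dataset(n_per_vial=10, seed=5, library=library)
            if p.c_ppix == 2.5
        ]
        idx = grid.band_indices(620, 640)
        w = grid.wavelengths[idx]
        raw = np.array([np.trapezoid(p.phi_fluo[idx], w) for p in pairs])
        cor = np.array([np.trapezoid(correct_dual_band(p)[idx], w) for p in pairs])
        cv = lambda x: np.std(x) / np.mean(x)
        assert cv(cor) <= 0.5 * cv(raw)


class TestClassicalPipeline:
    def test_zero_fluorescence_gives_zero_abundance(self, library, rng):
        p = SpectrumPair(
            np.zeros(library.grid.n_bands), rng.random(library.grid.n_bands) + 0.5,
            library.grid,
        )
        assert np.all(classical_pipeline(p, library).z == 0)

    def test_exactly_compensated_attenuation_recovers_abundance(self, library, rng):
        z_true = np.array([1.5, 0.0, 0.3, 0.0, 0.2])
        ref = rng.random(library.grid.n_bands) + 0.5
        s = dual_band_factor(ref, library.grid)
        p = SpectrumPair(s * mix(library, z_true), ref, library.grid)
        z = classical_pipeline(p, library).z
        assert np.max(np.abs(z - z_true)) < 1e-6

    def test_pure_attenuated_ppix_stays_on_support(self, library):
        grid = library.grid
        optics = OpticalProperties(42.0, 11.6, geom=0.5)
        pair = simulate_pair(
            np.array([2.0, 0, 0, 0, 0]), library, optics, NoiseModel(), seed=0
        )
        z = classical_pipeline(pair, library).z
        assert z[0] > 0
        assert np.all(z[1:] < 1e-6 * z[0])

    def test_geometry_only_variation_recovered_up_to_global_scale(self, library):
        """With fixed absorption/scattering and varying geometry the dual-band
        factor compensates the attenuation exactly."""
        ratios = []
        for c in (0.2, 0.6, 1.25, 2.5):
            for geom in (0.4, 1.0, 2.5):
                optics = OpticalProperties(42.0, 11.6, geom)
                pair = simulate_pair(
                    np.array([c, 0, 0, 0, 0]), library, optics, NoiseModel(), seed=0
                )
                ratios.append(classical_pipeline(pair, library).z[0] / c)
        assert np.ptp(ratios) < 1e-9 * np.mean(ratios)
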