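import numpy as np
import pytest

from fluorounmix.spectral_core import WavelengthGrid
from fluorounmix.synthetic import (
    GEOM_EXPONENT,
    NoiseModel,
    OpticalProperties,
    attenuation_curve,
    generate_pbh_dataset,
    generate_phantom_dataset,
    generate_unlabeled_dataset,
    make_endmembers,
    reflectance_curve,
    render_cubes,
    simulate_pair,
    _excitation_factor,
    _reflectance_shape,
)


class TestEndmembers:
    def test_seeded_library_is_reproducible(self, grid):
        a = make_endmembers(grid, seed=5)
        b = make_endmembers(grid, seed=5)
        np.testing.assert_array_equal(a.B, b.B)
        assert np.any(make_endmembers(grid, seed=6).B != a.B)

    def test_ppix634_peaks_near_634(self, grid):
        for seed in range(5):
            lib = make_endmembers(grid, seed=seed)
            peak = grid.wavelengths[np.argmax(lib.B[:, lib.index_of("ppix634")])]
            assert abs(peak - 634.0) <= 3.0 + 2.0  # grid step + perturbation

    def test_library_has_full_rank(self, library):
        sv = np.linalg.svd(library.B, compute_uv=False)
        assert (sv > 1e-6).sum() == 5

    def test_secondary_ppix_peak_present(self, library):
        col = library.B[:, 0]
        i704 = np.argmin(np.abs(library.grid.wavelengths - 704))
        assert 0.2 < col[i704] < 0.5

    def test_narrow_grid_rejected(self):
        with pytest.raises(ValueError):
            make_endmembers(WavelengthGrid(500.0, 3.0, 50))


class TestOpticalModel:
    def test_reflectance_scales_linearly_with_geometry(self, grid):
        base = OpticalProperties(42.0, 11.6, geom=1.0)
        double = OpticalProperties(42.0, 11.6, geom=2.0)
        np.testing.assert_allclose(
            reflectance_curve(double, grid), 2.0 * reflectance_curve(base, grid),
            rtol=1e-12,
        )

    def test_attenuation_scales_with_geometry_to_dual_band_power(self, grid):
        """A carries geom^(1+x) so the dual-band factor (which scales as
        geom^1.7 through the reflectance) cancels geometry exactly."""
        base = OpticalProperties(42.0, 11.6, geom=1.0)
        double = OpticalProperties(42.0, 11.6, geom=2.0)
        np.testing.assert_allclose(
            attenuation_curve(double, grid),
            2.0**GEOM_EXPONENT * attenuation_curve(base, grid),
            rtol=1e-12,
        )

    def test_vanishing_absorption_limit(self, grid):
        optics = OpticalProperties(1e-9, 11.6, geom=1.4)
        np.testing.assert_allclose(reflectance_curve(optics, grid), 1.4, rtol=1e-7)

    def test_attenuation_composes_from_helpers(self, grid):
        optics = OpticalProperties(37.0, 10.0, geom=1.3)
        rs = _reflectance_shape(optics, grid)
        idx = grid.band_indices(620.0, 640.0)
        manual = (
            optics.geom**GEOM_EXPONENT
            * _excitation_factor(optics)
            * rs**0.7
            * rs[idx].mean()
        )
        np.testing.assert_allclose(attenuation_curve(optics, grid), manual, rtol=1e-12)


class TestSimulatePair:
    def test_noise_free_limit_proportional_to_mixture(self, library):
        optics = OpticalProperties(1e-9, 11.6, geom=1.0)
        z = np.array([1.0, 0.2, 0.1, 0.0, 0.3])
        pair = simulate_pair(z, library, optics, NoiseModel(), seed=0)
        mixture = library.B @ z
        ratio = pair.phi_fluo[mixture > 1e-9] / mixture[mixture > 1e-9]
        assert np.ptp(ratio) < 1e-6 * ratio.mean()

    def test_seeded_pair_reproducible(self, library):
        optics = OpticalProperties(42.0, 11.6)
        kw = dict(noise=NoiseModel(gaussian_sd=0.01, poisson_scale=100.0), seed=42)
        a = simulate_pair(np.ones(5), library, optics, **kw)
        b = simulate_pair(np.ones(5), library, optics, **kw)
        np.testing.assert_array_equal(a.phi_fluo, b.phi_fluo)

    def test_noisy_mean_converges_to_noiseless(self, library):
        optics = OpticalProperties(42.0, 11.6)
        z = np.array([2.0, 0, 0.2, 0.2, 0.2])
        clean = simulate_pair(z, library, optics, NoiseModel(), seed=0).phi_fluo
        noise = NoiseModel(gaussian_sd=0.01)
        rng = np.random.default_rng(3)
        draws = np.stack(
            [simulate_pair(z, library, optics, noise, rng).phi_fluo for _ in range(4000)]
        )
        se = 0.01 / np.sqrt(4000)
        # clipping at 0 inflates the mean only where the signal is ~0; check
        # bands with clear signal
        strong = clean > 5 * 0.01
        assert np.all(np.abs(draws.mean(0)[strong] - clean[strong]) < 4 * se)


class TestPhantomDataset:
    def test_counts_and_concentrations(self, library):
        ds = generate_phantom_dataset(n_per_vial=3, seed=0, library=library)
        assert len(ds) == 45 * 3
        assert {p.c_ppix for p in ds} == {0.0, 0.2, 0.6, 1.25, 2.5}
        assert len({p.group_id for p in ds}) == 45
        assert all(p.unit_tag == "ug_per_ml" for p in ds)

    def test_within_vial_noiseless_spectra_identical(self, library):
        ds = generate_phantom_dataset(
            n_per_vial=4, seed=0, library=library, noise=NoiseModel()
        )
        by_group = {}
        for p in ds:
            by_group.setdefault(p.group_id, []).append(p)
        for pairs in by_group.values():
            ref = pairs[0].phi_fluo
            for p in pairs[1:]:
                np.testing.assert_array_equal(p.phi_fluo, ref)

    def test_determinism_under_seed(self, library):
        a = generate_phantom_dataset(n_per_vial=2, seed=9, library=library)
        b = generate_phantom_dataset(n_per_vial=2, seed=9, library=library)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.phi_fluo, y.phi_fluo)


class TestPbhDataset:
    def test_group_structure(self, library):
        ds = generate_pbh_dataset(n_per_sample=2, samples_per_conc=4, seed=1,
                                  library=library)
        assert len({p.group_id for p in ds}) == 7 * 4
        assert {p.c_ppix for p in ds} == {0.0, 0.5, 0.75, 1.0, 2.0, 3.0, 4.0}
        assert all(p.unit_tag == "pmol_per_mg" for p in ds)

    def test_zero_concentration_samples_have_no_ppix(self, library, monkeypatch):
        # observe the abundance vectors the generator feeds the forward model
        import fluorounmix.synthetic as syn

        recorded = []
        original = syn.simulate_pair

        def spy(z, *args, **kwargs):
            recorded.append((np.array(z, float), kwargs.get("c_ppix")))
            return original(z, *args, **kwargs)

        monkeypatch.setattr(syn, "simulate_pair", spy)
        syn.generate_pbh_dataset(n_per_sample=2, seed=1, library=library,
                                 noise=NoiseModel())
        zero = [z for z, c in recorded if c == 0.0]
        assert zero and all(z[0] == 0 and z[1] == 0 for z in zero)
        nonzero = [z for z, c in recorded if c and c > 0]
        assert all(z[0] > 0 and z[1] > 0 for z in nonzero)

    def test_optics_vary_across_groups(self, library):
        ds = generate_pbh_dataset(n_per_sample=1, seed=1, library=library,
                                  noise=NoiseModel())
        refs = {}
        for p in ds:
            refs[p.group_id] = p.phi_ref
        stack = np.stack(list(refs.values()))
        assert np.all(stack.std(axis=0)[stack.mean(axis=0) > 1e-6] > 0)


class TestUnlabeledDataset:
    def test_no_labels_and_determinism(self, library):
        a = generate_unlabeled_dataset(n=50, seed=2, library=library)
        b = generate_unlabeled_dataset(n=50, seed=2, library=library)
        assert all(p.c_ppix is None and p.unit_tag == "unlabeled" for p in a)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.phi_fluo, y.phi_fluo)

    def test_average_support_near_three_of_five(self, library, monkeypatch):
        # each endmember is present with probability 0.6, so the support
        # size is Binomial(5, 0.6): mean 3 of 5
        import fluorounmix.synthetic as syn

        sizes = []
        original = syn.simulate_pair

        def spy(z, *args, **kwargs):
            sizes.append(int((np.asarray(z) > 0).sum()))
            return original(z, *args, **kwargs)

        monkeypatch.setattr(syn, "simulate_pair", spy)
        syn.generate_unlabeled_dataset(n=400, seed=3, library=library,
                                       noise=NoiseModel())
        mean = np.mean(sizes)
        se = np.sqrt(5 * 0.6 * 0.4 / len(sizes))
        assert abs(mean - 3.0) < 3 * se


class TestRenderCubes:
    def test_deterministic_under_seed(self, library):
        ds = generate_phantom_dataset(n_per_vial=1, seed=0, library=library)[:4]
        a = render_cubes(ds, 50, 50, seed=5)
        b = render_cubes(ds, 50, 50, seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.data, y.data)

    def test_too_small_image_rejected(self, library):
        ds = generate_phantom_dataset(n_per_vial=1, seed=0, library=library)[:1]
        with pytest.raises(ValueError):
            render_cubes(ds, 25, 25, b=10)
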