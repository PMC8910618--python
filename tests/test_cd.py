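"""Tests for CD bookkeeping, SVD, Debye-Hückel fitting and ionic strength."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specbind.cd import (
    CDSpectrum,
    THETA_COIL,
    debye_huckel_curve,
    fit_debye_huckel,
    from_mre,
    helix_fraction,
    ionic_strength,
    read_cd_csv,
    separate_components,
    svd_family,
    theta_helix,
    to_mre,
    write_cd_csv,
)
from specbind.synthetic import (
    GroundTruth,
    coil_basis,
    gen_cd_salt_series,
    gen_mixture_spectrum,
    helix_basis,
)

WL = np.arange(190.0, 251.0, 1.0)


class TestMRE:
    def test_zero_signal_zero_mre(self):
        spec = to_mre(WL, np.zeros_like(WL), 40e-6, 0.1, 54)
        assert np.all(spec.ellipticity == 0.0)

    def test_worked_arithmetic_40uM_1mm_54res(self):
        # -10 mdeg at 40 uM, 1 mm path, 54 residues
        spec = to_mre(WL, np.full_like(WL, -10.0), 40e-6, 0.1, 54)
        assert spec.ellipticity[0] == pytest.approx(-4629.63, abs=0.01)

    def test_doubling_concentration_halves_mre(self):
        raw = np.sin(WL / 10.0) * 5.0
        a = to_mre(WL, raw, 20e-6, 0.1, 54)
        b = to_mre(WL, raw, 40e-6, 0.1, 54)
        assert np.allclose(a.ellipticity, 2.0 * b.ellipticity)

    def test_inverse_transform_round_trips(self):
        raw = np.cos(WL / 7.0) * 12.0
        spec = to_mre(WL, raw, 15e-6, 0.1, 54)
        assert np.allclose(from_mre(spec), raw, rtol=1e-12)

    @pytest.mark.parametrize("bad", ["concentration", "pathlength_cm", "n_residues"])
    def test_nonpositive_meta_rejected(self, bad):
        kwargs = dict(concentration=40e-6, pathlength_cm=0.1, n_residues=54)
        kwargs[bad] = 0
        with pytest.raises(ValueError, match=bad):
            to_mre(WL, np.zeros_like(WL), **kwargs)


class TestSVDFamily:
    def test_identical_spectra_have_one_nonzero_singular_value(self):
        spec = CDSpectrum(WL, np.sin(WL / 15.0) * 1000)
        svd = svd_family([spec, spec, spec])
        assert svd.n_significant(rtol=1e-10) == 1

    def test_two_shape_family_recovers_mixing_amplitudes(self):
        """A family built from a fixed mean shape plus a scaled difference
        shape has exactly rank 2, and the centred second-component loadings
        are proportional to the generator's mixing coefficients."""
        rng = np.random.default_rng(7)
        base = rng.normal(size=len(WL)) * 100 + 2000
        diff = np.cos(WL / 9.0) * 500
        mix = np.array([0.0, 0.3, 0.7, 1.0, 1.4])
        spectra = [CDSpectrum(WL, base + m * diff) for m in mix]
        svd = svd_family(spectra)
        assert svd.n_significant(rtol=1e-10) == 2
        amp = svd.amplitudes[1, :]
        centred = amp - amp.mean()
        target = mix - mix.mean()
        corr = abs(
            np.dot(centred, target) / np.linalg.norm(centred) / np.linalg.norm(target)
        )
        assert corr == pytest.approx(1.0, abs=1e-10)

    def test_reconstruction_identity_and_ordering_random_matrix(self):
        rng = np.random.default_rng(11)
        spectra = [CDSpectrum(WL, rng.normal(size=len(WL)) * 1e3) for _ in range(6)]
        svd = svd_family(spectra)
        matrix = np.column_stack([s.ellipticity for s in spectra])
        assert np.allclose(svd.reconstruct(), matrix, atol=1e-8)
        assert np.all(np.diff(svd.singular_values) <= 0)
        assert np.all(svd.singular_values >= 0)
        # rank-k error equals the l2 tail of discarded singular values
        for k in (1, 3):
            err = np.linalg.norm(matrix - svd.reconstruct(rank=k))
            tail = np.linalg.norm(svd.singular_values[k:])
            assert err == pytest.approx(tail, rel=1e-8)

    def test_first_component_positively_correlates_with_mean(self):
        spectra = [CDSpectrum(WL, -np.abs(np.sin(WL / 12.0)) * (1 + i)) for i in range(4)]
        svd = svd_family(spectra)
        mean = np.column_stack([s.ellipticity for s in spectra]).mean(axis=1)
        assert np.dot(svd.components[:, 0], mean) > 0

    def test_single_spectrum_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            svd_family([CDSpectrum(WL, np.zeros_like(WL))])

    def test_non_overlapping_grids_rejected(self):
        a = CDSpectrum(np.arange(190.0, 211.0), np.zeros(21))
        b = CDSpectrum(np.arange(260.0, 281.0), np.zeros(21))
        with pytest.raises(ValueError, match="overlap"):
            svd_family([a, b])


class TestDebyeHuckel:
    IONIC = np.array([0.001, 0.005, 0.02, 0.05, 0.1, 0.3, 0.7])

    def test_exact_recovery_from_noise_free_curve(self):
        amps = debye_huckel_curve(self.IONIC, s0=0.0, c1=2.0, c2=3.0)
        fit = fit_debye_huckel(amps, self.IONIC)
        assert fit.converged
        assert fit.s0 == pytest.approx(0.0, abs=1e-6)
        assert fit.c1 == pytest.approx(2.0, rel=1e-3)
        assert fit.c2 == pytest.approx(3.0, rel=1e-3)

    def test_constant_amplitudes_give_flat_curve(self):
        fit = fit_debye_huckel(np.full_like(self.IONIC, 5.0), self.IONIC)
        assert fit.c1 == pytest.approx(0.0, abs=1e-6)
        assert fit.s0 == pytest.approx(5.0, abs=1e-6)

    def test_curve_at_zero_ionic_strength_is_s0(self):
        amps = debye_huckel_curve(self.IONIC, 1.5, 2.0, 3.0)
        fit = fit_debye_huckel(amps, self.IONIC)
        assert fit.curve(np.array([0.0]))[0] == pytest.approx(fit.s0)

    def test_fitted_curve_monotone_and_bounded(self):
        amps = debye_huckel_curve(self.IONIC, 1.0, -2.5, 4.0)
        fit = fit_debye_huckel(amps, self.IONIC)
        grid = np.linspace(0, 1e4, 2000)
        curve = fit.curve(grid)
        diffs = np.diff(curve)
        assert np.all(diffs <= 1e-12) or np.all(diffs >= -1e-12)
        # saturates at s0 + c1/c2
        assert curve[-1] == pytest.approx(fit.s0 + fit.c1 / fit.c2, rel=1e-2)

    def test_limiting_law_option_pins_screening_to_zero(self):
        amps = 0.5 + 1.2 * np.sqrt(self.IONIC)
        fit = fit_debye_huckel(amps, self.IONIC, limiting_law=True)
        assert fit.c2 == 0.0
        assert fit.c1 == pytest.approx(1.2, rel=1e-6)

    def test_insufficient_span_rejected(self):
        with pytest.raises(ValueError, match="10-fold"):
            fit_debye_huckel(np.ones(4), np.array([0.1, 0.12, 0.15, 0.2]))


class TestSeparateComponents:
    def test_exact_mixture_recovers_protein_with_zero_residual(self):
        truth = GroundTruth(seed=0)
        triple = gen_mixture_spectrum(truth)
        mix = CDSpectrum(
            triple["protein"].wavelengths,
            triple["protein"].ellipticity + triple["dna"].ellipticity,
        )
        sep = separate_components(mix, triple["protein"], triple["dna"])
        assert sep["residual_norm"] == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(
            sep["protein"].ellipticity, triple["protein"].ellipticity, atol=1e-8
        )

    def test_bound_state_features_stay_in_protein_attribution(self):
        """When the mixture carries a bound-state protein shape absent from
        the free-protein basis, the protein-attributed spectrum keeps it and
        the projection residual concentrates below 250 nm (the protein
        far-UV region), not in the DNA bands above 250 nm."""
        truth = GroundTruth(helix_free=0.30, helix_bound=0.50, seed=0)
        triple = gen_mixture_spectrum(truth)
        sep = separate_components(triple["mixture"], triple["protein"], triple["dna"])
        wl = sep["wavelengths"]
        resid = np.abs(sep["residual"])
        assert resid[wl <= 250].sum() > 10 * resid[wl > 250].sum()

    def test_zero_mixture_zero_outputs(self):
        truth = GroundTruth(seed=0)
        triple = gen_mixture_spectrum(truth)
        zero = CDSpectrum(triple["mixture"].wavelengths,
                          np.zeros_like(triple["mixture"].ellipticity))
        sep = separate_components(zero, triple["protein"], triple["dna"])
        assert sep["residual_norm"] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sep["protein"].ellipticity, 0.0)

    def test_collinear_basis_flagged(self):
        base = CDSpectrum(WL, np.sin(WL / 11.0) * 1000)
        near = CDSpectrum(WL, base.ellipticity * (1 + 1e-12))
        sep = separate_components(base, base, near)
        assert sep["collinear"]


class TestHelixFraction:
    def test_pure_helix_basis_returns_one(self):
        spec = CDSpectrum(WL, helix_basis(WL, 54), meta={"n_residues": 54})
        assert helix_fraction(spec) == pytest.approx(1.0, abs=1e-9)

    def test_coil_anchor_returns_zero(self):
        spec = CDSpectrum(WL, coil_basis(WL), meta={"n_residues": 54})
        assert helix_fraction(spec) == pytest.approx(0.0, abs=1e-9)

    @given(f=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_in_mixing_fraction(self, f):
        ell = f * helix_basis(WL, 54) + (1 - f) * coil_basis(WL)
        spec = CDSpectrum(WL, ell, meta={"n_residues": 54})
        assert helix_fraction(spec) == pytest.approx(f, abs=1e-9)

    def test_free_state_spectrum_round_trips_thirty_percent(self):
        truth = GroundTruth(helix_free=0.30, seed=0)
        spec = gen_cd_salt_series(truth, [0.0, 0.1])[0]
        # at I = 0 the generated helix fraction equals the zero-screening value
        assert helix_fraction(spec) == pytest.approx(0.30, abs=0.02)

    def test_missing_222_nm_coverage_raises(self):
        grid = np.arange(240.0, 301.0)
        spec = CDSpectrum(grid, np.zeros_like(grid), meta={"n_residues": 54})
        with pytest.raises(ValueError, match="222"):
            helix_fraction(spec)

    def test_chain_length_correction(self):
        assert theta_helix(54) == pytest.approx(-40000 * (1 - 2.5 / 54))
        with pytest.raises(ValueError):
            theta_helix(2)


class TestIonicStrength:
    def test_one_to_one_salt(self):
        assert ionic_strength(recipe=[("NaCl", 0.05, 0)]) == pytest.approx(0.05)

    def test_phosphate_buffer_worked_example(self):
        # 25 mM sodium phosphate pH 6.8 + 50 mM NaCl ~ 0.09 M,
        # i.e. ~100 mM at nearest-100 reporting precision
        result = ionic_strength(
            recipe=[("NaCl", 0.05, 0)], buffers=[("phosphate", 0.025)], ph=6.8
        )
        assert result == pytest.approx(0.09, abs=0.005)
        assert round(result * 1000 / 100) * 100 == 100

    def test_empty_recipe_is_zero(self):
        assert ionic_strength(recipe=[], buffers=[]) == 0.0

    def test_unknown_buffer_lists_known_ones(self):
        with pytest.raises(ValueError, match="phosphate"):
            ionic_strength(buffers=[("carbonate", 0.01)], ph=7.0)

    def test_tris_base_gets_chloride_counterions(self):
        # fully protonated limit: 20 mM TrisH+ + 20 mM Cl- -> I = 0.02
        assert ionic_strength(buffers=[("tris", 0.02)], ph=2.0) == pytest.approx(
            0.02, rel=1e-3
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            ionic_strength(recipe=[("KF", -0.1, 0)])


class TestCdCsvIO:
    def test_mre_round_trip(self, tmp_path):
        spec = CDSpectrum(WL, np.sin(WL / 13.0) * 5000, meta={"n_residues": 54})
        path = tmp_path / "spec.csv"
        write_cd_csv(spec, path)
        back = read_cd_csv(path, meta={"n_residues": 54})
        assert np.allclose(back.ellipticity, spec.ellipticity)

    def test_mdeg_requires_sample_metadata(self, tmp_path):
        path = tmp_path / "raw.csv"
        path.write_text("wavelength_nm,signal,unit\n222,-10.0,mdeg\n250,-1.0,mdeg\n")
        with pytest.raises(ValueError, match="concentration"):
            read_cd_csv(path)
        spec = read_cd_csv(
            path,
            meta={"concentration": 40e-6, "pathlength_cm": 0.1, "n_residues": 54},
        )
        assert spec.ellipticity[0] == pytest.approx(-4629.63, abs=0.01)
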