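"""Phantom generation and spectral synthesis against ground truth."""

import numpy as np
import pytest
from scipy import ndimage

from carsense.amide import DEFAULT_BAND_MODEL
from carsense.synthetic import (
    BACKGROUND,
    CYTOPLASM,
    DEFAULT_COMPOSITIONS,
    NUCLEOLUS,
    NUCLEOPLASM,
    NoiseConfig,
    PhantomLayout,
    SpectralComposition,
    compose_region_spectrum,
    make_phantom,
    senescent_composition,
    synthesize_cube,
)

DENSE = np.arange(1540.0, 1740.0001, 0.01)


def dense_argmax(composition):
    """Brute-force peak position oracle on a 0.01 cm^-1 grid."""
    spec = compose_region_spectrum(
        SpectralComposition(composition.weights), DENSE, DEFAULT_BAND_MODEL
    )
    return DENSE[np.argmax(spec)]


class TestMakePhantom:
    def test_determinism_and_seed_sensitivity(self):
        layout = PhantomLayout(n_control=2, n_senescent=2)
        a = make_phantom(layout, seed=1)
        b = make_phantom(layout, seed=1)
        c = make_phantom(layout, seed=2)
        assert np.array_equal(a.label_image, b.label_image)
        assert not np.array_equal(a.label_image, c.label_image)

    def test_region_nesting_invariants(self, small_phantom):
        label, cells = small_phantom.label_image, small_phantom.cell_ids
        # every nucleolus pixel is 4-adjacent only to nucleus-extent or nucleolus
        grown = ndimage.binary_dilation(label == NUCLEOLUS)
        assert np.all(label[grown] >= NUCLEOPLASM)
        # labelled pixels always belong to a cell; background never does
        assert np.all(cells[label > BACKGROUND] > 0)
        assert np.all(label[cells == 0] == BACKGROUND)

    def test_control_cell_classifiable_as_control(self):
        # nucleus r=4 px at 0.5 um/pixel: area 16*pi*0.25 ~ 12.6 um^2 << 118
        layout = PhantomLayout(
            n_control=1, n_senescent=0, nucleus_radius_control=4.0,
            nucleolus_radius_control=1.5,
        )
        ph = make_phantom(layout, seed=0)
        nucleus_px = np.sum(ph.label_image >= NUCLEOPLASM)
        assert nucleus_px * 0.5**2 < 118.0
        assert ph.nuclei_per_cell[1] == 1

    def test_senescent_cells_are_binucleate(self, small_phantom):
        for cid, phen in small_phantom.phenotype.items():
            expected = 2 if phen == "senescent" else 1
            nucleus = (small_phantom.cell_ids == cid) & (
                small_phantom.label_image >= NUCLEOPLASM
            )
            _, n = ndimage.label(nucleus)
            assert n == expected == small_phantom.nuclei_per_cell[cid]

    def test_zero_nucleoli_requested(self):
        layout = PhantomLayout(n_control=1, n_senescent=0, nucleoli_per_nucleus=0)
        ph = make_phantom(layout, seed=0)
        assert not (ph.label_image == NUCLEOLUS).any()

    def test_unplaceable_layout_raises(self):
        layout = PhantomLayout(shape=(64, 64), n_control=9, n_senescent=9)
        with pytest.raises(ValueError, match="cannot place cell"):
            make_phantom(layout, seed=0)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            PhantomLayout(nucleus_radius_control=11.0)  # > cell radius 10


class TestComposeRegionSpectrum:
    def test_pure_alpha_peaks_at_1650(self):
        spec = compose_region_spectrum(SpectralComposition((0, 1, 0)), DENSE)
        assert DENSE[np.argmax(spec)] == pytest.approx(1650.0, abs=0.01)

    def test_zero_weights_zero_spectrum(self):
        spec = compose_region_spectrum(SpectralComposition((0, 0, 0)), DENSE)
        assert not spec.any()

    def test_equal_alpha_beta_peak_matches_dense_oracle(self):
        # frozen from the brute-force 0.01 cm^-1 argmax of the (0,1,1) sum
        assert dense_argmax(SpectralComposition((0, 1, 1))) == pytest.approx(1663.79, abs=0.02)

    def test_linearity_in_weights(self, amide_axis):
        comp = SpectralComposition((0.3, 1.0, 0.4), ch_weight=0.5)
        s1 = compose_region_spectrum(comp, amide_axis)
        s2 = compose_region_spectrum(comp.scaled(2.0), amide_axis)
        assert np.allclose(s2, 2 * s1, rtol=1e-12, atol=0)

    def test_uncovered_component_flagged(self):
        meta = {}
        compose_region_spectrum(
            SpectralComposition((0, 1, 0), ch_weight=1.0),
            np.arange(1540.0, 1741.0),
            meta=meta,
        )
        assert "ch" in meta["uncovered"]

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            SpectralComposition((-0.1, 1, 0))


class TestDefaultCompositionPeaks:
    def test_control_cytoplasm_peaks_at_1653(self):
        peak = dense_argmax(DEFAULT_COMPOSITIONS[("control", "cytoplasm")])
        assert abs(peak - 1653.0) <= 1.0

    def test_nucleolar_peaks_straddle_amyloid_threshold(self):
        control = dense_argmax(DEFAULT_COMPOSITIONS[("control", "nucleolus")])
        senescent = dense_argmax(DEFAULT_COMPOSITIONS[("senescent", "nucleolus")])
        assert control < 1660.0 < senescent
        assert DEFAULT_COMPOSITIONS[("senescent", "nucleolus")].beta_fraction >= 0.55


class TestSynthesizeCube:
    def test_noiseless_im_domain_reproduces_compositions(self, small_phantom):
        cube, truth = synthesize_cube(small_phantom, seed=0)
        axis = cube.axis_cm1
        for cid, phen in small_phantom.phenotype.items():
            sel = (small_phantom.cell_ids == cid) & (
                small_phantom.label_image == NUCLEOLUS
            )
            expected = compose_region_spectrum(
                DEFAULT_COMPOSITIONS[(phen, "nucleolus")], axis
            )
            assert np.allclose(cube.data[sel], expected)

    def test_ground_truth_beta_fraction_sweep_exact(self, small_phantom):
        for bf in (0.0, 0.25, 0.5, 0.75, 1.0):
            comp = senescent_composition(bf)
            assert comp.beta_fraction == pytest.approx(bf, abs=1e-15)

    def test_reproducibility_bit_identical(self, small_phantom):
        noise = NoiseConfig(sigma=0.01, baseline_amp=0.02)
        c1, _ = synthesize_cube(small_phantom, noise=noise, seed=5)
        c2, _ = synthesize_cube(small_phantom, noise=noise, seed=5)
        assert np.array_equal(c1.data, c2.data)

    def test_chi3_domain_im_band_areas_match_g_truth(self, small_phantom):
        cube, truth = synthesize_cube(small_phantom, mode="chi3_domain", seed=0)
        axis = cube.axis_cm1
        band = (axis >= 1540) & (axis <= 1740)
        bm = DEFAULT_BAND_MODEL
        for phen in ("control", "senescent"):
            comp = DEFAULT_COMPOSITIONS[(phen, "nucleolus")]
            from carsense.synthetic import _lorentzian_lines_for

            lines = _lorentzian_lines_for(comp, bm, resonant_scale=40.0)
            im = np.zeros(axis.size)
            for om, a, gm in lines:
                im += a * gm / ((om - axis) ** 2 + gm**2)
            area = np.trapezoid(im[band], axis[band])
            g_total = 40.0 * sum(comp.weights)
            assert area == pytest.approx(g_total, rel=0.05)

    def test_unknown_mode_rejected(self, small_phantom):
        with pytest.raises(ValueError, match="mode"):
            synthesize_cube(small_phantom, mode="frequency_domain")

    def test_region_mean_peaks_match_phenotype(self, small_phantom):
        cube, _ = synthesize_cube(small_phantom, seed=0)
        axis = cube.axis_cm1
        window = (axis >= 1540) & (axis <= 1740)
        for phen, cmp_fn in (("senescent", np.greater), ("control", np.less)):
            cells = [c for c, p in small_phantom.phenotype.items() if p == phen]
            sel = np.isin(small_phantom.cell_ids, cells) & (
                small_phantom.label_image == NUCLEOLUS
            )
            mean_spec = cube.data[sel].mean(axis=0)
            peak = axis[window][np.argmax(mean_spec[window])]
            assert cmp_fn(peak, 1660.0)
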