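"""Reference-spectrum measurement, assembly, and CSV round trips."""

import numpy as np
import pytest

from spectralbeads import SceneSpec
from spectralbeads.imageio import from_arrays
from spectralbeads.references import (
    ReferenceMatrix,
    assemble,
    background_spectrum,
    load_reference_csv,
    save_reference_csv,
    spectrum_from_reference_beads,
)
from spectralbeads.synth import default_reference_matrix, generate_reference_set

from conftest import draw_ring


def scene_with_constant_cores(core_values, shape=(64, 64)):
    """One bead; each emission channel constant at the given value inside the core."""
    bf = draw_ring(shape, (32, 32), 7)
    channels = [bf]
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    core = np.hypot(rr - 32, cc - 32) <= 5
    for value in core_values:
        grid = np.full(shape, 1.0)
        grid[core] = value
        channels.append(grid)
    names = ["Bright-field"] + [f"em{i}" for i in range(len(core_values))]
    return from_arrays({"ref": np.array(channels)}, names), names[1:]


class TestSpectrumFromReferenceBeads:
    def test_constant_core_returns_exact_values(self):
        values = [10.0, 20.0, 30.0]
        images, emission = scene_with_constant_cores(values)
        spectrum = spectrum_from_reference_beads(images, emission)
        np.testing.assert_allclose(spectrum, values)

    def test_half_low_half_high_median_convention(self):
        # half the core pixels at s, half at 3s -> per-channel median 2s
        from spectralbeads.beadfind import adaptive_threshold, segment_beads

        shape = (64, 64)
        bf = draw_ring(shape, (32, 32), 7)
        masks, _ = segment_beads(adaptive_threshold(bf), (10, 20))
        coords = np.argwhere(masks.core > 0)
        n = len(coords)
        grid = np.full(shape, 1.0)
        half = n // 2
        for i, (r, c) in enumerate(coords):
            if i < half:
                grid[r, c] = 5.0
            elif i < 2 * half:
                grid[r, c] = 15.0
            else:  # odd pixel count: one pixel at the midpoint value
                grid[r, c] = 10.0
        images = from_arrays({"ref": np.array([bf, grid])}, ["Bright-field", "em0"])
        spectrum = spectrum_from_reference_beads(images, ["em0"])
        # sort-based oracle over the segmented core pixels
        expected = np.median(np.sort(grid[masks.core > 0]))
        assert spectrum[0] == expected == 10.0

    def test_no_beads_errors_naming_set(self):
        blank = np.full((2, 32, 32), 100.0)
        images = from_arrays({"empty_set": blank}, ["Bright-field", "em0"])
        with pytest.raises(ValueError, match="empty_set"):
            spectrum_from_reference_beads(images, ["em0"])


class TestBackgroundSpectrum:
    def test_uniform_background(self):
        images = from_arrays(
            {"s": np.stack([np.full((16, 16), 3.0), np.full((16, 16), 9.0)])},
            ["em0", "em1"],
        )
        np.testing.assert_allclose(
            background_spectrum(images, (0, 0, 8, 8), ["em0", "em1"]), [3.0, 9.0]
        )

    def test_four_pixel_median_oracle(self):
        grid = np.zeros((2, 2))
        grid[0, 0], grid[0, 1], grid[1, 0], grid[1, 1] = 1, 2, 3, 100
        images = from_arrays({"s": grid[None]}, ["em0"])
        assert background_spectrum(images, (0, 0, 2, 2), ["em0"])[0] == 2.5

    def test_empty_roi_errors(self):
        images = from_arrays({"s": np.zeros((1, 8, 8))}, ["em0"])
        with pytest.raises(ValueError, match="empty"):
            background_spectrum(images, (0, 0, 0, 4), ["em0"])


class TestAssemble:
    def test_shape_9x5_and_unit_sums(self):
        rng = np.random.default_rng(0)
        spectra = {n: rng.random(9) + 0.1 for n in ["Dy", "Sm", "Tm", "Eu"]}
        matrix = assemble(spectra, rng.random(9) + 0.1, [f"c{i}" for i in range(9)])
        assert matrix.A.shape == (9, 5)
        np.testing.assert_allclose(matrix.A.sum(axis=0), 1.0, atol=1e-9)
        assert matrix.names[-1] == "background"

    def test_permutation_permutes_columns(self):
        rng = np.random.default_rng(1)
        vecs = {n: rng.random(4) + 0.1 for n in "abc"}
        bg = rng.random(4) + 0.1
        channels = list("wxyz")
        m1 = assemble({k: vecs[k] for k in "abc"}, bg, channels)
        m2 = assemble({k: vecs[k] for k in "cba"}, bg, channels)
        for name in "abc":
            np.testing.assert_allclose(m1.column(name), m2.column(name))

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError, match="zero"):
            assemble({"a": np.zeros(3)}, np.ones(3), list("xyz"))

    def test_normalization_idempotent(self):
        rng = np.random.default_rng(2)
        m = assemble({"a": rng.random(5)}, rng.random(5), list("abcde"))
        again = ReferenceMatrix(m.channels, m.names, m.A)
        np.testing.assert_allclose(again.A, m.A)

    def test_scale_invariance_of_measured_spectrum(self):
        """Globally rescaling reference images leaves the normalized column unchanged."""
        values = [10.0, 20.0, 30.0]
        images, emission = scene_with_constant_cores(values)
        s1 = spectrum_from_reference_beads(images, emission)
        scaled = images.map(lambda g: 3.0 * g, channels=set(emission))
        s2 = spectrum_from_reference_beads(scaled, emission)
        np.testing.assert_allclose(s2 / s2.sum(), s1 / s1.sum(), atol=1e-12)


class TestReferenceCsv:
    def test_round_trip(self, tmp_path, reference):
        path = tmp_path / "ref.csv"
        save_reference_csv(reference, path)
        loaded = load_reference_csv(path)
        assert loaded.names == reference.names
        assert loaded.channels == reference.channels
        np.testing.assert_allclose(loaded.A, reference.A, atol=1e-12)
        assert loaded.A.shape == (9, 5)

    def test_non_numeric_cell_names_location(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("channel,Dy,Eu\nc0,0.5,0.5\nc1,oops,0.5\n")
        with pytest.raises(ValueError, match="row 2.*'Dy'"):
            load_reference_csv(path)

    def test_missing_header_errors(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="channel"):
            load_reference_csv(path)


class TestClosureWithSynthScenes:
    def test_reference_scenes_recover_rendering_matrix(self):
        """Spectra measured from synthetic single-species bead sets reproduce
        the rendering matrix columnwise after normalization."""
        rendering = default_reference_matrix()
        spec = SceneSpec(
            image_shape=(256, 256), n_beads=10, read_noise_sd=0.0,
            eu_level_sd=0.0, seed=9, reference=rendering,
        )
        spectra = {}
        for lnp in rendering.lnp_names:
            images = generate_reference_set(spec, lnp)
            raw = spectrum_from_reference_beads(images, rendering.channels)
            # subtract the known background contribution before comparing
            raw = raw - rendering.column("background") * spec.background_level
            spectra[lnp] = raw
        assembled = assemble(
            spectra, rendering.column("background"), rendering.channels
        )
        np.testing.assert_allclose(assembled.A, rendering.A, atol=1e-6)

    def test_spectrum_invariant_to_bead_count(self):
        rendering = default_reference_matrix()
        base = dict(
            image_shape=(256, 256), read_noise_sd=0.0, eu_level_sd=0.0,
            seed=3, reference=rendering,
        )
        s1 = spectrum_from_reference_beads(
            generate_reference_set(SceneSpec(n_beads=4, **base), "Eu"),
            rendering.channels,
        )
        s2 = spectrum_from_reference_beads(
            generate_reference_set(SceneSpec(n_beads=12, **base), "Eu"),
            rendering.channels,
        )
        np.testing.assert_allclose(s1, s2, rtol=1e-9)

    def test_unknown_species_errors(self):
        with pytest.raises(ValueError, match="unknown species"):
            generate_reference_set(SceneSpec(), "Yb")
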