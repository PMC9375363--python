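import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from nir2dcos import (ImageDataset, TwoDcosImager, async_map,
                      correlation_maps, decimate_indices, generate_image_set,
                      hilbert_noda_matrix, integrated_map, render_map_image,
                      sync_map)
from nir2dcos.twodcos import colormap_lut


# -- independent elementwise oracles for the correlation definitions -------

def sync_oracle(Y):
    m, n = Y.shape
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            out[a, b] = sum(Y[t, a] * Y[t, b] for t in range(m)) / (m - 1)
    return out


def async_oracle(Y):
    m, n = Y.shape
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            acc = 0.0
            for j in range(m):
                for k in range(m):
                    if j != k:
                        acc += Y[j, a] * Y[k, b] / (np.pi * (k - j))
            out[a, b] = acc / (m - 1)
    return out


series = arrays(np.float64, st.tuples(st.integers(2, 4), st.integers(2, 8)),
                elements=st.floats(-10, 10, allow_nan=False))


class TestHilbertNoda:
    def test_m1_is_zero(self):
        np.testing.assert_array_equal(hilbert_noda_matrix(1), [[0.0]])

    def test_m2_entries(self):
        D = hilbert_noda_matrix(2)
        np.testing.assert_allclose(D, [[0.0, 1 / np.pi], [-1 / np.pi, 0.0]])
        assert D[0, 1] == pytest.approx(0.31831, abs=5e-6)

    def test_m3_off_diagonal(self):
        D = hilbert_noda_matrix(3)
        assert D[0, 2] == pytest.approx(1 / (2 * np.pi))
        assert D[0, 2] == pytest.approx(0.15915, abs=5e-6)
        np.testing.assert_array_equal(D, -D.T)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            hilbert_noda_matrix(0)


class TestMaps:
    def test_sync_worked_example(self):
        np.testing.assert_allclose(sync_map([[1, 2], [3, 4]]),
                                   [[10, 14], [14, 20]], rtol=1e-12)

    def test_async_worked_example(self):
        expected = (1 / np.pi) * np.array([[0.0, -2.0], [2.0, 0.0]])
        np.testing.assert_allclose(async_map([[1, 2], [3, 4]]), expected,
                                   atol=1e-12)
        assert async_map([[1, 2], [3, 4]])[0, 1] == pytest.approx(-0.63662,
                                                                  abs=5e-6)

    def test_integrated_worked_example(self):
        phi = sync_map([[1, 2], [3, 4]])
        psi = async_map([[1, 2], [3, 4]])
        W = integrated_map(phi, psi)
        np.testing.assert_allclose(W, [[0.0, -8.9127], [8.9127, 0.0]],
                                   atol=5e-5)

    def test_zero_rows_give_zero_maps(self):
        Z = np.zeros((2, 5))
        assert not sync_map(Z).any() and not async_map(Z).any()

    def test_identical_rows_zero_async(self, rng):
        row = rng.normal(size=6)
        np.testing.assert_array_equal(async_map(np.stack([row, row])), 0.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sync_map(np.ones((1, 4)))

    def test_integrated_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            integrated_map(np.ones((2, 2)), np.ones((3, 3)))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(series)
    def test_oracle_equivalence(self, Y):
        np.testing.assert_allclose(sync_map(Y), sync_oracle(Y), atol=1e-12)
        np.testing.assert_allclose(async_map(Y), async_oracle(Y), atol=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(series)
    def test_structural_invariants(self, Y):
        phi, psi = sync_map(Y), async_map(Y)
        np.testing.assert_array_equal(phi, phi.T)
        np.testing.assert_array_equal(psi, -psi.T)
        np.testing.assert_array_equal(np.diag(psi), 0.0)
        assert np.diag(phi).min() >= -1e-12
        W = integrated_map(phi, psi)
        np.testing.assert_array_equal(np.diag(W), 0.0)

    def test_centered_diagonal_still_nonnegative(self, rng):
        Y = rng.normal(size=(2, 6))
        phi_c = sync_map(Y, center=True)
        assert np.diag(phi_c).min() >= -1e-12

    def test_scaling_quadratic_and_quartic(self, rng):
        Y = rng.normal(size=(2, 5))
        c = 3.0
        maps1, maps2 = correlation_maps(Y), correlation_maps(c * Y)
        np.testing.assert_allclose(maps2.sync, c ** 2 * maps1.sync, rtol=1e-12)
        np.testing.assert_allclose(maps2.async_, c ** 2 * maps1.async_,
                                   rtol=1e-12)
        np.testing.assert_allclose(maps2.integrated,
                                   c ** 4 * maps1.integrated, rtol=1e-12)

    def test_row_swap_fixes_sync_negates_async(self, rng):
        Y = rng.normal(size=(2, 5))
        swapped = Y[::-1]
        np.testing.assert_allclose(sync_map(swapped), sync_map(Y), rtol=1e-12)
        np.testing.assert_allclose(async_map(swapped), -async_map(Y),
                                   atol=1e-12)

    def test_decimation_is_subblock_of_full_maps(self, rng):
        Y = rng.normal(size=(2, 40))
        idx = decimate_indices(40, 10)
        full = correlation_maps(Y)
        deci = correlation_maps(Y[:, idx])
        np.testing.assert_array_equal(deci.sync, full.sync[np.ix_(idx, idx)])
        np.testing.assert_array_equal(deci.async_,
                                      full.async_[np.ix_(idx, idx)])


class TestRendering:
    def test_constant_map_uniform_midcolor(self):
        img = render_map_image(np.full((4, 4), 7.3), size=16)
        mid = colormap_lut("jet")[128]
        assert (img.reshape(-1, 3) == mid).all()

    def test_determinism(self, rng):
        M = rng.normal(size=(10, 10))
        a = render_map_image(M, size=32)
        b = render_map_image(M, size=32)
        np.testing.assert_array_equal(a, b)

    def test_negation_inverts_colors(self, rng):
        M = rng.normal(size=(16, 16))
        a = render_map_image(M, size=16)
        b = render_map_image(-M, size=16)
        lut = colormap_lut("jet")
        inv = {tuple(c): tuple(lut[255 - q]) for q, c in enumerate(lut)}
        for pa, pb in zip(a.reshape(-1, 3), b.reshape(-1, 3)):
            assert inv[tuple(pa)] == tuple(pb)

    def test_size_and_shape_validation(self):
        with pytest.raises(ValueError, match="size"):
            render_map_image(np.ones((4, 4)), size=4)
        with pytest.raises(ValueError, match="square"):
            render_map_image(np.ones((4, 3)), size=16)


class TestImager:
    def test_requires_labels_at_transform(self, rng):
        X = rng.normal(size=(4, 20))
        imager = TwoDcosImager(image_size=16, max_points=10)
        imager.fit(X, ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="labels"):
            imager.transform(X)

    def test_unseen_class_rejected(self, rng):
        X = rng.normal(size=(4, 20))
        imager = TwoDcosImager(image_size=16, max_points=10)
        imager.fit(X, ["a", "a", "b", "b"])
        with pytest.raises(KeyError, match="unseen"):
            imager.transform(X[:1], ["z"])

    def test_images_differ_between_map_types(self, small_dataset):
        spectra, manifest = small_dataset
        y = manifest["drying_method"].to_numpy()
        out = {t: TwoDcosImager(t, image_size=32, max_points=32)
               .fit_transform(spectra.absorbance, y)
               for t in ("sync", "async", "integrated")}
        assert not np.array_equal(out["sync"], out["async"])
        assert not np.array_equal(out["async"], out["integrated"])


class TestGenerateImageSet:
    def test_small_counts(self, small_dataset):
        spectra, manifest = small_dataset
        ds = generate_image_set(spectra, manifest, groupings=("drying",),
                                types=("sync", "async", "integrated"),
                                image_size=16, max_points=16)
        assert len(ds) == spectra.n_samples * 3
        assert isinstance(ds, ImageDataset)
        assert set(ds.records["map_type"]) == {"sync", "async", "integrated"}

    def test_two_samples_one_grouping(self, small_dataset):
        spectra, manifest = small_dataset
        two = spectra.select([0, 1])
        ds = generate_image_set(two, manifest, groupings=("region",),
                                image_size=16, max_points=16)
        assert len(ds) == 6

    def test_degenerate_single_member_class(self):
        from nir2dcos import SpectrumSet
        s = SpectrumSet(np.arange(8)[::-1] + 0.0,
                        np.linspace(0, 1, 8)[None, :], ["only"])
        import pandas as pd
        man = pd.DataFrame({"sample_id": ["only"], "region": ["Hunan"],
                            "site": ["X"], "drying_method": ["sun"],
                            "replicate": [1]})
        ds = generate_image_set(s, man, groupings=("drying",),
                                types=("sync",), image_size=16, max_points=8)
        assert len(ds) == 1
        # class mean == the sample itself, so async of the pair is zero and
        # sync equals twice the outer square of the spectrum
        maps = correlation_maps(np.stack([s.absorbance[0]] * 2))
        assert not maps.async_.any()

    def test_empty_sample_set_rejected(self, small_dataset):
        from nir2dcos import SpectrumSet
        spectra, manifest = small_dataset
        with pytest.raises(ValueError):
            generate_image_set(
                SpectrumSet(spectra.wavenumbers,
                            np.empty((0, spectra.n_points)), []),
                manifest, image_size=16, max_points=16)

    def test_save_writes_index(self, small_dataset, tmp_path):
        spectra, manifest = small_dataset
        ds = generate_image_set(spectra.select([0, 1]), manifest,
                                groupings=("drying",), types=("sync",),
                                image_size=16, max_points=16)
        index = ds.save(tmp_path)
        assert index.exists()
        import json
        entries = json.loads(index.read_text())["images"]
        assert len(entries) == 2
        assert (tmp_path / entries[0]["path"]).exists()
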