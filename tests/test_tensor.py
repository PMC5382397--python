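import numpy as np
import pytest

import octoscope as oc
from octoscope.errors import InvalidSigma
from octoscope.tensor import (binarize_otsu, canny_edges, coherency_map,
                              coherent_image, eigenvalues_2x2, gradients,
                              otsu_threshold, structure_tensor)


def brute_force_otsu_bin(img, nbins=256):
    """Independent exhaustive Otsu: loop every candidate split of the
    nbins-bin histogram, maximize between-class variance, first max wins."""
    hist, edges = np.histogram(np.clip(img, 0, 1), bins=nbins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_k, best_var = None, -1.0
    total = hist.sum()
    for k in range(nbins - 1):
        w0 = hist[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (hist[k + 1:] * centers[k + 1:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_k = var, k
    return None if best_k is None else centers[best_k]


class TestGradients:
    def test_constant_image_has_zero_gradients(self):
        ds, dt = gradients(np.full((10, 10), 0.4))
        assert not ds.any() and not dt.any()

    def test_axial_ramp_gives_constant_sobel_response(self):
        # slope-1 ramp along rows: Sobel = (x[r+1]-x[r-1]) * (1+2+1) = 8
        img = np.arange(20, dtype=float)[:, None] * np.ones((1, 20))
        ds, dt = gradients(img)
        np.testing.assert_allclose(ds[1:-1, 1:-1], 8.0)
        np.testing.assert_allclose(dt[:, 1:-1], 0.0)

    def test_horizontal_step_peaks_at_band_boundary(self):
        img = np.zeros((20, 20))
        img[10:] = 1.0
        ds, dt = gradients(img)
        assert np.abs(ds).argmax(axis=0).tolist() == [9] * 20 or \
            np.abs(ds).argmax(axis=0).tolist() == [10] * 20
        np.testing.assert_allclose(dt[:, 1:-1], 0.0)


class TestEigenCoherency:
    def test_closed_form_matches_generic_eigensolver(self):
        # 1000 random PSD tensors vs numpy's symmetric eigensolver
        rng = np.random.default_rng(11)
        g = rng.standard_normal((1000, 2, 2))
        mats = g.transpose(0, 2, 1) @ g
        l1, l2 = eigenvalues_2x2(mats[:, 0, 0], mats[:, 0, 1], mats[:, 1, 1])
        ref = np.linalg.eigvalsh(mats)
        np.testing.assert_allclose(l1, ref[:, 1], atol=1e-10)
        np.testing.assert_allclose(l2, ref[:, 0], atol=1e-10)
        tr = ref[:, 0] + ref[:, 1]
        href = np.where(tr > 0, ((ref[:, 1] - ref[:, 0]) / np.where(tr > 0, tr, 1)) ** 2, 0)
        np.testing.assert_allclose(coherency_map(l1, l2), href, atol=1e-10)

    @pytest.mark.parametrize("l1,l2,expected", [
        (3.0, 1.0, 0.25),   # ((3-1)/(3+1))^2
        (2.0, 2.0, 0.0),    # isotropic
        (5.0, 0.0, 1.0),    # perfect linear structure
        (0.0, 0.0, 0.0),    # 0/0 convention
    ])
    def test_reference_coherency_values(self, l1, l2, expected):
        assert coherency_map(np.array([l1]), np.array([l2]))[0] == pytest.approx(expected)

    def test_tensor_field_invariants_on_random_images(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            img = rng.random((24, 24))
            field = structure_tensor(*gradients(img), sigma=2.0)
            assert (field.lambda1 >= field.lambda2 - 1e-12).all()
            assert (field.lambda2 >= 0).all()
            assert ((field.coherency >= 0) & (field.coherency <= 1)).all()
            assert field.gamma_st is field.gamma_ts

    def test_invalid_sigma_rejected(self):
        ds, dt = gradients(np.ones((8, 8)))
        with pytest.raises(InvalidSigma):
            structure_tensor(ds, dt, sigma=0.0)


class TestCoherentImage:
    def test_constant_scan_gives_zero_image(self):
        field = structure_tensor(*gradients(np.full((32, 32), 0.5)), sigma=2.0)
        assert not coherent_image(field).any()

    def test_noiseless_phantom_argmax_sits_on_layer_interfaces(self):
        scan, truth = oc.make_phantom(oc.PhantomSpec(label="healthy", speckle_scale=0))
        denoised = oc.preprocess_scan(scan)
        field = structure_tensor(*gradients(denoised), sigma=2.0)
        ic = coherent_image(field)
        # candidate interfaces: ILM, RPE stripe, choroid, and the sublayer
        # boundaries the phantom renders every SUBLAYER_PX
        from octoscope.phantom import RPE_STRIPE_PX, SUBLAYER_PX
        peak_rows = ic[:, 50:-50].argmax(axis=0)
        cols = np.arange(ic.shape[1])[50:-50]
        cands = [truth.ilm[cols], truth.choroid[cols],
                 truth.rpe[cols] - (RPE_STRIPE_PX - 1) / 2,
                 truth.rpe[cols] + (RPE_STRIPE_PX + 1) / 2]
        n_sub = int((truth.choroid - truth.ilm).max() // SUBLAYER_PX) + 1
        cands += [truth.ilm[cols] + k * SUBLAYER_PX for k in range(1, n_sub)]
        dist = np.min(np.abs(np.stack(cands) - peak_rows[None, :]), axis=0)
        assert np.percentile(dist, 95) <= 2.0

    def test_stripes_are_more_coherent_than_white_noise(self):
        rng = np.random.default_rng(9)
        noise = rng.random((64, 64))
        stripes = np.tile((np.arange(64) // 4 % 2).astype(float)[:, None], (1, 64))
        h_noise = structure_tensor(*gradients(noise), sigma=2.0).coherency.mean()
        h_str = structure_tensor(*gradients(stripes), sigma=2.0).coherency.mean()
        assert h_str > 2 * h_noise


class TestOtsu:
    def test_bimodal_two_level_image(self):
        img = np.concatenate([np.full(60, 0.2), np.full(40, 0.8)]).reshape(10, 10)
        t = otsu_threshold(img)
        assert 0.2 < t < 0.8
        assert binarize_otsu(img).mean() == pytest.approx(0.4)

    def test_matches_brute_force_on_quantized_images(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            nlev = rng.integers(2, 17)
            levels = rng.choice(256, size=nlev, replace=False) / 255.0
            img = rng.choice(levels, size=(32, 32))
            assert otsu_threshold(img) == pytest.approx(brute_force_otsu_bin(img))

    def test_constant_image_yields_empty_foreground_with_warning(self):
        with pytest.warns(UserWarning):
            mask = binarize_otsu(np.full((8, 8), 0.3))
        assert not mask.any()


class TestCanny:
    def test_empty_map_has_no_edges(self):
        assert not canny_edges(np.zeros((32, 32), dtype=bool)).any()

    def test_rectangle_edges_follow_morphological_boundary(self):
        from scipy import ndimage as ndi
        rect = np.zeros((100, 100), dtype=bool)
        rect[30:60, 20:80] = True
        edges = canny_edges(rect)
        boundary = rect & ~ndi.binary_erosion(rect)
        near = ndi.binary_dilation(boundary, iterations=1)
        assert edges.any()
        assert (edges & ~near).sum() == 0            # no stray edges
        covered = ndi.binary_dilation(edges, iterations=1) & boundary
        assert covered.sum() >= 0.7 * boundary.sum()  # boundary mostly traced

    def test_phantom_band_yields_two_dominant_edge_curves(self):
        scan, truth = oc.make_phantom(oc.PhantomSpec(label="healthy", speckle_scale=0))
        rows = np.arange(scan.shape[0])[:, None]
        band = (rows >= truth.ilm) & (rows <= truth.choroid)
        edges = canny_edges(band)
        runs_per_col = []
        for col in range(10, band.shape[1] - 10):
            e = edges[:, col]
            runs = np.count_nonzero(np.diff(np.concatenate(([0], e.view(np.int8)))) == 1)
            runs_per_col.append(runs)
        assert np.median(runs_per_col) == 2
        assert (np.array(runs_per_col) == 2).mean() >= 0.9
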