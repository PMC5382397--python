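import numpy as np
import pandas as pd
import pytest

import octoscope as oc
from octoscope import LayerSet, class_summary, cyst_energy, cyst_segmentation, rpe_profile
from octoscope.features import FEATURE_NAMES, feature_table


def haar_level2_approx_energy(mask):
    """Hand oracle: two explicit 2x2 orthonormal Haar averaging passes."""
    a = mask.astype(float)
    for _ in range(2):
        r, c = a.shape
        if r % 2:
            a = np.vstack([a, a[-1:]])
        if c % 2:
            a = np.hstack([a, a[:, -1:]])
        a = (a[0::2, 0::2] + a[1::2, 0::2] + a[0::2, 1::2] + a[1::2, 1::2]) / 2.0
    return float((a**2).sum())


class TestCystSegmentation:
    def test_healthy_noiseless_phantom_has_zero_cyst_area(self):
        scan, _ = oc.make_phantom(oc.PhantomSpec(label="healthy", speckle_scale=0))
        fv, _ = oc.extract_features(scan)
        assert fv.f4 == 0.0 and fv.f5 == 0.0

    def test_edema_cyst_area_tracks_ground_truth(self):
        scan, truth = oc.make_phantom(oc.PhantomSpec(label="RE", n_cysts=3,
                                                     speckle_scale=0, seed=8))
        _, arts = oc.extract_features(scan)
        seg = arts["cyst"]
        measured = seg.cyst_mask
        inter = (measured & truth.cyst_mask).sum()
        union = (measured | truth.cyst_mask).sum()
        assert inter / union >= 0.5
        assert 0.5 * truth.cyst_mask.sum() <= measured.sum() <= 1.15 * truth.cyst_mask.sum()

    def test_all_foreground_binmap_leaves_no_cysts(self):
        ls = LayerSet(ilm=np.full(64, 20.0), rpe=np.full(64, 60.0),
                      choroid=np.full(64, 80.0))
        seg = cyst_segmentation(ls, np.ones((100, 64), dtype=bool))
        assert seg.area == 0.0 and not seg.cyst_mask.any()
        np.testing.assert_array_equal(seg.column_profile, 0)

    def test_cyst_mask_subset_of_retina_mask(self):
        scan, _ = oc.make_phantom(oc.PhantomSpec(label="RE", seed=9))
        _, arts = oc.extract_features(scan)
        seg = arts["cyst"]
        assert not (seg.cyst_mask & ~seg.retina_mask).any()


class TestRPEProfile:
    def test_flat_trace_gives_zero_deviation(self):
        ls = LayerSet(ilm=np.full(200, 50.0), rpe=np.full(200, 150.0),
                      choroid=np.full(200, 200.0))
        prof = rpe_profile(ls)
        np.testing.assert_allclose(prof.deviation, 0.0, atol=1e-9)

    def test_single_dome_recovered_at_its_column(self):
        t = np.arange(1280, dtype=float)
        base = 200 + 1e-5 * (t - 640) ** 2
        h, c, w = 25.0, 700.0, 60.0
        dome = h * np.clip(1 - ((t - c) / w) ** 2, 0, None)
        ls = LayerSet(ilm=np.full(1280, 50.0), rpe=base - dome,
                      choroid=np.full(1280, 400.0))
        dev = rpe_profile(ls).deviation
        assert abs(dev.argmax() - c) <= 2
        assert 0.8 * h <= dev.max() <= 1.05 * h

    def test_deviation_is_mean_zero(self):
        rng = np.random.default_rng(4)
        ls = LayerSet(ilm=np.full(500, 10.0), rpe=150 + rng.random(500) * 20,
                      choroid=np.full(500, 400.0))
        assert rpe_profile(ls).deviation.mean() == pytest.approx(0.0, abs=1e-8)

    def test_drusen_phantom_exceeds_healthy_elevation(self):
        h, _ = oc.make_phantom(oc.PhantomSpec(label="healthy", speckle_scale=0, seed=5))
        a, truth = oc.make_phantom(oc.PhantomSpec(label="ARMD", speckle_scale=0, seed=5))
        dev_h = oc.extract_features(h)[1]["rpe_profile"].deviation
        dev_a = oc.extract_features(a)[1]["rpe_profile"].deviation
        min_drusen_um = min(hgt for _, hgt in truth.drusen_apices) * 3.5
        assert dev_a.max() > dev_h.max() + 0.5 * min_drusen_um


class TestCystEnergy:
    def test_empty_mask_has_zero_energy(self):
        assert cyst_energy(np.zeros((16, 16), dtype=bool)) == 0.0

    def test_solid_block_matches_hand_haar_oracle(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 2:6] = True
        assert cyst_energy(mask) == pytest.approx(haar_level2_approx_energy(mask))

    def test_matches_oracle_on_random_masks(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            mask = rng.random((32, 40)) > 0.6
            assert cyst_energy(mask) == pytest.approx(haar_level2_approx_energy(mask))

    def test_energy_grows_with_nested_area(self):
        prev = -1.0
        for half in (2, 4, 8, 12):
            mask = np.zeros((32, 32), dtype=bool)
            mask[16 - half:16 + half, 16 - half:16 + half] = True
            e = cyst_energy(mask)
            assert e > prev
            prev = e


class TestFeatureVector:
    def test_invariants_hold_on_phantom_cohort(self, table40):
        f = table40
        assert (f["f1"] >= f["f2"]).all() and (f["f2"] >= 0).all()
        np.testing.assert_allclose(f["f3"], (f["f1"] - f["f2"]).abs())
        np.testing.assert_allclose(f["f8"], (f["f6"] - f["f7"]).abs())
        assert (f["f6"] >= f["f7"]).all()
        assert (f[["f4", "f5", "f9"]] >= 0).all().all()
        zero_area = f["f4"] == 0
        assert (f.loc[zero_area, "f5"] == 0).all()

    def test_class_structure_matches_clinical_ordering(self, table40):
        med = table40.groupby("label").median(numeric_only=True)
        assert med.loc["RE", "f5"] > med.loc["CSCR", "f5"]
        others = ["healthy", "RE", "CSCR"]
        for feat in ("f6", "f8", "f9"):
            assert med.loc["ARMD", feat] > med.loc[others, feat].max()
        assert med.loc["healthy", "f4"] <= 0.01   # mm^2; essentially fluid-free
        assert (med.loc[["RE", "CSCR", "ARMD"], "f4"] > 0.05).all()

    def test_rotation_leaves_descriptor_nearly_unchanged(self):
        base, _ = oc.make_phantom(oc.PhantomSpec(label="RE", seed=5))
        rot, _ = oc.make_phantom(oc.PhantomSpec(label="RE", seed=5, rotation_deg=5.0))
        f0 = oc.extract_features(base)[0].to_array()
        f1 = oc.extract_features(rot)[0].to_array()
        assert np.linalg.norm(f1 - f0) <= 0.05 * np.linalg.norm(f0)

    def test_constant_thickness_profile_zeroes_f3(self):
        from octoscope.features import CystSegmentation, RPEProfile, feature_vector
        from octoscope.layers import ThicknessProfile
        fv = feature_vector(
            ThicknessProfile(rt=np.full(10, 42.0)),
            CystSegmentation(retina_mask=np.zeros((4, 4), bool),
                             cyst_mask=np.zeros((4, 4), bool), area=0.0,
                             column_profile=np.zeros(4)),
            RPEProfile(deviation=np.zeros(10), baseline_coeffs=np.zeros(3)))
        assert fv.f3 == 0.0 and fv.f1 == fv.f2 == 42.0


class TestFeatureTable:
    def test_summary_mean_and_sample_sd(self):
        table = pd.DataFrame({**{n: [1.0, 2.0, 3.0] for n in FEATURE_NAMES},
                              "label": ["x"] * 3})
        summ = class_summary(table).set_index("stat")
        assert summ.loc["mean", "f1"] == pytest.approx(2.0)
        assert summ.loc["sd", "f1"] == pytest.approx(1.0)   # ddof=1

    def test_single_row_sd_flagged_degenerate(self):
        table = pd.DataFrame({**{n: [5.0] for n in FEATURE_NAMES}, "label": ["x"]})
        summ = class_summary(table)
        sd_row = summ[summ["stat"] == "sd"].iloc[0]
        assert sd_row["f1"] == 0.0 and bool(sd_row["sd_degenerate"])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            feature_table([], ["a"])
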