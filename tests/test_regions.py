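"""Superpixel segmentation and core/junction/skin designation."""

import numpy as np
import imageio.v3 as iio
import pytest

import pbmap
from pbmap import slic_segment, designate_regions, load_manual_roi, RegionLabels


def _superpixel_means(labels, img):
    return np.array([img[labels == lab].mean() for lab in np.unique(labels) if lab > 0])


class TestSlic:
    def test_constant_image_tiles_with_equal_means(self):
        img = np.full((40, 40), 7.0)
        labels = slic_segment(img, n_segments=4, compactness=0.1)
        ids = np.unique(labels[labels > 0])
        assert 1 <= len(ids) <= 6
        assert np.allclose(_superpixel_means(labels, img), 7.0)

    def test_two_valued_halves_give_bimodal_superpixels(self):
        img = np.zeros((40, 60))
        img[:, 30:] = 100.0
        labels = slic_segment(img, n_segments=30, compactness=0.1)
        means = _superpixel_means(labels, img)
        # every superpixel is essentially pure: near 0 or near 100
        assert np.all((means < 10) | (means > 90))

    def test_deterministic(self, noisy_maps):
        a = slic_segment(noisy_maps.tau, n_segments=50, valid_mask=noisy_maps.mask)
        b = slic_segment(noisy_maps.tau, n_segments=50, valid_mask=noisy_maps.mask)
        assert np.array_equal(a, b)

    def test_phantom_tau_map_superpixel_means_bimodal(self, noisy_phantom, noisy_maps):
        _, truth = noisy_phantom
        labels = slic_segment(noisy_maps.tau, n_segments=60, valid_mask=noisy_maps.mask)
        means = _superpixel_means(labels, noisy_maps.tau)
        skin_tau, core_tau = 10.0, 6.0
        near_skin = np.abs(means - skin_tau) < 1.5
        near_core = np.abs(means - core_tau) < 1.5
        assert near_skin.sum() > 0 and near_core.sum() > 0
        assert (near_skin | near_core).mean() > 0.8

    def test_all_invalid_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            slic_segment(np.ones((10, 10)), valid_mask=np.zeros((10, 10), bool))

    def test_bad_n_segments_rejected(self):
        with pytest.raises(ValueError, match="n_segments"):
            slic_segment(np.ones((10, 10)), n_segments=1)


def _toy_labels():
    """2x2 grid of four superpixels on a 20x20 image."""
    labels = np.zeros((20, 20), int)
    labels[:10, :10] = 1
    labels[:10, 10:] = 2
    labels[10:, :10] = 3
    labels[10:, 10:] = 4
    return labels


def _toy_map(values, labels):
    img = np.zeros(labels.shape)
    for lab, v in values.items():
        img[labels == lab] = v
    return img


class TestDesignate:
    def _designate(self, values, skin_vals=None, **kw):
        labels = _toy_labels()
        img = _toy_map(values, labels)
        rng = np.random.default_rng(0)
        # skin reference: superpixel 1 with small spread
        skin_mask = labels == 1
        img[skin_mask] = 10.0 + rng.normal(0, 1.0, int(skin_mask.sum()))
        return designate_regions(labels, img, skin_mask=skin_mask, **kw)

    def test_high_z_superpixel_is_core(self):
        regions = self._designate({2: 10, 3: 10, 4: 15})  # z(4) ~ +5
        assert regions.designation[4] == "core"
        assert regions.designation[2] == "skin"

    def test_moderate_z_adjacent_to_core_is_junction(self):
        # 4 is core (z~+6), 2 touches 4 diagonally and has z~+2 -> junction
        regions = self._designate({2: 12, 3: 10, 4: 16})
        assert regions.designation[4] == "core"
        assert regions.designation[2] == "junction"
        assert regions.designation[3] == "skin"

    def test_moderate_z_isolated_stays_skin(self):
        regions = self._designate({2: 12, 3: 10, 4: 10})
        assert regions.designation[2] == "skin"

    def test_raising_z_core_never_adds_core(self, noisy_maps):
        labels = slic_segment(noisy_maps.af0, n_segments=80, valid_mask=noisy_maps.mask)
        n_prev = None
        for z in (2.0, 3.0, 4.0, 6.0):
            r = designate_regions(labels, noisy_maps.af0, valid_mask=noisy_maps.mask,
                                  z_core=z)
            n = r.counts()["core"]
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_affine_rescaling_invariance(self, noisy_maps):
        labels = slic_segment(noisy_maps.af0, n_segments=80, valid_mask=noisy_maps.mask)
        a = designate_regions(labels, noisy_maps.af0, valid_mask=noisy_maps.mask)
        b = designate_regions(labels, 3.5 * noisy_maps.af0 + 100.0,
                              valid_mask=noisy_maps.mask)
        assert a.designation == b.designation

    def test_partition_covers_all_superpixels(self, noisy_maps):
        labels = slic_segment(noisy_maps.af0, n_segments=80, valid_mask=noisy_maps.mask)
        r = designate_regions(labels, noisy_maps.af0, valid_mask=noisy_maps.mask)
        assert set(r.designation) == {int(v) for v in np.unique(labels) if v > 0}
        assert sum(r.counts().values()) == len(r.designation)

    def test_mostly_invalid_superpixel_excluded(self):
        labels = _toy_labels()
        img = _toy_map({1: 10, 2: 10, 3: 10, 4: 10}, labels)
        img[labels == 1] += np.linspace(-1, 1, 100)
        valid = np.ones((20, 20), bool)
        valid[10:, 10:] = False  # superpixel 4 fully invalid
        r = designate_regions(labels, img, skin_mask=labels == 1, valid_mask=valid)
        assert r.designation[4] == "excluded"

    def test_zero_skin_sd_rejected(self):
        labels = _toy_labels()
        img = _toy_map({1: 10, 2: 10, 3: 10, 4: 10}, labels)
        with pytest.raises(ValueError, match="degenerate"):
            designate_regions(labels, img, skin_mask=labels == 1)

    def test_phantom_designation_matches_ground_truth(self, noisy_phantom, noisy_maps):
        """Automatic designation agrees with truth on >= 90% of non-boundary pixels."""
        from scipy import ndimage as ndi

        _, truth = noisy_phantom
        maps = noisy_maps
        labels = slic_segment(maps.af0, n_segments=120, valid_mask=maps.mask)
        r = designate_regions(labels, maps.af0, valid_mask=maps.mask)
        lesion_pred = r.mask("core", "junction")
        lesion_true = np.isin(truth.region_mask, (pbmap.CORE, pbmap.JUNCTION))
        # exclude a 3-px band around the true lesion boundary and defects
        band = ndi.binary_dilation(lesion_true, iterations=3) & ~ndi.binary_erosion(
            lesion_true, iterations=3)
        score = lesion_pred == lesion_true
        sel = ~band & (truth.region_mask != pbmap.DEFECT) & maps.mask
        assert score[sel].mean() >= 0.90


class TestManualRoi:
    def test_all_zero_mask_is_all_skin(self):
        r = load_manual_roi(np.zeros((12, 12), dtype=np.uint8))
        assert set(r.designation.values()) == {"skin"}
        assert r.mask("skin").all()

    def test_phantom_truth_round_trip(self, noisy_phantom):
        _, truth = noisy_phantom
        roi = np.zeros(truth.region_mask.shape, dtype=np.uint8)
        roi[truth.region_mask == pbmap.JUNCTION] = 1
        roi[truth.region_mask == pbmap.CORE] = 2
        r = load_manual_roi(roi)
        assert np.array_equal(r.mask("core"), roi == 2)
        assert np.array_equal(r.mask("junction"), roi == 1)
        assert np.array_equal(r.mask("skin"), roi == 0)

    def test_unknown_value_rejected(self):
        roi = np.zeros((8, 8), dtype=np.uint8)
        roi[0, 0] = 7
        with pytest.raises(ValueError, match="7"):
            load_manual_roi(roi)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            load_manual_roi(np.zeros((8, 8), dtype=np.uint8), expected_shape=(9, 9))

    def test_reads_png_file(self, tmp_path):
        roi = np.zeros((10, 10), dtype=np.uint8)
        roi[4:6, 4:6] = 2
        iio.imwrite(tmp_path / "roi.png", roi)
        r = load_manual_roi(tmp_path / "roi.png", expected_shape=(10, 10))
        assert r.mask("core").sum() == 4


def test_region_labels_rejects_unknown_designation():
    with pytest.raises(ValueError, match="unknown designations"):
        RegionLabels(superpixel_labels=np.ones((4, 4), int), designation={1: "blob"})
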