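import numpy as np
import pytest

from dermakit import (
    NoEpidermisError, SegConfig, SyntheticSkinParams, compute_superpixels,
    diagonal_span_filter, extract_level1, generate_sample,
    iterative_unsupervised_segment, refine_mask, select_epidermis_cluster,
)
from dermakit.sampling import mask_principal_angle
from dermakit.studies import SEG_CONFIG, segmentation_sample_params

SMALL = SegConfig(n_channels=12, n_conv_blocks=2, max_iterations=40, min_clusters=3,
                  learning_rate=0.1, seed=0, min_component_area=200)


def layer_truth(sample):
    """Per-pixel ground-truth layer: 0 corneum, 1 epidermis, 2 dermis."""
    h, w = sample.epidermis_mask.shape
    rows = np.arange(h)[:, None]
    layer = np.full((h, w), 2)
    layer[sample.epidermis_mask] = 1
    layer[np.broadcast_to(rows < sample.params.corneum_thickness, (h, w)) & ~sample.epidermis_mask] = 0
    return layer


class TestSuperpixels:
    def test_two_homogeneous_halves(self):
        img = np.zeros((64, 64, 3), np.uint8)
        img[:, 32:] = 200
        sp = compute_superpixels(img, SegConfig(felzenszwalb_min_size=10, felzenszwalb_sigma=0.0))
        assert sp.n_segments == 2
        assert len(np.unique(sp.labels[:, :32])) == 1
        assert len(np.unique(sp.labels[:, 32:])) == 1

    def test_uniform_image_single_superpixel(self):
        img = np.full((64, 64, 3), 128, np.uint8)
        sp = compute_superpixels(img, SegConfig())
        assert sp.n_segments == 1

    def test_partition_property_and_layer_purity(self, band_sample):
        sp = compute_superpixels(band_sample.image, SegConfig())
        assert sp.labels.min() == 0 and sp.labels.max() == sp.n_segments - 1
        assert sp.labels.shape == band_sample.image.shape[:2]
        # assigning each superpixel its majority layer recovers >=95% of each layer
        truth = layer_truth(band_sample)
        pred = np.zeros_like(truth)
        for sid in range(sp.n_segments):
            m = sp.labels == sid
            pred[m] = np.bincount(truth[m], minlength=3).argmax()
        for layer in range(3):
            m = truth == layer
            assert (pred[m] == layer).mean() >= 0.95


@pytest.fixture(scope="module")
def segmented():
    sample = generate_sample(segmentation_sample_params(0))
    sp = compute_superpixels(sample.image, SMALL)
    labels = iterative_unsupervised_segment(sample.image, sp, SMALL)
    return sample, sp, labels


class TestIterativeSegmentation:
    def test_at_least_three_clusters_and_epidermis_iou(self, segmented):
        sample, _, labels = segmented
        assert len(np.unique(labels)) >= 3
        sel = select_epidermis_cluster(labels, sample.image, min_component_area=SMALL.min_component_area)
        gt = sample.epidermis_mask
        iou = (sel.mask & gt).sum() / (sel.mask | gt).sum()
        assert iou >= 0.80

    def test_seed_determinism(self, segmented):
        sample, sp, labels = segmented
        again = iterative_unsupervised_segment(sample.image, sp, SMALL)
        assert np.array_equal(labels, again)

    def test_uniform_image_collapses_with_warning(self):
        img = np.full((48, 48, 3), 180, np.uint8)
        cfg = SegConfig(n_channels=8, n_conv_blocks=1, max_iterations=5, seed=1)
        sp = compute_superpixels(img, cfg)
        with pytest.warns(UserWarning):
            labels = iterative_unsupervised_segment(img, sp, cfg)
        with pytest.raises(NoEpidermisError):
            select_epidermis_cluster(labels, img)


class TestSelectEpidermisCluster:
    def test_explicit_override_returned_verbatim(self):
        labels = np.zeros((20, 20), int)
        labels[5:10] = 3
        img = np.zeros((20, 20, 3), np.uint8)
        res = select_epidermis_cluster(labels, img, cluster_id=3)
        assert res.cluster_id == 3
        assert np.array_equal(res.mask, labels == 3)

    def test_tie_breaks_toward_lower_cluster_id(self):
        # two identical horizontal bands -> identical scores
        labels = np.full((40, 60), 9, int)
        labels[5:15] = 0
        labels[25:35] = 1
        img = np.full((40, 60, 3), 200, np.uint8)
        img[labels == 0] = (150, 100, 160)
        img[labels == 1] = (150, 100, 160)
        res = select_epidermis_cluster(labels, img, min_component_area=100)
        assert res.cluster_id == 0


class TestDiagonalSpanFilter:
    def test_diagonal_line_spans(self):
        m = np.eye(200, dtype=bool)
        assert diagonal_span_filter(m)

    def test_corner_blob_rejected(self):
        m = np.zeros((200, 200), bool)
        m[:40, :40] = True
        assert not diagonal_span_filter(m)

    def test_antidiagonal_band_accepted(self):
        m = np.fliplr(np.eye(200, dtype=bool))
        assert diagonal_span_filter(m)
        # brute-force corner-region oracle
        s = int(round(0.15 * 200))
        tl, br = m[:s, :s].any(), m[-s:, -s:].any()
        tr, bl = m[:s, -s:].any(), m[-s:, :s].any()
        assert (tl and br) or (tr and bl)

    def test_connected_component_requirement(self):
        # two disjoint corner blobs touch both corners but no single component spans
        m = np.zeros((200, 200), bool)
        m[:20, :20] = True
        m[-20:, -20:] = True
        assert not diagonal_span_filter(m)


class TestRefineMask:
    def test_specks_removed_band_preserved(self):
        m = np.zeros((128, 256), bool)
        m[40:80] = True
        rng = np.random.default_rng(0)
        specks = m.copy()
        for _ in range(10):
            r, c = rng.integers(0, 30), rng.integers(0, 256)
            specks[r : r + 2, c : c + 2] = True
        out = refine_mask(specks, kernel_radius=3, min_component_area=256)
        assert not out[:30].any()                       # specks gone
        assert out[43:77].all()                         # band interior intact
        assert (out ^ m)[40:80].sum() <= 2 * 256 * 2    # boundary within ~1-2 px

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning):
            out = refine_mask(np.zeros((32, 32), bool))
        assert not out.any()

    def test_full_frame_mask_unchanged(self):
        m = np.ones((64, 64), bool)
        assert np.array_equal(refine_mask(m), m)

    def test_monotonicity_never_adds_pixels(self):
        rng = np.random.default_rng(1)
        m = rng.random((64, 64)) > 0.4
        out = refine_mask(m, kernel_radius=2, min_component_area=16)
        assert not (out & ~m).any()  # opening is anti-extensive


class TestExtractLevel1:
    def test_horizontal_sample_rotated_to_diagonal_and_accepted(self):
        s = generate_sample(SyntheticSkinParams(image_height=192, image_width=192, seed=1))
        res = extract_level1(s.image, s.epidermis_mask, SegConfig(min_component_area=64))
        assert res.accepted
        ang = mask_principal_angle(res.level1_mask)
        assert min(abs(ang - 45), abs(ang + 45)) <= 10.0

    def test_diagonal_sample_accepted_without_rotation(self):
        s = generate_sample(SyntheticSkinParams(image_height=256, image_width=256, orientation_deg=45.0, seed=2))
        from dermakit.segmentation import refine_mask as rm

        mask = rm(s.epidermis_mask, 2, 64)
        ang_before = mask_principal_angle(mask)
        assert min(abs(ang_before - 45), abs(ang_before + 45)) <= 20.0
        res = extract_level1(s.image, mask, SegConfig(min_component_area=64))
        assert res.accepted
        # no rotation: level-1 mask is a crop of the input mask
        assert res.mask.shape == mask.shape

    def test_corner_blob_not_accepted(self):
        img = np.full((128, 128, 3), 220, np.uint8)
        m = np.zeros((128, 128), bool)
        m[:30, :30] = True
        res = extract_level1(img, m, SegConfig(auto_rotate=False))
        assert not res.accepted
        assert res.level1_image is None


def test_end_to_end_synthetic_iou(band_sample):
    """Full pipeline on one sample: accepted level-1 with high mask IoU."""
    from dermakit import segment_epidermis

    cfg = SegConfig(n_channels=12, n_conv_blocks=2, max_iterations=40, min_clusters=3,
                    learning_rate=0.1, seed=3, min_component_area=200)
    res = segment_epidermis(band_sample.image, cfg)
    assert res.accepted
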