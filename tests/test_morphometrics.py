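import numpy as np
import pytest
from hypothesis import given, settings, strategies as stv

from dermakit import (
    BoundaryPolyline, SyntheticSkinParams, TopologyError, compute_morphometrics,
    extract_boundaries, generate_sample, shortest_distance,
)


@pytest.fixture(scope="module")
def sinusoid_pair():
    x = np.arange(0.0, 1024.0 + 1)
    eb = BoundaryPolyline(np.column_stack([50 + 10 * np.sin(2 * np.pi * x / 128.0), x]), role="EB")
    es = BoundaryPolyline(np.column_stack([np.zeros_like(x), x]), role="ES")
    return eb, es


def hline(row, length, role):
    return BoundaryPolyline(np.column_stack([np.full(length, float(row)), np.arange(length, dtype=float)]), role=role)


def dense_distance_oracle(points, target, step=0.01):
    """Brute force: min distance to a densely resampled target polyline."""
    from dermakit.morphometrics import resample_polyline

    dense = resample_polyline(np.asarray(target, float), step)
    d = np.linalg.norm(points[:, None, :] - dense[None, :, :], axis=2)
    return d.min(axis=1)


class TestShortestDistance:
    def test_perpendicular_foot(self):
        target = BoundaryPolyline(np.array([[3.0, 0.0], [3.0, 10.0]]))
        assert shortest_distance((0.0, 0.0), target) == pytest.approx(3.0)

    def test_nearest_endpoint(self):
        target = BoundaryPolyline(np.array([[3.0, 0.0], [3.0, 10.0]]))
        assert shortest_distance((0.0, -5.0), target) == pytest.approx(np.sqrt(9 + 25), abs=1e-4)

    @settings(deadline=None, max_examples=25)
    @given(stv.integers(0, 10_000))
    def test_matches_dense_resampling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        poly = np.cumsum(rng.uniform(-3, 3, size=(6, 2)), axis=0)
        pts = rng.uniform(-5, 10, size=(5, 2))
        target = BoundaryPolyline(poly)
        got = np.array([shortest_distance(p, target) for p in pts])
        oracle = dense_distance_oracle(pts, poly)
        assert np.all(np.abs(got - oracle) < 2e-2)  # oracle granularity
        assert np.all(got <= oracle + 1e-9)          # exact <= discretized

    def test_matches_shapely(self):
        """Independent cross-check against shapely's exact point-segment distance."""
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import LineString, Point

        rng = np.random.default_rng(11)
        poly = np.cumsum(rng.uniform(-4, 4, size=(8, 2)), axis=0)
        target = BoundaryPolyline(poly)
        line = LineString([(r, c) for r, c in poly])
        for p in rng.uniform(-10, 10, size=(20, 2)):
            assert shortest_distance(p, target) == pytest.approx(line.distance(Point(*p)), abs=1e-6)


class TestComputeMorphometrics:
    def test_parallel_lines(self):
        r = compute_morphometrics(hline(70, 100, "EB"), hline(30, 100, "ES"))
        assert r.thickness == pytest.approx(40.0)
        assert r.rete_ridge_score == pytest.approx(0.0)
        # invariants: statistics recomputable from the per-point lists
        assert r.thickness == pytest.approx(float(np.mean(r.es_to_eb)))
        assert r.rete_ridge_score == pytest.approx(float(np.var(r.eb_to_es)))

    def test_sinusoid_matches_dense_oracle_within_2pct(self, sinusoid_pair):
        eb, es = sinusoid_pair
        r = compute_morphometrics(eb, es)
        # oracle: dense numeric distances on the analytic curves, same sampling
        from dermakit.morphometrics import resample_polyline

        eb_pts = resample_polyline(eb.points, 1.0)
        es_pts = resample_polyline(es.points, 1.0)
        d_es = dense_distance_oracle(es_pts, eb.points, step=0.05)
        d_eb = dense_distance_oracle(eb_pts, es.points, step=0.05)
        assert r.thickness == pytest.approx(float(np.mean(d_es)), rel=0.02)
        assert r.rete_ridge_score == pytest.approx(float(np.var(d_eb)), rel=0.02)
        # arc-length sampling pulls the variance slightly below A^2/2
        assert 0.8 * 50 < r.rete_ridge_score <= 50.5

    def test_definition_is_asymmetric(self, sinusoid_pair):
        eb, es = sinusoid_pair
        fwd = compute_morphometrics(eb, es)
        swapped = compute_morphometrics(es, eb)
        assert abs(fwd.thickness - swapped.thickness) > 0.1
        assert abs(fwd.rete_ridge_score - swapped.rete_ridge_score) > 1.0

    def test_rigid_motion_invariance(self, sinusoid_pair):
        eb, es = sinusoid_pair
        base = compute_morphometrics(eb, es)
        eb2 = eb.transformed(rotation_deg=33.0, center=(50, 500), shift=(12.5, -7.25))
        es2 = es.transformed(rotation_deg=33.0, center=(50, 500), shift=(12.5, -7.25))
        moved = compute_morphometrics(eb2, es2)
        assert moved.thickness == pytest.approx(base.thickness, rel=1e-6)
        assert moved.rete_ridge_score == pytest.approx(base.rete_ridge_score, rel=1e-6)

    def test_too_few_points_raise_at_construction(self):
        with pytest.raises(ValueError):
            BoundaryPolyline(np.zeros((1, 2)))
        with pytest.raises(ValueError):
            BoundaryPolyline(np.zeros((0, 2)))


class TestExtractBoundaries:
    def test_flat_band_boundaries_match_ground_truth(self, flat_sample):
        eb, es = extract_boundaries(flat_sample.epidermis_mask, flat_sample.image)
        # contour runs at the half-pixel level: ES at 29.5, EB at 69.5
        assert np.abs(es.points[:, 0] - 29.5).max() <= 1.0
        assert np.abs(eb.points[:, 0] - 69.5).max() <= 1.0
        r = compute_morphometrics(eb, es)
        assert r.thickness == pytest.approx(40.0, rel=0.05)

    def test_undulation_rule_assigns_sinusoidal_side_to_eb(self, sinus_sample):
        eb, es = extract_boundaries(sinus_sample.epidermis_mask, None)
        assert eb.points[:, 0].std() > es.points[:, 0].std()

    def test_stain_rule_matches_undulation_rule(self, sinus_sample):
        eb_img, _ = extract_boundaries(sinus_sample.epidermis_mask, sinus_sample.image)
        eb_geo, _ = extract_boundaries(sinus_sample.epidermis_mask, None)
        assert abs(eb_img.points[:, 0].mean() - eb_geo.points[:, 0].mean()) < 3.0

    def test_disk_mask_raises_topology_error(self):
        from skimage.draw import disk

        m = np.zeros((128, 128), bool)
        rr, cc = disk((64, 64), 40)
        m[rr, cc] = True
        with pytest.raises(TopologyError):
            extract_boundaries(m)


class TestOnSyntheticCohort:
    def test_score_strictly_increases_with_ridge_amplitude(self):
        scores = []
        for amp in (0.0, 5.0, 10.0, 15.0):
            s = generate_sample(SyntheticSkinParams(
                image_height=256, image_width=512, epidermis_thickness=40,
                ridge_amplitude=amp, ridge_wavelength=96.0, seed=21,
            ))
            scores.append(compute_morphometrics(s.eb_polyline, s.es_polyline).rete_ridge_score)
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_thickness_recovery_within_5pct_at_zero_amplitude(self):
        for seed in range(5):
            p = SyntheticSkinParams(image_height=256, image_width=256, epidermis_thickness=35,
                                    ridge_amplitude=0.0, seed=seed)
            s = generate_sample(p)
            eb, es = extract_boundaries(s.epidermis_mask, s.image)
            r = compute_morphometrics(eb, es)
            assert abs(r.thickness - 35) / 35 <= 0.05
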