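import numpy as np
import pytest

from ommascore import (
    CenterSet,
    EyeSceneSpec,
    NeighborFan,
    OmmatidiumScore,
    PipelineError,
    TooFewOmmatidia,
    make_lattice,
    neighbor_fan,
    odi_angle,
    odi_distance,
    phenotypic_score,
    rank_and_aggregate,
    score_image,
    score_pointset,
)


def _fan_from_polar(angles_deg, lengths=None):
    """Build a fan from polar angles (deg) and per-vector lengths."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    L = np.ones(6) if lengths is None else np.asarray(lengths, dtype=float)
    vectors = np.stack([L * np.sin(a), L * np.cos(a)], axis=1)
    return NeighborFan(center=(0.0, 0.0), vectors=vectors)


HEX_ANGLES = [0, 60, 120, 180, 240, 300]


def _score(d_total, dist=0.0):
    fan = _fan_from_polar(HEX_ANGLES)
    return OmmatidiumScore(fan=fan, odi_d=d_total, odi_a=0.0, dist_to_eye_center=dist)


class TestNeighborFan:
    def test_hexagonal_interior_point(self):
        gt = make_lattice(EyeSceneSpec(seed=0))
        pts = gt.centers.points
        center = np.array(gt.spec.ellipse_center)
        idx = int(np.argmin(((pts - center) ** 2).sum(axis=1)))
        fan = neighbor_fan(gt.centers, idx)
        np.testing.assert_allclose(fan.lengths, 10.0, rtol=1e-12)
        ang = np.arctan2(fan.vectors[:, 0], fan.vectors[:, 1])
        gaps = np.diff(np.sort(ang))
        np.testing.assert_allclose(gaps, np.pi / 3, atol=1e-9)

    def test_matches_brute_force_selection(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 100, size=(8, 2))
        for i in range(8):
            fan = neighbor_fan(CenterSet(points=pts), i)
            d = np.sqrt(((pts - pts[i]) ** 2).sum(axis=1))
            expect = set()
            for j in np.argsort(d)[1:7]:
                expect.add(tuple(np.round(pts[j] - pts[i], 9)))
            got = {tuple(np.round(v, 9)) for v in fan.vectors}
            assert got == expect

    def test_angles_sorted_counterclockwise(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 50, size=(30, 2))
        fan = neighbor_fan(CenterSet(points=pts), 0)
        ang = np.arctan2(fan.vectors[:, 0], fan.vectors[:, 1])
        assert np.all(np.diff(ang) > 0)

    def test_too_few_points_rejected(self):
        pts = np.arange(12, dtype=float).reshape(6, 2)
        with pytest.raises(TooFewOmmatidia):
            neighbor_fan(CenterSet(points=pts), 0)


class TestOdiDistance:
    def test_equal_lengths_score_zero(self):
        assert odi_distance(_fan_from_polar(HEX_ANGLES)) == 0.0

    def test_single_long_vector(self):
        # lengths {1,1,1,1,1,2}: sum of (|v|-1)/1 over the five non-minimal = 1
        fan = _fan_from_polar(HEX_ANGLES, lengths=[1, 1, 1, 1, 1, 2])
        assert odi_distance(fan) == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = _fan_from_polar(HEX_ANGLES, lengths=[1, 1, 1, 1, 1, 2])
        b = _fan_from_polar(HEX_ANGLES, lengths=[2, 2, 2, 2, 2, 4])
        assert odi_distance(a) == pytest.approx(odi_distance(b))

    def test_only_one_designated_minimum_excluded(self):
        # two vectors share the minimum; one stays in the five-term sum
        fan = _fan_from_polar(HEX_ANGLES, lengths=[1, 1, 2, 2, 2, 2])
        assert odi_distance(fan) == pytest.approx(0 + 1 + 1 + 1 + 1)


class TestOdiAngle:
    def test_regular_hexagon_scores_zero(self):
        assert odi_angle(_fan_from_polar(HEX_ANGLES)) == 0.0

    def test_hand_computed_perturbed_fan(self):
        # angles 0,70,120,180,240,300 -> adjacent gaps 70,50,60,60,60,60
        # ODI_A = 2*(10 + 10) degrees = 0.69813 rad
        fan = _fan_from_polar([0, 70, 120, 180, 240, 300])
        assert odi_angle(fan) == pytest.approx(0.69813, abs=1e-5)

    def test_rigid_rotation_invariance(self):
        base = [0, 70, 120, 180, 240, 300]
        ref = odi_angle(_fan_from_polar(base))
        for rot in (13.7, 91.0, 200.2):
            rotated = sorted((a + rot) % 360 for a in base)
            assert odi_angle(_fan_from_polar(rotated)) == pytest.approx(ref, abs=1e-12)


class TestRankAndAggregate:
    def test_perfect_order_sums_to_zero(self):
        scores = [_score(0.0) for _ in range(50)]
        odi_t, n_used = rank_and_aggregate(scores, N=20)
        assert odi_t == 0.0
        assert n_used == 20

    def test_log1p_of_e_minus_one(self):
        scores = [_score(np.e - 1), _score(np.e - 1)]
        odi_t, n_used = rank_and_aggregate(scores, N=2)
        assert odi_t == pytest.approx(2.0)

    def test_keeps_the_most_ordered_subset(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 10, size=300)
        scores = [_score(v) for v in d]
        odi_t, n_used = rank_and_aggregate(scores, N=200)
        assert n_used == 200
        expected = np.log1p(np.sort(d)[:200]).sum()  # brute-force sort oracle
        assert odi_t == pytest.approx(expected)

    def test_distance_breaks_ties(self):
        scores = [_score(1.0, dist=9.0), _score(1.0, dist=1.0), _score(5.0, dist=0.0)]
        odi_t, n_used = rank_and_aggregate(scores, N=2)
        assert odi_t == pytest.approx(2 * np.log1p(1.0))

    def test_small_eye_warns_and_uses_all(self):
        scores = [_score(1.0) for _ in range(5)]
        with pytest.warns(UserWarning, match="aggregating all"):
            odi_t, n_used = rank_and_aggregate(scores, N=10)
        assert n_used == 5

    def test_strict_log_mode(self):
        scores = [_score(1.0), _score(2.0)]
        odi_t, _ = rank_and_aggregate(scores, N=2, strict_log=True)
        assert odi_t == pytest.approx(np.log(1.0 + 1e-9) + np.log(2.0 + 1e-9))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            rank_and_aggregate([], N=5)


class TestPhenotypicScore:
    def test_zero_disorder_scores_zero(self):
        assert phenotypic_score(0.0, 200, 750) == 0.0

    def test_hand_computed_value(self):
        # (2/2) / ln(100) = 0.21715
        assert phenotypic_score(2.0, 2, 100) == pytest.approx(0.21715, abs=1e-5)

    def test_fusion_raises_score(self):
        assert phenotypic_score(10.0, 100, 300) < phenotypic_score(10.0, 100, 150)

    def test_too_few_ommatidia_rejected(self):
        with pytest.raises(TooFewOmmatidia):
            phenotypic_score(1.0, 1, 6)


class TestScorePointset:
    def test_perfect_lattice_scores_exactly_zero(self):
        gt = make_lattice(EyeSceneSpec(seed=0))
        res = score_pointset(gt.centers, eye_center=gt.spec.ellipse_center, N=200)
        assert res.P == 0.0
        assert res.odi_t == 0.0
        assert res.Z == 750

    def test_jitter_scores_positive(self):
        gt = make_lattice(EyeSceneSpec(seed=1, jitter_sigma=2.0))
        res = score_pointset(gt.centers, N=200)
        assert res.P > 0

    def test_similarity_invariance(self):
        gt = make_lattice(EyeSceneSpec(seed=1, jitter_sigma=1.0))
        pts = gt.centers.points
        base = score_pointset(pts, N=200).P
        rng = np.random.default_rng(0)
        for _ in range(20):
            theta = rng.uniform(0, 2 * np.pi)
            s = rng.uniform(0.2, 5.0)
            rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
            moved = s * pts @ rot.T + rng.uniform(-100, 100, size=2)
            assert abs(score_pointset(moved, N=200).P - base) < 1e-9

    def test_mean_score_increases_with_jitter(self):
        means = []
        for sigma in (0.0, 1.0, 4.0):
            vals = [
                score_pointset(make_lattice(EyeSceneSpec(seed=s, jitter_sigma=sigma)).centers, N=200).P
                for s in range(1, 4)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_too_few_centers_rejected(self):
        with pytest.raises(TooFewOmmatidia):
            score_pointset(np.zeros((6, 2)), N=10)


class TestScoreImage:
    def test_unreadable_path_fails_in_load_stage(self, tmp_path):
        with pytest.raises(PipelineError, match="load"):
            score_image(tmp_path / "missing.png", "brightfield")

    def test_flat_image_fails_in_localize_stage(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "flat.png"
        iio.imwrite(path, np.full((100, 100), 80, dtype=np.uint8))
        with pytest.raises(PipelineError, match="localize"):
            score_image(path, "brightfield")

    def test_full_pipeline_on_synthetic_scene(self, tmp_path):
        import imageio.v3 as iio
        from ommascore import render

        spec = EyeSceneSpec(seed=3, jitter_sigma=1.0)
        img = render(make_lattice(spec), spec)
        path = tmp_path / "scene.png"
        iio.imwrite(path, img.pixels)
        res = score_image(path, "brightfield")
        assert res.Z > 700
        assert res.N_used == 200
        assert res.P > 0
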