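import numpy as np
import pytest

from paleocanid import outline as ol
from paleocanid import synthetic as syn


def circle_outline(n=360, r=1.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = r * np.column_stack([np.cos(th), np.sin(th)])
    return ol.Outline2D(pts, anchors=(0, n // 2), specimen_id="circle")


class TestResampling:
    def test_unit_circle_equal_arc_angles(self):
        """Anchors at 0 and pi with counts (3, 3): semilandmarks sit at
        analytically known equal-arc angles."""
        o = circle_outline(720)
        cfg = ol.resample_outline(o, (3, 3))
        assert cfg.shape == (8, 2)
        angles = np.mod(np.arctan2(cfg[:, 1], cfg[:, 0]), 2 * np.pi)
        expected = np.array(
            [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4, np.pi,
             5 * np.pi / 4, 3 * np.pi / 2, 7 * np.pi / 4]
        )
        np.testing.assert_allclose(angles, expected, atol=2e-2)

    def test_default_count_is_142(self):
        o = circle_outline()
        assert ol.resample_outline(o).shape == (142, 2)
        assert ol.anchor_indices() == (0, 81)

    def test_square_spacing_matches_arc_length_oracle(self):
        # a square traversed counter-clockwise, anchors at opposite corners
        side = np.linspace(0, 1, 26)[:-1]
        pts = np.vstack(
            [
                np.column_stack([side, np.zeros_like(side)]),
                np.column_stack([np.ones_like(side), side]),
                np.column_stack([1 - side, np.ones_like(side)]),
                np.column_stack([np.zeros_like(side), 1 - side]),
            ]
        )
        o = ol.Outline2D(pts, anchors=(0, 50), specimen_id="square")
        n1 = 7
        cfg = ol.resample_outline(o, (n1, 5))
        # brute-force cumulative arc length oracle on curve 1 (perimeter
        # from corner (0,0) to corner (1,1) = 2.0)
        targets = 2.0 * np.arange(1, n1 + 1) / (n1 + 1)
        for p, t in zip(cfg[1 : n1 + 1], targets):
            if t <= 1.0:
                exp = np.array([t, 0.0])
            else:
                exp = np.array([1.0, t - 1.0])
            np.testing.assert_allclose(p, exp, atol=1e-9)

    def test_anchors_retained_exactly(self):
        o = circle_outline()
        cfg = ol.resample_outline(o)
        np.testing.assert_allclose(cfg[0], o.points[0])
        np.testing.assert_allclose(cfg[81], o.points[180])

    def test_coincident_anchors_rejected(self):
        pts = np.column_stack([np.cos(np.linspace(0, 2 * np.pi, 10, False)),
                               np.sin(np.linspace(0, 2 * np.pi, 10, False))])
        with pytest.raises(ValueError):
            ol.Outline2D(pts, anchors=(2, 2))


class TestGPA:
    def test_rotated_copy_has_zero_distance(self, rng):
        a = rng.normal(size=(20, 2))
        th = 1.1
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        sh = ol.gpa(np.array([a, a @ r.T + 5.0]))
        assert np.linalg.norm(sh.coords[0] - sh.coords[1]) < 1e-9

    def test_two_shape_rotation_matches_grid_search_oracle(self, rng):
        """Closed-form optimal rotation vs 0.01-degree brute force."""
        a = rng.normal(size=(15, 2))
        b = rng.normal(size=(15, 2))
        za, _ = ol._normalize(a)
        zb, _ = ol._normalize(b)
        r = ol.optimal_rotation(za, zb)
        angle = np.arctan2(r[1, 0], r[0, 0])
        grid = np.deg2rad(np.arange(-180, 180, 0.01))
        costs = []
        for th in grid:
            rm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            costs.append(((za @ rm - zb) ** 2).sum())
        best = grid[int(np.argmin(costs))]
        assert abs(np.angle(np.exp(1j * (angle - best)))) < np.deg2rad(0.011)
        assert ((za @ r - zb) ** 2).sum() <= min(costs) + 1e-3

    def test_aligned_set_is_centred_and_unit_size(self, outline_population):
        outlines, _ = outline_population
        configs = np.array([ol.resample_outline(o) for o in outlines[:8]])
        sh = ol.gpa(configs)
        for c in sh.coords:
            assert np.abs(c.mean(axis=0)).max() < 1e-9
            assert np.sqrt((c**2).sum()) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ol.gpa(np.zeros((2, 10, 2)))


class TestSliding:
    def test_identical_configurations_do_not_move(self, rng):
        base = circle_outline()
        cfg = ol.resample_outline(base, (10, 8))
        res = ol.slide_semilandmarks(
            np.array([cfg, cfg, cfg]), ol.anchor_indices((10, 8)))
        assert res.objective_path[0] == pytest.approx(0.0, abs=1e-12)
        assert len(res.objective_path) <= 2

    @pytest.mark.parametrize("mode", ["bending_energy", "procrustes_distance"])
    def test_objective_non_increasing(self, outline_population, mode):
        outlines, _ = outline_population
        configs = np.array([ol.resample_outline(o, (20, 15)) for o in outlines])
        res = ol.slide_semilandmarks(
            configs, ol.anchor_indices((20, 15)), mode=mode, max_iter=6
        )
        path = np.array(res.objective_path)
        assert (np.diff(path) <= 1e-12).all()

    def test_anchors_fixed_in_aligned_frame(self, outline_population):
        """Anchor landmarks never slide: they remain exactly the OPA image
        of the raw anchors (no tangent displacement is applied to them)."""
        outlines, _ = outline_population
        configs = np.array([ol.resample_outline(o, (20, 15)) for o in outlines[:6]])
        res = ol.slide_semilandmarks(configs, ol.anchor_indices((20, 15)),
                                     max_iter=3)
        a1, a2 = ol.anchor_indices((20, 15))
        # anchors are never slid along the curve: relative to an OPA
        # alignment of the raw configs onto the same mean, any apparent
        # anchor displacement comes only from the re-superimposition and
        # stays far below the inter-landmark spacing
        for raw, slid in zip(configs, res.configs):
            z, _ = ol._normalize(raw)
            z = z @ ol.optimal_rotation(z, res.mean_shape)
            spacing = np.median(np.linalg.norm(np.diff(slid, axis=0), axis=1))
            anchor_move = max(np.linalg.norm(z[a1] - slid[a1]),
                              np.linalg.norm(z[a2] - slid[a2]))
            assert anchor_move < 0.01
            assert anchor_move < spacing / 3

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            ol.slide_semilandmarks(np.zeros((2, 8, 2)), (0, 4), mode="banana")


class TestPCA:
    def test_score_variance_equals_shape_variance(self, outline_population):
        outlines, _ = outline_population
        configs = np.array([ol.resample_outline(o) for o in outlines[:10]])
        sh = ol.gpa(configs)
        res = ol.pca(sh)
        flat = sh.flat()
        total = ((flat - flat.mean(0)) ** 2).sum()
        assert res.scores.var(axis=0, ddof=1).sum() * (len(flat) - 1) == (
            pytest.approx(total, rel=1e-9)
        )

    def test_matches_eigendecomposition_oracle(self, rng):
        x = rng.normal(size=(5, 12))
        xc = x - x.mean(0)
        sh = ol.ShapeSet(
            coords=x.reshape(5, 6, 2), centroid_sizes=np.ones(5)
        )
        res = ol.pca(sh)
        cov = xc.T @ xc / 4
        w, v = np.linalg.eigh(cov)
        w, v = w[::-1], v[:, ::-1]
        for j in range(res.components.shape[0]):
            c = res.components[j]
            assert abs(abs(c @ v[:, j])) == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(
            res.explained_variance_ratio,
            (w / w.sum())[: res.components.shape[0]],
            atol=1e-9,
        )

    def test_too_few_specimens_rejected(self):
        sh = ol.ShapeSet(np.zeros((2, 5, 2)), np.ones(2))
        with pytest.raises(ValueError):
            ol.pca(sh)


class TestBgPCA:
    def _shapes(self, rng, sep=0.0, n=8):
        base = rng.normal(size=(6, 2))
        x = []
        groups = []
        for g in range(2):
            for _ in range(n):
                x.append(base + rng.normal(0, 0.01, size=(6, 2))
                         + g * sep * np.eye(6, 2))
                groups.append("ab"[g])
        return np.array([c.reshape(-1) for c in x]), groups

    def test_identical_group_means_give_zero_between_variance(self, rng):
        x, groups = self._shapes(rng, sep=0.0)
        # force exactly identical means by mirroring samples
        xs = np.vstack([x[:8], x[:8]])
        model = ol.BetweenGroupPCA().fit(xs, ["a"] * 8 + ["b"] * 8)
        assert model.between_group_variance_.sum() == pytest.approx(0.0, abs=1e-20)

    def test_two_groups_yield_single_between_axis(self, rng):
        x, groups = self._shapes(rng, sep=0.1)
        model = ol.BetweenGroupPCA().fit(x, groups)
        assert model.axis_is_between_.sum() == 1

    def test_residual_axes_flagged(self, rng):
        x, groups = self._shapes(rng, sep=0.1)
        model = ol.BetweenGroupPCA(n_residual_axes=2).fit(x, groups)
        assert list(model.axis_is_between_) == [True, False, False]

    def test_bgpc1_aligns_with_generating_contrast(self, outline_population):
        outlines, truth = outline_population
        configs = np.array([ol.resample_outline(o) for o in outlines])
        sh = ol.gpa(configs, groups=[o.group for o in outlines])
        model = ol.bgpca(sh)
        v = syn.contrast_configuration(truth)
        axis = model.components_[0]
        cos = abs(axis @ v) / (np.linalg.norm(axis) * np.linalg.norm(v))
        assert cos > 0.9

    def test_single_member_group_warns(self, rng):
        x, _ = self._shapes(rng)
        with pytest.warns(UserWarning, match="single member"):
            ol.BetweenGroupPCA().fit(x[:9], ["a"] * 8 + ["b"])


class TestProjection:
    @pytest.fixture()
    def fitted(self, outline_population):
        outlines, _ = outline_population
        configs = np.array([ol.resample_outline(o) for o in outlines])
        gp = ol.GeneralizedProcrustes().fit(configs)
        model = ol.bgpca(gp.to_shape_set(groups=[o.group for o in outlines]))
        return configs, gp, model

    def test_training_specimen_reprojects_to_its_score(self, fitted):
        configs, gp, model = fitted
        scores = ol.project_unknowns(model, gp, configs[:5])
        np.testing.assert_allclose(scores, model.scores_[:5], atol=1e-8)

    def test_group_mean_midpoint_projects_to_score_midpoint(self, fitted):
        configs, gp, model = fitted
        means = model.group_means_
        mid = (means[0] + means[1]) / 2
        score = model.transform(mid[None, :])[0]
        expect = model.group_mean_scores_.mean(axis=0)
        np.testing.assert_allclose(score, expect, atol=1e-10)

    def test_point_count_mismatch_rejected(self, fitted):
        configs, gp, model = fitted
        with pytest.raises(ValueError, match="mismatch"):
            gp.transform(np.zeros((1, 50, 2)))


class TestAllometry:
    def test_exact_linear_relation_gives_r2_one(self, rng):
        cs = rng.uniform(50, 150, size=30)
        scores = 0.3 * np.log(cs) - 1.0
        res = ol.test_allometry(scores[:, None], cs)
        assert res.r_squared[0] == pytest.approx(1.0, abs=1e-12)
        assert res.slopes[0] == pytest.approx(0.3, abs=1e-12)

    def test_zero_size_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ol.test_allometry(np.zeros((5, 1)), np.full(5, 10.0))

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ol.test_allometry(np.zeros((3, 1)), np.array([1.0, 2.0, 3.0]))


class TestAssignment:
    @pytest.fixture()
    def model(self, outline_population):
        outlines, _ = outline_population
        configs = np.array([ol.resample_outline(o) for o in outlines])
        sh = ol.gpa(configs, groups=[o.group for o in outlines])
        return ol.bgpca(sh)

    def test_group_mean_assigned_with_high_typicality(self, model):
        score = model.group_mean_scores_[0]
        res = ol.assign_group(model, score)
        assert res["label"] == model.classes_[0]
        assert res["typicality"][str(model.classes_[0])] == pytest.approx(1.0)

    def test_far_outlier_atypical_for_all_groups(self, model):
        span = np.abs(model.scores_).max()
        res = ol.assign_group(model, np.full(model.scores_.shape[1], 50 * span))
        assert all(t < 0.05 for t in res["typicality"].values())
        assert not res["overlap"]


class TestPipelineInvariances:
    def test_similarity_transform_leaves_scores_unchanged(self, outline_population):
        """Rotating, translating and scaling raw outlines changes no score."""
        outlines, _ = outline_population
        sub = outlines[::4]  # every 4th specimen: both groups represented
        configs = np.array([ol.resample_outline(o) for o in sub])
        gp = ol.GeneralizedProcrustes().fit(configs)
        model = ol.bgpca(gp.to_shape_set(groups=[o.group for o in sub]))
        th = 0.93
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = [
            ol.Outline2D(o.points @ r.T * 2.5 + np.array([3.0, -8.0]),
                         o.anchors, o.specimen_id, o.group)
            for o in sub
        ]
        mcfg = np.array([ol.resample_outline(o) for o in moved])
        scores = ol.project_unknowns(model, gp, mcfg)
        np.testing.assert_allclose(scores, model.scores_, atol=1e-8)

    def test_mirrored_outline_maps_to_same_shape(self, outline_population):
        outlines, _ = outline_population
        o = outlines[0]
        mirrored = ol.Outline2D(
            o.points * np.array([1.0, -1.0]), o.anchors, "mirror", o.group
        )
        a = ol.resample_outline(o)
        b = ol.resample_outline(mirrored)
        sh = ol.gpa(np.array([a, b]))
        assert np.linalg.norm(sh.coords[0] - sh.coords[1]) < 1e-9
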