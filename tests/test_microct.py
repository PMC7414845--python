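from itertools import combinations

import numpy as np
import pytest

from paleocanid import microct as mc
from paleocanid import synthetic as syn


class TestSegmentation:
    def test_three_mode_phantom_recovered(self, tooth_phantom):
        gray, labels, _ = tooth_phantom
        seg, thresholds = mc.segment_tissues(gray, n_classes=3)
        assert (seg.data == labels.data).mean() >= 0.99
        assert len(thresholds) == 2

    def test_constant_volume_rejected(self):
        gray = mc.GrayVolume(np.full((8, 8, 8), 7.0), 0.1)
        with pytest.raises(ValueError, match="degenerate histogram"):
            mc.segment_tissues(gray, n_classes=3)

    def test_manual_thresholds_match_digitize_oracle(self, tooth_phantom):
        gray, _, _ = tooth_phantom
        thr = [60.0, 150.0]
        seg, used = mc.segment_tissues(gray, thresholds=thr)
        oracle = np.digitize(gray.data, thr)
        np.testing.assert_array_equal(seg.data, oracle)
        np.testing.assert_allclose(used, thr)


class TestCervixPlane:
    def test_exact_horizontal_plane(self, rng):
        pts = np.column_stack(
            [np.full(40, 5.0), rng.uniform(0, 10, 40), rng.uniform(0, 10, 40)]
        )
        plane = mc.fit_cervix_plane(pts, toward=np.array([9.0, 5.0, 5.0]))
        np.testing.assert_allclose(np.abs(plane.normal), [1, 0, 0], atol=1e-9)
        assert plane.offset == pytest.approx(5.0, abs=1e-9)

    def test_noisy_plane_within_angular_tolerance(self, rng):
        base = np.column_stack(
            [np.zeros(200), rng.uniform(-5, 5, 200), rng.uniform(-5, 5, 200)]
        )
        noisy = base + rng.normal(0, 0.05, base.shape)
        plane = mc.fit_cervix_plane(noisy, toward=np.array([10.0, 0, 0]))
        angle = np.degrees(np.arccos(abs(plane.normal @ np.array([1.0, 0, 0]))))
        assert angle < 1.0

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            mc.fit_cervix_plane(np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0), np.zeros(10)])
        with pytest.raises(ValueError, match="collinear"):
            mc.fit_cervix_plane(pts)


class TestCrownSlice:
    def test_levels_within_one_voxel_of_phantom_truth(
        self, tooth_phantom, tooth_slice
    ):
        _, labels, truth = tooth_phantom
        vm = labels.voxel_mm
        # slice levels are in plane coordinates; the fitted plane offset
        # differs from the generator's cervix height, so compare absolute
        # heights along the (near-axial) normal
        found1 = tooth_slice.level1 + tooth_slice.plane.offset
        found2 = tooth_slice.level2 + tooth_slice.plane.offset
        assert abs(found1 - truth["level1"]) <= 1.5 * vm
        assert abs(found2 - truth["level2"]) <= 1.5 * vm

    def test_partition_conservation(self, tooth_phantom, tooth_slice):
        _, labels, _ = tooth_phantom
        for tissue in ("dentine", "enamel"):
            total = int(labels.mask(tissue).sum())
            assert (
                tooth_slice.counts_in[tissue] + tooth_slice.counts_out[tissue]
                == total
            )

    def test_single_cusp_phantom_rejected(self):
        cfg = syn.ToothPhantomConfig(
            seed=2, cusp_heights_mm=(0.45, 3.0), crest_height_mm=0.0,
            enamel_thickness_mm=0.3,
        )
        _, labels, truth = syn.gen_tooth_phantom(cfg)
        with pytest.raises(
            ValueError, match="single cusp|separation|valley|cross-section"
        ):
            mc.extract_crown_slice(labels, truth["cervix_plane"])


class TestDentinePercent:
    def test_formula_on_known_volumes(self):
        sl = mc.CrownSlice(
            level1=0.0, level2=1.0,
            plane=mc.Plane(np.array([1.0, 0, 0]), 0.0), voxel_mm=1.0,
            counts_in={"dentine": 75, "enamel": 25},
            counts_out={"dentine": 0, "enamel": 0},
            tooth_breadth_mm=5.0,
        )
        assert mc.dentine_percent(sl).percent == pytest.approx(75.0)
        sl.counts_in = {"dentine": 40, "enamel": 40}
        assert mc.dentine_percent(sl).percent == pytest.approx(50.0)

    def test_empty_slice_rejected(self):
        sl = mc.CrownSlice(
            level1=0.0, level2=1.0,
            plane=mc.Plane(np.array([1.0, 0, 0]), 0.0), voxel_mm=1.0,
            counts_in={"dentine": 0, "enamel": 0},
            counts_out={}, tooth_breadth_mm=5.0,
        )
        with pytest.raises(ValueError, match="Vc = 0"):
            mc.dentine_percent(sl)

    def test_matches_voxel_count_oracle(self, tooth_phantom, tooth_slice):
        """Direct voxel counting between the found planes reproduces the
        reported percentage."""
        _, labels, _ = tooth_phantom
        d = tooth_slice.plane.distance_grid(labels.data.shape, labels.voxel_mm)
        sel = (d > tooth_slice.level1) & (d < tooth_slice.level2)
        dent = int(((labels.data == 1) & sel).sum())
        enam = int(((labels.data == 2) & sel).sum())
        oracle = 100.0 * dent / (dent + enam)
        assert mc.dentine_percent(tooth_slice).percent == pytest.approx(
            oracle, abs=0.5
        )

    def test_rotation_and_rescaling_invariance(self, tooth_phantom):
        _, labels, _ = tooth_phantom

        def dp(vol):
            pts = mc.extract_cervix_points(vol)
            pl = mc.fit_cervix_plane(
                pts, toward=vol.coords_mm(vol.mask("enamel")).mean(axis=0)
            )
            return mc.dentine_percent(mc.extract_crown_slice(vol, pl)).percent

        base = dp(labels)
        rotated = mc.LabelVolume(
            np.transpose(labels.data, (2, 1, 0)).copy(),
            labels.voxel_mm, labels.semantics,
        )
        rescaled = mc.LabelVolume(labels.data, labels.voxel_mm * 2,
                                  labels.semantics)
        assert dp(rotated) == pytest.approx(base, abs=0.5)
        assert dp(rescaled) == pytest.approx(base, abs=0.5)


class TestWear:
    def test_truncation_flags_wear(self, tooth_plane):
        _, labels, _ = syn.gen_tooth_phantom(
            syn.ToothPhantomConfig(seed=1, wear_truncation_frac=0.2)
        )
        report = mc.detect_wear(labels, tooth_plane)
        assert report.worn

    def test_fully_removed_cap_has_severity_one(self, tooth_plane):
        _, labels, _ = syn.gen_tooth_phantom(
            syn.ToothPhantomConfig(seed=1, wear_truncation_frac=0.6)
        )
        report = mc.detect_wear(labels, tooth_plane)
        assert report.worn and report.severity == pytest.approx(1.0)

    def test_no_enamel_at_all_is_maximal_wear(self, tooth_phantom, tooth_plane):
        _, labels, _ = tooth_phantom
        data = labels.data.copy()
        data[data == 2] = 1
        bald = mc.LabelVolume(data, labels.voxel_mm, labels.semantics)
        report = mc.detect_wear(bald, tooth_plane)
        assert report.worn and report.severity == 1.0


class TestReconstruction:
    def test_self_reference_matches_direct_computation(
        self, tooth_phantom, tooth_plane
    ):
        _, labels, _ = tooth_phantom
        direct = mc.dentine_percent(
            mc.extract_crown_slice(labels, tooth_plane)
        ).percent
        res = mc.reconstruct_broken_cervix(labels, [labels])
        assert res[0].percent == pytest.approx(direct, abs=0.5)

    def test_broken_phantom_recovered_from_three_references(self, tooth_phantom):
        _, target, _ = syn.gen_tooth_phantom(
            syn.ToothPhantomConfig(seed=10, cervix_break_frac=0.10)
        )
        _, unbroken, _ = syn.gen_tooth_phantom(syn.ToothPhantomConfig(seed=10))
        pl = mc.fit_cervix_plane(
            mc.extract_cervix_points(unbroken),
            toward=unbroken.coords_mm(unbroken.mask("enamel")).mean(axis=0),
        )
        truth_pct = mc.dentine_percent(
            mc.extract_crown_slice(unbroken, pl)
        ).percent
        refs = [
            syn.gen_tooth_phantom(
                syn.ToothPhantomConfig(seed=s, enamel_thickness_mm=e,
                                       cusp_heights_mm=h)
            )[1]
            for s, e, h in (
                (11, 0.32, (2.0, 2.9)),
                (12, 0.40, (2.4, 3.1)),
                (13, 0.36, (2.1, 2.8)),
            )
        ]
        res = mc.reconstruct_broken_cervix(target, refs)
        assert len(res) == 3
        mean = np.mean([r.percent for r in res])
        assert mean == pytest.approx(truth_pct, abs=2.0)

    def test_insufficient_cervix_points_rejected(self, tooth_phantom):
        _, labels, _ = tooth_phantom
        with pytest.raises(ValueError, match="points"):
            mc.reconstruct_broken_cervix(labels, [labels], min_points=10**6)


class TestBvTv:
    def test_solid_phantom_is_one(self):
        vol, truth = syn.gen_epiphysis_phantom(
            syn.EpiphysisPhantomConfig(porosity=0.0, seed=1)
        )
        res = mc.bv_tv(vol, truth["separation_plane"])
        assert res.ratio == pytest.approx(1.0, abs=1e-9)
        assert res.maturity_call == "adult"

    def test_porosity_04_gives_060(self):
        vol, truth = syn.gen_epiphysis_phantom(
            syn.EpiphysisPhantomConfig(porosity=0.4, seed=3)
        )
        res = mc.bv_tv(vol, truth["separation_plane"])
        assert res.ratio == pytest.approx(0.60, abs=0.02)

    def test_matches_brute_force_voxel_count(self):
        vol, truth = syn.gen_epiphysis_phantom(
            syn.EpiphysisPhantomConfig(porosity=0.3, seed=5)
        )
        res = mc.bv_tv(vol, truth["separation_plane"])
        d = truth["separation_plane"].distance_grid(vol.data.shape, vol.voxel_mm)
        bone = (vol.data == 1) & (d > 0)
        assert res.bv_mm3 == pytest.approx(bone.sum() * vol.voxel_mm**3)

    def test_young_vs_adult_calls_match_generator(self):
        calls = {}
        for name, por, seeds in (("immature", 0.5, (1, 2, 3)),
                                 ("adult", 0.2, (4, 5, 6))):
            for s in seeds:
                vol, truth = syn.gen_epiphysis_phantom(
                    syn.EpiphysisPhantomConfig(porosity=por, seed=s)
                )
                res = mc.bv_tv(vol, truth["separation_plane"])
                calls.setdefault(name, []).append(res.maturity_call)
        assert calls["immature"] == ["immature"] * 3
        assert calls["adult"] == ["adult"] * 3

    def test_empty_proximal_side_rejected(self):
        vol, truth = syn.gen_epiphysis_phantom(
            syn.EpiphysisPhantomConfig(porosity=0.0, seed=1)
        )
        plane = mc.Plane(np.array([1.0, 0, 0]), 10_000.0)
        with pytest.raises(ValueError, match="proximal"):
            mc.bv_tv(vol, plane)


class TestCompareGroups:
    def test_exact_p_matches_rank_split_enumeration(self):
        """Fully separated 3 vs 3: U = 0 and the exact two-sided p equals
        the brute-force enumeration over all C(6,3) = 20 rank splits."""
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = mc.compare_groups(a, b)
        assert res["U"] == 0.0
        ranks = range(1, 7)
        u1s = [sum(comb) - 3 * 4 / 2 for comb in combinations(ranks, 3)]
        p_lo = np.mean([u <= 0.0 for u in u1s])
        p_hi = np.mean([u >= 0.0 for u in u1s])
        p_exact = 2 * min(p_lo, p_hi)
        assert p_exact == pytest.approx(0.1)
        assert res["p"] == pytest.approx(min(p_exact, 1.0), abs=1e-12)

    def test_identical_tied_values_give_p_one(self):
        res = mc.compare_groups([5.0] * 4, [5.0] * 4)
        assert res["p"] == pytest.approx(1.0)

    def test_fully_separated_large_groups_highly_significant(self):
        a = np.arange(21, dtype=float)
        b = np.arange(100, 123, dtype=float)
        res = mc.compare_groups(a, b)
        assert res["p"] < 1e-3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mc.compare_groups([], [1.0])

    def test_cohort_contrast_reproduces_direction_of_effect(self):
        """Thin-enamel ('wolf') phantoms show higher percent crown dentine,
        significant by Mann-Whitney at the study sample sizes."""
        vals = {"dog": [], "wolf": []}
        for group, cfg in syn.tooth_cohort_configs(n_dog=8, n_wolf=8, seed=8):
            _, labels, _ = syn.gen_tooth_phantom(cfg)
            pts = mc.extract_cervix_points(labels)
            pl = mc.fit_cervix_plane(
                pts, toward=labels.coords_mm(labels.mask("enamel")).mean(axis=0)
            )
            vals[group].append(
                mc.dentine_percent(mc.extract_crown_slice(labels, pl)).percent
            )
        assert np.mean(vals["wolf"]) > np.mean(vals["dog"])
        assert mc.compare_groups(vals["dog"], vals["wolf"])["p"] < 0.05
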