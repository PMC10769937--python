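"""Simulator contracts: determinism, neutrality, rigidity, partiality and
depth-dependent occlusion."""

from dataclasses import replace

import numpy as np
import pytest

import earreg
from earreg.errors import ConfigError, ModelError
from earreg.synthetic import (
    STRUCTURE_ORDER,
    EarModel,
    GroupBounds,
    JointBounds,
    LandmarkSet,
    SimulationConfig,
    build_template,
    generate_sample,
    ground_truth_field,
    sample_partial,
    simulate_nonrigid,
    simulate_rigid,
)


class TestBuildTemplate:
    def test_deterministic_for_fixed_seed(self):
        a = build_template(seed=7)
        b = build_template(seed=7)
        for name in a.structure_names:
            np.testing.assert_array_equal(a.structures[name].points, b.structures[name].points)

    def test_point_counts_match_request(self):
        counts = {k: 60 + 10 * i for i, k in enumerate(STRUCTURE_ORDER)}
        model = build_template(counts, seed=0)
        for k, n in counts.items():
            assert len(model.structures[k]) == n

    def test_centroid_depth_ordering(self, template):
        depths = [template.structures[k].points[:, 2].mean() for k in STRUCTURE_ORDER]
        assert all(a < b for a, b in zip(depths, depths[1:]))

    def test_minimum_count_enforced(self):
        with pytest.raises(ConfigError):
            build_template({"stapes": 10}, seed=0)

    def test_landmarks_are_cloud_vertices(self, template):
        for name, lms in template.landmarks.landmarks.items():
            pts = template.structures[name].points
            for lm in lms:
                assert np.min(np.linalg.norm(pts - lm, axis=1)) < 1e-12


class TestSimulateNonrigid:
    def test_zero_bounds_is_identity(self, template):
        cfg = SimulationConfig.neutral()
        out = simulate_nonrigid(template, cfg, seed=3)
        for name in template.structure_names:
            np.testing.assert_allclose(
                out.structures[name].points, template.structures[name].points, atol=1e-12
            )

    def test_deterministic_for_fixed_seed(self, template):
        cfg = SimulationConfig()
        a = simulate_nonrigid(template, cfg, seed=5)
        b = simulate_nonrigid(template, cfg, seed=5)
        for name in template.structure_names:
            np.testing.assert_array_equal(a.structures[name].points, b.structures[name].points)

    def test_vertex_displacement_bounded_by_control_displacement(self, template):
        """Trilinear weights are convex, so no vertex can move farther than
        the most-displaced control point of its structure's lattice."""
        from earreg.synthetic import _FFDLattice

        cfg = SimulationConfig()
        rng = np.random.default_rng(11)
        for name in template.structure_names:
            pts = template.structures[name].points
            lat = _FFDLattice(pts, cfg.lattice_resolution)
            lat.randomize_groups(cfg.nonrigid_bounds[name], rng)
            moved = lat.deform(pts)
            max_vertex = np.linalg.norm(moved - pts, axis=1).max()
            assert max_vertex <= lat.max_control_displacement() + 1e-9

    def test_negative_bounds_rejected(self, template):
        cfg = SimulationConfig()
        cfg.nonrigid_bounds["malleus"] = GroupBounds(-0.1, 1.0)
        with pytest.raises(ConfigError):
            simulate_nonrigid(template, cfg, seed=0)


class TestSimulateRigid:
    def test_zero_bounds_is_identity(self, template):
        cfg = SimulationConfig.neutral()
        out = simulate_rigid(template, cfg, seed=3)
        for name in template.structure_names:
            np.testing.assert_allclose(
                out.structures[name].points, template.structures[name].points, atol=1e-12
            )

    def test_malleus_joint_moves_only_downstream(self, template):
        """Rotating only the membrane->malleus joint moves malleus, incus and
        stapes; canal wall and membrane stay put."""
        cfg = SimulationConfig.neutral()
        cfg.rigid_bounds = [
            JointBounds(0, 0),
            JointBounds(15.0, 0.5),
            JointBounds(0, 0),
            JointBounds(0, 0),
        ]
        out = simulate_rigid(template, cfg, seed=4)
        disp = {
            n: np.linalg.norm(
                out.structures[n].points - template.structures[n].points, axis=1
            ).max()
            for n in template.structure_names
        }
        assert disp["canal_wall"] < 1e-12
        assert disp["tympanic_membrane"] < 1e-12
        assert disp["malleus"] > 1e-3
        assert disp["incus"] > 1e-3
        assert disp["stapes"] > 1e-3

    def test_within_structure_rigidity(self, template):
        cfg = SimulationConfig()
        out = simulate_rigid(template, cfg, seed=9)
        for name in template.structure_names:
            a = template.structures[name].points
            b = out.structures[name].points
            ia = np.arange(0, len(a) - 1)
            d0 = np.linalg.norm(a[ia] - a[ia + 1], axis=1)
            d1 = np.linalg.norm(b[ia] - b[ia + 1], axis=1)
            np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_missing_articulations_rejected(self, template):
        broken = EarModel(
            structures={k: template.structures[k] for k in ("canal_wall", "tympanic_membrane", "malleus")},
            articulation_points=template.articulation_points[:2],
            support_points=template.support_points,
            landmarks=template.landmarks,
            external_point=template.external_point,
        )
        broken.articulation_points = broken.articulation_points[:1]  # break invariant post-init
        with pytest.raises(ModelError):
            simulate_rigid(broken, SimulationConfig(), seed=0)


class TestGroundTruthField:
    def test_identity_variant_gives_zero_field(self, template):
        phi = ground_truth_field(template, template)
        assert phi.mean_norm() == 0.0

    def test_constant_translation(self, template):
        shifted = simulate_rigid(template, SimulationConfig.neutral(), seed=0)
        for name in shifted.structure_names:
            shifted.structures[name].points += np.array([1.0, 0.0, 0.0])
        phi = ground_truth_field(template, shifted)
        np.testing.assert_allclose(phi.vectors, [[1.0, 0.0, 0.0]] * len(phi), atol=1e-12)

    def test_mean_norm_matches_brute_force_toy_case(self):
        a = np.array([[0.0, 0, 0], [1, 0, 0], [0, 2, 0]])
        b = a + np.array([[3.0, 4, 0], [0, 0, 5], [0, 0, 0]])
        # brute force: (5 + 5 + 0) / 3
        expected = (5.0 + 5.0 + 0.0) / 3.0
        tpl = build_template(seed=0)
        phi = earreg.DisplacementField(b - a)
        assert abs(phi.mean_norm() - expected) < 1e-12

    def test_count_mismatch_rejected(self, template, small_template):
        with pytest.raises(ModelError):
            ground_truth_field(template, small_template)


class TestSamplePartial:
    def test_keep_all_config_returns_variant_exactly(self, template):
        cfg = SimulationConfig.keep_all()
        out = sample_partial(template, cfg, seed=2)
        np.testing.assert_array_equal(out.points, template.all_points().points)
        np.testing.assert_array_equal(out.source_index, np.arange(len(out)))

    def test_jitter_bound_respected(self, template):
        cfg = replace(SimulationConfig.keep_all(), jitter_delta=0.05)
        out = sample_partial(template, cfg, seed=2)
        ref = template.all_points().points[out.source_index]
        assert np.abs(out.points - ref).max() <= 0.05 + 1e-12

    def test_points_are_subset_of_variant_before_jitter(self, template):
        cfg = replace(SimulationConfig(), jitter_delta=0.0)
        out = sample_partial(template, cfg, seed=8)
        ref = template.all_points().points[out.source_index]
        np.testing.assert_array_equal(out.points, ref)

    def test_deeper_structure_retains_fewer_points(self):
        """Monte-Carlo over 200 seeds: two same-size structures at different
        depths — the deeper one keeps strictly fewer points on average."""
        rng = np.random.default_rng(0)
        shallow = rng.normal(scale=0.5, size=(100, 3)) + [0, 0, 1.0]
        deep = rng.normal(scale=0.5, size=(100, 3)) + [0, 0, 9.0]
        model = EarModel(
            structures={
                "shallow": earreg.PointCloud(shallow),
                "deep": earreg.PointCloud(deep),
            },
            articulation_points=np.array([[0.0, 0.0, 5.0]]),
            support_points={"shallow": shallow.mean(axis=0), "deep": deep.mean(axis=0)},
            landmarks=LandmarkSet({"shallow": shallow[:1], "deep": deep[:1]}),
            external_point=np.array([0.0, 0.0, 0.0]),
        )
        cfg = replace(
            SimulationConfig(),
            visibility_lambda=np.inf,
            rigid_bounds=[JointBounds(0, 0)],
        )
        kept_shallow, kept_deep = 0, 0
        for s in range(200):
            out = sample_partial(model, cfg, seed=s)
            kept_shallow += int((out.labels == 0).sum())
            kept_deep += int((out.labels == 1).sum())
        assert kept_deep < kept_shallow

    def test_visible_ratio_bounds(self, default_sample):
        assert 0.0 < default_sample.visible_ratio <= 1.0


class TestGenerateSample:
    def test_deterministic(self, template):
        cfg = SimulationConfig()
        a = generate_sample(cfg, seed=5, template=template)
        b = generate_sample(cfg, seed=5, template=template)
        np.testing.assert_array_equal(a.target.points, b.target.points)
        np.testing.assert_array_equal(a.gt_displacement.vectors, b.gt_displacement.vectors)
        assert a.visible_ratio == b.visible_ratio

    def test_neutral_config_end_to_end_identity(self, template):
        s = generate_sample(SimulationConfig.neutral(), seed=5, template=template)
        assert s.visible_ratio == 1.0
        assert s.gt_displacement.mean_norm() < 1e-12
        np.testing.assert_allclose(s.target.points, s.template.points, atol=1e-12)

    def test_visible_ratio_exact_fraction(self, default_sample):
        assert default_sample.visible_ratio == len(default_sample.target) / len(
            default_sample.variant
        )

    def test_mean_displacement_within_analytic_envelope(self, template):
        """The FFD + chain bounds give a hard ceiling on any vertex motion;
        the mean over samples must sit inside [0, envelope]."""
        cfg = SimulationConfig.keep_all()
        # envelope per structure: FFD slab motions (3 axis groups, each
        # translation + rotation about the group centroid) then the chain:
        # each joint rotation about a pivot within the assembly plus
        # translation. Bound rotation displacement by 2 sin(theta/2) * R.
        assembly_radius = template.all_points().bounding_box_diagonal()
        ffd = max(
            3 * (b.max_translation_mm + 2 * np.sin(np.radians(b.max_rotation_deg) / 2) * assembly_radius)
            for b in cfg.nonrigid_bounds.values()
        )
        chain = sum(
            b.max_translation_mm + 2 * np.sin(np.radians(b.max_rotation_deg) / 2) * assembly_radius
            for b in cfg.rigid_bounds
        )
        envelope = ffd + chain
        means = [
            generate_sample(cfg, seed=s, template=template).gt_displacement.mean_norm()
            for s in range(50)
        ]
        assert 0.0 < np.mean(means) < envelope


class TestGenerateDataset:
    def test_writes_n_samples_and_manifest(self, tmp_path):
        cfg = SimulationConfig(
            n_points_per_structure={k: 50 for k in STRUCTURE_ORDER}
        )
        manifest = earreg.generate_dataset(3, cfg, seed=1, out_dir=tmp_path)
        assert len(manifest["samples"]) == 3
        assert sorted(p.name for p in tmp_path.iterdir() if p.is_dir()) == [
            "sample_0000",
            "sample_0001",
            "sample_0002",
        ]
        assert (tmp_path / "manifest.json").exists()

    def test_rerun_is_bitwise_identical(self, tmp_path):
        import hashlib

        cfg = SimulationConfig(
            n_points_per_structure={k: 50 for k in STRUCTURE_ORDER}
        )
        earreg.generate_dataset(2, cfg, seed=3, out_dir=tmp_path / "a")
        earreg.generate_dataset(2, cfg, seed=3, out_dir=tmp_path / "b")
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                g = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert hashlib.sha256(f.read_bytes()).hexdigest() == hashlib.sha256(
                    g.read_bytes()
                ).hexdigest(), f.name

    def test_manifest_mean_displacement_matches_reload(self, tmp_path):
        from earreg import io as _io

        cfg = SimulationConfig(
            n_points_per_structure={k: 50 for k in STRUCTURE_ORDER}
        )
        manifest = earreg.generate_dataset(2, cfg, seed=5, out_dir=tmp_path)
        for row in manifest["samples"]:
            phi = _io.read_field(tmp_path / row["sample"] / "gt_displacement.csv")
            assert abs(phi.mean_norm() - row["mean_gt_displacement_mm"]) < 1e-12
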