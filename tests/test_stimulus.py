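"""Renderer geometry and condition-manipulation identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glossmvpa.envmaps import ENVMAP_KINDS, make_envmap
from glossmvpa.stimulus import (Scene, lookup_direction, make_monocular_pair, make_potato,
                                reflect, render_condition, render_layers)


class TestPotato:
    def test_zero_distortion_is_exact_sphere(self):
        pot = make_potato(seed=1, amplitude=0.0, base_radius=40.0)
        dirs = np.random.default_rng(0).standard_normal((200, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        assert np.allclose(pot.radius(dirs), 40.0)

    def test_same_seed_bitwise_identical(self):
        a = make_potato(seed=1, amplitude=0.2).to_mesh()
        b = make_potato(seed=1, amplitude=0.2).to_mesh()
        assert np.array_equal(np.asarray(a.vertices), np.asarray(b.vertices))

    def test_different_seeds_differ(self):
        a = make_potato(seed=1, amplitude=0.2).to_mesh()
        b = make_potato(seed=2, amplitude=0.2).to_mesh()
        assert np.abs(np.asarray(a.vertices) - np.asarray(b.vertices)).max() > 0

    def test_mesh_is_watertight_and_star_shaped(self):
        pot = make_potato(seed=3, amplitude=0.3)
        mesh = pot.to_mesh()
        assert mesh.is_watertight
        # star-shaped about the centroid: radius strictly positive everywhere
        assert pot.radius(np.eye(3)).min() > 0

    @pytest.mark.parametrize("amplitude", [-0.1, 0.5, 0.9])
    def test_invalid_amplitude_rejected(self, amplitude):
        with pytest.raises(ValueError):
            make_potato(seed=1, amplitude=amplitude)


class TestReflect:
    def test_normal_incidence_reflects_straight_back(self):
        n = np.array([0.0, 0.0, 1.0])
        assert np.allclose(reflect(n, n), n)

    def test_mirror_symmetry_at_45_degrees(self):
        s = np.sin(np.deg2rad(45.0))
        c = np.cos(np.deg2rad(45.0))
        omega = reflect(np.array([s, 0.0, c]), np.array([0.0, 0.0, 1.0]))
        assert np.allclose(omega, [-s, 0.0, c], atol=1e-15)

    def test_back_facing_rejected(self):
        with pytest.raises(ValueError):
            reflect(np.array([0.0, 0.0, -1.0]), np.array([0.0, 0.0, 1.0]))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_law_of_reflection_property(self, seed):
        """angle(n, omega) == angle(n, V) to 1e-12, |omega| == 1, coplanarity."""
        rng = np.random.default_rng(seed)
        V = rng.standard_normal((40, 3))
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        n = V + 0.7 * rng.standard_normal((40, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        ok = np.sum(n * V, axis=1) > 1e-6
        V, n = V[ok], n[ok]
        omega = reflect(V, n)
        assert np.allclose(np.linalg.norm(omega, axis=1), 1.0, atol=1e-12)
        a_in = np.arccos(np.clip(np.sum(n * V, axis=1), -1, 1))
        a_out = np.arccos(np.clip(np.sum(n * omega, axis=1), -1, 1))
        assert np.abs(a_in - a_out).max() < 1e-12
        # omega lies in the plane spanned by n and V
        assert np.abs(np.sum(np.cross(n, V) * omega, axis=1)).max() < 1e-12


class TestRenderConditions:
    def test_flat_images_bitwise_identical(self, scene):
        pair = render_condition(scene, "flat", seed=5)
        assert np.array_equal(pair.left, pair.right)
        assert pair.meta["flat_source_eye"] in ("left", "right")

    def test_anti_mirror_swaps_the_eyes_reflected_rays(self, scene):
        """At every surface point the anti-mirror left-eye lookup equals the
        mirror right-eye lookup (and vice versa)."""
        am = render_condition(scene, "anti_mirror")
        for eye, other in (("left", "right"), ("right", "left")):
            hit = am.meta[eye]["hit"]
            P = am.meta[eye]["point"][hit]
            n = am.meta[eye]["normal"][hit]
            got = am.meta[eye]["lookup"][hit]
            want = lookup_direction(scene, P, n, other, "mirror")
            ok = np.isfinite(want[:, 0]) & np.isfinite(got[:, 0])
            assert ok.mean() > 0.95
            assert np.abs(got[ok] - want[ok]).max() == 0.0

    def test_painted_lookup_identical_across_eyes(self, scene):
        """The painted condition samples the environment from the cyclopean
        ray at each surface point, so reflected features carry exactly the
        surface's own disparity."""
        pa = render_condition(scene, "painted")
        hit = pa.meta["left"]["hit"]
        P = pa.meta["left"]["point"][hit]
        n = pa.meta["left"]["normal"][hit]
        omL = lookup_direction(scene, P, n, "left", "painted")
        omR = lookup_direction(scene, P, n, "right", "painted")
        ok = np.isfinite(omL[:, 0]) & np.isfinite(omR[:, 0])
        assert np.abs(omL[ok] - omR[ok]).max() == 0.0

    def test_render_deterministic(self, scene):
        a = render_condition(scene, "mirror")
        b = render_condition(scene, "mirror")
        assert np.array_equal(a.left, b.left) and np.array_equal(a.right, b.right)

    def test_unknown_condition_rejected(self, scene):
        with pytest.raises(ValueError):
            render_condition(scene, "shiny")

    def test_eyes_must_be_distinct(self):
        with pytest.raises(ValueError):
            Scene(potato=make_potato(seed=1), env=make_envmap("gradient"),
                  interocular_mm=0.0)


class TestMonocularPair:
    @pytest.fixture(scope="class")
    def layers(self, scene):
        return render_layers(scene)

    def test_zero_rotation_identity(self, layers):
        glossy, matte = make_monocular_pair(layers, rotation_deg=0.0)
        assert np.array_equal(glossy, matte)

    def test_rotation_changes_only_inside_silhouette(self, layers):
        glossy, matte = make_monocular_pair(layers, rotation_deg=45.0)
        diff = np.abs(glossy - matte).sum(axis=2)
        assert diff[~layers.silhouette].max() == 0.0
        assert diff[layers.silhouette].max() > 0.0

    def test_full_turn_within_one_gray_level(self, layers):
        glossy, matte = make_monocular_pair(layers, rotation_deg=360.0)
        assert np.abs(glossy - matte).max() < 1.0 / 255.0


@pytest.mark.parametrize("kind", ENVMAP_KINDS)
def test_envmap_lookup_defined_for_every_direction(kind):
    env = make_envmap(kind, seed=4)
    dirs = np.random.default_rng(1).standard_normal((500, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    vals = env.sample(dirs)
    assert np.isfinite(vals).all()
    assert vals.min() >= 0.0 and vals.max() <= 1.0
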