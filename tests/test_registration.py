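"""Affine transforms, resampling and SSD registration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qmap import (
    AffineTransform,
    TemplateSpace,
    apply_transform,
    compose,
    estimate_affine,
    invert,
    normalize_subject,
    smooth,
)

angles = st.floats(-1.3, 1.3)
small = st.floats(-0.3, 0.3)
zooms = st.floats(0.5, 2.0)


@st.composite
def transforms(draw):
    return AffineTransform(
        translation=(draw(small) * 50, draw(small) * 50, draw(small) * 50),
        rotation=(draw(angles), draw(angles), draw(angles)),
        zoom=(draw(zooms), draw(zooms), draw(zooms)),
        shear=(draw(small), draw(small), draw(small)),
    )


class TestAffineTransform:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(t=transforms())
    def test_params_matrix_round_trip(self, t):
        back = AffineTransform.from_matrix(t.matrix)
        assert np.allclose(back.matrix, t.matrix, atol=1e-9)
        assert np.allclose(back.translation, t.translation, atol=1e-9)
        assert np.allclose(back.zoom, t.zoom, atol=1e-9)
        assert np.allclose(back.shear, t.shear, atol=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(t=transforms())
    def test_invert_composes_to_identity(self, t):
        eye = compose(invert(t), t)
        assert np.allclose(eye.matrix, np.eye(4), atol=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=transforms(), b=transforms(), x=st.tuples(small, small, small))
    def test_compose_is_function_composition(self, a, b, x):
        p = np.asarray(x) * 100.0
        lhs = compose(a, b).apply_points(p[None])[0]
        rhs = a.apply_points(b.apply_points(p[None]))[0]
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_invert_identity_is_identity(self):
        assert np.allclose(invert(AffineTransform.identity()).matrix, np.eye(4))

    def test_zero_zoom_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform(zoom=(0.0, 1.0, 1.0))

    def test_singular_matrix_rejected(self):
        m = np.eye(4)
        m[0, 0] = 0.0
        with pytest.raises(ValueError):
            AffineTransform.from_matrix(m)

    def test_json_round_trip_exact(self, tmp_path):
        t = AffineTransform((1.5, -2.0, 3.25), (0.1, -0.2, 0.05), (1.1, 0.9, 1.0), (0.02, 0.0, -0.01))
        t.to_json(tmp_path / "t.json")
        back = AffineTransform.from_json(tmp_path / "t.json")
        assert back == t


class TestApplyTransform:
    @pytest.fixture
    def target(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(1.0, 2.0, size=(12, 14, 10))
        return TemplateSpace(data=data, affine=np.diag([2.0, 2.0, 2.0, 1.0]))

    def test_identity_nearest_is_bit_identical(self, target):
        out = apply_transform(
            target.data, target.affine, AffineTransform.identity(), target, "nearest"
        )
        assert np.array_equal(out, target.data)

    def test_identity_trilinear_within_float_tolerance(self, target):
        out = apply_transform(target.data, target.affine, AffineTransform.identity(), target)
        assert np.allclose(out, target.data, atol=1e-12)

    def test_translate_there_and_back_restores_interior(self, target):
        fwd = AffineTransform(translation=(2.0, 0.0, 0.0))  # +1 voxel at 2 mm
        bwd = AffineTransform(translation=(-2.0, 0.0, 0.0))
        vol = (target.data * 100).astype(np.int32)
        there = apply_transform(vol, target.affine, fwd, target, "nearest")
        back = apply_transform(there, target.affine, bwd, target, "nearest")
        assert np.array_equal(back[1:-1], vol[1:-1])

    def test_constant_volume_stays_constant_in_field(self, target):
        vol = np.full(target.shape, 4.2)
        t = AffineTransform((1.0, -1.5, 0.5), (0.05, 0.02, -0.03), (1.02, 0.98, 1.0), (0.01, 0.0, 0.0))
        out = apply_transform(vol, target.affine, t, target)
        in_field = np.isfinite(out)
        assert in_field.any()
        assert np.allclose(out[in_field], 4.2, rtol=1e-12)

    def test_out_of_field_is_nan_for_floats(self, target):
        t = AffineTransform(translation=(1000.0, 0.0, 0.0))
        out = apply_transform(target.data, target.affine, t, target)
        assert np.isnan(out).all()

    def test_labels_nearest_no_novel_values(self, target):
        labels = (target.data > 1.5).astype(np.int16) * 3
        t = AffineTransform((3.0, -2.0, 1.0), (0.1, 0.0, -0.05), (1.05, 0.95, 1.0))
        out = apply_transform(labels, target.affine, t, target, "nearest")
        assert set(np.unique(out)) <= set(np.unique(labels)) | {0}
        assert out.dtype == labels.dtype

    def test_unknown_interpolation_rejected(self, target):
        with pytest.raises(ValueError):
            apply_transform(target.data, target.affine, AffineTransform.identity(), target, "cubic")


class TestEstimateAffine:
    def test_source_equals_template_gives_identity(self, template):
        tpl_s = smooth(template.data, 8.0, template.voxel_sizes)
        est = estimate_affine(tpl_s, template.affine, tpl_s, template.affine)
        assert np.allclose(est.translation, 0.0, atol=1e-3)
        assert np.allclose(est.rotation, 0.0, atol=1e-3)
        assert np.allclose(est.zoom, 1.0, atol=1e-3)
        assert np.allclose(est.shear, 0.0, atol=1e-3)

    def test_integer_voxel_translation_recovered(self, template):
        tpl_s = smooth(template.data, 8.0, template.voxel_sizes)
        t = AffineTransform(translation=(4.0, -2.0, 2.0))  # whole voxels at 2 mm
        src = np.nan_to_num(apply_transform(tpl_s, template.affine, t, template), nan=0.0)
        est = estimate_affine(src, template.affine, tpl_s, template.affine)
        # recovered translation is the inverse shift, within 0.25 voxel
        assert np.allclose(est.translation, (-4.0, 2.0, -2.0), atol=0.5)

    def test_known_transform_recovered(self, template):
        tpl_s = smooth(template.data, 8.0, template.voxel_sizes)
        t = AffineTransform(
            translation=(4.0, 3.0, -2.0),
            rotation=(np.deg2rad(5.0), 0.0, np.deg2rad(-3.0)),
            zoom=(1.05, 1.0, 0.98),
        )
        src = np.nan_to_num(apply_transform(tpl_s, template.affine, t, template), nan=0.0)
        est = estimate_affine(src, template.affine, tpl_s, template.affine)
        brain = template.data > 0
        idx = np.argwhere(brain).T.astype(float)
        world = template.affine[:3, :3] @ idx + template.affine[:3, 3:4]
        wh = np.vstack([world, np.ones(world.shape[1])])
        disp = ((t.matrix @ est.matrix) @ wh)[:3] - world
        assert np.linalg.norm(disp, axis=0).mean() <= 1.0  # mm, half a voxel

    def test_constant_image_rejected(self, template):
        with pytest.raises(ValueError):
            estimate_affine(
                np.ones_like(template.data), template.affine, template.data, template.affine
            )


class TestNormalizeSubject:
    def test_subject_already_in_template_space(self, template, canonical_spec):
        from qmap import make_phantom

        _, maps = make_phantom(canonical_spec, seed=3, tissue_variation=False)
        normalized, transform = normalize_subject(maps, template)
        assert np.allclose(transform.matrix, np.eye(4), atol=0.05)
        both = normalized.valid & maps.valid
        assert both.sum() > 0.9 * maps.valid.sum()
        assert np.nanmean(np.abs(normalized.r1 - maps.r1)[both]) < 0.02

    def test_jittered_subject_recovers_canonical_anatomy(self, template, canonical_spec):
        from scipy import ndimage

        from qmap import make_phantom

        jit = AffineTransform(
            translation=(4.0, -3.0, 2.0),
            rotation=(np.deg2rad(4.0), np.deg2rad(-3.0), np.deg2rad(5.0)),
            zoom=(1.06, 0.95, 1.03),
            shear=(0.03, -0.02, 0.02),
        )
        _, subj = make_phantom(canonical_spec, seed=5, jitter=jit, tissue_variation=False)
        _, canon = make_phantom(canonical_spec, seed=5, tissue_variation=False)
        normalized, transform = normalize_subject(subj, template)
        assert np.allclose(transform.matrix, invert(jit).matrix, atol=0.05)
        interior = ndimage.binary_erosion(canon.valid, iterations=2) & normalized.valid
        mean_abs = np.nanmean(np.abs(normalized.r1 - canon.r1)[interior])
        # below 5% of the WM-CSF R1 contrast (1.38 - 0.38 = 1.0 s^-1)
        assert mean_abs < 0.05

    def test_deterministic(self, template, canonical_spec):
        from qmap import make_phantom

        jit = AffineTransform(translation=(3.0, 1.0, -2.0), rotation=(0.03, -0.02, 0.04))
        _, subj = make_phantom(canonical_spec, seed=9, jitter=jit, tissue_variation=False)
        _, t1 = normalize_subject(subj, template)
        _, t2 = normalize_subject(subj, template)
        assert np.array_equal(t1.matrix, t2.matrix)
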