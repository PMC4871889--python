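"""Groupwise template construction and modality transport."""

import warnings

import numpy as np
import pytest

from chronoatlas.grids import ImageVolume
from chronoatlas.metrics import ncc_metric
from chronoatlas.phantoms import SyntheticCohortSpec, make_cohort, phantom_scheme
from chronoatlas.resample import resample_intensity
from chronoatlas.template import (
    build_symmetric_template,
    build_template,
    transport_modalities,
)
from chronoatlas.fusion import flip_labels_lr, majority_vote
from chronoatlas.transforms import CompositeTransform
from chronoatlas.validation import dice_coefficient

from conftest import random_diffeo_pair


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="module")
def small_cohort():
    spec = SyntheticCohortSpec(n_subjects=4, size=96, amplitude=2.0, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_cohort(spec)


class TestBuildTemplate:
    def test_single_subject_reproduces_subject(self, phantom64):
        img, _, _ = phantom64
        res = build_template([img], iterations=2)
        assert ncc_metric(res.template, img) >= 0.999

    def test_two_mirrored_deformations_center_the_template(self, phantom64):
        """Two subjects deformed by opposite warps: the template's anatomy
        sits at the midpoint (= undeformed phantom) to sub-voxel accuracy."""
        img, lab, _ = phantom64
        fwd, inv = random_diffeo_pair(img.shape, 2.5, 5.0, np.random.default_rng(4))
        plus = resample_intensity(img, CompositeTransform.from_displacement(fwd), img.grid)
        minus = resample_intensity(img, CompositeTransform.from_displacement(inv), img.grid)
        res = build_template([plus, minus], iterations=3)

        def centroid(image):
            w = np.clip(image.data, 0, None)
            g = image.grid.voxel_centers()
            return (w[..., None] * g).sum(axis=(0, 1)) / w.sum()

        assert np.linalg.norm(centroid(res.template) - centroid(img)) <= 0.5
        # structure also matches the midpoint anatomy closely
        assert ncc_metric(res.template, img) >= 0.97

    def test_displacement_decreases_from_off_center_init(self, small_cohort):
        """Initializing from one subject, the norm of the mean displacement
        field falls as the template drifts to the group-mean shape, and the
        per-subject displacement magnitude plateaus."""
        _, subjects = small_cohort
        res = build_template(
            [s.image for s in subjects], init=subjects[0].image, iterations=4
        )
        mean_field = [d["mean_field_norm"] for d in res.diagnostics]
        assert mean_field[-1] <= mean_field[0]
        # group-mean property: the final mean field is small
        assert mean_field[-1] <= 0.5
        disp = [d["mean_disp"] for d in res.diagnostics]
        assert disp[-1] <= disp[0] * 1.05

    def test_sharpness_does_not_decrease(self, small_cohort):
        _, subjects = small_cohort
        res = build_template(
            [s.image for s in subjects], init=subjects[0].image, iterations=4
        )
        sharp = [d["sharpness"] for d in res.diagnostics]
        assert sharp[-1] >= sharp[0] * 0.98

    def test_deterministic_under_identical_inputs(self, phantom64):
        img, _, _ = phantom64
        fwd, _ = random_diffeo_pair(img.shape, 1.5, 4.0, np.random.default_rng(2))
        other = resample_intensity(img, CompositeTransform.from_displacement(fwd), img.grid)
        r1 = build_template([img, other], iterations=2)
        r2 = build_template([img, other], iterations=2)
        assert np.array_equal(r1.template.data, r2.template.data)

    def test_grid_mismatch_rejected(self, phantom64):
        img, _, _ = phantom64
        other = ImageVolume(np.zeros((32, 32)))
        with pytest.raises(ValueError, match="share a grid"):
            build_template([img, other], iterations=1)


class TestSymmetricTemplate:
    def test_mirror_symmetric_input_gives_symmetric_template(self, phantom64):
        img, _, _ = phantom64
        res = build_symmetric_template([img], iterations=2)
        mirrored = np.flip(res.template.data, axis=0)
        assert ncc_metric(res.template.data, mirrored) >= 0.999

    def test_two_n_transforms_returned(self, small_cohort):
        _, subjects = small_cohort
        res = build_symmetric_template([s.image for s in subjects[:2]], iterations=1)
        assert len(res.per_subject) == 4

    def test_symmetric_more_mirror_similar_than_asymmetric(self):
        spec = SyntheticCohortSpec(
            n_subjects=3, size=96, amplitude=2.0, seed=9,
            laterality={"thalamus": 1.8, "putamen": 1.8, "caudate": 1.8, "hippocampus": 1.8},
        )
        _, subjects = make_cohort(spec)
        imgs = [s.image for s in subjects]
        asym = build_template(imgs, iterations=2)
        sym = build_symmetric_template(imgs, iterations=2)

        def mirror_ncc(t):
            return ncc_metric(t.template.data, np.flip(t.template.data, axis=0))

        assert mirror_ncc(sym) >= mirror_ncc(asym)


class TestTransportModalities:
    def test_own_image_matches_build_warp(self, small_cohort):
        _, subjects = small_cohort
        imgs = [s.image for s in subjects]
        res = build_template(imgs, iterations=1)
        transported = transport_modalities(imgs, res)
        for t, reg in zip(transported, res.per_subject):
            assert np.allclose(t.data, reg.warped_moving.data, atol=1e-9)

    def test_probabilities_renormalized(self, small_cohort):
        _, subjects = small_cohort
        imgs = [s.image for s in subjects[:2]]
        res = build_template(imgs, iterations=1)
        rng = np.random.default_rng(0)
        prob_maps = []
        for img in imgs:
            raw = rng.random((3,) + img.shape)
            raw /= raw.sum(axis=0)
            prob_maps.append([ImageVolume(raw[c]) for c in range(3)])
        out = transport_modalities(prob_maps, res)
        for maps in out:
            total = sum(m.data for m in maps)
            in_support = total > 0.5
            assert np.allclose(total[in_support], 1.0, atol=1e-6)

    def test_count_mismatch_rejected(self, small_cohort):
        _, subjects = small_cohort
        res = build_template([s.image for s in subjects[:2]], iterations=1)
        with pytest.raises(ValueError, match="transforms"):
            transport_modalities([subjects[0].labels], res)

    def test_fused_true_labels_recover_phantom(self, small_cohort):
        """True label maps transported to template space and fused recover
        the phantom's parcellation."""
        (pimg, plab, _), subjects = small_cohort
        imgs = [s.image for s in subjects]
        res = build_template(imgs, init=pimg, iterations=2)
        warped = transport_modalities([s.labels for s in subjects], res)
        fused = majority_vote(warped)
        dices = []
        for lid in plab.labels():
            d = dice_coefficient(fused, plab, int(lid))
            if d is not None:
                dices.append(d)
        assert np.mean(dices) >= 0.85
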