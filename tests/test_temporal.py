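"""Temporal chain construction, label propagation and per-step CC."""

import warnings

import numpy as np
import pytest

from chronoatlas.phantoms import (
    AgingSequenceSpec,
    make_aging_sequence,
    make_phantom,
)
from chronoatlas.resample import resample_labels
from chronoatlas.temporal import (
    TemporalSequence,
    build_temporal_chain,
    evaluate_chain_cc,
    propagate_atlas_labels,
)
from chronoatlas.transforms import CompositeTransform, concat_chain
from chronoatlas.validation import dice_coefficient


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


class TestSequenceValidation:
    def test_single_template_allowed_but_not_chainable(self, phantom64):
        img, _, _ = phantom64
        seq = TemporalSequence(templates=[img], ages=[1.0])
        with pytest.raises(ValueError, match="at least 2"):
            build_temporal_chain(None, seq, None)

    def test_ages_strictly_decreasing(self, phantom64):
        img, _, _ = phantom64
        with pytest.raises(ValueError, match="decreasing"):
            TemporalSequence(templates=[img, img], ages=[1.0, 2.0])


class TestBuildChain:
    def test_identical_templates_give_near_identity_chain(self, phantom64):
        img, _, _ = phantom64
        seq = TemporalSequence(templates=[img, img, img], ages=[2.0, 1.0, 0.0])
        chain = build_temporal_chain(None, seq, None)
        pts = img.grid.voxel_centers().reshape(-1, 2)
        disp = np.linalg.norm(chain.apply(pts) - pts, axis=1).reshape(img.shape)
        assert np.max(disp[4:-4, 4:-4]) <= 0.2

    def test_chain_endpoint_matches_known_truth(self):
        """3-stage ladder with known inter-stage warps: the composed chain
        lands within a voxel of the composed ground truth (median over the
        head, across fixed seeds)."""
        medians = []
        for seed in (0, 1, 2):
            spec = AgingSequenceSpec(
                n_stages=3, size=96, scales=[1.0, 0.95, 0.9],
                wm_intensities=[0.85, 0.75, 0.65], seed=seed,
            )
            seq, truths = make_aging_sequence(spec)
            chain = build_temporal_chain(None, seq, None)
            pts = seq.templates[-1].grid.voxel_centers().reshape(-1, 2)
            truth = pts
            for k in (1, 0):
                truth = truths[k].apply(truth)
            err = np.linalg.norm(chain.apply(pts) - truth, axis=1)
            _, lab, _ = make_phantom(size=96, seed=seed, scale=0.9)
            medians.append(np.median(err[(lab.data > 0).reshape(-1)]))
        assert np.median(medians) <= 1.0

    def test_two_stage_chain_consistent_with_direct_registration(self):
        """Chaining through an intermediate stage agrees with registering
        end to end directly, on a mild deformation."""
        from chronoatlas.registration import affine_register, diffeo_register

        spec = AgingSequenceSpec(
            n_stages=3, size=96, scales=[1.0, 0.97, 0.94],
            wm_intensities=[0.85, 0.8, 0.75], seed=4, deformation_amplitude=0.5,
        )
        seq, _ = make_aging_sequence(spec)
        chain = build_temporal_chain(None, seq, None)
        aff = affine_register(seq.templates[-1], seq.templates[0], metric="nmi")
        cfg = None
        from chronoatlas.registration import RegistrationConfig

        cfg = RegistrationConfig(metric="nmi")
        direct = diffeo_register(seq.templates[-1], seq.templates[0], config=cfg, init=aff)
        pts = seq.templates[-1].grid.voxel_centers().reshape(-1, 2)
        gap = np.linalg.norm(chain.apply(pts) - direct.forward.apply(pts), axis=1)
        _, lab, _ = make_phantom(size=96, seed=4, scale=0.94)
        assert np.median(gap[(lab.data > 0).reshape(-1)]) <= 1.0


class TestPropagateLabels:
    def test_identity_chain_keeps_labels(self, phantom64):
        _, lab, _ = phantom64
        chain = concat_chain([CompositeTransform.identity(2, source="atlas")])
        out = propagate_atlas_labels(lab, chain, lab.grid)
        assert np.array_equal(out.data, lab.data)

    def test_no_new_label_ids(self, phantom64):
        img, lab, _ = phantom64
        seq = TemporalSequence(templates=[img, img], ages=[1.0, 0.0])
        chain = build_temporal_chain(img, seq, None)
        out = resample_labels(lab, chain, lab.grid)
        assert set(np.unique(out.data)) <= set(np.unique(lab.data)) | {0}

    def test_single_pass_equals_sequential_coordinate_mapping(self):
        """Transporting through the composed chain equals mapping each voxel
        coordinate link by link and sampling once."""
        rng = np.random.default_rng(6)
        from conftest import random_diffeo_pair

        _, lab, _ = make_phantom(size=48, seed=1)
        links = []
        for seed in range(3):
            fwd, _ = random_diffeo_pair((48, 48), 1.5, 4.0, np.random.default_rng(seed))
            links.append(CompositeTransform.from_displacement(fwd))
        chain = concat_chain(links)
        transported = resample_labels(lab, chain, lab.grid)
        pts = lab.grid.voxel_centers().reshape(-1, 2)
        for link in links:
            pts = link.apply(pts)
        idx = np.ceil(lab.grid.world_to_index(pts) - 0.5).astype(int)
        inside = np.all((idx >= 0) & (idx < 48), axis=1)
        oracle = np.zeros(len(idx), dtype=lab.data.dtype)
        oracle[inside] = lab.data[tuple(idx[inside].T)]
        assert np.array_equal(transported.data.reshape(-1), oracle)

    def test_dice_degrades_with_deformation_amplitude(self):
        """Label transport quality is monotone in the stage-to-stage
        deformation amplitude (clearly separated amplitudes)."""
        dices = []
        for amp in (0.5, 4.0):
            spec = AgingSequenceSpec(n_stages=3, size=96, seed=2, deformation_amplitude=amp)
            seq, truths = make_aging_sequence(spec)
            chain = build_temporal_chain(None, seq, None)
            _, lab_old, _ = make_phantom(size=96, seed=2, scale=float(spec.scales[0]))
            # truth labels in youngest space via the composed true chain
            true_lab = lab_old
            prop = resample_labels(lab_old, chain, seq.templates[-1].grid)
            truth_chain_pts = seq.templates[-1].grid.voxel_centers().reshape(-1, 2)
            pts = truth_chain_pts
            for k in (1, 0):
                pts = truths[k].apply(pts)
            idx = np.ceil(lab_old.grid.world_to_index(pts) - 0.5).astype(int)
            inside = np.all((idx >= 0) & (idx < 96), axis=1)
            truth = np.zeros(len(idx), dtype=lab_old.data.dtype)
            truth[inside] = lab_old.data[tuple(idx[inside].T)]
            truth = truth.reshape(96, 96)
            vals = []
            for lid in np.unique(truth):
                if lid == 0:
                    continue
                from chronoatlas.grids import LabelMap

                d = dice_coefficient(prop, LabelMap(truth), int(lid))
                if d is not None:
                    vals.append(d)
            dices.append(np.mean(vals))
        assert dices[1] <= dices[0]
        assert dices[0] >= 0.80


class TestEvaluateChainCc:
    def test_identical_templates_all_ones(self, phantom64):
        img, _, _ = phantom64
        seq = TemporalSequence(templates=[img, img, img], ages=[2.0, 1.0, 0.0])
        chain = build_temporal_chain(None, seq, None)
        res = evaluate_chain_cc(seq, chain)
        assert all(v >= 0.999 for v in res["ncc"])

    def test_registered_beats_identity_links(self):
        spec = AgingSequenceSpec(n_stages=3, size=96, seed=5)
        seq, _ = make_aging_sequence(spec)
        chain = build_temporal_chain(None, seq, None)
        registered = evaluate_chain_cc(seq, chain)
        identity_links = [
            CompositeTransform.identity(2, target=f"stage{i + 1}", source=f"stage{i}")
            for i in reversed(range(len(seq) - 1))
        ]
        unregistered = evaluate_chain_cc(seq, concat_chain(identity_links))
        for reg, unreg in zip(registered["ncc"], unregistered["ncc"]):
            assert reg >= unreg
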