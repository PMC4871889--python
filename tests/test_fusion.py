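"""Majority voting, left-right flipping, asymmetry coefficient, volumetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronoatlas.fusion import (
    asymmetry_coefficient,
    asymmetry_report,
    flip_labels_lr,
    icv_proportions,
    majority_vote,
    region_volumes,
)
from chronoatlas.grids import LabelMap, LabelScheme, SchemeEntry
from chronoatlas.phantoms import make_phantom, phantom_scheme


def _vote_oracle(stack: np.ndarray) -> np.ndarray:
    """Exhaustive per-voxel counting with smallest-ID tie-break."""
    out = np.zeros(stack.shape[1:], dtype=stack.dtype)
    for idx in np.ndindex(*stack.shape[1:]):
        votes = stack[(slice(None),) + idx]
        ids, counts = np.unique(votes, return_counts=True)
        out[idx] = ids[np.argmax(counts)]  # unique sorts ids; argmax takes first max
    return out


class TestMajorityVote:
    def test_identical_maps(self):
        lab = LabelMap(np.random.default_rng(0).integers(0, 5, (12, 12)))
        assert np.array_equal(majority_vote([lab] * 3).data, lab.data)

    def test_simple_majority(self):
        maps = [LabelMap(np.full((4, 4), v)) for v in (5, 5, 7)]
        assert np.all(majority_vote(maps).data == 5)

    @pytest.mark.parametrize("n_maps,seed", [(2, 0), (3, 1), (5, 2), (7, 3)])
    def test_matches_counting_oracle_including_ties(self, n_maps, seed):
        rng = np.random.default_rng(seed)
        stack = rng.integers(0, 4, (n_maps, 16, 16)).astype(np.int32)
        maps = [LabelMap(s) for s in stack]
        assert np.array_equal(majority_vote(maps).data, _vote_oracle(stack))

    def test_grid_mismatch_rejected(self):
        a = LabelMap(np.zeros((8, 8), dtype=int))
        b = LabelMap(np.zeros((8, 8), dtype=int), spacing=(2.0, 2.0))
        with pytest.raises(ValueError, match="grid"):
            majority_vote([a, b])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestFlipLabels:
    def test_double_flip_is_identity(self):
        _, lab, _ = make_phantom(size=64, laterality={"thalamus": 1.6}, seed=1)
        scheme = phantom_scheme()
        twice = flip_labels_lr(flip_labels_lr(lab, scheme), scheme)
        assert np.array_equal(twice.data, lab.data)

    def test_symmetric_midline_structure_unchanged(self):
        data = np.zeros((16, 16), dtype=np.int32)
        data[6:10, 4:12] = 91  # symmetric about the even-size mirror axis
        scheme = LabelScheme({91: SchemeEntry("corpus callosum", "none")})
        lab = LabelMap(data)
        assert np.array_equal(flip_labels_lr(lab, scheme).data, data)

    def test_voxel_count_exchange(self):
        _, lab, _ = make_phantom(
            size=64, laterality={"thalamus": 1.7, "caudate": 1.3}, seed=2
        )
        scheme = phantom_scheme()
        flipped = flip_labels_lr(lab, scheme)
        for left_id, right_id in scheme.pairs():
            assert np.sum(lab.data == left_id) == np.sum(flipped.data == right_id)
            assert np.sum(lab.data == right_id) == np.sum(flipped.data == left_id)

    def test_hemispheric_id_without_partner_rejected(self):
        data = np.full((8, 8), 5, dtype=np.int32)
        scheme = LabelScheme({5: SchemeEntry("orphan left", "left", None)})
        with pytest.raises(ValueError, match="5"):
            flip_labels_lr(LabelMap(data), scheme)


class TestAsymmetryCoefficient:
    def test_equal_volumes_give_zero(self):
        assert asymmetry_coefficient(1.23, 1.23) == 0.0

    def test_one_side_absent_gives_two(self):
        assert asymmetry_coefficient(0.5, 0.0) == 2.0

    def test_amygdala_worked_value(self):
        # mean amygdala volumes 0.76 / 0.65 cm^3 -> S = 2*0.11/1.41
        assert asymmetry_coefficient(0.76, 0.65) == pytest.approx(0.15603, abs=5e-6)

    def test_both_zero_is_missing(self):
        assert asymmetry_coefficient(0.0, 0.0) is None

    @given(
        v=st.floats(0.01, 100.0),
        w=st.floats(0.01, 100.0),
        k=st.floats(0.01, 1000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, v, w, k):
        assert asymmetry_coefficient(k * v, k * w) == pytest.approx(
            asymmetry_coefficient(v, w), rel=1e-9
        )


class TestRegionVolumes:
    def test_block_volume(self):
        data = np.zeros((20, 20, 20), dtype=np.int32)
        data[:10, :10, :10] = 4
        table = region_volumes(LabelMap(data))  # 1 mm spacing
        assert table[4] == pytest.approx(1.0)  # 1000 mm^3 = 1 cm^3

    def test_conservation(self):
        rng = np.random.default_rng(1)
        lab = LabelMap(rng.integers(0, 6, (15, 15)), spacing=(2.0, 0.5))
        table = region_volumes(lab, include_background=True)
        assert sum(table.volumes.values()) == pytest.approx(table.total_volume_cm3)

    def test_matches_brute_force_counts(self):
        rng = np.random.default_rng(2)
        lab = LabelMap(rng.integers(0, 4, (10, 12)), spacing=(1.5, 2.0))
        table = region_volumes(lab)
        for lid in (1, 2, 3):
            count = int(np.sum(lab.data == lid))
            assert table[lid] == pytest.approx(count * 3.0 / 1000.0)


class TestIcvProportions:
    def _scheme(self):
        return LabelScheme(
            {
                1: SchemeEntry("a", "none", None, "front"),
                2: SchemeEntry("b", "none", None, "back"),
                3: SchemeEntry("c", "none", None, "mid"),
            }
        )

    def test_single_lobe_covering_mask_is_100(self):
        data = np.ones((10, 10), dtype=np.int32)
        mask = LabelMap(np.ones((10, 10), dtype=np.int32))
        scheme = LabelScheme({1: SchemeEntry("a", "none", None, "front")})
        out = icv_proportions(LabelMap(data), mask, scheme)
        assert out["front"] == pytest.approx(100.0)

    def test_sum_at_most_100(self):
        rng = np.random.default_rng(3)
        lab = LabelMap(rng.integers(0, 4, (20, 20)))
        mask = LabelMap((rng.random((20, 20)) > 0.3).astype(np.int32))
        out = icv_proportions(lab, mask, self._scheme())
        assert sum(out.values()) <= 100.0 + 1e-9

    def test_toy_hand_count(self):
        data = np.zeros((4, 4), dtype=np.int32)
        data[0, :] = 1  # 4 voxels
        data[1, :2] = 2  # 2 voxels
        data[2, 0] = 3  # 1 voxel
        mask = LabelMap(np.ones((4, 4), dtype=np.int32))  # 16 voxels
        out = icv_proportions(LabelMap(data), mask, self._scheme())
        assert out == {
            "front": pytest.approx(25.0),
            "back": pytest.approx(12.5),
            "mid": pytest.approx(6.25),
        }

    def test_empty_mask_rejected(self):
        lab = LabelMap(np.ones((4, 4), dtype=np.int32))
        with pytest.raises(ValueError, match="empty"):
            icv_proportions(lab, LabelMap(np.zeros((4, 4), dtype=np.int32)), self._scheme())


class TestAsymmetryReport:
    def test_mirror_symmetric_map_all_zero(self):
        _, lab, _ = make_phantom(size=64, laterality=1.0, seed=0)
        rep = asymmetry_report(lab, phantom_scheme())
        assert rep.max_s() == 0.0

    def test_two_to_one_pair(self):
        data = np.zeros((10, 10), dtype=np.int32)
        data[:4, :5] = 1  # 20 voxels "left"
        data[:2, 5:] = 2  # 10 voxels "right"
        scheme = LabelScheme(
            {
                1: SchemeEntry("blob left", "left", 2),
                2: SchemeEntry("blob right", "right", 1),
            }
        )
        rep = asymmetry_report(LabelMap(data), scheme)
        assert rep.rows[0]["S"] == pytest.approx(2.0 / 3.0)

    def test_matches_manual_per_pair_computation(self):
        _, lab, _ = make_phantom(
            size=64, laterality={"thalamus": 1.4, "hippocampus": 0.8}, seed=3
        )
        scheme = phantom_scheme()
        rep = asymmetry_report(lab, scheme)
        for row in rep.rows:
            v_l = np.sum(lab.data == row["left_id"]) / 1000.0
            v_r = np.sum(lab.data == row["right_id"]) / 1000.0
            expected = 2 * abs(v_l - v_r) / (v_l + v_r)
            assert row["S"] == pytest.approx(expected, abs=1e-12)
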