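"""Schedule generators: freezing, loss weights, curriculum, batching."""

import numpy as np
import pandas as pd
import pytest
from importlib import resources

from dermprio import (
    BackboneSpec,
    CurriculumSpec,
    HierarchySpec,
    LossWeightSchedule,
    THREE_LEVEL_SCHEDULE,
    TWO_LEVEL_SCHEDULE,
    bcnn_loss_weights,
    curriculum_order,
    curriculum_schedule,
    frozen_block_schedule,
    fuse_metadata,
    hierarchical_loss,
    stratified_batches,
)
from dermprio.taxonomy import DEFAULT_TAXONOMY


def _backbone(n=7):
    return BackboneSpec(blocks=tuple(f"block{i+1}" for i in range(n)), feature_dim=32)


class TestFrozenBlockSchedule:
    def test_priority_branch_config_starts_with_last_three_blocks(self):
        states = frozen_block_schedule(_backbone(7), cycles=6, initial_unfrozen=3)
        assert states[0].trainable_blocks == ("block5", "block6", "block7")
        assert states[0].learning_rates["head"] == pytest.approx(1e-4)
        assert states[0].learning_rates["block7"] == pytest.approx(1e-5)

    def test_single_cycle_is_three_epochs(self):
        states = frozen_block_schedule(_backbone(4), cycles=1)
        assert len(states) == 3
        assert all(s.phase == 0 for s in states)

    @pytest.mark.parametrize("cycles", [1, 3, 5])
    def test_total_epochs_closed_form(self, cycles):
        assert len(frozen_block_schedule(_backbone(6), cycles=cycles)) == 3 * cycles

    def test_unfreezing_grows_one_block_per_phase(self):
        states = frozen_block_schedule(_backbone(5), cycles=4)
        per_phase = {s.phase: s.trainable_blocks for s in states}
        assert [len(v) for v in per_phase.values()] == [1, 2, 3, 4]
        for k in range(3):
            assert set(per_phase[k]) <= set(per_phase[k + 1])

    def test_cycles_beyond_blocks_rejected(self):
        with pytest.raises(ValueError, match="cannot exceed"):
            frozen_block_schedule(_backbone(3), cycles=4)


class TestLossWeights:
    @pytest.mark.parametrize(
        "schedule,epoch,expected",
        [
            (TWO_LEVEL_SCHEDULE, 0, (0.98, 0.02)),
            (TWO_LEVEL_SCHEDULE, 5, (0.98, 0.02)),
            (TWO_LEVEL_SCHEDULE, 6, (0.3, 0.7)),
            (TWO_LEVEL_SCHEDULE, 12, (0.1, 0.9)),
            (TWO_LEVEL_SCHEDULE, 25, (0.0, 1.0)),
            (THREE_LEVEL_SCHEDULE, 0, (0.97, 0.02, 0.01)),
            (THREE_LEVEL_SCHEDULE, 7, (0.1, 0.8, 0.1)),
            (THREE_LEVEL_SCHEDULE, 12, (0.1, 0.2, 0.7)),
            (THREE_LEVEL_SCHEDULE, 18, (0.0, 0.0, 1.0)),
        ],
    )
    def test_packaged_handover_schedules(self, schedule, epoch, expected):
        assert bcnn_loss_weights(schedule, epoch) == expected

    def test_every_epoch_sums_to_one(self):
        for schedule in (TWO_LEVEL_SCHEDULE, THREE_LEVEL_SCHEDULE):
            for epoch in range(31):
                assert sum(bcnn_loss_weights(schedule, epoch)) == pytest.approx(1.0)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            bcnn_loss_weights(TWO_LEVEL_SCHEDULE, -1)

    def test_non_stochastic_vector_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            LossWeightSchedule(entries=((0, (0.5, 0.4)),))

    def test_hierarchical_loss_is_dot_product(self, rng):
        assert hierarchical_loss([5.0, 2.0], [0.0, 1.0]) == 2.0
        assert hierarchical_loss([2.0, 4.0], [0.5, 0.5]) == 3.0
        losses = rng.random(3)
        weights = rng.dirichlet(np.ones(3))
        assert hierarchical_loss(losses, weights) == pytest.approx(
            sum(l * w for l, w in zip(losses, weights))
        )
        with pytest.raises(ValueError):
            hierarchical_loss([1.0], [0.5, 0.5])


class TestCurriculumOrder:
    def test_flat_reference_f1_order(self):
        with resources.files("dermprio.data").joinpath("flat_f1_reference.csv").open() as fh:
            f1 = pd.read_csv(fh).set_index("code")["f1"].to_dict()
        order = curriculum_order(f1, forced_last=["SLent"])
        assert order[:3] == ["SebKer", "ActKer", "VWart"]
        assert order[-3:] == ["OtMalNeop", "BCC", "SLent"]

    def test_uniform_scores_tie_break_alphabetical(self):
        order = curriculum_order({c: 50.0 for c in DEFAULT_TAXONOMY.codes}, forced_last=[])
        assert order == sorted(DEFAULT_TAXONOMY.codes)

    def test_forced_order_covering_all_classes(self):
        forced = list(reversed(DEFAULT_TAXONOMY.codes))
        assert curriculum_order({c: 1.0 for c in DEFAULT_TAXONOMY.codes}, forced_last=forced) == forced

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            curriculum_order({"SebKer": 50.0})


class TestCurriculumSchedule:
    def test_outer_cycles_cover_class_counts_4_to_13(self):
        spec = CurriculumSpec(ordered_classes=DEFAULT_TAXONOMY.codes)
        states = curriculum_schedule(spec, _backbone(7))
        counts = sorted({len(s.active_classes) for s in states})
        assert counts == list(range(4, 14))
        assert len(states) == 10 * 6 * 3  # 10 outer cycles x 6 phases x 3 epochs

    def test_active_classes_nested_and_monotone(self):
        spec = CurriculumSpec(ordered_classes=DEFAULT_TAXONOMY.codes)
        states = curriculum_schedule(spec, _backbone(7))
        prev = set()
        for s in states:
            current = set(s.active_classes)
            assert prev <= current or len(current) == len(prev)
            if len(current) > len(prev):
                assert prev < current
                prev = current

    def test_refreeze_resets_to_phase0_blocks(self):
        spec = CurriculumSpec(ordered_classes=DEFAULT_TAXONOMY.codes)
        states = curriculum_schedule(spec, _backbone(7))
        starts = [s for s in states if s.phase == 0]
        assert all(s.trainable_blocks == starts[0].trainable_blocks for s in starts)

    def test_final_cycle_batch_size_is_13(self):
        spec = CurriculumSpec(ordered_classes=DEFAULT_TAXONOMY.codes)
        states = curriculum_schedule(spec, _backbone(7))
        assert states[-1].batch_size == 13

    def test_order_must_be_permutation(self):
        with pytest.raises(ValueError):
            CurriculumSpec(ordered_classes=DEFAULT_TAXONOMY.codes[:5])


class TestStratifiedBatches:
    def test_thirteen_class_transversals(self, rng):
        labels = np.repeat(np.arange(13), 30)
        batches = stratified_batches(labels, samples_per_class=200, seed=5)
        assert len(batches) == 200
        for batch in batches:
            assert len(batch) == 13
            assert sorted(labels[batch]) == list(range(13))

    def test_priority_mode_four_per_class(self):
        labels = np.repeat([0, 1, 2], 50)
        batches = stratified_batches(labels, samples_per_class=200, seed=1, per_class_per_batch=4)
        assert len(batches) == 50
        for batch in batches:
            assert len(batch) == 12
            assert np.bincount(labels[batch], minlength=3).tolist() == [4, 4, 4]

    def test_rare_class_oversampled_to_quota(self):
        labels = np.array([0] * 39 + [1] * 500)
        batches = stratified_batches(labels, samples_per_class=200, seed=2)
        flat = np.concatenate(batches)
        counts = np.bincount(labels[flat])
        assert counts.tolist() == [200, 200]

    def test_deterministic_given_seed(self):
        labels = np.repeat(np.arange(5), 20)
        a = stratified_batches(labels, samples_per_class=10, seed=3)
        b = stratified_batches(labels, samples_per_class=10, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_batches(np.array([]), samples_per_class=10)


class TestMetadataFusion:
    def test_appends_two_slots(self, rng):
        features = rng.random(32)
        fused = fuse_metadata(features, age=55.84, sex="female")
        assert fused.shape == (34,)
        assert fused[-2] == pytest.approx(0.5584)
        assert fused[-1] == 0.0

    def test_zero_features_pass_metadata_through(self):
        fused = fuse_metadata(np.zeros(8), age=30.0, sex="male")
        assert fused[:8].tolist() == [0.0] * 8
        assert fused[-2:].tolist() == [0.3, 1.0]

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            fuse_metadata(np.zeros(4), age=40.0, sex="unknown")


class TestHierarchySpec:
    def test_two_level_malignant_grouping(self):
        spec = HierarchySpec.two_level_default()
        assert spec.coarse_label("UncNeop") == "malignant"
        assert spec.coarse_label("MM") == "malignant"
        assert spec.coarse_label("SebKer") == "benign"
        assert spec.n_levels == 2

    def test_three_level_loads_and_covers_all_classes(self):
        spec = HierarchySpec.three_level_default()
        assert spec.n_levels == 3
        for code in DEFAULT_TAXONOMY.codes:
            for level in range(2):
                assert spec.coarse_label(code, level) in spec.levels[level].categories

    def test_pigmentation_override_for_bcc(self):
        spec = HierarchySpec.three_level_default()
        assert spec.coarse_label("BCC", 1) == "non-pigmented"
        assert spec.coarse_label("BCC", 1, override="pigmented") == "pigmented-non-melanocytic"
        with pytest.raises(ValueError):
            spec.coarse_label("Nev", 1, override="pigmented")
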