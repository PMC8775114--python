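"""Numpy backend and trainers: gradients, freezing, recovery."""

import numpy as np
import pytest

from dermprio import (
    CurriculumSpec,
    FusionConfig,
    TWO_LEVEL_SCHEDULE,
    curriculum_schedule,
    frozen_block_schedule,
)
from dermprio.fusion import default_knowledge_map
from dermprio.nn import Adam, Dense, MultiHeadModel, Sequential, cross_entropy, make_tiny_cnn, softmax
from dermprio.schedules import HierarchySpec
from dermprio.synthetic import GeneratorConfig, generate_cases
from dermprio.taxonomy import DEFAULT_PRIORITIES, DEFAULT_TAXONOMY
from dermprio.training import (
    TrainConfig,
    predict_probs,
    train_combined,
    train_flat,
    train_hierarchical,
)


@pytest.fixture(scope="module")
def small_cohort():
    """Rendered synthetic cohort shared by the training tests."""
    cfg = GeneratorConfig(image_size=32, seed=11)
    cases = generate_cases(cfg, n_per_class=30)
    X = np.stack([c.image for c in cases])
    y_dx = np.array([DEFAULT_TAXONOMY.position(c.diagnosis) for c in cases])
    y_pr = np.array([DEFAULT_PRIORITIES.severity(c.priority) for c in cases])
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(cases))
    split = 13 * 22
    return X, y_dx, y_pr, idx[:split], idx[split:]


class TestBackend:
    def test_dense_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        layer = Dense(4, 3, rng=rng)
        x = rng.normal(size=(5, 4))
        y = rng.integers(0, 3, 5)

        def loss_value():
            return cross_entropy(softmax(layer.forward(x)), y)

        probs = softmax(layer.forward(x))
        grad = probs.copy()
        grad[np.arange(5), y] -= 1
        layer.w.grad[...] = 0
        layer.backward(grad / 5)
        eps = 1e-6
        for idx in [(0, 0), (2, 1), (3, 2)]:
            orig = layer.w.value[idx]
            layer.w.value[idx] = orig + eps
            up = loss_value()
            layer.w.value[idx] = orig - eps
            down = loss_value()
            layer.w.value[idx] = orig
            assert layer.w.grad[idx] == pytest.approx((up - down) / (2 * eps), abs=1e-6)

    def test_adam_reduces_loss_on_toy_problem(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(64, 8))
        y = (x[:, 0] > 0).astype(int)
        layer = Dense(8, 2, rng=rng)
        opt = Adam()
        first = last = None
        for _ in range(60):
            probs = softmax(layer.forward(x))
            loss = cross_entropy(probs, y)
            first = loss if first is None else first
            grad = probs.copy()
            grad[np.arange(len(y)), y] -= 1
            layer.w.grad[...] = 0
            layer.b.grad[...] = 0
            layer.backward(grad / len(y))
            opt.step([(layer.params(), 0.05)])
            last = loss
        assert last < first / 3

    def test_frozen_blocks_do_not_move(self, small_cohort):
        X, y_dx, _, tr, _ = small_cohort
        model, spec = make_tiny_cnn(seed=4)
        frozen_name = spec.blocks[0]
        before = [p.value.copy() for p in model.blocks[0].params()]
        states = frozen_block_schedule(spec, cycles=1)  # only the last block trainable
        cfg = TrainConfig(head_lr=0.01, body_lr=0.01, samples_per_class=4, seed=0)
        train_flat(model, states[:1], X[tr], y_dx[tr], cfg)
        after = [p.value for p in model.blocks[0].params()]
        assert all(np.array_equal(b, a) for b, a in zip(before, after))
        assert frozen_name not in states[0].trainable_blocks


class TestFlatAndCurriculumRecovery:
    def test_flat_scheme_recovers_separable_classes(self, small_cohort):
        X, y_dx, _, tr, te = small_cohort
        model, spec = make_tiny_cnn(seed=0)
        states = frozen_block_schedule(spec, cycles=spec.n_blocks)
        cfg = TrainConfig(head_lr=0.01, body_lr=0.003, samples_per_class=20, seed=0)
        train_flat(model, states, X[tr], y_dx[tr], cfg)
        acc = (predict_probs(model, X[te]).argmax(1) == y_dx[te]).mean()
        assert acc > 0.90

    def test_curriculum_matches_flat_within_noise(self, small_cohort):
        X, y_dx, _, tr, te = small_cohort
        # flat reference
        flat_model, spec = make_tiny_cnn(seed=1)
        flat_states = frozen_block_schedule(spec, cycles=spec.n_blocks)
        cfg = TrainConfig(head_lr=0.01, body_lr=0.003, samples_per_class=20, seed=1)
        train_flat(flat_model, flat_states, X[tr], y_dx[tr], cfg)
        flat_acc = (predict_probs(flat_model, X[te]).argmax(1) == y_dx[te]).mean()
        # curriculum with a desk-scale schedule (1 epoch/phase, 3 groups)
        cur_model, spec2 = make_tiny_cnn(seed=1)
        cur_spec = CurriculumSpec(
            ordered_classes=DEFAULT_TAXONOMY.codes, epochs_per_phase=1, blocks_per_cycle=3
        )
        cur_states = curriculum_schedule(cur_spec, spec2)
        train_flat(cur_model, cur_states, X[tr], y_dx[tr], cfg)
        cur_acc = (predict_probs(cur_model, X[te]).argmax(1) == y_dx[te]).mean()
        assert cur_acc >= flat_acc - 0.10

    def test_active_class_growth_reflected_in_history(self, small_cohort):
        X, y_dx, _, tr, _ = small_cohort
        model, spec = make_tiny_cnn(seed=3)
        cur_spec = CurriculumSpec(
            ordered_classes=DEFAULT_TAXONOMY.codes, epochs_per_phase=1, blocks_per_cycle=1
        )
        states = curriculum_schedule(cur_spec, spec)
        cfg = TrainConfig(head_lr=0.01, body_lr=0.003, samples_per_class=4, seed=0)
        history = train_flat(model, states, X[tr], y_dx[tr], cfg)
        assert [h["n_active_classes"] for h in history] == list(range(4, 14))


class TestHierarchicalTraining:
    def test_bcnn_smoke_updates_both_heads(self, small_cohort):
        X, y_dx, _, tr, _ = small_cohort
        hierarchy = HierarchySpec.two_level_default()
        coarse = np.array(
            [
                hierarchy.levels[0].categories.index(
                    hierarchy.coarse_label(DEFAULT_TAXONOMY.codes[c])
                )
                for c in y_dx[tr]
            ]
        )
        model, spec = make_tiny_cnn(seed=5, extra_heads={"coarse": (1, 2)})
        states = frozen_block_schedule(spec, cycles=1)
        before = [p.value.copy() for _, head in model.heads.values() for p in head.params()]
        cfg = TrainConfig(head_lr=0.01, body_lr=0.003, samples_per_class=4, seed=0)
        history = train_hierarchical(
            model, states[:2], X[tr], {"coarse": coarse, "dx": y_dx[tr]},
            TWO_LEVEL_SCHEDULE, level_heads=("coarse", "dx"), cfg=cfg,
        )
        after = [p.value for _, head in model.heads.values() for p in head.params()]
        assert any(not np.array_equal(b, a) for b, a in zip(before, after))
        assert len(history) == 2


class TestCombinedTrainer:
    def test_gradient_flows_to_both_heads(self, small_cohort):
        X, y_dx, y_pr, tr, _ = small_cohort
        km = default_knowledge_map()
        model, spec = make_tiny_cnn(seed=6, extra_heads={"pr": (2, 3)})
        states = frozen_block_schedule(spec, cycles=1)
        dx_before = [p.value.copy() for p in model.heads["dx"][1].params()]
        pr_before = [p.value.copy() for p in model.heads["pr"][1].params()]
        cfg = TrainConfig(head_lr=0.01, body_lr=0.003, samples_per_class=4, seed=0)
        train_combined(model, states[:1], X[tr], y_dx[tr], y_pr[tr], km, cfg=cfg)
        assert any(
            not np.array_equal(b, a.value)
            for b, a in zip(dx_before, model.heads["dx"][1].params())
        )
        assert any(
            not np.array_equal(b, a.value)
            for b, a in zip(pr_before, model.heads["pr"][1].params())
        )

    def test_lambda_pr_zero_reduces_to_flat_diagnosis(self, small_cohort):
        X, y_dx, y_pr, tr, _ = small_cohort
        km = default_knowledge_map()
        states = None
        results = []
        for mode in ("combined", "flat"):
            model, spec = make_tiny_cnn(seed=7, extra_heads={"pr": (2, 3)})
            states = frozen_block_schedule(spec, cycles=1)
            cfg = TrainConfig(
                head_lr=0.01, body_lr=0.003, samples_per_class=4, seed=0,
                lambda_dx=1.0, lambda_pr=0.0,
            )
            if mode == "combined":
                train_combined(model, states[:2], X[tr], y_dx[tr], y_pr[tr], km, cfg=cfg)
            else:
                train_flat(model, states[:2], X[tr], y_dx[tr], cfg)
            results.append([p.value.copy() for p in model.heads["dx"][1].params()])
        # with no priority loss the diagnosis head follows the same trajectory
        assert all(np.allclose(a, b) for a, b in zip(*results))
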