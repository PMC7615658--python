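"""Affine int8 quantization: error bounds, plans, and fine-tune contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from morpheusnet.model import build_model, default_spec, estimate_size_bytes
from morpheusnet.quant import QuantizationPlan, apply_plan, quantize_tensor


class TestQuantizeTensor:
    def test_constant_tensor_dequantizes_exactly(self):
        qt = quantize_tensor(np.zeros(16))
        assert (qt.q == qt.zero_point).all()
        assert np.allclose(qt.dequantize(), 0.0)

    def test_linspace_error_within_half_scale(self):
        x = np.linspace(-1, 1, 255)
        qt = quantize_tensor(x)
        err = np.abs(qt.dequantize() - x)
        # bound is scale/2 up to float32 rounding of the stored values
        assert err.max() <= qt.scale / 2 + 1e-6

    def test_idempotent_fixed_point(self):
        x = np.random.default_rng(0).standard_normal(200)
        once = quantize_tensor(x)
        twice = quantize_tensor(once.dequantize())
        assert np.array_equal(once.q, twice.q)
        assert once.scale == pytest.approx(twice.scale, rel=1e-2)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            quantize_tensor(np.array([1.0, np.nan]))
        with pytest.raises(ValueError):
            quantize_tensor(np.array([np.inf]))

    @given(
        hnp.arrays(
            np.float64,
            st.integers(2, 64),
            elements=st.floats(-1e3, 1e3, allow_nan=False, width=32),
        )
    )
    @settings(deadline=None, max_examples=100)
    def test_error_bound_holds_for_arbitrary_tensors(self, x):
        qt = quantize_tensor(x)
        err = np.abs(qt.dequantize() - x)
        assert err.max() <= qt.scale / 2 + 1e-6 * max(1.0, np.abs(x).max())


@pytest.fixture()
def trained_stub():
    """A built (untrained) pinned model; weights are random but valid."""
    return build_model(default_spec(), seed=7)


class TestApplyPlan:
    def test_empty_plan_leaves_model_identical(self, trained_stub, rng):
        model = trained_stub
        plan = QuantizationPlan(included_blocks=set(), excluded_blocks=set(model.block_names))
        before = model.cnn.clone_state()
        apply_plan(model, plan)
        for a, b in zip(before, model.cnn.state_dict()):
            for k in a:
                assert np.array_equal(a[k], b[k])

    def test_starred_plan_leaves_start_and_identity_untouched(self, trained_stub):
        model = trained_stub
        plan = QuantizationPlan.excluding(model, {"start", "identity"})
        blocks = model.named_blocks()
        before = {
            name: [p.copy() for lyr in blocks[name].iter_layers() for p in lyr.params.values()]
            for name in plan.excluded_blocks
        }
        apply_plan(model, plan)
        for name, params in before.items():
            after = [p for lyr in blocks[name].iter_layers() for p in lyr.params.values()]
            for a, b in zip(params, after):
                assert np.array_equal(a, b)

    def test_unknown_block_rejected(self, trained_stub):
        plan = QuantizationPlan(included_blocks={"bogus"}, excluded_blocks=set())
        with pytest.raises(ValueError, match="bogus"):
            apply_plan(trained_stub, plan)

    def test_full_plan_weights_are_on_int8_grid(self, trained_stub):
        model = trained_stub
        apply_plan(model, QuantizationPlan.full(model))
        head = model.named_blocks()["head"]
        w = head.params["W"]
        qt = quantize_tensor(w)
        assert np.allclose(qt.dequantize(), w, atol=1e-6)

    def test_error_bound_for_every_tensor_in_plan(self, trained_stub):
        model = trained_stub
        blocks = model.named_blocks()
        plan = QuantizationPlan.full(model)
        originals = {}
        for name in plan.included_blocks:
            for i, lyr in enumerate(blocks[name].iter_layers()):
                for pname in lyr.quantizable:
                    if pname in lyr.params:
                        originals[(name, i, pname)] = lyr.params[pname].copy()
        apply_plan(model, plan)
        for (name, i, pname), orig in originals.items():
            lyr = list(blocks[name].iter_layers())[i]
            scale = quantize_tensor(orig).scale
            assert np.abs(lyr.params[pname] - orig).max() <= scale / 2 + 1e-9

    def test_sequence_learner_never_quantized(self, trained_stub):
        model = trained_stub
        before = model.seq.clone_state()
        apply_plan(model, QuantizationPlan.full(model))
        for a, b in zip(before, model.seq.state_dict()):
            for k in a:
                assert np.array_equal(a[k], b[k])


class TestSizeInteraction:
    def test_byte_budget_monotonicity(self, trained_stub):
        model = trained_stub
        full = estimate_size_bytes(model, QuantizationPlan.full(model))
        starred = estimate_size_bytes(model, QuantizationPlan.excluding(model, {"start", "identity"}))
        assert full <= starred <= estimate_size_bytes(model, None)


class TestFinetuneContracts:
    def test_zero_learning_rate_leaves_weights_unchanged(self, small_dataset):
        from morpheusnet.quant import finetune_quantized
        from morpheusnet.train import StageConfig, TrainConfig

        model = build_model(default_spec(), seed=1)
        plan = QuantizationPlan.full(model)
        cfg = TrainConfig(
            cnn=StageConfig(lr=0.0, batch_size=16, epochs=1),
            seq=StageConfig(lr=0.0, batch_size=16, epochs=1),
            seed=0,
        )
        reference = build_model(default_spec(), seed=1)
        apply_plan(reference, QuantizationPlan.full(reference))
        finetune_quantized(model, plan, small_dataset[:2], small_dataset[2:], cfg)
        # with lr 0, fine-tuned weights equal plain post-training quantization
        for a, b in zip(reference.cnn.state_dict(), model.cnn.state_dict()):
            for k in set(a) - {"running_mean", "running_var"}:
                assert np.allclose(a[k], b[k], atol=1e-7)

    def test_sequence_finetune_keeps_cnn_int8_fixed(self, small_dataset):
        # asserted inside finetune_quantized; this exercises the path
        from morpheusnet.quant import default_finetune_config, finetune_quantized

        model = build_model(default_spec(), seed=2)
        cfg = default_finetune_config(seed=0)
        cfg.cnn.epochs = cfg.seq.epochs = 1
        manifest = finetune_quantized(
            model, QuantizationPlan.full(model), small_dataset[:2], small_dataset[2:], cfg
        )
        assert manifest  # per-tensor scales/zero-points recorded
        head = model.named_blocks()["head"]
        w = head.params["W"]
        assert np.allclose(quantize_tensor(w).dequantize(), w, atol=1e-6)
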