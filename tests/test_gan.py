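"""Conditional GAN: architecture contracts, loss schedule, smoke training,
checkpointing and transfer learning.

All training-dependent assertions share the session-scoped ``smoke_run``
fixture (one 50-step training) so the suite performs a single training run.
"""

import numpy as np
import pytest

from myxovision import gan, synthetic
from myxovision.gan import (
    DiscriminatorConfig,
    GeneratorConfig,
    TrainConfig,
    g1_weight,
)
from myxovision.nn import Tensor

from conftest import TINY_DISC, TINY_GEN


class TestGeneratorArchitecture:
    def test_output_shapes_and_range(self):
        g = gan.build_generator(GeneratorConfig(**TINY_GEN))
        x = Tensor(np.random.default_rng(0).uniform(-1, 1, (1, 1, 32, 32)))
        out1, out2 = g(x)
        assert out1.shape == out2.shape == (1, 1, 32, 32)
        assert np.all(np.abs(out1.data) <= 1.0)
        assert np.all(np.abs(out2.data) <= 1.0)

    def test_two_heads_have_independent_parameters(self):
        g = gan.build_generator(GeneratorConfig(**TINY_GEN))
        head1 = {id(p) for p in g.head_clahe.parameters()}
        head2 = {id(p) for p in g.head_he.parameters()}
        assert head1.isdisjoint(head2)
        assert len(g.trunk.parameters()) > 0

    def test_earlier_branch_point_duplicates_more_parameters(self):
        """Branching right after the residual blocks duplicates every
        decoder stage in both heads; branching at the last boundary
        duplicates only the output convolutions."""
        counts = []
        for bp in range(3):  # n_downsample=2 → boundaries 0, 1, 2
            cfg = GeneratorConfig(**{**TINY_GEN, "branch_point": bp})
            counts.append(gan.build_generator(cfg).n_parameters())
        assert counts[0] > counts[1] > counts[2]

    def test_branch_point_duplication_arithmetic(self):
        """Moving the branch one stage earlier adds exactly one copy of
        that decoder stage's parameters (3×3 conv weight+bias plus the
        instance-norm affine pair)."""
        cfg1 = GeneratorConfig(**{**TINY_GEN, "branch_point": 1})
        cfg2 = GeneratorConfig(**{**TINY_GEN, "branch_point": 2})
        g1_, g2_ = gan.build_generator(cfg1), gan.build_generator(cfg2)
        # stage between boundary 1 and 2 maps 16→8 channels
        stage_params = (8 * 16 * 3 * 3 + 8) + (8 + 8)
        assert g1_.n_parameters() - g2_.n_parameters() == stage_params

    def test_invalid_branch_point_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(**{**TINY_GEN, "branch_point": 5}).validate()


class TestDiscriminatorArchitecture:
    def test_two_discriminators_are_independent(self):
        d1, d2 = gan.build_discriminators(DiscriminatorConfig(**TINY_DISC))
        p1 = {id(p) for p in d1.parameters()}
        p2 = {id(p) for p in d2.parameters()}
        assert p1.isdisjoint(p2)
        # different seeds → different initial values
        a = next(iter(d1.named_parameters().values())).data
        b = next(iter(d2.named_parameters().values())).data
        assert not np.array_equal(a, b)

    def test_patch_output_is_a_map_not_a_scalar(self):
        d, _ = gan.build_discriminators(DiscriminatorConfig(**TINY_DISC))
        x = Tensor(np.zeros((1, 2, 64, 64)))
        preds = d(x)
        assert len(preds) == 1  # one scale in the tiny config
        n, c, h, w = preds[0].shape
        assert c == 1 and h > 1 and w > 1

    def test_multi_scale_halves_resolution_per_scale(self):
        cfg = DiscriminatorConfig(**{**TINY_DISC, "n_scales": 2})
        d = gan.MultiScaleDiscriminator(cfg)
        preds = d(Tensor(np.zeros((1, 2, 64, 64))))
        assert len(preds) == 2
        # the coarser scale sees a half-resolution input, so its patch map
        # is roughly half as wide (boundary padding blurs the exact factor)
        assert preds[1].shape[2] < preds[0].shape[2]
        assert abs(preds[0].shape[2] - 2 * preds[1].shape[2]) <= 4

    def test_feature_lists_expose_intermediate_maps(self):
        d, _ = gan.build_discriminators(DiscriminatorConfig(**TINY_DISC))
        feats = d.features(Tensor(np.zeros((1, 2, 32, 32))))
        assert len(feats[0]) >= 3  # input block, middle blocks, prediction


class TestSchedule:
    def test_g1_weight_endpoints_and_midpoint(self):
        cfg = TrainConfig(g1_weight_initial=1.0, g1_weight_floor=0.5,
                          g1_decay_epochs=500)
        assert g1_weight(0, cfg) == 1.0
        assert g1_weight(250, cfg) == pytest.approx(0.75)
        assert g1_weight(500, cfg) == 0.5
        assert g1_weight(1999, cfg) == 0.5

    def test_g1_weight_is_monotone_nonincreasing(self):
        cfg = TrainConfig()
        ws = [g1_weight(e, cfg) for e in range(0, 700, 50)]
        assert all(a >= b for a, b in zip(ws, ws[1:]))

    def test_decay_longer_than_run_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=100, g1_decay_epochs=500).validate()


class TestLosses:
    def test_d_loss_zero_when_predictions_perfect(self):
        """If D outputs exactly 1 on real and 0 on fake the LSGAN loss
        vanishes; verified through a stub discriminator."""

        class Stub:
            def __init__(self, r, f):
                self.r, self.f = r, f
                self.calls = 0

            def __call__(self, x):
                self.calls += 1
                return [Tensor(np.full((1, 1, 4, 4), self.r if self.calls == 1
                                       else self.f))]

        stub = Stub(1.0, 0.0)
        loss = gan.lsgan_d_loss(stub, Tensor(np.zeros((1, 2, 8, 8))),
                                Tensor(np.zeros((1, 2, 8, 8))))
        assert float(loss.data) == 0.0

    def test_feature_matching_zero_on_identical_inputs(self):
        d, _ = gan.build_discriminators(DiscriminatorConfig(**TINY_DISC))
        x = Tensor(np.random.default_rng(1).normal(size=(1, 2, 32, 32)))
        loss = gan.feature_matching_loss(d, x, x)
        assert float(loss.data) == 0.0

    def test_he_only_loss_reaches_the_shared_trunk(self):
        """A loss on the HE head alone must produce gradients in the shared
        trunk — the branched architecture trains the trunk from both heads."""
        g = gan.build_generator(GeneratorConfig(**TINY_GEN))
        g.zero_grad()
        x = Tensor(np.random.default_rng(2).uniform(-1, 1, (1, 1, 16, 16)))
        _, he = g(x)
        (he * he).mean().backward()
        trunk_gmax = max(
            np.abs(p.grad).max() for p in g.trunk.parameters()
            if p.grad is not None
        )
        assert trunk_gmax > 0
        for p in g.head_clahe.parameters():
            assert p.grad is None or np.all(p.grad == 0)


class TestTraining:
    def test_loss_decreases_over_smoke_run(self, smoke_run):
        log = smoke_run["log"]
        first = np.mean([e["g_total"] for e in log[:5]])
        last = np.mean([e["g_total"] for e in log[-5:]])
        assert last < first

    def test_trained_model_reconstructs_better_than_untrained(self, smoke_run):
        data = smoke_run["data"]
        def recon_mse(model):
            errs = []
            for i in range(data["phase"].shape[0]):
                o1, o2 = model.translate(data["phase"][i, 0])
                errs.append(np.mean((o1 - data["fluor_clahe"][i, 0]) ** 2)
                            + np.mean((o2 - data["fluor_he"][i, 0]) ** 2))
            return float(np.mean(errs))

        assert recon_mse(smoke_run["model"]) < recon_mse(smoke_run["untrained"])

    def test_zero_lr_step_leaves_parameters_unchanged(self, pair_dataset):
        model = gan.Pix2PixHDHE(
            GeneratorConfig(**TINY_GEN), DiscriminatorConfig(**TINY_DISC),
            TrainConfig(lr=1e-30, batch_size=2),
        )
        before = {k: v.copy() for k, v in model.G.state_dict().items()}
        batch = {k: v[:2] for k, v in pair_dataset.items()}
        model.training_step(batch)
        after = model.G.state_dict()
        for k in before:
            assert np.allclose(before[k], after[k], atol=1e-20)

    def test_translate_is_deterministic(self, smoke_run):
        phase = smoke_run["data"]["phase"][0, 0]
        a1, a2 = smoke_run["model"].translate(phase)
        b1, b2 = smoke_run["model"].translate(phase)
        assert np.array_equal(a1, b1) and np.array_equal(a2, b2)

    def test_translate_pads_odd_sizes_and_crops_back(self, smoke_run):
        phase = np.random.default_rng(3).uniform(-1, 1, (60, 61))
        o1, o2 = smoke_run["model"].translate(phase)
        assert o1.shape == o2.shape == (60, 61)
        assert np.all(np.abs(o1) <= 1.0)

    def test_translate_rejects_stacks(self, smoke_run):
        with pytest.raises(ValueError):
            smoke_run["model"].translate(np.zeros((2, 16, 16)))


class TestCheckpointing:
    def test_reload_is_bit_identical(self, smoke_run):
        loaded = gan.Pix2PixHDHE.load_checkpoint(smoke_run["ckpt"])
        orig = smoke_run["model"].G.state_dict()
        for k, v in loaded.G.state_dict().items():
            assert np.array_equal(v, orig[k])
        assert loaded.epoch == smoke_run["model"].epoch

    def test_resume_zero_steps_is_a_pure_load(self, smoke_run):
        model = gan.resume_training(smoke_run["ckpt"], smoke_run["data"], 0)
        orig = smoke_run["model"].G.state_dict()
        for k, v in model.G.state_dict().items():
            assert np.array_equal(v, orig[k])

    def test_transfer_to_ripples_improves_reconstruction(self, smoke_run):
        """Resume the aggregate-trained checkpoint on ripple scenes: a short
        continuation must reduce HE reconstruction error on the new data."""
        frames_p, frames_h = [], []
        for s in range(4):
            p = synthetic.RippleSceneParams(
                field_size_px=64, wavelength_um=16.0, seed=s
            )
            ph, fl, _ = synthetic.generate_ripple_scene(p)
            frames_p.append(ph.values * 2 - 1)
            frames_h.append(fl.values * 2 - 1)
        data = {
            "phase": np.stack(frames_p)[:, None],
            "fluor_clahe": np.stack(frames_h)[:, None],
            "fluor_he": np.stack(frames_h)[:, None],
        }

        def recon(model):
            errs = []
            for i in range(4):
                _, o2 = model.translate(data["phase"][i, 0])
                errs.append(np.mean((o2 - data["fluor_he"][i, 0]) ** 2))
            return float(np.mean(errs))

        before = recon(gan.Pix2PixHDHE.load_checkpoint(smoke_run["ckpt"]))
        tuned = gan.resume_training(
            smoke_run["ckpt"], data, 20, rng=np.random.default_rng(7)
        )
        assert recon(tuned) < before

    def test_reset_schedule_restarts_g1_weight(self, smoke_run, tmp_path):
        model = gan.Pix2PixHDHE.load_checkpoint(smoke_run["ckpt"])
        model.epoch = 600  # past the decay window
        ckpt = tmp_path / "late.ckpt"
        model.save_checkpoint(ckpt)
        cont = gan.resume_training(ckpt, smoke_run["data"], 0)
        fresh = gan.resume_training(ckpt, smoke_run["data"], 0,
                                    reset_schedule=True)
        assert g1_weight(cont.epoch, cont.train_cfg) == 0.5
        assert g1_weight(fresh.epoch, fresh.train_cfg) == 1.0
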