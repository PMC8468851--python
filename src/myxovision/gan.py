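"""pix2pixHD-HE: conditional GAN translating phase-contrast to fluorescence.

The generator is an encoder–residual–decoder network in the pix2pixHD
lineage whose decoder *branches* into two output heads: one synthesizes the
CLAHE-normalized fluorescence channel, the other the histogram-equalized
(HE) channel.  The HE channel must be its own output because histogram
equalization is not invertible — it cannot be derived from the normalized
output after the fact — and it is what carries the dim inter-aggregate
streams.  Two independent patch discriminators judge the two channels, each
conditioned on the input phase-contrast image.  Training uses least-squares
adversarial losses plus discriminator feature matching; the loss weight of
the first head (G1) is linearly decayed over the early epochs while the
second head's weight (G2) stays constant, shifting capacity toward the HE
channel as training progresses.

Everything runs on the in-package numpy autodiff engine; a tiny
configuration (64×64 fields, base width 8) trains end-to-end on CPU in
seconds, and checkpoints allow transfer learning by resuming from trained
parameters on a new pattern class (e.g. aggregates → ripples).
"""

from __future__ import annotations

import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    Conv2d,
    InstanceNorm2d,
    LeakyReLU,
    Module,
    ReLU,
    ResBlock,
    Sequential,
    Tanh,
    Tensor,
    UpsampleNearest,
)


@dataclass
class GeneratorConfig:
    in_channels: int = 1
    out_channels_per_head: int = 1
    base_width: int = 64
    n_downsample: int = 4
    n_resblocks: int = 9
    branch_point: int = 2   # index into the decoder-boundary candidates
    seed: int = 0

    def validate(self) -> None:
        if min(self.base_width, self.n_downsample, self.n_resblocks) < 1:
            raise ValueError("architecture sizes must be positive")
        n_candidates = self.n_downsample + 1
        if not 0 <= self.branch_point < n_candidates:
            raise ValueError(
                f"branch_point must be one of 0..{n_candidates - 1} "
                f"(decoder-stage boundaries; {n_candidates - 1} duplicates "
                "only the output layers)"
            )

    def tiny(self) -> "GeneratorConfig":
        """Desk-scale configuration used throughout the test suite."""
        return GeneratorConfig(
            base_width=8, n_downsample=2, n_resblocks=2,
            branch_point=min(self.branch_point, 2), seed=self.seed,
        )


@dataclass
class DiscriminatorConfig:
    in_channels: int = 2     # phase image + one generated/real channel
    base_width: int = 64
    n_layers: int = 3
    n_scales: int = 2
    seed: int = 0


@dataclass
class TrainConfig:
    lr: float = 5e-5
    epochs: int = 2000
    g1_decay_epochs: int = 500
    g1_weight_initial: float = 1.0
    g1_weight_floor: float = 0.5
    g2_weight: float = 1.0
    feature_matching_weight: float = 10.0
    batch_size: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.g1_decay_epochs > self.epochs:
            raise ValueError("g1_decay_epochs must not exceed epochs")


def g1_weight(epoch: int, cfg: TrainConfig) -> float:
    """Linear decay of the first head's loss weight.

    Decays from ``g1_weight_initial`` to ``g1_weight_floor`` over the first
    ``g1_decay_epochs`` epochs, constant afterwards.
    """
    if epoch >= cfg.g1_decay_epochs:
        return cfg.g1_weight_floor
    frac = epoch / cfg.g1_decay_epochs
    return cfg.g1_weight_initial + frac * (cfg.g1_weight_floor - cfg.g1_weight_initial)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

class Generator(Module):
    """Shared trunk + two branched heads.

    Branch candidates sit at decoder-stage boundaries: candidate 0 is before
    the first upsampling stage (everything after the residual blocks is
    duplicated), candidate ``n_downsample`` duplicates only the final output
    convolution.  ``trunk`` holds the shared modules; ``head_clahe`` and
    ``head_he`` are structurally identical duplicated tails with independent
    parameters.
    """

    def __init__(self, cfg: GeneratorConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.base_width
        nd = cfg.n_downsample

        encoder: list[Module] = [
            Conv2d(cfg.in_channels, w, 7, pad=3, pad_mode="reflect", rng=rng),
            InstanceNorm2d(w),
            ReLU(),
        ]
        ch = w
        for _ in range(nd):
            encoder += [
                Conv2d(ch, ch * 2, 3, stride=2, pad=1, rng=rng),
                InstanceNorm2d(ch * 2),
                ReLU(),
            ]
            ch *= 2
        encoder += [ResBlock(ch, rng=rng) for _ in range(cfg.n_resblocks)]

        # decoder stages, grouped so the branch can split between them
        stages: list[list[Module]] = []
        for _ in range(nd):
            stages.append([
                UpsampleNearest(2),
                Conv2d(ch, ch // 2, 3, pad=1, rng=rng),
                InstanceNorm2d(ch // 2),
                ReLU(),
            ])
            ch //= 2
        out_stage_channels = ch

        def make_tail(start_stage: int, rng_: np.random.Generator) -> Sequential:
            mods: list[Module] = []
            ch_ = cfg.base_width * 2 ** (nd - start_stage)
            for _ in range(start_stage, nd):
                mods += [
                    UpsampleNearest(2),
                    Conv2d(ch_, ch_ // 2, 3, pad=1, rng=rng_),
                    InstanceNorm2d(ch_ // 2),
                    ReLU(),
                ]
                ch_ //= 2
            mods += [
                Conv2d(
                    out_stage_channels, cfg.out_channels_per_head, 7,
                    pad=3, pad_mode="reflect", rng=rng_,
                ),
                Tanh(),
            ]
            return Sequential(*mods)

        bp = cfg.branch_point
        shared: list[Module] = list(encoder)
        for stage in stages[:bp]:
            shared += stage
        self.trunk = Sequential(*shared)
        self.head_clahe = make_tail(bp, rng)
        self.head_he = make_tail(bp, rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:  # type: ignore[override]
        h = self.trunk(x)
        return self.head_clahe(h), self.head_he(h)


def build_generator(cfg: GeneratorConfig | None = None) -> Generator:
    return Generator(cfg or GeneratorConfig())


# ---------------------------------------------------------------------------
# discriminators
# ---------------------------------------------------------------------------

class PatchDiscriminator(Module):
    """Single-scale PatchGAN returning all intermediate feature maps."""

    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator):
        w = cfg.base_width
        blocks: list[Sequential] = [
            Sequential(Conv2d(cfg.in_channels, w, 4, stride=2, pad=2, rng=rng),
                       LeakyReLU(0.2))
        ]
        ch = w
        for i in range(1, cfg.n_layers):
            stride = 2 if i < cfg.n_layers - 1 else 1
            blocks.append(Sequential(
                Conv2d(ch, ch * 2, 4, stride=stride, pad=2, rng=rng),
                InstanceNorm2d(ch * 2),
                LeakyReLU(0.2),
            ))
            ch *= 2
        blocks.append(Sequential(Conv2d(ch, 1, 4, stride=1, pad=2, rng=rng)))
        self.blocks = blocks

    def features(self, x: Tensor) -> list[Tensor]:
        feats = []
        for b in self.blocks:
            x = b(x)
            feats.append(x)
        return feats

    def forward(self, x: Tensor) -> Tensor:
        return self.features(x)[-1]


class MultiScaleDiscriminator(Module):
    """Independent patch discriminators at successively halved resolutions."""

    def __init__(self, cfg: DiscriminatorConfig | None = None):
        cfg = cfg or DiscriminatorConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.scales = [PatchDiscriminator(cfg, rng) for _ in range(cfg.n_scales)]

    def features(self, x: Tensor) -> list[list[Tensor]]:
        out = []
        for i, d in enumerate(self.scales):
            xi = x
            for _ in range(i):
                xi = xi.avg_pool2()
            out.append(d.features(xi))
        return out

    def forward(self, x: Tensor) -> list[Tensor]:  # type: ignore[override]
        return [feats[-1] for feats in self.features(x)]


def build_discriminators(
    cfg: DiscriminatorConfig | None = None,
) -> tuple[MultiScaleDiscriminator, MultiScaleDiscriminator]:
    """Two independent discriminators: one per generated channel."""
    cfg = cfg or DiscriminatorConfig()
    cfg_he = DiscriminatorConfig(**{**asdict(cfg), "seed": cfg.seed + 1})
    return MultiScaleDiscriminator(cfg), MultiScaleDiscriminator(cfg_he)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _mean_sq(t: Tensor) -> Tensor:
    return (t * t).mean()


def lsgan_d_loss(d: MultiScaleDiscriminator, real: Tensor, fake: Tensor) -> Tensor:
    """Least-squares discriminator loss, averaged over scales."""
    loss = Tensor(0.0)
    reals = d(real)
    fakes = d(fake)
    for pr, pf in zip(reals, fakes):
        loss = loss + 0.5 * (_mean_sq(pr - 1.0) + _mean_sq(pf))
    return loss * (1.0 / len(reals))


def lsgan_g_loss(d: MultiScaleDiscriminator, fake: Tensor) -> Tensor:
    loss = Tensor(0.0)
    preds = d(fake)
    for pf in preds:
        loss = loss + _mean_sq(pf - 1.0)
    return loss * (1.0 / len(preds))


def feature_matching_loss(
    d: MultiScaleDiscriminator, real: Tensor, fake: Tensor
) -> Tensor:
    """L1 distance between discriminator features of real and fake pairs.

    Real-pair features are detached: the generator matches them, the
    discriminator is not pulled toward the generator.
    """
    loss = Tensor(0.0)
    n_terms = 0
    real_feats = d.features(real)
    fake_feats = d.features(fake)
    for rf_scale, ff_scale in zip(real_feats, fake_feats):
        for rf, ff in zip(rf_scale[:-1], ff_scale[:-1]):
            loss = loss + (ff - rf.detach()).abs().mean()
            n_terms += 1
    return loss * (1.0 / max(n_terms, 1))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class Pix2PixHDHE:
    """Model bundle: generator, two discriminators, three Adam optimizers."""

    def __init__(
        self,
        gen_cfg: GeneratorConfig | None = None,
        disc_cfg: DiscriminatorConfig | None = None,
        train_cfg: TrainConfig | None = None,
    ):
        self.gen_cfg = gen_cfg or GeneratorConfig()
        self.disc_cfg = disc_cfg or DiscriminatorConfig()
        self.train_cfg = train_cfg or TrainConfig()
        self.train_cfg.validate()
        self.G = build_generator(self.gen_cfg)
        self.D_clahe, self.D_he = build_discriminators(self.disc_cfg)
        lr = self.train_cfg.lr
        self.opt_g = Adam(self.G.parameters(), lr=lr)
        self.opt_d1 = Adam(self.D_clahe.parameters(), lr=lr)
        self.opt_d2 = Adam(self.D_he.parameters(), lr=lr)
        self.epoch = 0

    # -- one optimization step ----------------------------------------------
    def training_step(
        self, batch: dict[str, np.ndarray], epoch: int | None = None
    ) -> dict[str, float]:
        """One joint update on a batch of (phase, fluor_clahe, fluor_he).

        Batch arrays have shape (N, 1, H, W) with values in [−1, 1].  The
        generator loss is w1(epoch)·L_clahe + w2·L_he, each head loss being
        adversarial + feature matching against its own discriminator.
        """
        cfg = self.train_cfg
        ep = self.epoch if epoch is None else epoch
        phase = Tensor(batch["phase"])
        real1 = Tensor(batch["fluor_clahe"])
        real2 = Tensor(batch["fluor_he"])

        fake1, fake2 = self.G(phase)

        # discriminator updates on detached fakes
        losses: dict[str, float] = {}
        for name, d, opt, real, fake in (
            ("d_clahe", self.D_clahe, self.opt_d1, real1, fake1),
            ("d_he", self.D_he, self.opt_d2, real2, fake2),
        ):
            d.zero_grad()
            pair_real = Tensor.concat([phase, real], axis=1)
            pair_fake = Tensor.concat([phase, fake.detach()], axis=1)
            d_loss = lsgan_d_loss(d, pair_real, pair_fake)
            if not np.isfinite(d_loss.data):
                raise FloatingPointError(f"non-finite {name} loss")
            d_loss.backward()
            opt.step()
            losses[name] = float(d_loss.data)

        # generator update
        self.G.zero_grad()
        self.D_clahe.zero_grad()
        self.D_he.zero_grad()
        head_losses = []
        for d, real, fake in (
            (self.D_clahe, real1, fake1),
            (self.D_he, real2, fake2),
        ):
            pair_real = Tensor.concat([phase, real], axis=1)
            pair_fake = Tensor.concat([phase, fake], axis=1)
            adv = lsgan_g_loss(d, pair_fake)
            fm = feature_matching_loss(d, pair_real, pair_fake)
            head_losses.append(adv + cfg.feature_matching_weight * fm)
        w1 = g1_weight(ep, cfg)
        g_loss = w1 * head_losses[0] + cfg.g2_weight * head_losses[1]
        if not np.isfinite(g_loss.data):
            raise FloatingPointError("non-finite generator loss")
        g_loss.backward()
        self.opt_g.step()

        losses.update({
            "g_total": float(g_loss.data),
            "g_clahe": float(head_losses[0].data),
            "g_he": float(head_losses[1].data),
            "w1": w1,
        })
        return losses

    def fit(
        self,
        dataset: dict[str, np.ndarray],
        n_steps: int,
        rng: np.random.Generator | None = None,
        steps_per_epoch: int | None = None,
        log: list | None = None,
    ) -> dict[str, float]:
        """Train for ``n_steps`` mini-batch steps on an in-memory dataset.

        ``dataset`` arrays are (M, 1, H, W); batches are sampled with
        replacement.  The epoch counter (driving the G1 weight schedule)
        advances every ``steps_per_epoch`` steps (default: one epoch per
        pass over the dataset).
        """
        cfg = self.train_cfg
        rng = rng or np.random.default_rng(cfg.seed)
        m = dataset["phase"].shape[0]
        spe = steps_per_epoch or max(1, m // cfg.batch_size)
        last: dict[str, float] = {}
        for step in range(n_steps):
            idx = rng.integers(0, m, size=cfg.batch_size)
            batch = {k: v[idx] for k, v in dataset.items()}
            last = self.training_step(batch)
            if log is not None:
                log.append({"step": step, "epoch": self.epoch, **last})
            if (step + 1) % spe == 0:
                self.epoch += 1
        return last

    # -- inference -----------------------------------------------------------
    def translate(self, phase: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic forward pass on one 2-D phase image in [−1, 1].

        Inputs whose sides are not divisible by 2^n_downsample are
        reflect-padded up and the outputs cropped back.
        """
        phase = np.asarray(phase, dtype=np.float64)
        if phase.ndim != 2:
            raise ValueError("translate expects a single 2-D image")
        h, w = phase.shape
        mult = 2 ** self.gen_cfg.n_downsample
        ph = (-h) % mult
        pw = (-w) % mult
        padded = np.pad(phase, ((0, ph), (0, pw)), mode="reflect") \
            if (ph or pw) else phase
        x = Tensor(padded[None, None])
        out1, out2 = self.G(x)
        return (
            out1.data[0, 0, :h, :w].copy(),
            out2.data[0, 0, :h, :w].copy(),
        )

    # -- checkpointing -------------------------------------------------------
    def save_checkpoint(self, path: str | Path) -> None:
        state = {
            "gen_cfg": asdict(self.gen_cfg),
            "disc_cfg": asdict(self.disc_cfg),
            "train_cfg": asdict(self.train_cfg),
            "G": self.G.state_dict(),
            "D_clahe": self.D_clahe.state_dict(),
            "D_he": self.D_he.state_dict(),
            "opt_g": self.opt_g.state_dict(),
            "opt_d1": self.opt_d1.state_dict(),
            "opt_d2": self.opt_d2.state_dict(),
            "epoch": self.epoch,
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load_checkpoint(cls, path: str | Path) -> "Pix2PixHDHE":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        model = cls(
            GeneratorConfig(**state["gen_cfg"]),
            DiscriminatorConfig(**state["disc_cfg"]),
            TrainConfig(**state["train_cfg"]),
        )
        model.G.load_state_dict(state["G"])
        model.D_clahe.load_state_dict(state["D_clahe"])
        model.D_he.load_state_dict(state["D_he"])
        model.opt_g.load_state_dict(state["opt_g"])
        model.opt_d1.load_state_dict(state["opt_d1"])
        model.opt_d2.load_state_dict(state["opt_d2"])
        model.epoch = int(state["epoch"])
        return model


def resume_training(
    ckpt_path: str | Path,
    dataset: dict[str, np.ndarray],
    n_steps: int,
    *,
    reset_schedule: bool = False,
    rng: np.random.Generator | None = None,
    log: list | None = None,
) -> Pix2PixHDHE:
    """Transfer learning: continue from saved parameters on a new dataset.

    The previously learned parameters are the starting point; with
    ``reset_schedule`` the epoch counter (and hence the G1 weight schedule)
    restarts from zero, otherwise it continues where the checkpoint left
    off.
    """
    model = Pix2PixHDHE.load_checkpoint(ckpt_path)
    if reset_schedule:
        model.epoch = 0
    if n_steps > 0:
        model.fit(dataset, n_steps, rng=rng, log=log)
    return model
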