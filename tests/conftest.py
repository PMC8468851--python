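"""Shared fixtures: synthetic scenes and a session-scoped smoke-trained GAN."""

from __future__ import annotations

import numpy as np
import pytest

from myxovision import gan, synthetic
from myxovision.prep import clahe_normalize, hist_equalize

TINY_GEN = dict(base_width=8, n_downsample=2, n_resblocks=2, branch_point=2, seed=0)
TINY_DISC = dict(base_width=8, n_scales=1, seed=0)


def make_pair_dataset(n: int = 8, size: int = 64, base_seed: int = 0) -> dict:
    """n aligned (phase, fluor_clahe, fluor_he) triplets in [−1, 1]."""
    phase, c_t, h_t = [], [], []
    for s in range(n):
        p = synthetic.AggregateSceneParams(
            field_size_px=size, n_aggregates=2, radius_range_px=(6, 10),
            background_noise_sigma=0.01, seed=base_seed + s,
        )
        ph, fl, _ = synthetic.generate_aggregate_scene(p)
        phase.append(ph.values * 2 - 1)
        c_t.append(clahe_normalize(fl).values * 2 - 1)
        h_t.append(hist_equalize(fl).values * 2 - 1)
    return {
        "phase": np.stack(phase)[:, None],
        "fluor_clahe": np.stack(c_t)[:, None],
        "fluor_he": np.stack(h_t)[:, None],
    }


@pytest.fixture(scope="session")
def pair_dataset() -> dict:
    return make_pair_dataset()


@pytest.fixture(scope="session")
def smoke_run(pair_dataset, tmp_path_factory):
    """One 50-step smoke training shared by every GAN assertion.

    Returns the trained model, its loss log, an untrained twin, and a saved
    checkpoint path.
    """
    gcfg = gan.GeneratorConfig(**TINY_GEN)
    dcfg = gan.DiscriminatorConfig(**TINY_DISC)
    tcfg = gan.TrainConfig(batch_size=4, seed=0)
    untrained = gan.Pix2PixHDHE(gcfg, dcfg, tcfg)
    model = gan.Pix2PixHDHE(gcfg, dcfg, tcfg)
    log: list = []
    model.fit(pair_dataset, 50, rng=np.random.default_rng(1), log=log)
    ckpt = tmp_path_factory.mktemp("ckpt") / "smoke.ckpt"
    model.save_checkpoint(ckpt)
    return {
        "model": model,
        "untrained": untrained,
        "log": log,
        "ckpt": ckpt,
        "data": pair_dataset,
    }
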