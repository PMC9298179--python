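"""Multistep adversarial training of the enhancement GAN.

The schedule has three phases: (1) the generator alone is trained on the
non-adversarial terms of its objective until it produces primary-quality
images, (2) the discriminator alone is trained to separate those fakes from
real targets, (3) the adversarial game alternates discriminator and
generator updates with the full objectives.  This staging stabilises the
game: neither player enters it untrained.

Runs are bit-reproducible from (dataset, config): batch sampling is the only
randomness and flows from the config seed; checkpoints capture weights,
Adam state, step counter and the sampler RNG state, so
``resume(train(n)) == train(2n)`` exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import losses as L
from . import nn
from .image_io import to_batch
from .model import Discriminator, DiscriminatorConfig, Generator, GeneratorConfig
from .synthetic_cells import PairedDataset

__all__ = [
    "TrainingConfig", "TrainState", "TrainingDivergedError", "train", "resume",
    "save_checkpoint", "load_checkpoint", "default_batch_size",
]

#: (input size px -> batch size) regimes; 256/20 is the canonical default
BATCH_SIZE_REGIMES = {128: 32, 256: 20, 512: 4}


def default_batch_size(input_size: int) -> int:
    return BATCH_SIZE_REGIMES.get(input_size, 8)


class TrainingDivergedError(RuntimeError):
    """A loss term became non-finite; the message names the term and step."""


@dataclass
class TrainingConfig:
    input_size: int = 256
    batch_size: int | None = None  # None -> regime default for input_size
    steps_phase1_g: int = 1000
    steps_phase2_d: int = 1000
    steps_phase3_game: int = 10000
    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    loss_weights: L.LossWeights = field(default_factory=L.LossWeights)
    seed: int = 0
    checkpoint_every: int = 0  # 0 -> final checkpoint only
    d_steps_per_g: int = 1
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    extractor_seed: int = 17
    deterministic: bool = True  # numpy path is deterministic; kept for config echo

    def __post_init__(self) -> None:
        if self.batch_size is None:
            self.batch_size = default_batch_size(self.input_size)
        if min(self.steps_phase1_g, self.steps_phase2_d, self.steps_phase3_game) < 0:
            raise ValueError("phase step counts must be >= 0")
        if self.d_steps_per_g < 1:
            raise ValueError("d_steps_per_g must be >= 1")

    @property
    def total_steps(self) -> int:
        return self.steps_phase1_g + self.steps_phase2_d + self.steps_phase3_game

    def phase_of(self, step: int) -> int:
        """Phase of 1-based wall step."""
        if step <= self.steps_phase1_g:
            return 1
        if step <= self.steps_phase1_g + self.steps_phase2_d:
            return 2
        return 3

    # fields that must agree between a checkpoint and a resume config
    _ARCH_FIELDS = ("input_size", "batch_size", "generator", "discriminator",
                    "extractor_seed", "seed", "lr", "betas", "d_steps_per_g")


@dataclass
class TrainState:
    """Live checkpoint: networks, optimizers, sampler RNG and step counter."""

    generator: Generator
    discriminator: Discriminator
    adam_g: nn.Adam
    adam_d: nn.Adam
    rng: np.random.Generator
    config: TrainingConfig
    step: int = 0

    @property
    def phase(self) -> int:
        return self.config.phase_of(max(self.step, 1))


def _init_state(config: TrainingConfig) -> TrainState:
    g = Generator(config.generator, seed=config.seed)
    d = Discriminator(config.discriminator, seed=config.seed + 1)
    return TrainState(
        generator=g, discriminator=d,
        adam_g=nn.Adam(g.params(), lr=config.lr, betas=config.betas),
        adam_d=nn.Adam(d.params(), lr=config.lr, betas=config.betas),
        rng=np.random.default_rng(config.seed), config=config)


def _dataset_arrays(dataset: PairedDataset) -> tuple[np.ndarray, np.ndarray]:
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    z = to_batch(dataset.inputs()).data.astype(nn.DTYPE)
    x = to_batch(dataset.targets()).data.astype(nn.DTYPE)
    return z, x


def _check_finite(report: L.LossReport, step: int) -> None:
    for name, value in asdict(report).items():
        if not np.isfinite(value):
            raise TrainingDivergedError(f"{name} is non-finite at step {step}")


def _g_update(state: TrainState, z: np.ndarray, x: np.ndarray,
              extractor: L.FeatureExtractor, adversarial: bool) -> L.LossReport:
    """One generator step; returns the unweighted loss terms."""
    cfg = state.config
    w = cfg.loss_weights
    g = state.generator
    xh = g.forward(z)

    l_rec, g_rec = L.reconstruction_grad(x, xh)
    l_tv, g_tv = L.tv_grad(xh)
    dxh = w.lambda_rec * g_rec + w.lambda_tv * g_tv
    l_feat = l_style = 0.0
    if w.lambda_feat > 0:
        l_feat, g_feat = L.feature_grad(x, xh, extractor)
        dxh += w.lambda_feat * g_feat
    if w.lambda_style > 0:
        l_style, g_style = L.style_grad(x, xh, extractor)
        dxh += w.lambda_style * g_style

    l_adv_g = 0.0
    if adversarial and w.lambda_adv_g > 0:
        d = state.discriminator
        d_fake = d.forward(xh)
        _, _, dadv = L.adversarial_grads(np.array([0.5]), d_fake)
        _, l_adv_g = L.adversarial_losses(np.array([0.5]), d_fake)
        # data gradient through the (frozen-for-this-step) discriminator;
        # its parameter grads are cleared before the next D update
        dxh += w.lambda_adv_g * d.backward(dadv)

    g.zero_grad()
    g.backward(dxh.astype(nn.DTYPE))
    state.adam_g.step()

    total = (w.lambda_rec * l_rec + w.lambda_feat * l_feat + w.lambda_style * l_style
             + w.lambda_tv * l_tv + w.lambda_adv_g * l_adv_g)
    return L.LossReport(l_rec=l_rec, l_feat=l_feat, l_style=l_style, l_tv=l_tv,
                        l_adv_g=l_adv_g, l_g_total=float(total))


def _d_update(state: TrainState, z: np.ndarray, x: np.ndarray) -> float:
    """One discriminator step against frozen-generator fakes."""
    d = state.discriminator
    xh = state.generator.forward(z)  # no G update here
    d.zero_grad()
    d_real = d.forward(x)
    g_real, _, _ = L.adversarial_grads(d_real, np.array([0.5]))
    d.backward(g_real)
    d_fake = d.forward(xh)
    _, g_fake, _ = L.adversarial_grads(np.array([0.5]), d_fake)
    d.backward(g_fake)
    l_adv_d, _ = L.adversarial_losses(d_real, d_fake)
    state.adam_d.step()
    return l_adv_d


def _sample(state: TrainState, n: int) -> np.ndarray:
    bs = state.config.batch_size
    return state.rng.choice(n, size=bs, replace=bs > n)


def _run(state: TrainState, dataset: PairedDataset,
         out_dir: str | Path | None = None) -> pd.DataFrame:
    cfg = state.config
    z_all, x_all = _dataset_arrays(dataset)
    extractor = L.RandomConvExtractor(seed=cfg.extractor_seed)
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    while state.step < cfg.total_steps:
        step = state.step + 1
        phase = cfg.phase_of(step)
        report = L.LossReport()
        if phase == 1:
            idx = _sample(state, len(dataset))
            report = _g_update(state, z_all[idx], x_all[idx], extractor, adversarial=False)
        elif phase == 2:
            idx = _sample(state, len(dataset))
            report.l_adv_d = _d_update(state, z_all[idx], x_all[idx])
        else:
            for _ in range(cfg.d_steps_per_g):
                idx = _sample(state, len(dataset))
                report.l_adv_d = _d_update(state, z_all[idx], x_all[idx])
            idx = _sample(state, len(dataset))
            g_report = _g_update(state, z_all[idx], x_all[idx], extractor, adversarial=True)
            g_report.l_adv_d = report.l_adv_d
            report = g_report
        _check_finite(report, step)
        state.step = step
        rows.append({"step": step, "phase": phase, **asdict(report)})
        if out_dir and cfg.checkpoint_every and step % cfg.checkpoint_every == 0:
            save_checkpoint(state, out_dir / f"step{step:07d}.ckpt.npz")
    history = pd.DataFrame(rows)
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(state, out_dir / "final.ckpt.npz")
        history.to_csv(out_dir / "history.csv", index=False)
    return history


def train(dataset: PairedDataset, config: TrainingConfig,
          out_dir: str | Path | None = None) -> tuple[TrainState, pd.DataFrame]:
    """Run the full three-phase schedule from scratch."""
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    state = _init_state(config)
    history = _run(state, dataset, out_dir)
    return state, history


def resume(checkpoint: "TrainState | str | Path", dataset: PairedDataset,
           config: TrainingConfig,
           out_dir: str | Path | None = None) -> tuple[TrainState, pd.DataFrame]:
    """Continue a run from a checkpoint up to ``config.total_steps``.

    The architecture/optimizer fields of ``config`` must match the
    checkpoint; phase extensions (larger step counts) are allowed.
    """
    state = checkpoint if isinstance(checkpoint, TrainState) else load_checkpoint(checkpoint)
    mismatches = [f for f in TrainingConfig._ARCH_FIELDS
                  if getattr(state.config, f) != getattr(config, f)]
    if mismatches:
        raise ValueError(f"resume config differs from checkpoint in: {mismatches}")
    state.config = config
    history = _run(state, dataset, out_dir)
    return state, history


# ------------------------------------------------------------- persistence

def _config_to_json(config: TrainingConfig) -> str:
    d = asdict(config)
    d["loss_weights"] = asdict(config.loss_weights)
    d["generator"] = asdict(config.generator)
    d["discriminator"] = asdict(config.discriminator)
    return json.dumps(d)


def _config_from_json(blob: str) -> TrainingConfig:
    d = json.loads(blob)
    d["loss_weights"] = L.LossWeights(**d["loss_weights"])
    d["generator"] = GeneratorConfig(**d["generator"])
    d["discriminator"] = DiscriminatorConfig(**d["discriminator"])
    d["betas"] = tuple(d["betas"])
    return TrainingConfig(**d)


def save_checkpoint(state: TrainState, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for prefix, params in (("g", state.generator.params()),
                           ("d", state.discriminator.params())):
        for i, p in enumerate(params):
            arrays[f"{prefix}_{i}"] = p.value
    for prefix, adam in (("mg", state.adam_g), ("md", state.adam_d)):
        st = adam.state()
        for i, (m, v) in enumerate(zip(st["m"], st["v"])):
            arrays[f"{prefix}_m{i}"] = m
            arrays[f"{prefix}_v{i}"] = v
    meta = {
        "config": _config_to_json(state.config),
        "step": state.step,
        "t_g": state.adam_g.t,
        "t_d": state.adam_d.t,
        "rng_state": state.rng.bit_generator.state,
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path) -> TrainState:
    with np.load(Path(path)) as blob:
        meta = json.loads(bytes(blob["meta"]).decode())
        config = _config_from_json(meta["config"])
        state = _init_state(config)
        for prefix, params in (("g", state.generator.params()),
                               ("d", state.discriminator.params())):
            for i, p in enumerate(params):
                stored = blob[f"{prefix}_{i}"]
                if stored.shape != p.value.shape:
                    raise ValueError(f"checkpoint/architecture mismatch on "
                                     f"{prefix}_{i}: {stored.shape} vs {p.value.shape}")
                p.value[...] = stored
        for prefix, adam, t_key in (("mg", state.adam_g, "t_g"), ("md", state.adam_d, "t_d")):
            adam.t = int(meta[t_key])
            for i in range(len(adam.m)):
                adam.m[i][...] = blob[f"{prefix}_m{i}"]
                adam.v[i][...] = blob[f"{prefix}_v{i}"]
    state.step = int(meta["step"])
    state.rng.bit_generator.state = meta["rng_state"]
    return state
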