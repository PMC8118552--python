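"""Conditional GAN over the autoencoder latent space.

The generator maps (32-d uniform(-1,1) noise, K-d condition profile) to a
64-d latent vector; the discriminator scores (latent, condition) pairs as
real or generated. Training is the standard alternating scheme with the
non-saturating generator objective: the discriminator minimizes

    L_D = mean[ -log D(z_i) - log(1 - D(G(r_i))) ]

and the generator minimizes ``-mean log D(G(r_i))`` (equivalently maximizes
the printed objective ``mean log D(G(r_i))``). Real latent encodings enter
only the discriminator path; the generator learns purely through the
discriminator's gradients, so it never observes encodings of real cells.

Working in the 64-d latent space rather than gene space sidesteps GAN
instability in high dimensions; generated latents are decoded to expression
profiles by the autoencoder's decoder afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import Adam, Dense, Sequential

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "GanTrainConfig",
    "GeneratorModel", "DiscriminatorModel",
    "discriminator_loss", "generator_loss",
    "train_cgan", "generate_latents", "GanDivergence",
]

PROB_CLIP = 1e-7  # probability clipping before logs


@dataclass
class GeneratorSpec:
    noise_dim: int = 32
    condition_dim: int = 8
    hidden_dims: tuple = (256, 512)
    output_dim: int = 64  # autoencoder latent dimension; linear output


@dataclass
class DiscriminatorSpec:
    latent_dim: int = 64
    condition_dim: int = 8
    hidden_dims: tuple = (512,)


@dataclass
class GanTrainConfig:
    learning_rate: float = 5e-5
    max_epochs: int = 50_000
    batch_size: int = 128
    seed: int = 0
    d_steps_per_g_step: int = 1
    #: epochs over which both losses must plateau (relative change < plateau_tol)
    #: before stopping early; also the window for the divergence detector
    equilibrium_window: int = 500
    plateau_tol: float = 1e-4

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class GanDivergence(RuntimeError):
    """Raised when GAN training collapses (non-finite loss or pinned D)."""

    def __init__(self, message: str, history: pd.DataFrame):
        super().__init__(message)
        self.history = history


def discriminator_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """Mean of -log D(real) - log(1 - D(fake)) with probability clipping."""
    d_real = np.asarray(d_real, dtype=float).ravel()
    d_fake = np.asarray(d_fake, dtype=float).ravel()
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("empty batch")
    p = np.clip(d_real, PROB_CLIP, 1 - PROB_CLIP)
    q = np.clip(d_fake, PROB_CLIP, 1 - PROB_CLIP)
    return float(np.mean(-np.log(p) - np.log(1.0 - q)))


def generator_loss(d_fake: np.ndarray) -> float:
    """Non-saturating generator loss ``-mean log D(fake)`` (minimized).

    The maximized objective ``mean log D(fake)`` is its negation.
    """
    d_fake = np.asarray(d_fake, dtype=float).ravel()
    if d_fake.size == 0:
        raise ValueError("empty batch")
    q = np.clip(d_fake, PROB_CLIP, 1 - PROB_CLIP)
    return float(-np.mean(np.log(q)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class GeneratorModel:
    """Latent-space generator conditioned on an adjacent profile."""

    def __init__(self, spec: GeneratorSpec, channel_ids, seed: int):
        self.spec = spec
        self.channel_ids = list(channel_ids)
        self.seed = seed
        rng = np.random.default_rng(seed)
        layers = []
        prev = spec.noise_dim + spec.condition_dim
        for h in spec.hidden_dims:
            layers.append(Dense(prev, h, "relu", rng))
            prev = h
        layers.append(Dense(prev, spec.output_dim, "linear", rng))
        self.net = Sequential(layers)

    def sample(self, profiles: np.ndarray, noise: np.ndarray,
               training: bool = False) -> np.ndarray:
        inp = np.concatenate([noise, profiles], axis=1)
        return self.net.forward(inp, training)


class DiscriminatorModel:
    """Scores (latent, condition) pairs; sigmoid output in (0,1)."""

    def __init__(self, spec: DiscriminatorSpec, seed: int):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        layers = []
        prev = spec.latent_dim + spec.condition_dim
        for h in spec.hidden_dims:
            layers.append(Dense(prev, h, "relu", rng))
            prev = h
        layers.append(Dense(prev, 1, "linear", rng))  # logit; sigmoid applied below
        self.net = Sequential(layers)

    def logits(self, latents: np.ndarray, profiles: np.ndarray,
               training: bool = False) -> np.ndarray:
        inp = np.concatenate([latents, profiles], axis=1)
        return self.net.forward(inp, training).ravel()

    def predict_proba(self, latents: np.ndarray, profiles: np.ndarray) -> np.ndarray:
        return _sigmoid(self.logits(latents, profiles))


def train_cgan(latents: np.ndarray, profiles, gspec: GeneratorSpec | None = None,
               dspec: DiscriminatorSpec | None = None,
               cfg: GanTrainConfig | None = None):
    """Adversarial training of generator and discriminator on real latents.

    ``profiles`` may be an :class:`~.preprocess.AdjacentProfiles` or a plain
    simplex array. Returns ``(generator, discriminator, history)`` where
    ``history`` has per-epoch L_D, L_G (both conventions) and the
    discriminator's mean output on real and generated batches.
    """
    weights = getattr(profiles, "weights", None)
    channel_ids = getattr(profiles, "channel_ids", None)
    if weights is None:
        weights = np.asarray(profiles, dtype=float)
        channel_ids = [f"channel_{k}" for k in range(weights.shape[1])]
    latents = np.asarray(latents, dtype=float)
    if latents.shape[0] != weights.shape[0]:
        raise ValueError("latents and profiles are not row-aligned")
    cfg = cfg or GanTrainConfig()
    gspec = gspec or GeneratorSpec(condition_dim=weights.shape[1],
                                   output_dim=latents.shape[1])
    dspec = dspec or DiscriminatorSpec(latent_dim=latents.shape[1],
                                       condition_dim=weights.shape[1])
    if gspec.output_dim != latents.shape[1] or dspec.latent_dim != latents.shape[1]:
        raise ValueError("latent dimension mismatch between specs and data")

    rng = np.random.default_rng(cfg.seed)
    gen = GeneratorModel(gspec, channel_ids, cfg.seed + 1)
    disc = DiscriminatorModel(dspec, cfg.seed + 2)
    g_opt = Adam(gen.net.params, cfg.learning_rate)
    d_opt = Adam(disc.net.params, cfg.learning_rate)

    n = latents.shape[0]
    bs = min(cfg.batch_size, n)
    records = []

    def d_update(zb, rb):
        m = zb.shape[0]
        noise = rng.uniform(-1.0, 1.0, size=(m, gspec.noise_dim))
        fake = gen.sample(rb, noise, training=False)
        # real pass
        logit_r = disc.logits(zb, rb, training=True)
        p_r = _sigmoid(logit_r)
        disc.net.backward(((p_r - 1.0) / m)[:, None])  # fused sigmoid+BCE
        d_grads_real = [g.copy() for g in disc.net.grads]
        # fake pass
        logit_f = disc.logits(fake, rb, training=True)
        p_f = _sigmoid(logit_f)
        disc.net.backward((p_f / m)[:, None])
        grads = [gr + gf for gr, gf in zip(d_grads_real, disc.net.grads)]
        d_opt.step(grads)
        return p_r, p_f

    def g_update(rb):
        m = rb.shape[0]
        noise = rng.uniform(-1.0, 1.0, size=(m, gspec.noise_dim))
        inp = np.concatenate([noise, rb], axis=1)
        fake = gen.net.forward(inp, training=True)
        logit_f = disc.logits(fake, rb, training=True)
        p_f = _sigmoid(logit_f)
        # non-saturating: minimize -log D(fake); grad at logit = (p - 1)/m
        dfake = disc.net.backward(((p_f - 1.0) / m)[:, None])[:, :gspec.output_dim]
        gen.net.backward(dfake)
        g_opt.step(gen.net.grads)
        return p_f

    window = cfg.equilibrium_window
    pinned = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        p_r_all, p_f_all = [], []
        for start in range(0, n, bs):
            batch = order[start:start + bs]
            zb, rb = latents[batch], weights[batch]
            for _ in range(cfg.d_steps_per_g_step):
                p_r, p_f = d_update(zb, rb)
            p_f_g = g_update(rb)
            p_r_all.append(p_r)
            p_f_all.append(p_f_g)
        p_r_all = np.concatenate(p_r_all)
        p_f_all = np.concatenate(p_f_all)
        ld = discriminator_loss(p_r_all, p_f_all)
        lg = generator_loss(p_f_all)
        records.append({"epoch": epoch, "loss_d": ld, "loss_g_min": lg,
                        "loss_g_objective": -lg,
                        "d_real_mean": float(p_r_all.mean()),
                        "d_fake_mean": float(p_f_all.mean())})
        if not (np.isfinite(ld) and np.isfinite(lg)):
            raise GanDivergence(f"non-finite GAN loss at epoch {epoch}",
                                pd.DataFrame(records))
        acc = 0.5 * (np.mean(p_r_all > 0.5) + np.mean(p_f_all <= 0.5))
        pinned = pinned + 1 if acc >= 1.0 else 0
        if pinned >= window:
            raise GanDivergence(
                f"discriminator accuracy pinned at 1.0 for {window} epochs",
                pd.DataFrame(records))
        if epoch >= 2 * window:
            recent = pd.DataFrame(records[-2 * window:])
            first = recent.iloc[:window][["loss_d", "loss_g_min"]].mean()
            second = recent.iloc[window:][["loss_d", "loss_g_min"]].mean()
            rel = np.abs(second - first) / np.maximum(np.abs(first), 1e-12)
            if (rel < cfg.plateau_tol).all():
                break

    return gen, disc, pd.DataFrame(records)


def generate_latents(generator: GeneratorModel, profiles: np.ndarray,
                     n_per_profile: int, seed: int = 0) -> np.ndarray:
    """Simulate latent encodings for each conditioning profile.

    Returns a ``(n_profiles, n_per_profile, latent_dim)`` tensor; noise is
    uniform(-1,1) per replicate and the whole draw is seed-deterministic.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    sums = profiles.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.flatnonzero(np.abs(sums - 1.0) > 1e-6)[0])
        raise ValueError(f"conditioning profile {bad} is off the simplex "
                         f"(sum={sums[bad]:.6f})")
    rng = np.random.default_rng(seed)
    p, k = profiles.shape
    noise = rng.uniform(-1.0, 1.0, size=(p, n_per_profile, generator.spec.noise_dim))
    rep = np.repeat(profiles, n_per_profile, axis=0)
    out = generator.sample(rep, noise.reshape(p * n_per_profile, -1))
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("generator produced non-finite latents")
    return out.reshape(p, n_per_profile, generator.spec.output_dim)
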