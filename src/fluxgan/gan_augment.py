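"""WGAN-GP augmentation of the minority expression class.

A Wasserstein GAN with gradient penalty learns the minority-class expression
distribution and synthesizes candidate profiles for downstream biological
filtration.  The generator maps a 100-d latent vector through widths
250 -> 500 -> 1000 to the gene dimension with a Tanh output; the critic
mirrors it (1000 -> 500 -> 250 -> 1, linear output).  Expression values are
min-max scaled per gene to [-1, 1] to match the Tanh range, and the critic
is trained with the interpolated-sample gradient penalty
``lambda * E[(||grad_xhat D(xhat)|| - 1)^2]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import SYNTHETIC, ExpressionMatrix
from .nn import MLP, Adam


@dataclass(frozen=True)
class GANConfig:
    z_dim: int = 100
    gen_hidden: tuple[int, ...] = (250, 500, 1000)
    critic_hidden: tuple[int, ...] = (1000, 500, 250)
    leaky_alpha: float = 0.2
    gp_lambda: float = 10.0
    lr: float = 1e-4
    betas: tuple[float, float] = (0.0, 0.9)
    epochs: int = 2000
    batch_size: int = 2
    critic_steps_per_gen: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (gradient-penalty pairs)")
        for name in ("z_dim", "gp_lambda", "lr", "epochs", "critic_steps_per_gen"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FeatureScaler:
    """Per-gene min-max scaling to [-1, 1]; constant genes map to -1 and are
    inverse-mapped back to their constant.  Inverse clamps to the training
    range."""

    minimum: np.ndarray
    maximum: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        return cls(minimum=X.min(axis=0), maximum=X.max(axis=0))

    @property
    def span(self) -> np.ndarray:
        return self.maximum - self.minimum

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.span > 0, self.span, 1.0)
        scaled = 2.0 * (X - self.minimum) / span - 1.0
        return np.where(self.span > 0, scaled, -1.0)

    def inverse_transform(self, Y: np.ndarray) -> np.ndarray:
        Y = np.clip(Y, -1.0, 1.0)
        return self.minimum + (Y + 1.0) / 2.0 * self.span


@dataclass
class GeneratorBundle:
    """A trained generator plus everything needed to emit expression rows."""

    net: MLP
    z_dim: int
    gene_ids: list[str]
    minority_label: str


def _interpolates(
    real: np.ndarray, fake: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    # one interpolation coefficient per row (standard WGAN-GP)
    u = rng.uniform(0.0, 1.0, size=(real.shape[0], 1))
    return u * real + (1.0 - u) * fake


def gradient_penalty(
    critic: MLP,
    real_batch: np.ndarray,
    fake_batch: np.ndarray,
    rng: np.random.Generator | int = 0,
    gp_lambda: float = 10.0,
) -> float:
    """gp_lambda * mean over interpolates of (||grad_x critic(x)||_2 - 1)^2."""
    if real_batch.shape != fake_batch.shape:
        raise ValueError(
            f"batch shape mismatch: {real_batch.shape} vs {fake_batch.shape}"
        )
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    xhat = _interpolates(real_batch, fake_batch, rng)
    cache: dict = {}
    critic.forward(xhat, cache)
    g = critic.input_gradient(cache)
    norms = np.linalg.norm(g, axis=1)
    return float(gp_lambda * np.mean((norms - 1.0) ** 2))


def _gp_with_param_grads(
    critic: MLP, xhat: np.ndarray, gp_lambda: float
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Penalty value and its gradient w.r.t. critic parameters."""
    cache: dict = {}
    critic.forward(xhat, cache)
    g = critic.input_gradient(cache)
    norms = np.linalg.norm(g, axis=1)
    safe = np.where(norms > 1e-12, norms, 1.0)
    penalty = float(gp_lambda * np.mean((norms - 1.0) ** 2))
    # d penalty / d g_b, rows with zero gradient norm contribute no direction
    r = (2.0 * gp_lambda / xhat.shape[0]) * ((norms - 1.0) / safe)[:, None] * g
    dWs, dbs = critic.gradient_norm_param_grads(cache, r)
    return penalty, dWs, dbs


def _sum_grads(*grad_lists):
    out = []
    for parts in zip(*grad_lists):
        total = parts[0].copy()
        for p in parts[1:]:
            total += p
        out.append(total)
    return out


def build_generator(n_genes: int, cfg: GANConfig, rng: np.random.Generator) -> MLP:
    dims = (cfg.z_dim, *cfg.gen_hidden, n_genes)
    return MLP.create(dims, rng, leaky_alpha=cfg.leaky_alpha, output="tanh")


def build_critic(n_genes: int, cfg: GANConfig, rng: np.random.Generator) -> MLP:
    dims = (n_genes, *cfg.critic_hidden, 1)
    return MLP.create(dims, rng, leaky_alpha=cfg.leaky_alpha, output="linear")


def _train_scaled(
    X: np.ndarray, cfg: GANConfig
) -> tuple[MLP, MLP, pd.DataFrame]:
    """Core loop on data already scaled to [-1, 1]; X is samples x genes."""
    n_samples, n_genes = X.shape
    if n_samples < 2:
        raise ValueError("need >= 2 minority samples to train (interpolation pairs)")
    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(n_genes, cfg, rng)
    critic = build_critic(n_genes, cfg, rng)
    opt_c = Adam(critic.parameters(), lr=cfg.lr, beta1=cfg.betas[0], beta2=cfg.betas[1])
    opt_g = Adam(gen.parameters(), lr=cfg.lr, beta1=cfg.betas[0], beta2=cfg.betas[1])

    history = {"epoch": [], "critic_loss": [], "generator_loss": []}
    last_gen_loss = np.nan
    critic_counter = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_samples)
        epoch_closses = []
        for start in range(0, n_samples, cfg.batch_size):
            real = X[order[start : start + cfg.batch_size]]
            B = real.shape[0]
            z = rng.standard_normal((B, cfg.z_dim))
            fake = gen.forward(z)

            # critic update: minimize E[D(fake)] - E[D(real)] + GP
            cache_f: dict = {}
            out_f = critic.forward(fake, cache_f)
            dW_f, db_f, _ = critic.backward(cache_f, np.full_like(out_f, 1.0 / B))
            cache_r: dict = {}
            out_r = critic.forward(real, cache_r)
            dW_r, db_r, _ = critic.backward(cache_r, np.full_like(out_r, -1.0 / B))
            xhat = _interpolates(real, fake, rng)
            gp, dW_p, db_p = _gp_with_param_grads(critic, xhat, cfg.gp_lambda)
            closs = float(out_f.mean() - out_r.mean() + gp)
            opt_c.step(_sum_grads(dW_f, dW_r, dW_p) + _sum_grads(db_f, db_r, db_p))
            epoch_closses.append(closs)

            critic_counter += 1
            if critic_counter % cfg.critic_steps_per_gen == 0:
                # generator update: minimize -E[D(G(z))]
                z = rng.standard_normal((cfg.batch_size, cfg.z_dim))
                cache_g: dict = {}
                fake = gen.forward(z, cache_g)
                cache_c: dict = {}
                out = critic.forward(fake, cache_c)
                _, _, grad_fake = critic.backward(
                    cache_c, np.full_like(out, -1.0 / out.shape[0])
                )
                dW_g, db_g, _ = gen.backward(cache_g, grad_fake)
                opt_g.step(dW_g + db_g)
                last_gen_loss = float(-out.mean())

        history["epoch"].append(epoch)
        history["critic_loss"].append(float(np.mean(epoch_closses)))
        history["generator_loss"].append(last_gen_loss)

    return gen, critic, pd.DataFrame(history)


def train_wgan_gp(
    data: ExpressionMatrix, config: GANConfig
) -> tuple[GeneratorBundle, FeatureScaler, pd.DataFrame]:
    """Train on a minority-class expression matrix; returns the generator
    bundle, the fitted scaler and the per-epoch loss history."""
    labels = set(data.labels.values())
    if len(labels) != 1:
        raise ValueError(f"training data must hold a single class, got {sorted(labels)}")
    X = data.values.to_numpy().T  # samples x genes
    scaler = FeatureScaler.fit(X)
    gen, _, history = _train_scaled(scaler.transform(X), config)
    bundle = GeneratorBundle(
        net=gen,
        z_dim=config.z_dim,
        gene_ids=data.gene_ids,
        minority_label=labels.pop(),
    )
    return bundle, scaler, history


def sample_synthetic(
    generator: GeneratorBundle,
    scaler: FeatureScaler,
    n: int,
    seed: int = 0,
    sample_prefix: str = "SYN",
) -> ExpressionMatrix:
    """Draw ``n`` synthetic minority profiles in the original expression
    space (inverse-scaled, clipped at 0)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, generator.z_dim))
    scaled = generator.net.forward(z)
    X = np.clip(scaler.inverse_transform(scaled), 0.0, None)
    samples = [f"{sample_prefix}{i:04d}" for i in range(n)]
    df = pd.DataFrame(X.T, index=generator.gene_ids, columns=samples)
    return ExpressionMatrix(
        values=df,
        labels={s: generator.minority_label for s in samples},
        origin={s: SYNTHETIC for s in samples},
    )


def save_generator(bundle: GeneratorBundle, scaler: FeatureScaler, path) -> None:
    """Serialize generator weights + scaler to one portable .npz file."""
    meta = {
        "z_dim": bundle.z_dim,
        "gene_ids": bundle.gene_ids,
        "minority_label": bundle.minority_label,
        "leaky_alpha": bundle.net.leaky_alpha,
        "n_layers": bundle.net.n_layers,
    }
    arrays = {"__meta__": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for i, (W, b) in enumerate(zip(bundle.net.weights, bundle.net.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    arrays["scaler_min"] = scaler.minimum
    arrays["scaler_max"] = scaler.maximum
    np.savez(path, **arrays)


def load_generator(path) -> tuple[GeneratorBundle, FeatureScaler]:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    weights = [data[f"W{i}"] for i in range(meta["n_layers"])]
    biases = [data[f"b{i}"] for i in range(meta["n_layers"])]
    net = MLP(weights=weights, biases=biases, leaky_alpha=meta["leaky_alpha"], output="tanh")
    bundle = GeneratorBundle(
        net=net,
        z_dim=meta["z_dim"],
        gene_ids=list(meta["gene_ids"]),
        minority_label=meta["minority_label"],
    )
    scaler = FeatureScaler(minimum=data["scaler_min"], maximum=data["scaler_max"])
    return bundle, scaler
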