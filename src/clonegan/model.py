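"""Adversarial autoencoder linking copy-number profiles to expression data.

An encoder maps each DNA cell's preprocessed copy-number vector x to a
low-dimensional latent z; a decoder reconstructs x from z; a generator
produces a synthetic expression vector from the same z; and a discriminator
is trained to tell generated expression vectors from real (unpaired)
scRNA-seq cells.  The joint objective is

    L = L_adv(y, z; G, D) + lambda * L_rec(x, x_hat)

with the GAN value function L_adv = E[log D(y)] + E[log(1 - D(G(z)))] and
the scaled squared reconstruction error L_rec = ||x - x_hat||^2 / (2M).
Because the discriminator pushes the generated expression distribution
toward the real one, clonal structure visible in expression space is
impressed onto the latent representation even where the copy-number signal
is noisy.

Training stability follows common GAN practice: a FIFO buffer of previously
generated samples is re-used for discriminator updates (each fresh sample
is used directly with probability 0.5, otherwise a stored sample is played
back and replaced), and the generator's own update uses the non-saturating
objective by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ProcessedMatrix
from .nn import MLP, Adam, make_mlp

EPS_CLAMP = 1e-7


@dataclass
class ModelConfig:
    """Hyper-parameters of the adversarial autoencoder.

    Defaults follow the reference configuration: four hidden layers of
    512/256/128/64 units, latent dimension 3, lambda 5, a 64-sample buffer
    with 50% fresh-sample usage, and Adam with betas (0.5, 0.999).
    """

    cn_dim: int = 1024
    rna_dim: int = 1024
    hidden_sizes: tuple[int, ...] = (512, 256, 128, 64)
    latent_dim: int = 3
    lambda_weight: float = 5.0
    learning_rate: float = 1e-3
    epochs: int = 150
    dna_batch: int = 64
    buffer_size: int = 64
    buffer_use_prob: float = 0.5
    leaky_slope: float = 0.2
    adam_betas: tuple[float, float] = (0.9, 0.999)
    saturating_generator: bool = False
    adversarial: bool = True  # False -> plain autoencoder ablation
    ema_decay: float | None = 0.995  # EMA of encoder weights for inference
    embed_avg_epochs: int = 0  # average embeddings over the last k epochs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.latent_dim >= self.hidden_sizes[-1]:
            raise ValueError("latent_dim must be in [1, last hidden size)")
        if self.cn_dim < self.latent_dim or self.rna_dim < self.latent_dim:
            raise ValueError("input dims must be at least latent_dim")
        if self.dna_batch not in (32, 64, 128):
            raise ValueError("dna_batch must be one of 32, 64, 128")
        if self.buffer_size < 1:
            raise ValueError("buffer_size must be >= 1")
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be non-negative")
        if not 0.0 <= self.buffer_use_prob <= 1.0:
            raise ValueError("buffer_use_prob must be in [0, 1]")


class SampleBuffer:
    """FIFO-replaceable pool of previously generated expression vectors.

    While filling, every fresh sample is stored and returned.  Once full,
    a fresh sample is returned unchanged with probability ``use_prob``;
    otherwise a uniformly chosen stored sample is returned and replaced by
    the fresh one.  Capacity is never exceeded.
    """

    def __init__(self, capacity: int, use_prob: float = 0.5):
        self.capacity = capacity
        self.use_prob = use_prob
        self.samples: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self.samples)

    def draw(self, fresh: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if len(self.samples) < self.capacity:
            self.samples.append(fresh.copy())
            return fresh
        if rng.random() < self.use_prob:
            return fresh
        idx = int(rng.integers(len(self.samples)))
        stored = self.samples[idx]
        self.samples[idx] = fresh.copy()
        return stored

    def draw_batch(self, fresh: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return np.stack([self.draw(row, rng) for row in fresh])


@dataclass
class ModelState:
    """Weights of the four networks plus the generated-sample buffer."""

    encoder: MLP
    decoder: MLP
    generator: MLP
    discriminator: MLP
    buffer: SampleBuffer
    config: ModelConfig

    def state_dict(self) -> dict:
        return {
            "encoder": self.encoder.state_dict(),
            "decoder": self.decoder.state_dict(),
            "generator": self.generator.state_dict(),
            "discriminator": self.discriminator.state_dict(),
        }


def save_checkpoint(state: ModelState, path) -> None:
    """Write all four networks' weights, the config and the buffer to one
    .npz archive."""
    import json

    from dataclasses import asdict

    arrays = {}
    for net in ("encoder", "decoder", "generator", "discriminator"):
        for k, v in getattr(state, net).state_dict().items():
            arrays[f"{net}/{k}"] = v
    for i, sample in enumerate(state.buffer.samples):
        arrays[f"buffer/{i}"] = sample
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(state.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> ModelState:
    """Rebuild a ModelState from a checkpoint written by save_checkpoint."""
    import json

    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["config_json"]).decode())
        for key in ("hidden_sizes", "adam_betas"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = ModelConfig(**cfg_dict)
        state = init_model(config)
        for net in ("encoder", "decoder", "generator", "discriminator"):
            prefix = f"{net}/"
            sd = {
                k[len(prefix):]: data[k]
                for k in data.files
                if k.startswith(prefix)
            }
            getattr(state, net).load_state_dict(sd)
        buffer_keys = sorted(
            (k for k in data.files if k.startswith("buffer/")),
            key=lambda k: int(k.split("/")[1]),
        )
        state.buffer.samples = [data[k].copy() for k in buffer_keys]
    return state


@dataclass
class LatentEmbedding:
    """Per-DNA-cell latent vectors, row order matching the input cells."""

    z_matrix: np.ndarray
    cell_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.z_matrix.shape


def init_model(config: ModelConfig) -> ModelState:
    """Build the four networks with He-initialized weights.

    Encoder: cn_dim -> hidden sizes -> latent (linear output, LeakyReLU +
    BatchNorm on hidden blocks).  Decoder and generator mirror the encoder
    (latent -> reversed hidden sizes -> cn_dim / rna_dim, linear outputs).
    Discriminator: rna_dim -> 32 -> 64 -> 1 with LeakyReLU hidden layers,
    no BatchNorm, sigmoid output.
    """
    ss = np.random.SeedSequence(config.seed, spawn_key=(0,))
    enc_rng, dec_rng, gen_rng, dis_rng = (
        np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(4)
    )
    hid = list(config.hidden_sizes)
    encoder = make_mlp(
        [config.cn_dim, *hid, config.latent_dim], enc_rng,
        leaky_slope=config.leaky_slope, batch_norm=True,
    )
    decoder = make_mlp(
        [config.latent_dim, *hid[::-1], config.cn_dim], dec_rng,
        leaky_slope=config.leaky_slope, batch_norm=True,
    )
    generator = make_mlp(
        [config.latent_dim, *hid[::-1], config.rna_dim], gen_rng,
        leaky_slope=config.leaky_slope, batch_norm=True,
    )
    discriminator = make_mlp(
        [config.rna_dim, 32, 64, 1], dis_rng,
        leaky_slope=config.leaky_slope, batch_norm=False,
        final_activation="sigmoid",
    )
    return ModelState(
        encoder=encoder,
        decoder=decoder,
        generator=generator,
        discriminator=discriminator,
        buffer=SampleBuffer(config.buffer_size, config.buffer_use_prob),
        config=config,
    )


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray, m: int | None = None) -> float:
    """Scaled squared error ||x - x_hat||^2 / (2M), averaged over a batch."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_hat = np.atleast_2d(np.asarray(x_hat, dtype=float))
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    m = x.shape[1] if m is None else m
    per_row = np.sum((x - x_hat) ** 2, axis=1) / (2.0 * m)
    return float(per_row.mean())


def adversarial_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """GAN value function mean(log D(y)) + mean(log(1 - D(G(z)))).

    Discriminator outputs are clamped to [eps, 1 - eps] before the logs,
    so the value is always finite.  The discriminator ascends this value;
    the generator descends its second term.
    """
    d_real = np.clip(np.atleast_1d(np.asarray(d_real, dtype=float)),
                     EPS_CLAMP, 1.0 - EPS_CLAMP)
    d_fake = np.clip(np.atleast_1d(np.asarray(d_fake, dtype=float)),
                     EPS_CLAMP, 1.0 - EPS_CLAMP)
    return float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))


def combined_loss(adv: float, rec: float, lambda_weight: float) -> float:
    """Joint objective adv + lambda * rec."""
    if lambda_weight < 0:
        raise ValueError("lambda_weight must be non-negative")
    return float(adv + lambda_weight * rec)


def batch_sizes(n_dna: int, n_rna: int, dna_batch: int) -> tuple[int, int]:
    """Match the RNA batch size to the DNA batch by the dataset-size ratio."""
    if n_dna < 1 or n_rna < 1 or dna_batch < 1:
        raise ValueError("counts must be positive")
    rna_batch = int(round(dna_batch * n_rna / n_dna))
    rna_batch = max(1, min(rna_batch, n_rna))
    return dna_batch, rna_batch


def _clamped_log_grad(d: np.ndarray, sign: float, n: int) -> np.ndarray:
    """Gradient of -(sign/n) * sum log(term) wrt the raw discriminator output,
    where term = d (sign=+1 on real/fresh path) or 1-d (sign=-1 path handled
    by caller); zero where the clamp is active."""
    inside = (d > EPS_CLAMP) & (d < 1.0 - EPS_CLAMP)
    g = np.zeros_like(d)
    g[inside] = sign / (np.clip(d[inside], EPS_CLAMP, 1 - EPS_CLAMP) * n)
    return g


def train(
    state: ModelState,
    xp: ProcessedMatrix,
    yp: ProcessedMatrix,
    config: ModelConfig | None = None,
) -> tuple[ModelState, LatentEmbedding, list[dict]]:
    """Train the adversarial autoencoder and return embeddings for all cells.

    Each epoch iterates over shuffled DNA mini-batches; RNA batches (sized by
    the dataset-size ratio) are drawn by cycling an independently shuffled
    RNA index.  Per iteration: (i) the discriminator ascends the GAN value
    function on a real batch and a buffer-mediated fake batch; (ii) the
    encoder, decoder and generator descend the combined objective, with the
    generator term in non-saturating form unless configured otherwise.
    With ``config.adversarial=False`` only the reconstruction term is
    trained (plain-autoencoder ablation).

    Returns the trained state, the latent embedding (evaluation mode), and a
    per-epoch log of adversarial loss, reconstruction loss and discriminator
    accuracy.
    """
    cfg = config or state.config
    X = np.asarray(xp.values, dtype=float)
    Y = np.asarray(yp.values, dtype=float)
    if X.shape[1] != cfg.cn_dim:
        raise ValueError(f"CN matrix has {X.shape[1]} features, expected {cfg.cn_dim}")
    if Y.shape[1] != cfg.rna_dim:
        raise ValueError(f"RNA matrix has {Y.shape[1]} features, expected {cfg.rna_dim}")
    n_dna, n_rna = X.shape[0], Y.shape[0]
    dna_b, rna_b = batch_sizes(n_dna, n_rna, min(cfg.dna_batch, n_dna))

    ss = np.random.SeedSequence(cfg.seed, spawn_key=(1,))
    shuffle_rng, buffer_rng = (
        np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(2)
    )

    opt_ae = Adam(
        [state.encoder, state.decoder] + ([state.generator] if cfg.adversarial else []),
        lr=cfg.learning_rate, betas=cfg.adam_betas,
    )
    opt_d = Adam([state.discriminator], lr=cfg.learning_rate, betas=cfg.adam_betas)

    log: list[dict] = []
    rna_order = shuffle_rng.permutation(n_rna)
    rna_pos = 0

    # EMA of encoder weights: the minimax game keeps the last iterate
    # oscillating, so inference uses a smoothed trajectory average
    ema = state.encoder.state_dict() if cfg.ema_decay is not None else None
    z_sum, z_count = None, 0

    def next_rna_batch() -> np.ndarray:
        nonlocal rna_order, rna_pos
        idx = []
        while len(idx) < rna_b:
            if rna_pos >= n_rna:
                rna_order = shuffle_rng.permutation(n_rna)
                rna_pos = 0
            take = min(rna_b - len(idx), n_rna - rna_pos)
            idx.extend(rna_order[rna_pos:rna_pos + take])
            rna_pos += take
        return Y[np.asarray(idx)]

    for epoch in range(cfg.epochs):
        dna_order = shuffle_rng.permutation(n_dna)
        adv_vals, rec_vals, d_accs = [], [], []
        for start in range(0, n_dna - dna_b + 1, dna_b):
            xb = X[dna_order[start:start + dna_b]]

            if cfg.adversarial:
                # --- discriminator step (ascend the value function) ---
                yb = next_rna_batch()
                z = state.encoder.forward(xb, train=True)
                fake = state.generator.forward(z, train=True)
                fake_used = state.buffer.draw_batch(fake, buffer_rng)

                d_real = state.discriminator.forward(yb, train=True)
                grad_real = -_clamped_log_grad(d_real, 1.0, d_real.shape[0])
                opt_d.zero_grad()
                state.discriminator.backward(grad_real)
                d_fake = state.discriminator.forward(fake_used, train=True)
                one_minus = 1.0 - d_fake
                grad_fake = _clamped_log_grad(one_minus, 1.0, d_fake.shape[0])
                # d/dd log(1-d) = -1/(1-d); minimizing the negated value fn
                state.discriminator.backward(grad_fake)
                opt_d.step()

                adv_vals.append(
                    adversarial_loss(d_real.ravel(), d_fake.ravel())
                )
                d_accs.append(
                    0.5 * float((d_real > 0.5).mean())
                    + 0.5 * float((d_fake <= 0.5).mean())
                )

            # --- joint encoder/decoder(/generator) step ---
            opt_ae.zero_grad()
            z = state.encoder.forward(xb, train=True)
            x_hat = state.decoder.forward(z, train=True)
            resid = x_hat - xb
            rec = float(np.sum(resid**2) / (2.0 * cfg.cn_dim * xb.shape[0]))
            rec_vals.append(rec)
            grad_xhat = cfg.lambda_weight * resid / (cfg.cn_dim * xb.shape[0])
            grad_z = state.decoder.backward(grad_xhat)

            if cfg.adversarial:
                fake = state.generator.forward(z, train=True)
                d_gen = state.discriminator.forward(fake, train=True)
                if cfg.saturating_generator:
                    # descend mean log(1 - D(G(z)))
                    grad_d = _clamped_log_grad(1.0 - d_gen, -1.0, d_gen.shape[0])
                else:
                    # non-saturating: descend -mean log D(G(z))
                    grad_d = _clamped_log_grad(d_gen, -1.0, d_gen.shape[0])
                grad_fake = state.discriminator.backward(grad_d)
                grad_z = grad_z + state.generator.backward(grad_fake)

            state.encoder.backward(grad_z)
            opt_ae.step()

            if ema is not None:
                d = cfg.ema_decay
                for k, v in state.encoder.state_dict().items():
                    ema[k] = d * ema[k] + (1.0 - d) * v

            if not (np.isfinite(rec) and (not adv_vals or np.isfinite(adv_vals[-1]))):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch start {start}"
                )

        log.append({
            "epoch": epoch,
            "adv_loss": float(np.mean(adv_vals)) if adv_vals else float("nan"),
            "rec_loss": float(np.mean(rec_vals)) if rec_vals else float("nan"),
            "d_accuracy": float(np.mean(d_accs)) if d_accs else float("nan"),
            "buffer_occupancy": len(state.buffer),
        })

        if cfg.embed_avg_epochs > 0 and epoch >= cfg.epochs - cfg.embed_avg_epochs:
            # per-cell trajectory average over the final epochs: cells that
            # oscillate around a cluster core settle onto it
            snap = state.encoder.forward(X, train=False)
            if z_sum is None:
                z_sum, z_count = snap, 1
            else:
                z_sum, z_count = z_sum + snap, z_count + 1

    if ema is not None and cfg.epochs > 0:
        state.encoder.load_state_dict(ema)
    if z_sum is not None:
        z = z_sum / z_count
        if not np.all(np.isfinite(z)):
            raise FloatingPointError("non-finite latent representation")
        embedding = LatentEmbedding(z_matrix=z, cell_ids=list(xp.cell_ids))
    else:
        embedding = encode(state, xp)
    return state, embedding, log


def encode(state: ModelState, xp: ProcessedMatrix) -> LatentEmbedding:
    """Deterministic forward pass through the encoder in evaluation mode."""
    X = np.asarray(xp.values, dtype=float)
    if X.shape[1] != state.config.cn_dim:
        raise ValueError(
            f"CN matrix has {X.shape[1]} features, expected {state.config.cn_dim}"
        )
    z = state.encoder.forward(X, train=False)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite latent representation")
    return LatentEmbedding(z_matrix=z, cell_ids=list(xp.cell_ids))


def discriminator_accuracy(
    state: ModelState, y_real: np.ndarray, y_fake: np.ndarray
) -> float:
    """Held-out real/fake classification accuracy at threshold 0.5."""
    d_real = state.discriminator.forward(np.atleast_2d(y_real), train=False)
    d_fake = state.discriminator.forward(np.atleast_2d(y_fake), train=False)
    return 0.5 * float((d_real > 0.5).mean()) + 0.5 * float((d_fake <= 0.5).mean())
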