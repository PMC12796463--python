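"""PC-VAE architecture: permutation-invariant encoder, Gaussian latent space,
expanding point-cloud decoder.

Encoder: every localization is transformed independently by a shared-weight
MLP stack (64 -> 128 -> 1024 channels, each layer followed by batch
normalization and ReLU); mean pooling over the points produces one global
1024-vector per particle, which two separate MLP heads map to the latent mean
and log-variance. Because the per-point transform is shared and the pooling is
symmetric, the encoding is invariant to any permutation of the input points.

Decoder: fully connected layers (256 -> 512 -> 1024, Tanh + batch norm) expand
the latent vector; a learned linear skip projection of z is added at the
1024-neuron layer. The global vector is tiled into a fixed-length point
sequence, concatenated with a learned per-index embedding, passed through two
1024-channel pointwise (kernel-size-1) convolutions, a 4-head self-attention
over the point axis with a residual connection, and a final linear map to p
coordinates with Tanh output, so every generated coordinate lies in (-1, 1).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``n_output_points`` is the fixed reconstruction size N_s; the Chamfer loss
    tolerates input/reconstruction size mismatch, so N_s is decoupled from the
    localization count of any particle.
    """

    p: int = 2
    d: int = 8
    encoder_widths: tuple[int, ...] = (64, 128, 1024)
    decoder_fc_widths: tuple[int, ...] = (256, 512, 1024)
    n_attention_heads: int = 4
    n_output_points: int = 128
    index_embed_dim: int = 32
    batchnorm: bool = True

    def __post_init__(self):
        if self.p not in (2, 3):
            raise ValueError("p must be 2 or 3")
        if self.d < 1:
            raise ValueError("latent dimension d must be >= 1")
        if any(w <= 0 for w in self.encoder_widths + self.decoder_fc_widths):
            raise ValueError("all layer widths must be positive")
        if self.decoder_fc_widths[-1] % self.n_attention_heads:
            raise ValueError("attention heads must divide the channel width")
        if self.n_output_points < 1:
            raise ValueError("n_output_points must be >= 1")


@dataclass(frozen=True)
class LatentCode:
    """Per-particle posterior: mean, standard deviation, optional sample."""

    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray | None = None

    def __post_init__(self):
        if np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("sigma must be strictly positive")


class PointNetEncoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        widths = (cfg.p,) + tuple(cfg.encoder_widths)
        self.layers = [nn.Linear(a, b, rng) for a, b in zip(widths, widths[1:])]
        self.norms = [nn.BatchNorm1d(w) if cfg.batchnorm else nn.Identity()
                      for w in cfg.encoder_widths]
        head_width = 512
        feat = cfg.encoder_widths[-1]
        self.mu_head = [nn.Linear(feat, head_width, rng),
                        nn.Linear(head_width, cfg.d, rng)]
        self.logvar_head = [nn.Linear(feat, head_width, rng),
                            nn.Linear(head_width, cfg.d, rng)]

    def point_features(self, flat_points: Tensor) -> Tensor:
        """Shared-weight per-point MLP stack on a (total_points, p) array."""
        h = flat_points
        for lin, norm in zip(self.layers, self.norms):
            h = ag.relu(norm(lin(h)))
        return h

    def _heads(self, pooled: Tensor) -> tuple[Tensor, Tensor]:
        mu = self.mu_head[1](ag.relu(self.mu_head[0](pooled)))
        logvar = self.logvar_head[1](ag.relu(self.logvar_head[0](pooled)))
        return mu, logvar

    def forward_batch(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Encode a (B, N, p) batch of equal-size particles -> (mu, logvar)."""
        b, n, p = x.shape
        h = self.point_features(ag.reshape(x, (b * n, p)))
        pooled = ag.tmean(ag.reshape(h, (b, n, -1)), axis=1)
        return self._heads(pooled)

    def forward_ragged(self, flat_points: Tensor, lengths) -> tuple[Tensor, Tensor]:
        """Encode particles of unequal size given concatenated points."""
        h = self.point_features(flat_points)
        pooled = ag.segment_mean(h, lengths)
        return self._heads(pooled)


class PointCloudDecoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        widths = (cfg.d,) + tuple(cfg.decoder_fc_widths)
        self.fc = [nn.Linear(a, b, rng) for a, b in zip(widths, widths[1:])]
        self.fc_norms = [nn.BatchNorm1d(w) if cfg.batchnorm else nn.Identity()
                         for w in cfg.decoder_fc_widths]
        channels = cfg.decoder_fc_widths[-1]
        self.skip = nn.Linear(cfg.d, channels, rng)
        self.index_embed = nn.Parameter(
            rng.uniform(-0.1, 0.1, (cfg.n_output_points, cfg.index_embed_dim)))
        self.conv1 = nn.Linear(channels + cfg.index_embed_dim, channels, rng)
        self.conv2 = nn.Linear(channels, channels, rng)
        self.conv_norms = [nn.BatchNorm1d(channels) if cfg.batchnorm
                           else nn.Identity() for _ in range(2)]
        self.attention = nn.MultiheadSelfAttention(
            channels, cfg.n_attention_heads, rng)
        self.out = nn.Linear(channels, cfg.p, rng)

    def forward_batch(self, z: Tensor) -> Tensor:
        """Decode a (B, d) latent batch into (B, N_s, p) point clouds."""
        cfg = self.cfg
        b = z.shape[0]
        ns = cfg.n_output_points
        h = z
        for lin, norm in zip(self.fc, self.fc_norms):
            h = ag.tanh(norm(lin(h)))
        h = ag.add(h, self.skip(z))                   # (B, C)
        channels = cfg.decoder_fc_widths[-1]
        # tile the global feature along a fixed-length point axis and attach a
        # learned per-index embedding so the pointwise convs can differentiate
        # the output points
        tiled = ag.broadcast_to(ag.reshape(h, (b, 1, channels)),
                                (b, ns, channels))
        emb = ag.broadcast_to(
            ag.reshape(self.index_embed, (1, ns, cfg.index_embed_dim)),
            (b, ns, cfg.index_embed_dim))
        h = ag.concatenate([tiled, emb], axis=-1)
        h = ag.reshape(h, (b * ns, channels + cfg.index_embed_dim))
        h = ag.tanh(self.conv_norms[0](self.conv1(h)))
        h = ag.tanh(self.conv_norms[1](self.conv2(h)))
        h = ag.reshape(h, (b, ns, channels))
        h = ag.add(h, self.attention(h))
        return ag.tanh(self.out(h))


class PCVAEModel(nn.Module):
    """Encoder phi + decoder theta with their architecture configuration."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.encoder = PointNetEncoder(config, rng)
        self.decoder = PointCloudDecoder(config, rng)


# -- functional interface -----------------------------------------------------

def _check_points(model: PCVAEModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 2 or x.shape[1] != model.config.p:
        raise ValueError(
            f"expected (N, {model.config.p}) points, got shape {x.shape}")
    return x


def encode(model: PCVAEModel, x: np.ndarray) -> LatentCode:
    """Map one particle (normalized coordinates) to its posterior (mu, sigma).

    Uses every localization; evaluation-mode batch statistics make the result
    deterministic and independent of point order.
    """
    x = _check_points(model, x)
    was_training = model.training
    model.eval()
    try:
        with ag.no_grad():
            mu, logvar = model.encoder.forward_batch(Tensor(x[None]))
    finally:
        if was_training:
            model.train()
    mu = np.asarray(mu.data[0], dtype=np.float64)
    sigma = np.exp(0.5 * np.asarray(logvar.data[0], dtype=np.float64))
    return LatentCode(mu=mu, sigma=sigma)


def reparameterize(mu: np.ndarray, sigma: np.ndarray,
                   eps: np.ndarray) -> np.ndarray:
    """z = mu + sigma * eps (elementwise), the differentiable sampling form."""
    mu, sigma, eps = (np.asarray(a) for a in (mu, sigma, eps))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    if not (mu.shape == sigma.shape == eps.shape):
        raise ValueError("mu, sigma and eps must share their shape")
    return mu + sigma * eps


def decode(model: PCVAEModel, z: np.ndarray) -> np.ndarray:
    """Generate the fixed-size (N_s, p) reconstruction for one latent vector."""
    z = np.asarray(z, dtype=np.float32)
    if z.shape != (model.config.d,):
        raise ValueError(f"expected latent of length {model.config.d}, "
                         f"got shape {z.shape}")
    was_training = model.training
    model.eval()
    try:
        with ag.no_grad():
            recon = model.decoder.forward_batch(Tensor(z[None]))
    finally:
        if was_training:
            model.train()
    return np.asarray(recon.data[0], dtype=np.float64)


def forward(model: PCVAEModel, x: np.ndarray,
            rng: np.random.Generator | int | None = None,
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """encode -> reparameterize (one eps draw) -> decode, for one particle."""
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    code = encode(model, x)
    eps = rng.standard_normal(model.config.d)
    z = reparameterize(code.mu, code.sigma, eps)
    return decode(model, z), code.mu, code.sigma


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(model: PCVAEModel, path) -> None:
    """Single-archive checkpoint: config echo + all parameters and buffers."""
    arrays = {f"param:{k}": v.data for k, v in model.named_parameters()}
    arrays.update({f"buffer:{k}": v for k, v in model.named_buffers()})
    cfg = asdict(model.config)
    cfg["encoder_widths"] = list(cfg["encoder_widths"])
    cfg["decoder_fc_widths"] = list(cfg["decoder_fc_widths"])
    arrays["config_json"] = np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> PCVAEModel:
    with np.load(path) as archive:
        cfg_dict = json.loads(bytes(archive["config_json"]).decode())
        cfg_dict["encoder_widths"] = tuple(cfg_dict["encoder_widths"])
        cfg_dict["decoder_fc_widths"] = tuple(cfg_dict["decoder_fc_widths"])
        config = ModelConfig(**cfg_dict)
        model = PCVAEModel(config)
        params = dict(model.named_parameters())
        buffers = dict(model.named_buffers())
        for key in archive.files:
            if key.startswith("param:"):
                name = key[len("param:"):]
                if name not in params:
                    raise ValueError(f"checkpoint parameter {name!r} does not "
                                     "match the model architecture")
                params[name].data = archive[key].astype(np.float32)
            elif key.startswith("buffer:"):
                name = key[len("buffer:"):]
                _assign_buffer(model, name, archive[key])
    model.eval()
    return model


def _assign_buffer(module: nn.Module, dotted: str, value: np.ndarray) -> None:
    # resolve paths with list indices, e.g. "encoder.norms.0.running_mean"
    parts = dotted.split(".")
    obj = module
    for part in parts[:-1]:
        obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
    setattr(obj, parts[-1], value)
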