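"""U-Net backbone with bottleneck metadata fusion, plus symbolic layer tables.

The image path is a standard U-Net: encoder blocks of two 3×3 same-padding
convolutions + ReLU, 2×2 max pooling with channel doubling (64→128→256→512),
and a 1024-channel two-convolution bottleneck.  For a 224×224 input the
latent map is 7×7×1024: after the four width-doubling pools an extra
*width-preserving* max pool halves 14→7, and the decoder mirrors it with a
parameter-free nearest 2× upsample before the four transposed-convolution
blocks.  This keeps the latent at 7×7 while the trainable budget stays at
≈31M parameters.

The metadata branch embeds each categorical attribute group (4-dim lookup
per group by default), concatenates the embeddings, applies dense layers of
36 and s² units (49 for the 7×7 latent) with ReLU, and reshapes to s×s×1.
Fusion strategies:

* ``embedding_concat`` — channel concatenation at the bottleneck (default);
* ``onehot_dense``     — the raw 29-vector through the dense layers, then
                         concatenated (no embedding lookup);
* ``weighted``         — w_img·F_latent + w_meta·M_embed broadcast across
                         channels, with w_img + w_meta = 1;
* ``none``             — image-only U-Net.

With ``bayesian=True`` a dropout layer follows every two-convolution block,
kept active at inference for Monte Carlo Dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nn
from .nn import autograd as ag
from .data_model import MetadataSchema, default_schema

FUSION_STRATEGIES = ("none", "onehot_dense", "weighted", "embedding_concat")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    input_size: int = 224
    input_channels: int = 3
    encoder_widths: tuple[int, ...] = (64, 128, 256, 512)
    bottleneck_width: int = 1024
    n_pool: int = 5
    metadata_width: int = 29
    embed_dim: int = 4
    fusion_strategy: str = "embedding_concat"
    fusion_weights: tuple[float, float] | None = None  # (w_img, w_meta)
    dropout_rate: float = 0.5
    bayesian: bool = False
    out_channels: int = 1

    def __post_init__(self):
        if self.fusion_strategy not in FUSION_STRATEGIES:
            raise ConfigError(f"unknown fusion strategy {self.fusion_strategy!r}")
        if self.input_size % (2 ** self.n_pool):
            raise ConfigError(
                f"input_size {self.input_size} not divisible by 2^{self.n_pool}")
        if self.n_pool < len(self.encoder_widths):
            raise ConfigError("n_pool must be >= number of encoder blocks")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.fusion_strategy == "weighted":
            if self.fusion_weights is None:
                raise ConfigError("weighted fusion requires fusion_weights")
            w_img, w_meta = self.fusion_weights
            if w_img < 0 or w_meta < 0 or not np.isclose(w_img + w_meta, 1.0):
                raise ConfigError(
                    f"fusion weights must be non-negative and sum to 1, "
                    f"got {self.fusion_weights}")

    @property
    def bottleneck_size(self) -> int:
        """Spatial side length s of the latent map (input / 2^n_pool)."""
        return self.input_size // (2 ** self.n_pool)

    @property
    def n_extra_pools(self) -> int:
        return self.n_pool - len(self.encoder_widths)

    @property
    def meta_dense_widths(self) -> tuple[int, int]:
        """(36, s²): the second dense width generalizes 49 to any latent size."""
        return (36, self.bottleneck_size ** 2)

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("encoder_widths", "fusion_weights"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def tiny_config(**overrides) -> ModelConfig:
    """A reduced-width configuration for desk-scale experiments (32×32)."""
    base = dict(input_size=32, encoder_widths=(8, 16), bottleneck_width=32,
                n_pool=3, dropout_rate=0.1)
    base.update(overrides)
    return ModelConfig(**base)


# ---------------------------------------------------------------------
# symbolic description + parameter audit
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class LayerRecord:
    kind: str
    name: str
    input_shape: tuple
    output_shape: tuple
    n_params: int


@dataclass
class NetworkDescription:
    records: list[LayerRecord] = field(default_factory=list)

    def add(self, kind, name, in_shape, out_shape, n_params=0):
        self.records.append(LayerRecord(kind, name, tuple(in_shape),
                                        tuple(out_shape), int(n_params)))

    def extend(self, other: "NetworkDescription"):
        self.records.extend(other.records)

    @property
    def total_params(self) -> int:
        return sum(r.n_params for r in self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def count_parameters(description: NetworkDescription) -> int:
    """Total trainable parameters of a described network."""
    return int(description.total_params)


def _conv_params(cin, cout, k=3):
    return (k * k * cin + 1) * cout


def _dense_params(nin, nout):
    return (nin + 1) * nout


def build_encoder(cfg: ModelConfig) -> NetworkDescription:
    """Describe the contracting path + bottleneck (shapes are H×W×C)."""
    d = NetworkDescription()
    s, c = cfg.input_size, cfg.input_channels
    for i, w in enumerate(cfg.encoder_widths, start=1):
        d.add("conv3x3+relu", f"enc{i}_conv1", (s, s, c), (s, s, w), _conv_params(c, w))
        d.add("conv3x3+relu", f"enc{i}_conv2", (s, s, w), (s, s, w), _conv_params(w, w))
        if cfg.bayesian:
            d.add("dropout", f"enc{i}_dropout", (s, s, w), (s, s, w))
        d.add("maxpool2x2", f"enc{i}_pool", (s, s, w), (s // 2, s // 2, w))
        s, c = s // 2, w
    for j in range(cfg.n_extra_pools):
        d.add("maxpool2x2", f"extra_pool{j + 1}", (s, s, c), (s // 2, s // 2, c))
        s //= 2
    bw = cfg.bottleneck_width
    d.add("conv3x3+relu", "bottleneck_conv1", (s, s, c), (s, s, bw), _conv_params(c, bw))
    d.add("conv3x3+relu", "bottleneck_conv2", (s, s, bw), (s, s, bw), _conv_params(bw, bw))
    if cfg.bayesian:
        d.add("dropout", "bottleneck_dropout", (s, s, bw), (s, s, bw))
    return d


def build_metadata_branch(cfg: ModelConfig,
                          schema: MetadataSchema | None = None) -> NetworkDescription:
    """Describe the metadata path: embeddings → dense(36) → dense(s²) → s×s×1."""
    schema = schema or default_schema()
    if schema.total_width != cfg.metadata_width:
        raise ConfigError(
            f"schema width {schema.total_width} != cfg.metadata_width "
            f"{cfg.metadata_width}")
    d = NetworkDescription()
    s = cfg.bottleneck_size
    d1, d2 = cfg.meta_dense_widths
    if cfg.fusion_strategy == "onehot_dense":
        n_in = cfg.metadata_width
        d.add("dense+relu", "meta_dense1", (n_in,), (d1,), _dense_params(n_in, d1))
    else:
        for g in schema.groups:
            d.add("embedding", f"embed_{g.name}", (1,), (cfg.embed_dim,),
                  g.vocab * cfg.embed_dim)
        n_in = schema.n_groups * cfg.embed_dim
        d.add("concat", "embed_concat", (schema.n_groups, cfg.embed_dim), (n_in,))
        d.add("dense+relu", "meta_dense1", (n_in,), (d1,), _dense_params(n_in, d1))
    d.add("dense+relu", "meta_dense2", (d1,), (d2,), _dense_params(d1, d2))
    d.add("reshape", "meta_reshape", (d2,), (s, s, 1))
    return d


def build_decoder(cfg: ModelConfig) -> NetworkDescription:
    """Describe the expanding path back to input_size × input_size × out."""
    d = NetworkDescription()
    s = cfg.bottleneck_size
    c = cfg.bottleneck_width
    if cfg.fusion_strategy in ("embedding_concat", "onehot_dense"):
        c += 1  # fused metadata channel
    for j in range(cfg.n_extra_pools):
        d.add("upsample2x", f"extra_up{j + 1}", (s, s, c), (2 * s, 2 * s, c))
        s *= 2
    widths = list(cfg.encoder_widths)[::-1]
    for i, w in enumerate(widths, start=1):
        d.add("tconv2x2", f"dec{i}_upconv", (s, s, c), (2 * s, 2 * s, w),
              (2 * 2 * c + 1) * w)
        s *= 2
        d.add("concat", f"dec{i}_skip", (s, s, w), (s, s, 2 * w))
        d.add("conv3x3+relu", f"dec{i}_conv1", (s, s, 2 * w), (s, s, w),
              _conv_params(2 * w, w))
        d.add("conv3x3+relu", f"dec{i}_conv2", (s, s, w), (s, s, w),
              _conv_params(w, w))
        if cfg.bayesian:
            d.add("dropout", f"dec{i}_dropout", (s, s, w), (s, s, w))
        c = w
    d.add("conv1x1+sigmoid", "head", (s, s, c), (s, s, cfg.out_channels),
          _dense_params(c, cfg.out_channels))
    return d


def build_model(cfg: ModelConfig,
                schema: MetadataSchema | None = None) -> NetworkDescription:
    """Full symbolic description; total_params is the trainable count."""
    d = build_encoder(cfg)
    if cfg.fusion_strategy != "none":
        d.extend(build_metadata_branch(cfg, schema))
        s = cfg.bottleneck_size
        bw = cfg.bottleneck_width
        if cfg.fusion_strategy == "weighted":
            d.add("weighted_fusion", "fusion", (s, s, bw), (s, s, bw))
        else:
            d.add("concat_fusion", "fusion", (s, s, bw), (s, s, bw + 1))
    d.extend(build_decoder(cfg))
    return d


# ---------------------------------------------------------------------
# fusion as a standalone op
# ---------------------------------------------------------------------

def fuse(f_latent, m_embed, strategy: str,
         weights: tuple[float, float] | None = None):
    """Fuse a latent image block (N,C,s,s) with a metadata block (N,1,s,s)."""
    if strategy == "none":
        return f_latent
    if strategy in ("embedding_concat", "onehot_dense"):
        return ag.concat([ag.astensor(f_latent), ag.astensor(m_embed)], axis=1)
    if strategy == "weighted":
        if weights is None or not np.isclose(sum(weights), 1.0) or min(weights) < 0:
            raise ConfigError(f"weighted fusion needs weights summing to 1, got {weights}")
        w_img, w_meta = weights
        return w_img * ag.astensor(f_latent) + w_meta * ag.astensor(m_embed)
    raise ConfigError(f"unknown fusion strategy {strategy!r}")


# ---------------------------------------------------------------------
# runnable model
# ---------------------------------------------------------------------

class MetaUNet(nn.Module):
    """The runnable network; see module docstring for the architecture.

    Backbone layers are initialised before the metadata branch from one
    seeded generator, so two configs differing only in fusion strategy share
    identical backbone initial weights for the same seed.
    """

    def __init__(self, cfg: ModelConfig, schema: MetadataSchema | None = None,
                 seed: int = 0):
        self.cfg = cfg
        self.schema = schema or default_schema()
        if cfg.fusion_strategy != "none" and \
                self.schema.total_width != cfg.metadata_width:
            raise ConfigError(
                f"schema width {self.schema.total_width} != metadata_width "
                f"{cfg.metadata_width}")
        rng = np.random.default_rng(seed)

        # encoder
        self.enc_blocks = []
        c = cfg.input_channels
        for w in cfg.encoder_widths:
            self.enc_blocks.append([nn.Conv2d(c, w, rng=rng), nn.Conv2d(w, w, rng=rng)])
            c = w
        bw = cfg.bottleneck_width
        self.bottleneck = [nn.Conv2d(c, bw, rng=rng), nn.Conv2d(bw, bw, rng=rng)]

        # decoder
        c = bw + (1 if cfg.fusion_strategy in ("embedding_concat", "onehot_dense")
                  else 0)
        self.dec_up = []
        self.dec_blocks = []
        for w in reversed(cfg.encoder_widths):
            self.dec_up.append(nn.ConvTranspose2d(c, w, rng=rng))
            self.dec_blocks.append([nn.Conv2d(2 * w, w, rng=rng),
                                    nn.Conv2d(w, w, rng=rng)])
            c = w
        self.head = nn.Conv2d(c, cfg.out_channels, k=1, pad=0, rng=rng)

        # metadata branch (after the backbone: same-seed backbones align)
        self.embeddings = None
        self.meta_dense = None
        if cfg.fusion_strategy != "none":
            d1, d2 = cfg.meta_dense_widths
            if cfg.fusion_strategy == "onehot_dense":
                n_in = cfg.metadata_width
            else:
                self.embeddings = [nn.Embedding(g.vocab, cfg.embed_dim, rng=rng)
                                   for g in self.schema.groups]
                n_in = self.schema.n_groups * cfg.embed_dim
            self.meta_dense = [nn.Dense(n_in, d1, rng=rng), nn.Dense(d1, d2, rng=rng)]

    # -- forward --------------------------------------------------------
    def _metadata_block(self, metadata: np.ndarray):
        cfg = self.cfg
        n = metadata.shape[0]
        if cfg.fusion_strategy == "onehot_dense":
            for row in metadata:
                self.schema.validate(row)
            h = ag.astensor(np.asarray(metadata, float))
        else:
            idx = np.stack([self.schema.group_indices(row) for row in metadata])
            embs = [emb(idx[:, gi]) for gi, emb in enumerate(self.embeddings)]
            h = ag.concat(embs, axis=1)
        h = ag.relu(self.meta_dense[0](h))
        h = ag.relu(self.meta_dense[1](h))
        s = cfg.bottleneck_size
        return ag.reshape(h, (n, 1, s, s))

    def forward(self, images, metadata=None, stochastic: bool = False,
                rng: np.random.Generator | None = None):
        """Forward pass.

        ``images``: (N, C, H, W) array or Tensor.  ``stochastic`` keeps
        dropout sampling active (training or Monte Carlo inference); the
        draws come from ``rng``.
        """
        cfg = self.cfg
        drop = cfg.bayesian and stochastic and cfg.dropout_rate > 0
        if drop and rng is None:
            raise ValueError("stochastic forward pass requires an rng")

        x = ag.astensor(images)
        if x.shape[2] != cfg.input_size or x.shape[3] != cfg.input_size:
            raise ConfigError(
                f"expected {cfg.input_size}×{cfg.input_size} input, "
                f"got {x.shape[2]}×{x.shape[3]}")
        skips = []
        for conv1, conv2 in self.enc_blocks:
            x = ag.relu(conv2(ag.relu(conv1(x))))
            if drop:
                x = ag.dropout(x, cfg.dropout_rate, rng)
            skips.append(x)
            x = ag.maxpool2x(x)
        for _ in range(cfg.n_extra_pools):
            x = ag.maxpool2x(x)
        x = ag.relu(self.bottleneck[1](ag.relu(self.bottleneck[0](x))))
        if drop:
            x = ag.dropout(x, cfg.dropout_rate, rng)

        if cfg.fusion_strategy != "none":
            if metadata is None:
                raise ConfigError(
                    f"fusion strategy {cfg.fusion_strategy!r} requires metadata")
            m = self._metadata_block(np.asarray(metadata))
            x = fuse(x, m, cfg.fusion_strategy, cfg.fusion_weights)

        for _ in range(cfg.n_extra_pools):
            x = ag.upsample2x(x)
        for up, (conv1, conv2), skip in zip(self.dec_up, self.dec_blocks,
                                            reversed(skips)):
            x = up(x)
            x = ag.concat([x, _match_crop(skip, x)], axis=1)
            x = ag.relu(conv2(ag.relu(conv1(x))))
            if drop:
                x = ag.dropout(x, cfg.dropout_rate, rng)
        return ag.sigmoid(self.head(x))

    def predict(self, images, metadata=None) -> np.ndarray:
        """Deterministic per-pixel lesion probabilities, shape (N, H, W)."""
        out = self.forward(images, metadata, stochastic=False)
        return out.data[:, 0]


def _match_crop(skip, x):
    """Center-crop the skip tensor to x's spatial size (no-op when equal)."""
    sh, sw = skip.shape[2], skip.shape[3]
    xh, xw = x.shape[2], x.shape[3]
    if (sh, sw) == (xh, xw):
        return skip
    if sh < xh or sw < xw:
        raise ConfigError(
            f"skip connection {sh}×{sw} smaller than decoder map {xh}×{xw}")
    dy, dx = (sh - xh) // 2, (sw - xw) // 2
    # slicing a Tensor: implement via reshape-free crop on the tape
    return _crop(skip, dy, dx, xh, xw)


def _crop(t, dy, dx, h, w):
    t = ag.astensor(t)
    data = t.data[:, :, dy:dy + h, dx:dx + w]

    def backward(g):
        full = np.zeros_like(t.data)
        full[:, :, dy:dy + h, dx:dx + w] = g
        t._accumulate(full)

    return ag._make(data, (t,), backward)


def images_to_batch(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack LesionSamples into (images NCHW, masks NHW, metadata N×29)."""
    imgs = np.stack([s.image.transpose(2, 0, 1) for s in samples])
    masks = np.stack([s.mask for s in samples]).astype(float)
    meta = np.stack([s.metadata for s in samples])
    return imgs, masks, meta
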