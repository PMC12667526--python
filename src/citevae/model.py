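"""The multimodal VAE for paired CITE-seq RNA/ADT data.

Architecture, per cell:

  h_r = ReLU(align(Xr @ W_r) + b_r)        modality encoders with a
  h_a = ReLU(align(Xa @ W_a) + b_a)        learnable z-score alignment layer
  y   = w_r h_r + w_a h_a                  softmax-normalized adaptive fusion
  y'  = LayerNorm(y + Drop(MHA(y)))        multi-head self-attention over
                                           L feature-token subspaces
  mu, logvar = Drop(align(y' @ W) + b)     Gaussian head
  z   = mu + exp(logvar/2) * eps           reparameterized sample
  z'  = LayerNorm(z + Drop(MHA(z)))        decoder-side attention
  h   = ReLU(align(z' @ W_h) + b_h)        hidden layer symmetric to encoder
  Xr_hat, Xa_hat = linear(h)               modality-specific reconstructions

The alignment layer z-scores each cell across its features (with a small
epsilon stabilizer) and then applies learnable scale gamma and shift beta,
initialized to 1 and 0. Fusion weights start at raw logits 0, i.e. exactly
(0.5, 0.5) after the softmax. Three ablations are reachable by config:
concatenation fusion, no attention, no alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .autodiff import Tensor, as_tensor, concat

__all__ = [
    "ModelConfig",
    "AlignmentParams",
    "EncoderParams",
    "FusionWeights",
    "AttentionParams",
    "GaussianHead",
    "DecoderParams",
    "ModelState",
    "LatentResult",
    "feature_align",
    "layer_norm",
    "encode",
    "fuse",
    "mha_block",
    "to_gaussian",
    "sample_latent",
    "decode",
    "forward",
    "init_state",
]


@dataclass
class ModelConfig:
    """Hyperparameters and ablation switches.

    Defaults are the published operating point: 200 hidden units per
    encoder, a 100-dimensional latent, 4 attention heads, Adam at lr 0.01,
    KL weight alpha 1e-4, and a 50-epoch reconstruction-only pretrain
    followed by 100 joint epochs.
    """

    d_hidden: int = 200
    z_dim: int = 100
    n_head: int = 4
    n_tokens_enc: int = 10
    n_tokens_dec: int = 5
    dropout_p: float = 0.1
    lr: float = 0.01
    alpha: float = 1e-4
    pretrain_epochs: int = 50
    train_epochs: int = 100
    seed: int = 0
    fusion_mode: str = "adaptive"
    use_attention: bool = True
    use_alignment: bool = True
    eps: float = 1e-5
    dtype: str = "float32"

    @property
    def fused_dim(self) -> int:
        return self.d_hidden if self.fusion_mode == "adaptive" else 2 * self.d_hidden

    def validate(self) -> "ModelConfig":
        if self.fusion_mode not in ("adaptive", "concat"):
            raise ValueError(f"fusion_mode must be adaptive|concat, got {self.fusion_mode}")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must lie in [0, 1)")
        for dim, L, where in [
            (self.fused_dim, self.n_tokens_enc, "fused features"),
            (self.z_dim, self.n_tokens_dec, "latent"),
        ]:
            _check_divisible(dim, L, self.n_head, where)
        return self


def _check_divisible(dim: int, L: int, n_head: int, where: str):
    if dim % L != 0 or (dim // L) % n_head != 0:
        raise ValueError(
            f"{where}: dimension {dim} must split into {L} tokens whose "
            f"width is divisible by {n_head} heads "
            f"(dim={dim}, L={L}, n_head={n_head})"
        )


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class AlignmentParams:
    gamma: Tensor  # scale, init 1
    beta: Tensor   # shift, init 0


@dataclass
class EncoderParams:
    W: Tensor
    b: Tensor
    align: AlignmentParams


@dataclass
class FusionWeights:
    """Per-hidden-feature fusion logits, softmaxed pairwise per coordinate.

    Each of the D hidden coordinates carries its own (w_r, w_a) pair with
    w_r + w_a = 1; the scalar weights reported downstream are the means
    over coordinates. Both logit vectors start at 0, so every coordinate
    begins at exactly (0.5, 0.5).
    """

    raw_r: Tensor
    raw_a: Tensor

    def weights(self) -> tuple[float, float]:
        e_r, e_a = np.exp(self.raw_r.data), np.exp(self.raw_a.data)
        s = e_r + e_a
        return float(np.mean(e_r / s)), float(np.mean(e_a / s))


@dataclass
class AttentionParams:
    Wq: Tensor
    Wk: Tensor
    Wv: Tensor
    Wo: Tensor
    ln_gamma: Tensor
    ln_beta: Tensor


@dataclass
class GaussianHead:
    W_mu: Tensor
    b_mu: Tensor
    W_sigma: Tensor
    b_sigma: Tensor
    align_mu: AlignmentParams
    align_sigma: AlignmentParams


@dataclass
class DecoderParams:
    attention: AttentionParams
    W_hidden: Tensor
    b_hidden: Tensor
    align_hidden: AlignmentParams
    W_out_r: Tensor
    b_out_r: Tensor
    W_out_a: Tensor
    b_out_a: Tensor


@dataclass
class LatentResult:
    """Per-cell posterior parameters, sample and fusion weights."""

    mu: np.ndarray
    logvar: np.ndarray
    z: np.ndarray
    w_r: float
    w_a: float


@dataclass
class ModelState:
    config: ModelConfig
    encoder_r: EncoderParams
    encoder_a: EncoderParams
    fusion: FusionWeights
    attention: AttentionParams
    gauss: GaussianHead
    decoder: DecoderParams

    def named_parameters(self):
        """Yield (name, Tensor) for every learnable parameter."""

        def walk(prefix, obj):
            for f in fields(obj):
                value = getattr(obj, f.name)
                if isinstance(value, Tensor):
                    yield f"{prefix}{f.name}", value
                elif hasattr(value, "__dataclass_fields__"):
                    yield from walk(f"{prefix}{f.name}.", value)

        for group in ("encoder_r", "encoder_a", "fusion", "attention", "gauss", "decoder"):
            yield from walk(f"{group}.", getattr(self, group))

    def to_arrays(self) -> dict:
        return {name: np.asarray(t.data) for name, t in self.named_parameters()}

    def load_arrays(self, arrays: dict):
        for name, t in self.named_parameters():
            t.data = np.asarray(arrays[name], dtype=t.data.dtype)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _glorot(rng, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(
        rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype),
        requires_grad=True,
    )


def _zeros(shape, dtype):
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)


def _ones(shape, dtype):
    return Tensor(np.ones(shape, dtype=dtype), requires_grad=True)


def _alignment(dim, dtype) -> AlignmentParams:
    return AlignmentParams(gamma=_ones(dim, dtype), beta=_zeros(dim, dtype))


def _attention(rng, d_l, dim, dtype) -> AttentionParams:
    return AttentionParams(
        Wq=_glorot(rng, d_l, d_l, dtype),
        Wk=_glorot(rng, d_l, d_l, dtype),
        Wv=_glorot(rng, d_l, d_l, dtype),
        Wo=_glorot(rng, d_l, d_l, dtype),
        ln_gamma=_ones(dim, dtype),
        ln_beta=_zeros(dim, dtype),
    )


def init_state(config: ModelConfig, d_genes: int, d_adt: int, rng=None) -> ModelState:
    """Build a freshly initialized parameter set.

    Weight matrices are Glorot-uniform, biases zero, alignment scale/shift
    (1, 0), and both raw fusion logits 0 so the initial weights are exactly
    (0.5, 0.5).
    """
    config.validate()
    dtype = np.dtype(config.dtype)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    D, Z = config.d_hidden, config.z_dim
    fused = config.fused_dim
    return ModelState(
        config=config,
        encoder_r=EncoderParams(
            W=_glorot(rng, d_genes, D, dtype), b=_zeros(D, dtype),
            align=_alignment(D, dtype),
        ),
        encoder_a=EncoderParams(
            W=_glorot(rng, d_adt, D, dtype), b=_zeros(D, dtype),
            align=_alignment(D, dtype),
        ),
        fusion=FusionWeights(
            raw_r=_zeros(D, dtype),
            raw_a=_zeros(D, dtype),
        ),
        attention=_attention(rng, fused // config.n_tokens_enc, fused, dtype),
        gauss=GaussianHead(
            W_mu=_glorot(rng, fused, Z, dtype), b_mu=_zeros(Z, dtype),
            W_sigma=_glorot(rng, fused, Z, dtype), b_sigma=_zeros(Z, dtype),
            align_mu=_alignment(Z, dtype), align_sigma=_alignment(Z, dtype),
        ),
        decoder=DecoderParams(
            attention=_attention(rng, Z // config.n_tokens_dec, Z, dtype),
            W_hidden=_glorot(rng, Z, D, dtype), b_hidden=_zeros(D, dtype),
            align_hidden=_alignment(D, dtype),
            W_out_r=_glorot(rng, D, d_genes, dtype), b_out_r=_zeros(d_genes, dtype),
            W_out_a=_glorot(rng, D, d_adt, dtype), b_out_a=_zeros(d_adt, dtype),
        ),
    )


# ---------------------------------------------------------------------------
# forward operations
# ---------------------------------------------------------------------------

def _row_standardize(H: Tensor, eps: float) -> Tensor:
    m = H.mean(axis=-1, keepdims=True)
    centered = H - m
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps) ** -0.5


def feature_align(H, params: AlignmentParams, eps: float = 1e-5) -> Tensor:
    """Per-cell z-score across features, then learnable scale and shift.

    Centering uses each row's own mean/variance so the operation is
    independent of batch composition; eps stabilizes constant rows.
    """
    return _row_standardize(as_tensor(H), eps) * params.gamma + params.beta


def layer_norm(H, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Standard layer normalization (same row statistics as feature_align)."""
    return _row_standardize(as_tensor(H), eps) * gamma + beta


def _dropout(H: Tensor, p: float, rng, training: bool) -> Tensor:
    if not training or p <= 0:
        return H
    mask = (rng.random(H.shape) >= p).astype(H.data.dtype) / (1.0 - p)
    return H * mask


def encode(X, params: EncoderParams, eps: float = 1e-5, use_alignment: bool = True) -> Tensor:
    """ReLU(align(X @ W) + b); alignment is the identity when ablated."""
    X = as_tensor(X)
    if X.shape[-1] != params.W.shape[0]:
        raise ValueError(
            f"input has {X.shape[-1]} features but encoder expects {params.W.shape[0]}"
        )
    H = X @ params.W
    if use_alignment:
        H = feature_align(H, params.align, eps)
    return (H + params.b).relu()


def fuse(h_r, h_a, fw: FusionWeights, mode: str = "adaptive"):
    """Combine modality embeddings.

    adaptive: convex combination with softmax-normalized learnable weights.
    concat:   column concatenation (ablation); weights reported as (1, 1).
    """
    h_r, h_a = as_tensor(h_r), as_tensor(h_a)
    if mode == "concat":
        return concat([h_r, h_a], axis=-1), 1.0, 1.0
    if h_r.shape != h_a.shape:
        raise ValueError(f"embedding shapes differ: {h_r.shape} vs {h_a.shape}")
    e_r, e_a = fw.raw_r.exp(), fw.raw_a.exp()
    denom = (e_r + e_a) ** -1.0
    w_r, w_a = e_r * denom, e_a * denom
    y = h_r * w_r + h_a * w_a
    return y, float(np.mean(w_r.data)), float(np.mean(w_a.data))


def mha_block(
    y,
    params: AttentionParams,
    L: int,
    n_head: int,
    dropout_p: float = 0.0,
    rng=None,
    training: bool = False,
    eps: float = 1e-5,
    use_attention: bool = True,
    return_attn: bool = False,
):
    """Multi-head self-attention over L feature tokens, with residual + LN.

    The (B, D) input is reshaped to (B, L, D/L) tokens; q, k, v are linear
    projections split into n_head heads of width d = D/(L*n_head); each head
    applies softmax(q k^T / sqrt(d)) v over the token axis. Heads are
    concatenated, projected by Wo, flattened back to (B, D), and combined
    as LayerNorm(y + Dropout(attended)). With use_attention=False the block
    is the identity.
    """
    y = as_tensor(y)
    if not use_attention:
        return (y, None) if return_attn else y
    B, D = y.shape
    _check_divisible(D, L, n_head, "attention input")
    d_l = D // L
    d = d_l // n_head

    tokens = y.reshape(B, L, d_l)

    def heads(W):
        proj = tokens @ W                      # (B, L, d_l)
        return proj.reshape(B, L, n_head, d).transpose(0, 2, 1, 3)  # (B, n, L, d)

    q, k, v = heads(params.Wq), heads(params.Wk), heads(params.Wv)
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
    attn = scores.softmax(axis=-1)             # (B, n, L, L)
    context = attn @ v                         # (B, n, L, d)
    merged = context.transpose(0, 2, 1, 3).reshape(B, L, d_l) @ params.Wo
    out = merged.reshape(B, D)
    out = _dropout(out, dropout_p, rng, training)
    result = layer_norm(y + out, params.ln_gamma, params.ln_beta, eps)
    return (result, attn.data) if return_attn else result


def to_gaussian(
    y_prime,
    head: GaussianHead,
    dropout_p: float = 0.0,
    rng=None,
    training: bool = False,
    eps: float = 1e-5,
    use_alignment: bool = True,
):
    """Project refined features to posterior mean and log-variance."""
    y_prime = as_tensor(y_prime)

    def branch(W, b, align):
        H = y_prime @ W
        if use_alignment:
            H = feature_align(H, align, eps)
        return _dropout(H + b, dropout_p, rng, training)

    mu = branch(head.W_mu, head.b_mu, head.align_mu)
    logvar = branch(head.W_sigma, head.b_sigma, head.align_sigma)
    return mu, logvar


def sample_latent(mu, logvar, noise):
    """Reparameterized draw z = mu + exp(logvar/2) * noise."""
    mu, logvar = as_tensor(mu), as_tensor(logvar)
    if isinstance(noise, np.random.Generator):
        noise = noise.standard_normal(mu.shape).astype(mu.data.dtype)
    return mu + (logvar * 0.5).exp() * noise


def decode(
    z,
    params: DecoderParams,
    L_dec: int,
    n_head: int,
    dropout_p: float = 0.0,
    rng=None,
    training: bool = False,
    eps: float = 1e-5,
    use_attention: bool = True,
    use_alignment: bool = True,
):
    """Attention-refined latent -> shared hidden layer -> per-modality linear."""
    z = as_tensor(z)
    z_ref = mha_block(
        z, params.attention, L_dec, n_head,
        dropout_p=dropout_p, rng=rng, training=training, eps=eps,
        use_attention=use_attention,
    )
    H = z_ref @ params.W_hidden
    if use_alignment:
        H = feature_align(H, params.align_hidden, eps)
    hidden = (H + params.b_hidden).relu()
    Xr_hat = hidden @ params.W_out_r + params.b_out_r
    Xa_hat = hidden @ params.W_out_a + params.b_out_a
    return Xr_hat, Xa_hat


def forward(Xr, Xa, state: ModelState, mode: str = "eval", rng=None):
    """Full pass; returns graph tensors plus the fusion weights.

    mode="train" enables dropout and stochastic sampling (requires rng);
    mode="eval" is deterministic with z = mu.
    """
    cfg = state.config
    training = mode == "train"
    if training and rng is None:
        raise ValueError("train mode requires a random generator")
    h_r = encode(Xr, state.encoder_r, cfg.eps, cfg.use_alignment)
    h_a = encode(Xa, state.encoder_a, cfg.eps, cfg.use_alignment)
    y, w_r, w_a = fuse(h_r, h_a, state.fusion, cfg.fusion_mode)
    y_prime = mha_block(
        y, state.attention, cfg.n_tokens_enc, cfg.n_head,
        dropout_p=cfg.dropout_p, rng=rng, training=training, eps=cfg.eps,
        use_attention=cfg.use_attention,
    )
    mu, logvar = to_gaussian(
        y_prime, state.gauss, dropout_p=cfg.dropout_p, rng=rng,
        training=training, eps=cfg.eps, use_alignment=cfg.use_alignment,
    )
    if training:
        z = sample_latent(mu, logvar, rng)
    else:
        z = mu
    Xr_hat, Xa_hat = decode(
        z, state.decoder, cfg.n_tokens_dec, cfg.n_head,
        dropout_p=cfg.dropout_p, rng=rng, training=training, eps=cfg.eps,
        use_attention=cfg.use_attention, use_alignment=cfg.use_alignment,
    )
    return mu, logvar, z, Xr_hat, Xa_hat, w_r, w_a


def forward_eval(Xr, Xa, state: ModelState) -> tuple[LatentResult, np.ndarray, np.ndarray]:
    """Deterministic evaluation pass returning plain arrays."""
    mu, logvar, z, Xr_hat, Xa_hat, w_r, w_a = forward(Xr, Xa, state, mode="eval")
    return (
        LatentResult(mu=mu.data.copy(), logvar=logvar.data.copy(), z=z.data.copy(),
                     w_r=w_r, w_a=w_a),
        Xr_hat.data.copy(),
        Xa_hat.data.copy(),
    )
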