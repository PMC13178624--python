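"""PVNet: phase-velocity regression from single-depth phase images.

A hierarchical hybrid CNN/transformer that maps one lateral×temporal
phase-difference image to the surface-acoustic-wave phase velocity (m/s) at
that depth.  The backbone is a four-stage pyramid of ConvEncoder blocks
(depthwise 3×3 + pointwise convolutions with a GELU bottleneck and residual)
capped per stage by a SwiftFormer encoder block whose token mixing is
Efficient Additive Attention (EAA) — linear in token count — with rotary
positional embeddings (RoPE) applied to the query/key projections.  Spatial
resolution halves between stages; a global average pool feeds a small
regression head.

Training follows the standard protocol for this task: MSE loss, Adam,
early stopping on validation loss.  All randomness is explicitly seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.ndimage import map_coordinates

from . import nn
from .nn import Tensor

__all__ = [
    "PVNetConfig", "TrainingConfig", "PVNet", "rope_rotate", "eaa",
    "prepare_images", "resize_bilinear", "train", "evaluate_mae",
]


# ---------------------------------------------------------------------------
# standalone numerical operations (the math, testable without the network)


def rope_rotate(tokens: np.ndarray, positions: np.ndarray,
                base: float = 10000.0) -> np.ndarray:
    """Rotate adjacent element pairs of each token by its position angle.

    Token at position m has pair (x_{2i}, x_{2i+1}) rotated by m * theta_i,
    theta_i = base**(-2i/D).  An isometry; inner products between rotated
    tokens depend only on relative position.
    """
    tokens = np.asarray(tokens, dtype=np.float64)
    D = tokens.shape[-1]
    if D % 2:
        raise ValueError("rope_rotate needs an even feature dimension")
    cos, sin = nn._rope_tables(np.asarray(positions, dtype=np.float64), D, base)
    return nn._rope_apply(tokens, cos, sin)


def eaa(Q: np.ndarray, K: np.ndarray, w_a: np.ndarray,
        W: np.ndarray | None = None, b: np.ndarray | None = None) -> np.ndarray:
    """Efficient Additive Attention on token matrices Q, K of shape (N, D).

    alpha = softmax(Q @ w_a / sqrt(D)) over tokens; the global query
    q = sum_i alpha_i Q_i summarizes the sequence; the output is
    Linear(K ⊙ q) + Q with the linear map (W, b) defaulting to identity.
    Cost is linear in N.
    """
    Q = np.asarray(Q, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    if Q.shape != K.shape:
        raise ValueError(f"Q and K shapes differ: {Q.shape} vs {K.shape}")
    N, D = Q.shape
    if np.asarray(w_a).shape != (D,):
        raise ValueError(f"w_a must have shape ({D},)")
    s = Q @ w_a / math.sqrt(D)
    s = s - s.max()
    alpha = np.exp(s)
    alpha /= alpha.sum()
    q = alpha @ Q                                  # (D,)
    mod = K * q[None, :]
    if W is not None:
        mod = mod @ W
    if b is not None:
        mod = mod + b
    return mod + Q


def eaa_macs(N: int, D: int) -> int:
    """Multiply-accumulate count of the alpha/global-query computation.

    Saliency Q@w_a (N*D), weighted pooling alpha@Q (N*D) and the K⊙q
    modulation (N*D): linear in the token count N.
    """
    return 3 * N * D


# ---------------------------------------------------------------------------
# configuration


_VARIANTS: dict[str, dict[str, Any]] = {
    # desk-scale preset: small dims and a 64x64 input so a forward pass is
    # sub-second on one CPU core
    "tiny": dict(input_size=(64, 64), stage_dims=(16, 32, 48, 64),
                 stage_depths=(1, 1, 1, 1), head_hidden=32, mlp_ratio=2),
    "S": dict(input_size=(320, 320), stage_dims=(48, 64, 96, 128),
              stage_depths=(2, 2, 2, 2), head_hidden=128),
    "base": dict(input_size=(320, 320), stage_dims=(64, 96, 160, 224),
                 stage_depths=(2, 2, 6, 2), head_hidden=256),
    "L": dict(input_size=(320, 320), stage_dims=(96, 128, 192, 256),
              stage_depths=(3, 3, 9, 3), head_hidden=256),
}


@dataclass
class PVNetConfig:
    """Architecture hyper-parameters.

    The spatial size shrinks 4× in the stem and 2× between stages, so
    ``input_size`` must be divisible by 32.  ``stage_depths[i]`` ConvEncoder
    blocks are followed by one SwiftFormer block in stage i.  All stage widths
    must be even so RoPE can pair feature elements.
    """

    input_size: tuple[int, int] = (320, 320)
    stage_dims: tuple[int, int, int, int] = (64, 96, 160, 224)
    stage_depths: tuple[int, int, int, int] = (2, 2, 6, 2)
    mlp_ratio: int = 4
    rope_base: float = 10000.0
    head_hidden: int = 256

    def __post_init__(self) -> None:
        if len(self.stage_dims) != 4 or len(self.stage_depths) != 4:
            raise ValueError("exactly 4 stages are required")
        if any(d % 2 for d in self.stage_dims):
            raise ValueError("stage dims must be even (RoPE pairs elements)")
        H, W = self.input_size
        if H % 32 or W % 32:
            raise ValueError("input_size must be divisible by 32")

    @classmethod
    def preset(cls, variant: str, **overrides: Any) -> "PVNetConfig":
        if variant not in _VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {sorted(_VARIANTS)}")
        kw = dict(_VARIANTS[variant])
        kw.update(overrides)
        return cls(**kw)


@dataclass
class TrainingConfig:
    """Optimization protocol: MSE loss with Adam and early stopping."""

    lr: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 15
    seed: int = 0
    val_frac: float = 0.2
    target_val_mae: float | None = None  # optional additional stop for short studies

    def __post_init__(self) -> None:
        if self.lr < 0 or self.batch_size < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("training hyper-parameters must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if not (0 < self.val_frac < 1):
            raise ValueError("val_frac must be in (0, 1)")


# ---------------------------------------------------------------------------
# network modules


class ConvEncoder(nn.Module):
    """Depthwise 3×3 → BN → 1×1 expand → GELU → 1×1 project, with residual."""

    def __init__(self, channels: int, mlp_ratio: int, rng: np.random.Generator):
        super().__init__()
        hidden = mlp_ratio * channels
        self.dw = nn.DWConv3x3(channels, rng)
        self.bn = nn.BatchNorm2d(channels)
        self.pw1 = nn.Conv1x1(channels, hidden, rng)
        self.pw2 = nn.Conv1x1(hidden, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.pw1(self.bn(self.dw(x)))
        return self.pw2(nn.gelu(h)) + x


class EAAttention(nn.Module):
    """Learned Q/K projections + RoPE + additive attention + output linear."""

    def __init__(self, dim: int, rope_base: float, rng: np.random.Generator):
        super().__init__()
        self.dim = dim
        self.rope_base = rope_base
        self.wq = nn.Linear(dim, dim, rng)
        self.wk = nn.Linear(dim, dim, rng)
        self.w_a = nn.Parameter(rng.standard_normal(dim) / math.sqrt(dim))
        self.proj = nn.Linear(dim, dim, rng)
        self.scale = 1.0 / math.sqrt(dim)

    def forward(self, tokens: Tensor) -> Tensor:
        # tokens: (B, N, D); positions are flattened row-major indices
        N = tokens.shape[1]
        pos = np.arange(N, dtype=np.float64)
        Q = nn.rope(self.wq(tokens), pos, self.rope_base)
        K = nn.rope(self.wk(tokens), pos, self.rope_base)
        s = nn.matmul(Q, nn.reshape(self.w_a, (self.dim, 1)))      # (B, N, 1)
        alpha = nn.softmax(s * self.scale, axis=1)
        q = nn.mean(nn.mul(alpha, Q), axis=1, keepdims=True) * float(N)  # (B, 1, D)
        return self.proj(nn.mul(K, q)) + Q


class SwiftFormerBlock(nn.Module):
    """Local mixing, EAA-with-RoPE token mixing, then the linear block."""

    def __init__(self, channels: int, rope_base: float, rng: np.random.Generator):
        super().__init__()
        self.dw1 = nn.DWConv3x3(channels, rng)
        self.pw1 = nn.Conv1x1(channels, channels, rng)
        self.attn = EAAttention(channels, rope_base, rng)
        self.dw2 = nn.DWConv3x3(channels, rng)
        self.bn2 = nn.BatchNorm2d(channels)
        self.pw2 = nn.Conv1x1(channels, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        h = self.pw1(self.dw1(x))
        tokens = nn.reshape(nn.transpose(h, (0, 2, 3, 1)), (B, H * W, C))
        tokens = self.attn(tokens)
        h = nn.transpose(nn.reshape(tokens, (B, H, W, C)), (0, 3, 1, 2))
        return self.pw2(self.bn2(self.dw2(h))) + x


class _Stem(nn.Module):
    """Patch-embedding stem: one 4×4 stride-4 convolution (4× downsampling)."""

    def __init__(self, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.c1 = nn.Conv2d(1, out_dim, 4, 4, 0, rng)
        self.n1 = nn.BatchNorm2d(out_dim)

    def forward(self, x: Tensor) -> Tensor:
        return nn.gelu(self.n1(self.c1(x)))


class _Downsample(nn.Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(n_in, n_out, 3, 2, 1, rng)
        self.bn = nn.BatchNorm2d(n_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x))


class PVNet(nn.Module):
    """The full regressor: stem → 4 stages → global pool → head → scalar m/s."""

    def __init__(self, config: PVNetConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.Generator(np.random.PCG64(seed))
        dims = config.stage_dims
        self.stem = _Stem(dims[0], rng)
        self.stages: list[list[nn.Module]] = []
        self.downsamples: list[nn.Module] = []
        for i in range(4):
            blocks: list[nn.Module] = [ConvEncoder(dims[i], config.mlp_ratio, rng)
                                       for _ in range(config.stage_depths[i])]
            blocks.append(SwiftFormerBlock(dims[i], config.rope_base, rng))
            self.stages.append(blocks)
            if i < 3:
                self.downsamples.append(_Downsample(dims[i], dims[i + 1], rng))
        self.head1 = nn.Linear(dims[3], config.head_hidden, rng)
        self.head2 = nn.Linear(config.head_hidden, 1, rng)

    # Module.parameters only walks dict values / flat lists, so expose the
    # nested stage lists explicitly.
    def parameters(self) -> list[nn.Parameter]:
        params = self.stem.parameters()
        for blocks in self.stages:
            for b in blocks:
                params.extend(b.parameters())
        for d in self.downsamples:
            params.extend(d.parameters())
        params.extend(self.head1.parameters())
        params.extend(self.head2.parameters())
        return params

    def modules(self):
        yield self
        yield from self.stem.modules()
        for blocks in self.stages:
            for b in blocks:
                yield from b.modules()
        for d in self.downsamples:
            yield from d.modules()
        yield from self.head1.modules()
        yield from self.head2.modules()

    def forward(self, x: Tensor) -> Tensor:
        """Batch of normalized phase images (B, 1, H, W) → velocities (B,)."""
        B, C, H, W = x.shape
        if (H, W) != self.config.input_size or C != 1:
            raise ValueError(f"expected input (B, 1, {self.config.input_size[0]}, "
                             f"{self.config.input_size[1]}), got {x.shape}")
        h = self.stem(x)
        for i in range(4):
            for block in self.stages[i]:
                h = block(h)
            if i < 3:
                h = self.downsamples[i](h)
        pooled = nn.mean(h, axis=(2, 3))                  # (B, D)
        out = self.head2(nn.gelu(self.head1(pooled)))     # (B, 1)
        return nn.reshape(out, (B,))

    def predict(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Predict velocities for raw phase images (N, X, T); eval mode, no grad."""
        prepped = prepare_images(images, self.config.input_size)
        self.eval()
        preds = []
        with nn.no_grad():
            for i in range(0, len(prepped), batch_size):
                out = self.forward(Tensor(prepped[i:i + batch_size]))
                preds.append(out.data)
        return np.concatenate(preds)


# ---------------------------------------------------------------------------
# image preparation


def resize_bilinear(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of one 2-D image to ``out_hw`` (corner-aligned grid)."""
    H, W = out_hw
    r = np.linspace(0.0, img.shape[0] - 1.0, H)
    c = np.linspace(0.0, img.shape[1] - 1.0, W)
    rr, cc = np.meshgrid(r, c, indexing="ij")
    return map_coordinates(img.astype(np.float64), [rr, cc], order=1, mode="nearest")


def prepare_images(images: np.ndarray, input_size: tuple[int, int]) -> np.ndarray:
    """Resize raw phase images to the network input and scale [-pi,pi) → [-1,1).

    Returns a (N, 1, H, W) float64 batch.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    out = np.empty((images.shape[0], 1, *input_size))
    for i, img in enumerate(images):
        out[i, 0] = resize_bilinear(img, input_size)
    return out / np.pi


# ---------------------------------------------------------------------------
# training / evaluation


def train(images: np.ndarray, labels: np.ndarray, tcfg: TrainingConfig,
          mcfg: PVNetConfig, verbose: bool = False
          ) -> tuple[PVNet, dict[str, list[float]]]:
    """Train PVNet on labelled phase images; returns best-validation model.

    The data are split train/validation with the seeded shuffle, optimized
    with Adam on MSE, and early-stopped when validation loss fails to improve
    for ``patience`` epochs.  Deterministic given ``tcfg.seed``.
    """
    labels = np.asarray(labels, dtype=np.float64)
    if len(images) != len(labels) or len(labels) == 0:
        raise ValueError("need equally many images and labels, at least one pair")
    n_val = int(round(tcfg.val_frac * len(labels)))
    if n_val == 0 or n_val == len(labels):
        raise ValueError("validation split is empty; adjust val_frac or data size")

    ss = np.random.SeedSequence(tcfg.seed)
    split_rng, model_seed, epoch_rng = (np.random.Generator(np.random.PCG64(s))
                                        for s in ss.spawn(3))
    prepped = prepare_images(images, mcfg.input_size)
    order = split_rng.permutation(len(labels))
    val_idx, train_idx = order[:n_val], order[n_val:]
    Xtr, ytr = prepped[train_idx], labels[train_idx]
    Xva, yva = prepped[val_idx], labels[val_idx]

    model = PVNet(mcfg, seed=int(model_seed.integers(2 ** 31)))
    opt = nn.Adam(model.parameters(), lr=tcfg.lr)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "val_mae": []}
    best_loss = np.inf
    best_state = model.state_dict()
    bad_epochs = 0

    for epoch in range(tcfg.max_epochs):
        model.train()
        perm = epoch_rng.permutation(len(ytr))
        losses = []
        for i in range(0, len(perm), tcfg.batch_size):
            idx = perm[i:i + tcfg.batch_size]
            if idx.size < 2:
                continue  # batch norm needs at least two samples
            opt.zero_grad()
            pred = model(Tensor(Xtr[idx]))
            loss = nn.mse_loss(pred, ytr[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_pred = _predict_prepped(model, Xva, tcfg.batch_size)
        val_loss = float(np.mean((val_pred - yva) ** 2))
        val_mae = float(np.mean(np.abs(val_pred - yva)))
        history["train_loss"].append(float(np.mean(losses)) if losses else np.nan)
        history["val_loss"].append(val_loss)
        history["val_mae"].append(val_mae)
        if verbose:  # pragma: no cover
            print(f"epoch {epoch + 1}: train {history['train_loss'][-1]:.4f} "
                  f"val {val_loss:.4f} mae {val_mae:.3f}")
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= tcfg.patience:
                break
        if tcfg.target_val_mae is not None and val_mae < tcfg.target_val_mae:
            break

    model.load_state_dict(best_state)
    model.eval()
    return model, history


def _predict_prepped(model: PVNet, X: np.ndarray, batch_size: int) -> np.ndarray:
    model.eval()
    preds = []
    with nn.no_grad():
        for i in range(0, len(X), batch_size):
            preds.append(model(Tensor(X[i:i + batch_size])).data)
    model.train()
    return np.concatenate(preds)


def write_profile_from_predictions(stack, predictions: np.ndarray,
                                   path) -> None:
    """Emit network predictions as a velocity-profile CSV compatible with the
    interface stage."""
    from .core_io import VelocityProfile, write_profile

    prof = VelocityProfile(depth_index=stack.depth_indices(), dz=stack.dz,
                           v_raw=np.clip(np.asarray(predictions, dtype=np.float64),
                                         1e-6, None))
    write_profile(prof, path)


def evaluate_mae(model: PVNet, images: np.ndarray, labels: np.ndarray
                 ) -> tuple[float, float]:
    """Mean and standard deviation of |prediction − target| in m/s."""
    labels = np.asarray(labels, dtype=np.float64)
    if len(labels) == 0:
        raise ValueError("cannot evaluate on an empty set")
    pred = model.predict(np.asarray(images))
    err = np.abs(pred - labels)
    return float(err.mean()), float(err.std())
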