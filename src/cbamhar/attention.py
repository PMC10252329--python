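"""Channel and spatial attention for convolutional feature maps.

A convolutional block attention module (CBAM) refines an intermediate
feature map ``X`` of shape ``(C, H, W)`` — ``C`` filter channels, ``H``
time steps, ``W`` sensor signals in this package's activity-recognition
setting — with two sigmoid-valued multiplicative masks:

* **Channel attention** pools each channel over all ``(H, W)`` positions
  (average and max), pushes both pooled descriptors through one shared
  bottleneck MLP (``C -> C/r -> C``, reduction ratio ``r``), sums the two
  outputs and applies a sigmoid.  Each channel of ``X`` is then scaled by
  its mask value.
* **Spatial attention** pools across channels into an average plane and a
  max plane, stacks them (average first), convolves with a single
  ``k x k`` kernel (zero-padded, size-preserving, no bias) and applies a
  sigmoid.  Every channel is multiplied elementwise by the resulting
  ``H x W`` mask.

The combined mode applies the channel step first and computes the spatial
mask from the channel-refined features.

The functions here operate on single feature maps in float64 and are the
reference semantics for the batched training layers in
:mod:`cbamhar.nn`; the two are held together by tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
from scipy.signal import correlate2d

__all__ = [
    "AttentionSpec",
    "ChannelAttentionParams",
    "SpatialAttentionParams",
    "spatial_pool",
    "channel_pool",
    "channel_attention_mask",
    "spatial_attention_mask",
    "apply_channel_mask",
    "apply_spatial_mask",
    "cbam_forward",
    "attention_param_count",
    "CANONICAL_REDUCTION_RATIOS",
    "CANONICAL_KERNEL_SIZES",
    "PLACEMENTS",
]

#: reduction ratios / kernel sizes covered by the experiment grid
CANONICAL_REDUCTION_RATIOS = (1, 2, 4, 8, 16)
CANONICAL_KERNEL_SIZES = (3, 5, 7)

#: valid attention placements: after conv layer 1-4, or after every conv layer
PLACEMENTS = (1, 2, 3, 4, "all")

Mode = Literal["CH", "SP", "CHSP"]
Placement = Union[int, str]


class DimensionError(ValueError):
    """Shapes of a feature map and attention parameters do not agree."""


class ConfigurationError(ValueError):
    """An attention specification is structurally invalid."""


def _as_feature_map(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 3 or min(x.shape) < 1:
        raise DimensionError(
            f"feature map must be 3-D (C, H, W) with positive dims, got shape {x.shape}"
        )
    if not np.all(np.isfinite(x)):
        raise DimensionError("feature map contains non-finite entries")
    return x


@dataclass(frozen=True)
class AttentionSpec:
    """Where and how an attention block is inserted.

    Parameters
    ----------
    mode:
        ``"CH"`` channel only, ``"SP"`` spatial only, ``"CHSP"`` channel
        followed by spatial.
    r:
        Reduction ratio of the shared MLP bottleneck (channel modes).
    k:
        Spatial convolution kernel size, odd (spatial modes).
    placement:
        Conv layer index 1-4 after which the block sits, or ``"all"`` for
        an independent block after every conv layer.
    """

    mode: Mode
    r: Optional[int] = None
    k: Optional[int] = None
    placement: Placement = "all"

    def __post_init__(self):
        if self.mode not in ("CH", "SP", "CHSP"):
            raise ConfigurationError(f"unknown attention mode {self.mode!r}")
        if self.placement not in PLACEMENTS:
            raise ConfigurationError(
                f"placement must be one of {PLACEMENTS}, got {self.placement!r}"
            )
        if self.uses_channel:
            if self.r is None or int(self.r) <= 0:
                raise ConfigurationError("channel attention requires a positive r")
            if self.r not in CANONICAL_REDUCTION_RATIOS:
                warnings.warn(
                    f"reduction ratio r={self.r} is outside the canonical grid "
                    f"{CANONICAL_REDUCTION_RATIOS}",
                    stacklevel=2,
                )
        elif self.r is not None:
            raise ConfigurationError("r given but mode has no channel attention")
        if self.uses_spatial:
            if self.k is None or int(self.k) <= 0:
                raise ConfigurationError("spatial attention requires a positive k")
            if self.k % 2 == 0:
                raise ConfigurationError("spatial kernel size k must be odd")
            if self.k not in CANONICAL_KERNEL_SIZES:
                warnings.warn(
                    f"kernel size k={self.k} is outside the canonical grid "
                    f"{CANONICAL_KERNEL_SIZES}",
                    stacklevel=2,
                )
        elif self.k is not None:
            raise ConfigurationError("k given but mode has no spatial attention")

    @property
    def uses_channel(self) -> bool:
        return self.mode in ("CH", "CHSP")

    @property
    def uses_spatial(self) -> bool:
        return self.mode in ("SP", "CHSP")


@dataclass
class ChannelAttentionParams:
    """Weights of the shared bottleneck MLP (``C -> C/r -> C``).

    One weight set serves both the average- and max-pooled descriptors.
    Trainable scalar count is ``2*C*(C/r) + C + C/r``.
    """

    w_hidden: np.ndarray  # (C, C/r)
    b_hidden: np.ndarray  # (C/r,)
    w_out: np.ndarray  # (C/r, C)
    b_out: np.ndarray  # (C,)
    hidden_activation: str = "relu"  # "relu" (default) or "identity"

    def __post_init__(self):
        c, h = self.w_hidden.shape
        if self.w_out.shape != (h, c) or self.b_hidden.shape != (h,) or self.b_out.shape != (c,):
            raise DimensionError("inconsistent shared-MLP weight shapes")
        if self.hidden_activation not in ("relu", "identity"):
            raise ConfigurationError(f"unknown activation {self.hidden_activation!r}")

    @property
    def n_channels(self) -> int:
        return self.w_hidden.shape[0]

    @property
    def n_params(self) -> int:
        return sum(a.size for a in (self.w_hidden, self.b_hidden, self.w_out, self.b_out))

    def mlp(self, v: np.ndarray) -> np.ndarray:
        """Apply the shared MLP to a length-C descriptor."""
        h = v @ self.w_hidden + self.b_hidden
        if self.hidden_activation == "relu":
            h = np.maximum(h, 0.0)
        return h @ self.w_out + self.b_out

    @classmethod
    def initialise(
        cls,
        n_channels: int,
        r: int,
        rng: np.random.Generator,
        hidden_activation: str = "relu",
        scale: float | None = None,
    ) -> "ChannelAttentionParams":
        if r <= 0:
            raise ConfigurationError("reduction ratio must be positive")
        if n_channels % r != 0:
            raise ConfigurationError(
                f"C={n_channels} is not divisible by reduction ratio r={r}"
            )
        hidden = n_channels // r
        s1 = scale if scale is not None else np.sqrt(6.0 / (n_channels + hidden))
        s2 = scale if scale is not None else np.sqrt(6.0 / (hidden + n_channels))
        return cls(
            w_hidden=rng.uniform(-s1, s1, size=(n_channels, hidden)),
            b_hidden=np.zeros(hidden),
            w_out=rng.uniform(-s2, s2, size=(hidden, n_channels)),
            b_out=np.zeros(n_channels),
            hidden_activation=hidden_activation,
        )


@dataclass
class SpatialAttentionParams:
    """Weights of the ``k x k`` two-plane-to-one convolution (no bias).

    ``kernel[0]`` acts on the channel-average plane, ``kernel[1]`` on the
    channel-max plane.  Trainable scalar count is ``k*k*2``.
    """

    kernel: np.ndarray  # (2, k, k)

    def __post_init__(self):
        if self.kernel.ndim != 3 or self.kernel.shape[0] != 2:
            raise DimensionError("spatial kernel must have shape (2, k, k)")
        k1, k2 = self.kernel.shape[1:]
        if k1 != k2:
            raise DimensionError("spatial kernel must be square")
        if k1 % 2 == 0:
            raise ConfigurationError("spatial kernel size must be odd")

    @property
    def kernel_size(self) -> int:
        return self.kernel.shape[1]

    @property
    def n_params(self) -> int:
        return self.kernel.size

    @classmethod
    def initialise(
        cls, k: int, rng: np.random.Generator, scale: float | None = None
    ) -> "SpatialAttentionParams":
        if k <= 0:
            raise ConfigurationError("kernel size must be positive")
        if k % 2 == 0:
            raise ConfigurationError("kernel size must be odd")
        s = scale if scale is not None else np.sqrt(6.0 / (2 * k * k + 1))
        return cls(kernel=rng.uniform(-s, s, size=(2, k, k)))


# ---------------------------------------------------------------------------
# pooling


def spatial_pool(x) -> tuple[np.ndarray, np.ndarray]:
    """Global average/max pool over the spatial ``(H, W)`` positions.

    Returns length-``C`` descriptors ``(favg, fmax)``.
    """
    x = _as_feature_map(x)
    return x.mean(axis=(1, 2)), x.max(axis=(1, 2))


def channel_pool(x) -> tuple[np.ndarray, np.ndarray]:
    """Average/max pool across channels; returns two ``H x W`` planes."""
    x = _as_feature_map(x)
    return x.mean(axis=0), x.max(axis=0)


# ---------------------------------------------------------------------------
# masks


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def channel_attention_mask(x, p: ChannelAttentionParams) -> np.ndarray:
    """Length-``C`` sigmoid mask from the shared-MLP channel attention."""
    x = _as_feature_map(x)
    if x.shape[0] != p.n_channels:
        raise DimensionError(
            f"feature map has C={x.shape[0]} channels, params expect {p.n_channels}"
        )
    favg, fmax = spatial_pool(x)
    return _sigmoid(p.mlp(favg) + p.mlp(fmax))


def spatial_attention_mask(x, p: SpatialAttentionParams) -> np.ndarray:
    """``H x W`` sigmoid mask from the two-plane spatial convolution.

    The average plane is stacked first, then the max plane; the
    convolution is size-preserving with zero-padded borders and no bias.
    """
    x = _as_feature_map(x)
    favg, fmax = channel_pool(x)
    # correlate2d == the conv layer's cross-correlation; 'same' keeps H x W
    pre = correlate2d(favg, p.kernel[0], mode="same", fillvalue=0.0) + correlate2d(
        fmax, p.kernel[1], mode="same", fillvalue=0.0
    )
    return _sigmoid(pre)


def apply_channel_mask(x, mask) -> np.ndarray:
    """Scale every ``(h, w)`` entry of channel ``c`` by ``mask[c]``."""
    x = _as_feature_map(x)
    mask = np.asarray(mask, dtype=float)
    if mask.shape != (x.shape[0],):
        raise DimensionError(
            f"channel mask length {mask.shape} does not match C={x.shape[0]}"
        )
    return x * mask[:, None, None]


def apply_spatial_mask(x, mask) -> np.ndarray:
    """Multiply every channel elementwise by the ``H x W`` mask."""
    x = _as_feature_map(x)
    mask = np.asarray(mask, dtype=float)
    if mask.shape != x.shape[1:]:
        raise DimensionError(
            f"spatial mask shape {mask.shape} does not match (H, W)={x.shape[1:]}"
        )
    return x * mask[None, :, :]


def cbam_forward(
    x,
    spec: AttentionSpec,
    ch: Optional[ChannelAttentionParams] = None,
    sp: Optional[SpatialAttentionParams] = None,
) -> np.ndarray:
    """Run the attention block named by *spec* on one feature map.

    In combined mode the channel step runs first and the spatial mask is
    computed from the channel-refined features, not the raw input.
    """
    x = _as_feature_map(x)
    if spec.uses_channel:
        if ch is None:
            raise ConfigurationError("mode requires channel attention parameters")
        x = apply_channel_mask(x, channel_attention_mask(x, ch))
    if spec.uses_spatial:
        if sp is None:
            raise ConfigurationError("mode requires spatial attention parameters")
        x = apply_spatial_mask(x, spatial_attention_mask(x, sp))
    return x


# ---------------------------------------------------------------------------
# parameter accounting


def attention_param_count(
    spec: AttentionSpec, n_channels: int, n_conv_layers: int = 4
) -> int:
    """Closed-form count of trainable scalars added by *spec*.

    Channel attention costs ``2*C*(C/r) + C + C/r`` (shared MLP with both
    biases), spatial attention ``k*k*2`` (bias-free conv), combined the
    sum.  Placement ``"all"`` inserts one independent block after each of
    the ``n_conv_layers`` conv layers, multiplying the single-block count.
    """
    per_block = 0
    if spec.uses_channel:
        r = int(spec.r)
        if n_channels % r != 0:
            raise ConfigurationError(
                f"C={n_channels} is not divisible by reduction ratio r={r}"
            )
        hidden = n_channels // r
        per_block += 2 * n_channels * hidden + n_channels + hidden
    if spec.uses_spatial:
        k = int(spec.k)
        per_block += k * k * 2
    if spec.placement == "all":
        return per_block * n_conv_layers
    return per_block
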