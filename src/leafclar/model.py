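"""MF-RANet: residual-attention backbone with a multi-scale detail path.

The classifier combines two feature roads:

* **Main road** — a ResNet50-style backbone (bottleneck blocks 3/4/6/3) with
  every ReLU replaced by ELU and a residual attention module (RAM) applied to
  each stage's output.  A 224×224 input produces stage maps B1..B4 with
  spatial sizes 56/28/14/7.

* **Detail road** — a feature-pyramid fusion path adapted from detection-style
  FPN augmentation to whole-image classification: 1×1 lateral projections
  give M1..M4; residual feature enhancement pools the top level at three
  ratios and adds the weighted, upsampled context back (P5); a top-down
  pathway with 3×3 smoothing produces P1..P4; the levels are adaptively
  pooled to 7×7 and fused by per-pixel spatial weights (adaptive spatial
  fusion).  Shared auxiliary classification heads on M1..M4 provide the
  consistency supervision; their loss is weighted by ``aux_weight``.
  Localization terms carry a ``loc_weight`` factor in the loss formula but
  default to zero — classification has no box targets.

The head concatenates the globally pooled B4 descriptor with the pooled
fused detail descriptor and maps to class logits; training minimizes
label-smoothed cross entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import ops
from .attention import ResidualAttention

BASE_STAGE_WIDTHS = (256, 512, 1024, 2048)
BASE_LATERAL_WIDTH = 256
STAGE_BLOCKS = (3, 4, 6, 3)


@dataclass
class ModelConfig:
    """Architecture and loss hyperparameters.

    ``width_multiplier`` scales every channel count (desk-scale reduction);
    ``aux_weight`` balances the auxiliary consistency losses against the main
    loss; ``loc_weight`` multiplies localization terms (0: classification
    only); ``rfe_weights`` are the three context weights of residual feature
    enhancement; ``smoothing`` is the label-smoothing epsilon.
    """

    n_classes: int = 6
    input_size: int = 224
    width_multiplier: float = 1.0
    elu_alpha: float = 1.0
    activation: str = "elu"
    aux_weight: float = 0.25
    loc_weight: float = 0.0
    rfe_weights: tuple = (0.1, 0.2, 0.3)
    smoothing: float = 0.1
    use_ram: bool = True
    use_detail: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.smoothing < 1.0:
            raise ValueError("smoothing must be in [0, 1)")
        if any(w < 0 for w in self.rfe_weights) or len(self.rfe_weights) != 3:
            raise ValueError("rfe_weights must be three nonnegative reals")
        if self.elu_alpha <= 0 or self.width_multiplier <= 0:
            raise ValueError("elu_alpha and width_multiplier must be positive")

    def scaled(self, base: int) -> int:
        return max(1, int(round(base * self.width_multiplier)))

    @property
    def stage_widths(self) -> tuple:
        return tuple(self.scaled(w) for w in BASE_STAGE_WIDTHS)

    @property
    def lateral_width(self) -> int:
        return self.scaled(BASE_LATERAL_WIDTH)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rfe_weights"] = list(self.rfe_weights)
        return d


# ---------------------------------------------------------------------------
# pointwise reference functions (NumPy)
# ---------------------------------------------------------------------------

def elu(x, alpha: float = 1.0):
    """Exponential linear unit: ``x`` for ``x > 0``, ``alpha*(e^x - 1)`` else.

    Continuous at zero and lower-bounded by ``-alpha``; the derivative of the
    negative branch, ``alpha * e^x``, never vanishes, so negative inputs keep
    a live gradient.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0)))
    return out if out.ndim else float(out)


def softmax(z) -> np.ndarray:
    """Stable softmax (max-subtracted); the result sums to one."""
    return ops.softmax_np(np.asarray(z, dtype=np.float64), axis=-1)


def smooth_labels(y: int, n_classes: int, epsilon: float) -> np.ndarray:
    """Smoothed target: ``1 - eps`` on the true class, ``eps/(K-1)`` elsewhere."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must be in [0, 1)")
    if not 0 <= y < n_classes:
        raise ValueError("class index out of range")
    p = np.full(n_classes, epsilon / (n_classes - 1), dtype=np.float64)
    p[y] = 1.0 - epsilon
    return p


def smoothed_cross_entropy(q, y: int, epsilon: float) -> float:
    """Cross entropy of probabilities ``q`` against the smoothed target.

    ``-sum_i P_i log q_i`` with ``P`` from :func:`smooth_labels`; probabilities
    are floored at 1e-12 inside the logarithm.  ``epsilon = 0`` reduces to
    standard cross entropy.
    """
    q = np.asarray(q, dtype=np.float64)
    p = smooth_labels(y, q.shape[-1], epsilon)
    return float(-(p * np.log(np.maximum(q, 1e-12))).sum())


def total_loss(main_logits, aux_logits, target, config: ModelConfig):
    """Main smoothed cross entropy plus weighted mean auxiliary loss.

    ``loss = sce(main) + aux_weight * mean_k sce(aux_k)`` (+ ``loc_weight``
    times localization terms, identically zero without box targets).  With
    ``aux_weight = 0`` or no auxiliary heads the result is exactly the main
    loss.  Accepts tensors (returns a graph scalar) for training.
    """
    target = np.atleast_1d(np.asarray(target, dtype=np.int64))
    main = main_logits if isinstance(main_logits, nn.Tensor) else \
        nn.Tensor(np.atleast_2d(main_logits))
    loss = ops.smoothed_cross_entropy_logits(main, target, config.smoothing)
    if aux_logits and config.aux_weight > 0:
        aux_terms = [
            ops.smoothed_cross_entropy_logits(
                a if isinstance(a, nn.Tensor) else nn.Tensor(np.atleast_2d(a)),
                target, config.smoothing)
            for a in aux_logits
        ]
        aux_sum = aux_terms[0]
        for t in aux_terms[1:]:
            aux_sum = aux_sum + t
        loss = loss + aux_sum * (config.aux_weight / len(aux_terms))
    return loss


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

class Bottleneck(nn.Module):
    """1×1 reduce → 3×3 (stride) → 1×1 expand, with a projection shortcut
    when the shape changes.  The last BN starts at zero so each block begins
    as an identity plus a learnable residual."""

    def __init__(self, in_ch, mid_ch, out_ch, stride, activation, alpha):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, mid_ch, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(mid_ch)
        self.conv2 = nn.Conv2d(mid_ch, mid_ch, 3, stride=stride, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(mid_ch)
        self.conv3 = nn.Conv2d(mid_ch, out_ch, 1, bias=False)
        self.bn3 = nn.BatchNorm2d(out_ch, zero_init=True)
        self.act = nn.Activation(activation, alpha)
        if in_ch != out_ch or stride != 1:
            self.short_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False)
            self.short_bn = nn.BatchNorm2d(out_ch)
        else:
            self.short_conv = None

    def forward(self, x):
        h = self.act(self.bn1(self.conv1(x)))
        h = self.act(self.bn2(self.conv2(h)))
        h = self.bn3(self.conv3(h))
        s = self.short_bn(self.short_conv(x)) if self.short_conv is not None else x
        return self.act(h + s)


class Backbone(nn.Module):
    """Stem + four bottleneck stages (3/4/6/3), RAM after each stage."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        act, alpha = config.activation, config.elu_alpha
        stem_ch = config.scaled(64)
        self.stem_conv = nn.Conv2d(3, stem_ch, 7, stride=2, padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(stem_ch)
        self.act = nn.Activation(act, alpha)
        widths = config.stage_widths
        mids = tuple(config.scaled(w // 4) for w in BASE_STAGE_WIDTHS)
        stages = []
        in_ch = stem_ch
        for si, (out_ch, mid_ch, n_blocks) in enumerate(zip(widths, mids, STAGE_BLOCKS)):
            blocks = []
            for bi in range(n_blocks):
                stride = 2 if (si > 0 and bi == 0) else 1
                blocks.append(Bottleneck(in_ch, mid_ch, out_ch, stride, act, alpha))
                in_ch = out_ch
            stages.append(nn.Sequential(*blocks))
        self.stages = nn.ModuleList(stages)
        self.stage_sizes = tuple(config.input_size // f for f in (4, 8, 16, 32))
        if config.use_ram:
            self.rams = nn.ModuleList(
                ResidualAttention(w, s, act, alpha)
                for w, s in zip(widths, self.stage_sizes))
        else:
            self.rams = None

    def forward(self, x):
        size = self.config.input_size
        if x.shape[-2:] != (size, size):
            raise ValueError(f"backbone expects {size}×{size} input, got {x.shape[-2:]}")
        h = self.act(self.stem_bn(self.stem_conv(x)))
        h = ops.maxpool2d(h, 3, 2, padding=1)
        feats = []
        for si, stage in enumerate(self.stages):
            h = stage(h)
            if self.rams is not None:
                h = self.rams[si](h)
            feats.append(h)
        return tuple(feats)


# ---------------------------------------------------------------------------
# detail road
# ---------------------------------------------------------------------------

def residual_feature_enhancement(x, rfe_weights=(0.1, 0.2, 0.3),
                                 ratios=(0.1, 0.2, 0.3)):
    """Multi-ratio pooled context added residually to the top-level map.

    The input is adaptively average-pooled to ``ceil(r * s)`` (minimum 1) for
    each ratio ``r`` of the spatial size ``s``, bilinearly upsampled back and
    added with weights ``rfe_weights``.  Pooling and upsampling both preserve
    constants, so a constant input ``c`` maps to ``c * (1 + sum(weights))``.
    """
    is_tensor = isinstance(x, nn.Tensor)
    t = x if is_tensor else nn.Tensor(np.asarray(x, dtype=np.float32))
    h, w = t.shape[-2:]
    out = t
    for weight, ratio in zip(rfe_weights, ratios):
        th = max(1, int(np.ceil(ratio * h)))
        tw = max(1, int(np.ceil(ratio * w)))
        ctx = ops.resize_bilinear(ops.adaptive_avg_pool2d(t, (th, tw)), (h, w))
        out = out + ctx * float(weight)
    return out if is_tensor else out.data


def weighted_level_fusion(features, weights) -> np.ndarray:
    """Reference fusion: per-pixel convex combination across levels.

    ``features`` is a list of L equally shaped (B, C, H, W) arrays and
    ``weights`` a (B, L, H, W) array summing to one across axis 1.
    """
    feats = [np.asarray(f, dtype=np.float64) for f in features]
    w = np.asarray(weights, dtype=np.float64)
    if len(feats) < 2:
        raise ValueError("fusion requires at least two levels")
    if any(f.shape != feats[0].shape for f in feats):
        raise ValueError("all level features must share one shape")
    if w.shape[1] != len(feats):
        raise ValueError("one weight map per level required")
    out = np.zeros_like(feats[0])
    for l, f in enumerate(feats):
        out += w[:, l:l + 1] * f
    return out


class AdaptiveSpatialFusion(nn.Module):
    """Per-level spatial weight maps (softmax across levels) fuse the levels."""

    def __init__(self, channels: int, n_levels: int,
                 activation: str = "elu", alpha: float = 1.0):
        super().__init__()
        self.n_levels = n_levels
        self.conv1 = nn.Conv2d(channels * n_levels, channels, 3, padding=1)
        self.act = nn.Activation(activation, alpha)
        self.conv2 = nn.Conv2d(channels, n_levels, 1)

    def weight_maps(self, features):
        h = self.act(self.conv1(ops.concat(list(features), axis=1)))
        return ops.channel_softmax(self.conv2(h))

    def forward(self, features):
        features = list(features)
        if len(features) < 2:
            raise ValueError("adaptive spatial fusion requires >= 2 levels")
        if any(f.shape != features[0].shape for f in features):
            raise ValueError("level features must have equal shapes")
        if len(features) != self.n_levels:
            raise ValueError(f"built for {self.n_levels} levels, got {len(features)}")
        w = self.weight_maps(features)
        out = ops.narrow(w, 1, 0, 1) * features[0]
        for l in range(1, len(features)):
            out = out + ops.narrow(w, 1, l, 1) * features[l]
        return out


@dataclass
class DetailPyramid:
    """Laterally projected stage maps M1..M4, fused maps P1..P4, context P5."""

    m: list
    p: list
    p5: object


class DetailPath(nn.Module):
    """Lateral projections, residual feature enhancement, top-down fusion,
    adaptive spatial fusion and the shared auxiliary head."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        cw = config.lateral_width
        self.rfe_weights = tuple(config.rfe_weights)
        self.laterals = nn.ModuleList(
            nn.Conv2d(c, cw, 1) for c in config.stage_widths)
        self.smooths = nn.ModuleList(
            nn.Conv2d(cw, cw, 3, padding=1) for _ in range(4))
        self.asf = AdaptiveSpatialFusion(cw, 4, config.activation, config.elu_alpha)
        # the auxiliary head (normalization + classifier) is shared across levels
        self.aux_norm = nn.BatchNorm1d(cw)
        self.aux_head = nn.Linear(cw, config.n_classes, init_std=0.01)

    def pyramid(self, feats) -> DetailPyramid:
        if len(feats) != 4:
            raise ValueError("detail path expects four stage maps")
        for a, b in zip(feats[:-1], feats[1:]):
            if a.shape[-1] != 2 * b.shape[-1] or a.shape[-2] != 2 * b.shape[-2]:
                raise ValueError("stage maps must halve spatially stage to stage")
        m = [lat(f) for lat, f in zip(self.laterals, feats)]
        p5 = residual_feature_enhancement(m[3], self.rfe_weights)
        t = m[3] + p5
        p = [None] * 4
        p[3] = self.smooths[3](t)
        for k in (2, 1, 0):
            t = m[k] + ops.resize_bilinear(t, m[k].shape[-2:])
            p[k] = self.smooths[k](t)
        return DetailPyramid(m=m, p=p, p5=p5)

    def forward(self, feats):
        pyr = self.pyramid(feats)
        pooled = [ops.adaptive_avg_pool2d(pk, (7, 7)) for pk in pyr.p]
        fused = self.asf(pooled)
        aux = [self.aux_head(self.aux_norm(ops.global_avg_pool(mk)))
               for mk in pyr.m]
        return fused, aux, pyr


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

class MFRANet(nn.Module):
    """Main + detail feature roads feeding one fully connected classifier."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        self.backbone = Backbone(config)
        head_in = config.stage_widths[-1]
        if config.use_detail:
            self.detail = DetailPath(config)
            head_in += config.lateral_width
        else:
            self.detail = None
        # normalizing the pooled descriptor keeps logits on the label-smoothing
        # loss's natural scale; without it deep multiplicative paths inflate
        # the head input and training oscillates
        self.head_norm = nn.BatchNorm1d(head_in)
        self.fc = nn.Linear(head_in, config.n_classes, init_std=0.01)
        nn.init_parameters(self, config.seed)

    def forward(self, x):
        """Return ``(main_logits, aux_logits, class_probabilities)``.

        ``aux_logits`` is a list of four tensors from the shared auxiliary
        head (empty when the detail path is disabled); probabilities are the
        softmax of the main logits.
        """
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(np.asarray(x, dtype=np.float32))
        feats = self.backbone(x)
        desc = ops.global_avg_pool(feats[3])
        aux = []
        if self.detail is not None:
            fused, aux, _ = self.detail(feats)
            desc = ops.concat([desc, ops.global_avg_pool(fused)], axis=1)
        logits = self.fc(self.head_norm(desc))
        probs = ops.softmax_np(logits.data, axis=1)
        return logits, aux, probs

    def predict(self, x, batch_size: int = 32) -> np.ndarray:
        """Argmax class indices (ties break toward the lower index)."""
        x = np.asarray(x, dtype=np.float32)
        out = []
        was_training = self.training
        self.eval()
        with nn.no_grad():
            for i in range(0, len(x), batch_size):
                _, _, probs = self.forward(x[i:i + batch_size])
                out.append(probs.argmax(axis=1))
        if was_training:
            self.train()
        return np.concatenate(out)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        nn.save_checkpoint(path, self, self.config.to_dict())

    @classmethod
    def load(cls, path, expected_config: ModelConfig | None = None) -> "MFRANet":
        import numpy as _np
        import json as _json
        with _np.load(path) as npz:
            cfg_dict = _json.loads(bytes(npz["__config__"].tobytes()).decode())
        if expected_config is not None and expected_config.to_dict() != cfg_dict:
            raise ValueError("checkpoint was produced by a different model config")
        cfg_dict["rfe_weights"] = tuple(cfg_dict["rfe_weights"])
        model = cls(ModelConfig(**cfg_dict))
        nn.load_checkpoint(path, model)
        return model
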