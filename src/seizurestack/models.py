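"""The three spectrogram classifiers and their shared interface.

* ``custom2dcnn`` — six sequential 2-D convolutions (the first maps
  1→64 channels with kernel (2,4) and padding (1,2), then a
  64→64→128→128→256→256 schedule with 3×3 kernels), max-pooling after
  every second convolution, adaptive average pooling to 1×1 and a fully
  connected 256 → 128 → 64 → 1 chain with ReLU and two dropouts (p=0.25).
* ``resnet18`` — an 18-layer residual network whose stem accepts a single
  input channel (kernel 7, stride 2, padding 3) and whose head is
  512 → 256 → 1 with one dropout (p=0.25).  Residual blocks compute the
  residual mapping H(x) = F(x) + x with
  F(x) = BN2(Conv2(ReLU(BN1(Conv1(x))))) — with a zeroed branch the block
  is the exact identity and its input gradient is exactly 1.
* ``efficientnet_b0`` — the compound-scaled B0 plan of mobile inverted
  bottleneck (MBConv) blocks with squeeze-excitation and swish, a
  1-channel stem (kernel 3, stride 2, padding 1), and a 1280 → 1 head
  with one dropout (p=0.2).

All models end in a single logit; ``forward_probability`` applies the
sigmoid, ``extract_features`` returns the activation immediately before
the final 1-unit layer (penultimate widths 64 / 256 / 1280 at
width_scale 1).  ``width_scale`` multiplies every channel/feature width
so that test-sized models train in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .types import SpectrogramImage, ValidationError

__all__ = [
    "ARCHS",
    "PENULTIMATE_WIDTHS",
    "ModelConfig",
    "ShapeError",
    "PretrainedWeightsUnavailable",
    "build_model",
    "build_custom_2dcnn",
    "adapt_resnet18",
    "adapt_efficientnet_b0",
    "forward_probability",
    "extract_features",
    "penultimate_width",
    "zero_residual_branch",
    "BasicBlock",
]

ARCHS = ("custom2dcnn", "resnet18", "efficientnet_b0")

#: penultimate feature widths at width_scale = 1
PENULTIMATE_WIDTHS = {"custom2dcnn": 64, "resnet18": 256, "efficientnet_b0": 1280}

_DEFAULT_DROPOUT = {"custom2dcnn": 0.25, "resnet18": 0.25, "efficientnet_b0": 0.2}


class ShapeError(ValidationError):
    """Input tensor does not match the model's declared input contract."""


class PretrainedWeightsUnavailable(RuntimeError):
    """Pretrained initialization was requested but no checkpoint exists."""


@dataclass(frozen=True)
class ModelConfig:
    arch: str
    pretrained: bool = False
    dropout: float | None = None  # None -> the arch's default rate
    width_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.arch not in ARCHS:
            raise ValidationError(f"unknown arch {self.arch!r}; choose from {ARCHS}")
        if self.dropout is not None and not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")
        if not 0.0 < self.width_scale <= 1.0:
            raise ValidationError("width_scale must be in (0, 1]")

    @property
    def dropout_rate(self) -> float:
        return _DEFAULT_DROPOUT[self.arch] if self.dropout is None else self.dropout


def _scaled(width: int, width_scale: float) -> int:
    return max(1, int(round(width * width_scale)))


def penultimate_width(arch: str, width_scale: float = 1.0) -> int:
    return _scaled(PENULTIMATE_WIDTHS[arch], width_scale)


def _check_input(x: nn.Tensor, min_hw: tuple[int, int], arch: str) -> None:
    if x.ndim != 4:
        raise ShapeError(f"{arch}: expected [batch, 1, H, W], got shape {x.shape}")
    if x.shape[1] != 1:
        raise ShapeError(
            f"{arch}: stem accepts a single input channel, got {x.shape[1]}"
        )
    if x.shape[2] < min_hw[0] or x.shape[3] < min_hw[1]:
        raise ShapeError(
            f"{arch}: input {x.shape[2]}x{x.shape[3]} below minimum "
            f"{min_hw[0]}x{min_hw[1]}"
        )


class _BackboneMixin:
    """Common probability / feature plumbing over `features` + `head`."""

    def forward(self, x):
        return self.head(self.features(x)).reshape(-1)

    def probability(self, x):
        return nn.sigmoid(self.head(self.features(x)).reshape(-1))


class Custom2DCNN(_BackboneMixin, nn.Module):
    MIN_HW = (8, 8)

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.config = cfg
        ws = cfg.width_scale
        rng = np.random.default_rng(cfg.seed)
        c64, c128, c256 = _scaled(64, ws), _scaled(128, ws), _scaled(256, ws)
        p = cfg.dropout_rate
        self.conv1 = nn.Conv2d(1, c64, (2, 4), padding=(1, 2), rng=rng)
        self.conv2 = nn.Conv2d(c64, c64, 3, padding=1, rng=rng)
        self.conv3 = nn.Conv2d(c64, c128, 3, padding=1, rng=rng)
        self.conv4 = nn.Conv2d(c128, c128, 3, padding=1, rng=rng)
        self.conv5 = nn.Conv2d(c128, c256, 3, padding=1, rng=rng)
        self.conv6 = nn.Conv2d(c256, c256, 3, padding=1, rng=rng)
        self.pool = nn.MaxPool2d(2)
        self.fc1 = nn.Linear(c256, c128, rng=rng)
        self.drop1 = nn.Dropout(p)
        self.fc2 = nn.Linear(c128, _scaled(64, ws), rng=rng)
        self.drop2 = nn.Dropout(p)
        self.head = nn.Linear(_scaled(64, ws), 1, rng=rng)

    def features(self, x):
        _check_input(x, self.MIN_HW, "custom2dcnn")
        h = nn.relu(self.conv1(x))
        h = self.pool(nn.relu(self.conv2(h)))
        h = nn.relu(self.conv3(h))
        h = self.pool(nn.relu(self.conv4(h)))
        h = nn.relu(self.conv5(h))
        h = self.pool(nn.relu(self.conv6(h)))
        h = nn.global_avg_pool(h)  # adaptive average pool to 1x1
        h = self.drop1(nn.relu(self.fc1(h)))
        return self.drop2(nn.relu(self.fc2(h)))


class BasicBlock(nn.Module):
    """Residual block computing H(x) = F(x) + shortcut(x)."""

    def __init__(self, cin: int, cout: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, 1, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.downsample = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride, bias=False, rng=rng),
                nn.BatchNorm2d(cout),
            )
        else:
            self.downsample = nn.Identity()

    @property
    def has_identity_shortcut(self) -> bool:
        return isinstance(self.downsample, nn.Identity)

    def forward(self, x):
        f = self.bn2(self.conv2(nn.relu(self.bn1(self.conv1(x)))))
        return f + self.downsample(x)


class ResNet18(_BackboneMixin, nn.Module):
    MIN_HW = (8, 8)

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.config = cfg
        ws = cfg.width_scale
        rng = np.random.default_rng(cfg.seed)
        c = [_scaled(w, ws) for w in (64, 128, 256, 512)]
        self.stem = nn.Conv2d(1, c[0], 7, 2, 3, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c[0])
        self.maxpool = nn.MaxPool2d(3, 2, 1)
        blocks = []
        cin = c[0]
        for stage, cout in enumerate(c):
            for b in range(2):
                stride = 2 if (stage > 0 and b == 0) else 1
                blocks.append(BasicBlock(cin, cout, stride, rng))
                cin = cout
        self.blocks = nn.ModuleList(blocks)
        self.fc = nn.Linear(c[3], _scaled(256, ws), rng=rng)
        self.drop = nn.Dropout(cfg.dropout_rate)
        self.head = nn.Linear(_scaled(256, ws), 1, rng=rng)

    def features(self, x):
        _check_input(x, self.MIN_HW, "resnet18")
        h = self.maxpool(nn.relu(self.bn(self.stem(x))))
        for blk in self.blocks:
            h = blk(h)
        h = nn.global_avg_pool(h)
        return self.drop(nn.relu(self.fc(h)))


class MBConv(nn.Module):
    """Mobile inverted bottleneck with squeeze-excitation and swish."""

    def __init__(self, cin: int, cout: int, expand: int, stride: int,
                 kernel: int, rng: np.random.Generator):
        super().__init__()
        mid = cin * expand
        if expand != 1:
            self.expand_conv = nn.Conv2d(cin, mid, 1, bias=False, rng=rng)
            self.expand_bn = nn.BatchNorm2d(mid)
        else:
            self.expand_conv = None
        self.dw = nn.Conv2d(mid, mid, kernel, stride, kernel // 2,
                            groups=mid, bias=False, rng=rng)
        self.dw_bn = nn.BatchNorm2d(mid)
        se_dim = max(1, cin // 4)
        self.se_reduce = nn.Linear(mid, se_dim, rng=rng)
        self.se_expand = nn.Linear(se_dim, mid, rng=rng)
        self.project = nn.Conv2d(mid, cout, 1, bias=False, rng=rng)
        self.project_bn = nn.BatchNorm2d(cout)
        self.use_skip = stride == 1 and cin == cout
        self._mid = mid

    def forward(self, x):
        h = x
        if self.expand_conv is not None:
            h = nn.silu(self.expand_bn(self.expand_conv(h)))
        h = nn.silu(self.dw_bn(self.dw(h)))
        s = nn.global_avg_pool(h)  # [B, mid]
        s = nn.sigmoid(self.se_expand(nn.silu(self.se_reduce(s))))
        h = h * s.reshape(s.shape[0], self._mid, 1, 1)
        h = self.project_bn(self.project(h))
        if self.use_skip:
            h = h + x
        return h


#: B0 block plan: (expansion, output channels, repeats, first stride, kernel)
_B0_PLAN = [
    (1, 16, 1, 1, 3),
    (6, 24, 2, 2, 3),
    (6, 40, 2, 2, 5),
    (6, 80, 3, 2, 3),
    (6, 112, 3, 1, 5),
    (6, 192, 4, 2, 5),
    (6, 320, 1, 1, 3),
]


class EfficientNetB0(_BackboneMixin, nn.Module):
    MIN_HW = (8, 8)

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.config = cfg
        ws = cfg.width_scale
        rng = np.random.default_rng(cfg.seed)
        c_stem = _scaled(32, ws)
        self.stem = nn.Conv2d(1, c_stem, 3, 2, 1, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(c_stem)
        blocks = []
        cin = c_stem
        for expand, cout, reps, stride, kernel in _B0_PLAN:
            cout = _scaled(cout, ws)
            for r in range(reps):
                blocks.append(MBConv(cin, cout, expand,
                                     stride if r == 0 else 1, kernel, rng))
                cin = cout
        self.blocks = nn.ModuleList(blocks)
        c_head = _scaled(1280, ws)
        self.head_conv = nn.Conv2d(cin, c_head, 1, bias=False, rng=rng)
        self.head_bn = nn.BatchNorm2d(c_head)
        self.drop = nn.Dropout(cfg.dropout_rate)
        self.head = nn.Linear(c_head, 1, rng=rng)

    def features(self, x):
        _check_input(x, self.MIN_HW, "efficientnet_b0")
        h = nn.silu(self.stem_bn(self.stem(x)))
        for blk in self.blocks:
            h = blk(h)
        h = nn.silu(self.head_bn(self.head_conv(h)))
        return self.drop(nn.global_avg_pool(h))


_BUILDERS = {
    "custom2dcnn": Custom2DCNN,
    "resnet18": ResNet18,
    "efficientnet_b0": EfficientNetB0,
}


def build_model(cfg: ModelConfig, pretrained_weights=None) -> nn.Module:
    """Build any of the three architectures from its config.

    ``pretrained_weights``: path to an .npz state dict used to initialize
    the backbone when ``cfg.pretrained`` is set.  A 3-channel stem in the
    provided weights is collapsed to 1 channel by averaging over input
    channels; head weights are always freshly initialized.
    """
    model = _BUILDERS[cfg.arch](cfg)
    if cfg.pretrained:
        if cfg.arch == "custom2dcnn":
            raise ValidationError("pretrained weights apply to the two backbone archs only")
        if pretrained_weights is None or not Path(pretrained_weights).is_file():
            raise PretrainedWeightsUnavailable(
                f"pretrained initialization for {cfg.arch} requested but no "
                f"weight file was provided (got {pretrained_weights!r})"
            )
        _load_backbone_weights(model, pretrained_weights)
    return model


def build_custom_2dcnn(cfg: ModelConfig) -> Custom2DCNN:
    if cfg.arch != "custom2dcnn":
        raise ValidationError(f"config arch is {cfg.arch!r}, expected custom2dcnn")
    return build_model(cfg)


def adapt_resnet18(cfg: ModelConfig, pretrained_weights=None) -> ResNet18:
    if cfg.arch != "resnet18":
        raise ValidationError(f"config arch is {cfg.arch!r}, expected resnet18")
    return build_model(cfg, pretrained_weights)


def adapt_efficientnet_b0(cfg: ModelConfig, pretrained_weights=None) -> EfficientNetB0:
    if cfg.arch != "efficientnet_b0":
        raise ValidationError(f"config arch is {cfg.arch!r}, expected efficientnet_b0")
    return build_model(cfg, pretrained_weights)


def _load_backbone_weights(model: nn.Module, path) -> None:
    state = dict(np.load(path))
    own = model.state_dict()
    head_prefixes = ("head", "fc", "drop")
    for name, arr in state.items():
        if name.startswith(head_prefixes) or name not in own:
            continue
        if own[name].shape != arr.shape:
            if arr.ndim == 4 and arr.shape[1] == 3 and own[name].shape[1] == 1:
                arr = arr.mean(axis=1, keepdims=True)  # RGB stem -> mono stem
            else:
                raise ValidationError(
                    f"pretrained weight {name} has shape {arr.shape}, "
                    f"model expects {own[name].shape}"
                )
        own[name] = np.asarray(arr, dtype=np.float64)
    model.load_state_dict(own)


def as_batch(image) -> np.ndarray:
    """Coerce a SpectrogramImage / 2-D array / batch into [B, 1, H, W]."""
    if isinstance(image, SpectrogramImage):
        arr = image.values
    else:
        arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        return arr[None, None]
    if arr.ndim == 3:
        return arr[:, None]
    if arr.ndim == 4:
        return arr
    raise ShapeError(f"cannot interpret array of ndim {arr.ndim} as image batch")


def forward_probability(model: nn.Module, image) -> float | np.ndarray:
    """Seizure probability in (0, 1); deterministic (dropout inactive)."""
    batch = as_batch(image)
    single = isinstance(image, SpectrogramImage) or np.asarray(
        getattr(image, "values", image)).ndim == 2
    model.eval()
    probs = model.probability(nn.Tensor(batch)).data
    return float(probs[0]) if single else probs


def extract_features(model: nn.Module, image) -> np.ndarray:
    """Penultimate activation (the stacking ensemble's per-model features)."""
    batch = as_batch(image)
    single = isinstance(image, SpectrogramImage) or np.asarray(
        getattr(image, "values", image)).ndim == 2
    model.eval()
    feats = model.features(nn.Tensor(batch)).data
    return feats[0] if single else feats


def zero_residual_branch(block: BasicBlock) -> None:
    """Zero a residual block's branch so it computes the identity map."""
    for p in (block.conv1.weight, block.conv2.weight,
              block.bn1.gamma, block.bn1.beta, block.bn2.gamma, block.bn2.beta):
        p.data = np.zeros_like(p.data)
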