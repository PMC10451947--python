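"""The lightweight finger-vein identification network.

Architecture (112×112×3 input):

* **input flow** — 3×3 DBB → ReLU → coordinate attention → APS, taking
  the map to 56×56×16;
* **middle flow** — four diverse-branch residual blocks (DBRB) with
  channel widths 16→32→64→128→256 and spatial trajectory
  56→28→14→7→(pad to 8)→4, ending at 4×4×256;
* **output flow** — global average pooling to a 256-d vector, dropout,
  then a bias-free cosine classifier head on the L2-normalized
  embedding.

Each DBRB runs two 3×3 DBB convolutions, coordinate attention and an
APS downsample on the main path, and a 1×1 convolution + APS on the
shortcut; the shortcut reuses the phase the main path selected so the
two half-resolution grids stay aligned before the residual addition.

``reparameterize_model`` collapses every DBB into a single convolution
(deploy mode); ``profile_model`` counts parameters and MACs of the
deployed network.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .attention import CoordinateAttention
from .autodiff import Tensor, no_grad, profile_macs
from .nn import (BatchNorm2d, Conv2d, Dropout, Module, global_avg_pool,
                 l2_normalize)
from .reparam import DiverseBranchBlock, fused_to_conv
from .sampling import APSDownsample


@dataclass(frozen=True)
class ILCNNConfig:
    num_classes: int
    input_size: int = 112
    in_channels: int = 3
    stage_channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    embedding_dim: int = 256
    dropout_rate: float = 0.2
    scale: float = 64.0          # cosine-logit scale s
    aps_p: float = 2.0
    block_style: str = "dbrb"    # dbrb | basic (ablation variant)
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 1:
            raise ValueError("need at least one identity class")
        if len(self.stage_channels) != 5:
            raise ValueError("expect one input width plus four block widths")
        if self.stage_channels[-1] != self.embedding_dim:
            raise ValueError("last stage width must equal the embedding dim")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        if self.block_style not in ("dbrb", "basic"):
            raise ValueError("block_style must be 'dbrb' or 'basic'")


class DBRB(Module):
    """Diverse-branch residual block (train-structure form)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 aps_p: float = 2.0, deploy: bool = False):
        super().__init__()
        conv = (lambda ci, co: fused_like_conv(ci, co, rng)) if deploy else \
               (lambda ci, co: DiverseBranchBlock(ci, co, 3, rng=rng))
        self.conv1 = conv(cin, cout)
        self.conv2 = conv(cout, cout)
        self.attn = CoordinateAttention(cout, rng=rng)
        self.aps = APSDownsample(aps_p)
        self.shortcut = Conv2d(cin, cout, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        m = self.conv1(x).relu()
        m = self.conv2(m)
        m = self.attn(m)
        m, phase = self.aps(m)
        s, _ = self.aps(self.shortcut(x), forced_phase=phase)
        return (m + s).relu()


def fused_like_conv(cin: int, cout: int,
                    rng: np.random.Generator) -> Conv2d:
    """Deploy-mode stand-in for a 3×3 DBB: one same-padded convolution."""
    return Conv2d(cin, cout, 3, stride=1, padding=1, bias=True, rng=rng)


class BasicResidualBlock(Module):
    """Plain ResNet-style block (the ablation baseline): two 3×3
    convolutions with BN, stride-2 downsampling, 1×1 strided shortcut.
    No DBB, no attention, no adaptive sampling."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, stride=2, padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, stride=1, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.shortcut = Conv2d(cin, cout, 1, stride=2, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        m = self.bn1(self.conv1(x)).relu()
        m = self.bn2(self.conv2(m))
        return (m + self.shortcut(x)).relu()


class ILCNN(Module):
    def __init__(self, cfg: ILCNNConfig, deploy: bool = False):
        super().__init__()
        self.cfg = cfg
        self.deploy = deploy
        rng = np.random.default_rng(cfg.seed)
        c0 = cfg.stage_channels[0]
        if deploy:
            self.stem = fused_like_conv(cfg.in_channels, c0, rng)
        else:
            self.stem = DiverseBranchBlock(cfg.in_channels, c0, 3, rng=rng)
        self.stem_attn = CoordinateAttention(c0, rng=rng)
        self.stem_aps = APSDownsample(cfg.aps_p)
        widths = cfg.stage_channels
        if cfg.block_style == "dbrb":
            self.blocks = [DBRB(widths[i], widths[i + 1], rng,
                                aps_p=cfg.aps_p, deploy=deploy)
                           for i in range(4)]
        else:
            self.blocks = [BasicResidualBlock(widths[i], widths[i + 1], rng)
                           for i in range(4)]
        self.dropout = Dropout(cfg.dropout_rate,
                               rng=np.random.default_rng(cfg.seed + 1))
        from .nn import Parameter
        head = rng.normal(0.0, 0.01, (cfg.num_classes, cfg.embedding_dim))
        self.head_weight = Parameter(head.astype(np.float32))

    # -- forward pieces -------------------------------------------------------
    def features(self, x: Tensor) -> Tensor:
        """Input + middle flow: NCHW image batch -> 4×4×C_last map."""
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels \
                or x.shape[2] != self.cfg.input_size \
                or x.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"expected (N, {self.cfg.in_channels}, {self.cfg.input_size}, "
                f"{self.cfg.input_size}) input, got {x.shape}")
        y = self.stem(x).relu()
        y = self.stem_attn(y)
        y, _ = self.stem_aps(y)
        self.input_flow_shape = y.shape
        for block in self.blocks:
            y = block(y)
        self.middle_flow_shape = y.shape
        return y

    def embed(self, x: Tensor) -> Tensor:
        """Pooled 256-d embedding after dropout (not yet normalized)."""
        pooled = global_avg_pool(self.features(x))
        return self.dropout(pooled)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (unit-norm embedding, margin-free cosine logits s·cosθ)."""
        emb = l2_normalize(self.embed(x), axis=1)
        w = l2_normalize(self.head_weight, axis=1)
        logits = self.cfg.scale * (emb @ w.transpose(1, 0))
        return emb, logits

    # -- checkpointing --------------------------------------------------------
    def save(self, path) -> None:
        state = self.state_dict()
        meta = json.dumps({"config": asdict(self.cfg), "deploy": self.deploy})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **state)

    @classmethod
    def load(cls, path) -> "ILCNN":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        cfg_dict = meta["config"]
        cfg_dict["stage_channels"] = tuple(cfg_dict["stage_channels"])
        model = cls(ILCNNConfig(**cfg_dict), deploy=meta["deploy"])
        model.load_state_dict(state)
        return model


def build_ilcnn(cfg: ILCNNConfig, deploy: bool = False) -> ILCNN:
    return ILCNN(cfg, deploy=deploy)


def reparameterize_model(model: ILCNN) -> ILCNN:
    """Fuse every DBB, producing an equivalent deploy-mode network.

    The model must be in evaluation state (populated running BN
    statistics); the fused convolutions are computed in double
    precision and cast back to the working dtype.
    """
    if model.deploy:
        raise RuntimeError("model is already in deploy mode")
    if model.training:
        raise RuntimeError(
            "switch to eval() before fusing: equivalence holds only for "
            "fixed BN statistics")
    if model.cfg.block_style != "dbrb":
        raise RuntimeError("only the DBRB variant carries DBB layers to fuse")
    deployed = ILCNN(model.cfg, deploy=True)
    deployed.eval()
    state = {}
    src = dict(model.named_parameters())
    src_buf = dict(model.named_buffers())

    def put_fused(prefix: str, block: DiverseBranchBlock):
        fk = block.fuse()
        state[f"{prefix}.weight"] = fk.weight.astype(np.float32)
        state[f"{prefix}.bias"] = fk.bias.astype(np.float32)

    put_fused("stem", model.stem)
    for i, block in enumerate(model.blocks):
        put_fused(f"blocks.{i}.conv1", block.conv1)
        put_fused(f"blocks.{i}.conv2", block.conv2)
    # everything that is not a DBB copies over verbatim
    for name, p in src.items():
        if not (name.startswith("stem.") or
                ".conv1." in name or ".conv2." in name):
            state[name] = p.data
    for name, b in src_buf.items():
        if not (name.startswith("stem.") or
                ".conv1." in name or ".conv2." in name):
            state[name] = b
    deployed.load_state_dict(state)
    return deployed


@dataclass
class ModelProfile:
    param_count: int          # backbone (through the embedding)
    mac_count: int            # backbone MACs for one 112×112×3 input
    params_millions: float
    gmacs: float
    head_param_count: int
    total_param_count: int

    def __post_init__(self):
        assert self.total_param_count == self.param_count + self.head_param_count


def profile_model(model: ILCNN, input_size: int | None = None) -> ModelProfile:
    """Count trainable parameters and multiply-accumulates (deploy mode).

    MAC convention: ``K² · Cin · Cout · Hout · Wout`` per convolution
    plus ``in · out`` per linear map, at a single input of the given
    resolution.  The backbone figures exclude the class-count-dependent
    classifier head; both are reported.
    """
    if not model.deploy:
        raise RuntimeError("profile the fused (deploy-mode) model; "
                           "run reparameterize_model first")
    input_size = input_size or model.cfg.input_size
    head = model.head_weight.data.size
    total = sum(p.data.size for p in model.parameters())
    backbone = total - head
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, model.cfg.in_channels, input_size, input_size),
                        dtype=np.float32))
    with no_grad(), profile_macs() as counter:
        model.embed(x)
    macs = counter.macs
    if was_training:
        model.train()
    return ModelProfile(
        param_count=backbone,
        mac_count=macs,
        params_millions=round(backbone / 1e6, 2),
        gmacs=round(macs / 1e9, 2),
        head_param_count=head,
        total_param_count=total,
    )
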