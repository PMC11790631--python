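"""Two-stream residual network with cross-stream fusion.

Each stream is a ResNet-18-style backbone (17 convolutional layers: one 7x7
stem plus four stages of two basic blocks with two 3x3 convs each).  The two
streams process the front and the back view of the same flower.  Fusion
happens in two places:

* **Cross-stream residual connections** in the final (512-channel) stage:
  each stream's block output is ``h(x_p) + h(x_q) + F(x_p, W_p)``, i.e. the
  other stream's identity-mapped activation joins the residual update.
* **Weighted fully-connected fusion**: before each per-stream FC layer the
  other stream's vector is added with weight ``alpha`` (default 1/3, an own-
  to-cross ratio of 1:3): ``out_p = G_p(y_p + alpha * y_q)``.

The two 32-d stream vectors are concatenated (64-d) and a final FC layer
produces the class logits.

Residual additions carry no post-add activation: a block computes the
additive form ``h(x) + F(x)`` exactly, with the nonlinearity inside the
residual branch ``F = conv-BN-relu-conv-BN``.  This keeps the block's output
identical to the stated update rule (and lets the degenerate cases, e.g.
``F = 0``, hold to machine precision) while behaving like a pre-activation
residual design.
"""

from __future__ import annotations

import dataclasses
import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

MODES = ("two_stream_full", "front_only", "back_only", "concat_only", "conv_cross_only")

#: stage channel plan of the canonical (224-input) backbone
CANONICAL_CHANNELS = (64, 64, 128, 256, 512)
#: reduced plan for the desk-scale (32-input) profile
FAST_CHANNELS = (8, 8, 16, 32, 64)


@dataclass
class ModelSpec:
    """Architecture description for :func:`build_two_stream`."""

    num_classes: int
    stage_channels: tuple = CANONICAL_CHANNELS
    blocks_per_stage: int = 2
    fc_dims: tuple = (128, 32)
    fusion_alpha: float = 1.0 / 3.0
    cross_residual_stage: int | None = 4  # 1-based stage index; None disables
    fc_fusion_enabled: bool = True
    mode: str = "two_stream_full"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.fusion_alpha < 0:
            raise ValueError("fusion_alpha must be >= 0")
        self.stage_channels = tuple(int(c) for c in self.stage_channels)
        self.fc_dims = tuple(int(d) for d in self.fc_dims)
        if len(self.stage_channels) != 5:
            raise ValueError("stage_channels must have 5 entries (stem + 4 stages)")

    @property
    def single_stream(self) -> bool:
        return self.mode in ("front_only", "back_only")

    @property
    def use_cross_residual(self) -> bool:
        if self.single_stream or self.mode == "concat_only":
            return False
        return self.cross_residual_stage is not None

    @property
    def use_fc_fusion(self) -> bool:
        if self.single_stream or self.mode in ("concat_only", "conv_cross_only"):
            return False
        return self.fc_fusion_enabled

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if d.get("cross_residual_stage") is not None:
            d["cross_residual_stage"] = int(d["cross_residual_stage"])
        return cls(**d)


def fast_spec(num_classes: int, **overrides) -> ModelSpec:
    """Desk-scale spec: reduced channels and FC widths for 32x32 inputs."""
    kw = dict(stage_channels=FAST_CHANNELS, fc_dims=(32, 16))
    kw.update(overrides)
    return ModelSpec(num_classes=num_classes, **kw)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class BasicBlock(nn.Module):
    """Residual basic block: out = h(x) + F(x), F = conv-BN-relu-conv-BN.

    ``h`` is the identity, or a 1x1 strided projection (conv + BN) when the
    block changes resolution or channel count.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride, 1, rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, 1, 1, rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.ds_conv = nn.Conv2d(in_ch, out_ch, 1, stride, 0, rng)
            self.ds_bn = nn.BatchNorm2d(out_ch)
        else:
            self.ds_conv = None
            self.ds_bn = None

    def residual_branch(self, x: Tensor) -> Tensor:
        out = self.bn1.forward(self.conv1.forward(x))
        out = nn.relu(out)
        return self.bn2.forward(self.conv2.forward(out))

    def shortcut(self, x: Tensor) -> Tensor:
        if self.ds_conv is None:
            return x
        return self.ds_bn.forward(self.ds_conv.forward(x))

    def forward(self, x: Tensor) -> Tensor:
        return nn.add(self.shortcut(x), self.residual_branch(x))


class CrossStreamBlock(nn.Module):
    """Paired residual blocks whose shortcut sums both streams.

    For each stream p (with q the other stream)::

        Re_p  = h_p(x_p + x_q)          # h_p identity, or projection when downsampling
        out_p = Re_p + F_p(x_p, W_p)

    Both outputs are computed synchronously from the pre-update inputs.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.front = BasicBlock(in_ch, out_ch, stride, rng)
        self.back = BasicBlock(in_ch, out_ch, stride, rng)

    def forward(self, x_front: Tensor, x_back: Tensor):
        if x_front.shape != x_back.shape:
            raise ValueError(
                f"stream shape mismatch: {x_front.shape} vs {x_back.shape}"
            )
        summed = nn.add(x_front, x_back)
        out_f = nn.add(self.front.shortcut(summed), self.front.residual_branch(x_front))
        out_b = nn.add(self.back.shortcut(summed), self.back.residual_branch(x_back))
        return out_f, out_b


def cross_stream_block_forward(x_front, x_back, block: CrossStreamBlock):
    """Apply one cross-stream residual block to a pre-update activation pair."""
    xf = x_front if isinstance(x_front, Tensor) else Tensor(x_front)
    xb = x_back if isinstance(x_back, Tensor) else Tensor(x_back)
    return block.forward(xf, xb)


def fc_fusion_forward(y_front, y_back, g_front, g_back, alpha: float):
    """Weighted FC fusion: out_p = G_p(y_p + alpha * y_q), synchronously.

    ``g_front``/``g_back`` are callables (e.g. :class:`nn.Linear` forward
    methods or the identity).  ``alpha`` is the cross-stream weight; the
    paper's 1:3 own-to-cross ratio corresponds to ``alpha = 1/3``.
    """
    yf = y_front if isinstance(y_front, Tensor) else Tensor(y_front)
    yb = y_back if isinstance(y_back, Tensor) else Tensor(y_back)
    if yf.shape != yb.shape:
        raise ValueError(f"stream dim mismatch: {yf.shape} vs {yb.shape}")
    fused_f = nn.add(yf, nn.scale(yb, alpha)) if alpha != 0 else yf
    fused_b = nn.add(yb, nn.scale(yf, alpha)) if alpha != 0 else yb
    return g_front(fused_f), g_back(fused_b)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class _Stream(nn.Module):
    """One backbone stream: stem + 4 stages of basic blocks (17 convs)."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator, cross_final: bool):
        super().__init__()
        ch = spec.stage_channels
        self.stem_conv = nn.Conv2d(3, ch[0], 7, 2, 3, rng)
        self.stem_bn = nn.BatchNorm2d(ch[0])
        self.stages = []
        in_ch = ch[0]
        for stage_idx in range(1, 5):
            out_ch = ch[stage_idx]
            blocks = []
            for b in range(spec.blocks_per_stage):
                stride = 2 if (stage_idx > 1 and b == 0) else 1
                blocks.append(BasicBlock(in_ch, out_ch, stride, rng))
                in_ch = out_ch
            self.stages.append(blocks)

    def stem(self, x: Tensor) -> Tensor:
        out = nn.relu(self.stem_bn.forward(self.stem_conv.forward(x)))
        return nn.maxpool2d(out, 3, 2, 1)


class TwoStreamNet(nn.Module):
    """The full classifier; see the module docstring for the fusion scheme."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator | int | None = None):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.spec = spec
        d1, d2 = spec.fc_dims
        feat = spec.stage_channels[-1]
        if spec.single_stream:
            self.stream = _Stream(spec, rng, cross_final=False)
            self.fc1 = nn.Linear(feat, d1, rng)
            self.fc3 = nn.Linear(d1, d2, rng)
            self.head = nn.Linear(d2, spec.num_classes, rng)
        else:
            self.stream_front = _Stream(spec, rng, cross_final=spec.use_cross_residual)
            self.stream_back = _Stream(spec, rng, cross_final=spec.use_cross_residual)
            self.fc1 = nn.Linear(feat, d1, rng)   # front 512 -> 128
            self.fc2 = nn.Linear(feat, d1, rng)   # back  512 -> 128
            self.fc3 = nn.Linear(d1, d2, rng)     # front 128 -> 32
            self.fc4 = nn.Linear(d1, d2, rng)     # back  128 -> 32
            self.head = nn.Linear(2 * d2, spec.num_classes, rng)  # FC5: 64 -> classes

    # -- forward ------------------------------------------------------------

    def _run_stages(self, front: Tensor, back: Tensor, cache: dict | None):
        """Run both streams through the 4 stages, crossing in the final one."""
        sf, sb = self.stream_front, self.stream_back
        xf, xb = sf.stem(front), sb.stem(back)
        for stage_idx in range(4):
            final = stage_idx == 3
            for bf, bb in zip(sf.stages[stage_idx], sb.stages[stage_idx]):
                if final and self.spec.use_cross_residual:
                    summed = nn.add(xf, xb)
                    nf = nn.add(bf.shortcut(summed), bf.residual_branch(xf))
                    nb = nn.add(bb.shortcut(summed), bb.residual_branch(xb))
                    xf, xb = nf, nb
                else:
                    xf, xb = bf.forward(xf), bb.forward(xb)
        if cache is not None:
            cache["stage4_front"], cache["stage4_back"] = xf, xb
        return xf, xb

    def forward(self, front, back=None, cache: dict | None = None) -> Tensor:
        """Return the logits tensor for a batch (NCHW float arrays or Tensors)."""
        spec = self.spec
        if spec.single_stream:
            x = front if spec.mode == "front_only" else (back if back is not None else front)
            if spec.mode == "back_only" and back is not None:
                x = back
            x = x if isinstance(x, Tensor) else Tensor(x)
            s = self.stream
            out = s.stem(x)
            for stage in s.stages:
                for block in stage:
                    out = block.forward(out)
            if cache is not None:
                cache["stage4"] = out
            z = nn.global_avg_pool(out)
            a = nn.relu(self.fc1.forward(z))
            b = nn.relu(self.fc3.forward(a))
            if cache is not None:
                cache["embedding"] = b
            return self.head.forward(b)

        if back is None:
            raise ValueError("two-stream modes require both views")
        front = front if isinstance(front, Tensor) else Tensor(front)
        back = back if isinstance(back, Tensor) else Tensor(back)
        if front.shape != back.shape:
            raise ValueError(f"view shape mismatch: {front.shape} vs {back.shape}")
        xf, xb = self._run_stages(front, back, cache)
        zf, zb = nn.global_avg_pool(xf), nn.global_avg_pool(xb)
        alpha = spec.fusion_alpha if spec.use_fc_fusion else 0.0
        af, ab = fc_fusion_forward(zf, zb, self.fc1.forward, self.fc2.forward, alpha)
        af, ab = nn.relu(af), nn.relu(ab)
        bf, bb = fc_fusion_forward(af, ab, self.fc3.forward, self.fc4.forward, alpha)
        bf, bb = nn.relu(bf), nn.relu(bb)
        fused = nn.concat(bf, bb, axis=1)
        if cache is not None:
            cache["embedding"] = fused
        return self.head.forward(fused)

    # -- introspection ------------------------------------------------------

    def conv_layers(self, stream: str = "front"):
        """Ordered conv layers of one stream (stem first); length 17.

        Downsample projections are listed alongside their block but do not
        count toward the 17 (matching the usual ResNet-18 layer count).
        """
        if self.spec.single_stream:
            s = self.stream
        else:
            s = self.stream_front if stream == "front" else self.stream_back
        layers = [s.stem_conv]
        for stage in s.stages:
            for block in stage:
                layers.extend([block.conv1, block.conv2])
        return layers

    def conv_units(self, stream: str = "front"):
        """(conv, bn) pairs per conv layer plus downsample units, in order.

        Unit i corresponds to conv layer i; downsample projections travel
        with the *first* conv of their block.
        """
        if self.spec.single_stream:
            s = self.stream
        else:
            s = self.stream_front if stream == "front" else self.stream_back
        units = [[(s.stem_conv, s.stem_bn)]]
        for stage in s.stages:
            for block in stage:
                first = [(block.conv1, block.bn1)]
                if block.ds_conv is not None:
                    first.append((block.ds_conv, block.ds_bn))
                units.append(first)
                units.append([(block.conv2, block.bn2)])
        return units

    def streams(self):
        if self.spec.single_stream:
            return ("single",)
        return ("front", "back")


def build_two_stream(spec: ModelSpec, rng: np.random.Generator | int | None = None) -> TwoStreamNet:
    """Construct the network described by ``spec`` with seeded initialization."""
    return TwoStreamNet(spec, rng)


# ---------------------------------------------------------------------------
# shape chain
# ---------------------------------------------------------------------------

def forward_shapes(spec: ModelSpec, input_size: int = 224):
    """Analytic per-stage output shapes, as an ordered list of (name, shape).

    Spatial shapes are (H, W, C); FC shapes are (dim,).  For a 224 input and
    the canonical channel plan this reproduces the printed chain
    112x112x64 -> 56x56x64 -> 56x56x64 -> 28x28x128 -> 14x14x256 -> 7x7x512
    -> 1x1x512 -> 128 -> 32 -> 64 -> num_classes.
    """
    ch = spec.stage_channels
    s = (input_size + 2 * 3 - 7) // 2 + 1          # 7x7 stride-2 pad-3 stem
    shapes = [("conv1", (s, s, ch[0]))]
    s = (s + 2 * 1 - 3) // 2 + 1                   # 3x3 stride-2 pad-1 maxpool
    shapes.append(("maxpool", (s, s, ch[0])))
    for stage_idx in range(1, 5):
        if stage_idx > 1:
            s = (s + 2 * 1 - 3) // 2 + 1           # first block strides by 2
        shapes.append((f"conv{stage_idx + 1}", (s, s, ch[stage_idx])))
    shapes.append(("avgpool", (1, 1, ch[4])))
    shapes.append(("fc_1", (spec.fc_dims[0],)))
    shapes.append(("fc_2", (spec.fc_dims[1],)))
    if not spec.single_stream:
        shapes.append(("concat", (2 * spec.fc_dims[1],)))
    shapes.append(("logits", (spec.num_classes,)))
    return shapes


def conv_layer_count(spec: ModelSpec) -> int:
    """Conv layers per stream: stem + stages * blocks * 2."""
    return 1 + 4 * spec.blocks_per_stage * 2


def shallow_conv_layer_count(spec: ModelSpec) -> int:
    """Conv layers in the shallow (transfer-frozen) part: stem + stages 1-3."""
    return 1 + 3 * spec.blocks_per_stage * 2


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------

def classify(model: TwoStreamNet, view_pair):
    """Logits and argmax prediction for one preprocessed view pair.

    ``view_pair`` provides ``front`` and ``back`` as HWC float arrays of
    identical square shape.  Ties break to the lowest class index.
    """
    front = np.asarray(view_pair.front, dtype=np.float64)
    back = np.asarray(view_pair.back, dtype=np.float64)
    for name, v in (("front", front), ("back", back)):
        if v.ndim != 3 or v.shape[2] != 3 or v.shape[0] != v.shape[1]:
            raise ValueError(f"{name} view is not a preprocessed square HWC image: {v.shape}")
    fb = front.transpose(2, 0, 1)[None]
    bb = back.transpose(2, 0, 1)[None]
    model.eval()
    logits = model.forward(fb, bb).data[0]
    return logits, int(np.argmax(logits))


def count_parameters(model: TwoStreamNet) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.data.size for p in model.parameters() if p.trainable))


# ---------------------------------------------------------------------------
# checkpoint round-trip
# ---------------------------------------------------------------------------

def _state_arrays(model: TwoStreamNet):
    arrays = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"param_{i:04d}"] = p.data
    bn_idx = 0
    for m in model.modules():
        if isinstance(m, nn.BatchNorm2d):
            arrays[f"bn_mean_{bn_idx:04d}"] = m.running_mean
            arrays[f"bn_var_{bn_idx:04d}"] = m.running_var
            bn_idx += 1
    return arrays


def get_state(model: TwoStreamNet):
    """Deep-copied state (parameters + batch-norm statistics)."""
    return {k: v.copy() for k, v in _state_arrays(model).items()}


def set_state(model: TwoStreamNet, state: dict):
    for i, p in enumerate(model.parameters()):
        p.data = state[f"param_{i:04d}"].copy()
    bn_idx = 0
    for m in model.modules():
        if isinstance(m, nn.BatchNorm2d):
            m.running_mean = state[f"bn_mean_{bn_idx:04d}"].copy()
            m.running_var = state[f"bn_var_{bn_idx:04d}"].copy()
            bn_idx += 1
    return model


def save_checkpoint(model: TwoStreamNet, path, classes=None, preprocess_config=None, extra=None):
    """Serialize weights + spec + label ordering + preprocessing config.

    The container is a zip holding one .npy per array plus a JSON metadata
    entry; float64 arrays round-trip bit-exactly.
    """
    meta = {
        "model_spec": model.spec.to_dict(),
        "classes": list(classes) if classes is not None else None,
        "preprocess_config": preprocess_config,
        "extra": extra or {},
    }
    arrays = _state_arrays(model)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for k, v in arrays.items():
            buf = io.BytesIO()
            np.save(buf, v)
            zf.writestr(k + ".npy", buf.getvalue())


def load_checkpoint(path):
    """Rebuild a model from :func:`save_checkpoint`; returns (model, meta)."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        state = {}
        for name in zf.namelist():
            if name.endswith(".npy"):
                state[name[:-4]] = np.load(io.BytesIO(zf.read(name)))
    spec = ModelSpec.from_dict(meta["model_spec"])
    model = build_two_stream(spec, rng=0)
    set_state(model, state)
    return model, meta
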