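"""Multi-task encoder-decoder for joint lesion segmentation and diagnosis.

The backbone is a U-Net with six stride-2 encoder blocks (feature widths
32, 64, 128, 256, 320, 320 by default), so input height and width must be
multiples of 64 and the bottleneck is the input size divided by 64. Each
encoder block is conv(stride 2) -> BN -> ReLU -> conv(stride 1) -> BN ->
ReLU. The decoder mirrors it with five blocks (transpose conv x2 upsample,
skip concatenation from the same-resolution encoder level, two stride-1
convs), a final stride-2 transpose conv back to full resolution, and a 1x1
conv producing two-channel softmax segmentation logits.

A classification sub-module pools encoder (and, per variant, mask-attended
decoder) features through a dense hidden layer to a single sigmoid melanoma
logit. The variant ladder adds one mechanism at a time:

* ``seg-only`` - pure segmentation U-Net (classification disabled).
* ``mtl0``     - classification head on the global-average-pooled bottleneck.
* ``mtl1``     - adds pooled, mask-attended features of the last two decoder
  levels (the pass-1 foreground probability gates the features spatially).
* ``mtl2``     - adds the joint reverse connection: the classification
  head's penultimate activations produce per-channel sigmoid gates for the
  last two decoder levels, which are recomputed in a second pass under
  those gates; the level-5 encoder map is also fused into the head.
* ``mtl3``     - passes the last two encoder maps through CBAM
  (channel-then-spatial attention) before they reach the head.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DEFAULT_WIDTHS = (32, 64, 128, 256, 320, 320)

VARIANTS = ("seg-only", "mtl0", "mtl1", "mtl2", "mtl3")


class ShapeError(ValueError):
    pass


@dataclass
class NetworkConfig:
    """Architecture flags; the named variants nest monotonically."""

    widths: tuple[int, ...] = DEFAULT_WIDTHS
    cls_enabled: bool = True
    decoder_to_cls: bool = False
    reverse_join: bool = False
    cbam: bool = False
    cls_hidden_units: int = 128
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7

    def __post_init__(self):
        self.widths = tuple(int(w) for w in self.widths)
        if len(self.widths) != 6:
            raise ValueError("exactly six encoder widths are required")
        if self.cbam and not self.cls_enabled:
            raise ValueError("cbam requires the classification head")
        if self.cbam and self.widths[-1] % self.cbam_reduction:
            raise ValueError(
                f"cbam reduction {self.cbam_reduction} must divide width {self.widths[-1]}"
            )
        if self.cbam_spatial_kernel % 2 == 0:
            raise ValueError("cbam spatial kernel must be odd")

    @property
    def decoder_widths(self) -> tuple[int, ...]:
        return tuple(reversed(self.widths))[1:]

    @classmethod
    def from_variant(cls, name: str, **overrides) -> "NetworkConfig":
        if name not in VARIANTS:
            raise ValueError(f"unknown variant {name!r}; expected one of {VARIANTS}")
        flags = dict(
            cls_enabled=name != "seg-only",
            decoder_to_cls=name in ("mtl1", "mtl2", "mtl3"),
            reverse_join=name in ("mtl2", "mtl3"),
            cbam=name == "mtl3",
        )
        flags.update(overrides)
        return cls(**flags)


@dataclass
class NetworkOutput:
    """Forward-pass results, with pass-1 intermediates exposed for testing."""

    seg_prob: Tensor  # (N, 2, H, W), softmax over channel axis
    cls_prob: Tensor | None  # (N, 1) sigmoid melanoma probability
    seg_prob_pass1: Tensor  # pass-1 segmentation (== seg_prob without reverse join)
    gates: tuple[Tensor, Tensor] | None  # reverse gates for the last two decoder levels
    cls_hidden: Tensor | None  # penultimate classification activations


class _ConvBNRelu(ad.Layer):
    def __init__(self, c_in, c_out, stride, rng):
        self.conv = ad.Conv2d(c_in, c_out, 3, stride, rng)
        self.bn = ad.BatchNorm2d(c_out)

    def __call__(self, x):
        return ad.relu(self.bn(self.conv(x)))

    def parameters(self):
        return self.conv.parameters() + self.bn.parameters()


class CBAM(ad.Layer):
    """Convolutional Block Attention Module: channel then spatial gating."""

    def __init__(self, channels, reduction, spatial_kernel, rng):
        if channels % reduction:
            raise ValueError("channel count must be divisible by the reduction ratio")
        self.fc1 = ad.Linear(channels, channels // reduction, rng)
        self.fc2 = ad.Linear(channels // reduction, channels, rng)
        self.spatial = ad.Conv2d(2, 1, spatial_kernel, 1, rng)

    def channel_attention(self, x: Tensor) -> Tensor:
        avg = ad.global_avg_pool(x)
        mx = ad.global_max_pool(x)
        shared = lambda v: self.fc2(ad.relu(self.fc1(v)))  # noqa: E731
        gate = ad.sigmoid(ad.add(shared(avg), shared(mx)))  # (N, C)
        n, c = gate.shape
        return ad.mul(x, ad.reshape(gate, (n, c, 1, 1)))

    def spatial_attention(self, x: Tensor) -> Tensor:
        mean_map = ad.tmean(x, axis=1, keepdims=True)
        max_map = ad.tmax(x, axis=1, keepdims=True)
        gate = ad.sigmoid(self.spatial(ad.concat([mean_map, max_map], axis=1)))
        return ad.mul(x, gate)

    def __call__(self, x):
        return self.spatial_attention(self.channel_attention(x))

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters() + self.spatial.parameters()


def segmentation_probabilities(seg_logits) -> Tensor:
    """Per-pixel softmax over the two segmentation channels.

    Binarize the foreground channel at 0.5 for a mask output.
    """
    return ad.softmax(ad.as_tensor(seg_logits), axis=1)


def apply_mask_attention(seg_prob_fg: Tensor, feat: Tensor) -> Tensor:
    """Multiply features by the (resized) foreground probability map.

    ``seg_prob_fg`` is (N, 1, H, W); it is bilinearly resized to the feature
    map's spatial dims and broadcast across channels.
    """
    _, _, h, w = feat.shape
    resized = ad.bilinear_resize(seg_prob_fg, h, w)
    return ad.mul(feat, resized)


class MultiTaskUNet:
    """The joint segmentation + classification network."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        w = cfg.widths
        dw = cfg.decoder_widths

        self.enc_blocks = []
        c_in = 3
        for width in w:
            self.enc_blocks.append(
                (_ConvBNRelu(c_in, width, 2, rng), _ConvBNRelu(width, width, 1, rng))
            )
            c_in = width

        # decoder block i: upsample from prev width, concat encoder level
        # (depth-1-i), two stride-1 convs
        self.dec_blocks = []
        prev = w[-1]
        for i, width in enumerate(dw):
            up = ad.ConvTranspose2d(prev, width, rng)
            skip_w = w[len(w) - 2 - i]
            conv1 = _ConvBNRelu(width + skip_w, width, 1, rng)
            conv2 = _ConvBNRelu(width, width, 1, rng)
            self.dec_blocks.append((up, conv1, conv2))
            prev = width

        self.final_up = ad.ConvTranspose2d(dw[-1], dw[-1], rng)
        self.final_bn = ad.BatchNorm2d(dw[-1])
        self.seg_head = ad.Conv2d(dw[-1], 2, 1, 1, rng)

        self.cls_fc1 = self.cls_fc2 = None
        self.gate_fc = None
        self.cbam5 = self.cbam6 = None
        if cfg.cls_enabled:
            in_dim = w[-1]
            if cfg.reverse_join:
                in_dim += w[-2]
            if cfg.decoder_to_cls:
                in_dim += dw[-2] + dw[-1]
            self.cls_in_dim = in_dim
            self.cls_fc1 = ad.Linear(in_dim, cfg.cls_hidden_units, rng)
            self.cls_fc2 = ad.Linear(cfg.cls_hidden_units, 1, rng)
            if cfg.reverse_join:
                self.gate_fc = (
                    ad.Linear(cfg.cls_hidden_units, dw[-2], rng),
                    ad.Linear(cfg.cls_hidden_units, dw[-1], rng),
                )
            if cfg.cbam:
                self.cbam5 = CBAM(w[-2], cfg.cbam_reduction, cfg.cbam_spatial_kernel, rng)
                self.cbam6 = CBAM(w[-1], cfg.cbam_reduction, cfg.cbam_spatial_kernel, rng)

    # -- bookkeeping -------------------------------------------------------

    def _layers(self):
        out = []
        for b in self.enc_blocks:
            out.extend(b)
        for up, c1, c2 in self.dec_blocks:
            out.extend([up, c1, c2])
        out.extend([self.final_up, self.final_bn, self.seg_head])
        for layer in (self.cls_fc1, self.cls_fc2, self.cbam5, self.cbam6):
            if layer is not None:
                out.append(layer)
        if self.gate_fc is not None:
            out.extend(self.gate_fc)
        return out

    def parameters(self):
        params = []
        for layer in self._layers():
            params.extend(layer.parameters())
        return params

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def _bn_layers(self):
        for layer in self._layers():
            if isinstance(layer, ad.BatchNorm2d):
                yield layer
            elif isinstance(layer, _ConvBNRelu):
                yield layer.bn

    def train(self):
        for bn in self._bn_layers():
            bn.training = True

    def eval(self):
        for bn in self._bn_layers():
            bn.training = False

    # -- forward passes ----------------------------------------------------

    def encoder_forward(self, x: Tensor) -> list[Tensor]:
        """Six encoder feature maps; level i has spatial dims input / 2^i."""
        _, _, h, wd = x.shape
        if h % 64 or wd % 64:
            raise ShapeError(f"input dims {h}x{wd} must be multiples of 64")
        feats = []
        cur = x
        for down, keep in self.enc_blocks:
            cur = keep(down(cur))
            feats.append(cur)
        return feats

    def decoder_forward(
        self,
        enc_maps: list[Tensor],
        gates: tuple[Tensor, Tensor] | None = None,
        start_block: int = 0,
        cached_input: Tensor | None = None,
    ) -> tuple[list[Tensor], Tensor]:
        """Run decoder blocks ``start_block..`` and the segmentation head.

        ``gates`` are per-channel multipliers for the last two decoder
        levels, applied to the upsampled map before skip concatenation and
        convolution; ``None`` entries (or a ``None`` tuple) mean no gating.
        """
        n_blocks = len(self.dec_blocks)
        cur = enc_maps[-1] if start_block == 0 else cached_input
        feats: list[Tensor] = []
        for i in range(start_block, n_blocks):
            up, conv1, conv2 = self.dec_blocks[i]
            cur = up(cur)
            if gates is not None and i >= n_blocks - 2:
                gate = gates[i - (n_blocks - 2)]
                if gate is not None:
                    n, c = gate.shape
                    if c != cur.shape[1]:
                        raise ValueError(
                            f"gate length {c} does not match level width {cur.shape[1]}"
                        )
                    cur = ad.mul(cur, ad.reshape(gate, (n, c, 1, 1)))
            skip = enc_maps[n_blocks - 1 - i]
            cur = conv2(conv1(ad.concat([cur, skip], axis=1)))
            feats.append(cur)
        full = ad.relu(self.final_bn(self.final_up(cur)))
        logits = self.seg_head(full)
        return feats, logits

    def classification_head(
        self, enc_maps: list[Tensor], dec_feats: list[Tensor], seg_prob_fg: Tensor | None
    ) -> tuple[Tensor, Tensor]:
        """Pooled-feature classifier; returns (logit, penultimate activations)."""
        if not self.cfg.cls_enabled:
            raise ValueError("classification head is disabled in this configuration")
        f6, f5 = enc_maps[-1], enc_maps[-2]
        if self.cfg.cbam:
            f6 = self.cbam6(f6)
            f5 = self.cbam5(f5)
        pooled = [ad.global_avg_pool(f6)]
        if self.cfg.reverse_join:
            pooled.append(ad.global_avg_pool(f5))
        if self.cfg.decoder_to_cls:
            if seg_prob_fg is None:
                raise ValueError("decoder_to_cls requires the pass-1 segmentation map")
            for feat in (dec_feats[-2], dec_feats[-1]):
                pooled.append(ad.global_avg_pool(apply_mask_attention(seg_prob_fg, feat)))
        vec = pooled[0] if len(pooled) == 1 else ad.concat(pooled, axis=1)
        hidden = ad.relu(self.cls_fc1(vec))
        logit = self.cls_fc2(hidden)
        return logit, hidden

    def compute_reverse_gates(self, hidden: Tensor) -> tuple[Tensor, Tensor]:
        """Sigmoid channel gates for the last two decoder levels."""
        if self.gate_fc is None:
            raise ValueError("reverse join is disabled in this configuration")
        return tuple(ad.sigmoid(fc(hidden)) for fc in self.gate_fc)

    def forward(self, x, gate_override=None) -> NetworkOutput:
        """Full forward pass.

        With the reverse join enabled the last two decoder levels are
        computed twice: pass 1 ungated (its segmentation feeds the mask
        attention and the classification head), pass 2 under the gates
        derived from the classification pathway. ``gate_override`` injects
        fixed gate tensors into pass 2 (testing hook).
        """
        x = ad.as_tensor(x)
        enc = self.encoder_forward(x)
        dec_feats, logits1 = self.decoder_forward(enc)
        seg_prob1 = segmentation_probabilities(logits1)
        fg1 = ad.slice_channels(seg_prob1, 1, 2)

        cls_prob = hidden = None
        if self.cfg.cls_enabled:
            fg_for_cls = fg1 if self.cfg.decoder_to_cls else None
            logit, hidden = self.classification_head(enc, dec_feats, fg_for_cls)
            cls_prob = ad.sigmoid(logit)

        gates = None
        seg_prob = seg_prob1
        if self.cfg.reverse_join:
            gates = gate_override if gate_override is not None else self.compute_reverse_gates(hidden)
            n_blocks = len(self.dec_blocks)
            cached = dec_feats[n_blocks - 3]
            _, logits2 = self.decoder_forward(
                enc, gates=gates, start_block=n_blocks - 2, cached_input=cached
            )
            seg_prob = segmentation_probabilities(logits2)

        return NetworkOutput(seg_prob, cls_prob, seg_prob1, gates, hidden)

    def predict(self, x) -> tuple[np.ndarray, np.ndarray | None]:
        """Binary masks (threshold 0.5 on foreground) and melanoma probabilities."""
        out = self.forward(x)
        masks = (out.seg_prob.data[:, 1] > 0.5).astype(np.uint8)
        probs = out.cls_prob.data[:, 0].copy() if out.cls_prob is not None else None
        return masks, probs


# -- serialization ---------------------------------------------------------


def save_checkpoint(model: MultiTaskUNet, path) -> None:
    """Single-file checkpoint: weights, BN running stats, embedded config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i:04d}": p.data for i, p in enumerate(model.parameters())}
    for i, bn in enumerate(model._bn_layers()):
        arrays[f"bn_{i:04d}_mean"] = bn.running_mean
        arrays[f"bn_{i:04d}_var"] = bn.running_var
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> MultiTaskUNet:
    with np.load(Path(path)) as data:
        cfg_dict = json.loads(bytes(data["config_json"]).decode())
        cfg_dict["widths"] = tuple(cfg_dict["widths"])
        model = MultiTaskUNet(NetworkConfig(**cfg_dict))
        for i, p in enumerate(model.parameters()):
            p.data = data[f"param_{i:04d}"].astype(np.float32)
        for i, bn in enumerate(model._bn_layers()):
            bn.running_mean = data[f"bn_{i:04d}_mean"].astype(np.float32)
            bn.running_var = data[f"bn_{i:04d}_var"].astype(np.float32)
    model.eval()
    return model
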