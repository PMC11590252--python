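"""A 3D U-Net-style segmenter producing per-voxel 3-class probabilities.

The network is a canonical two-level 3D U-Net with a bridge — five
composite layers in total: two encoder blocks (conv3-norm-ReLU twice,
then 2^3 max pool), a bridge block, and two decoder blocks (2^3
transposed convolution, skip concatenation, conv3-norm-ReLU twice),
closed by a 1^3 output convolution and a channel softmax.  All
convolutions are same-padded so the output spatial shape equals the
input shape; inputs of arbitrary size >= 8 voxels per axis are padded
internally to the required divisibility and cropped back.

With the default configuration the receptive field is 44 voxels per
axis, i.e. >= 35 Å on the 1 Å working grid, which is what motivates the
34 Å crop padding: every center-box voxel sees a full field of context.
The architecture is deliberately config-driven (levels, channels) so a
different variant can be dropped in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import List, Optional, Tuple

import numpy as np

from . import nn
from .losses import (
    CHANNEL_TO_CLASS, N_CLASSES, ProbabilityMap, softmax,
)
from .volumes import BoxSpec, DensityMap, LabelMap, center_box


@dataclass
class ModelConfig:
    """Architecture and initialisation settings.

    n_levels encoder/decoder levels (plus one bridge); base_channels is
    the channel width at the top level and doubles per level.  Inputs
    are padded internally to a multiple of ``2**n_levels``.
    """

    n_levels: int = 2
    base_channels: int = 8
    in_channels: int = 1
    n_classes: int = N_CLASSES
    spacing: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_levels < 1 or self.base_channels < 1 or self.in_channels < 1:
            raise ValueError("n_levels, base_channels and in_channels must be >= 1")
        if self.n_classes != N_CLASSES:
            raise ValueError("the segmenter is fixed at 3 output classes")


class UNet3D:
    """The segmentation network; build via :func:`build_model`."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        self.enc: List[nn.Sequential] = []
        self.pools: List[nn.MaxPool2] = []
        cin = config.in_channels
        for lvl in range(config.n_levels):
            cout = c * 2 ** lvl
            self.enc.append(nn.conv_block(cin, cout, rng))
            self.pools.append(nn.MaxPool2())
            cin = cout
        self.bridge = nn.conv_block(cin, cin * 2, rng)
        self.ups: List[nn.TransposedConv2] = []
        self.dec: List[nn.Sequential] = []
        for lvl in reversed(range(config.n_levels)):
            cout = c * 2 ** lvl
            self.ups.append(nn.TransposedConv2(cout * 2, cout, rng))
            self.dec.append(nn.conv_block(cout * 2, cout, rng))
        self.out_conv = nn.Conv3d(c, config.n_classes, rng, kernel=1)

    # -- plumbing ----------------------------------------------------------

    def layers(self) -> List[nn.Layer]:
        out: List[nn.Layer] = []
        for blk in self.enc:
            out.extend(blk.all_layers())
        out.extend(self.bridge.all_layers())
        for up, blk in zip(self.ups, self.dec):
            out.append(up)
            out.extend(blk.all_layers())
        out.append(self.out_conv)
        return out

    def zero_grads(self) -> None:
        for layer in self.layers():
            layer.zero_grads()

    def parameter_vector(self) -> np.ndarray:
        return np.concatenate([
            p.ravel() for layer in self.layers() for p in layer.params.values()
        ])

    # -- forward / backward ------------------------------------------------

    def _pad_amount(self, shape) -> List[Tuple[int, int]]:
        mult = 2 ** self.config.n_levels
        return [(0, (-n) % mult) for n in shape]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits with the same spatial shape as the input.

        x: (in_channels, D, H, W) float32.
        """
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[0] != self.config.in_channels:
            raise ValueError("input must be (in_channels, D, H, W)")
        self._orig_shape = x.shape[1:]
        pads = self._pad_amount(x.shape[1:])
        self._pads = pads
        x = np.pad(x.astype(np.float32), [(0, 0)] + pads)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bridge.forward(x)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[0])
            x = np.concatenate([skip, x], axis=0)
            x = blk.forward(x)
        logits = self.out_conv.forward(x)
        d, h, w = self._orig_shape
        return logits[:, :d, :h, :w]

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from dL/dlogits (cropped shape)."""
        pads = self._pads
        dlog = np.pad(dlogits.astype(np.float32), [(0, 0)] + pads)
        dx = self.out_conv.backward(dlog)
        dskips = []
        for up, blk, c_skip in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            dx = blk.backward(dx)
            dskip, dx = dx[:c_skip], dx[c_skip:]
            dskips.append(dskip)
            dx = up.backward(dx)
        dx = self.bridge.backward(dx)
        # dskips were collected shallow-first (decoder backward runs from the
        # top); the encoder backward walks deep-first, so reverse them
        for blk, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            dx = pool.backward(dx)
            dx = blk.backward(dx + dskip)

    # -- receptive field ---------------------------------------------------

    def receptive_field(self, probe_size: int = 96) -> int:
        """Receptive-field extent (voxels) measured by support propagation.

        Propagates a one-voxel seed through the network topology using
        pure support arithmetic (convolutions dilate by one voxel per
        3^3 kernel, pooling halves, transposed convolution doubles, skip
        concatenation unions), which equals the input extent that can
        influence one output voxel.
        """
        from scipy import ndimage as ndi

        sup = np.zeros((probe_size,) * 3, dtype=bool)
        sup[(probe_size // 2,) * 3] = True
        struct = np.ones((3, 3, 3), dtype=bool)

        def block(s):  # two 3^3 convs
            return ndi.binary_dilation(ndi.binary_dilation(s, struct), struct)

        skips = []
        for _ in range(self.config.n_levels):
            sup = block(sup)
            skips.append(sup)
            n = sup.shape[0] // 2
            sup = sup.reshape(n, 2, n, 2, n, 2).any(axis=(1, 3, 5))
        sup = block(sup)
        for skip in reversed(skips):
            sup = np.repeat(np.repeat(np.repeat(sup, 2, 0), 2, 1), 2, 2)
            sup = sup | skip
            sup = block(sup)
        idx = np.argwhere(sup)
        return int(idx[:, 0].max() - idx[:, 0].min() + 1)


def build_model(config: Optional[ModelConfig] = None) -> UNet3D:
    """Construct a seeded network; same seed gives bit-identical parameters."""
    return UNet3D(config or ModelConfig())


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def normalize_input(values: np.ndarray) -> np.ndarray:
    """Per-map z-score normalisation applied before the network."""
    v = values.astype(np.float32)
    std = float(v.std())
    return (v - v.mean()) / (std if std > 1e-8 else 1.0)


def predict(model: UNet3D, dm: DensityMap) -> ProbabilityMap:
    """Per-voxel class probabilities for a density map.

    The map spacing must match the spacing the model was configured for
    (resample first otherwise).
    """
    if abs(dm.spacing - model.config.spacing) > 1e-6:
        raise ValueError(
            f"map spacing {dm.spacing} != model spacing {model.config.spacing}; "
            "resample the map first"
        )
    logits = model.forward(normalize_input(dm.values)[None])
    return ProbabilityMap(softmax(logits), dm.spacing, dm.origin)


def probabilities_to_labels(pm: ProbabilityMap) -> LabelMap:
    """Argmax over classes; any exact tie for the maximum -> background."""
    p = pm.probs
    best = p.max(axis=0)
    n_best = (np.abs(p - best[None]) < 1e-12).sum(axis=0)
    ch = p.argmax(axis=0)
    lut = np.array([CHANNEL_TO_CLASS[c] for c in range(3)], dtype=np.uint8)
    classes = lut[ch]
    classes[n_best > 1] = 0
    return LabelMap(classes, pm.spacing, pm.origin)


def segment(model: UNet3D, dm: DensityMap, box: BoxSpec) -> LabelMap:
    """Predict, take the per-voxel argmax, and remove the crop padding."""
    labels = probabilities_to_labels(predict(model, dm))
    return center_box(labels, box)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: UNet3D, path) -> None:
    """Save parameters + config (npz with an embedded JSON config)."""
    arrays = {}
    for i, layer in enumerate(model.layers()):
        for k, p in layer.params.items():
            arrays[f"l{i}.{k}"] = p
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> UNet3D:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = UNet3D(cfg)
        for i, layer in enumerate(model.layers()):
            for k in layer.params:
                layer.params[k] = data[f"l{i}.{k}"].copy()
    return model
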