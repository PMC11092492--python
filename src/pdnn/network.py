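"""Gain-modulated four-layer recurrent convolutional network.

The architecture follows the CORnet-S family of recurrent models of the
ventral/dorsal visual stream: a feedforward V1 stage followed by three
recurrent bottleneck blocks with weight sharing across time steps and a
skip branch, here named V1, V2, V3 and IPS after the dorsal-stream
regions being modelled. Three modifications define the model:

* every rectification is ``y = G * max(0, x)`` where ``G`` is the neural
  gain (excitability) shared across the whole network;
* batch-normalization affine parameters are permanently frozen at scale
  1 and shift 0, so normalization standardizes the input to each
  nonlinearity to mean 0, variance 1 and the gain alone controls response
  amplitude;
* the decoder is a 19-way readout (results 0..18) from the globally
  pooled IPS activity at the final time step.

The network is trained from random initialization -- no pre-trained
weights are used anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad

LAYERS = ("V1", "V2", "V3", "IPS")


@dataclass(frozen=True)
class ArchConfig:
    base_channels: tuple = (64, 128, 256, 512)
    recurrence: tuple = (1, 2, 2, 2)  # V1 entry kept for symmetry; V1 is feedforward
    width_scale: float = 1.0
    bottleneck_scale: int = 4
    output_classes: int = 19

    def __post_init__(self):
        if len(self.base_channels) != 4 or len(self.recurrence) != 4:
            raise ValueError("need exactly four layers (V1, V2, V3, IPS)")
        if any(t < 1 for t in self.recurrence):
            raise ValueError("recurrence steps must be >= 1")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")

    @property
    def channels(self) -> tuple:
        return tuple(max(1, round(c * self.width_scale)) for c in self.base_channels)

    def to_json(self) -> str:
        return json.dumps({
            "base_channels": list(self.base_channels),
            "recurrence": list(self.recurrence),
            "width_scale": self.width_scale,
            "bottleneck_scale": self.bottleneck_scale,
            "output_classes": self.output_classes,
        })

    @classmethod
    def from_json(cls, s: str) -> "ArchConfig":
        d = json.loads(s)
        return cls(tuple(d["base_channels"]), tuple(d["recurrence"]),
                   d["width_scale"], d["bottleneck_scale"], d["output_classes"])


# small preset used throughout the test suite and example configs
DESK = ArchConfig(width_scale=1 / 32, bottleneck_scale=4)


def gain_relu(x, gain):
    """Elementwise G * max(0, x) on plain arrays (G > 0)."""
    if gain <= 0:
        raise ValueError(f"gain must be positive, got {gain}")
    return gain * np.maximum(0.0, x)


def _he(rng, shape):
    fan_in = int(np.prod(shape[1:]))
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class _Block:
    """Recurrent bottleneck block with weight sharing across time steps.

    Convolution weights are shared across the ``times`` recurrence steps;
    normalization statistics are kept per step. At the first step the
    input is downsampled (stride 2) and a 1x1 skip projection provides
    the residual; at later steps the previous output is the residual.
    """

    def __init__(self, name, cin, cout, times, bottleneck, rng):
        self.name = name
        self.times = times
        cmid = max(1, cout * bottleneck)
        self.params = {
            f"{name}.conv_input": ad.Parameter(_he(rng, (cout, cin, 1, 1))),
            f"{name}.skip": ad.Parameter(_he(rng, (cout, cout, 1, 1))),
            f"{name}.conv1": ad.Parameter(_he(rng, (cmid, cout, 1, 1))),
            f"{name}.conv2": ad.Parameter(_he(rng, (cmid, cmid, 3, 3))),
            f"{name}.conv3": ad.Parameter(_he(rng, (cout, cmid, 1, 1))),
        }
        self.norms = {f"{name}.norm_skip": ad.BatchNorm2d(cout)}
        for t in range(times):
            self.norms[f"{name}.norm1_{t}"] = ad.BatchNorm2d(cmid)
            self.norms[f"{name}.norm2_{t}"] = ad.BatchNorm2d(cmid)
            self.norms[f"{name}.norm3_{t}"] = ad.BatchNorm2d(cout)

    def forward(self, x, gain, training):
        p, nm, n = self.params, self.norms, self.name
        x = ad.conv2d(x, p[f"{n}.conv_input"])
        for t in range(self.times):
            if t == 0:
                skip = nm[f"{n}.norm_skip"](ad.conv2d(x, p[f"{n}.skip"], stride=2), training)
                stride = 2
            else:
                skip = x
                stride = 1
            y = ad.gain_relu(nm[f"{n}.norm1_{t}"](ad.conv2d(x, p[f"{n}.conv1"]), training), gain)
            y = ad.gain_relu(
                nm[f"{n}.norm2_{t}"](ad.conv2d(y, p[f"{n}.conv2"], stride=stride, pad=1), training),
                gain,
            )
            y = nm[f"{n}.norm3_{t}"](ad.conv2d(y, p[f"{n}.conv3"]), training)
            x = ad.gain_relu(ad.add(y, skip), gain)
        return x


class GainNetwork:
    """The full V1->V2->V3->IPS network with a 19-way decoder."""

    def __init__(self, arch: ArchConfig, gain: float, seed: int = 0):
        if gain <= 0:
            raise ValueError(f"gain must be positive, got {gain}")
        self.arch = arch
        self.gain = float(gain)
        self.seed = int(seed)
        self.iteration = 0
        c1, c2, c3, c4 = arch.channels
        rng = np.random.default_rng(seed)
        self.params = {
            "V1.conv1": ad.Parameter(_he(rng, (c1, 3, 7, 7))),
            "V1.conv2": ad.Parameter(_he(rng, (c1, c1, 3, 3))),
        }
        self.norms = {
            "V1.norm1": ad.BatchNorm2d(c1),
            "V1.norm2": ad.BatchNorm2d(c1),
        }
        self.blocks = []
        for name, cin, cout, times in (
            ("V2", c1, c2, arch.recurrence[1]),
            ("V3", c2, c3, arch.recurrence[2]),
            ("IPS", c3, c4, arch.recurrence[3]),
        ):
            blk = _Block(name, cin, cout, times, arch.bottleneck_scale, rng)
            self.params.update(blk.params)
            self.norms.update(blk.norms)
            self.blocks.append(blk)
        self.params["decoder.w"] = ad.Parameter(
            (rng.standard_normal((c4, arch.output_classes)) / np.sqrt(c4)).astype(np.float32)
        )
        self.params["decoder.b"] = ad.Parameter(np.zeros(arch.output_classes, dtype=np.float32))

    # -- forward -----------------------------------------------------------

    def forward(self, batch: np.ndarray, training: bool, collect: bool = False):
        """Run a (B, 3, 28, 140) batch; returns (logits Tensor, activations).

        ``activations`` maps layer name to the (B, units) activity at the
        layer's final recurrence step (post gain-rectification, hence
        nonnegative), or is None when ``collect`` is False.
        """
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim != 4 or batch.shape[1:] != (3, 28, 140):
            raise ValueError(f"expected (B, 3, 28, 140) input, got {batch.shape}")
        p, nm = self.params, self.norms
        x = ad.Tensor(batch)
        x = ad.gain_relu(nm["V1.norm1"](ad.conv2d(x, p["V1.conv1"], stride=2, pad=3), training),
                         self.gain)
        x = ad.maxpool2d(x, k=3, stride=2, pad=1)
        x = ad.gain_relu(nm["V1.norm2"](ad.conv2d(x, p["V1.conv2"], pad=1), training), self.gain)
        acts = {} if collect else None
        if collect:
            acts["V1"] = x.data.reshape(len(batch), -1).copy()
        for blk in self.blocks:
            x = blk.forward(x, self.gain, training)
            if collect:
                acts[blk.name] = x.data.reshape(len(batch), -1).copy()
        pooled = ad.mean_spatial(x)
        logits = ad.linear(pooled, p["decoder.w"], p["decoder.b"])
        return logits, acts

    def responses(self, batch: np.ndarray) -> np.ndarray:
        """Argmax responses (0..18) in evaluation mode."""
        logits, _ = self.forward(batch, training=False)
        return logits.data.argmax(axis=1)

    # -- persistence -------------------------------------------------------

    def state_arrays(self) -> dict:
        arrays = {f"param::{k}": v.data for k, v in self.params.items()}
        for k, bn in self.norms.items():
            arrays[f"norm::{k}::running_mean"] = bn.running_mean
            arrays[f"norm::{k}::running_var"] = bn.running_var
        return arrays

    def save(self, path) -> None:
        meta = {"arch": self.arch.to_json(), "gain": self.gain,
                "seed": self.seed, "iteration": self.iteration}
        np.savez(path, meta_json=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.state_arrays())

    @classmethod
    def load(cls, path) -> "GainNetwork":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta_json"]).decode())
            net = cls(ArchConfig.from_json(meta["arch"]), meta["gain"], meta["seed"])
            net.iteration = meta["iteration"]
            for k in net.params:
                net.params[k].data = z[f"param::{k}"].copy()
            for k, bn in net.norms.items():
                bn.load_state({
                    "running_mean": z[f"norm::{k}::running_mean"],
                    "running_var": z[f"norm::{k}::running_var"],
                })
        return net

    def normalization_affine(self) -> list:
        """The frozen affine (scale, shift) pairs of every normalization."""
        return [(bn.scale, bn.shift) for bn in self.norms.values()]


def build_network(arch: ArchConfig, gain: float, seed: int = 0) -> GainNetwork:
    return GainNetwork(arch, gain, seed)


def gain_grid(n: int = 17, step: float = 0.25, start: float = 1.0) -> np.ndarray:
    """The excitability grid G = start + step * k, k = 0..n-1 (default 1..5)."""
    return start + step * np.arange(n)


def forward_collect(net: GainNetwork, batch: np.ndarray):
    """Evaluation-mode forward pass returning (logits, per-layer activations)."""
    logits, acts = net.forward(batch, training=False, collect=True)
    return logits.data, acts
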