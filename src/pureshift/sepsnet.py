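"""SE-PSNet: a lightweight 1-D residual convolutional network with
squeeze-and-excitation channel attention for pure-shift spectrum recovery.

The network maps a length-N real spectrum (the Fourier transform of a
chunk-undersampled FID) to the artifact-free fully sampled spectrum.  It is
built from CBLD blocks (convolution, batch normalization, leaky rectifier,
dropout): an entry CBLD lifts 1 -> C channels with kernel 9; six residual
blocks each apply CBLD -> SE gate -> CBLD with kernel 21 around an identity
skip; a 1x1 convolution plus batch normalization (no activation, no dropout)
folds the C channels back to the single output spectrum.  Feature-map length
stays N throughout ('same' padding, stride 1).

Setting ``use_se=False`` gives the ablation variant (non-SE-PSNet) with the
identical layer stack minus the attention gates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import (
    BatchNorm1d,
    Conv1d,
    Dropout,
    LeakyReLU,
    Residual,
    SEGate,
    Sequential,
)
from .simkit import Spectrum1D

__all__ = [
    "NetworkConfig",
    "Model",
    "build_model",
    "se_gate",
    "count_parameters",
    "count_flops",
    "reconstruct",
    "reconstruct_batch",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    Defaults reproduce the reference architecture: N = 8192 input points,
    C = 32 feature channels, kernel 9 in the entry CBLD block and 21 inside
    the six SE residual blocks, SE bottleneck reduction 2, dropout 0.1,
    leaky-rectifier negative slope 0.01.
    """

    n_input: int = 8192
    channels: int = 32
    k_cbld: int = 9
    k_res: int = 21
    n_res_blocks: int = 6
    se_reduction: int = 2
    dropout_rate: float = 0.1
    leaky_slope: float = 0.01
    use_se: bool = True
    #: initial gain of the output-block batch norm.  Unit-max-normalized
    #: spectra have a small RMS, so a small initial output scale saves the
    #: optimizer many epochs of plain rescaling; 1.0 reaches the same
    #: converged loss, just slower.
    output_gamma_init: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_input", "channels", "k_cbld", "k_res", "se_reduction"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_res_blocks < 0:
            raise ValueError("n_res_blocks must be >= 0")
        if self.channels % self.se_reduction != 0:
            raise ValueError(
                f"se_reduction {self.se_reduction} must divide channels {self.channels}"
            )
        if self.k_cbld % 2 == 0 or self.k_res % 2 == 0:
            raise ValueError("kernel sizes must be odd ('same' padding is exact)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class Model:
    """A built (possibly trained) network plus its configuration."""

    config: NetworkConfig
    net: Sequential
    training_meta: dict = field(default_factory=dict)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map (batch, N) real spectra to (batch, N) outputs."""
        if x.ndim != 2 or x.shape[1] != self.config.n_input:
            raise ValueError(
                f"expected input of shape (batch, {self.config.n_input}), got {x.shape}"
            )
        y = self.net.forward(x[:, :, None].astype(np.float32), training)
        return y[:, :, 0]

    def se_gates(self) -> list[SEGate]:
        return [l for l in _nn.iter_layers(self.net) if isinstance(l, SEGate)]


def _cbld(c_in: int, c_out: int, k: int, cfg: NetworkConfig,
          rng: np.random.Generator, dtype) -> list:
    return [
        Conv1d(c_in, c_out, k, rng, dtype=dtype),
        BatchNorm1d(c_out, dtype=dtype),
        LeakyReLU(cfg.leaky_slope),
        Dropout(cfg.dropout_rate, rng),
    ]


def build_model(config: NetworkConfig, seed: int = 0,
                dtype=np.float32) -> Model:
    """Instantiate the network with seeded variance-scaling initialization."""
    rng = np.random.default_rng(seed)
    c = config.channels
    layers: list = _cbld(1, c, config.k_cbld, config, rng, dtype)
    for _ in range(config.n_res_blocks):
        body: list = _cbld(c, c, config.k_res, config, rng, dtype)
        if config.use_se:
            body.append(SEGate(c, config.se_reduction, rng, dtype=dtype))
        body += _cbld(c, c, config.k_res, config, rng, dtype)
        layers.append(Residual(Sequential(body)))
    out_bn = BatchNorm1d(1, dtype=dtype)
    out_bn.gamma[...] = config.output_gamma_init
    layers += [Conv1d(c, 1, 1, rng, dtype=dtype), out_bn]
    return Model(config=config, net=Sequential(layers),
                 training_meta={"init_seed": seed})


def se_gate(gate: SEGate, feature_map: np.ndarray) -> np.ndarray:
    """Apply one squeeze-and-excitation gate to a (C, N) feature map.

    Returns the rescaled feature map; the per-channel gate scalars are
    ``sigmoid(W2 relu(W1 mean_N(x)))`` and lie strictly in (0, 1).
    """
    x = np.asarray(feature_map, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("feature map must be (channels, length)")
    s = gate.gate(x.T[None])[0]          # internal layout is (B, N, C)
    return x * s[:, None]


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------

def count_parameters(config: NetworkConfig, detailed: bool = False):
    """Exact count of learnable scalars of the architecture.

    Counts convolution weights and biases, batch-normalization affine pairs,
    and (when ``use_se``) the SE bottleneck weights and biases.  Running
    statistics are buffers, not parameters, and are excluded.
    """
    c, r = config.channels, config.se_reduction
    conv = (1 * c * config.k_cbld + c)                    # entry
    conv += 2 * config.n_res_blocks * (c * c * config.k_res + c)
    conv += c * 1 * 1 + 1                                 # 1x1 output
    bn = 2 * c * (1 + 2 * config.n_res_blocks) + 2 * 1
    se = 0
    if config.use_se:
        h = c // r
        se = config.n_res_blocks * (c * h + h + h * c + c)
    total = conv + bn + se
    if detailed:
        return {"conv": conv, "batchnorm": bn, "se": se, "total": total}
    return total


def model_size_mb(config: NetworkConfig, bytes_per_scalar: int = 4) -> float:
    """Serialized parameter size in MB (2**20 bytes) at 4 bytes per scalar."""
    return count_parameters(config) * bytes_per_scalar / 2**20


def count_flops(config: NetworkConfig, n_input: int | None = None,
                detailed: bool = False):
    """Multiply-add count of one forward pass.

    The headline count follows the convolution convention
    ``N x C_in x C_out x K`` summed over all convolution layers; SE dense
    layers, biases and normalizations are reported separately in the detailed
    breakdown and excluded from the headline number.
    """
    n = config.n_input if n_input is None else n_input
    c = config.channels
    conv = n * 1 * c * config.k_cbld
    conv += 2 * config.n_res_blocks * n * c * c * config.k_res
    conv += n * c * 1 * 1
    se = 0
    if config.use_se:
        h = c // config.se_reduction
        se = config.n_res_blocks * 2 * c * h
    if detailed:
        bias_norm = n * (c * (2 + 4 * config.n_res_blocks) + 3)
        return {"conv_macs": conv, "se_macs": se, "bias_norm_ops": bias_norm}
    return conv


# ---------------------------------------------------------------------------
# inference & persistence
# ---------------------------------------------------------------------------

def reconstruct_batch(model: Model, spectra: np.ndarray) -> np.ndarray:
    """Inference on a (batch, N) array; outputs unit-max normalized rows."""
    out = model.forward(np.asarray(spectra, dtype=np.float32), training=False)
    peak = np.max(np.abs(out), axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    return out / peak


def reconstruct(model: Model, spectrum: Spectrum1D) -> Spectrum1D:
    """Recover the artifact-free spectrum from an undersampled one.

    Deterministic for fixed weights: dropout is off and batch normalization
    uses running statistics, so the output does not depend on batch
    composition.
    """
    if len(spectrum) != model.config.n_input:
        raise ValueError(
            f"spectrum length {len(spectrum)} != model input {model.config.n_input}"
        )
    out = model.forward(spectrum.values[None, :].astype(np.float32), training=False)[0]
    norm = float(np.max(np.abs(out)))
    if norm > 0:
        out = out / norm
    return Spectrum1D(values=out.astype(np.float64), axis_hz=spectrum.axis_hz,
                      norm_factor=norm)


def save_model(model: Model, path: str | Path) -> None:
    """Write weights, buffers, config and training metadata to one .npz."""
    arrays = {f"param/{k}": v for k, v in _nn.named_parameters(model.net).items()}
    arrays |= {f"buffer/{k}": v for k, v in _nn.named_buffers(model.net).items()}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    arrays["meta_json"] = np.frombuffer(
        json.dumps(model.training_meta, default=str).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path: str | Path) -> Model:
    with np.load(path) as data:
        config = NetworkConfig(**json.loads(bytes(data["config_json"]).decode()))
        meta = json.loads(bytes(data["meta_json"]).decode())
        model = build_model(config, seed=int(meta.get("init_seed", 0)))
        params = _nn.named_parameters(model.net)
        buffers = _nn.named_buffers(model.net)
        for key in data.files:
            if key.startswith("param/"):
                params[key[6:]][...] = data[key]
            elif key.startswith("buffer/"):
                buffers[key[7:]][...] = data[key]
    model.training_meta = meta
    return model
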