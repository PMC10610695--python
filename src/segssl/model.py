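"""Encoder / projector architecture for accelerometer windows.

The backbone is a three-block 1-D CNN over the time axis (conv → batch norm
→ ReLU → max-pool 2), global average pooling to a d-dimensional feature, and
two two-layer MLP projectors: ``fp1`` feeds the contrastive loss, ``fp2``
(L2-normalized output) feeds segment discrimination and the memory bank. A
single affine head on top of the frozen encoder is used only by the linear
evaluation protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .nn import Tensor, as_tensor

__all__ = ["ModelSpec", "HarModel", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    ``channels[-1]`` is the feature dimension d (global average pooling over
    time makes the last conv width the encoder output); both projectors map
    d → d. Defaults give the documented d=128 architecture; narrower
    encoders are valid specs for scaled-down runs.
    """

    channels: tuple[int, int, int] = (32, 64, 128)
    kernel: int = 5
    proj_hidden: int | None = None  # defaults to d
    n_classes: int | None = None  # linear head width (evaluation only)

    def __post_init__(self) -> None:
        if len(self.channels) != 3:
            raise ValueError("encoder has exactly 3 convolutional blocks")
        if self.kernel < 1:
            raise ValueError("kernel length must be positive")

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "channels": list(self.channels),
                "kernel": self.kernel,
                "proj_hidden": self.proj_hidden,
                "n_classes": self.n_classes,
            }
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        raw = yaml.safe_load(text)
        raw["channels"] = tuple(raw["channels"])
        return cls(**raw)


def _gather_patches(x: Tensor, k: int) -> Tensor:
    """All length-k sliding patches of (B, L, C) as (B, L-k+1, k, C).

    The backward pass scatters with k slice-adds instead of a generic
    fancy-index accumulate, which dominates conv runtime otherwise.
    """
    L_out = x.shape[1] - k + 1
    val = np.lib.stride_tricks.sliding_window_view(x.value, k, axis=1)
    out = Tensor(np.ascontiguousarray(val.transpose(0, 1, 3, 2)), _parents=(x,))

    def backward(g: np.ndarray) -> None:
        full = np.zeros_like(x.value)
        for j in range(k):
            full[:, j : j + L_out, :] += g[:, :, j, :]
        x._accumulate(full)

    out._backward = backward if out.requires_grad else None
    return out


class _Conv1d:
    """Valid (unpadded) 1-D convolution over (batch, time, channels)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (k * c_in))
        self.W = Tensor(rng.normal(0, std, size=(k * c_in, c_out)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.k = k

    def __call__(self, x: Tensor) -> Tensor:
        L_out = x.shape[1] - self.k + 1
        patches = _gather_patches(x, self.k)  # (B, L_out, k, C_in)
        flat = patches.reshape((x.shape[0], L_out, self.k * x.shape[2]))
        return flat @ self.W + self.b

    def params(self) -> dict[str, Tensor]:
        return {"W": self.W, "b": self.b}


class _BatchNorm1d:
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mu = x.mean(axis=(0, 1), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 1), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.value.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.value.ravel()
            )
            xhat = centered / (var + self.eps).sqrt()
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta

    def params(self) -> dict[str, Tensor]:
        return {"gamma": self.gamma, "beta": self.beta}


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / d_in)
        self.W = Tensor(rng.normal(0, std, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self) -> dict[str, Tensor]:
        return {"W": self.W, "b": self.b}


def _maxpool2(x: Tensor) -> Tensor:
    B, L, C = x.shape
    if L % 2:  # drop the trailing sample rather than pad
        x = x[:, : L - 1, :]
        L -= 1
    return x.reshape((B, L // 2, 2, C)).max(axis=2)


class HarModel:
    """Encoder fe, projectors fp1/fp2, and an optional linear head.

    All parameters are initialized from one RNG stream so a run is
    reproducible from a single seed. ``train`` toggles batch-norm mode.
    """

    def __init__(self, spec: ModelSpec, rng: np.random.Generator | int = 0):
        if isinstance(rng, int):
            rng = np.random.default_rng(rng)
        self.spec = spec
        c1, c2, c3 = spec.channels
        k = spec.kernel
        self.conv = [
            _Conv1d(3, c1, k, rng),
            _Conv1d(c1, c2, k, rng),
            _Conv1d(c2, c3, k, rng),
        ]
        self.bn = [_BatchNorm1d(c1), _BatchNorm1d(c2), _BatchNorm1d(c3)]
        d = spec.feature_dim
        h = spec.proj_hidden or d
        self.fp1 = [_Linear(d, h, rng), _Linear(h, d, rng)]
        self.fp2 = [_Linear(d, h, rng), _Linear(h, d, rng)]
        self.head = (
            _Linear(d, spec.n_classes, rng) if spec.n_classes is not None else None
        )

    # ------------------------------------------------------------- forward

    def encode(self, windows, train: bool = False) -> Tensor:
        """(B, L, 3) windows → (B, d) features (global average pool)."""
        x = as_tensor(windows)
        if x.ndim != 3 or x.shape[2] != 3:
            raise ValueError(f"expected (batch, L, 3) input, got {x.shape}")
        for conv, bn in zip(self.conv, self.bn):
            x = conv(x)
            x = bn(x, train)
            x = x.relu()
            x = _maxpool2(x)
        return x.mean(axis=1)

    def project_contrastive(self, features: Tensor) -> Tensor:
        """fp1: (B, d) → (B, d), feeds the NT-Xent loss."""
        h = self.fp1[0](features).relu()
        return self.fp1[1](h)

    def project_sd(self, features: Tensor) -> Tensor:
        """fp2: (B, d) → (B, d) with unit-norm rows (memory-bank features)."""
        h = self.fp2[0](features).relu()
        return self.fp2[1](h).normalize(axis=-1)

    def classify(self, features: Tensor) -> Tensor:
        if self.head is None:
            raise RuntimeError("model was built without a linear head")
        return self.head(features)

    # ------------------------------------------------------------ parameters

    def params(self, groups: tuple[str, ...] = ("enc", "fp1", "fp2", "head")) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        if "enc" in groups:
            for i, (conv, bn) in enumerate(zip(self.conv, self.bn)):
                for name, p in conv.params().items():
                    out[f"enc.conv{i}.{name}"] = p
                for name, p in bn.params().items():
                    out[f"enc.bn{i}.{name}"] = p
        for tag, proj in (("fp1", self.fp1), ("fp2", self.fp2)):
            if tag in groups:
                for i, lin in enumerate(proj):
                    for name, p in lin.params().items():
                        out[f"{tag}.lin{i}.{name}"] = p
        if "head" in groups and self.head is not None:
            for name, p in self.head.params().items():
                out[f"head.{name}"] = p
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All parameters plus batch-norm running statistics, by name."""
        out = {k: p.value.copy() for k, p in self.params().items()}
        for i, bn in enumerate(self.bn):
            out[f"enc.bn{i}.running_mean"] = bn.running_mean.copy()
            out[f"enc.bn{i}.running_var"] = bn.running_var.copy()
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.params()
        for k, p in params.items():
            p.value = np.array(arrays[k], dtype=np.float64)
        for i, bn in enumerate(self.bn):
            bn.running_mean = np.array(arrays[f"enc.bn{i}.running_mean"])
            bn.running_var = np.array(arrays[f"enc.bn{i}.running_var"])


def save_checkpoint(model: HarModel, path: str | Path) -> None:
    """Serialize parameters + running stats with an embedded spec manifest."""
    arrays = model.state_arrays()
    arrays["__spec_yaml__"] = np.frombuffer(
        model.spec.to_yaml().encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path: str | Path) -> HarModel:
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    spec = ModelSpec.from_yaml(bytes(arrays.pop("__spec_yaml__")).decode())
    model = HarModel(spec, rng=0)
    model.load_state_arrays(arrays)
    return model
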