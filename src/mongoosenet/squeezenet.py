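"""1-D fire-module ("SqueezeNet"-style) classifier as a pure function.

The network treats the selected clinical feature vector as a
single-channel 1-D signal: an initial convolution, a stack of fire
modules (a width-1 "squeeze" convolution feeding a concatenated
width-1/width-3 "expand" pair, rectifiers throughout), optional
max-pooling between modules, a final width-1 convolution down to the two
class channels, global average pooling and a softmax.

There is no gradient path: the forward pass is a deterministic function
of a flat parameter vector, so any black-box optimizer can train it.
The flat layout is a fixed bijection onto the per-layer weight/bias
tensors (`flatten` / `unflatten`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConvSpec",
    "FireSpec",
    "NetworkSpec",
    "parameter_count",
    "flatten",
    "unflatten",
    "forward",
    "predict_batch",
]


@dataclass(frozen=True)
class ConvSpec:
    filters: int
    width: int
    stride: int = 1


@dataclass(frozen=True)
class FireSpec:
    """Fire module: squeeze must compress (squeeze < expand1 + expand3)."""

    squeeze: int
    expand1: int
    expand3: int

    @property
    def out_channels(self) -> int:
        return self.expand1 + self.expand3


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description; all sizes fixed before training.

    ``maxpool_after`` lists fire-module indices (0-based) after which a
    max-pool of ``pool_width`` / ``pool_stride`` is applied.
    """

    input_length: int
    initial_conv: ConvSpec | None = ConvSpec(4, 3, 1)
    fire_modules: tuple[FireSpec, ...] = (FireSpec(2, 2, 2), FireSpec(2, 2, 2))
    maxpool_after: tuple[int, ...] = (1,)
    pool_width: int = 2
    pool_stride: int = 2
    n_classes: int = 2

    def __post_init__(self):
        if self.input_length < 1:
            raise ValueError("input_length must be >= 1")
        for i, f in enumerate(self.fire_modules):
            if min(f.squeeze, f.expand1, f.expand3) < 1:
                raise ValueError(f"fire module {i}: all filter counts must be >= 1")
            if f.squeeze >= f.expand1 + f.expand3:
                raise ValueError(
                    f"fire module {i}: squeeze ({f.squeeze}) must be smaller than "
                    f"expand1 + expand3 ({f.expand1 + f.expand3})"
                )
        for i in self.maxpool_after:
            if not 0 <= i < max(len(self.fire_modules), 1):
                raise ValueError(f"maxpool_after index {i} out of range")
        if self.spatial_length() < 1:
            raise ValueError("spatial length collapses below 1 after pooling")

    # -- shape bookkeeping ------------------------------------------------
    def spatial_length(self) -> int:
        """Signal length after the initial conv, fires and pools."""
        length = self.input_length
        if self.initial_conv is not None:
            length = -(-length // self.initial_conv.stride)  # same padding
        for i in range(len(self.fire_modules)):
            if i in self.maxpool_after:
                if length < self.pool_width:
                    return 0
                length = 1 + (length - self.pool_width) // self.pool_stride
        return length

    def layers(self) -> list[tuple[str, int, int, int]]:
        """Ordered (name, c_in, c_out, width) for every conv in the net."""
        out: list[tuple[str, int, int, int]] = []
        channels = 1
        if self.initial_conv is not None:
            out.append(("conv0", channels, self.initial_conv.filters, self.initial_conv.width))
            channels = self.initial_conv.filters
        for i, f in enumerate(self.fire_modules):
            out.append((f"fire{i}/squeeze", channels, f.squeeze, 1))
            out.append((f"fire{i}/expand1", f.squeeze, f.expand1, 1))
            out.append((f"fire{i}/expand3", f.squeeze, f.expand3, 3))
            channels = f.out_channels
        out.append(("final", channels, self.n_classes, 1))
        return out

    def spec_hash(self) -> str:
        """Short digest guarding parameter files against spec mismatch."""
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]

    # -- presets ----------------------------------------------------------
    @classmethod
    def micro(cls, input_length: int) -> "NetworkSpec":
        """Default compact architecture for small tabular inputs."""
        return cls(input_length=input_length)

    @classmethod
    def full8(cls, input_length: int) -> "NetworkSpec":
        """Eight-fire-module layout scaled to 1-D input, for fidelity runs."""
        fires = tuple(
            FireSpec(s, e, e)
            for s, e in [(2, 8), (2, 8), (4, 16), (4, 16), (6, 24), (6, 24), (8, 32), (8, 32)]
        )
        return cls(
            input_length=input_length,
            initial_conv=ConvSpec(8, 3, 1),
            fire_modules=fires,
            maxpool_after=(3, 7),
        )


def _layer_sizes(spec: NetworkSpec) -> list[tuple[str, tuple[int, int, int], int]]:
    """(name, weight shape (c_out, c_in, w), bias length) per layer."""
    return [(name, (c_out, c_in, w), c_out) for name, c_in, c_out, w in spec.layers()]


def parameter_count(spec: NetworkSpec) -> int:
    """Total weights + biases: Σ over convs of c_in·c_out·w + c_out."""
    return sum(c_out * c_in * w + c_out for _, c_in, c_out, w in spec.layers())


def flatten(tensors: dict[str, tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Concatenate per-layer (weight, bias) pairs into one flat vector."""
    parts = []
    for w, b in tensors.values():
        parts.append(np.asarray(w, dtype=float).ravel())
        parts.append(np.asarray(b, dtype=float).ravel())
    return np.concatenate(parts) if parts else np.empty(0)


def unflatten(spec: NetworkSpec, vector: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Slice the flat vector back into per-layer weight/bias tensors."""
    vector = np.asarray(vector, dtype=float)
    expected = parameter_count(spec)
    if vector.ndim != 1 or vector.size != expected:
        raise ValueError(
            f"parameter vector length mismatch: expected {expected}, got {vector.size}"
        )
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    offset = 0
    for name, wshape, blen in _layer_sizes(spec):
        wlen = int(np.prod(wshape))
        w = vector[offset : offset + wlen].reshape(wshape)
        offset += wlen
        b = vector[offset : offset + blen]
        offset += blen
        out[name] = (w, b)
    return out


def _conv1d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 1) -> np.ndarray:
    """Batched 1-D convolution with zero 'same' padding.

    x: (batch, c_in, L); w: (c_out, c_in, width); returns
    (batch, c_out, ceil(L/stride)).
    """
    width = w.shape[2]
    left = (width - 1) // 2
    right = width - 1 - left
    xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, width, axis=2)
    windows = windows[:, :, ::stride, :]  # (batch, c_in, L_out, width)
    return np.einsum("bclw,ocw->bol", windows, w) + b[None, :, None]


def _maxpool1d(x: np.ndarray, width: int, stride: int) -> np.ndarray:
    length = x.shape[2]
    if length < width:
        raise ValueError("signal shorter than pool window")
    windows = np.lib.stride_tricks.sliding_window_view(x, width, axis=2)
    return windows[:, :, ::stride, :].max(axis=3)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _forward_batch(spec: NetworkSpec, params: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Probabilities (batch, n_classes) for feature rows (batch, input_length)."""
    tensors = unflatten(spec, params)
    x = batch[:, None, :]  # single channel
    if spec.initial_conv is not None:
        w, b = tensors["conv0"]
        x = _relu(_conv1d_same(x, w, b, spec.initial_conv.stride))
    for i in range(len(spec.fire_modules)):
        ws, bs = tensors[f"fire{i}/squeeze"]
        sq = _relu(_conv1d_same(x, ws, bs))
        w1, b1 = tensors[f"fire{i}/expand1"]
        w3, b3 = tensors[f"fire{i}/expand3"]
        x = _relu(np.concatenate(
            [_conv1d_same(sq, w1, b1), _conv1d_same(sq, w3, b3)], axis=1
        ))
        if i in spec.maxpool_after:
            x = _maxpool1d(x, spec.pool_width, spec.pool_stride)
    wf, bf = tensors["final"]
    logits = _conv1d_same(x, wf, bf).mean(axis=2)  # global average pool
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def forward(spec: NetworkSpec, params: np.ndarray, features: np.ndarray) -> tuple[float, float]:
    """Class probability pair (p_normal, p_abnormal) for one feature vector."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 1 or features.size != spec.input_length:
        raise ValueError(
            f"feature length mismatch: expected {spec.input_length}, got {features.size}"
        )
    probs = _forward_batch(spec, np.asarray(params, dtype=float), features[None, :])[0]
    return float(probs[0]), float(probs[1])


def predict_batch(
    spec: NetworkSpec, params: np.ndarray, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels and probability matrix for a feature matrix.

    An exact probability tie resolves to class 0 (normal).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != spec.input_length:
        raise ValueError(
            f"feature-count mismatch: expected {spec.input_length} columns, "
            f"got {features.shape[1] if features.ndim == 2 else 'non-2D input'}"
        )
    probs = _forward_batch(spec, np.asarray(params, dtype=float), features)
    labels = (probs[:, 1] > probs[:, 0]).astype(int)
    return labels, probs


# -- parameter-vector file round trip ------------------------------------

def save_params(path, spec: NetworkSpec, params: np.ndarray) -> None:
    """Single-column text file; header names the spec hash."""
    params = np.asarray(params, dtype=float)
    np.savetxt(path, params, header=f"spec_hash={spec.spec_hash()}")


def load_params(path, spec: NetworkSpec) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
    expected = f"spec_hash={spec.spec_hash()}"
    if header != expected:
        raise ValueError(f"parameter file {path} was saved for a different spec "
                         f"({header!r} != {expected!r})")
    params = np.loadtxt(path)
    if params.size != parameter_count(spec):
        raise ValueError("parameter file length does not match spec")
    return np.atleast_1d(params)
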