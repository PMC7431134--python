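"""Residual U-Net variants for label-free to fluorescence translation.

Three variants share one code path on ``(batch, channel, z, y, x)``
tensors:

* 2D — slice to slice; 3x3 kernels on a singleton z axis.
* 2.5D — stack of N odd input slices to the central output slice;
  3x3x3 encoder kernels, Nx2x2 average pooling (stride 1x2x2, reflected
  z), skip connections through Nx1x1 valid convolutions that collapse z,
  1x3x3 decoder kernels after 1x2x2 bilinear upsampling.
* 3D — stack to stack; 3x3x3 kernels, 2x2x2 pooling and upsampling.

Every encoder/decoder block is two (convolution, ReLU, batch norm)
repeats with a parameter-free residual shortcut from block input to
block output (channels matched by zero-padding or truncation).
Downsampling is a fixed-weight 2x2 stride-2 averaging kernel; decoder
features are upsampled by linear interpolation and concatenated with the
skip features of the same level.  The output block is a single
convolution with no activation (regression head).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag

DEFAULT_FILTERS = {
    "2D": (16, 32, 64, 128, 256),
    "2.5D": (16, 32, 64, 128, 256),
    "3D": (16, 32, 64, 128),
}


@dataclass
class ModelSpec:
    """Declarative description of a U-Net variant."""

    variant: str
    in_channels: int = 1
    out_channels: int = 1
    n_input_slices: int = 5
    filters: tuple = None

    def __post_init__(self) -> None:
        if self.variant not in ("2D", "2.5D", "3D"):
            raise ValueError(f"variant must be 2D, 2.5D or 3D, got {self.variant!r}")
        if self.filters is None:
            self.filters = DEFAULT_FILTERS[self.variant]
        self.filters = tuple(int(f) for f in self.filters)
        if any(b <= a for a, b in zip(self.filters, self.filters[1:])):
            raise ValueError(f"filters must strictly increase, got {self.filters}")
        if self.in_channels < 1 or self.out_channels != 1:
            raise ValueError("in_channels must be >= 1 and out_channels must be 1")
        if self.variant == "2.5D":
            if self.n_input_slices % 2 == 0 or self.n_input_slices < 1:
                raise ValueError(
                    f"2.5D n_input_slices must be odd, got {self.n_input_slices}"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelSpec":
        payload = dict(payload)
        if payload.get("filters") is not None:
            payload["filters"] = tuple(payload["filters"])
        return cls(**payload)


class Module:
    def parameters(self):
        return []

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


class Conv(Module):
    def __init__(self, rng, cin, cout, kernel, padding="same", bias=True):
        fan_in = cin * int(np.prod(kernel))
        scale = np.sqrt(2.0 / fan_in)
        self.w = ag.parameter(rng.normal(0.0, scale, size=(cout, cin) + tuple(kernel)))
        self.b = ag.parameter(np.zeros(cout)) if bias else None
        self.padding = padding

    def __call__(self, x):
        return ag.conv(x, self.w, self.b, padding=self.padding)

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])


class BatchNorm(Module):
    def __init__(self, channels):
        self.gamma = ag.parameter(np.ones(channels))
        self.beta = ag.parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.training = True

    def __call__(self, x):
        return ag.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var, self.training
        )

    def parameters(self):
        return [self.gamma, self.beta]


class ResidualBlock(Module):
    """(conv -> ReLU -> batch norm) x2 plus an input->output shortcut."""

    def __init__(self, rng, cin, cout, kernel):
        self.conv1 = Conv(rng, cin, cout, kernel)
        self.bn1 = BatchNorm(cout)
        self.conv2 = Conv(rng, cout, cout, kernel)
        self.bn2 = BatchNorm(cout)
        self.cout = cout

    def __call__(self, x):
        h = self.bn1(ag.relu(self.conv1(x)))
        h = self.bn2(ag.relu(self.conv2(h)))
        return ag.add(h, ag.match_channels(x, self.cout))

    def parameters(self):
        return (
            self.conv1.parameters()
            + self.bn1.parameters()
            + self.conv2.parameters()
            + self.bn2.parameters()
        )


class UNet(Module):
    """Residual U-Net; construct through :func:`build_model`."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        variant = spec.variant
        n = spec.n_input_slices if variant == "2.5D" else 1
        self.n_slices = n

        if variant == "2D":
            enc_kernel = dec_kernel = out_kernel = (1, 3, 3)
            self.pool_kernel, self.pool_stride = (1, 2, 2), (1, 2, 2)
            self.pool_pad = ((0, 0), (0, 0), (0, 0))
            self.up_factors = (1, 2, 2)
        elif variant == "3D":
            enc_kernel = dec_kernel = out_kernel = (3, 3, 3)
            self.pool_kernel, self.pool_stride = (2, 2, 2), (2, 2, 2)
            self.pool_pad = ((0, 0), (0, 0), (0, 0))
            self.up_factors = (2, 2, 2)
        else:  # 2.5D
            enc_kernel = (min(3, n), 3, 3)
            dec_kernel = out_kernel = (1, 3, 3)
            zpad = (n - 1) // 2
            self.pool_kernel, self.pool_stride = (n, 2, 2), (1, 2, 2)
            self.pool_pad = ((zpad, zpad), (0, 0), (0, 0))
            self.up_factors = (1, 2, 2)

        filters = spec.filters
        self.encoder = []
        cin = spec.in_channels
        for f in filters:
            self.encoder.append(ResidualBlock(rng, cin, f, enc_kernel))
            cin = f

        self.skips = None
        if variant == "2.5D":
            self.skips = [Conv(rng, f, f, (n, 1, 1), padding="valid") for f in filters]

        self.decoder = [
            ResidualBlock(rng, f + below, f, dec_kernel)
            for f, below in zip(filters[-2::-1], filters[:0:-1])
        ]
        self.out_conv = Conv(rng, filters[0], spec.out_channels, out_kernel)

    # -- plumbing -----------------------------------------------------------

    def parameters(self):
        params = []
        for block in self.encoder + self.decoder:
            params += block.parameters()
        if self.skips is not None:
            for conv in self.skips:
                params += conv.parameters()
        params += self.out_conv.parameters()
        return params

    def _batch_norms(self):
        for block in self.encoder + self.decoder:
            yield block.bn1
            yield block.bn2

    def train(self):
        for bn in self._batch_norms():
            bn.training = True

    def eval(self):
        for bn in self._batch_norms():
            bn.training = False

    def state_dict(self):
        state = {"params": [p.data.copy() for p in self.parameters()], "bn": []}
        for bn in self._batch_norms():
            state["bn"].append((bn.running_mean.copy(), bn.running_var.copy()))
        return state

    def load_state_dict(self, state):
        for p, data in zip(self.parameters(), state["params"]):
            p.data = data.copy()
        for bn, (mean, var) in zip(self._batch_norms(), state["bn"]):
            bn.running_mean = mean.copy()
            bn.running_var = var.copy()

    # -- forward ------------------------------------------------------------

    def _validate_input(self, x):
        b, c, d, h, w = x.shape
        if c != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} channels, got {c}")
        levels = len(self.spec.filters)
        div = 2 ** (levels - 1)
        if h % div or w % div or h < div or w < div:
            raise ValueError(
                f"spatial size {(h, w)} must be a positive multiple of {div} "
                f"(input smaller than the receptive field)"
            )
        if self.spec.variant == "2.5D" and d != self.n_slices:
            raise ValueError(f"2.5D input window must have {self.n_slices} slices, got {d}")
        if self.spec.variant == "2D" and d != 1:
            raise ValueError(f"2D input must have a singleton z axis, got {d}")
        if self.spec.variant == "3D" and (d % div or d < div):
            raise ValueError(f"3D input depth {d} must be a positive multiple of {div}")

    def __call__(self, x):
        if not isinstance(x, ag.Tensor):
            x = ag.Tensor(x)
        self._validate_input(x.data)
        feats = []
        h = x
        for i, block in enumerate(self.encoder):
            h = block(h)
            feats.append(h)
            if i < len(self.encoder) - 1:
                padded = ag.pad_spatial(h, self.pool_pad, mode="reflect")
                h = ag.avg_pool(padded, self.pool_kernel, self.pool_stride)
        if self.skips is not None:
            feats = [conv(f) for conv, f in zip(self.skips, feats)]
        h = feats[-1]
        for block, skip in zip(self.decoder, feats[-2::-1]):
            h = ag.upsample_linear(h, self.up_factors)
            h = block(ag.concat_channels([skip, h]))
        return self.out_conv(h)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference forward pass (evaluation-mode batch norm)."""
        self.eval()
        out = self(ag.Tensor(np.asarray(x, dtype=np.float64)))
        self.train()
        return out.data


def build_model(spec: ModelSpec, seed: int = 0) -> UNet:
    """Instantiate a residual U-Net for the given specification."""
    return UNet(spec, seed=seed)


def count_parameters(model: UNet) -> int:
    """Total trainable parameters (convolution weights and biases plus
    batch-norm scale/shift)."""
    return int(sum(p.data.size for p in model.parameters()))
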