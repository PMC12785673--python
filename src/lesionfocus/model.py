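"""The 2.5D UNet-48 segmentation network, in NumPy.

Architecture (channel widths 48→96→192→384 and back, Group Normalization
with 8 groups, bilinear upsampling with skip concatenation, 1x1
convolution head to 5 classes + softmax):

    d1: DoubleConv(3→48)              u3: Up + concat(c3) + DoubleConv(→192)
    d2: DoubleConv(48→96)   (pool)    u2: Up + concat(c2) + DoubleConv(→96)
    d3: DoubleConv(96→192)  (pool)    u1: Up + concat(c1) + DoubleConv(→48)
    d4: DoubleConv(192→384) (pool)    head: 1x1 Conv(48→5) + softmax

Inputs are (B, 3, H, W) stacks of three adjacent z-scored B-scans; H and W
must be divisible by 8 (three pooling stages).  Forward, backward (for
training) and input-gradient evaluation (for GradientSHAP) are all
explicit NumPy code built on :mod:`lesionfocus.nn`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BilinearUp2, ChannelSoftmax, Conv2d, GroupNorm, MaxPool2, ReLU

__all__ = ["ModelSpec", "DoubleConv", "UNet", "build_unet", "parameter_count"]


@dataclass(frozen=True)
class ModelSpec:
    in_channels: int = 3
    n_classes: int = 5
    widths: tuple[int, int, int, int] = (48, 96, 192, 384)
    norm_groups: int = 8
    seed: int = 42


class DoubleConv:
    """(Conv3x3 → GroupNorm → ReLU) x 2."""

    def __init__(self, cin: int, cout: int, groups: int,
                 rng: np.random.Generator) -> None:
        self.layers = [
            Conv2d(cin, cout, 3, rng), GroupNorm(cout, groups), ReLU(),
            Conv2d(cout, cout, 3, rng), GroupNorm(cout, groups), ReLU(),
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class UNet:
    """UNet-48 with explicit forward/backward passes."""

    def __init__(self, spec: ModelSpec | None = None) -> None:
        self.spec = spec = spec or ModelSpec()
        rng = np.random.default_rng(spec.seed)
        w1, w2, w3, w4 = spec.widths
        g = spec.norm_groups
        self.d1 = DoubleConv(spec.in_channels, w1, g, rng)
        self.d2 = DoubleConv(w1, w2, g, rng)
        self.d3 = DoubleConv(w2, w3, g, rng)
        self.d4 = DoubleConv(w3, w4, g, rng)
        self.pools = [MaxPool2() for _ in range(3)]
        self.ups = [BilinearUp2() for _ in range(3)]
        self.u3 = DoubleConv(w4 + w3, w3, g, rng)
        self.u2 = DoubleConv(w3 + w2, w2, g, rng)
        self.u1 = DoubleConv(w2 + w1, w1, g, rng)
        self.head = Conv2d(w1, spec.n_classes, 1, rng)
        self.softmax = ChannelSoftmax()

    # -- parameter bookkeeping -------------------------------------------
    def _blocks(self) -> dict[str, object]:
        return {"d1": self.d1, "d2": self.d2, "d3": self.d3, "d4": self.d4,
                "u3": self.u3, "u2": self.u2, "u1": self.u1, "head": self.head}

    def _layers_with_params(self):
        for bname, block in self._blocks().items():
            layers = block.layers if isinstance(block, DoubleConv) else [block]
            for i, layer in enumerate(layers):
                if getattr(layer, "params", None):
                    yield f"{bname}.{i}", layer

    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{name}.{k}": v
                for name, layer in self._layers_with_params()
                for k, v in layer.params.items()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{name}.{k}": v
                for name, layer in self._layers_with_params()
                for k, v in layer.grads.items()}

    def zero_grad(self) -> None:
        for _, layer in self._layers_with_params():
            layer.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for k, v in state.items():
            params[k][...] = v

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, 3, H, W) float32 → (B, 5, H, W) probability simplex."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[-1] % 8 or x.shape[-2] % 8:
            raise ValueError("H and W must be divisible by 8")
        c1 = self.d1.forward(x)
        c2 = self.d2.forward(self.pools[0].forward(c1))
        c3 = self.d3.forward(self.pools[1].forward(c2))
        c4 = self.d4.forward(self.pools[2].forward(c3))
        s3 = np.concatenate([self.ups[0].forward(c4), c3], axis=1)
        u3 = self.u3.forward(s3)
        s2 = np.concatenate([self.ups[1].forward(u3), c2], axis=1)
        u2 = self.u2.forward(s2)
        s1 = np.concatenate([self.ups[2].forward(u2), c1], axis=1)
        u1 = self.u1.forward(s1)
        self._logits = self.head.forward(u1)
        return self.softmax.forward(self._logits)

    @property
    def logits(self) -> np.ndarray:
        return self._logits

    def backward(self, dprob: np.ndarray | None = None,
                 dlogits: np.ndarray | None = None) -> np.ndarray:
        """Backprop from dL/dprob (or directly from dL/dlogits) to dL/dinput.

        Parameter gradients accumulate into each layer's ``grads``.
        """
        if (dprob is None) == (dlogits is None):
            raise ValueError("provide exactly one of dprob or dlogits")
        dz = self.softmax.backward(dprob) if dlogits is None else dlogits
        dz = np.asarray(dz, dtype=np.float32)
        w4 = self.spec.widths[3]
        w3_, w2_ = self.spec.widths[2], self.spec.widths[1]
        du1 = self.head.backward(dz)
        ds1 = self.u1.backward(du1)
        dup2, dc1_skip = ds1[:, :w2_], ds1[:, w2_:]
        du2 = self.ups[2].backward(dup2)
        ds2 = self.u2.backward(du2)
        dup3, dc2_skip = ds2[:, :w3_], ds2[:, w3_:]
        du3 = self.ups[1].backward(dup3)
        ds3 = self.u3.backward(du3)
        dc4_up, dc3_skip = ds3[:, :w4], ds3[:, w4:]
        dc4 = self.ups[0].backward(dc4_up)
        dp3 = self.d4.backward(dc4)
        dc3 = self.pools[2].backward(dp3) + dc3_skip
        dp2 = self.d3.backward(dc3)
        dc2 = self.pools[1].backward(dp2) + dc2_skip
        dp1 = self.d2.backward(dc2)
        dc1 = self.pools[0].backward(dp1) + dc1_skip
        return self.d1.backward(dc1)

    # -- attribution support ---------------------------------------------
    def input_gradient(self, x: np.ndarray, class_index: int,
                       region_mask: np.ndarray) -> np.ndarray:
        """Gradient of the region-summed class logit with respect to x.

        The explained scalar is ``sum over region pixels of
        logits[class_index]`` — the standard lesion-summed class score for
        segmentation attribution.
        """
        x = np.asarray(x, dtype=np.float32)
        squeeze = x.ndim == 3
        self.forward(x)
        dlogits = np.zeros_like(self._logits)
        dlogits[:, class_index] = np.asarray(region_mask, dtype=np.float32)[None]
        self.zero_grad()
        dx = self.backward(dlogits=dlogits)
        return dx[0] if squeeze else dx


def build_unet(spec: ModelSpec | None = None) -> UNet:
    return UNet(spec)


def parameter_count(model_or_spec: UNet | ModelSpec | None = None) -> int:
    model = (model_or_spec if isinstance(model_or_spec, UNet)
             else UNet(model_or_spec))
    return sum(int(v.size) for v in model.parameters().values())
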