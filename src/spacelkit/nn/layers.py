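"""Dense layers and small MLP stacks used by the deconvolution and domain models."""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .autodiff import Tensor, relu, softmax


def he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


def xavier_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


_INITS = {"he": he_init, "xavier": xavier_init}


class Dense:
    """Affine layer ``x @ W + b`` with optional activation."""

    def __init__(
        self,
        fan_in: int,
        fan_out: int,
        rng: np.random.Generator,
        activation: Callable[[Tensor], Tensor] | None = relu,
        init: str = "he",
    ):
        self.W = Tensor(_INITS[init](rng, fan_in, fan_out), requires_grad=True)
        self.b = Tensor(np.zeros(fan_out), requires_grad=True)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W + self.b
        return self.activation(out) if self.activation else out

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Stack of Dense layers; ``hidden(x)`` exposes the last hidden activation."""

    def __init__(
        self,
        dims: Sequence[int],
        rng: np.random.Generator,
        out_activation: Callable[[Tensor], Tensor] | None = None,
        init: str = "he",
    ):
        self.layers = [
            Dense(a, b, rng, activation=relu, init=init)
            for a, b in zip(dims[:-2], dims[1:-1])
        ]
        self.out = Dense(dims[-2], dims[-1], rng, activation=out_activation, init=init)

    def forward(self, x: Tensor, return_hidden: bool = False):
        h = x
        for layer in self.layers:
            h = layer(h)
        y = self.out(h)
        return (y, h) if return_hidden else y

    __call__ = forward

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in self.layers:
            params.extend(layer.parameters())
        params.extend(self.out.parameters())
        return params


def softmax_head(t: Tensor) -> Tensor:
    return softmax(t, axis=-1)
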