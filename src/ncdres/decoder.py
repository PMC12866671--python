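"""Edge decoder: concatenation pooling plus a three-layer MLP.

A candidate (ncRNA, drug) pair is represented by concatenating the two node
embeddings (ncRNA block first) and scored with::

    P = W3 . LeakyReLU( W2 . LeakyReLU( W1 h + b1 ) + b2 ) + b3

P is a raw logit; the training loss applies the logistic sigmoid.  The two
hidden widths default to (hidden, hidden // 2), a conventional tapering MLP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .io import NcdresError


@dataclass
class DecoderParams:
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.W1.shape[1] != self.W2.shape[0] or self.W2.shape[1] != self.W3.shape[0]:
            raise NcdresError("decoder layer dimensions are inconsistent")
        if self.W3.shape[1] != 1:
            raise NcdresError("decoder output dimension must be 1")
        for name in ("W1", "b1", "W2", "b2", "W3", "b3"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise NcdresError(f"non-finite decoder parameter {name}")

    @classmethod
    def init(
        cls,
        input_dim: int,
        hidden1: int | None = None,
        hidden2: int | None = None,
        leaky_slope: float = 0.01,
        rng: np.random.Generator | None = None,
    ) -> "DecoderParams":
        rng = rng or np.random.default_rng(0)
        h1 = hidden1 if hidden1 is not None else input_dim // 2
        h2 = hidden2 if hidden2 is not None else max(h1 // 2, 1)

        def glorot(a: int, b: int) -> np.ndarray:
            limit = np.sqrt(6.0 / (a + b))
            return rng.uniform(-limit, limit, size=(a, b))

        return cls(
            glorot(input_dim, h1), np.zeros(h1),
            glorot(h1, h2), np.zeros(h2),
            glorot(h2, 1), np.zeros(1),
            leaky_slope,
        )

    def to_arrays(self) -> dict[str, np.ndarray]:
        return {
            "W1": self.W1, "b1": self.b1,
            "W2": self.W2, "b2": self.b2,
            "W3": self.W3, "b3": self.b3,
        }

    @classmethod
    def from_arrays(
        cls, arrays: dict[str, np.ndarray], leaky_slope: float = 0.01
    ) -> "DecoderParams":
        return cls(
            np.asarray(arrays["W1"]), np.asarray(arrays["b1"]),
            np.asarray(arrays["W2"]), np.asarray(arrays["b2"]),
            np.asarray(arrays["W3"]), np.asarray(arrays["b3"]),
            leaky_slope,
        )


def pair_features(h_ncrna: Tensor, h_drug: Tensor) -> Tensor:
    """Concatenation pooling, ncRNA block first."""
    return ad.concat_cols(h_ncrna, h_drug)


def score_pairs_taped(
    joint: Tensor,
    params: DecoderParams,
    param_tensors: dict[str, Tensor] | None = None,
) -> Tensor:
    """MLP logits on the tape; returns an (n_pairs,) tensor."""

    def pt(key: str) -> Tensor:
        if param_tensors is not None and key in param_tensors:
            return param_tensors[key]
        return Tensor(getattr(params, key))

    if joint.value.ndim != 2 or joint.value.shape[1] != params.W1.shape[0]:
        raise NcdresError(
            f"pair feature dim {joint.value.shape} incompatible with decoder "
            f"input dim {params.W1.shape[0]}"
        )
    z1 = ad.leaky_relu(ad.add(ad.matmul(joint, pt("W1")), pt("b1")), params.leaky_slope)
    z2 = ad.leaky_relu(ad.add(ad.matmul(z1, pt("W2")), pt("b2")), params.leaky_slope)
    logits = ad.add(ad.matmul(z2, pt("W3")), pt("b3"))
    flat = Tensor(
        logits.value[:, 0],
        (logits,),
        lambda g: logits._accumulate(g[:, None]),
    )
    if not np.all(np.isfinite(flat.value)):
        raise NcdresError("non-finite decoder output")
    return flat


def score_pairs(
    h_ncrna: np.ndarray, h_drug: np.ndarray, params: DecoderParams
) -> np.ndarray:
    """Plain-array scoring of aligned (ncRNA, drug) embedding rows."""
    joint = pair_features(Tensor(np.atleast_2d(h_ncrna)), Tensor(np.atleast_2d(h_drug)))
    return score_pairs_taped(joint, params).value


def bce_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean sigmoid binary cross-entropy (stabilised log-sum-exp form)."""
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if logits.shape != labels.shape:
        raise NcdresError("logits and labels must have identical shape")
    if logits.size == 0:
        raise NcdresError("empty input to bce_loss")
    if not np.all(np.isin(labels, (0.0, 1.0))):
        raise NcdresError("labels must be binary")
    return float(ad.bce_with_logits(Tensor(logits), labels).value)
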