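"""Four classifier architectures over per-subject feature maps.

Each model consumes a (slices x features) matrix — by default 200 x 20 —
and outputs the probability of the positive (ADHD) class through a single
sigmoid unit:

* ``cnn2d`` — the matrix is treated as a one-channel image; two 3x3
  convolution blocks with 2x2 max pooling capture joint slice-feature
  patterns;
* ``cnn1d`` — features are channels, slices the length axis; two kernel-5
  convolution blocks with pooling capture patterns along the slice axis;
* ``lstm`` / ``gru`` — the slice axis is a 200-step sequence of 20-dim
  inputs read inferior to superior; the final hidden state summarises it.

Every trunk feeds a dense head (ReLU + dropout + sigmoid output). With
``use_covariates`` the 5 normalised personal attributes (age, gender,
handedness, IQ, LD_OR_ODD) are concatenated to the first dense layer's
input — multimodal fusion at the dense stage. All trainable weights sit
under an L2 penalty (default 0.01); initialisation is fully seeded, so a
spec determines the parameter inventory bit for bit.

Layer widths are configurable; the defaults are small enough to train on
a single CPU while keeping each architecture's character.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .features import FeatureMap

__all__ = ["ARCHS", "ModelSpec", "Prediction", "Classifier", "build_model", "predict",
           "N_COVARIATES"]

ARCHS = ("cnn2d", "cnn1d", "lstm", "gru")
N_COVARIATES = 5

_DEFAULT_HIDDEN = {"cnn2d": (16, 32), "cnn1d": (32, 64), "lstm": (64,), "gru": (64,)}


@dataclass(frozen=True)
class ModelSpec:
    arch: str
    use_covariates: bool = False
    hidden_sizes: tuple[int, ...] | None = None
    dense_units: int = 64
    dropout: float = 0.2
    l2_strength: float = 0.01
    init_seed: int = 0

    def __post_init__(self):
        if self.arch not in ARCHS:
            raise ValueError(f"arch must be one of {ARCHS}, got {self.arch!r}")
        if self.l2_strength < 0:
            raise ValueError(f"l2_strength must be >= 0, got {self.l2_strength}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")

    @property
    def trunk_sizes(self) -> tuple[int, ...]:
        return self.hidden_sizes if self.hidden_sizes is not None else _DEFAULT_HIDDEN[self.arch]


@dataclass(frozen=True)
class Prediction:
    probability: float
    label_hat: int
    threshold: float = 0.5


class Classifier:
    """One architecture instance with seeded weights and manual gradients."""

    def __init__(self, spec: ModelSpec, input_shape: tuple[int, int], n_covariates: int = 0):
        if spec.use_covariates and n_covariates != N_COVARIATES:
            raise ValueError(f"use_covariates requires n_covariates={N_COVARIATES}, "
                             f"got {n_covariates}")
        if not spec.use_covariates and n_covariates not in (0, None):
            raise ValueError("n_covariates must be 0 when use_covariates is False")
        self.spec = spec
        self.input_shape = tuple(input_shape)
        self.n_covariates = n_covariates if spec.use_covariates else 0
        rng = np.random.default_rng(np.random.SeedSequence([77, spec.init_seed]))
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence([78, spec.init_seed]))
        self._build(rng)

    # -- construction -----------------------------------------------------

    def _build(self, rng: np.random.Generator) -> None:
        S, F = self.input_shape
        h = self.spec.trunk_sizes
        arch = self.spec.arch
        if arch == "cnn2d":
            self.trunk = [nn.Conv2D(1, h[0], 3, rng), nn.ReLU(), nn.MaxPool2D(2),
                          nn.Conv2D(h[0], h[1], 3, rng), nn.ReLU(), nn.MaxPool2D(2),
                          nn.Flatten()]
            flat = (S // 2 // 2) * (F // 2 // 2) * h[1]
        elif arch == "cnn1d":
            self.trunk = [nn.Conv1D(F, h[0], 5, rng), nn.ReLU(), nn.MaxPool1D(2),
                          nn.Conv1D(h[0], h[1], 5, rng), nn.ReLU(), nn.MaxPool1D(2),
                          nn.Flatten()]
            flat = (S // 2 // 2) * h[1]
        elif arch == "lstm":
            self.trunk = [nn.LSTMLast(F, h[0], rng)]
            flat = h[0]
        else:
            self.trunk = [nn.GRULast(F, h[0], rng)]
            flat = h[0]
        self.dense1 = nn.Dense(flat + self.n_covariates, self.spec.dense_units, rng, "dense1")
        self.relu1 = nn.ReLU()
        self.drop1 = nn.Dropout(self.spec.dropout, self._dropout_rng)
        self.dense2 = nn.Dense(self.spec.dense_units, 1, rng, "dense2")
        self._flat = flat

    def _as_trunk_input(self, X: np.ndarray) -> np.ndarray:
        arch = self.spec.arch
        if arch == "cnn2d":
            return X[:, None, :, :]                 # (N, 1, S, F)
        if arch == "cnn1d":
            return X.transpose(0, 2, 1)             # (N, F, S)
        return X                                     # (N, S, F) sequence

    # -- forward / backward ----------------------------------------------

    def forward_logit(self, X: np.ndarray, covariates: np.ndarray | None = None,
                      train: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1:] != self.input_shape:
            raise ValueError(f"expected feature maps of shape (N, {self.input_shape[0]}, "
                             f"{self.input_shape[1]}), got {X.shape}")
        if self.spec.use_covariates:
            if covariates is None:
                raise ValueError("model was built with covariate fusion; covariates missing")
            covariates = np.asarray(covariates, dtype=np.float64)
            if covariates.ndim != 2 or covariates.shape != (X.shape[0], self.n_covariates):
                raise ValueError(f"expected covariates of shape ({X.shape[0]}, "
                                 f"{self.n_covariates}), got {np.shape(covariates)}")
        elif covariates is not None:
            raise ValueError("model was built without covariate fusion; covariates supplied")

        out = self._as_trunk_input(X)
        for layer in self.trunk:
            out = layer.forward(out, train=train)
        if self.spec.use_covariates:
            out = np.concatenate([out, covariates], axis=1)
        out = self.dense1.forward(out, train=train)
        out = self.relu1.forward(out, train=train)
        out = self.drop1.forward(out, train=train)
        return self.dense2.forward(out, train=train)[:, 0]

    def forward(self, X, covariates=None, train: bool = False) -> np.ndarray:
        """Probabilities in (0, 1), one per subject."""
        return nn.sigmoid(self.forward_logit(X, covariates, train=train))

    def backward(self, dlogit: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logit)."""
        d = self.dense2.backward(dlogit[:, None])
        d = self.drop1.backward(d)
        d = self.relu1.backward(d)
        d = self.dense1.backward(d)
        if self.spec.use_covariates:
            d = d[:, :self._flat]                   # covariates are inputs, not params
        for i, layer in enumerate(reversed(self.trunk)):
            last = i == len(self.trunk) - 1
            d = layer.backward(d, need_input_grad=not last)

    # -- parameters -------------------------------------------------------

    def params(self) -> list[nn.Param]:
        out = []
        for layer in self.trunk:
            out.extend(layer.params())
        out.extend(self.dense1.params())
        out.extend(self.dense2.params())
        return out

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Checkpoint: weights .npz plus a JSON of the spec."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz",
                 **{f"p{i}": p.value for i, p in enumerate(self.params())})
        meta = dict(spec=asdict(self.spec), input_shape=list(self.input_shape),
                    n_covariates=self.n_covariates)
        meta["spec"]["hidden_sizes"] = (list(self.spec.hidden_sizes)
                                        if self.spec.hidden_sizes is not None else None)
        (directory / "model.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "Classifier":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        spec_d = meta["spec"]
        if spec_d.get("hidden_sizes") is not None:
            spec_d["hidden_sizes"] = tuple(spec_d["hidden_sizes"])
        model = cls(ModelSpec(**spec_d), tuple(meta["input_shape"]), meta["n_covariates"])
        with np.load(directory / "weights.npz") as npz:
            model.set_weights([npz[f"p{i}"] for i in range(len(model.params()))])
        return model


def build_model(spec: ModelSpec, input_shape: tuple[int, int],
                n_covariates: int = 0) -> Classifier:
    """Construct one seeded classifier for the given feature-map shape."""
    return Classifier(spec, input_shape, n_covariates)


def predict(model: Classifier, fmap: FeatureMap,
            covariates: np.ndarray | None = None, threshold: float = 0.5) -> Prediction:
    """Deterministic single-subject inference (dropout inactive)."""
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=np.float64).reshape(1, -1)
    p = float(model.forward(fmap.matrix[None], cov, train=False)[0])
    return Prediction(probability=p, label_hat=int(p >= threshold), threshold=threshold)
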