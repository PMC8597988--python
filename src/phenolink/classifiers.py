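"""Phenotype classifier contract and a trainable reference implementation.

One differentiable classifier per phenotype maps an image to a softmax
distribution over that phenotype's variant domain, and exposes gradients of
scalar functions of its outputs with respect to the input pixels — the only
two capabilities the matching attack, the privacy defense and adversarial
training need. The reference implementation is a small one-hidden-layer
neural network (tanh hidden units, softmax head) on flattened pixels with
hand-derived backpropagation. The nonlinearity matters: like the large face
models it stands in for, a finitely trained network sits well inside the
data's decision margins, which is what makes small adversarial
perturbations effective and adversarial training meaningful; a linear model
would be near max-margin by default and essentially immune to
imperceptible noise on these images.

The softmax head initializes to zero, so an untrained ensemble outputs
exactly uniform distributions; hidden weights are seeded random, and
training is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .genomes import PhenotypeProfile
from .images import ImageTensor
from .matching import PredictionSet
from .schema import PhenotypeSchema

#: classifier-probability floor inside log g, for gradient-stable objectives
G_FLOOR = 1e-20

#: hidden width of the reference network
HIDDEN_UNITS = 64

#: pixels are centered at mid-gray before the first layer so tanh units
#: operate in their linear range regardless of image brightness
INPUT_CENTER = 0.5


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class MLPSoftmaxClassifier:
    """One-hidden-layer tanh network with a softmax output head.

    Parameters: ``w1`` (hidden, features), ``b1`` (hidden,), ``w2``
    (classes, hidden), ``b2`` (classes,).
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray

    @classmethod
    def initialize(cls, n_features: int, n_classes: int, rng: np.random.Generator,
                   hidden: int | None = None) -> "MLPSoftmaxClassifier":
        if hidden is None:
            hidden = HIDDEN_UNITS
        # zero output head -> exactly uniform softmax before training
        return cls(
            w1=rng.normal(0.0, 1.0 / np.sqrt(n_features), size=(hidden, n_features)),
            b1=np.zeros(hidden),
            w2=np.zeros((n_classes, hidden)),
            b2=np.zeros(n_classes),
        )

    def forward(self, flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (softmax probabilities, hidden activations)."""
        a = np.tanh((flat - INPUT_CENTER) @ self.w1.T + self.b1)
        return _softmax(a @ self.w2.T + self.b2), a

    def predict_proba(self, flat: np.ndarray) -> np.ndarray:
        return self.forward(flat)[0]

    def proba_and_input_grad_fn(
        self, flat: np.ndarray
    ) -> tuple[np.ndarray, Callable[[np.ndarray], np.ndarray]]:
        """Probabilities plus a closure mapping d/dlogits to d/dinput."""
        g, a = self.forward(flat)

        def input_grad(grad_logits: np.ndarray) -> np.ndarray:
            da = grad_logits @ self.w2
            dz1 = da * (1.0 - a * a)
            return dz1 @ self.w1

        return g, input_grad

    def copy(self) -> "MLPSoftmaxClassifier":
        return MLPSoftmaxClassifier(
            self.w1.copy(), self.b1.copy(), self.w2.copy(), self.b2.copy()
        )


@dataclass
class ClassifierEnsemble:
    """One classifier per phenotype, sharing a fixed input image shape."""

    schema: PhenotypeSchema
    image_shape: tuple[int, int, int]
    classifiers: dict[str, MLPSoftmaxClassifier]
    train_ids: tuple[str, ...] = ()

    def _flat(self, image: ImageTensor) -> np.ndarray:
        if tuple(image.shape) != tuple(self.image_shape):
            raise ValueError(
                f"image shape {image.shape} does not match ensemble {self.image_shape}"
            )
        return image.pixels.reshape(-1)

    def predict_distributions(self, image: ImageTensor) -> PredictionSet:
        """Softmax distribution and argmax variant per phenotype (pure)."""
        flat = self._flat(image)
        dists = {
            p: self.classifiers[p].predict_proba(flat) for p in self.schema.phenotypes
        }
        return PredictionSet.from_distributions(image.image_id, dists, self.schema)

    def weighted_logsoftmax_value_and_grad(
        self, pixels: np.ndarray, weights: Mapping[str, np.ndarray], expected_form: bool = False
    ) -> tuple[float, np.ndarray]:
        """Value and pixel-gradient of sum_p sum_v c_{p,v} * f(g_p(v, x)).

        ``f`` is ``log g`` by default; with ``expected_form`` the objective is
        the expectation ``sum_v c_{p,v} g_p(v, x)`` instead. Gradients flow
        through the exact softmax Jacobian; the log uses a floor of
        ``G_FLOOR`` in the value only.
        """
        flat = pixels.reshape(-1)
        value = 0.0
        grad = np.zeros_like(flat)
        for p in self.schema.phenotypes:
            g, input_grad = self.classifiers[p].proba_and_input_grad_fn(flat)
            c = np.asarray(weights[p], dtype=float)
            if expected_form:
                value += float(c @ g)
                grad_logits = g * (c - float(g @ c))
            else:
                value += float(c @ np.log(np.clip(g, G_FLOOR, None)))
                grad_logits = c - g * c.sum()
            grad += input_grad(grad_logits)
        return value, grad.reshape(pixels.shape)

    def crossentropy_value_and_grad(
        self, pixels: np.ndarray, phenotype: str, target_index: int
    ) -> tuple[float, np.ndarray]:
        """Cross-entropy -log g_p(target, x) and its pixel gradient."""
        flat = pixels.reshape(-1)
        g, input_grad = self.classifiers[phenotype].proba_and_input_grad_fn(flat)
        value = -float(np.log(max(g[target_index], G_FLOOR)))
        grad_logits = g.copy()
        grad_logits[target_index] -= 1.0
        return value, input_grad(grad_logits).reshape(pixels.shape)

    def copy(self) -> "ClassifierEnsemble":
        return ClassifierEnsemble(
            schema=self.schema,
            image_shape=self.image_shape,
            classifiers={p: c.copy() for p, c in self.classifiers.items()},
            train_ids=self.train_ids,
        )

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file .npz checkpoint (arrays + a JSON metadata blob)."""
        arrays = {}
        for p, c in self.classifiers.items():
            for name in ("w1", "b1", "w2", "b2"):
                arrays[f"{name}_{p}"] = getattr(c, name)
        meta = {
            "phenotypes": list(self.schema.phenotypes),
            "variant_domain": {p: list(v) for p, v in self.schema.variant_domain.items()},
            "snp_map": {p: list(v) for p, v in self.schema.snp_map.items()},
            "image_shape": list(self.image_shape),
            "train_ids": list(self.train_ids),
        }
        arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(str(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierEnsemble":
        with np.load(str(path)) as data:
            meta = json.loads(bytes(data["meta_json"]).decode())
            schema = PhenotypeSchema(
                phenotypes=tuple(meta["phenotypes"]),
                variant_domain={p: tuple(v) for p, v in meta["variant_domain"].items()},
                snp_map={p: tuple(v) for p, v in meta["snp_map"].items()},
            )
            classifiers = {
                p: MLPSoftmaxClassifier(
                    data[f"w1_{p}"].copy(), data[f"b1_{p}"].copy(),
                    data[f"w2_{p}"].copy(), data[f"b2_{p}"].copy(),
                )
                for p in schema.phenotypes
            }
        return cls(
            schema=schema,
            image_shape=tuple(meta["image_shape"]),
            classifiers=classifiers,
            train_ids=tuple(meta["train_ids"]),
        )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_reference_classifiers(
    train_images: Sequence[ImageTensor],
    labels: Sequence[PhenotypeProfile],
    schema: PhenotypeSchema,
    epochs: int = 30,
    seed: int = 0,
    learning_rate: float = 0.01,
    batch_size: int = 32,
    class_weighting: bool = False,
) -> ClassifierEnsemble:
    """Train one network per phenotype from scratch.

    Seeded initialization and epoch shuffling, Adam updates on (optionally
    class-weighted) cross-entropy. Raises if any phenotype has fewer than
    two classes in the training labels.
    """
    if len(train_images) != len(labels):
        raise ValueError("images and labels must align")
    if not train_images:
        raise ValueError("empty training set")
    shape = tuple(train_images[0].shape)
    X = np.stack([im.pixels.reshape(-1) for im in train_images])
    ensemble = ClassifierEnsemble(
        schema=schema,
        image_shape=shape,  # type: ignore[arg-type]
        classifiers={},
        train_ids=tuple(im.image_id for im in train_images),
    )
    rng = np.random.default_rng(seed)
    for p in schema.phenotypes:
        dom = schema.domain(p)
        y = np.array([schema.variant_index(p, lab.values[p]) for lab in labels])
        present = np.unique(y)
        if len(present) < 2:
            raise ValueError(f"phenotype {p!r} has a single class in training data")
        if class_weighting:
            counts = np.bincount(y, minlength=len(dom)).astype(float)
            cw = np.where(counts > 0, len(y) / (len(present) * np.maximum(counts, 1)), 0.0)
        else:
            cw = np.ones(len(dom))
        clf = MLPSoftmaxClassifier.initialize(X.shape[1], len(dom), rng)
        ensemble.classifiers[p] = _train_one(
            clf, X, y, epochs, learning_rate, batch_size, rng, cw
        )
    return ensemble


def _train_one(
    clf: MLPSoftmaxClassifier,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int,
    lr: float,
    batch_size: int,
    rng: np.random.Generator,
    class_weights: np.ndarray,
) -> MLPSoftmaxClassifier:
    n = X.shape[0]
    params = [clf.w1, clf.b1, clf.w2, clf.b2]
    moments = [(np.zeros_like(p), np.zeros_like(p)) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    sample_w = class_weights[y]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            Xb, yb, wb = X[idx] - INPUT_CENTER, y[idx], sample_w[idx]
            a = np.tanh(Xb @ clf.w1.T + clf.b1)
            probs = _softmax(a @ clf.w2.T + clf.b2)
            du = probs.copy()
            du[np.arange(len(yb)), yb] -= 1.0
            du *= wb[:, None] / len(yb)
            g_w2 = du.T @ a
            g_b2 = du.sum(axis=0)
            da = du @ clf.w2
            dz1 = da * (1.0 - a * a)
            g_w1 = dz1.T @ Xb
            g_b1 = dz1.sum(axis=0)
            t += 1
            for (m, v), param, g in zip(moments, params, (g_w1, g_b1, g_w2, g_b2)):
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                param -= lr * mhat / (np.sqrt(vhat) + eps)
    return clf


def continue_training(
    ensemble: ClassifierEnsemble,
    train_images: Sequence[ImageTensor],
    labels: Sequence[PhenotypeProfile],
    epochs: int = 1,
    seed: int = 0,
    learning_rate: float = 0.005,
    batch_size: int = 32,
) -> ClassifierEnsemble:
    """Run further training epochs starting from the given parameters."""
    X = np.stack([im.pixels.reshape(-1) for im in train_images])
    out = ensemble.copy()
    rng = np.random.default_rng(seed)
    schema = ensemble.schema
    for p in schema.phenotypes:
        y = np.array([schema.variant_index(p, lab.values[p]) for lab in labels])
        out.classifiers[p] = _train_one(
            out.classifiers[p], X, y, epochs, learning_rate, batch_size, rng,
            np.ones(len(schema.domain(p))),
        )
    return out


def predict_distributions(
    ensemble: ClassifierEnsemble, image: ImageTensor, schema: PhenotypeSchema | None = None
) -> PredictionSet:
    """Functional alias for :meth:`ClassifierEnsemble.predict_distributions`."""
    return ensemble.predict_distributions(image)


def evaluate_accuracy(
    ensemble: ClassifierEnsemble,
    images: Sequence[ImageTensor],
    labels: Sequence[PhenotypeProfile],
) -> dict[str, float]:
    """Held-out argmax accuracy per phenotype."""
    correct = {p: 0 for p in ensemble.schema.phenotypes}
    for im, lab in zip(images, labels):
        preds = ensemble.predict_distributions(im)
        for p in ensemble.schema.phenotypes:
            correct[p] += preds.argmax_variants[p] == lab.values[p]
    return {p: c / len(images) for p, c in correct.items()}
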