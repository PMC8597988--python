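"""Privacy defense: small l-infinity image perturbations against linkage.

The defended objective couples the classifier softmax outputs with the
genotype-conditional phenotype probabilities of the image's *true* genome:

    min_{|delta|_inf <= eps}  sum_p sum_v  log g_p(v, x + delta) * log P(v | y)

Both log factors are nonpositive, so every term is nonnegative and the
minimum redistributes prediction mass toward variants with low P(v | y)
(the optimum places g proportional to -log P). An alternative
expected-log-likelihood form, sum_v g_p(v, x+delta) * log P(v | y), is
available behind a flag. Optimization is projected gradient descent with
adaptive first/second-moment (Adam-style) step scaling: after every step the
noise is clipped to [-eps, eps] and pixels to [0, 1]. The best iterate by
objective is returned, so the final objective never exceeds the initial one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .classifiers import ClassifierEnsemble
from .conditional import ConditionalModel, variant_probs_given_genome
from .genomes import Genome
from .images import ImageTensor
from .schema import PhenotypeSchema


@dataclass
class PerturbationConfig:
    """Projected-gradient-descent settings for crafting perturbations.

    ``step_size`` defaults to ``epsilon / 10`` when left as None.
    """

    epsilon: float
    steps: int = 100
    step_size: float | None = None
    init: Literal["zero", "random"] = "zero"
    seed: int = 0
    objective_form: Literal["double_log", "expected"] = "double_log"

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must be in [0, 1]")
        if self.steps < 0:
            raise ValueError("steps must be >= 0")

    @property
    def effective_step(self) -> float:
        return self.epsilon / 10.0 if self.step_size is None else self.step_size


@dataclass
class DefenseResult:
    """Outcome of a perturbation run.

    Invariants: ``max|delta| <= epsilon`` bit-exactly, perturbed pixels in
    [0, 1], and ``final_objective <= initial_objective`` (best iterate).
    """

    perturbed_image: ImageTensor
    delta: np.ndarray
    objective_trace: list[float]
    initial_objective: float
    final_objective: float


def _log_conditional_weights(
    genome: Genome, model: ConditionalModel, schema: PhenotypeSchema
) -> dict[str, np.ndarray]:
    """c_{p,v} = log P(v | y), floored at the model's probability floor."""
    return {
        p: np.log(
            np.clip(variant_probs_given_genome(p, genome, model, schema), model.prob_floor, None)
        )
        for p in schema.phenotypes
    }


def defense_objective(
    image: ImageTensor,
    genome: Genome,
    ensemble: ClassifierEnsemble,
    model: ConditionalModel,
    schema: PhenotypeSchema,
    objective_form: Literal["double_log", "expected"] = "double_log",
) -> float:
    """Evaluate the defense objective at the (unperturbed) image."""
    weights = _log_conditional_weights(genome, model, schema)
    value, _ = ensemble.weighted_logsoftmax_value_and_grad(
        image.pixels, weights, expected_form=(objective_form == "expected")
    )
    return value


def _pgd_minimize(
    pixels: np.ndarray,
    value_and_grad,
    config: PerturbationConfig,
) -> tuple[np.ndarray, list[float], float, float]:
    """Adam-scaled PGD on delta; returns (best_delta, trace, initial, best)."""
    def project(delta: np.ndarray) -> np.ndarray:
        # pixel box first, epsilon box last: the final clip makes
        # max|delta| <= epsilon hold bit-exactly despite float rounding
        delta = np.clip(pixels + delta, 0.0, 1.0) - pixels
        return np.clip(delta, -config.epsilon, config.epsilon)

    rng = np.random.default_rng(config.seed)
    if config.init == "random" and config.epsilon > 0:
        delta = project(rng.uniform(-config.epsilon, config.epsilon, size=pixels.shape))
    else:
        delta = np.zeros_like(pixels)
    value0, _ = value_and_grad(pixels + delta)
    best_delta = delta.copy()
    best_value = value0
    trace = [value0]
    m = np.zeros_like(delta)
    v = np.zeros_like(delta)
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    step = config.effective_step
    for t in range(1, config.steps + 1):
        _, grad = value_and_grad(pixels + delta)
        m = beta1 * m + (1 - beta1) * grad
        v = beta2 * v + (1 - beta2) * grad * grad
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        delta = project(delta - step * mhat / (np.sqrt(vhat) + eps_adam))
        value, _ = value_and_grad(pixels + delta)
        trace.append(value)
        if value < best_value:
            best_value = value
            best_delta = delta.copy()
    return best_delta, trace, value0, best_value


def craft_defense_perturbation(
    image: ImageTensor,
    genome: Genome,
    ensemble: ClassifierEnsemble,
    model: ConditionalModel,
    schema: PhenotypeSchema,
    config: PerturbationConfig,
) -> DefenseResult:
    """Minimize the matching objective of an image to its true genome.

    PGD with box projection of both the noise and the resulting pixels;
    deterministic given config (the seed only matters for random init).
    """
    weights = _log_conditional_weights(genome, model, schema)
    expected = config.objective_form == "expected"

    def value_and_grad(px: np.ndarray) -> tuple[float, np.ndarray]:
        return ensemble.weighted_logsoftmax_value_and_grad(px, weights, expected_form=expected)

    delta, trace, v0, vbest = _pgd_minimize(image.pixels, value_and_grad, config)
    perturbed = ImageTensor(np.clip(image.pixels + delta, 0.0, 1.0), image.image_id)
    return DefenseResult(perturbed, delta, trace, v0, vbest)


def targeted_phenotype_perturbation(
    image: ImageTensor,
    target_phenotype: str,
    ensemble: ClassifierEnsemble,
    config: PerturbationConfig,
) -> DefenseResult:
    """Single-phenotype misclassification baseline.

    Maximizes the target classifier's cross-entropy against its clean-image
    argmax (objective recorded as negative cross-entropy so smaller is
    better, matching the defense convention).
    """
    if target_phenotype not in ensemble.schema.phenotypes:
        raise ValueError(f"unknown phenotype {target_phenotype!r}")
    clean_pred = ensemble.predict_distributions(image)
    target_idx = ensemble.schema.variant_index(
        target_phenotype, clean_pred.argmax_variants[target_phenotype]
    )

    def value_and_grad(px: np.ndarray) -> tuple[float, np.ndarray]:
        ce, grad = ensemble.crossentropy_value_and_grad(px, target_phenotype, target_idx)
        return -ce, -grad

    delta, trace, v0, vbest = _pgd_minimize(image.pixels, value_and_grad, config)
    perturbed = ImageTensor(np.clip(image.pixels + delta, 0.0, 1.0), image.image_id)
    return DefenseResult(perturbed, delta, trace, v0, vbest)
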