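"""Adversarial training of the classifier ensemble and robustness evaluation.

Models an attacker who retrains phenotype classifiers to shrug off the
privacy perturbations: several passes over the training pairs, each pass
regenerating matching-score perturbations (random starting points) against
the current model and then taking a training epoch on the perturbed inputs.
Robust models are then evaluated by defending held-out images at a grid of
budgets and measuring top-k matching success — including budget 0, the
clean-input accuracy the robust model gives up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._rng import subseed
from .classifiers import ClassifierEnsemble, continue_training
from .conditional import ConditionalModel
from .defense import (
    PerturbationConfig,
    _log_conditional_weights,
    _pgd_minimize,
    craft_defense_perturbation,
)
from .genomes import Genome, PhenotypeProfile
from .images import ImageTensor
from .matching import RISK_COLUMNS, build_score_matrix, top_k_success, truth_from_pairs
from .schema import PhenotypeSchema


@dataclass
class RobustTrainConfig:
    """Adversarial-training settings.

    ``passes`` defaults to five regenerate-then-train rounds; each pass
    trains on the perturbed images plus a ``mix_ratio`` share of clean
    copies (default 1.0: full augmentation, perturbed alongside clean, which
    preserves clean accuracy; 0.0 replaces clean inputs outright). ``attack``
    picks the perturbation objective: the matching-score defense
    ("matching", needs paired genomes) or summed per-classifier
    cross-entropy on the true labels ("crossentropy").
    """

    epsilon_train: float
    passes: int = 5
    train_fraction: float = 0.6
    seed: int = 0
    attack: Literal["matching", "crossentropy"] = "matching"
    steps: int = 50
    mix_ratio: float = 1.0
    epochs_per_pass: int = 1
    learning_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.passes < 0:
            raise ValueError("passes must be >= 0")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if not (0.0 <= self.mix_ratio <= 1.0):
            raise ValueError("mix_ratio must be in [0, 1]")


def split_pairs(
    n: int, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded train/test index split (approximately 60/40 by default)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    return np.sort(order[:n_train]), np.sort(order[n_train:])


def _crossentropy_attack(
    image: ImageTensor,
    label: PhenotypeProfile,
    ensemble: ClassifierEnsemble,
    config: PerturbationConfig,
) -> ImageTensor:
    """Untargeted attack minimizing sum_p log g_p(true variant, x + delta)."""
    schema = ensemble.schema
    weights = {}
    for p in schema.phenotypes:
        vec = np.zeros(len(schema.domain(p)))
        vec[schema.variant_index(p, label.values[p])] = 1.0
        weights[p] = vec

    def value_and_grad(px: np.ndarray):
        return ensemble.weighted_logsoftmax_value_and_grad(px, weights)

    delta, _, _, _ = _pgd_minimize(image.pixels, value_and_grad, config)
    return ImageTensor(np.clip(image.pixels + delta, 0.0, 1.0), image.image_id)


def adversarial_train(
    ensemble: ClassifierEnsemble,
    images: Sequence[ImageTensor],
    genomes: Sequence[Genome],
    labels: Sequence[PhenotypeProfile],
    model: ConditionalModel,
    schema: PhenotypeSchema,
    config: RobustTrainConfig,
) -> ClassifierEnsemble:
    """Iteratively retrain on freshly perturbed paired data.

    Each pass crafts perturbations against the *current* ensemble from
    random starting points, then runs ``epochs_per_pass`` training epochs on
    the perturbed images (plus a ``mix_ratio`` share of clean copies).
    ``passes = 0`` returns an identical copy of the input ensemble.
    """
    if not (len(images) == len(genomes) == len(labels)):
        raise ValueError("images, genomes and labels must align")
    current = ensemble.copy()
    current.train_ids = tuple(im.image_id for im in images)
    n = len(images)
    rng = np.random.default_rng(subseed(config.seed, "mix"))
    for pass_i in range(config.passes):
        perturbed: list[ImageTensor] = []
        for im, gen, lab in zip(images, genomes, labels):
            pcfg = PerturbationConfig(
                epsilon=config.epsilon_train,
                steps=config.steps,
                init="random",
                seed=subseed(config.seed, f"pass{pass_i}:{im.image_id}"),
            )
            if config.attack == "matching":
                perturbed.append(
                    craft_defense_perturbation(im, gen, current, model, schema, pcfg).perturbed_image
                )
            else:
                perturbed.append(_crossentropy_attack(im, lab, current, pcfg))
        train_imgs = list(perturbed)
        train_labels = list(labels)
        if config.mix_ratio > 0:
            n_clean = int(round(config.mix_ratio * n))
            keep = rng.choice(n, size=n_clean, replace=False)
            train_imgs += [images[i] for i in keep]
            train_labels += [labels[i] for i in keep]
        current = continue_training(
            current,
            train_imgs,
            train_labels,
            epochs=config.epochs_per_pass,
            seed=subseed(config.seed, f"train_pass{pass_i}"),
            learning_rate=config.learning_rate,
        )
        current.train_ids = tuple(im.image_id for im in images)
    return current


def evaluate_robustness(
    robust_ensemble: ClassifierEnsemble,
    clean_ensemble: ClassifierEnsemble,
    test_images: Sequence[ImageTensor],
    test_genomes: Sequence[Genome],
    model: ConditionalModel,
    schema: PhenotypeSchema,
    eval_epsilons: Sequence[float],
    k: int,
    seed: int,
    defense_steps: int = 100,
) -> pd.DataFrame:
    """Top-k matching success of both ensembles under white-box defenses.

    For each budget (0 means clean inputs), test images are defended against
    the ensemble under evaluation and matching success over the test gallery
    is reported. Raises if any test image was seen during the robust
    ensemble's adversarial training.
    """
    test_ids = {im.image_id for im in test_images}
    overlap = test_ids & set(robust_ensemble.train_ids)
    if overlap:
        raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")
    rows = []
    for label, ens in (("robust", robust_ensemble), ("clean", clean_ensemble)):
        for eps in eval_epsilons:
            preds = []
            for im, gen in zip(test_images, test_genomes):
                if eps == 0:
                    preds.append(ens.predict_distributions(im))
                else:
                    pcfg = PerturbationConfig(
                        epsilon=eps,
                        steps=defense_steps,
                        seed=subseed(seed, f"eval:{label}:{eps}:{im.image_id}"),
                    )
                    res = craft_defense_perturbation(im, gen, ens, model, schema, pcfg)
                    preds.append(ens.predict_distributions(res.perturbed_image))
            matrix = build_score_matrix(
                preds, test_genomes, model, schema, truth_from_pairs(preds, test_genomes)
            )
            rows.append(
                {
                    "mode": f"{label}_model_defended",
                    "population_size": len(test_genomes),
                    "k_or_tau": k,
                    "epsilon": eps,
                    "metric": "topk_success",
                    "value": top_k_success(matrix, k),
                    "n_replicates": 1,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows, columns=RISK_COLUMNS)
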