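"""End-to-end experiment orchestration from a single JSON config.

One master seed fans out into named substreams (fit cohort, evaluation
cohort, classifier training, sweeps, defenses, adversarial training), so
adding a stage never perturbs earlier stages' randomness and re-running the
same config reproduces every report byte for byte. Outputs are tidy CSVs
mirroring the three experiment families — risk curves vs population size,
ROC/AUC, defense effectiveness vs budget, and robust-model evaluation — plus
a provenance manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import subseed
from .classifiers import evaluate_accuracy, train_reference_classifiers
from .cohort import default_generator_spec, generate_cohort, render_images
from .conditional import fit_conditional_tables
from .defense import PerturbationConfig, craft_defense_perturbation, targeted_phenotype_perturbation
from .matching import (
    RISK_COLUMNS,
    baseline_upper_bound,
    build_score_matrix,
    population_sweep,
    random_baseline,
    roc_report,
    top_k_success,
    truth_from_pairs,
)
from .robust import RobustTrainConfig, adversarial_train, evaluate_robustness, split_pairs


@dataclass
class ExperimentConfig:
    """Parameters of a full synthetic re-identification study."""

    master_seed: int = 0
    # cohorts
    n_fit: int = 500  # fitting cohort for the conditional tables
    n_eval: int = 126  # paired image-genome gallery under attack
    n_train_images: int = 300  # classifier training cohort
    image_size: int = 32
    render_noise_sd: float = 0.05
    # classifier
    epochs: int = 30
    # matching evaluation
    k_list: tuple[int, ...] = (1, 5)
    population_sizes: tuple[int, ...] = (5, 10, 20, 50, 126)
    replicates: int = 20
    # defense
    defense_epsilons: tuple[float, ...] = (0.001, 0.01, 0.05)
    defense_steps: int = 100
    # adversarial training
    robust_epsilon: float = 0.01
    robust_passes: int = 5
    robust_eval_epsilons: tuple[float, ...] = (0.0, 0.001, 0.01, 0.025)
    train_fraction: float = 0.6

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json_str())

    def to_json_str(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        d = json.loads(Path(path).read_text())
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(d[f.name], list):
                d[f.name] = tuple(d[f.name])
        return cls(**d)


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run simulate -> fit -> train -> match -> sweep -> defend -> advtrain.

    Writes ``risk_curves.csv``, ``roc.csv``, ``defense.csv``, ``robust.csv``
    and ``manifest.json`` into ``out_dir`` and returns their paths. Any
    stage failure aborts with the stage name attached.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_test"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise RuntimeError(f"output directory {out} is not writable: {exc}") from exc

    ms = config.master_seed
    stage = "simulate"
    try:
        fit_spec = default_generator_spec(
            config.n_fit,
            seed=subseed(ms, "fit_cohort"),
            image_size=config.image_size,
            render_noise_sd=config.render_noise_sd,
        )
        fit_genomes, fit_profiles = generate_cohort(fit_spec)
        eval_spec = dataclasses.replace(fit_spec, n_individuals=config.n_eval,
                                        seed=subseed(ms, "eval_cohort"))
        eval_genomes, eval_profiles = generate_cohort(eval_spec)
        train_spec = dataclasses.replace(fit_spec, n_individuals=config.n_train_images,
                                         seed=subseed(ms, "train_cohort"))
        _, train_profiles = generate_cohort(train_spec)
        train_images = render_images(train_profiles, train_spec)
        eval_images = render_images(eval_profiles, eval_spec)

        stage = "fit"
        model = fit_conditional_tables(fit_genomes, fit_profiles, fit_spec.schema)
        schema = fit_spec.schema

        stage = "train"
        ensemble = train_reference_classifiers(
            train_images, train_profiles, schema,
            epochs=config.epochs, seed=subseed(ms, "classifier"),
        )
        accuracy = evaluate_accuracy(ensemble, eval_images, eval_profiles)

        stage = "match"
        predictions = [ensemble.predict_distributions(im) for im in eval_images]
        matrix = build_score_matrix(
            predictions, eval_genomes, model, schema,
            truth_from_pairs(predictions, eval_genomes),
        )

        stage = "sweep"
        sizes = [s for s in config.population_sizes if s <= config.n_eval]
        risk_rows = []
        for k in config.k_list:
            ks = [s for s in sizes if s >= k]
            risk_rows.append(population_sweep(
                matrix, ks, k, config.replicates, subseed(ms, f"sweep_k{k}")))
            risk_rows.append(random_baseline(ks, k))
            risk_rows.append(baseline_upper_bound(
                eval_profiles, eval_genomes, model, schema, k, ks,
                config.replicates, subseed(ms, f"upper_k{k}")))
        risk_curves = pd.concat(risk_rows, ignore_index=True)

        stage = "roc"
        roc_rows = roc_report(matrix, seed=ms)

        stage = "defend"
        defense_rows = []
        for eps in config.defense_epsilons:
            for mode, craft in (("full_defense", "full"), ("sex_only_attack", "sex")):
                preds = []
                for im, gen in zip(eval_images, eval_genomes):
                    pcfg = PerturbationConfig(
                        epsilon=eps, steps=config.defense_steps,
                        seed=subseed(ms, f"defense:{mode}:{eps}:{im.image_id}"),
                    )
                    if craft == "full":
                        res = craft_defense_perturbation(im, gen, ensemble, model, schema, pcfg)
                    else:
                        res = targeted_phenotype_perturbation(im, "sex", ensemble, pcfg)
                    preds.append(ensemble.predict_distributions(res.perturbed_image))
                dm = build_score_matrix(preds, eval_genomes, model, schema,
                                        truth_from_pairs(preds, eval_genomes))
                defense_rows.append({
                    "mode": mode,
                    "population_size": config.n_eval,
                    "k_or_tau": 1,
                    "epsilon": eps,
                    "metric": "topk_success",
                    "value": top_k_success(dm, 1),
                    "n_replicates": 1,
                    "seed": ms,
                })
        defense = pd.DataFrame(defense_rows, columns=RISK_COLUMNS)

        stage = "advtrain"
        # The base model for this stage is retrained with the clean copies of
        # the adversarial-training pair images included, and the comparison
        # model receives the same extra passes on clean inputs (epsilon 0), so
        # the robust-vs-clean contrast isolates the adversarial noise itself.
        tr_idx, te_idx = split_pairs(
            config.n_eval, config.train_fraction, subseed(ms, "robust_split"))
        base_for_robust = train_reference_classifiers(
            train_images + [eval_images[i] for i in tr_idx],
            train_profiles + [eval_profiles[i] for i in tr_idx],
            schema, epochs=config.epochs, seed=subseed(ms, "classifier_robust"),
        )
        pair_args = (
            [eval_images[i] for i in tr_idx],
            [eval_genomes[i] for i in tr_idx],
            [eval_profiles[i] for i in tr_idx],
            model, schema,
        )
        robust = adversarial_train(base_for_robust, *pair_args, RobustTrainConfig(
            epsilon_train=config.robust_epsilon, passes=config.robust_passes,
            train_fraction=config.train_fraction, seed=subseed(ms, "advtrain"),
        ))
        control = adversarial_train(base_for_robust, *pair_args, RobustTrainConfig(
            epsilon_train=0.0, passes=config.robust_passes,
            train_fraction=config.train_fraction, seed=subseed(ms, "advtrain"),
        ))
        stage = "evalrobust"
        robust_rows = evaluate_robustness(
            robust, control,
            [eval_images[i] for i in te_idx],
            [eval_genomes[i] for i in te_idx],
            model, schema, config.robust_eval_epsilons, k=1,
            seed=subseed(ms, "evalrobust"),
        )
    except Exception as exc:
        raise RuntimeError(f"experiment stage {stage!r} failed: {exc}") from exc

    paths = {}
    for name, df in (
        ("risk_curves", risk_curves),
        ("roc", roc_rows),
        ("defense", defense),
        ("robust", robust_rows),
    ):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        paths[name] = path

    cfg_str = config.to_json_str()
    manifest = {
        "config": json.loads(cfg_str),
        "config_sha256": hashlib.sha256(cfg_str.encode()).hexdigest(),
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "classifier_holdout_accuracy": {p: round(a, 6) for p, a in accuracy.items()},
        "seeds": {"master": ms},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mpath
    return paths
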