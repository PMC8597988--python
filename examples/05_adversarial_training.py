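"""Can an attacker neutralize the defense by adversarially training classifiers?

Trains a base ensemble whose training data include the clean copies of the
adversarial-training pairs, hardens it with five passes of adversarial
training at a fixed budget, and compares robust vs clean models on a held-out
test split — on clean inputs and under the defense at the training budget.
"""

import dataclasses

import phenolink as pl
from phenolink._rng import subseed

SEED = 7
EPS = 0.01

spec = pl.default_generator_spec(300, seed=subseed(SEED, "fit"), render_noise_sd=0.1)
fg, fp = pl.generate_cohort(spec)
model = pl.fit_conditional_tables(fg, fp, spec.schema)

pair_spec = dataclasses.replace(spec, n_individuals=60, seed=subseed(SEED, "pairs"))
genomes, profiles = pl.generate_cohort(pair_spec)
images = pl.render_images(profiles, pair_spec)
train_spec = dataclasses.replace(spec, n_individuals=200, seed=subseed(SEED, "train"))
_, tp = pl.generate_cohort(train_spec)
timgs = pl.render_images(tp, train_spec)

tr, te = pl.split_pairs(60, 0.6, subseed(SEED, "split"))
ensemble = pl.train_reference_classifiers(
    timgs + [images[i] for i in tr], tp + [profiles[i] for i in tr],
    spec.schema, epochs=30, seed=subseed(SEED, "clf"),
)
pair_args = ([images[i] for i in tr], [genomes[i] for i in tr],
             [profiles[i] for i in tr], model, spec.schema)
robust = pl.adversarial_train(ensemble, *pair_args, pl.RobustTrainConfig(
    epsilon_train=EPS, passes=5, seed=subseed(SEED, "adv")))
# control: identical extra passes on clean inputs (budget 0), so the contrast
# isolates the adversarial noise itself
control = pl.adversarial_train(ensemble, *pair_args, pl.RobustTrainConfig(
    epsilon_train=0.0, passes=5, seed=subseed(SEED, "adv")))
report = pl.evaluate_robustness(
    robust, control, [images[i] for i in te], [genomes[i] for i in te],
    model, spec.schema, [0.0, EPS], k=1, seed=subseed(SEED, "eval"),
)
print(report.to_string(index=False))
print(f"\nrows show top-1 matching success on the {len(te)}-pair test split;")
print("'clean_model' is the control given the same extra passes on clean inputs.")
print(f"epsilon 0 is clean input, epsilon {EPS} is the defense re-optimized against")
print("each model. The adversarially trained model's edge under attack is modest")
print("and shows up on means across replicates (a single small split, as here,")
print("can tie); the defense still bites both models at this budget.")
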