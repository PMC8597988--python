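"""Privacy-defense objective, PGD feasibility and effectiveness direction."""

import dataclasses
import math

import numpy as np
import pytest

import phenolink as pl
from phenolink.classifiers import G_FLOOR
from phenolink.defense import defense_objective
from phenolink.matching import build_score_matrix, top_k_success, truth_from_pairs


def loop_objective(image, genome, ensemble, model, schema, expected_form=False):
    """Independent oracle: explicit double loop over phenotypes and variants."""
    from phenolink.conditional import variant_probs_given_genome

    preds = ensemble.predict_distributions(image)
    total = 0.0
    for p in schema.phenotypes:
        probs = variant_probs_given_genome(p, genome, model, schema)
        for i, v in enumerate(schema.domain(p)):
            g = preds.distributions[p][i]
            c = math.log(max(probs[i], model.prob_floor))
            total += (g * c) if expected_form else (math.log(max(g, G_FLOOR)) * c)
    return total


@pytest.mark.parametrize("expected_form", [False, True])
def test_objective_matches_double_loop_oracle(trained_setup, expected_form):
    spec, model, ensemble, genomes, _, images = trained_setup
    form = "expected" if expected_form else "double_log"
    for im, gen in zip(images[:5], genomes[:5]):
        got = defense_objective(im, gen, ensemble, model, spec.schema, objective_form=form)
        assert got == pytest.approx(
            loop_objective(im, gen, ensemble, model, spec.schema, expected_form), rel=1e-9
        )


def test_objective_annihilated_when_all_conditionals_are_one(trained_setup):
    """If P(v|y) = 1 for every variant, each weight log P is 0 and the
    objective is 0 regardless of the classifier outputs (and so is its
    gradient)."""
    spec, _, ensemble, _, _, images = trained_setup
    zero_weights = {
        p: np.zeros(len(spec.schema.domain(p))) for p in spec.schema.phenotypes
    }
    value, grad = ensemble.weighted_logsoftmax_value_and_grad(images[0].pixels, zero_weights)
    assert value == 0.0
    np.testing.assert_array_equal(grad, 0.0)


def test_objective_decreases_when_mass_moves_to_low_probability_variants():
    """Sign behavior on a two-variant toy, against the loop oracle."""
    from phenolink.schema import PhenotypeSchema

    sch = PhenotypeSchema(
        phenotypes=("sex",), variant_domain={"sex": ("F", "M")}, snp_map={"sex": ("rs1",)}
    )
    tables = {("sex", "rs1"): {"AA": np.array([0.9, 0.1])}}
    model = pl.ConditionalModel(schema=sch, tables=tables, smoothing_alpha=0.0)
    c = np.log([0.9, 0.1])

    def toy_objective(g):
        return float(np.sum(np.log(np.clip(g, G_FLOOR, None)) * c))

    # moving probability mass toward M (the low-P variant) lowers the objective
    assert toy_objective([0.2, 0.8]) < toy_objective([0.8, 0.2])
    # the unconstrained-on-simplex optimum is g proportional to -log P
    opt = -c / (-c).sum()
    perturbations = [np.array([0.01, -0.01]), np.array([-0.01, 0.01])]
    for d in perturbations:
        assert toy_objective(opt) <= toy_objective(opt + d)


def test_epsilon_zero_is_identity(trained_setup):
    spec, model, ensemble, genomes, _, images = trained_setup
    cfg = pl.PerturbationConfig(epsilon=0.0, steps=20, seed=1)
    res = pl.craft_defense_perturbation(images[0], genomes[0], ensemble, model, spec.schema, cfg)
    np.testing.assert_array_equal(res.delta, 0.0)
    np.testing.assert_array_equal(res.perturbed_image.pixels, images[0].pixels)
    assert res.final_objective == res.initial_objective


def test_feasibility_is_bit_exact(trained_setup):
    spec, model, ensemble, genomes, _, images = trained_setup
    for init in ("zero", "random"):
        cfg = pl.PerturbationConfig(epsilon=0.01, steps=40, seed=3, init=init)
        for im, gen in zip(images[:4], genomes[:4]):
            res = pl.craft_defense_perturbation(im, gen, ensemble, model, spec.schema, cfg)
            assert np.abs(res.delta).max() <= 0.01 + 1e-9
            assert res.perturbed_image.pixels.min() >= 0.0
            assert res.perturbed_image.pixels.max() <= 1.0


def test_best_iterate_objective_never_exceeds_initial(trained_setup):
    spec, model, ensemble, genomes, _, images = trained_setup
    cfg = pl.PerturbationConfig(epsilon=0.01, steps=100, seed=5)
    for im, gen in zip(images[:5], genomes[:5]):
        res = pl.craft_defense_perturbation(im, gen, ensemble, model, spec.schema, cfg)
        assert res.final_objective <= res.initial_objective
        assert res.final_objective == min(res.objective_trace)


def test_defense_deterministic_given_config(trained_setup):
    spec, model, ensemble, genomes, _, images = trained_setup
    cfg = pl.PerturbationConfig(epsilon=0.02, steps=30, seed=11, init="random")
    r1 = pl.craft_defense_perturbation(images[0], genomes[0], ensemble, model, spec.schema, cfg)
    r2 = pl.craft_defense_perturbation(images[0], genomes[0], ensemble, model, spec.schema, cfg)
    np.testing.assert_array_equal(r1.delta, r2.delta)
    assert r1.objective_trace == r2.objective_trace


def test_negative_steps_rejected():
    with pytest.raises(ValueError):
        pl.PerturbationConfig(epsilon=0.01, steps=-1)
    with pytest.raises(ValueError):
        pl.PerturbationConfig(epsilon=1.5)


# -- targeted baseline --------------------------------------------------------


def test_targeted_epsilon_zero_unchanged(trained_setup):
    spec, _, ensemble, _, _, images = trained_setup
    cfg = pl.PerturbationConfig(epsilon=0.0, steps=10, seed=0)
    res = pl.targeted_phenotype_perturbation(images[0], "sex", ensemble, cfg)
    np.testing.assert_array_equal(res.perturbed_image.pixels, images[0].pixels)


def test_targeted_flip_rate_nondecreasing_in_epsilon(trained_setup):
    spec, model, ensemble, genomes, profiles, images = trained_setup
    rates = []
    for eps in (0.001, 0.01, 0.05):
        flips = 0
        for im in images:
            cfg = pl.PerturbationConfig(epsilon=eps, steps=60, seed=2)
            res = pl.targeted_phenotype_perturbation(im, "sex", ensemble, cfg)
            before = ensemble.predict_distributions(im).argmax_variants["sex"]
            after = ensemble.predict_distributions(res.perturbed_image).argmax_variants["sex"]
            flips += before != after
        rates.append(flips / len(images))
    assert rates[0] <= rates[1] <= rates[2]


def test_unknown_target_phenotype_rejected(trained_setup):
    spec, _, ensemble, _, _, images = trained_setup
    cfg = pl.PerturbationConfig(epsilon=0.01, steps=5, seed=0)
    with pytest.raises(ValueError, match="unknown phenotype"):
        pl.targeted_phenotype_perturbation(images[0], "height", ensemble, cfg)


def test_full_defense_lowers_true_pair_score_at_least_as_much_as_sex_attack(trained_setup):
    """The matching-tailored objective beats the single-phenotype baseline."""
    spec, model, ensemble, genomes, _, images = trained_setup
    eps = 0.01
    full_scores, sex_scores = [], []
    for im, gen in zip(images, genomes):
        cfg = pl.PerturbationConfig(epsilon=eps, steps=60, seed=8)
        full = pl.craft_defense_perturbation(im, gen, ensemble, model, spec.schema, cfg)
        sex = pl.targeted_phenotype_perturbation(im, "sex", ensemble, cfg)
        for res, acc in ((full, full_scores), (sex, sex_scores)):
            preds = ensemble.predict_distributions(res.perturbed_image)
            acc.append(pl.score_pair(preds, gen, model, spec.schema))
    assert np.mean(full_scores) <= np.mean(sex_scores)


def test_defended_success_not_above_undefended(trained_setup):
    spec, model, ensemble, genomes, _, images = trained_setup
    preds = [ensemble.predict_distributions(im) for im in images]
    truth = truth_from_pairs(preds, genomes)
    base = top_k_success(build_score_matrix(preds, genomes, model, spec.schema, truth), 1)
    dpreds = []
    for im, gen in zip(images, genomes):
        cfg = pl.PerturbationConfig(epsilon=0.025, steps=60, seed=6)
        res = pl.craft_defense_perturbation(im, gen, ensemble, model, spec.schema, cfg)
        dpreds.append(ensemble.predict_distributions(res.perturbed_image))
    defended = top_k_success(build_score_matrix(dpreds, genomes, model, spec.schema, truth), 1)
    assert defended <= base
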