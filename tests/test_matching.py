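"""Matching scores, top-k evaluation and ROC/AUC against independent oracles."""

import itertools
import math

import numpy as np
import pytest

import phenolink as pl
from phenolink.matching import PredictionSet, ScoreMatrix, roc_and_auc
from phenolink.schema import PhenotypeSchema

# -- score_pair --------------------------------------------------------------


def _delta_predictions(image_id, variants, schema):
    dists = {}
    for p, v in variants.items():
        vec = np.zeros(len(schema.domain(p)))
        vec[schema.variant_index(p, v)] = 1.0
        dists[p] = vec
    return PredictionSet.from_distributions(image_id, dists, schema)


@pytest.fixture(scope="module")
def hand_model(schema):
    """Single-SNP-per-phenotype model with hand-set conditional entries."""
    one_snp = {p: (schema.relevant_snps(p)[0],) for p in schema.phenotypes}
    sch = pl.default_schema(one_snp)
    probs = {"sex": [0.5, 0.5], "hair": [0.25, 0.5, 0.25], "skin": [0.1, 0.6, 0.3],
             "eye": [0.2, 0.5, 0.3]}
    tables = {
        (p, sch.relevant_snps(p)[0]): {"AA": np.array(probs[p])}
        for p in sch.phenotypes
    }
    model = pl.ConditionalModel(schema=sch, tables=tables, smoothing_alpha=0.0)
    genome = pl.Genome("g0", {rsid: "AA" for rsid in sch.all_snps})
    return sch, model, genome


def test_score_pair_is_log_sum_of_conditionals(hand_model):
    sch, model, genome = hand_model
    preds = _delta_predictions(
        "i0", {"sex": "F", "hair": "black", "skin": "pale", "eye": "blue"}, sch
    )
    # direct arithmetic oracle: ln(0.5 * 0.25 * 0.1 * 0.2) = ln 0.0025
    got = pl.score_pair(preds, genome, model, sch)
    assert got == pytest.approx(math.log(0.0025))
    assert got == pytest.approx(-5.9915, abs=1e-4)


def test_score_zero_when_all_probs_one(schema):
    one_snp = {p: (schema.relevant_snps(p)[0],) for p in schema.phenotypes}
    sch = pl.default_schema(one_snp)
    tables = {}
    for p in sch.phenotypes:
        m = len(sch.domain(p))
        vec = np.zeros(m)
        vec[0] = 1.0
        tables[(p, sch.relevant_snps(p)[0])] = {"AA": vec}
    model = pl.ConditionalModel(schema=sch, tables=tables, smoothing_alpha=0.0)
    genome = pl.Genome("g0", {rsid: "AA" for rsid in sch.all_snps})
    preds = _delta_predictions(
        "i0", {p: sch.domain(p)[0] for p in sch.phenotypes}, sch
    )
    assert pl.score_pair(preds, genome, model, sch) == 0.0


def test_zero_probability_floored_not_infinite(hand_model):
    sch, model, genome = hand_model
    # brown hair has probability 0.25; blue eye 0.2 -> replace one table with a zero
    model.tables[("sex", sch.relevant_snps("sex")[0])]["AA"] = np.array([0.0, 1.0])
    preds = _delta_predictions(
        "i0", {"sex": "F", "hair": "black", "skin": "pale", "eye": "blue"}, sch
    )
    score = pl.score_pair(preds, genome, model, sch)
    assert np.isfinite(score)
    # exactly the 1e-12 floor in place of the zero factor
    assert score == pytest.approx(math.log(1e-12) + math.log(0.25 * 0.1 * 0.2))
    # strictly below the same score with that factor at 1e-6 instead
    model.tables[("sex", sch.relevant_snps("sex")[0])]["AA"] = np.array([1e-6, 1 - 1e-6])
    assert score < pl.score_pair(preds, genome, model, sch)


def test_build_score_matrix_matches_double_loop(trained_setup):
    spec, model, ensemble, genomes, profiles, images = trained_setup
    preds = [ensemble.predict_distributions(im) for im in images[:5]]
    matrix = pl.build_score_matrix(preds, genomes[:5], model, spec.schema)
    for i, ps in enumerate(preds):
        for j, g in enumerate(genomes[:5]):
            assert matrix.scores[i, j] == pytest.approx(
                pl.score_pair(ps, g, model, spec.schema), abs=1e-9
            )


def test_matrix_column_order_equivariance(trained_setup):
    spec, model, ensemble, genomes, profiles, images = trained_setup
    preds = [ensemble.predict_distributions(im) for im in images[:4]]
    m1 = pl.build_score_matrix(preds, genomes[:4], model, spec.schema)
    perm = [2, 0, 3, 1]
    m2 = pl.build_score_matrix(preds, [genomes[i] for i in perm], model, spec.schema)
    np.testing.assert_allclose(m2.scores, m1.scores[:, perm])


def test_duplicate_ids_rejected(trained_setup):
    spec, model, ensemble, genomes, _, images = trained_setup
    preds = [ensemble.predict_distributions(im) for im in images[:2]]
    with pytest.raises(ValueError, match="duplicate"):
        pl.build_score_matrix(preds, [genomes[0], genomes[0]], model, spec.schema)


def test_matrix_tsv_roundtrip(tmp_path):
    m = ScoreMatrix(["a", "b"], ["x", "y", "z"], np.log(np.random.default_rng(0).random((2, 3))))
    path = tmp_path / "m.tsv"
    m.to_tsv(path)
    back = ScoreMatrix.from_tsv(path)
    np.testing.assert_allclose(back.scores, m.scores)
    assert back.image_ids == m.image_ids and back.genome_ids == m.genome_ids


# -- top-k -------------------------------------------------------------------


def _random_matrix(rng, n_img, n_gen):
    scores = np.log(rng.random((n_img, n_gen)))
    ids = [f"i{k}" for k in range(n_img)]
    gids = [f"g{k}" for k in range(n_gen)]
    truth = {f"i{k}": f"g{k % n_gen}" for k in range(n_img)}
    return ScoreMatrix(ids, gids, scores, truth)


def exhaustive_topk_oracle(matrix, k):
    """Enumerate each row's full ranking explicitly (stable order on ties)."""
    hits = 0
    col = {g: j for j, g in enumerate(matrix.genome_ids)}
    for i, img in enumerate(matrix.image_ids):
        row = matrix.scores[i]
        order = sorted(range(len(row)), key=lambda j: (-row[j], j))
        hits += col[matrix.truth[img]] in order[:k]
    return hits / len(matrix.image_ids)


@pytest.mark.parametrize("k", [1, 2, 4, 8])
def test_topk_agrees_with_exhaustive_ranking_oracle(k):
    rng = np.random.default_rng(42)
    for _ in range(25):
        m = _random_matrix(rng, 8, 8)
        assert pl.top_k_success(m, k) == pytest.approx(exhaustive_topk_oracle(m, k))


def test_topk_with_ties_deterministic_and_expected_modes():
    scores = np.array([[-1.0, -1.0, -2.0]])
    m = ScoreMatrix(["i0"], ["g0", "g1", "g2"], scores, {"i0": "g1"})
    # deterministic order: g0 wins the tie, so truth is rank 2
    assert pl.top_k_success(m, 1) == 0.0
    assert pl.top_k_success(m, 2) == 1.0
    # expected mode: truth is in top-1 with probability 1/2
    assert pl.top_k_success(m, 1, tie_break="expected") == pytest.approx(0.5)


def test_topk_monotone_in_k():
    rng = np.random.default_rng(3)
    m = _random_matrix(rng, 10, 12)
    vals = [pl.top_k_success(m, k) for k in range(1, 13)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    assert vals[-1] == 1.0  # k = N captures everything


def test_topk_k_bounds():
    m = _random_matrix(np.random.default_rng(0), 3, 5)
    with pytest.raises(ValueError):
        pl.top_k_success(m, 0)
    with pytest.raises(ValueError):
        pl.top_k_success(m, 6)


def test_random_scores_match_analytic_rate():
    """Top-1 success on uninformative scores is k/N within Monte Carlo error."""
    rng = np.random.default_rng(2024)
    n_rep, n_gen, n_img = 2000, 20, 5
    succ = np.empty(n_rep)
    for r in range(n_rep):
        succ[r] = pl.top_k_success(_random_matrix(rng, n_img, n_gen), 1)
    se = succ.std(ddof=1) / np.sqrt(n_rep)
    assert abs(succ.mean() - 1 / n_gen) < 3 * se + 1e-12


# -- population sweep --------------------------------------------------------


def test_sweep_size_one_is_certain_success():
    m = _random_matrix(np.random.default_rng(1), 6, 10)
    df = pl.population_sweep(m, [1], k=1, replicates=3, seed=0)
    assert df["value"].iloc[0] == 1.0


def test_sweep_tracks_k_over_s_for_random_scores():
    rng = np.random.default_rng(5)
    m = _random_matrix(rng, 40, 60)
    df = pl.population_sweep(m, [5, 10, 20], k=1, replicates=40, seed=9)
    for _, row in df.iterrows():
        expected = 1.0 / row["population_size"]
        assert abs(row["value"] - expected) < 0.08


def test_sweep_k5_dominates_k1_on_same_subsamples():
    m = _random_matrix(np.random.default_rng(8), 15, 30)
    k1 = pl.population_sweep(m, [10, 20], k=1, replicates=10, seed=4)
    k5 = pl.population_sweep(m, [10, 20], k=5, replicates=10, seed=4)
    assert (k5["value"].to_numpy() >= k1["value"].to_numpy()).all()


def test_sweep_rejects_size_below_k():
    m = _random_matrix(np.random.default_rng(0), 4, 10)
    with pytest.raises(ValueError):
        pl.population_sweep(m, [2], k=3, replicates=2, seed=0)


def test_random_baseline_is_k_over_s():
    df = pl.random_baseline([2, 5, 10], k=2)
    np.testing.assert_allclose(df["value"], [1.0, 0.4, 0.2])


# -- upper bound -------------------------------------------------------------


def test_upper_bound_equals_predicted_when_predictions_are_truth(fitted_cohort):
    spec, genomes, profiles, model = fitted_cohort
    sub_g, sub_p = genomes[:25], profiles[:25]
    preds = pl.simulate_noisy_predictions(sub_p, 0.0, spec.schema, seed=5)
    truth = {pr.individual_id: pr.individual_id for pr in sub_p}
    matrix = pl.build_score_matrix(preds, sub_g, model, spec.schema, truth)
    predicted = pl.population_sweep(matrix, [5, 15, 25], 1, replicates=8, seed=77)
    upper = pl.baseline_upper_bound(
        sub_p, sub_g, model, spec.schema, 1, [5, 15, 25], replicates=8, seed=77
    )
    np.testing.assert_allclose(predicted["value"], upper["value"])


def test_upper_bound_dominates_noisy_predictions_on_average(fitted_cohort):
    spec, genomes, profiles, model = fitted_cohort
    sub_g, sub_p = genomes[:30], profiles[:30]
    diffs = []
    for seed in range(20):
        preds = pl.simulate_noisy_predictions(sub_p, 0.3, spec.schema, seed=seed)
        truth = {pr.individual_id: pr.individual_id for pr in sub_p}
        matrix = pl.build_score_matrix(preds, sub_g, model, spec.schema, truth)
        noisy = pl.top_k_success(matrix, 1)
        upper_matrix = pl.build_score_matrix(
            [pl.PredictionSet.from_profile(pr, spec.schema) for pr in sub_p],
            sub_g, model, spec.schema, truth,
        )
        diffs.append(pl.top_k_success(upper_matrix, 1) - noisy)
    assert np.mean(diffs) >= 0


# -- ROC / AUC ----------------------------------------------------------------


def test_separable_scores_give_auc_one_and_zero():
    n = 6
    scores = np.full((n, n), -10.0)
    np.fill_diagonal(scores, -1.0)
    ids = [f"i{k}" for k in range(n)]
    gids = [f"g{k}" for k in range(n)]
    truth = {f"i{k}": f"g{k}" for k in range(n)}
    m = ScoreMatrix(ids, gids, scores, truth)
    _, auc = roc_and_auc(m, mode="tau")
    assert auc == pytest.approx(1.0)
    # anti-separable: true pair strictly lowest
    m2 = ScoreMatrix(ids, gids, -scores, truth)
    _, auc2 = roc_and_auc(m2, mode="tau")
    assert auc2 == pytest.approx(0.0)


def test_random_scores_auc_near_half():
    rng = np.random.default_rng(99)
    aucs = [roc_and_auc(_random_matrix(rng, 5, 50), mode="tau")[1] for _ in range(200)]
    se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
    assert abs(np.mean(aucs) - 0.5) < 3 * se + 1e-12


def test_tau_mode_auc_matches_sklearn():
    """Independent cross-check of the pooled ROC against scikit-learn."""
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(12)
    for _ in range(10):
        m = _random_matrix(rng, 8, 15)
        labels = np.zeros_like(m.scores, dtype=bool)
        labels[np.arange(8), m.true_column_indices()] = True
        _, auc = roc_and_auc(m, mode="tau")
        assert auc == pytest.approx(roc_auc_score(labels.ravel(), m.scores.ravel()))


def test_k_mode_endpoints():
    m = _random_matrix(np.random.default_rng(4), 6, 9)
    pts, _ = roc_and_auc(m, mode="k")
    np.testing.assert_allclose(pts[0], [0.0, 0.0])
    np.testing.assert_allclose(pts[-1], [1.0, 1.0])
    # monotone nondecreasing in both coordinates
    assert (np.diff(pts[:, 0]) >= -1e-12).all() and (np.diff(pts[:, 1]) >= -1e-12).all()


def test_roc_requires_truth():
    m = ScoreMatrix(["a"], ["x"], np.array([[-1.0]]), truth=None)
    with pytest.raises(ValueError, match="truth"):
        roc_and_auc(m, mode="tau")
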