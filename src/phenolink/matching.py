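"""Image-genome matching scores and re-identification risk evaluation.

The matching score for image i and genome j is the naive-Bayes log-likelihood

    p_ij = sum_p log P(z_{i,p} | y_j)

over the four phenotypes, where z_{i,p} is the classifier's most likely
variant for phenotype p on image i and P(. | y_j) comes from the empirical
conditional tables. Risk is evaluated by top-k matching success as a function
of gallery (population) size, and by ROC/AUC treating each image-genome pair
as a binary match/non-match decision, thresholded either on rank k or on a
score cutoff tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .conditional import ConditionalModel, variant_probs_given_genome
from .genomes import Genome, PhenotypeProfile
from .schema import PhenotypeSchema

#: Tidy risk-report columns; every stochastic row carries its seed and
#: replicate count.
RISK_COLUMNS = [
    "mode",
    "population_size",
    "k_or_tau",
    "epsilon",
    "metric",
    "value",
    "n_replicates",
    "seed",
]


@dataclass
class PredictionSet:
    """Per-image classifier output: a distribution per phenotype plus argmax."""

    image_id: str
    distributions: dict[str, np.ndarray]
    argmax_variants: dict[str, str]

    @classmethod
    def from_distributions(
        cls, image_id: str, distributions: Mapping[str, np.ndarray], schema: PhenotypeSchema
    ) -> "PredictionSet":
        """Build with argmax variants derived from the distributions.

        Ties break toward the earlier variant in domain order.
        """
        dists = {}
        argmax = {}
        for p, vec in distributions.items():
            vec = np.asarray(vec, dtype=float)
            if abs(vec.sum() - 1.0) > 1e-6:
                raise ValueError(f"distribution for {p!r} does not sum to 1")
            dists[p] = vec
            argmax[p] = schema.domain(p)[int(np.argmax(vec))]
        return cls(image_id=image_id, distributions=dists, argmax_variants=argmax)

    @classmethod
    def from_profile(cls, profile: PhenotypeProfile, schema: PhenotypeSchema) -> "PredictionSet":
        """Degenerate prediction set placing all mass on the true variants.

        Used by the true-phenotype upper-bound baseline.
        """
        dists = {}
        argmax = {}
        for p, v in profile.values.items():
            dom = schema.domain(p)
            vec = np.zeros(len(dom))
            vec[schema.variant_index(p, v)] = 1.0
            dists[p] = vec
            argmax[p] = v
        return cls(image_id=profile.individual_id, distributions=dists, argmax_variants=argmax)


@dataclass
class ScoreMatrix:
    """Dense image x genome log-likelihood scores, with optional truth map."""

    image_ids: list[str]
    genome_ids: list[str]
    scores: np.ndarray
    truth: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.image_ids), len(self.genome_ids)):
            raise ValueError("score matrix shape does not match id lists")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        for ids, label in ((self.image_ids, "image"), (self.genome_ids, "genome")):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {label} ids")
        if self.truth is not None:
            gset = set(self.genome_ids)
            for img, gen in self.truth.items():
                if gen not in gset:
                    raise ValueError(f"truth genome {gen!r} for image {img!r} not in matrix")

    def true_column_indices(self) -> np.ndarray:
        """Index of each image's true genome column (images without truth error)."""
        if self.truth is None:
            raise ValueError("score matrix has no truth mapping")
        col = {g: j for j, g in enumerate(self.genome_ids)}
        return np.array([col[self.truth[i]] for i in self.image_ids], dtype=int)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.scores, index=self.image_ids, columns=self.genome_ids)
        df.index.name = "image_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, truth: dict[str, str] | None = None) -> "ScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(), truth)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def genome_log_tables(
    genomes: Sequence[Genome], model: ConditionalModel, schema: PhenotypeSchema
) -> dict[str, np.ndarray]:
    """Per-phenotype matrix of floored log P(v | y_j): shape (n_genomes, |domain|)."""
    out = {}
    for p in schema.phenotypes:
        rows = [variant_probs_given_genome(p, g, model, schema) for g in genomes]
        probs = np.clip(np.asarray(rows), model.prob_floor, None)
        out[p] = np.log(probs)
    return out


def score_pair(
    predictions: PredictionSet,
    genome: Genome,
    model: ConditionalModel,
    schema: PhenotypeSchema,
) -> float:
    """Log-likelihood matching score: sum over phenotypes of log P(z_p | y).

    Each factor is floored at ``model.prob_floor`` before the log so zero-count
    tables (alpha = 0) still yield a finite, strongly negative score.
    """
    total = 0.0
    for p in schema.phenotypes:
        if p not in predictions.argmax_variants:
            raise ValueError(f"predictions for image {predictions.image_id!r} lack {p!r}")
        probs = variant_probs_given_genome(p, genome, model, schema)
        prob = probs[schema.variant_index(p, predictions.argmax_variants[p])]
        total += float(np.log(max(prob, model.prob_floor)))
    return total


def build_score_matrix(
    predictions: Sequence[PredictionSet],
    genomes: Sequence[Genome],
    model: ConditionalModel,
    schema: PhenotypeSchema,
    truth: dict[str, str] | None = None,
) -> ScoreMatrix:
    """Score every image-genome pair. Deterministic given inputs."""
    if not predictions or not genomes:
        raise ValueError("predictions and genomes must be non-empty")
    image_ids = [ps.image_id for ps in predictions]
    genome_ids = [g.individual_id for g in genomes]
    logs = genome_log_tables(genomes, model, schema)  # (N, m) per phenotype
    scores = np.zeros((len(predictions), len(genomes)))
    for p in schema.phenotypes:
        zidx = np.array(
            [schema.variant_index(p, ps.argmax_variants[p]) for ps in predictions]
        )
        scores += logs[p][:, zidx].T  # (I, N)
    return ScoreMatrix(image_ids, genome_ids, scores, truth)


def truth_from_pairs(predictions: Sequence[PredictionSet], genomes: Sequence[Genome]) -> dict[str, str]:
    """Identity truth map for cohorts where image i belongs to genome i."""
    return {ps.image_id: g.individual_id for ps, g in zip(predictions, genomes)}


# ---------------------------------------------------------------------------
# Top-k success and population sweeps
# ---------------------------------------------------------------------------

def _true_ranks(scores: np.ndarray, true_cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per image: (#strictly better columns, #tied columns excluding truth)."""
    true_scores = scores[np.arange(len(true_cols)), true_cols]
    better = (scores > true_scores[:, None]).sum(axis=1)
    tied = (scores == true_scores[:, None]).sum(axis=1) - 1
    return better, tied


def top_k_success(
    matrix: ScoreMatrix,
    k: int,
    tie_break: Literal["order", "expected"] = "order",
) -> float:
    """Fraction of images whose true genome scores among the k largest in row.

    ``tie_break="order"``: among equal scores the earlier genome in matrix
    order wins (deterministic). ``"expected"``: report the expected success
    fraction under uniformly random tie ordering.
    """
    n = len(matrix.genome_ids)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    true_cols = matrix.true_column_indices()
    if tie_break == "order":
        succ = _topk_order_success(matrix.scores, true_cols, k)
        return float(np.mean(succ))
    better, tied = _true_ranks(matrix.scores, true_cols)
    # truth lands uniformly among its tie group of size tied+1
    slots = np.clip(k - better, 0, tied + 1)
    return float(np.mean(slots / (tied + 1)))


def _topk_order_success(scores: np.ndarray, true_cols: np.ndarray, k: int) -> np.ndarray:
    rows = np.arange(scores.shape[0])
    true_scores = scores[rows, true_cols]
    better = (scores > true_scores[:, None]).sum(axis=1)
    tied_before = (
        (scores == true_scores[:, None]) & (np.arange(scores.shape[1])[None, :] < true_cols[:, None])
    ).sum(axis=1)
    return (better + tied_before) < k


def population_sweep(
    matrix: ScoreMatrix,
    sizes: Sequence[int],
    k: int,
    replicates: int,
    seed: int,
    mode_label: str = "predicted",
) -> pd.DataFrame:
    """Top-k success vs gallery size, by seeded subsampling.

    For each size s and each probe image, a gallery of s genomes is drawn:
    the image's true genome plus s-1 others sampled uniformly without
    replacement (a match is assumed to exist in the gallery). Success is
    recomputed within the subsample; means over images and replicates are
    reported with replicate counts. Galleries are resampled independently per
    size.
    """
    n = len(matrix.genome_ids)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    true_cols = matrix.true_column_indices()
    rows_out = []
    for size in sizes:
        if size > n:
            raise ValueError(f"population size {size} exceeds {n} genomes")
        if size < k:
            raise ValueError(f"population size {size} smaller than k={k}")
        rep_means = np.empty(replicates)
        for r in range(replicates):
            successes = np.empty(len(matrix.image_ids), dtype=bool)
            for i, t in enumerate(true_cols):
                others = np.delete(np.arange(n), t)
                gallery = np.concatenate(
                    [[t], rng.choice(others, size=size - 1, replace=False)]
                ) if size > 1 else np.array([t])
                gallery.sort()  # keep original genome order for tie-breaks
                sub = matrix.scores[i, gallery][None, :]
                t_sub = np.array([int(np.searchsorted(gallery, t))])
                successes[i] = _topk_order_success(sub, t_sub, k)[0]
            rep_means[r] = successes.mean()
        rows_out.append(
            {
                "mode": mode_label,
                "population_size": size,
                "k_or_tau": k,
                "epsilon": np.nan,
                "metric": "topk_success",
                "value": float(rep_means.mean()),
                "n_replicates": replicates,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows_out, columns=RISK_COLUMNS)


def random_baseline(sizes: Sequence[int], k: int) -> pd.DataFrame:
    """Analytic random-matching lower bound: success = k / s."""
    rows = [
        {
            "mode": "random_lower_bound",
            "population_size": s,
            "k_or_tau": k,
            "epsilon": np.nan,
            "metric": "topk_success",
            "value": min(1.0, k / s),
            "n_replicates": 0,
            "seed": -1,
        }
        for s in sizes
    ]
    return pd.DataFrame(rows, columns=RISK_COLUMNS)


def baseline_upper_bound(
    truth_phenotypes: Sequence[PhenotypeProfile],
    genomes: Sequence[Genome],
    model: ConditionalModel,
    schema: PhenotypeSchema,
    k: int,
    sizes: Sequence[int],
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """True-phenotype upper bound: score with ground-truth variants as z_{i,p}."""
    predictions = [PredictionSet.from_profile(pr, schema) for pr in truth_phenotypes]
    truth = {pr.individual_id: pr.individual_id for pr in truth_phenotypes}
    matrix = build_score_matrix(predictions, genomes, model, schema, truth)
    return population_sweep(matrix, sizes, k, replicates, seed, mode_label="true_phenotype_upper_bound")


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_and_auc(
    matrix: ScoreMatrix,
    mode: Literal["k", "tau"] = "tau",
    macro_average: bool = False,
) -> tuple[np.ndarray, float]:
    """ROC points and AUC over pooled image-genome pairs.

    Positives are the true pairs. Mode "tau" predicts a match when the score
    is >= a cutoff, swept over all distinct scores; mode "k" predicts the
    image's top-k genomes as matches, swept over k = 0..N. AUC is trapezoidal
    over the sorted ROC points. ``macro_average`` (mode "tau" only) averages
    per-image AUCs instead of pooling.
    """
    true_cols = matrix.true_column_indices()
    scores = matrix.scores
    n_img, n_gen = scores.shape
    if mode == "tau":
        if macro_average:
            aucs = []
            for i in range(n_img):
                labels = np.zeros(n_gen, dtype=bool)
                labels[true_cols[i]] = True
                pts, auc = _roc_from_scores(scores[i], labels)
                aucs.append(auc)
            labels = np.zeros_like(scores, dtype=bool)
            labels[np.arange(n_img), true_cols] = True
            pts, _ = _roc_from_scores(scores.ravel(), labels.ravel())
            return pts, float(np.mean(aucs))
        labels = np.zeros_like(scores, dtype=bool)
        labels[np.arange(n_img), true_cols] = True
        return _roc_from_scores(scores.ravel(), labels.ravel())
    if mode == "k":
        pts = [(0.0, 0.0)]  # k = 0 anchor
        n_pos = n_img
        n_neg = n_img * (n_gen - 1)
        for k in range(1, n_gen + 1):
            tp = int(_topk_order_success(scores, true_cols, k).sum())
            fp = k * n_img - tp
            pts.append((fp / n_neg, tp / n_pos))
        pts_arr = np.array(pts)
        auc = float(np.trapezoid(pts_arr[:, 1], pts_arr[:, 0]))
        return pts_arr, auc
    raise ValueError(f"unknown ROC mode {mode!r}")


def _roc_from_scores(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC by sweeping the cutoff over distinct scores (predict >= cutoff)."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(float)
    tps = np.cumsum(y)
    fps = np.cumsum(1.0 - y)
    # collapse ties: keep the last point of each distinct-score block
    distinct = np.r_[s[1:] != s[:-1], True]
    tps, fps = tps[distinct], fps[distinct]
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    tpr = np.r_[0.0, tps / max(n_pos, 1)]
    fpr = np.r_[0.0, fps / max(n_neg, 1)]
    pts = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return pts, auc


def roc_report(matrix: ScoreMatrix, seed: int = -1) -> pd.DataFrame:
    """Tidy rows for both ROC modes' AUCs."""
    rows = []
    for mode in ("tau", "k"):
        _, auc = roc_and_auc(matrix, mode=mode)
        rows.append(
            {
                "mode": f"roc_{mode}",
                "population_size": len(matrix.genome_ids),
                "k_or_tau": np.nan,
                "epsilon": np.nan,
                "metric": "auc",
                "value": auc,
                "n_replicates": 1,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows, columns=RISK_COLUMNS)
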