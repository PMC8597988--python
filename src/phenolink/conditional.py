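"""Empirical phenotype-given-genotype conditional tables.

The linkage score rests on ``P(v_p | y_j)``: the probability of observing
phenotype variant ``v_p`` given genome ``y_j``, expressed as a product of
per-SNP conditionals over the phenotype's relevant SNPs,

    P(v | y) = prod_{s in snps(p)} P(v | genotype of y at s).

Each per-SNP conditional is estimated empirically from a fitting cohort by
counting, with additive (Laplace) smoothing ``alpha`` so that unseen
(genotype, variant) cells do not produce log(0) downstream. Genotypes never
observed during fitting are served the uniform distribution over the domain.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .genomes import Genome, PhenotypeProfile, align_cohort
from .schema import PhenotypeSchema

#: Probability floor applied only at log-conversion time, never to stored tables.
PROB_FLOOR = 1e-12


@dataclass
class ConditionalModel:
    """Per-(phenotype, SNP, genotype) conditional distributions over variants.

    ``tables[(phenotype, rsid)][genotype]`` is a probability vector over the
    phenotype's variant domain, in domain order.
    """

    schema: PhenotypeSchema
    tables: dict[tuple[str, str], dict[str, np.ndarray]]
    smoothing_alpha: float = 1.0
    prob_floor: float = PROB_FLOOR
    #: how a relevant SNP missing from a genome contributes: "skip" (neutral 1)
    #: or "uniform" (factor 1/|domain|).
    missing_policy: Literal["skip", "uniform"] = "skip"

    def __post_init__(self) -> None:
        for (p, rsid), by_geno in self.tables.items():
            m = len(self.schema.domain(p))
            for g, vec in by_geno.items():
                vec = np.asarray(vec, dtype=float)
                by_geno[g] = vec
                if vec.shape != (m,):
                    raise ValueError(f"table ({p},{rsid},{g}) has wrong length")
                if abs(vec.sum() - 1.0) > 1e-9:
                    raise ValueError(f"table ({p},{rsid},{g}) does not sum to 1")

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        payload = {
            "smoothing_alpha": self.smoothing_alpha,
            "prob_floor": self.prob_floor,
            "missing_policy": self.missing_policy,
            "schema": {
                "phenotypes": list(self.schema.phenotypes),
                "variant_domain": {p: list(v) for p, v in self.schema.variant_domain.items()},
                "snp_map": {p: list(v) for p, v in self.schema.snp_map.items()},
            },
            "tables": {
                f"{p}|{rsid}": {g: [float(x) for x in vec] for g, vec in by_geno.items()}
                for (p, rsid), by_geno in self.tables.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "ConditionalModel":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        schema = PhenotypeSchema(
            phenotypes=tuple(payload["schema"]["phenotypes"]),
            variant_domain={p: tuple(v) for p, v in payload["schema"]["variant_domain"].items()},
            snp_map={p: tuple(v) for p, v in payload["schema"]["snp_map"].items()},
        )
        tables = {}
        for key, by_geno in payload["tables"].items():
            p, rsid = key.split("|", 1)
            tables[(p, rsid)] = {g: np.asarray(vec) for g, vec in by_geno.items()}
        return cls(
            schema=schema,
            tables=tables,
            smoothing_alpha=payload["smoothing_alpha"],
            prob_floor=payload["prob_floor"],
            missing_policy=payload["missing_policy"],
        )

    def lookup(self, phenotype: str, rsid: str, genotype: str) -> np.ndarray:
        """Conditional distribution over variants; uniform for unseen genotypes."""
        by_geno = self.tables.get((phenotype, rsid))
        m = len(self.schema.domain(phenotype))
        if by_geno is None or genotype not in by_geno:
            return np.full(m, 1.0 / m)
        return by_geno[genotype]


def fit_conditional_tables(
    cohort_genomes: Sequence[Genome],
    cohort_phenotypes: Sequence[PhenotypeProfile],
    schema: PhenotypeSchema,
    smoothing_alpha: float = 1.0,
    missing_policy: Literal["skip", "uniform"] = "skip",
) -> ConditionalModel:
    """Estimate per-SNP conditionals by smoothed empirical counting.

    For each (phenotype, rsID, observed genotype g), the entry for variant v is

        (count(v, g) + alpha) / (count(g) + alpha * |domain|).

    Missing genotypes are not counted. Raises on an empty cohort or on
    individuals present in only one of the two lists.
    """
    if smoothing_alpha < 0:
        raise ValueError("smoothing_alpha must be nonnegative")
    genomes, profiles = align_cohort(list(cohort_genomes), list(cohort_phenotypes))
    for pr in profiles:
        pr.validate(schema)

    tables: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for p in schema.phenotypes:
        dom = schema.domain(p)
        m = len(dom)
        vidx = {v: i for i, v in enumerate(dom)}
        for rsid in schema.relevant_snps(p):
            counts: dict[str, np.ndarray] = {}
            for genome, profile in zip(genomes, profiles):
                g = genome.genotype_at(rsid)
                if g is None or p not in profile.values:
                    continue
                counts.setdefault(g, np.zeros(m))[vidx[profile.values[p]]] += 1
            by_geno = {}
            for g, cvec in counts.items():
                denom = cvec.sum() + smoothing_alpha * m
                if denom == 0:
                    continue  # alpha=0 with zero counts cannot happen (g was observed)
                by_geno[g] = (cvec + smoothing_alpha) / denom
            tables[(p, rsid)] = by_geno
    return ConditionalModel(
        schema=schema,
        tables=tables,
        smoothing_alpha=smoothing_alpha,
        missing_policy=missing_policy,
    )


def phenotype_prob_given_genome(
    variant: str,
    phenotype: str,
    genome: Genome,
    model: ConditionalModel,
    schema: PhenotypeSchema,
) -> float:
    """``P(variant | genome)`` as a product over the phenotype's relevant SNPs.

    SNPs missing from the genome contribute a neutral factor of 1 under the
    default "skip" policy (or 1/|domain| under "uniform"). Raises if the
    phenotype has no relevant SNPs configured.
    """
    return float(variant_probs_given_genome(phenotype, genome, model, schema)[
        schema.variant_index(phenotype, variant)
    ])


def variant_probs_given_genome(
    phenotype: str,
    genome: Genome,
    model: ConditionalModel,
    schema: PhenotypeSchema,
) -> np.ndarray:
    """Vector of ``P(v | genome)`` over the phenotype's whole variant domain.

    Raw per-SNP products; not renormalized across variants (the matching score
    uses raw products). See :func:`normalized_variant_probs` for diagnostics.
    """
    snps = schema.relevant_snps(phenotype)
    if not snps:
        raise ValueError(f"phenotype {phenotype!r} has no relevant SNPs configured")
    m = len(schema.domain(phenotype))
    out = np.ones(m)
    for rsid in snps:
        g = genome.genotype_at(rsid)
        if g is None:
            if model.missing_policy == "uniform":
                out *= 1.0 / m
            continue  # "skip": neutral factor
        out *= model.lookup(phenotype, rsid, g)
    return out


def normalized_variant_probs(
    phenotype: str,
    genome: Genome,
    model: ConditionalModel,
    schema: PhenotypeSchema,
) -> np.ndarray:
    """Diagnostic only: the raw product renormalized to sum to 1."""
    raw = variant_probs_given_genome(phenotype, genome, model, schema)
    total = raw.sum()
    if total <= 0:
        return np.full_like(raw, 1.0 / len(raw))
    return raw / total
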