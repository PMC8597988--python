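"""Synthetic genotype-phenotype-image cohorts with known generating laws.

The real curated image-genome pairs behind this line of work are not
publicly releasable, so experiments run on fully synthetic cohorts whose
generating distributions are known exactly:

* genotypes are sampled per SNP under Hardy-Weinberg equilibrium from
  configurable alt-allele frequencies;
* each phenotype is sampled from its per-SNP conditional tables combined by
  the same product rule the matching scorer assumes (then renormalized), so
  fitted tables have a well-defined target (see
  :func:`implied_variant_tables`); a misspecified "vote" mode exists for
  robustness experiments;
* images deterministically encode phenotypes as colored regions (hair band,
  skin field, eye patches, a brightness cue for sex) plus seeded Gaussian
  pixel noise — a rule-based decoder recovers phenotypes exactly at zero
  noise;
* a direct noisy-prediction simulator bypasses images entirely for fast
  matching experiments with a configurable classifier error rate.

Both genotype-assignment constructions used for synthetic image-genome
pairing are provided: *ideal* (most-representative genome for a phenotype
profile) and *realistic* (random draw among phenotype-matching genomes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from ._rng import substream
from .conditional import ConditionalModel, variant_probs_given_genome
from .genomes import Genome, PhenotypeProfile, canonical_genotype
from .images import ImageTensor
from .matching import PredictionSet
from .schema import PhenotypeSchema, default_schema


@dataclass
class GeneratorSpec:
    """Full description of a synthetic cohort's generating process."""

    n_individuals: int
    schema: PhenotypeSchema
    alleles: dict[str, tuple[str, str]]  # rsid -> (ref, alt)
    allele_freqs: dict[str, float]  # rsid -> alt-allele frequency
    #: (phenotype, rsid) -> genotype -> distribution over the variant domain
    generating_tables: dict[tuple[str, str], dict[str, np.ndarray]]
    seed: int
    image_size: int = 32
    render_noise_sd: float = 0.05
    confusion_level: float = 0.1
    combine: Literal["product", "vote"] = "product"

    def __post_init__(self) -> None:
        for rsid, f in self.allele_freqs.items():
            if not (0.0 < f < 1.0):
                raise ValueError(f"allele frequency for {rsid} must be in (0,1), got {f}")
        for (p, rsid), by_geno in self.generating_tables.items():
            m = len(self.schema.domain(p))
            for g, vec in by_geno.items():
                vec = np.asarray(vec, dtype=float)
                by_geno[g] = vec
                if vec.shape != (m,) or abs(vec.sum() - 1.0) > 1e-9:
                    raise ValueError(f"generating table ({p},{rsid},{g}) invalid")

    def genotype_strings(self, rsid: str) -> tuple[str, str, str]:
        """Canonical genotypes for 0, 1, 2 copies of the alt allele."""
        ref, alt = self.alleles[rsid]
        return (
            canonical_genotype(ref + ref),
            canonical_genotype(ref + alt),
            canonical_genotype(alt + alt),
        )


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
_ALT_FREQS = [0.4, 0.5, 0.6]
_HOMOZYGOTE_PEAKS = [0.85, 0.8, 0.75, 0.7]


def default_generator_spec(
    n_individuals: int,
    seed: int,
    schema: PhenotypeSchema | None = None,
    image_size: int = 32,
    render_noise_sd: float = 0.05,
    confusion_level: float = 0.1,
) -> GeneratorSpec:
    """Standard synthetic study conditions.

    All SNPs of a trait act along the same axis, the way real pigmentation
    variants do (additive effects along a light/dark continuum rather than
    each SNP pointing at an unrelated category): the reference homozygote
    favors the first variant of the domain, the alternate homozygote the
    last, with 0.7-0.85 penetrance (known eye-color SNPs reach and exceed
    this), and heterozygotes lean moderately (0.55-0.6) toward the middle
    variant (toward the second for two-variant traits). Alt-allele
    frequencies cycle through 0.4 / 0.5 / 0.6 — common variants, so all
    three genotype classes are well represented in moderate cohorts.
    """
    schema = schema or default_schema()
    alleles: dict[str, tuple[str, str]] = {}
    freqs: dict[str, float] = {}
    tables: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    snp_counter = 0
    for p in schema.phenotypes:
        dom = schema.domain(p)
        m = len(dom)
        for t, rsid in enumerate(schema.relevant_snps(p)):
            if rsid not in alleles:
                alleles[rsid] = _ALLELE_PAIRS[snp_counter % len(_ALLELE_PAIRS)]
                freqs[rsid] = _ALT_FREQS[snp_counter % len(_ALT_FREQS)]
                snp_counter += 1
            ref, alt = alleles[rsid]
            g0, g1, g2 = (
                canonical_genotype(ref + ref),
                canonical_genotype(ref + alt),
                canonical_genotype(alt + alt),
            )
            def peaked(idx: int, w: float) -> np.ndarray:
                vec = np.full(m, (1.0 - w) / (m - 1))
                vec[idx] = w
                return vec
            w_homo = _HOMOZYGOTE_PEAKS[t % len(_HOMOZYGOTE_PEAKS)]
            tables[(p, rsid)] = {
                g0: peaked(0, w_homo),
                g1: peaked(m // 2, 0.55 if m > 2 else 0.6),
                g2: peaked(m - 1, w_homo),
            }
    return GeneratorSpec(
        n_individuals=n_individuals,
        schema=schema,
        alleles=alleles,
        allele_freqs=freqs,
        generating_tables=tables,
        seed=seed,
        image_size=image_size,
        render_noise_sd=render_noise_sd,
        confusion_level=confusion_level,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: GeneratorSpec) -> tuple[list[Genome], list[PhenotypeProfile]]:
    """Sample a cohort: HWE genotypes, then phenotypes from the combined tables.

    Pure function of the spec (all randomness flows from ``spec.seed``).
    """
    rng = substream(spec.seed, "cohort")
    schema = spec.schema
    n = spec.n_individuals
    snps = schema.all_snps
    # alt-allele dosage per (individual, snp)
    dosage = {
        rsid: rng.binomial(2, spec.allele_freqs[rsid], size=n) for rsid in snps
    }
    geno_strings = {rsid: spec.genotype_strings(rsid) for rsid in snps}
    ids = [f"ind{i:05d}" for i in range(n)]
    genomes = [
        Genome(ids[i], {rsid: geno_strings[rsid][dosage[rsid][i]] for rsid in snps})
        for i in range(n)
    ]
    profiles = []
    sampled: dict[str, np.ndarray] = {}
    for p in schema.phenotypes:
        dom = schema.domain(p)
        m = len(dom)
        rel = schema.relevant_snps(p)
        if spec.combine == "product":
            weights = np.ones((n, m))
            for rsid in rel:
                table = np.stack([spec.generating_tables[(p, rsid)][g]
                                  for g in geno_strings[rsid]])  # (3, m)
                weights *= table[dosage[rsid]]
            weights /= weights.sum(axis=1, keepdims=True)
        else:  # "vote": one relevant SNP, drawn uniformly, decides
            pick = rng.integers(len(rel), size=n)
            weights = np.empty((n, m))
            for s_idx, rsid in enumerate(rel):
                table = np.stack([spec.generating_tables[(p, rsid)][g]
                                  for g in geno_strings[rsid]])
                sel = pick == s_idx
                weights[sel] = table[dosage[rsid][sel]]
        u = rng.random(n)
        sampled[p] = (weights.cumsum(axis=1) > u[:, None]).argmax(axis=1)
    for i in range(n):
        profiles.append(
            PhenotypeProfile(
                ids[i],
                {p: schema.domain(p)[sampled[p][i]] for p in schema.phenotypes},
            )
        )
    return genomes, profiles


def implied_variant_tables(spec: GeneratorSpec) -> dict[tuple[str, str], dict[str, np.ndarray]]:
    """Exact per-SNP conditionals P(variant | genotype at that SNP) implied
    by the generator.

    With several SNPs per phenotype combined by a renormalized product, the
    marginal conditional at one SNP is not the raw generating row: the other
    SNPs' genotypes are integrated out under Hardy-Weinberg weights. This
    enumerates all genotype combinations exactly (panels are small) and is
    the correct convergence target for empirically fitted tables. For a
    single-SNP phenotype it reduces to the generating table itself.
    """
    schema = spec.schema
    out: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for p in schema.phenotypes:
        rel = schema.relevant_snps(p)
        m = len(schema.domain(p))
        hwe = {}
        for rsid in rel:
            f = spec.allele_freqs[rsid]
            hwe[rsid] = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        tables = {
            rsid: np.stack([spec.generating_tables[(p, rsid)][g]
                            for g in spec.genotype_strings(rsid)])
            for rsid in rel
        }
        # joint accumulation: P(dosage combo) * P(v | combo)
        acc: dict[str, dict[int, np.ndarray]] = {rsid: {d: np.zeros(m) for d in range(3)} for rsid in rel}
        marg: dict[str, dict[int, float]] = {rsid: {d: 0.0 for d in range(3)} for rsid in rel}
        for combo in itertools.product(range(3), repeat=len(rel)):
            prob = float(np.prod([hwe[rsid][d] for rsid, d in zip(rel, combo)]))
            if spec.combine == "product":
                w = np.ones(m)
                for rsid, d in zip(rel, combo):
                    w = w * tables[rsid][d]
                w = w / w.sum()
            else:  # vote: uniform mixture over relevant SNPs' rows
                w = np.mean([tables[rsid][d] for rsid, d in zip(rel, combo)], axis=0)
            for rsid, d in zip(rel, combo):
                acc[rsid][d] += prob * w
                marg[rsid][d] += prob
        for rsid in rel:
            gs = spec.genotype_strings(rsid)
            out[(p, rsid)] = {
                gs[d]: acc[rsid][d] / marg[rsid][d] for d in range(3)
            }
    return out


# ---------------------------------------------------------------------------
# Genotype assignment (synthetic image-genome pairing)
# ---------------------------------------------------------------------------

def _matching_pool(
    profile: PhenotypeProfile,
    pool_genomes: Sequence[Genome],
    pool_profiles: Sequence[PhenotypeProfile],
) -> list[Genome]:
    matches = [
        g
        for g, pr in zip(pool_genomes, pool_profiles)
        if all(pr.values.get(p) == v for p, v in profile.values.items())
    ]
    if not matches:
        raise ValueError(
            f"no genome in pool matches phenotypes of {profile.individual_id!r}"
        )
    return matches


def assign_genotype_ideal(
    profile: PhenotypeProfile,
    pool_genomes: Sequence[Genome],
    pool_profiles: Sequence[PhenotypeProfile],
    model: ConditionalModel,
    schema: PhenotypeSchema,
) -> Genome:
    """Most-representative genome: among phenotype-matching pool genomes,
    maximize the product over phenotypes of P(profile's variant | genome).

    Ties break deterministically toward the smallest individual_id.
    """
    matches = _matching_pool(profile, pool_genomes, pool_profiles)
    def product_likelihood(g: Genome) -> float:
        total = 1.0
        for p, v in profile.values.items():
            total *= variant_probs_given_genome(p, g, model, schema)[
                schema.variant_index(p, v)
            ]
        return total
    return max(matches, key=lambda g: (product_likelihood(g), g.individual_id))


def assign_genotype_realistic(
    profile: PhenotypeProfile,
    pool_genomes: Sequence[Genome],
    pool_profiles: Sequence[PhenotypeProfile],
    seed: int,
) -> Genome:
    """Random draw among phenotype-matching pool genomes (seeded, uniform)."""
    matches = _matching_pool(profile, pool_genomes, pool_profiles)
    rng = np.random.default_rng(seed)
    return matches[int(rng.integers(len(matches)))]


# ---------------------------------------------------------------------------
# Image rendering and decoding
# ---------------------------------------------------------------------------

#: Per-pixel encoding strength of a variant within its region. Kept small so
#: the phenotype signal is weak per pixel but strong in aggregate over a
#: region of hundreds of pixels — the regime of real face photographs, where
#: per-pixel trait evidence is faint and classifiers integrate over many
#: pixels. This is what makes small (imperceptible-scale) l-infinity
#: perturbations a meaningful threat: a perturbation comparable to the
#: per-pixel signal can flip predictions while staying visually negligible.
ENCODING_STRENGTH = 0.05

_BASE_GRAY = 0.5

#: Channel-offset patterns distinguishing up to three variants of a trait.
_OFFSET_PATTERNS_3 = [(+1.0, 0.0, -1.0), (-1.0, +1.0, 0.0), (0.0, -1.0, +1.0)]
_OFFSET_PATTERNS_2 = [(+1.0, +1.0, +1.0), (-1.0, -1.0, -1.0)]


def _variant_colors(schema: PhenotypeSchema) -> dict[str, dict[str, np.ndarray]]:
    """Prototype RGB color of each variant: mid-gray plus a small offset."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for p in schema.phenotypes:
        dom = schema.domain(p)
        patterns = _OFFSET_PATTERNS_2 if len(dom) == 2 else _OFFSET_PATTERNS_3
        out[p] = {
            v: _BASE_GRAY + ENCODING_STRENGTH * np.array(patterns[i % len(patterns)])
            for i, v in enumerate(dom)
        }
    return out


def _regions(size: int) -> dict[str, tuple[slice, slice]]:
    """Pixel regions (row slice, col slice) per phenotype cue."""
    q = size // 4
    e = max(size // 8, 2)
    eye_r = slice(size // 3, size // 3 + e)
    return {
        "hair": (slice(0, q), slice(0, size)),
        "sex": (slice(size - e, size), slice(0, size)),
        "eye_left": (eye_r, slice(q, q + e)),
        "eye_right": (eye_r, slice(size - q - e, size - q)),
        "skin": (slice(q, size - e), slice(0, size)),
    }


def render_images(
    profiles: Sequence[PhenotypeProfile], spec: GeneratorSpec
) -> list[ImageTensor]:
    """Deterministic phenotype-encoding layout plus seeded Gaussian noise.

    Skin fills the midfield, hair the top band, two eye patches sit on the
    skin, and the bottom band is a brightness cue for sex. Noise is clipped
    back to [0, 1]. At zero noise, identical phenotype profiles give
    identical images.
    """
    size = spec.image_size
    reg = _regions(size)
    colors = _variant_colors(spec.schema)
    rng = substream(spec.seed, "render")
    out = []
    for profile in profiles:
        img = np.full((size, size, 3), _BASE_GRAY)
        img[reg["skin"][0], reg["skin"][1]] = colors["skin"][profile.values["skin"]]
        img[reg["hair"][0], reg["hair"][1]] = colors["hair"][profile.values["hair"]]
        eye_color = colors["eye"][profile.values["eye"]]
        img[reg["eye_left"][0], reg["eye_left"][1]] = eye_color
        img[reg["eye_right"][0], reg["eye_right"][1]] = eye_color
        img[reg["sex"][0], reg["sex"][1]] = colors["sex"][profile.values["sex"]]
        if spec.render_noise_sd > 0:
            img = img + rng.normal(0.0, spec.render_noise_sd, size=img.shape)
        out.append(ImageTensor(np.clip(img, 0.0, 1.0), profile.individual_id))
    return out


def decode_image(image: ImageTensor, schema: PhenotypeSchema) -> PhenotypeProfile:
    """Rule-based (non-learned) decoder: nearest prototype color per region.

    Serves as an oracle for the rendering contract — exact at zero noise.
    """
    size = image.shape[0]
    reg = _regions(size)
    colors = _variant_colors(schema)
    means = {
        "hair": image.pixels[reg["hair"][0], reg["hair"][1]].mean(axis=(0, 1)),
        "sex": image.pixels[reg["sex"][0], reg["sex"][1]].mean(axis=(0, 1)),
        "eye": (
            image.pixels[reg["eye_left"][0], reg["eye_left"][1]].mean(axis=(0, 1))
            + image.pixels[reg["eye_right"][0], reg["eye_right"][1]].mean(axis=(0, 1))
        )
        / 2,
        "skin": image.pixels[reg["skin"][0], slice(0, size // 8)].mean(axis=(0, 1)),
    }
    values = {}
    for p in schema.phenotypes:
        protos = colors[p]
        values[p] = min(
            schema.domain(p),
            key=lambda v: float(np.sum((means[p] - protos[v]) ** 2)),
        )
    return PhenotypeProfile(image.image_id, values)


# ---------------------------------------------------------------------------
# Direct noisy-prediction simulation (image-free matching experiments)
# ---------------------------------------------------------------------------

def simulate_noisy_predictions(
    profiles: Sequence[PhenotypeProfile],
    confusion_level: float,
    schema: PhenotypeSchema,
    seed: int,
    peak: float = 0.8,
) -> list[PredictionSet]:
    """Classifier-error simulator bypassing images.

    Per phenotype, the argmax variant equals the truth with probability
    ``1 - confusion_level``, otherwise a uniformly chosen wrong variant; the
    emitted distribution places ``peak`` mass on the argmax and spreads the
    rest evenly. Lets matching experiments dial prediction error directly
    (e.g. a hard trait like eye color).
    """
    if not (0.0 <= confusion_level <= 1.0):
        raise ValueError("confusion_level must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for profile in profiles:
        dists = {}
        for p in schema.phenotypes:
            dom = schema.domain(p)
            m = len(dom)
            true_idx = schema.variant_index(p, profile.values[p])
            if rng.random() < confusion_level and m > 1:
                wrong = [i for i in range(m) if i != true_idx]
                arg_idx = wrong[int(rng.integers(len(wrong)))]
            else:
                arg_idx = true_idx
            vec = np.full(m, (1.0 - peak) / (m - 1) if m > 1 else 0.0)
            vec[arg_idx] = peak if m > 1 else 1.0
            dists[p] = vec
        out.append(PredictionSet.from_distributions(profile.individual_id, dists, schema))
    return out
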