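import dataclasses

import numpy as np
import pytest

import phenolink as pl
from phenolink.schema import PhenotypeSchema


@pytest.fixture(scope="session")
def schema():
    return pl.default_schema()


@pytest.fixture(scope="session")
def toy_schema():
    """One phenotype, one SNP: the smallest scorable configuration."""
    return PhenotypeSchema(
        phenotypes=("eye",),
        variant_domain={"eye": ("blue", "brown", "intermediate")},
        snp_map={"eye": ("rs1",)},
    )


@pytest.fixture(scope="session")
def fitted_cohort():
    """A moderate synthetic cohort with its fitted conditional model."""
    spec = pl.default_generator_spec(400, seed=11)
    genomes, profiles = pl.generate_cohort(spec)
    model = pl.fit_conditional_tables(genomes, profiles, spec.schema)
    return spec, genomes, profiles, model


@pytest.fixture(scope="session")
def trained_setup(fitted_cohort):
    """Fitted model plus a trained ensemble and a 30-pair evaluation cohort."""
    spec, _, _, model = fitted_cohort
    train_spec = dataclasses.replace(spec, n_individuals=200, seed=21)
    _, train_profiles = pl.generate_cohort(train_spec)
    train_images = pl.render_images(train_profiles, train_spec)
    ensemble = pl.train_reference_classifiers(
        train_images, train_profiles, spec.schema, epochs=30, seed=3
    )
    eval_spec = dataclasses.replace(spec, n_individuals=30, seed=22)
    eval_genomes, eval_profiles = pl.generate_cohort(eval_spec)
    eval_images = pl.render_images(eval_profiles, eval_spec)
    return spec, model, ensemble, eval_genomes, eval_profiles, eval_images
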