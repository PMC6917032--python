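import pytest

from pgxtext.classifier import train
from pgxtext.synthetic import (
    GeneratorConfig,
    cancer_chemical_ids,
    default_chemical_filter_config,
    default_exclusion_words,
    default_keywords,
    generate,
    generate_labeled_candidates,
)


@pytest.fixture(scope="session")
def corpus30():
    """Medium synthetic corpus with multi-entity sentences enabled."""
    return generate(GeneratorConfig(seed=3, n_documents=30, multi_entity_rate=0.1))


@pytest.fixture(scope="session")
def trained_models():
    """One classifier per group, trained on separable synthetic candidates."""
    return {
        g: train(generate_labeled_candidates(300, g, seed=42), g, seed=42)
        for g in ("group1", "group2")
    }


@pytest.fixture(scope="session")
def pipeline_kwargs(trained_models):
    return dict(
        chem_config=default_chemical_filter_config(),
        keywords=default_keywords(),
        exclusion_words=default_exclusion_words(),
        models=trained_models,
        cancer_chemical_ids=cancer_chemical_ids(),
    )
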