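import numpy as np
import pytest

from icdsem.catalog import IcdCatalog, IcdCode, PhenotypeDefinition, restrict_to_catalog
from icdsem.encoder import HashingTextEncoder, get_or_encode
from icdsem.fusion import EnsembleProducer
from icdsem.retrieval import EncoderProducer
from icdsem.synth import SynthConfig, make_catalog_and_phenotypes, make_diagnosis_records


@pytest.fixture
def tiny_catalog() -> IcdCatalog:
    return IcdCatalog(
        [
            IcdCode("ICD10CM", "F50.0", "anorexia nervosa"),
            IcdCode("ICD10CM", "F50.2", "bulimia nervosa"),
            IcdCode("ICD9CM", "307.1", "anorexia nervosa"),
            IcdCode("ICD10CM", "I21.9", "acute myocardial infarction"),
            IcdCode("ICD9CM", "410.9", "myocardial infarction unspecified"),
        ]
    )


def make_defn(pid, keys, name="q", category="Mental", parent=None) -> PhenotypeDefinition:
    return PhenotypeDefinition(
        phenotype_id=pid,
        name=name,
        category=category,
        parent_id=parent,
        icd_set=frozenset(keys),
    )


@pytest.fixture(scope="session")
def synth_world():
    """Benchmark-scale synthetic world: 5,000 codes, 100 non-trivial phenotypes."""
    config = SynthConfig.nontrivial(7)
    catalog, definitions = make_catalog_and_phenotypes(config)
    definitions = [restrict_to_catalog(d, catalog) for d in definitions]
    return config, catalog, definitions


@pytest.fixture(scope="session")
def noisy_producers(synth_world):
    """Three toy encoders with partially independent noise over the world catalogue."""
    _, catalog, _ = synth_world
    producers = []
    for seed in (11, 22, 33):
        backend = HashingTextEncoder(dimension=256, seed=seed, noise_sigma=1.0)
        embeddings = get_or_encode(catalog.descriptions, backend, keys=catalog.keys)
        producers.append(EncoderProducer(backend=backend, catalog_embeddings=embeddings))
    return producers


@pytest.fixture(scope="session")
def synth_records(synth_world):
    config, catalog, definitions = synth_world
    return make_diagnosis_records(config, catalog, definitions)
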