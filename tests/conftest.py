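import pytest

from acemine import data_path, default_spec, generate_corpus, load_inventory, run_pipeline
from acemine.textproc import Sentence, tokenize


@pytest.fixture(scope="session")
def seed_inventory():
    with open(data_path("pattern_inventory.tsv"), encoding="utf-8") as fh:
        return load_inventory(fh)


@pytest.fixture(scope="session")
def gen_bundle():
    """A 200-publication synthetic corpus with planted associations."""
    return generate_corpus(default_spec(n_publications=200, seed=1))


@pytest.fixture(scope="session")
def pipeline_result(gen_bundle):
    return run_pipeline(
        gen_bundle.records,
        gen_bundle.inventory,
        gen_bundle.entity_lexicon,
        gen_bundle.mapping_table,
        drug_lexicon=gen_bundle.drug_lexicon,
    )


def make_sentence(text, pmid="X1", index=0):
    s = Sentence(pmid=pmid, index=index, text=text, start=0, end=len(text))
    return s, tokenize(s)
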