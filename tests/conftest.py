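import pytest

import bioresnet as br


@pytest.fixture(scope="session")
def lexicon() -> br.HeadLexicon:
    return br.default_head_lexicon()


@pytest.fixture(scope="session")
def small_dictionary() -> br.DescriptorDictionary:
    return br.DescriptorDictionary.from_terms(
        [
            "gene", "protein", "gene expression", "gene expression data",
            "phylogenetic tree", "hierarchical clustering", "motif",
        ]
    )


def annotate_text(text: str, lexicon, dictionary) -> list[br.SentenceRecord]:
    return [br.annotate(r, lexicon, dictionary) for r in br.split_sentences(text)]


@pytest.fixture(scope="session")
def planted_bundle():
    """Small deterministic 2-community corpus used across modules."""
    spec = br.SyntheticSpec(
        n_communities=2, resources_per_community=3, sentences_per_resource=8,
        noise=0.0, n_generic=0, seed=7,
    )
    return br.generate_corpus(spec)


@pytest.fixture(scope="session")
def planted_profiles(planted_bundle):
    records = br.extract_corpus(
        planted_bundle.documents.items(),
        planted_bundle.head_lexicon,
        planted_bundle.dictionary,
    )
    return br.build_profiles(records)
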