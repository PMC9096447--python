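import dataclasses

import pytest

import biotagme as bt
from biotagme.wiki import Page, WikiSnapshot


@pytest.fixture(scope="session")
def synth_config() -> bt.SynthConfig:
    """The benchmark conditions: 50 entities, 200 docs, 40 planted pairs."""
    return bt.SynthConfig()


@pytest.fixture(scope="session")
def synth_wiki(synth_config):
    return bt.generate_wiki(synth_config)


@pytest.fixture(scope="session")
def synth_corpus(synth_config, synth_wiki):
    return bt.generate_corpus(synth_wiki, synth_config)


@pytest.fixture(scope="session")
def synth_annotations(synth_wiki, synth_corpus):
    docs, _truth = synth_corpus
    return bt.annotate_corpus(docs, synth_wiki)


@pytest.fixture(scope="session")
def clean_setup():
    """Noise-free, unambiguous variant of the benchmark conditions."""
    config = dataclasses.replace(bt.SynthConfig(), ambiguity_rate=0.0, noise_mention_rate=0.0)
    wiki = bt.generate_wiki(config)
    docs, truth = bt.generate_corpus(wiki, config)
    return config, wiki, docs, truth


@pytest.fixture()
def tiny_wiki() -> WikiSnapshot:
    """Hand-built 10-page snapshot with one ambiguous anchor.

    Pages 1-3 are biological (categories under root 1), page 4 is a city
    (root 10); pages 5-9 only exist as link sources.  The anchor "factor"
    is ambiguous between page 2 (bio, commonness 0.75) and page 4.
    """
    pages = {
        1: Page(1, "Blood Coagulation", frozenset({2})),
        2: Page(2, "Factor", frozenset({2})),
        3: Page(3, "Thrombin", frozenset({3})),
        4: Page(4, "Paris", frozenset({11})),
        **{i: Page(i, f"Hub {i}") for i in range(5, 10)},
    }
    links = {
        (5, 1), (6, 1), (7, 1),
        (5, 2), (6, 2), (8, 2),
        (5, 3), (7, 3),
        (9, 4),
    }
    return WikiSnapshot(
        pages=pages,
        links=links,
        category_parents={2: {1}, 3: {1}, 11: {10}},
        bio_roots=frozenset({1}),
        anchors={
            "blood coagulation": {1: 4},
            "factor": {2: 3, 4: 1},
            "thrombin": {3: 2},
        },
        anchor_occurrences={"blood coagulation": 4, "factor": 4, "thrombin": 2},
    )
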