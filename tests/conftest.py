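"""Shared fixtures.

The expensive session fixtures (`world`, `models`, `dev_predictions`) train
the full pipeline once on the default synthetic study and are reused by the
pipeline and acceptance tests.
"""

from __future__ import annotations

import pytest

from relmine.corpus import Corpus, Document, Mention, Relation, Span, parse_pubtator
from relmine.pipeline import PipelineConfig, run_pipeline, train_pipeline
from relmine.synthetic import SyntheticSpec, make_world


@pytest.fixture(scope="session")
def world():
    """The default desk-scale study: 200 train / 50 dev docs, seed 7."""
    return make_world(SyntheticSpec())


@pytest.fixture(scope="session")
def models(world):
    return train_pipeline(world, seed=0)


@pytest.fixture(scope="session")
def dev_predictions(world, models):
    pred, manifest = run_pipeline(world.dev, models, PipelineConfig(seed=0))
    return pred


@pytest.fixture
def tiny_doc():
    """A hand-crafted two-entity document with one relation."""
    title = "Alpha binds beta ."
    abstract = "The alpha protein binds beta in cells ."
    text = title + " " + abstract
    mentions = [
        Mention(Span(0, 5), "Alpha", "Gene", ("G1",)),
        Mention(Span(12, 16), "beta", "Gene", ("G2",)),
        Mention(Span(23, 28), "alpha", "Gene", ("G1",)),
        Mention(Span(43, 47), "beta", "Gene", ("G2",)),
    ]
    for m in mentions:
        assert text[m.span.start:m.span.end] == m.surface
    return Document("90001", title, abstract, mentions,
                    [Relation(("G1", "G2"), "Bind", "Novel")])


PUBTATOR_FIXTURE = """\
90002|t|Gamma causes delta syndrome .
90002|a|We studied gamma and delta syndrome in mice .
90002\t0\t5\tGamma\tGene\tG9
90002\t13\t27\tdelta syndrome\tDisease\tD9
90002\t41\t46\tgamma\tGene\tG9
90002\tAssociation\tD9\tG9\tNovel
"""


@pytest.fixture
def pubtator_fixture_text():
    return PUBTATOR_FIXTURE


@pytest.fixture
def pubtator_fixture_corpus():
    return parse_pubtator(PUBTATOR_FIXTURE)
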