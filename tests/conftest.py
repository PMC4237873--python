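import random
import warnings

import pytest

from clintemprel.annotation_layer import TreeNode
from clintemprel.relation_pipeline import Featurizer, PipelineConfig, TemporalPipeline
from clintemprel.rule_engine import starter_negative_rules, starter_rules
from clintemprel.synthetic_fixtures import DEFAULT_MIX, SEMREL_MIX, generate_corpus


@pytest.fixture(scope="session")
def train_corpus():
    return generate_corpus(11, 20, DEFAULT_MIX, sentences_per_doc=6)


@pytest.fixture(scope="session")
def test_corpus():
    return generate_corpus(12, 8, DEFAULT_MIX, sentences_per_doc=6, doc_prefix="test")


@pytest.fixture(scope="session")
def semrel_corpora():
    train = generate_corpus(3, 24, SEMREL_MIX, sentences_per_doc=6)
    test = generate_corpus(4, 8, SEMREL_MIX, sentences_per_doc=6, doc_prefix="test")
    return train, test


@pytest.fixture(scope="session")
def fitted_ensemble(semrel_corpora):
    from clintemprel.semrel_ensemble import EnsembleConfig, SemRelEnsemble

    train, test = semrel_corpora
    corpus = {**train.docs, **test.docs}
    ens = SemRelEnsemble(EnsembleConfig(k=20))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ens.fit(train.semrel_instances, corpus)
    return ens, corpus


@pytest.fixture(scope="session")
def fitted_pipeline(train_corpus, test_corpus):
    """Pipeline trained on the default-mix fixture corpus with the planted
    semantic-relation labels as the medsem oracle."""
    medsem = train_corpus.gold_semrel_model()
    medsem._labels.update(test_corpus.gold_semrel_model()._labels)
    feat = Featurizer({**train_corpus.docs, **test_corpus.docs},
                      thesaurus=train_corpus.thesaurus, wordnet=train_corpus.wordnet,
                      medsem_model=medsem)
    pipe = TemporalPipeline(PipelineConfig(), featurizer=feat, rules=starter_rules(),
                            negative_rules=starter_negative_rules())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe.fit(train_corpus.docs)
    return pipe


# ---------------------------------------------------------------------------
# random tree generation for structural oracles
# ---------------------------------------------------------------------------

_LABELS = ["S", "NP", "VP", "PP", "A", "B", "C", "D"]


def random_tree(rng: random.Random, max_nodes: int) -> TreeNode:
    """A random rooted ordered labeled tree with at most max_nodes nodes;
    leaves get token indices in left-to-right order."""
    budget = rng.randint(2, max_nodes)
    counter = [0]

    def build(b: int) -> tuple[TreeNode, int]:
        node = TreeNode(label=rng.choice(_LABELS))
        used = 1
        n_children = rng.randint(1, 3) if b > 1 else 0
        for _ in range(n_children):
            if used >= b:
                break
            child, u = build(rng.randint(1, max(1, b - used)))
            child.parent = node
            node.children.append(child)
            used += u
        return node, used

    root, _ = build(budget)
    for i, leaf in enumerate(root.leaves()):
        leaf.token_index = i
    return root
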