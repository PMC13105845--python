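"""Shared fixtures.

The expensive trained models (used by the MLM-learnability, completion and
ablation acceptance tests) are session-scoped so the suite trains each one
exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from glycoformer.graphs import parse_iupac
from glycoformer.model import ModelConfig
from glycoformer.synthetic import ToyGrammar, generate_corpus
from glycoformer.tokenizer import build_vocab, encode
from glycoformer.training import TrainConfig, pretrain

ACCEPT_SEED = 7
TOY_N = 2000

# desk-scale training recipe: the published learning rate (1e-6) targets an
# ~84k-glycan corpus and long schedules; on a 2k toy corpus the optimizer
# needs a larger rate, brief warmup with cosine decay, and two masking draws
# per glycan per epoch to converge inside 50 epochs
DESK_RECIPE = dict(
    lr=2e-3, batch_size=16, warmup_epochs=3, cosine_decay=True,
    plans_per_glycan=2, max_epochs=50, refit_full=False,
)


@pytest.fixture(scope="session")
def toy_corpus():
    """2,000 toy-grammar glycans with family labels (the stated world)."""
    return generate_corpus(ToyGrammar(seed=ACCEPT_SEED), TOY_N, ACCEPT_SEED)


@pytest.fixture(scope="session")
def toy_strings(toy_corpus):
    return [s for s, _ in toy_corpus]


@pytest.fixture(scope="session")
def toy_graphs(toy_strings):
    return [parse_iupac(s) for s in toy_strings]


@pytest.fixture(scope="session")
def toy_vocab(toy_graphs):
    return build_vocab(toy_graphs)


@pytest.fixture(scope="session")
def toy_tokenized(toy_graphs, toy_vocab):
    return [encode(g, toy_vocab) for g in toy_graphs]


def _train(toy_strings, toy_vocab, mode, **overrides):
    kw = dict(DESK_RECIPE)
    kw.update(overrides)
    tcfg = TrainConfig(seed=ACCEPT_SEED, **kw)
    cfg = ModelConfig.from_scale(
        "ss", toy_vocab.node_size, toy_vocab.edge_size,
        dropout=0.0, seed=ACCEPT_SEED,
    )
    return pretrain(toy_strings, cfg=cfg, tcfg=tcfg, mode=mode,
                    vocab=toy_vocab)


@pytest.fixture(scope="session")
def trained_balanced(toy_strings, toy_vocab):
    """ss-scale encoder pretrained with balanced 35%/35% masking."""
    return _train(toy_strings, toy_vocab, "balanced")


@pytest.fixture(scope="session")
def trained_node_only(toy_strings, toy_vocab):
    """Ablation: 70% node / 0% edge masking, shorter schedule."""
    return _train(toy_strings, toy_vocab, "node_only",
                  max_epochs=25, plans_per_glycan=1)


@pytest.fixture(scope="session")
def trained_edge_only(toy_strings, toy_vocab):
    """Ablation: 0% node / 70% edge masking, shorter schedule."""
    return _train(toy_strings, toy_vocab, "edge_only",
                  max_epochs=25, plans_per_glycan=1)


@pytest.fixture(scope="session")
def held_out_tokenized(toy_vocab):
    """A fresh 300-glycan sample from the same grammar, disjoint seed."""
    records = generate_corpus(ToyGrammar(seed=ACCEPT_SEED), 300,
                              ACCEPT_SEED + 10_000)
    return [encode(parse_iupac(s), toy_vocab) for s, _ in records]
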