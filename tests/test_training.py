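"""Masking plans, MLM loss composition, and the pretraining loop."""

from __future__ import annotations

import numpy as np
import pytest

from glycoformer.graphs import parse_iupac
from glycoformer.model import GlycanEncoder, ModelConfig, batch_tokenized
from glycoformer.tokenizer import MASK, build_vocab, encode
from glycoformer.training import (
    TrainConfig, apply_masking, attention_summary, make_masking_plan,
    masked_accuracy, mlm_loss, pretrain,
)


@pytest.fixture(scope="module")
def chain5():
    """Linear 5-residue chain: 4 bonds, the two leaf-touching ones
    terminal, so exactly 2 eligible masking targets."""
    g = parse_iupac("Gal(b1-3)Glc(b1-4)Man(a1-2)Fuc(a1-3)GalNAc")
    vocab = build_vocab([g])
    return g, vocab, encode(g, vocab)


class TestMaskingPlan:
    def test_zero_ratio_masks_nothing(self, chain5):
        _, _, tg = chain5
        plan = make_masking_plan(tg, 0.0, 0.0, seed=1)
        assert not plan.masked_node_positions
        assert not plan.masked_edge_positions

    def test_full_node_ratio_masks_all_nodes(self, chain5):
        _, _, tg = chain5
        plan = make_masking_plan(tg, 1.0, 0.0, seed=1)
        assert len(plan.masked_node_positions) == 5

    def test_half_edge_ratio_masks_only_eligible_edges(self, chain5):
        """4 bonds; only the bond touching the non-root leaf is terminal,
        leaving 3 eligible; ratio 0.5 -> 2 masked, never the terminal one."""
        _, _, tg = chain5
        eligible = set(tg.eligible_edge_positions())
        assert len(eligible) == 3
        for seed in range(20):
            plan = make_masking_plan(tg, 0.0, 0.5, seed=seed)
            assert len(plan.masked_edge_positions) == 2
            assert {p for p, _ in plan.masked_edge_positions} <= eligible

    def test_deterministic_under_seed(self, chain5):
        _, _, tg = chain5
        a = make_masking_plan(tg, 0.4, 0.5, seed=11)
        b = make_masking_plan(tg, 0.4, 0.5, seed=11)
        assert a == b

    def test_ratio_out_of_range_raises(self, chain5):
        _, _, tg = chain5
        with pytest.raises(ValueError):
            make_masking_plan(tg, 1.5, 0.0, seed=0)

    def test_apply_masking_preserves_unmasked_inputs(self, chain5):
        _, _, tg = chain5
        plan = make_masking_plan(tg, 0.4, 0.5, seed=2)
        batch, nt, et = apply_masking([tg], [plan])
        masked = set(plan.all_masked_positions)
        for pos in range(len(tg)):
            if pos in masked:
                assert batch.content[0, pos] == MASK
            else:
                assert batch.content[0, pos] == tg.content_ids[pos]
        # identifiers and types stay visible everywhere
        assert tuple(batch.types[0, :len(tg)]) == tg.types


class TestLoss:
    def _uniform_logits(self, B, T, V):
        return np.zeros((B, T, V))

    def test_uniform_logits_give_log_vocab(self, chain5):
        """Uniform logits: node term = ln(content vocab size)."""
        _, vocab, tg = chain5
        plan = make_masking_plan(tg, 0.4, 0.0, seed=3)
        _, nt, et = apply_masking([tg], [plan])
        V = vocab.node_size
        loss, parts = mlm_loss(
            self._uniform_logits(1, len(tg), V),
            self._uniform_logits(1, len(tg), vocab.edge_size), nt, et,
        )
        n_content = len(vocab.content_ids("node"))
        assert np.isclose(parts["node"], np.log(n_content), atol=1e-9)
        assert parts["edge"] == 0.0

    def test_edge_weight_scales_edge_term(self, chain5):
        """Only edges masked: loss = 0.5 * edge cross-entropy."""
        _, vocab, tg = chain5
        plan = make_masking_plan(tg, 0.0, 1.0, seed=3)
        _, nt, et = apply_masking([tg], [plan])
        loss, parts = mlm_loss(
            self._uniform_logits(1, len(tg), vocab.node_size),
            self._uniform_logits(1, len(tg), vocab.edge_size), nt, et,
            edge_loss_weight=0.5,
        )
        assert np.isclose(loss, 0.5 * parts["edge"], atol=1e-12)

    def test_crafted_logits_match_hand_computed_ce(self, chain5):
        """One masked node + one masked edge with hand-set logits equals the
        manually computed weighted cross-entropy, exactly."""
        _, vocab, tg = chain5
        T = len(tg)
        Vn, Ve = vocab.node_size, vocab.edge_size
        node_logits = np.zeros((1, T, Vn))
        edge_logits = np.zeros((1, T, Ve))
        nt = np.full((1, T), -1); et = np.full((1, T), -1)
        npos, epos = 2, T - 2
        nt[0, npos] = 5
        et[0, epos] = 6
        node_logits[0, npos, 4:] = [1.0, 2.0, 0.5, -1.0, 0.0][: Vn - 4]
        edge_logits[0, epos, 4:] = [0.2, -0.3, 1.7, 0.0][: Ve - 4]

        def ce(logit_row, truth):
            z = logit_row[4:]
            return -(z[truth - 4] - np.log(np.exp(z).sum()))

        expected = ce(node_logits[0, npos], 5) + 0.5 * ce(edge_logits[0, epos], 6)
        loss, _ = mlm_loss(node_logits, edge_logits, nt, et, 0.5)
        assert np.isclose(loss, expected, atol=1e-6)

    def test_no_masked_positions_gives_zero(self, chain5):
        _, vocab, tg = chain5
        T = len(tg)
        nt = np.full((1, T), -1); et = np.full((1, T), -1)
        loss, _ = mlm_loss(np.zeros((1, T, vocab.node_size)),
                           np.zeros((1, T, vocab.edge_size)), nt, et)
        assert loss == 0.0

    def test_gradients_match_finite_differences(self, chain5):
        _, vocab, tg = chain5
        rng = np.random.default_rng(0)
        T = len(tg)
        node_logits = rng.standard_normal((1, T, vocab.node_size))
        edge_logits = rng.standard_normal((1, T, vocab.edge_size))
        nt = np.full((1, T), -1); et = np.full((1, T), -1)
        nt[0, 1] = 4; nt[0, 3] = 6; et[0, T - 1] = 5
        loss, _, dn, de = mlm_loss(node_logits, edge_logits, nt, et, 0.5,
                                   return_grads=True)
        eps = 1e-6
        for arr, grad in ((node_logits, dn), (edge_logits, de)):
            idx = (0, 1, 5)
            old = arr[idx]
            arr[idx] = old + eps
            lp, _ = mlm_loss(node_logits, edge_logits, nt, et, 0.5)
            arr[idx] = old - eps
            lm, _ = mlm_loss(node_logits, edge_logits, nt, et, 0.5)
            arr[idx] = old
            assert np.isclose((lp - lm) / (2 * eps), grad[idx], atol=1e-6)


def _small_world(n=60, seed=5):
    from glycoformer.synthetic import ToyGrammar, generate_corpus

    strings = [s for s, _ in generate_corpus(ToyGrammar(seed=seed), n, seed)]
    graphs = [parse_iupac(s) for s in strings]
    vocab = build_vocab(graphs)
    cfg = ModelConfig(vocab.node_size, vocab.edge_size, depth=1, d=16,
                      heads=2, dropout=0.0, seed=seed)
    return strings, vocab, cfg


class TestPretrainLoop:
    def test_zero_lr_leaves_parameters_unchanged(self):
        strings, vocab, cfg = _small_world()
        tcfg = TrainConfig(lr=0.0, max_epochs=1, refit_full=False,
                           ema_decay=None, seed=5)
        before = dict(GlycanEncoder(cfg).params)
        res = pretrain(strings, cfg=cfg, tcfg=tcfg, vocab=vocab)
        for k, v in res.encoder.params.items():
            assert np.allclose(v, before[k], atol=1e-12)

    def test_same_seed_identical_loss_curves(self):
        strings, vocab, cfg = _small_world()
        tcfg = TrainConfig(lr=1e-3, max_epochs=3, refit_full=False, seed=5)
        a = pretrain(strings, cfg=cfg, tcfg=tcfg, vocab=vocab)
        b = pretrain(strings, cfg=cfg, tcfg=tcfg, vocab=vocab)
        assert a.log.equals(b.log)
        for k in a.encoder.params:
            assert np.array_equal(a.encoder.params[k], b.encoder.params[k])

    def test_node_only_mode_never_masks_edges(self):
        strings, vocab, cfg = _small_world()
        tcfg = TrainConfig(lr=1e-3, max_epochs=2, refit_full=False, seed=5)
        res = pretrain(strings, cfg=cfg, tcfg=tcfg, mode="node_only",
                       vocab=vocab)
        assert np.isnan(res.log.val_edge_acc).all()

    def test_refit_uses_selected_epoch_count(self):
        strings, vocab, cfg = _small_world()
        tcfg = TrainConfig(lr=1e-3, max_epochs=3, refit_full=True, seed=5)
        res = pretrain(strings, cfg=cfg, tcfg=tcfg, vocab=vocab)
        assert 1 <= res.best_epoch <= 3

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError):
            pretrain([], tcfg=TrainConfig())


class TestAttentionSummary:
    def test_rows_sum_to_one_on_tiny_model(self):
        strings, vocab, cfg = _small_world(20)
        enc = GlycanEncoder(cfg)
        tgs = [encode(parse_iupac(s), vocab) for s in strings[:20]]
        block = attention_summary(enc, tgs)
        assert block.shape == (3, 3)
        assert np.allclose(block.sum(axis=1), 1.0, atol=1e-5)

    def test_uniform_attention_gives_column_shares(self):
        """If every query attends uniformly, each block entry equals the
        share of key tokens of that type."""
        strings, vocab, cfg = _small_world(1)
        enc = GlycanEncoder(cfg)
        # zero out q/k so attention is exactly uniform over real tokens
        for l in range(cfg.depth):
            for nm in ("Wq", "Wk"):
                enc.params[f"l{l}.attn.{nm}"][:] = 0.0
            enc.params[f"l{l}.attn.wb_q"][:] = 0.0
            enc.params[f"l{l}.attn.wb_k"][:] = 0.0
        tg = encode(parse_iupac(strings[0]), vocab)
        block = attention_summary(enc, [tg])
        t = len(tg)
        shares = np.array([tg.n_nodes / t, tg.n_edges / t, 1 / t])
        assert np.allclose(block, np.tile(shares, (3, 1)), atol=1e-9)


class TestMaskedAccuracy:
    def test_perfect_predictor_scores_one(self):
        """An encoder whose head always produces the true label scores 1."""
        strings, vocab, cfg = _small_world(10)
        graphs = [parse_iupac(s) for s in strings]
        tgs = [encode(g, vocab) for g in graphs]
        plans = [make_masking_plan(tg, 0.5, 0.5, seed=i)
                 for i, tg in enumerate(tgs)]

        class Oracle(GlycanEncoder):
            def forward(self, batch, **kw):  # remember truth via closure
                self._batch = batch
                return super().forward(batch, **kw)

            def mlm_heads(self, token_states):
                B, T, _ = token_states.shape
                nl = np.zeros((B, T, self.cfg.node_vocab_size))
                el = np.zeros((B, T, self.cfg.edge_vocab_size))
                for b, tg in enumerate(current):
                    for pos in range(len(tg)):
                        nl[b, pos, tg.content_ids[pos] % self.cfg.node_vocab_size] = 50
                        el[b, pos, tg.content_ids[pos] % self.cfg.edge_vocab_size] = 50
                return nl, el

        enc = Oracle(cfg)
        current = tgs
        out = masked_accuracy(enc, tgs, plans)
        assert out["node_acc"] == 1.0
        assert out["edge_acc"] == 1.0
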