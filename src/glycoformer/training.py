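"""Masked-language-model pretraining for the glycan encoder.

Node (monosaccharide) and edge (linkage) tokens are masked at configured
ratios and predicted from context.  Masked positions have their content id
replaced by the MASK token at input time; their identifier and type
embeddings stay visible, so the model always knows *where* the masked
residue or bond sits in the tree — only *what* it is must be inferred.
Terminal linkages (bonds touching a leaf residue) are excluded from the
prediction targets: with a leaf on one side they lack two-sided context.

The loss is cross-entropy averaged over masked node positions plus an
edge-loss weight (default 0.5) times the cross-entropy averaged over masked
edge positions.  Optimization is AdamW with decoupled weight decay and
global-norm gradient clipping; a 90/10 train/validation split with patience-
based early stopping on mean validation loss selects the epoch count, after
which the model can be refit on the full corpus for that many epochs.

Masking counts are fixed per glycan (``round(ratio * n_eligible)``) rather
than per-token Bernoulli draws, which makes every plan deterministic under
its seed; plans are resampled each epoch from seeds derived from
``(base_seed, epoch)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .graphs import parse_iupac
from .model import Batch, GlycanEncoder, ModelConfig, batch_tokenized
from .tokenizer import (
    EDGE, GRAPH_TYPE, MASK, NODE, TokenizedGraph, Vocabulary, build_vocab,
    encode,
)

__all__ = [
    "MaskingPlan", "TrainConfig", "make_masking_plan", "apply_masking",
    "mlm_loss", "pretrain", "PretrainResult", "attention_summary",
    "masked_accuracy",
]

MaskMode = Literal["balanced", "node_only", "edge_only"]


@dataclass(frozen=True)
class MaskingPlan:
    """Which token positions of one glycan are masked, and their truths."""

    masked_node_positions: tuple[tuple[int, int], ...]  # (token pos, true id)
    masked_edge_positions: tuple[tuple[int, int], ...]
    node_ratio: float
    edge_ratio: float
    seed: int
    # positions masked at input time but never scored (terminal bonds in the
    # all-linkages-unknown scenario)
    masked_input_only: tuple[int, ...] = ()

    @property
    def all_masked_positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.masked_node_positions) + tuple(
            p for p, _ in self.masked_edge_positions
        ) + self.masked_input_only


def _fixed_count(ratio: float, n: int) -> int:
    # round-half-up so ratio 0.5 of 2 eligible positions masks exactly 1
    return int(np.floor(ratio * n + 0.5))


def make_masking_plan(
    tg: TokenizedGraph, node_ratio: float, edge_ratio: float, seed: int
) -> MaskingPlan:
    """Choose masked positions uniformly without replacement.

    ``round(node_ratio * n_nodes)`` node tokens and
    ``round(edge_ratio * n_eligible_edges)`` non-terminal edge tokens are
    masked; the [Graph] token and padding are never masked.
    """
    for r in (node_ratio, edge_ratio):
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"masking ratio {r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    node_pos = list(tg.node_positions)
    elig_edge_pos = tg.eligible_edge_positions()
    k_n = _fixed_count(node_ratio, len(node_pos))
    k_e = _fixed_count(edge_ratio, len(elig_edge_pos))
    chosen_n = sorted(rng.choice(node_pos, size=k_n, replace=False)) if k_n else []
    chosen_e = sorted(rng.choice(elig_edge_pos, size=k_e, replace=False)) if k_e else []
    return MaskingPlan(
        masked_node_positions=tuple((int(p), tg.content_ids[p]) for p in chosen_n),
        masked_edge_positions=tuple((int(p), tg.content_ids[p]) for p in chosen_e),
        node_ratio=node_ratio,
        edge_ratio=edge_ratio,
        seed=seed,
    )


def apply_masking(
    tgs: Sequence[TokenizedGraph], plans: Sequence[MaskingPlan]
) -> tuple[Batch, np.ndarray, np.ndarray]:
    """Batch the glycans with masked inputs and build target arrays.

    Returns ``(batch, node_targets, edge_targets)`` where the target arrays
    are (B, T) ints holding the true content id at scored masked positions
    and -1 elsewhere.
    """
    batch = batch_tokenized(tgs)
    B, T = batch.content.shape
    node_targets = np.full((B, T), -1, dtype=np.int64)
    edge_targets = np.full((B, T), -1, dtype=np.int64)
    for i, plan in enumerate(plans):
        for p, true_id in plan.masked_node_positions:
            batch.content[i, p] = MASK
            node_targets[i, p] = true_id
        for p, true_id in plan.masked_edge_positions:
            batch.content[i, p] = MASK
            edge_targets[i, p] = true_id
        for p in plan.masked_input_only:
            batch.content[i, p] = MASK
    return batch, node_targets, edge_targets


def mlm_loss(
    node_logits: np.ndarray,
    edge_logits: np.ndarray,
    node_targets: np.ndarray,
    edge_targets: np.ndarray,
    edge_loss_weight: float = 0.5,
    return_grads: bool = False,
):
    """Weighted masked cross-entropy.

    ``loss = mean-CE(node positions) + w_e * mean-CE(edge positions)``;
    an empty target set contributes 0.  Cross-entropy is over content
    classes only (special ids are excluded from the softmax).  With
    ``return_grads`` the per-logit gradients are also returned.
    """
    parts = {}
    grads = []
    for name, logits, targets, w in (
        ("node", node_logits, node_targets, 1.0),
        ("edge", edge_logits, edge_targets, edge_loss_weight),
    ):
        sel = targets >= 0
        n = int(sel.sum())
        dlogits = np.zeros_like(logits)
        if n == 0:
            parts[name] = 0.0
        else:
            logp = GlycanEncoder.content_log_probs(logits[sel])
            truth = targets[sel]
            parts[name] = float(-logp[np.arange(n), truth].mean())
            if return_grads:
                probs = np.exp(logp)
                probs[np.arange(n), truth] -= 1.0
                dlogits[sel] = probs * (w / n)
        grads.append(dlogits)
    total = parts["node"] + edge_loss_weight * parts["edge"]
    if return_grads:
        return total, parts, grads[0], grads[1]
    return total, parts


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.  The learning-rate default follows large-corpus
    pretraining practice; desk-scale toy corpora need a larger rate (1e-3)
    to move within tens of epochs."""

    lr: float = 1e-6
    weight_decay: float = 0.01
    edge_loss_weight: float = 0.5
    patience: int | None = None      # None: 15 for ss/small, 30 otherwise
    val_fraction: float = 0.10
    max_epochs: int = 100
    batch_size: int = 32
    warmup_epochs: int = 0           # linear LR warmup
    cosine_decay: bool = False       # cosine decay to lr/10 over max_epochs
    adam_betas: tuple[float, float] = (0.9, 0.98)
    ema_decay: float | None = 0.999  # per-step weight EMA; None disables
    plans_per_glycan: int = 1        # distinct masking draws per glycan/epoch
    grad_clip: float = 1.0
    node_ratio: float = 0.35
    edge_ratio: float = 0.35
    refit_full: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.edge_loss_weight < 0:
            raise ValueError("edge loss weight must be >= 0")

    def resolved_patience(self, scale_name: str) -> int:
        if self.patience is not None:
            return self.patience
        return 15 if scale_name in ("ss", "small") else 30


def _ratios_for_mode(mode: MaskMode, tcfg: TrainConfig) -> tuple[float, float]:
    if mode == "balanced":
        return tcfg.node_ratio, tcfg.edge_ratio
    if mode == "node_only":
        return 0.70, 0.0
    if mode == "edge_only":
        return 0.0, 0.70
    raise ValueError(f"unknown masking mode {mode!r}")


class _AdamW:
    def __init__(self, params: dict[str, np.ndarray], lr, weight_decay,
                 betas=(0.9, 0.999), eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            # biases and LayerNorm parameters (1-D) are exempt from decay
            wd = self.wd if params[k].ndim > 1 else 0.0
            params[k] -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                    + wd * params[k])


def _clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale


def masked_accuracy(
    enc: GlycanEncoder,
    tgs: Sequence[TokenizedGraph],
    plans: Sequence[MaskingPlan],
    edge_loss_weight: float = 0.5,
    batch_size: int = 64,
) -> dict[str, float]:
    """Loss and top-1 accuracy over the scored masked positions."""
    tot_loss = 0.0
    n_batches = 0
    hits = {"node": 0, "edge": 0}
    counts = {"node": 0, "edge": 0}
    for start in range(0, len(tgs), batch_size):
        chunk = slice(start, start + batch_size)
        batch, nt, et = apply_masking(tgs[chunk], plans[chunk])
        out = enc.forward(batch)
        node_logits, edge_logits = enc.mlm_heads(out.token_states)
        loss, _ = mlm_loss(node_logits, edge_logits, nt, et, edge_loss_weight)
        tot_loss += loss
        n_batches += 1
        for name, logits, targets in (("node", node_logits, nt),
                                      ("edge", edge_logits, et)):
            sel = targets >= 0
            if sel.any():
                logp = GlycanEncoder.content_log_probs(logits[sel])
                hits[name] += int((logp.argmax(-1) == targets[sel]).sum())
                counts[name] += int(sel.sum())
    return {
        "loss": tot_loss / max(n_batches, 1),
        "node_acc": hits["node"] / counts["node"] if counts["node"] else float("nan"),
        "edge_acc": hits["edge"] / counts["edge"] if counts["edge"] else float("nan"),
    }


@dataclass
class PretrainResult:
    encoder: GlycanEncoder
    vocab: Vocabulary
    log: pd.DataFrame
    best_epoch: int
    mode: MaskMode


def _epoch_seed(base: int, epoch: int, salt: int = 0) -> int:
    ss = np.random.SeedSequence([base, epoch, salt])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _epoch_lr(tcfg: TrainConfig, epoch: int) -> float:
    """Linear warmup then optional cosine decay to lr/10."""
    if tcfg.warmup_epochs and epoch <= tcfg.warmup_epochs:
        return tcfg.lr * epoch / tcfg.warmup_epochs
    if not tcfg.cosine_decay:
        return tcfg.lr
    span = max(1, tcfg.max_epochs - tcfg.warmup_epochs)
    t = (epoch - tcfg.warmup_epochs) / span
    return tcfg.lr * (0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * min(t, 1.0))))


def _train_one_epoch(enc, opt, tgs, order, ratios, epoch, tcfg, ema=None):
    opt.lr = _epoch_lr(tcfg, epoch)
    rng = np.random.default_rng([tcfg.seed, epoch, 7])
    # each glycan can appear several times with independent masking draws;
    # bucket by length (random tie-break) so batches pad minimally, then
    # visit batches in random order
    reps = [(i, r) for i in order for r in range(tcfg.plans_per_glycan)]
    noise = rng.random(len(reps))
    by_len = sorted(range(len(reps)),
                    key=lambda k: (len(tgs[reps[k][0]]), noise[k]))
    batches = [
        [reps[k] for k in by_len[s:s + tcfg.batch_size]]
        for s in range(0, len(by_len), tcfg.batch_size)
    ]
    rng.shuffle(batches)
    losses = []
    for pairs in batches:
        chunk = [tgs[i] for i, _ in pairs]
        plans = [
            make_masking_plan(tgs[i], ratios[0], ratios[1],
                              _epoch_seed(tcfg.seed, epoch,
                                          1000 + int(i) * 4 + r))
            for i, r in pairs
        ]
        batch, nt, et = apply_masking(chunk, plans)
        out, cache = enc.forward(batch, train=enc.cfg.dropout > 0, rng=rng,
                                 return_cache=True)
        node_logits, edge_logits = enc.mlm_heads(out.token_states)
        loss, _, dnl, del_ = mlm_loss(node_logits, edge_logits, nt, et,
                                      tcfg.edge_loss_weight, return_grads=True)
        grads = {k: np.zeros_like(v) for k, v in enc.params.items()}
        d_states = enc.head_backward(out.token_states, dnl, del_, grads)
        body_grads = enc.backward(cache, d_states)
        for k, g in body_grads.items():
            grads[k] += g
        _clip_grads(grads, tcfg.grad_clip)
        opt.step(enc.params, grads)
        if ema is not None:
            a = tcfg.ema_decay
            for k, v in enc.params.items():
                ema[k] = a * ema[k] + (1.0 - a) * v
        losses.append(loss)
    return float(np.mean(losses)) if losses else float("nan")


def pretrain(
    corpus: Iterable[str] | Sequence[TokenizedGraph],
    cfg: ModelConfig | None = None,
    tcfg: TrainConfig | None = None,
    mode: MaskMode = "balanced",
    vocab: Vocabulary | None = None,
    scale: str = "ss",
) -> PretrainResult:
    """Pretrain an encoder with masked-token prediction.

    ``corpus`` may be IUPAC-condensed strings (a vocabulary is then built
    from them) or pre-encoded :class:`TokenizedGraph` objects with an
    explicit ``vocab``.  The corpus is split 90/10; early stopping triggers
    when mean validation loss has not improved for ``patience`` epochs, and
    with ``refit_full`` the returned model is retrained on the whole corpus
    for the selected number of epochs (the log covers the selection phase).
    """
    tcfg = tcfg or TrainConfig()
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    if isinstance(corpus[0], str):
        graphs = [parse_iupac(s) for s in corpus]
        if vocab is None:
            vocab = build_vocab(graphs)
        tgs = [encode(g, vocab) for g in graphs]
    else:
        if vocab is None:
            raise ValueError("pre-tokenized corpus needs an explicit vocab")
        tgs = list(corpus)
    if cfg is None:
        cfg = ModelConfig.from_scale(scale, vocab.node_size, vocab.edge_size,
                                     seed=tcfg.seed)
    ratios = _ratios_for_mode(mode, tcfg)
    patience = tcfg.resolved_patience(cfg.scale_name)

    split_rng = np.random.default_rng([tcfg.seed, 11])
    perm = split_rng.permutation(len(tgs))
    n_val = max(1, int(round(tcfg.val_fraction * len(tgs))))
    val_idx = perm[:n_val]
    train_idx = perm[n_val:]
    val_tgs = [tgs[i] for i in val_idx]
    # fixed validation masking so epochs are comparable
    val_plans = [
        make_masking_plan(tg, ratios[0], ratios[1],
                          _epoch_seed(tcfg.seed, 0, 2000 + int(i)))
        for i, tg in zip(val_idx, val_tgs)
    ]

    enc = GlycanEncoder(cfg)
    opt = _AdamW(enc.params, tcfg.lr, tcfg.weight_decay, betas=tcfg.adam_betas)
    ema = ({k: v.copy() for k, v in enc.params.items()}
           if tcfg.ema_decay else None)
    rows = []
    best_loss = np.inf
    best_epoch = 0
    since_best = 0
    for epoch in range(1, tcfg.max_epochs + 1):
        train_loss = _train_one_epoch(enc, opt, tgs, train_idx, ratios,
                                      epoch, tcfg, ema)
        if ema is not None:
            raw, enc.params = enc.params, ema
        val = masked_accuracy(enc, val_tgs, val_plans, tcfg.edge_loss_weight)
        if ema is not None:
            enc.params = raw
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val["loss"], "val_node_acc": val["node_acc"],
                     "val_edge_acc": val["edge_acc"]})
        if val["loss"] < best_loss - 1e-9:
            best_loss = val["loss"]
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    log = pd.DataFrame(rows)

    if tcfg.refit_full and best_epoch > 0:
        enc = GlycanEncoder(cfg)
        opt = _AdamW(enc.params, tcfg.lr, tcfg.weight_decay, betas=tcfg.adam_betas)
        ema = ({k: v.copy() for k, v in enc.params.items()}
               if tcfg.ema_decay else None)
        all_idx = np.arange(len(tgs))
        for epoch in range(1, best_epoch + 1):
            _train_one_epoch(enc, opt, tgs, all_idx, ratios, epoch, tcfg, ema)
    if ema is not None:
        enc.params = ema

    return PretrainResult(encoder=enc, vocab=vocab, log=log,
                          best_epoch=best_epoch, mode=mode)


def attention_summary(
    enc: GlycanEncoder, tgs: Sequence[TokenizedGraph], batch_size: int = 64
) -> np.ndarray:
    """Head-averaged final-layer attention, block-averaged by token type.

    Entry (i, j) is the average total attention a query token of type i
    (node / edge / graph) places on key tokens of type j, pooled over all
    real query tokens in the sample.  Rows sum to 1.
    """
    if not tgs:
        raise ValueError("empty sample")
    sums = np.zeros((3, 3))
    counts = np.zeros(3)
    for start in range(0, len(tgs), batch_size):
        batch = batch_tokenized(tgs[start:start + batch_size])
        out = enc.forward(batch, return_attention=True)
        attn = out.attention_maps[-1].mean(axis=1)     # (B, T, T) head-avg
        for b in range(attn.shape[0]):
            real = batch.mask[b]
            a = attn[b][np.ix_(real, real)]
            ttypes = batch.types[b][real]
            for i, qt in enumerate((NODE, EDGE, GRAPH_TYPE)):
                qsel = ttypes == qt
                if not qsel.any():
                    continue
                for j, kt in enumerate((NODE, EDGE, GRAPH_TYPE)):
                    ksel = ttypes == kt
                    sums[i, j] += a[np.ix_(qsel, ksel)].sum()
                counts[i] += int(qsel.sum())
    with np.errstate(invalid="ignore"):
        block = sums / counts[:, None]
    return block
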