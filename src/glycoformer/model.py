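"""Tokenized graph transformer encoder, implemented on NumPy.

The architecture treats each monosaccharide (node) and glycosidic bond
(edge) as an independent token.  A token's input embedding is the sum of

* a content embedding looked up by token id (separate tables for the node
  and edge vocabularies),
* a linear projection of its identifier features — node v carries
  ``[P_v, P_v]``, edge (u, v) carries ``[P_u, P_v]`` where the ``P`` rows
  are fixed, seeded orthonormal vectors (orthogonal random features).
  Orthonormality makes incidence detectable from attention inner products:
  ``<[P_u,P_v], [P_u,P_w]> = 1 + delta(v, w)``,
* a trainable type embedding (node / edge / graph-summary).

A trainable ``[Graph]`` token is prepended; its final hidden state is the
whole-glycan embedding used downstream.  The encoder is a stack of post-norm
transformer blocks (sub-layer, residual add, LayerNorm) with full attention
over all real tokens, so cost is O((n+m+1)^2 d) per glycan.  Two linear
heads map hidden states to node-vocabulary and edge-vocabulary logits for
masked-token prediction.

Everything here is float64 and seeded: the same config and seed reproduce
parameters and identifier bank bit-identically.  Forward passes cache the
intermediates needed by :func:`backward`, which returns exact gradients for
all trainable parameters (the identifier bank is fixed, not trained).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import erf

from .tokenizer import (
    EDGE, GRAPH_TYPE, NODE, PAD, SPECIALS, TokenizedGraph, Vocabulary,
)

__all__ = [
    "ModelConfig", "IdentifierBank", "EncoderOutput", "GlycanEncoder",
    "SCALES", "batch_tokenized", "save_checkpoint", "load_checkpoint",
]

# depth x width x heads presets; supplementary-scale stand-ins, configurable
SCALES: dict[str, tuple[int, int, int]] = {
    "ss": (2, 64, 4),
    "small": (4, 128, 4),
    "medium": (8, 256, 8),
    "large": (12, 512, 16),
}

_NEG = -1e30  # additive mask for padding keys / excluded classes


@dataclass(frozen=True)
class ModelConfig:
    node_vocab_size: int
    edge_vocab_size: int
    depth: int = 2
    d: int = 64
    heads: int = 4
    identifier_dim: int = 64
    max_nodes: int = 64
    dropout: float = 0.1
    tie_heads: bool = False  # optionally share MLM head weights with embeddings
    scale_name: str = "ss"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d % self.heads:
            raise ValueError("model width must be divisible by heads")
        if self.max_nodes > self.identifier_dim:
            raise ValueError("max_nodes cannot exceed identifier_dim")
        if min(self.depth, self.d, self.heads, self.identifier_dim) <= 0:
            raise ValueError("all dimensions must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def from_scale(cls, scale: str, node_vocab_size: int,
                   edge_vocab_size: int, **kw) -> "ModelConfig":
        depth, d, heads = SCALES[scale]
        kw.setdefault("identifier_dim", max(64, kw.get("max_nodes", 64)))
        return cls(node_vocab_size=node_vocab_size,
                   edge_vocab_size=edge_vocab_size,
                   depth=depth, d=d, heads=heads, scale_name=scale, **kw)


class IdentifierBank:
    """Fixed orthonormal identifier vectors, one row per node slot.

    ``P`` is the Q factor of a seeded Gaussian ``d_p x d_p`` matrix (signs
    fixed so QR is unique), hence exactly orthonormal rows: ``P P^T = I``.
    The bank is shared across all graphs — row ``v`` identifies canonical
    node index ``v`` — and regenerating with the same seed is bit-identical.
    """

    def __init__(self, d_p: int, seed: int):
        self.d_p = d_p
        self.seed = seed
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((d_p, d_p))
        q, r = np.linalg.qr(a)
        # make decomposition unique: force positive diagonal of R
        q = q * np.sign(np.diag(r))[np.newaxis, :]
        self.P = np.ascontiguousarray(q)

    def orthogonality_error(self) -> float:
        return float(np.abs(self.P @ self.P.T - np.eye(self.d_p)).max())


@dataclass
class EncoderOutput:
    """Per-token final states plus the [Graph] summary embedding."""

    token_states: np.ndarray          # (B, T, d)
    graph_embedding: np.ndarray       # (B, d) == token_states[:, 0]
    mask: np.ndarray                  # (B, T) True at real tokens
    attention_maps: np.ndarray | None = None   # (L, B, H, T, T)


# ---------------------------------------------------------------------------
# batching

@dataclass
class Batch:
    """Padded arrays for a list of tokenized glycans."""

    content: np.ndarray    # (B, T) int token ids (per-type spaces)
    types: np.ndarray      # (B, T) int, NODE/EDGE/GRAPH_TYPE; PAD marked in mask
    u: np.ndarray          # (B, T) int endpoint 1
    v: np.ndarray          # (B, T) int endpoint 2
    mask: np.ndarray       # (B, T) bool, True at real tokens
    lengths: np.ndarray    # (B,)


def batch_tokenized(tgs: Sequence[TokenizedGraph]) -> Batch:
    B = len(tgs)
    T = max(len(tg) for tg in tgs)
    content = np.full((B, T), PAD, dtype=np.int64)
    types = np.zeros((B, T), dtype=np.int64)
    u = np.zeros((B, T), dtype=np.int64)
    v = np.zeros((B, T), dtype=np.int64)
    mask = np.zeros((B, T), dtype=bool)
    lengths = np.zeros(B, dtype=np.int64)
    for i, tg in enumerate(tgs):
        t = len(tg)
        content[i, :t] = tg.content_ids
        types[i, :t] = tg.types
        ep = np.asarray(tg.endpoints, dtype=np.int64)
        u[i, :t] = ep[:, 0]
        v[i, :t] = ep[:, 1]
        mask[i, :t] = True
        lengths[i] = t
    return Batch(content, types, u, v, mask, lengths)


# ---------------------------------------------------------------------------
# numerics helpers

def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0))) + x * phi


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


_LN_EPS = 1e-5


def _layernorm_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dgamma = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    dbeta = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m = dxhat.mean(-1, keepdims=True)
    mx = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m - xhat * mx)
    return dx, dgamma, dbeta


class GlycanEncoder:
    """The full encoder: parameters, forward, backward, MLM heads."""

    def __init__(self, cfg: ModelConfig, bank: IdentifierBank | None = None):
        if bank is None:
            bank = IdentifierBank(cfg.identifier_dim, cfg.seed)
        if bank.d_p != cfg.identifier_dim:
            raise ValueError("identifier bank dimension mismatch")
        self.cfg = cfg
        self.bank = bank
        self.params = self._init_params()

    # -- parameters --------------------------------------------------------
    def _init_params(self) -> dict[str, np.ndarray]:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed + 1)
        d, dp = cfg.d, cfg.identifier_dim
        s = 1.0 / np.sqrt(d)

        def lin(shape, scale):
            return rng.standard_normal(shape) * scale

        p: dict[str, np.ndarray] = {
            "emb.node": lin((cfg.node_vocab_size, d), 0.02),
            "emb.edge": lin((cfg.edge_vocab_size, d), 0.02),
            "emb.graph": lin((d,), 0.02),
            "emb.type": lin((3, d), 0.02),
            "emb.Wid": lin((2 * dp, d), 1.0 / np.sqrt(2 * dp)),
            "head.node.b": np.zeros(cfg.node_vocab_size),
            "head.edge.b": np.zeros(cfg.edge_vocab_size),
        }
        if not cfg.tie_heads:
            p["head.node.W"] = lin((d, cfg.node_vocab_size), s)
            p["head.edge.W"] = lin((d, cfg.edge_vocab_size), s)
        for l in range(cfg.depth):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"l{l}.attn.{name}"] = lin((d, d), s)
                p[f"l{l}.attn.{name[:1].lower()}b_{name[1:].lower()}"] = np.zeros(d)
            p[f"l{l}.ln1.g"] = np.ones(d)
            p[f"l{l}.ln1.b"] = np.zeros(d)
            p[f"l{l}.mlp.W1"] = lin((d, 4 * d), s)
            p[f"l{l}.mlp.b1"] = np.zeros(4 * d)
            p[f"l{l}.mlp.W2"] = lin((4 * d, d), 1.0 / np.sqrt(4 * d))
            p[f"l{l}.mlp.b2"] = np.zeros(d)
            p[f"l{l}.ln2.g"] = np.ones(d)
            p[f"l{l}.ln2.b"] = np.zeros(d)
        return p

    # -- embedding ---------------------------------------------------------
    def embed_tokens(self, batch: Batch) -> tuple[np.ndarray, dict]:
        """Input embeddings: content + identifier projection + type."""
        cfg, p, P = self.cfg, self.params, self.bank.P
        if batch.u.max(initial=0) >= cfg.max_nodes or \
           batch.v.max(initial=0) >= cfg.max_nodes:
            raise ValueError(
                f"glycan too large for identifier bank "
                f"(node index >= max_nodes={cfg.max_nodes})"
            )
        B, T = batch.content.shape
        is_node = batch.types == NODE
        is_edge = batch.types == EDGE
        is_graph = (batch.types == GRAPH_TYPE) & batch.mask

        content = np.zeros((B, T, cfg.d))
        content[is_node] = p["emb.node"][batch.content[is_node]]
        content[is_edge] = p["emb.edge"][batch.content[is_edge]]
        content[is_graph] = p["emb.graph"]

        ident = np.concatenate([P[batch.u], P[batch.v]], axis=-1)  # (B,T,2dp)
        ident[is_graph] = 0.0
        ident[~batch.mask] = 0.0
        x_id = ident @ p["emb.Wid"]

        type_emb = p["emb.type"][batch.types]
        x = content + x_id + type_emb
        x[~batch.mask] = 0.0
        cache = {"ident": ident, "is_node": is_node, "is_edge": is_edge,
                 "is_graph": is_graph, "batch": batch}
        return x, cache

    # -- forward -----------------------------------------------------------
    def forward(
        self,
        batch: Batch,
        *,
        train: bool = False,
        rng: np.random.Generator | None = None,
        return_attention: bool = False,
        return_cache: bool = False,
    ):
        """Run the encoder.

        In training mode, dropout is applied after the attention projection
        and the MLP output using ``rng``; in inference mode the pass is
        deterministic.  Returns :class:`EncoderOutput`, plus the backprop
        cache when ``return_cache`` is set.
        """
        cfg, p = self.cfg, self.params
        drop = cfg.dropout if train else 0.0
        if drop > 0 and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        x, emb_cache = self.embed_tokens(batch)
        B, T, d = x.shape
        H = cfg.heads
        dh = d // H
        key_mask = np.where(batch.mask, 0.0, _NEG)[:, None, None, :]

        caches = []
        attn_maps = [] if return_attention else None
        for l in range(cfg.depth):
            x_in = x
            q = x @ p[f"l{l}.attn.Wq"] + p[f"l{l}.attn.wb_q"]
            k = x @ p[f"l{l}.attn.Wk"] + p[f"l{l}.attn.wb_k"]
            v = x @ p[f"l{l}.attn.Wv"] + p[f"l{l}.attn.wb_v"]
            qh = q.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            kh = k.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            vh = v.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh)
            scores = scores + key_mask
            attn = _softmax(scores, axis=-1)
            if attn_maps is not None:
                attn_maps.append(attn)
            ctx = attn @ vh                       # (B,H,T,dh)
            ctx2 = ctx.transpose(0, 2, 1, 3).reshape(B, T, d)
            a_out = ctx2 @ p[f"l{l}.attn.Wo"] + p[f"l{l}.attn.wb_o"]
            if drop > 0:
                m1 = (rng.random(a_out.shape) >= drop) / (1.0 - drop)
                a_out = a_out * m1
            else:
                m1 = None
            res1 = x_in + a_out
            x1, ln1_cache = _layernorm_fwd(res1, p[f"l{l}.ln1.g"], p[f"l{l}.ln1.b"])

            z = x1 @ p[f"l{l}.mlp.W1"] + p[f"l{l}.mlp.b1"]
            hgel = _gelu(z)
            f = hgel @ p[f"l{l}.mlp.W2"] + p[f"l{l}.mlp.b2"]
            if drop > 0:
                m2 = (rng.random(f.shape) >= drop) / (1.0 - drop)
                f = f * m2
            else:
                m2 = None
            res2 = x1 + f
            x2, ln2_cache = _layernorm_fwd(res2, p[f"l{l}.ln2.g"], p[f"l{l}.ln2.b"])

            caches.append({
                "x_in": x_in, "qh": qh, "kh": kh, "vh": vh, "attn": attn,
                "ctx2": ctx2, "m1": m1, "ln1": ln1_cache, "x1": x1,
                "z": z, "hgel": hgel, "m2": m2, "ln2": ln2_cache,
            })
            x = x2

        x = x * batch.mask[:, :, None]
        out = EncoderOutput(
            token_states=x,
            graph_embedding=x[:, 0, :],
            mask=batch.mask,
            attention_maps=np.stack(attn_maps) if attn_maps else None,
        )
        if return_cache:
            return out, {"emb": emb_cache, "layers": caches, "batch": batch}
        return out

    # -- heads -------------------------------------------------------------
    def mlm_heads(self, token_states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Node-vocab and edge-vocab logits at every position.

        With ``tie_heads`` (default) the output projections are the
        transposed content-embedding tables, the usual weight tying of
        masked-language models; biases stay separate."""
        p = self.params
        w_n = p["emb.node"].T if self.cfg.tie_heads else p["head.node.W"]
        w_e = p["emb.edge"].T if self.cfg.tie_heads else p["head.edge.W"]
        node_logits = token_states @ w_n + p["head.node.b"]
        edge_logits = token_states @ w_e + p["head.edge.b"]
        return node_logits, edge_logits

    @staticmethod
    def content_log_probs(logits: np.ndarray) -> np.ndarray:
        """Log-softmax restricted to content classes (specials excluded)."""
        masked = logits.copy()
        masked[..., list(SPECIALS.values())] = _NEG
        z = masked - masked.max(-1, keepdims=True)
        return z - np.log(np.exp(z).sum(-1, keepdims=True))

    # -- backward ----------------------------------------------------------
    def backward(self, cache: dict, d_states: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss wrt all trainable parameters, given
        d(loss)/d(token_states)."""
        cfg, p = self.cfg, self.params
        batch: Batch = cache["batch"]
        B, T = batch.content.shape
        d = cfg.d
        H = cfg.heads
        dh = d // H
        grads: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in p.items()}
        dx = d_states * batch.mask[:, :, None]

        for l in reversed(range(cfg.depth)):
            c = cache["layers"][l]
            # LN2
            dres2, dg2, db2 = _layernorm_bwd(dx, c["ln2"])
            grads[f"l{l}.ln2.g"] += dg2
            grads[f"l{l}.ln2.b"] += db2
            df = dres2.copy()
            if c["m2"] is not None:
                df = df * c["m2"]
            grads[f"l{l}.mlp.W2"] += c["hgel"].reshape(-1, c["hgel"].shape[-1]).T @ df.reshape(-1, d)
            grads[f"l{l}.mlp.b2"] += df.sum((0, 1))
            dhgel = df @ p[f"l{l}.mlp.W2"].T
            dz = dhgel * _gelu_grad(c["z"])
            grads[f"l{l}.mlp.W1"] += c["x1"].reshape(-1, d).T @ dz.reshape(-1, dz.shape[-1])
            grads[f"l{l}.mlp.b1"] += dz.sum((0, 1))
            dx1 = dres2 + dz @ p[f"l{l}.mlp.W1"].T
            # LN1
            dres1, dg1, db1 = _layernorm_bwd(dx1, c["ln1"])
            grads[f"l{l}.ln1.g"] += dg1
            grads[f"l{l}.ln1.b"] += db1
            da_out = dres1.copy()
            if c["m1"] is not None:
                da_out = da_out * c["m1"]
            grads[f"l{l}.attn.Wo"] += c["ctx2"].reshape(-1, d).T @ da_out.reshape(-1, d)
            grads[f"l{l}.attn.wb_o"] += da_out.sum((0, 1))
            dctx2 = da_out @ p[f"l{l}.attn.Wo"].T
            dctx = dctx2.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            attn = c["attn"]
            dattn = dctx @ c["vh"].transpose(0, 1, 3, 2)
            dvh = attn.transpose(0, 1, 3, 2) @ dctx
            dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
            dscores /= np.sqrt(dh)
            dqh = dscores @ c["kh"]
            dkh = dscores.transpose(0, 1, 3, 2) @ c["qh"]
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, d)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, d)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, d)
            x_in = c["x_in"]
            grads[f"l{l}.attn.Wq"] += x_in.reshape(-1, d).T @ dq.reshape(-1, d)
            grads[f"l{l}.attn.wb_q"] += dq.sum((0, 1))
            grads[f"l{l}.attn.Wk"] += x_in.reshape(-1, d).T @ dk.reshape(-1, d)
            grads[f"l{l}.attn.wb_k"] += dk.sum((0, 1))
            grads[f"l{l}.attn.Wv"] += x_in.reshape(-1, d).T @ dv.reshape(-1, d)
            grads[f"l{l}.attn.wb_v"] += dv.sum((0, 1))
            dx = (dres1
                  + dq @ p[f"l{l}.attn.Wq"].T
                  + dk @ p[f"l{l}.attn.Wk"].T
                  + dv @ p[f"l{l}.attn.Wv"].T)

        # embedding
        emb = cache["emb"]
        dx = dx * batch.mask[:, :, None]
        is_node, is_edge, is_graph = emb["is_node"], emb["is_edge"], emb["is_graph"]
        np.add.at(grads["emb.node"], batch.content[is_node], dx[is_node])
        np.add.at(grads["emb.edge"], batch.content[is_edge], dx[is_edge])
        grads["emb.graph"] += dx[is_graph].sum(0)
        np.add.at(grads["emb.type"], batch.types[batch.mask], dx[batch.mask])
        ident = emb["ident"]
        grads["emb.Wid"] += ident.reshape(-1, ident.shape[-1]).T @ dx.reshape(-1, cfg.d)
        return grads

    # convenience: head gradients feed into d_states
    def head_backward(
        self,
        token_states: np.ndarray,
        d_node_logits: np.ndarray,
        d_edge_logits: np.ndarray,
        grads: dict[str, np.ndarray],
    ) -> np.ndarray:
        p = self.params
        d = token_states.shape[-1]
        ts2 = token_states.reshape(-1, d)
        dwn = ts2.T @ d_node_logits.reshape(-1, d_node_logits.shape[-1])
        dwe = ts2.T @ d_edge_logits.reshape(-1, d_edge_logits.shape[-1])
        grads["head.node.b"] += d_node_logits.sum((0, 1))
        grads["head.edge.b"] += d_edge_logits.sum((0, 1))
        if self.cfg.tie_heads:
            grads["emb.node"] += dwn.T
            grads["emb.edge"] += dwe.T
            w_n, w_e = p["emb.node"].T, p["emb.edge"].T
        else:
            grads["head.node.W"] += dwn
            grads["head.edge.W"] += dwe
            w_n, w_e = p["head.node.W"], p["head.edge.W"]
        return d_node_logits @ w_n.T + d_edge_logits @ w_e.T


# ---------------------------------------------------------------------------
# checkpoints

def _vocab_fingerprint(vocab: Vocabulary) -> str:
    payload = json.dumps(
        [sorted(vocab.node_vocab.items()), sorted(vocab.edge_vocab.items())]
    ).encode()
    return hashlib.sha256(payload).hexdigest()


def save_checkpoint(path: str | Path, enc: GlycanEncoder,
                    vocab: Vocabulary, extra: dict | None = None) -> None:
    """Single .npz archive: config, vocab (and its hash), seed, parameters."""
    meta = {
        "config": asdict(enc.cfg),
        "vocab_hash": _vocab_fingerprint(vocab),
        "node_vocab": vocab.node_vocab,
        "edge_vocab": vocab.edge_vocab,
        "extra": extra or {},
    }
    arrays = {f"param:{k}": v for k, v in enc.params.items()}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path,
                    vocab: Vocabulary | None = None
                    ) -> tuple[GlycanEncoder, Vocabulary, dict]:
    """Load a checkpoint; verifies vocab compatibility if one is supplied."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        params = {k[len("param:"):]: z[k] for k in z.files if k.startswith("param:")}
    ck_vocab = Vocabulary(
        {k: int(v) for k, v in meta["node_vocab"].items()},
        {k: int(v) for k, v in meta["edge_vocab"].items()},
    )
    if vocab is not None and _vocab_fingerprint(vocab) != meta["vocab_hash"]:
        raise ValueError("checkpoint was trained with a different vocabulary")
    cfg = ModelConfig(**meta["config"])
    enc = GlycanEncoder(cfg)
    for k in enc.params:
        enc.params[k] = params[k]
    return enc, ck_vocab, meta.get("extra", {})
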