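"""Ambiguous-sequence completion: scenario masking, ranking, hit@K.

Public glycan repositories contain many entries with unknown residues or
linkages.  Two empirical ambiguity patterns are simulated here:

* ``LINKAGES_INTACT`` — all glycosidic bonds known, 10–90% of
  monosaccharides unknown;
* ``LINKAGES_ALL_MASKED`` — every bond unknown, 0–90% of monosaccharides
  unknown.

In the second scenario terminal bonds are masked at input time too (a real
ambiguous entry hides them as well), but they are never scored: they stay
excluded from prediction targets, exactly as during pretraining.

For each masked position the model's head yields a softmax distribution over
the content vocabulary (special tokens excluded); candidates are ranked by
descending probability and scored with hit@K — the fraction of masked
positions whose true token appears in the top K.  Node and edge targets are
reported separately; averaging is micro (over positions) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .model import GlycanEncoder
from .tokenizer import SPECIALS, TokenizedGraph, Vocabulary
from .training import MaskingPlan, apply_masking, make_masking_plan

__all__ = [
    "ScenarioKind", "AmbiguityScenario", "RankedPrediction",
    "apply_scenario", "rank_candidates", "hit_at_k", "evaluate_completion",
    "DEFAULT_KS",
]

DEFAULT_KS = (1, 2, 3, 5, 10, 20, 30)


class ScenarioKind(str, Enum):
    LINKAGES_INTACT = "linkages_intact"
    LINKAGES_ALL_MASKED = "linkages_all_masked"


_GRIDS = {
    ScenarioKind.LINKAGES_INTACT: np.round(np.arange(0.1, 0.91, 0.1), 1),
    ScenarioKind.LINKAGES_ALL_MASKED: np.round(np.arange(0.0, 0.91, 0.1), 1),
}


@dataclass(frozen=True)
class AmbiguityScenario:
    kind: ScenarioKind
    mono_mask_ratio: float
    seed: int = 0

    def __post_init__(self) -> None:
        grid = _GRIDS[self.kind]
        if not np.any(np.isclose(self.mono_mask_ratio, grid)):
            warnings.warn(
                f"mono_mask_ratio {self.mono_mask_ratio} is off the standard "
                f"grid {list(grid)} for {self.kind.value}; proceeding",
                stacklevel=2,
            )


def apply_scenario(tg: TokenizedGraph, scenario: AmbiguityScenario) -> MaskingPlan:
    """Build the masking plan one scenario implies for one glycan.

    ``LINKAGES_INTACT`` masks only monosaccharides, at the given ratio.
    ``LINKAGES_ALL_MASKED`` masks every edge token; non-terminal bonds are
    scored targets while terminal bonds are input-only masks.
    """
    if scenario.kind is ScenarioKind.LINKAGES_INTACT:
        return make_masking_plan(tg, scenario.mono_mask_ratio, 0.0, scenario.seed)
    plan = make_masking_plan(tg, scenario.mono_mask_ratio, 1.0, scenario.seed)
    terminal = tuple(
        pos for j, pos in enumerate(tg.edge_positions)
        if tg.terminal_edge_flags[j]
    )
    return MaskingPlan(
        masked_node_positions=plan.masked_node_positions,
        masked_edge_positions=plan.masked_edge_positions,
        node_ratio=plan.node_ratio,
        edge_ratio=1.0,
        seed=plan.seed,
        masked_input_only=terminal,
    )


@dataclass(frozen=True)
class RankedPrediction:
    """Full-vocabulary ranking for one masked position."""

    glycan_index: int
    position: int
    target_type: Literal["node", "edge"]
    true_id: int
    ranked_ids: tuple[int, ...]       # content ids, best first
    probabilities: tuple[float, ...]  # matching, descending

    @property
    def rank_of_truth(self) -> int:
        """1-based rank of the true token."""
        return self.ranked_ids.index(self.true_id) + 1


def rank_candidates(
    enc: GlycanEncoder,
    tgs: Sequence[TokenizedGraph],
    plans: Sequence[MaskingPlan],
    vocab: Vocabulary,
    batch_size: int = 64,
) -> list[RankedPrediction]:
    """Softmax-rank content-vocabulary candidates at every scored masked
    position.  Special tokens are excluded from the candidate set."""
    if len(tgs) != len(plans):
        raise ValueError("one plan per glycan required")
    if enc.cfg.node_vocab_size != vocab.node_size or \
       enc.cfg.edge_vocab_size != vocab.edge_size:
        raise ValueError("checkpoint vocabulary does not match supplied vocab")
    preds: list[RankedPrediction] = []
    node_content = np.array(vocab.content_ids("node"))
    edge_content = np.array(vocab.content_ids("edge"))
    for start in range(0, len(tgs), batch_size):
        chunk_t = tgs[start:start + batch_size]
        chunk_p = plans[start:start + batch_size]
        batch, _, _ = apply_masking(chunk_t, chunk_p)
        out = enc.forward(batch)
        node_logits, edge_logits = enc.mlm_heads(out.token_states)
        for b, plan in enumerate(chunk_p):
            for target_type, positions, logits, content in (
                ("node", plan.masked_node_positions, node_logits, node_content),
                ("edge", plan.masked_edge_positions, edge_logits, edge_content),
            ):
                for pos, true_id in positions:
                    logp = GlycanEncoder.content_log_probs(logits[b, pos])
                    p = np.exp(logp[content])
                    p = p / p.sum()
                    order = np.argsort(-p, kind="stable")
                    preds.append(RankedPrediction(
                        glycan_index=start + b,
                        position=pos,
                        target_type=target_type,
                        true_id=int(true_id),
                        ranked_ids=tuple(int(i) for i in content[order]),
                        probabilities=tuple(float(x) for x in p[order]),
                    ))
    return preds


def hit_at_k(
    predictions: Sequence[RankedPrediction],
    ks: Sequence[int] = DEFAULT_KS,
    average: Literal["micro", "macro"] = "micro",
) -> dict[str, dict[int, float]]:
    """hit@K per target type: fraction of masked positions whose true token
    ranks within the top K.  ``macro`` averages per-glycan hit rates
    instead of pooling positions."""
    if not predictions:
        raise ValueError("no predictions to score")
    if any(k <= 0 for k in ks):
        raise ValueError("K values must be positive")
    out: dict[str, dict[int, float]] = {}
    for target_type in ("node", "edge"):
        sub = [p for p in predictions if p.target_type == target_type]
        if not sub:
            continue
        ranks = np.array([p.rank_of_truth for p in sub])
        if average == "micro":
            out[target_type] = {k: float((ranks <= k).mean()) for k in ks}
        else:
            gids = np.array([p.glycan_index for p in sub])
            res = {}
            for k in ks:
                hit = ranks <= k
                per_glycan = [hit[gids == g].mean() for g in np.unique(gids)]
                res[k] = float(np.mean(per_glycan))
            out[target_type] = res
    return out


def evaluate_completion(
    enc: GlycanEncoder,
    tgs: Sequence[TokenizedGraph],
    vocab: Vocabulary,
    kind: ScenarioKind,
    mono_ratios: Sequence[float],
    ks: Sequence[int] = DEFAULT_KS,
    seed: int = 0,
) -> pd.DataFrame:
    """Full scenario sweep; returns a tidy table
    (scenario, mono_ratio, target_type, K, hit_rate, n_targets)."""
    rows = []
    for ratio in mono_ratios:
        scen_seed = int(np.random.SeedSequence([seed, int(round(ratio * 100))])
                        .generate_state(1)[0] % (2 ** 31))
        plans = [
            apply_scenario(tg, AmbiguityScenario(kind, ratio, scen_seed + i))
            for i, tg in enumerate(tgs)
        ]
        preds = rank_candidates(enc, tgs, plans, vocab)
        if not preds:
            continue
        table = hit_at_k(preds, ks)
        for target_type, by_k in table.items():
            n = sum(1 for p in preds if p.target_type == target_type)
            for k, rate in by_k.items():
                rows.append({
                    "scenario": kind.value, "mono_ratio": ratio,
                    "target_type": target_type, "K": k,
                    "hit_rate": rate, "n_targets": n,
                })
    return pd.DataFrame(rows)
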