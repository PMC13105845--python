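"""Toy glycan generator: branched trees from a probabilistic grammar.

Real pretraining corpora (tens of thousands of curated repository entries)
cannot ship with the package, so tests and desk-scale experiments run on
glycans sampled from a small grammar with two engineered properties:

* the linkage between a parent and a child residue is a *deterministic*
  function of the two residues, so a model that sees (or can infer) both
  endpoints of a bond can reach top-1 linkage accuracy of 1.0 — masked-bond
  completion has an exact ceiling;
* each residue's children are drawn from a parent-specific categorical
  distribution, so masked residues are predictable well above chance from
  their parent and their visible bond labels, but not perfectly — mimicking
  genuine annotation ambiguity.

The family label attached to each glycan is its root (reducing-end)
residue, which gives downstream classification tests a linearly decodable
target.  Default sizes keep glycans in the 5–20 residue regime typical of
repository entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graphs import GlycanGraph, serialize_iupac

__all__ = ["ToyGrammar", "generate_corpus", "make_fixtures", "FixtureSet"]

DEFAULT_MONO = (
    "Gal", "Glc", "Man", "GlcNAc", "GalNAc",
    "NeuNAc", "Fuc", "Xyl", "GlcA", "Rha",
)
DEFAULT_LINKAGES = (
    "a1-2", "a1-3", "a1-4", "a1-6", "b1-2", "b1-3", "b1-4", "b1-6",
)
# child-slot probabilities: skewed so that the rare positions where no
# visible context pins a masked token down are still guessable with high
# probability (keeps the generator's exact-recovery guarantee near 1.0),
# while node completion remains stochastic rather than trivially determined
_CHILD_PROBS = (0.85, 0.15)


def _default_children(mono: Sequence[str]) -> dict[str, tuple[tuple[str, ...], tuple[float, ...]]]:
    n = len(mono)
    out = {}
    for i, parent in enumerate(mono):
        kids = tuple(mono[(i + off) % n] for off in (1, 3))
        out[parent] = (kids, _CHILD_PROBS[: len(kids)])
    return out


def _default_linkage_rule(
    mono: Sequence[str],
    linkages: Sequence[str],
    children: dict[str, tuple[tuple[str, ...], tuple[float, ...]]],
) -> dict[tuple[str, str], str]:
    """Maximally context-determined: label = linkages[(2 i_parent + slot) % 8]
    where slot is the child's position in the parent's allowed-child list.

    With two allowed children per parent the label sets of any one parent,
    of a child's two candidate parents, and of a grandparent's two allowed
    children are all pairwise disjoint, so (parent, label) -> child,
    (child, label) -> parent and even (grandparent, label) -> (parent,
    child) are unique, and every visible bond pins both of its endpoints
    modulo 4.  Masked bonds are therefore deducible from almost any
    surviving local context — the exact-recovery ceiling the generator
    promises."""
    rule: dict[tuple[str, str], str] = {}
    for i, parent in enumerate(mono):
        kids, _ = children[parent]
        for j, child in enumerate(kids):
            rule[(parent, child)] = linkages[(2 * i + j) % len(linkages)]
    return rule


@dataclass(frozen=True)
class ToyGrammar:
    """A stated world for offline testing; see module docstring."""

    mono_vocab: tuple[str, ...] = DEFAULT_MONO
    linkage_vocab: tuple[str, ...] = DEFAULT_LINKAGES
    child_distribution: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = field(
        default_factory=lambda: _default_children(DEFAULT_MONO))
    linkage_rule: dict[tuple[str, str], str] | None = None
    branch_prob: float = 0.3
    stop_prob: float = 0.30
    max_depth: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.linkage_rule is None:
            object.__setattr__(
                self, "linkage_rule",
                _default_linkage_rule(self.mono_vocab, self.linkage_vocab,
                                      self.child_distribution),
            )
        for parent, (kids, probs) in self.child_distribution.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"child probabilities for {parent} must sum to 1")
            for child in kids:
                if (parent, child) not in self.linkage_rule:
                    raise ValueError(
                        f"no linkage rule for allowed pair ({parent}, {child})"
                    )

    def sample_tree(self, rng: np.random.Generator) -> GlycanGraph:
        """Depth-first sampling from the reducing end outward."""
        labels: list[str] = []
        edges: list[tuple[int, int, str]] = []

        def grow(parent_idx: int, depth: int) -> None:
            # depth is the parent's level (root = 0); max_depth counts levels
            if depth >= self.max_depth - 1:
                return
            if rng.random() < self.stop_prob and depth > 0:
                return
            n_children = 2 if rng.random() < self.branch_prob else 1
            parent_lab = labels[parent_idx]
            kids, probs = self.child_distribution[parent_lab]
            for _ in range(n_children):
                child_lab = kids[rng.choice(len(kids), p=np.asarray(probs))]
                child_idx = len(labels)
                labels.append(child_lab)
                edges.append(
                    (child_idx, parent_idx, self.linkage_rule[(parent_lab, child_lab)])
                )
                grow(child_idx, depth + 1)

        root_lab = self.mono_vocab[rng.integers(len(self.mono_vocab))]
        labels.append(root_lab)
        grow(0, 0)
        return GlycanGraph(tuple(labels), tuple(edges), root=0)


def generate_corpus(
    grammar: ToyGrammar, n: int, seed: int | None = None
) -> list[tuple[str, str]]:
    """Sample ``n`` glycans; returns (IUPAC-condensed string, family label).

    The family label is the root residue.  Deterministic under
    ``seed`` (defaults to the grammar's own seed).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(grammar.seed if seed is None else seed)
    out = []
    for _ in range(n):
        tree = grammar.sample_tree(rng)
        out.append((serialize_iupac(tree), tree.nodes[tree.root]))
    return out


@dataclass(frozen=True)
class FixtureSet:
    """Small bundled corpus: repository-style printed strings plus
    grammar-generated glycans with known parse trees."""

    printed_resolved: tuple[str, ...]
    printed_preexpansion: tuple[str, ...]   # contain '/', expandable
    generated: tuple[str, ...]

    @property
    def all_strings(self) -> tuple[str, ...]:
        return self.printed_resolved + self.printed_preexpansion + self.generated

    @property
    def resolved(self) -> tuple[str, ...]:
        return self.printed_resolved + self.generated


def make_fixtures(n_generated: int = 20, seed: int = 42) -> FixtureSet:
    """Standard fixture bundle (>= 24 strings).

    Includes classic mucin-type O-glycan cores, a sialyl motif before
    linkage expansion, and a residue carrying a chemical-modification
    suffix kept verbatim as its own token.
    """
    printed_resolved = (
        "Gal(b1-3)GalNAc",                    # O-glycan core 1
        "GlcNAc(b1-6)GalNAc",                 # O-glycan core 6
        "GalNAc3,4,6Ac3",                     # modified residue, one token
        "Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc",  # N-glycan core
    )
    printed_preexpansion = ("NeuNAc(a2-3/6)Gal",)
    grammar = ToyGrammar(seed=seed)
    generated = tuple(s for s, _ in generate_corpus(grammar, n_generated, seed))
    return FixtureSet(printed_resolved, printed_preexpansion, generated)
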