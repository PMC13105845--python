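"""Vocabularies and flat token sequences for the graph transformer.

Every monosaccharide residue and every glycosidic bond becomes an
independent token.  Residue tokens and linkage tokens live in two disjoint
id spaces (the model has two classification heads), each with its own
reserved special ids.  A tokenized glycan is the sequence

    [Graph], node_0 ... node_{n-1}, edge_0 ... edge_{m-1}

where each token carries an (u, v) endpoint pair: a node token for node v
carries (v, v), an edge token for bond child->parent carries (child, parent).
The endpoints select orthonormal identifier vectors at embedding time, which
is how the encoder sees connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .graphs import GlycanGraph

__all__ = ["Vocabulary", "TokenizedGraph", "build_vocab", "encode",
           "SPECIALS", "MASK", "PAD", "UNK", "GRAPH"]

# reserved ids, identical in both vocab spaces
MASK, PAD, UNK, GRAPH = 0, 1, 2, 3
SPECIALS = {"<mask>": MASK, "<pad>": PAD, "<unk>": UNK, "<graph>": GRAPH}

NODE, EDGE, GRAPH_TYPE = 0, 1, 2  # token type codes

_VOCAB_HEADER = "# glycoformer vocab v1"


@dataclass(frozen=True)
class Vocabulary:
    """Paired monosaccharide / linkage dictionaries with shared specials.

    Ids are contiguous; the four specials occupy ids 0..3 in both spaces and
    content tokens start at 4.  The two spaces are disjoint: a node id and an
    edge id never refer to the same dictionary.
    """

    node_vocab: dict[str, int]
    edge_vocab: dict[str, int]

    def __post_init__(self) -> None:
        for name, vocab in (("node", self.node_vocab), ("edge", self.edge_vocab)):
            ids = sorted(vocab.values())
            if ids != list(range(len(ids))):
                raise ValueError(f"{name} vocab ids not contiguous from 0")
            for tok, i in SPECIALS.items():
                if vocab.get(tok) != i:
                    raise ValueError(f"{name} vocab missing special {tok!r}")

    @property
    def node_size(self) -> int:
        return len(self.node_vocab)

    @property
    def edge_size(self) -> int:
        return len(self.edge_vocab)

    @property
    def n_specials(self) -> int:
        return len(SPECIALS)

    def node_id(self, label: str) -> int:
        return self.node_vocab.get(label, UNK)

    def edge_id(self, label: str) -> int:
        return self.edge_vocab.get(label, UNK)

    def node_label(self, idx: int) -> str:
        return self._rev_node[idx]

    def edge_label(self, idx: int) -> str:
        return self._rev_edge[idx]

    @property
    def _rev_node(self) -> dict[int, str]:
        return {i: s for s, i in self.node_vocab.items()}

    @property
    def _rev_edge(self) -> dict[int, str]:
        return {i: s for s, i in self.edge_vocab.items()}

    def content_ids(self, kind: Literal["node", "edge"]) -> list[int]:
        """Ids of real (non-special) tokens in one space, sorted."""
        vocab = self.node_vocab if kind == "node" else self.edge_vocab
        return sorted(i for s, i in vocab.items() if s not in SPECIALS)

    # -- persistence: plain text, token<TAB>id, one file per space ---------
    def save(self, node_path: str | Path, edge_path: str | Path) -> None:
        for path, vocab in ((node_path, self.node_vocab), (edge_path, self.edge_vocab)):
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(_VOCAB_HEADER + "\n")
                for tok, i in sorted(vocab.items(), key=lambda kv: kv[1]):
                    fh.write(f"{tok}\t{i}\n")

    @classmethod
    def load(cls, node_path: str | Path, edge_path: str | Path) -> "Vocabulary":
        def read(path):
            out: dict[str, int] = {}
            with open(path, encoding="utf-8") as fh:
                header = fh.readline().rstrip("\n")
                if header != _VOCAB_HEADER:
                    raise ValueError(f"unrecognized vocab header in {path}")
                for line in fh:
                    tok, i = line.rstrip("\n").split("\t")
                    out[tok] = int(i)
            return out

        return cls(read(node_path), read(edge_path))


@dataclass(frozen=True)
class TokenizedGraph:
    """Flat token view of one glycan, the unit consumed by the encoder.

    ``content_ids[k]``, ``types[k]`` and ``endpoints[k]`` describe token k.
    Position 0 is always the [Graph] summary token (endpoints (0, 0) by
    convention; it receives a zero identifier at embedding time).  Node
    tokens follow in node-index order, then edge tokens in child-index
    order.  ``terminal_edge_flags[j]`` marks edge token j as incident to a
    leaf (degree-1 non-root) node; such bonds have one-sided context and are
    excluded from masking targets.
    """

    content_ids: tuple[int, ...]
    types: tuple[int, ...]
    endpoints: tuple[tuple[int, int], ...]
    n_nodes: int
    n_edges: int
    terminal_edge_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.content_ids) != 1 + self.n_nodes + self.n_edges:
            raise ValueError("token count must be 1 + n_nodes + n_edges")
        if self.types[0] != GRAPH_TYPE:
            raise ValueError("position 0 must be the [Graph] token")
        if len(self.terminal_edge_flags) != self.n_edges:
            raise ValueError("one terminal flag per edge token")

    def __len__(self) -> int:
        return len(self.content_ids)

    @property
    def node_positions(self) -> range:
        return range(1, 1 + self.n_nodes)

    @property
    def edge_positions(self) -> range:
        return range(1 + self.n_nodes, 1 + self.n_nodes + self.n_edges)

    def eligible_edge_positions(self) -> list[int]:
        """Edge token positions that are valid masking targets
        (non-terminal bonds)."""
        start = 1 + self.n_nodes
        return [start + j for j in range(self.n_edges)
                if not self.terminal_edge_flags[j]]


def build_vocab(
    corpus: Iterable[GlycanGraph], min_count: int = 1
) -> Vocabulary:
    """Count labels over a corpus and assign contiguous ids.

    Labels seen fewer than ``min_count`` times are left out and will encode
    as UNK.  Content ids are assigned in (count-descending, label) order so
    that vocabulary construction is deterministic for a given corpus.
    """
    node_counts: dict[str, int] = {}
    edge_counts: dict[str, int] = {}
    n = 0
    for g in corpus:
        n += 1
        for lab in g.nodes:
            node_counts[lab] = node_counts.get(lab, 0) + 1
        for _, _, lab in g.edges:
            edge_counts[lab] = edge_counts.get(lab, 0) + 1
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")

    def assign(counts: dict[str, int]) -> dict[str, int]:
        vocab = dict(SPECIALS)
        kept = sorted(
            (lab for lab, c in counts.items() if c >= min_count),
            key=lambda lab: (-counts[lab], lab),
        )
        for lab in kept:
            vocab[lab] = len(vocab)
        return vocab

    return Vocabulary(assign(node_counts), assign(edge_counts))


def encode(g: GlycanGraph, vocab: Vocabulary) -> TokenizedGraph:
    """Convert a glycan tree into its flat token sequence."""
    content: list[int] = [GRAPH]
    types: list[int] = [GRAPH_TYPE]
    endpoints: list[tuple[int, int]] = [(0, 0)]

    for v, lab in enumerate(g.nodes):
        content.append(vocab.node_id(lab))
        types.append(NODE)
        endpoints.append((v, v))

    edges = sorted(g.edges, key=lambda e: e[0])  # child-index order
    flags: list[bool] = []
    for child, parent, lab in edges:
        content.append(vocab.edge_id(lab))
        types.append(EDGE)
        endpoints.append((child, parent))
        leaf = (g.degree(child) == 1 and child != g.root) or (
            g.degree(parent) == 1 and parent != g.root
        )
        flags.append(leaf)

    return TokenizedGraph(
        content_ids=tuple(content),
        types=tuple(types),
        endpoints=tuple(endpoints),
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        terminal_edge_flags=tuple(flags),
    )
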