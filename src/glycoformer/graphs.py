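"""Rooted labeled trees for glycans and IUPAC-condensed text handling.

A glycan is modeled as a rooted tree whose nodes are monosaccharide residues
(e.g. ``Gal``, ``GlcNAc``, ``NeuNAc``) and whose edges are glycosidic bonds
labeled with anomeric configuration and carbon positions (e.g. ``b1-3``).
The root is the reducing-end residue, i.e. the rightmost residue of the
IUPAC-condensed string.

The text grammar handled here:

* residues are read left (non-reducing termini) to right (reducing end);
* ``A(L)B`` makes residue ``A`` a child of residue ``B`` via a bond labeled
  ``L``;
* a bracketed substring ``[...]`` immediately preceding residue ``B`` is an
  independent branch whose root attaches to ``B`` with the branch's trailing
  linkage, e.g. ``Man(a1-3)[Man(a1-6)]Man`` gives the central Man two
  children.

Residue tokens are kept verbatim — stereochemistry prefixes and chemical
modifications such as ``GalNAc3,4,6Ac3`` stay inside the token; no chemical
normalization is attempted.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GlycanGraph",
    "CurationReport",
    "GlycanParseError",
    "AmbiguousGlycanError",
    "parse_iupac",
    "serialize_iupac",
    "curate_corpus",
    "read_corpus",
    "expand_ambiguous_linkages",
]


class GlycanParseError(ValueError):
    """Malformed IUPAC-condensed text (unbalanced brackets, empty tokens...)."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)
        self.offset = offset


class AmbiguousGlycanError(ValueError):
    """The string contains ambiguity markers ('?' or '/') and cannot be
    parsed as a fully resolved structure; callers decide filter vs expand."""


@dataclass(frozen=True)
class GlycanGraph:
    """A rooted labeled tree: monosaccharide nodes, glycosidic-bond edges.

    ``nodes[i]`` is the label of node ``i``; node indices follow the textual
    left-to-right order of residues in the source notation.  Each edge is a
    ``(child, parent, label)`` triple — the familiar head–relation–tail
    reading of the notation.  ``root`` is the reducing-end residue.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[int, int, str], ...]
    root: int

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if n == 0:
            raise GlycanParseError("glycan has no residues")
        if len(self.edges) != n - 1:
            raise GlycanParseError(
                f"not a tree: {n} nodes but {len(self.edges)} edges"
            )
        if not (0 <= self.root < n):
            raise GlycanParseError(f"root index {self.root} out of range")
        parents: dict[int, int] = {}
        for child, parent, label in self.edges:
            if child in parents:
                raise GlycanParseError(f"node {child} has two parents")
            if not label:
                raise GlycanParseError("empty linkage label")
            parents[child] = parent
        if self.root in parents:
            raise GlycanParseError("root must not have a parent")
        # connectivity: walk up from every node to the root
        for v in range(n):
            seen = set()
            while v != self.root:
                if v in seen or v not in parents:
                    raise GlycanParseError("graph is not connected to root")
                seen.add(v)
                v = parents[v]
        for label in self.nodes:
            if not label:
                raise GlycanParseError("empty residue label")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def children(self, v: int) -> list[tuple[int, str]]:
        """(child_index, linkage) pairs for node ``v``, in edge order."""
        return [(c, l) for c, p, l in self.edges if p == v]

    def degree(self, v: int) -> int:
        return sum(1 for c, p, _ in self.edges if c == v or p == v)

    def to_networkx(self):
        """Undirected networkx.Graph with 'label' attributes (for kernels)."""
        import networkx as nx

        g = nx.Graph()
        for i, lab in enumerate(self.nodes):
            g.add_node(i, label=lab)
        for child, parent, lab in self.edges:
            g.add_edge(child, parent, label=lab)
        return g


_TOKEN_RE = re.compile(r"\(|\)|\[|\]|[^()\[\]]+")
_AMBIG_CHARS = ("?", "/")


def _lex(text: str) -> list[tuple[str, str, int]]:
    """Split into (kind, value, offset) tokens: RES, LINK, '[', ']'."""
    out: list[tuple[str, str, int]] = []
    i = 0
    depth_paren = 0
    for m in _TOKEN_RE.finditer(text):
        tok = m.group(0)
        if tok == "(":
            if depth_paren:
                raise GlycanParseError("nested '(' not allowed", m.start())
            depth_paren = 1
            out.append(("(", tok, m.start()))
        elif tok == ")":
            if not depth_paren:
                raise GlycanParseError("unbalanced ')'", m.start())
            depth_paren = 0
            out.append((")", tok, m.start()))
        elif tok in ("[", "]"):
            if depth_paren:
                raise GlycanParseError("bracket inside linkage", m.start())
            out.append((tok, tok, m.start()))
        else:
            kind = "LINK" if depth_paren else "RES"
            out.append((kind, tok, m.start()))
        i = m.end()
    if depth_paren:
        raise GlycanParseError("unbalanced '('", len(text))
    return out


def parse_iupac(text: str, *, allow_ambiguous: bool = False) -> GlycanGraph:
    """Parse IUPAC-condensed notation into a :class:`GlycanGraph`.

    Parameters
    ----------
    text:
        e.g. ``"Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"``.
    allow_ambiguous:
        when False (default), any ``?`` or ``/`` raises
        :class:`AmbiguousGlycanError` so the caller can filter or expand.

    Returns
    -------
    GlycanGraph with node indices in textual left-to-right residue order and
    the reducing-end (rightmost) residue as root.
    """
    if not text or not text.strip():
        raise GlycanParseError("empty glycan string")
    text = text.strip()
    if not allow_ambiguous:
        for ch in _AMBIG_CHARS:
            if ch in text:
                raise AmbiguousGlycanError(
                    f"ambiguous symbol {ch!r} in {text!r}; "
                    "curate (filter/expand) before parsing"
                )

    tokens = _lex(text)

    nodes: list[str] = []
    edges: list[tuple[int, int, str]] = []
    # pending: completed subtrees (by root node idx) waiting, with their
    # trailing linkage, to attach to the next residue at this bracket level
    pending: list[tuple[int, str]] = []
    stack: list[list[tuple[int, str]]] = []
    last_node: int | None = None  # residue not yet given a trailing linkage

    i = 0
    while i < len(tokens):
        kind, value, off = tokens[i]
        if kind == "RES":
            value = value.strip()
            if not value:
                raise GlycanParseError("empty residue token", off)
            idx = len(nodes)
            nodes.append(value)
            for child, link in pending:
                edges.append((child, idx, link))
            pending = []
            last_node = idx
            i += 1
        elif kind == "(":
            if last_node is None:
                raise GlycanParseError("linkage with no preceding residue", off)
            if i + 2 >= len(tokens) or tokens[i + 1][0] != "LINK" or tokens[i + 2][0] != ")":
                raise GlycanParseError("malformed linkage parentheses", off)
            link = tokens[i + 1][1].strip()
            if not link:
                raise GlycanParseError("empty linkage token", off)
            pending.append((last_node, link))
            last_node = None
            i += 3
        elif kind == "[":
            if last_node is not None:
                raise GlycanParseError(
                    "branch bracket must follow a linkage or start of chain", off
                )
            stack.append(pending)
            pending = []
            last_node = None
            i += 1
        elif kind == "]":
            if not stack:
                raise GlycanParseError("unbalanced ']'", off)
            if last_node is not None or len(pending) != 1:
                raise GlycanParseError(
                    "bracketed branch must end with a linkage", off
                )
            outer = stack.pop()
            outer.extend(pending)
            pending = outer
            last_node = None
            i += 1
        else:  # pragma: no cover - lexer guarantees
            raise GlycanParseError(f"unexpected token {value!r}", off)

    if stack:
        raise GlycanParseError("unbalanced '['", len(text))
    if last_node is None:
        raise GlycanParseError("glycan must end with a residue (reducing end)")
    if pending:
        raise GlycanParseError("dangling branch without attachment")
    return GlycanGraph(tuple(nodes), tuple(edges), root=last_node)


def serialize_iupac(g: GlycanGraph) -> str:
    """Write a :class:`GlycanGraph` back to IUPAC-condensed notation.

    Branch order is normalized deterministically: among the children of a
    node, the child whose linkage label sorts lexicographically greatest
    continues the main chain; the remaining children appear bracketed, in
    lexicographic order of (linkage, subtree-text).  Round-tripping through
    :func:`parse_iupac` yields an isomorphic labeled tree.
    """

    def render(v: int) -> str:
        kids = g.children(v)
        if not kids:
            return g.nodes[v]
        rendered = sorted(
            ((link, render(c)) for c, link in kids),
            key=lambda t: (t[0], t[1]),
        )
        main_link, main_text = rendered[-1]
        branches = "".join(f"[{txt}({lnk})]" for lnk, txt in rendered[:-1])
        return f"{main_text}({main_link}){branches}{g.nodes[v]}"

    return render(g.root)


# ---------------------------------------------------------------------------
# corpus curation

def expand_ambiguous_linkages(
    link: str, *, max_variants: int = 16
) -> list[str]:
    """Alternatives for one linkage label: ``"a2-3/6"`` -> ``["a2-3","a2-6"]``.

    A ``/`` separates admissible position alternatives after the ``-``; a
    fully specified alternative (containing ``-``) replaces the whole label,
    e.g. ``"a1-3/b1-4"`` -> ``["a1-3", "b1-4"]``.  Labels without ``/`` are
    returned unchanged (singleton list).
    """
    if "/" not in link:
        return [link]
    if "-" in link:
        head, _, tail = link.rpartition("-")
        parts = tail.split("/")
        # some alternatives may themselves be full linkages, e.g. "a1-3/b1-4"
        # detected by a '-' inside the raw split of the whole string
        raw_alts = link.split("/")
        if all("-" in a for a in raw_alts):
            out = raw_alts
        else:
            out = [f"{head}-{p}" for p in parts]
    else:
        out = link.split("/")
    if any(not a for a in out):
        raise AmbiguousGlycanError(f"malformed alternative list in {link!r}")
    if len(out) > max_variants:
        raise AmbiguousGlycanError(
            f"{link!r} has {len(out)} alternatives, exceeding cap"
        )
    return out


@dataclass
class CurationReport:
    """Outcome of corpus curation.

    Every input string lands in exactly one of: ``kept`` (fully resolved,
    passed through), ``rejected_ambiguous`` (contains ``?``; with reason), or
    ``expansions`` (contained ``/`` in linkages; maps input to the cartesian
    product of resolved variants).
    """

    kept: list[str] = field(default_factory=list)
    rejected_ambiguous: list[tuple[str, str]] = field(default_factory=list)
    expansions: dict[str, list[str]] = field(default_factory=dict)

    @property
    def resolved(self) -> list[str]:
        """kept strings plus every expansion variant, input order preserved."""
        out = list(self.kept)
        for variants in self.expansions.values():
            out.extend(variants)
        return out

    def write(self, path: str | Path) -> None:
        """Three-section tab-separated report file."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# kept\n")
            for s in self.kept:
                fh.write(s + "\n")
            fh.write("# rejected_ambiguous\n")
            for s, reason in self.rejected_ambiguous:
                fh.write(f"{s}\t{reason}\n")
            fh.write("# expansions\n")
            for src, variants in self.expansions.items():
                fh.write(src + "\t" + "\t".join(variants) + "\n")


def curate_corpus(
    texts: Iterable[str], *, max_variants_per_entry: int = 16
) -> CurationReport:
    """Filter and expand a corpus of IUPAC-condensed strings.

    Strings containing ``?`` anywhere are rejected (checked before
    expansion).  Strings with ``/`` inside one or more linkage labels are
    expanded into the cartesian product of the admissible alternatives, each
    variant becoming an independent entry; the product is capped at
    ``max_variants_per_entry`` (capped entries are rejected with a logged
    warning rather than truncated).  Fully resolved strings pass through.
    """
    report = CurationReport()
    for text in texts:
        if "?" in text:
            report.rejected_ambiguous.append((text, "contains '?'"))
            continue
        if "/" not in text:
            # validate structure eagerly so bad strings surface here
            parse_iupac(text)
            report.kept.append(text)
            continue
        try:
            g = parse_iupac(text, allow_ambiguous=True)
        except GlycanParseError:
            raise
        if any("/" in lab for lab in g.nodes):
            raise AmbiguousGlycanError(
                f"'/' outside a linkage context in {text!r}"
            )
        per_edge: list[list[str]] = []
        for child, parent, lab in g.edges:
            per_edge.append(expand_ambiguous_linkages(lab))
        n_variants = 1
        for alts in per_edge:
            n_variants *= len(alts)
        if n_variants > max_variants_per_entry:
            logger.warning(
                "%r expands to %d variants (cap %d); rejecting",
                text, n_variants, max_variants_per_entry,
            )
            report.rejected_ambiguous.append(
                (text, f"expansion count {n_variants} exceeds cap")
            )
            continue
        variants = []
        for combo in itertools.product(*per_edge) if per_edge else [()]:
            edges = tuple(
                (c, p, lab) for (c, p, _), lab in zip(g.edges, combo)
            )
            variants.append(
                serialize_iupac(GlycanGraph(g.nodes, edges, g.root))
            )
        report.expansions[text] = variants
    return report


def read_corpus(path: str | Path) -> list[tuple[str, str | None]]:
    """Read a corpus file: one IUPAC string per line, optional TAB + label.

    Blank lines and lines starting with ``#`` are skipped.  Records are
    returned in file order as ``(glycan, label-or-None)``.
    """
    path = Path(path)
    records: list[tuple[str, str | None]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" in line:
                glycan, label = line.split("\t", 1)
                records.append((glycan.strip(), label.strip()))
            else:
                records.append((line.strip(), None))
    return records


def write_corpus(
    records: Sequence[tuple[str, str | None]], path: str | Path
) -> None:
    """Inverse of :func:`read_corpus`."""
    with open(path, "w", encoding="utf-8") as fh:
        for glycan, label in records:
            fh.write(glycan if label is None else f"{glycan}\t{label}")
            fh.write("\n")
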