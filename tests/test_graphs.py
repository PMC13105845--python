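"""IUPAC-condensed parsing, serialization and corpus curation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycoformer.graphs import (
    AmbiguousGlycanError,
    GlycanGraph,
    GlycanParseError,
    curate_corpus,
    expand_ambiguous_linkages,
    parse_iupac,
    read_corpus,
    serialize_iupac,
    write_corpus,
)
from glycoformer.synthetic import ToyGrammar, generate_corpus


def canonical_form(g: GlycanGraph, v: int | None = None):
    """Order-independent canonical form of a rooted labeled tree (oracle
    for isomorphism checks, independent of the serializer)."""
    if v is None:
        v = g.root
    kids = sorted(
        (link, canonical_form(g, c)) for c, link in g.children(v)
    )
    return (g.nodes[v], tuple(kids))


# 20 real repository-style glycans with hand-enumerated structure:
# (string, n_nodes, root_label, sorted node labels, sorted edge labels)
REAL_GLYCANS = [
    ("Gal(b1-4)Glc", 2, "Glc", ["Gal", "Glc"], ["b1-4"]),
    ("Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc", 4, "Glc",
     ["Gal", "Gal", "Glc", "GlcNAc"], ["b1-3", "b1-4", "b1-4"]),
    ("Fuc(a1-2)Gal(b1-4)Glc", 3, "Glc",
     ["Fuc", "Gal", "Glc"], ["a1-2", "b1-4"]),
    ("Gal(b1-4)[Fuc(a1-3)]GlcNAc", 3, "GlcNAc",
     ["Fuc", "Gal", "GlcNAc"], ["a1-3", "b1-4"]),
    ("Fuc(a1-2)Gal(b1-3)[Fuc(a1-4)]GlcNAc", 4, "GlcNAc",
     ["Fuc", "Fuc", "Gal", "GlcNAc"], ["a1-2", "a1-4", "b1-3"]),
    ("NeuNAc(a2-3)Gal(b1-4)Glc", 3, "Glc",
     ["Gal", "Glc", "NeuNAc"], ["a2-3", "b1-4"]),
    ("NeuNAc(a2-6)Gal(b1-4)GlcNAc", 3, "GlcNAc",
     ["Gal", "GlcNAc", "NeuNAc"], ["a2-6", "b1-4"]),
    ("Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc", 5, "GlcNAc",
     ["GlcNAc", "GlcNAc", "Man", "Man", "Man"],
     ["a1-3", "a1-6", "b1-4", "b1-4"]),
    ("Man(a1-2)Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc", 6, "GlcNAc",
     ["GlcNAc", "GlcNAc", "Man", "Man", "Man", "Man"],
     ["a1-2", "a1-3", "a1-6", "b1-4", "b1-4"]),
    ("Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc", 6,
     "GlcNAc", ["Fuc", "GlcNAc", "GlcNAc", "Man", "Man", "Man"],
     ["a1-3", "a1-6", "a1-6", "b1-4", "b1-4"]),
    ("Gal(b1-3)GalNAc", 2, "GalNAc", ["Gal", "GalNAc"], ["b1-3"]),
    ("Gal(b1-3)[GlcNAc(b1-6)]GalNAc", 3, "GalNAc",
     ["Gal", "GalNAc", "GlcNAc"], ["b1-3", "b1-6"]),
    ("GlcNAc(b1-3)GalNAc", 2, "GalNAc", ["GalNAc", "GlcNAc"], ["b1-3"]),
    ("NeuNAc(a2-3)Gal(b1-3)[NeuNAc(a2-6)]GalNAc", 4, "GalNAc",
     ["Gal", "GalNAc", "NeuNAc", "NeuNAc"], ["a2-3", "a2-6", "b1-3"]),
    ("GalNAc(a1-3)[Fuc(a1-2)]Gal(b1-4)GlcNAc", 4, "GlcNAc",
     ["Fuc", "Gal", "GalNAc", "GlcNAc"], ["a1-2", "a1-3", "b1-4"]),
    ("Gal(a1-3)[Fuc(a1-2)]Gal(b1-4)GlcNAc", 4, "GlcNAc",
     ["Fuc", "Gal", "Gal", "GlcNAc"], ["a1-2", "a1-3", "b1-4"]),
    ("NeuNAc(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc", 4, "GlcNAc",
     ["Fuc", "Gal", "GlcNAc", "NeuNAc"], ["a1-3", "a2-3", "b1-4"]),
    ("Glc(a1-4)Glc(a1-4)Glc", 3, "Glc",
     ["Glc", "Glc", "Glc"], ["a1-4", "a1-4"]),
    ("Man(a1-3)[Xyl(b1-2)][Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc", 6,
     "GlcNAc", ["GlcNAc", "GlcNAc", "Man", "Man", "Man", "Xyl"],
     ["a1-3", "a1-6", "b1-2", "b1-4", "b1-4"]),
    ("GlcA(b1-3)Gal(b1-3)Gal(b1-4)Xyl", 4, "Xyl",
     ["Gal", "Gal", "GlcA", "Xyl"], ["b1-3", "b1-3", "b1-4"]),
]


class TestParse:
    @pytest.mark.parametrize(
        "text,n,root,node_labels,edge_labels", REAL_GLYCANS,
        ids=[r[0] for r in REAL_GLYCANS],
    )
    def test_real_glycans_structure(self, text, n, root, node_labels,
                                    edge_labels):
        """Node/edge label multisets of real glycans match hand enumeration."""
        g = parse_iupac(text)
        assert g.n_nodes == n
        assert g.n_edges == n - 1
        assert g.nodes[g.root] == root
        assert sorted(g.nodes) == node_labels
        assert sorted(l for _, _, l in g.edges) == edge_labels

    def test_triples_of_branched_core(self):
        """Child->parent triples of the pentasaccharide N-glycan core."""
        g = parse_iupac("Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc")
        triples = {(g.nodes[c], l, g.nodes[p]) for c, p, l in g.edges}
        assert triples == {
            ("Man", "a1-3", "Man"),
            ("Man", "a1-6", "Man"),
            ("Man", "b1-4", "GlcNAc"),
            ("GlcNAc", "b1-4", "GlcNAc"),
        }
        # the central mannose carries two children and one parent
        central = next(i for i, lab in enumerate(g.nodes)
                       if lab == "Man" and len(g.children(i)) == 2)
        assert g.degree(central) == 3
        assert g.root == g.n_nodes - 1  # rightmost residue

    def test_single_residue(self):
        g = parse_iupac("GalNAc")
        assert g.n_nodes == 1 and g.n_edges == 0
        assert g.nodes[g.root] == "GalNAc"

    def test_modified_residue_token_kept_verbatim(self):
        g = parse_iupac("Gal(b1-3)GalNAc3,4,6Ac3")
        assert g.nodes[g.root] == "GalNAc3,4,6Ac3"

    def test_node_indices_follow_text_order(self):
        g = parse_iupac("Gal(b1-3)[GlcNAc(b1-6)]GalNAc")
        assert g.nodes == ("Gal", "GlcNAc", "GalNAc")
        assert g.root == 2

    @pytest.mark.parametrize("bad", [
        "", "   ", "Gal(b1-3", "Gal)b1-3(Gal", "Gal(b1-3))Gal",
        "[Gal(b1-3)]", "Gal(b1-3)[GalNAc", "Gal()Gal", "(b1-3)Gal",
        "Gal(b1-3)[Glc]GalNAc",
    ])
    def test_malformed_strings_raise(self, bad):
        with pytest.raises(GlycanParseError):
            parse_iupac(bad)

    @pytest.mark.parametrize("ambig", ["NeuNAc(a2-?)Gal", "NeuNAc(a2-3/6)Gal"])
    def test_ambiguous_symbols_raise_validation_error(self, ambig):
        with pytest.raises(AmbiguousGlycanError):
            parse_iupac(ambig)

    def test_tree_property_on_generated_corpus(self, toy_graphs):
        for g in toy_graphs[:500]:
            assert g.n_edges == g.n_nodes - 1  # plus connectivity via invariants


class TestSerialize:
    def test_round_trip_identity_simple(self):
        assert serialize_iupac(parse_iupac("Gal(b1-3)GalNAc")) == "Gal(b1-3)GalNAc"
        assert serialize_iupac(parse_iupac("GalNAc")) == "GalNAc"

    def test_round_trip_isomorphism_1000_generated(self):
        """parse(serialize(g)) is the same labeled tree for 1,000 glycans."""
        corpus = generate_corpus(ToyGrammar(seed=123), 1000, 123)
        for s, _ in corpus:
            g = parse_iupac(s)
            assert canonical_form(parse_iupac(serialize_iupac(g))) == \
                canonical_form(g)

    def test_branch_order_normalized_deterministically(self):
        a = parse_iupac("Gal(b1-3)[GlcNAc(b1-6)]GalNAc")
        b = parse_iupac("GlcNAc(b1-6)[Gal(b1-3)]GalNAc")
        assert serialize_iupac(a) == serialize_iupac(b)


@st.composite
def random_trees(draw):
    labels = ["Gal", "Glc", "Man", "GlcNAc", "Fuc"]
    links = ["a1-2", "a1-3", "b1-4", "b1-6"]
    n = draw(st.integers(1, 12))
    node_labels = [draw(st.sampled_from(labels)) for _ in range(n)]
    edges = []
    for child in range(1, n):
        parent = draw(st.integers(0, child - 1))
        edges.append((child, parent, draw(st.sampled_from(links))))
    return GlycanGraph(tuple(node_labels), tuple(edges), root=0)


class TestProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(random_trees())
    def test_serialize_parse_round_trip(self, g):
        assert canonical_form(parse_iupac(serialize_iupac(g))) == \
            canonical_form(g)


class TestCuration:
    def test_question_mark_rejected(self):
        rep = curate_corpus(["NeuNAc(a2-?)Gal"])
        assert rep.rejected_ambiguous[0][0] == "NeuNAc(a2-?)Gal"
        assert not rep.kept and not rep.expansions

    def test_slash_expansion_two_variants(self):
        rep = curate_corpus(["NeuNAc(a2-3/6)Gal"])
        assert sorted(rep.expansions["NeuNAc(a2-3/6)Gal"]) == [
            "NeuNAc(a2-3)Gal", "NeuNAc(a2-6)Gal",
        ]

    def test_resolved_passes_through(self):
        rep = curate_corpus(["Gal(b1-3)GalNAc"])
        assert rep.kept == ["Gal(b1-3)GalNAc"]

    def test_question_mark_beats_slash(self):
        """Entries with both markers are rejected, not expanded."""
        rep = curate_corpus(["NeuNAc(a2-3/6)Gal(b1-?)Glc"])
        assert len(rep.rejected_ambiguous) == 1

    def test_cartesian_product_of_two_ambiguous_linkages(self):
        rep = curate_corpus(["NeuNAc(a2-3/6)Gal(b1-3/4)Glc"])
        variants = rep.expansions["NeuNAc(a2-3/6)Gal(b1-3/4)Glc"]
        assert len(variants) == 4
        assert len(set(variants)) == 4
        for v in variants:
            parse_iupac(v)  # all resolved

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(2, 3), min_size=1, max_size=3))
    def test_expansion_count_law(self, alt_counts):
        """k ambiguous linkages with a_i alternatives give prod(a_i)
        variants."""
        residues = ["Gal", "Glc", "Man", "GlcNAc"]
        parts = []
        for i, a in enumerate(alt_counts):
            alts = "/".join(str(2 + j) for j in range(a))
            parts.append(f"{residues[i % 4]}(b1-{alts})")
        text = "".join(parts) + "GalNAc"
        rep = curate_corpus([text], max_variants_per_entry=64)
        expected = int(np.prod(alt_counts))
        assert len(rep.expansions[text]) == expected

    def test_expansion_cap_rejects_blowup(self):
        text = "".join("Gal(b1-2/3/4/6)" for _ in range(3)) + "Glc"  # 64 > 16
        rep = curate_corpus(texts=[text])
        assert rep.rejected_ambiguous and "cap" in rep.rejected_ambiguous[0][1]

    def test_slash_outside_linkage_raises(self):
        with pytest.raises(AmbiguousGlycanError):
            curate_corpus(["Gal/Glc(b1-3)Man"])

    def test_expand_single_linkage_helper(self):
        assert expand_ambiguous_linkages("a1-3/5") == ["a1-3", "a1-5"]
        assert expand_ambiguous_linkages("b1-4") == ["b1-4"]


class TestCorpusIO:
    def test_read_write_round_trip(self, tmp_path):
        path = tmp_path / "corpus.tsv"
        records = [("Gal(b1-3)GalNAc", "O"), ("GalNAc", None)]
        write_corpus(records, path)
        assert read_corpus(path) == records

    def test_comments_and_blanks_skipped(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("# header\nGal(b1-4)Glc\n\nGal(b1-3)GalNAc\tO\n")
        assert read_corpus(path) == [
            ("Gal(b1-4)Glc", None), ("Gal(b1-3)GalNAc", "O"),
        ]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("")
        assert read_corpus(path) == []

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(OSError):
            read_corpus(tmp_path / "absent.tsv")

    def test_curation_report_file(self, tmp_path):
        rep = curate_corpus(
            ["Gal(b1-3)GalNAc", "NeuNAc(a2-?)Gal", "NeuNAc(a2-3/6)Gal"]
        )
        out = tmp_path / "report.tsv"
        rep.write(out)
        text = out.read_text()
        assert "# kept" in text and "# expansions" in text
        assert "NeuNAc(a2-3)Gal\tNeuNAc(a2-6)Gal" in text
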