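import pytest

from semfact.examples import ibuprofen_chemoprevention, thalidomide_tnf
from semfact.graphs import (
    AlignmentError,
    ConllError,
    collapse,
    path_between,
    prune_trigger_nodes,
    read_dependencies,
    transform_to_semantic,
)

SIMPLE = """\
# sent_id = s1
1\tIbuprofen\tIbuprofen\t_\tNNP\t_\t2\tnsubj\t_\tstart_char=0|end_char=9
2\ttreats\ttreat\t_\tVBZ\t_\t0\troot\t_\tstart_char=10|end_char=16
3\tpain\tpain\t_\tNN\t_\t2\tdobj\t_\tstart_char=17|end_char=21
4\t.\t.\t_\t.\t_\t2\tpunct\t_\tstart_char=21|end_char=22
"""

PREP = """\
1\ttreatment\ttreatment\t_\tNN\t_\t0\troot\t_\tstart_char=0|end_char=9
2\tof\tof\t_\tIN\t_\t1\tprep\t_\tstart_char=10|end_char=12
3\tcancer\tcancer\t_\tNN\t_\t2\tpobj\t_\tstart_char=13|end_char=19
"""


class TestReader:
    def test_reads_tokens_offsets_and_edges(self):
        (g,) = read_dependencies(SIMPLE)
        assert g.sent_id == "s1"
        assert [t.text for t in g.tokens] == ["Ibuprofen", "treats", "pain", "."]
        assert g.token(1).char_span == (0, 9)
        assert g.token(2).pos == "VBZ" and g.token(2).is_verbal
        assert g.root == 2

    def test_xpos_preferred_over_upos(self):
        text = SIMPLE.replace("_\tNNP", "PROPN\tNNP")
        (g,) = read_dependencies(text)
        assert g.token(1).pos == "NNP"

    def test_multiword_range_lines_skipped(self):
        lines = SIMPLE.splitlines()
        lines.insert(1, "1-2\tIbuprofen treats\t_\t_\t_\t_\t_\t_\t_\t_")
        (g,) = read_dependencies("\n".join(lines))
        assert len(g.tokens) == 4

    def test_two_sentences(self):
        graphs = read_dependencies(SIMPLE + "\n" + SIMPLE.replace("s1", "s2"))
        assert [g.position for g in graphs] == [0, 1]

    def test_bad_column_count(self):
        with pytest.raises(ConllError, match="10 columns"):
            read_dependencies("1\tfoo\tfoo\tNN\n")

    def test_multiple_roots_rejected(self):
        bad = SIMPLE.replace("2\tdobj", "0\troot")
        with pytest.raises(ConllError, match="root"):
            read_dependencies(bad)

    def test_cycle_rejected(self):
        bad = SIMPLE.replace(
            "2\ttreats\ttreat\t_\tVBZ\t_\t0\troot",
            "2\ttreats\ttreat\t_\tVBZ\t_\t3\tdep",
        ).replace("3\tpain\tpain\t_\tNN\t_\t2\tdobj", "3\tpain\tpain\t_\tNN\t_\t2\tdobj")
        with pytest.raises(ConllError):
            read_dependencies(bad)


class TestCollapse:
    def test_prep_pobj_collapses_with_anchor(self):
        (g,) = read_dependencies(PREP)
        c = collapse(g)
        labels = {(e.head, e.dependent): e.label for e in c.edges}
        assert labels[(1, 3)] == "prep_of"
        assert (1, 2) not in labels and (2, 3) not in labels
        assert c.anchor_map[2] == 1

    def test_dangling_preposition_left_with_warning(self, caplog):
        text = PREP.replace("2\tpobj", "2\tdep")
        (g,) = read_dependencies(text)
        with caplog.at_level("WARNING"):
            c = collapse(g)
        assert any("dangling" in r.message for r in caplog.records)
        assert {(e.head, e.dependent, e.label) for e in c.edges} == {
            (e.head, e.dependent, e.label) for e in g.edges
        }

    def test_cc_conj_collapses_to_coordinator_label(self):
        text = """\
1\tA\ta\t_\tNN\t_\t0\troot\t_\tstart_char=0|end_char=1
2\tand\tand\t_\tCC\t_\t1\tcc\t_\tstart_char=2|end_char=5
3\tB\tb\t_\tNN\t_\t1\tconj\t_\tstart_char=6|end_char=7
"""
        (g,) = read_dependencies(text)
        c = collapse(g)
        labels = {e.label for e in c.edges}
        assert "conj_and" in labels and "cc" not in labels

    def test_ud_case_obl_collapses(self):
        text = """\
1\ttreated\ttreat\t_\tVBN\t_\t0\troot\t_\tstart_char=0|end_char=7
2\twith\twith\t_\tIN\t_\t3\tcase\t_\tstart_char=8|end_char=12
3\taspirin\taspirin\t_\tNN\t_\t1\tobl\t_\tstart_char=13|end_char=20
"""
        (g,) = read_dependencies(text)
        c = collapse(g)
        labels = {(e.head, e.dependent): e.label for e in c.edges}
        assert labels[(1, 3)] == "prep_with"


class TestTransform:
    def _graph(self, doc, dictionary):
        graphs = [collapse(g) for g in read_dependencies(doc.conllu)]
        return transform_to_semantic(
            graphs, doc.entities, doc.predications, dictionary
        )

    def test_aux_and_neg_edges_inverted(self, dictionary):
        sg = self._graph(ibuprofen_chemoprevention(), dictionary)
        # "may" (token 6) governs "have" (token 7)
        assert sg.label((0, 6), (0, 7)) == "AUX"

    def test_coordination_distributes_shared_material(self, dictionary):
        sg = self._graph(ibuprofen_chemoprevention(), dictionary)
        # prep_in over "chemoprevention" also reaches the conjunct "treatment"
        assert sg.label((0, 8), (0, 13)) == "PREP_IN"
        # and treatment inherits prep_of -> cancer
        assert sg.label((0, 13), (0, 16)) == "PREP_OF"

    def test_graph_is_acyclic_and_annotated(self, dictionary):
        doc = ibuprofen_chemoprevention()
        sg = self._graph(doc, dictionary)
        assert sg.is_acyclic()
        ent_ids = {e.id for ents in sg.entities.values() for e in ents}
        assert ent_ids == {e.id for e in doc.entities}
        assert any(sg.predications.values())

    def test_multitoken_entity_resolves_to_head(self, dictionary):
        sg = self._graph(ibuprofen_chemoprevention(), dictionary)
        # "breast cancer" spans tokens 15-16; head is "cancer" (16)
        node = next(n for n, ents in sg.entities.items() if ents[0].id == "T5")
        assert sg.token(node).text == "cancer"

    def test_trigger_senses_attached(self, dictionary):
        sg = self._graph(ibuprofen_chemoprevention(), dictionary)
        lemmas = {sg.token(n).lemma for n in sg.senses}
        assert {"may", "suggest"} <= lemmas

    def test_cross_sentence_span_rejected(self, dictionary):
        doc = ibuprofen_chemoprevention()
        graphs = [collapse(g) for g in read_dependencies(doc.conllu)]
        two = read_dependencies(doc.conllu)
        # duplicate the sentence to create a second sentence range
        import dataclasses

        offset = len(doc.text) + 1
        shifted = dataclasses.replace(
            two[0],
            tokens=[
                dataclasses.replace(
                    t,
                    char_span=(t.char_span[0] + offset, t.char_span[1] + offset),
                )
                for t in two[0].tokens
            ],
            position=1,
        )
        bad_entity = type(doc.entities[0])(
            id="TX",
            type="x",
            span=(doc.entities[-1].span[0], offset + 5),
            text="x",
        )
        with pytest.raises(AlignmentError, match="TX"):
            transform_to_semantic(
                graphs + [collapse(shifted)], [bad_entity], [], dictionary
            )

    def test_unaligned_span_rejected(self, dictionary):
        doc = ibuprofen_chemoprevention()
        graphs = [collapse(g) for g in read_dependencies(doc.conllu)]
        bad = type(doc.entities[0])(id="TX", type="x", span=(5000, 5004), text="x")
        with pytest.raises(AlignmentError):
            transform_to_semantic(graphs, [bad], [], dictionary)


class TestPruning:
    def test_overlapping_trigger_senses_dropped(self, dictionary):
        doc = ibuprofen_chemoprevention()
        graphs = [collapse(g) for g in read_dependencies(doc.conllu)]
        sg = transform_to_semantic(graphs, doc.entities, doc.predications, dictionary)
        # "potential" (token 8) is covered by entity T3: its sense must go
        assert any(sg.token(n).lemma == "potential" for n in sg.senses)
        prune_trigger_nodes(sg, doc.entities, doc.predications)
        assert not any(sg.token(n).lemma == "potential" for n in sg.senses)
        assert {sg.token(n).lemma for n in sg.senses} == {"may", "suggest"}

    def test_idempotent(self, dictionary):
        doc = ibuprofen_chemoprevention()
        graphs = [collapse(g) for g in read_dependencies(doc.conllu)]
        sg = transform_to_semantic(graphs, doc.entities, doc.predications, dictionary)
        prune_trigger_nodes(sg, doc.entities, doc.predications)
        before = dict(sg.senses)
        prune_trigger_nodes(sg, doc.entities, doc.predications)
        assert sg.senses == before

    def test_topology_untouched(self, dictionary):
        doc = thalidomide_tnf()
        graphs = [collapse(g) for g in read_dependencies(doc.conllu)]
        sg = transform_to_semantic(graphs, doc.entities, doc.predications, dictionary)
        edges_before = sg.edges()
        prune_trigger_nodes(sg, doc.entities, doc.predications)
        assert sg.edges() == edges_before


class TestPaths:
    @pytest.fixture()
    def sg(self, dictionary):
        doc = ibuprofen_chemoprevention()
        graphs = [collapse(g) for g in read_dependencies(doc.conllu)]
        return transform_to_semantic(graphs, doc.entities, doc.predications, dictionary)

    def test_self_path_is_empty(self, sg):
        assert path_between(sg, (0, 3), (0, 3)) == []

    def test_directed_path_found(self, sg):
        path = path_between(sg, (0, 3), (0, 16))  # suggest -> cancer
        assert path is not None
        assert path[0][0] == (0, 3) and path[-1][1] == (0, 16)
        for u, v, lab in path:
            assert sg.label(u, v) == lab

    def test_reverse_orientation_found(self, sg):
        # cancer has no outgoing path to suggest; reverse orientation is used
        path = path_between(sg, (0, 16), (0, 3))
        assert path is not None
        # traversal starts at "cancer"; edges keep their true direction
        assert path[0][1] == (0, 16) and path[-1][0] == (0, 3)

    def test_disconnected_returns_none(self, sg):
        # punctuation is attached, so synthesize an isolated node
        from semfact.graphs import Token

        sg.add_node((5, 1), Token(1, "x", "x", "NN"))
        assert path_between(sg, (0, 3), (5, 1)) is None

    def test_unknown_node_raises(self, sg):
        with pytest.raises(KeyError):
            path_between(sg, (9, 9), (0, 3))


def test_to_dot_export(dictionary):
    doc = ibuprofen_chemoprevention()
    graphs = [collapse(g) for g in read_dependencies(doc.conllu)]
    sg = transform_to_semantic(graphs, doc.entities, doc.predications, dictionary)
    dot = sg.to_dot()
    assert dot.startswith("digraph") and "Ibuprofen" in dot and "->" in dot
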