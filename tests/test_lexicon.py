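import pytest

from semfact.lexicon import (
    CategoryPath,
    DictionaryFormatError,
    EmbeddingDictionary,
    EmbeddingSense,
    ModalityScale,
    NoScaleError,
    load_dictionary,
    normalize_pos,
    scale_of,
    write_dictionary,
)


class TestCategoryPath:
    def test_parse_and_str(self):
        c = CategoryPath.parse("modal.epistemic.speculative")
        assert c.top_level == "modal"
        assert c.subpath == ("epistemic", "speculative")
        assert c.leaf == "speculative"
        assert str(c) == "modal.epistemic.speculative"

    def test_modal_and_shifter_flags(self):
        assert CategoryPath.parse("modal.epistemic.deductive").is_modal
        shifter = CategoryPath.parse("valence_shifter.scale_shifter.negation")
        assert shifter.is_scale_shifter and not shifter.is_modal

    def test_unknown_top_level_rejected(self):
        with pytest.raises(DictionaryFormatError):
            CategoryPath.parse("bogus.level")

    def test_modal_requires_subpath(self):
        with pytest.raises(DictionaryFormatError):
            CategoryPath("modal")

    def test_empty_path_rejected(self):
        with pytest.raises(DictionaryFormatError):
            CategoryPath.parse("")


class TestScales:
    @pytest.mark.parametrize(
        "leaf,scale",
        [
            ("speculative", ModalityScale.EPISTEMIC),
            ("deductive", ModalityScale.EPISTEMIC),
            ("demonstrative", ModalityScale.EPISTEMIC),
            ("counterfactive", ModalityScale.EPISTEMIC),
            ("permissive", ModalityScale.DEONTIC),
            ("obligative", ModalityScale.DEONTIC),
            ("potential", ModalityScale.POTENTIAL),
            ("volitive", ModalityScale.POTENTIAL),
            ("success", ModalityScale.SUCCESS),
            ("interrogative", ModalityScale.INTERROGATIVE),
        ],
    )
    def test_leaf_scales(self, leaf, scale):
        assert scale_of(CategoryPath("modal", (leaf,))) is scale

    def test_non_modal_has_no_scale(self):
        with pytest.raises(NoScaleError):
            scale_of(CategoryPath.parse("valence_shifter.scale_shifter.negation"))

    def test_unknown_modal_leaf(self):
        with pytest.raises(NoScaleError):
            scale_of(CategoryPath("modal", ("telepathic",)))


class TestEmbeddingSense:
    def _modal(self, **kw):
        base = dict(
            lemma="may",
            pos="MD",
            category=CategoryPath.parse("modal.epistemic.speculative"),
            dep_types=frozenset({"AUX"}),
            prior_value=0.5,
        )
        base.update(kw)
        return EmbeddingSense(**base)

    def test_valid_modal(self):
        s = self._modal()
        assert s.scale is ModalityScale.EPISTEMIC
        assert not s.is_negation

    def test_modal_requires_prior(self):
        with pytest.raises(DictionaryFormatError):
            self._modal(prior_value=None)

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_prior_range(self, bad):
        with pytest.raises(DictionaryFormatError):
            self._modal(prior_value=bad)

    def test_shifter_requires_shift_function(self):
        with pytest.raises(DictionaryFormatError):
            EmbeddingSense(
                lemma="not",
                pos="RB",
                category=CategoryPath.parse(
                    "valence_shifter.scale_shifter.negation"
                ),
                dep_types=frozenset({"NEG"}),
            )

    def test_shifter_rejects_prior(self):
        with pytest.raises(DictionaryFormatError):
            EmbeddingSense(
                lemma="not",
                pos="RB",
                category=CategoryPath.parse(
                    "valence_shifter.scale_shifter.negation"
                ),
                dep_types=frozenset({"NEG"}),
                prior_value=0.5,
                shift_function="negate",
            )

    def test_source_introducers(self):
        deductive = self._modal(
            category=CategoryPath.parse("modal.epistemic.deductive"),
            prior_value=0.75,
        )
        assert deductive.introduces_source
        assert not self._modal().introduces_source


@pytest.mark.parametrize(
    "raw,norm",
    [
        ("VBD", "VB"), ("VBZ", "VB"), ("VBP", "VB"), ("VBN", "VB"),
        ("VBG", "VB"), ("NNS", "NN"), ("JJR", "JJ"), ("RBS", "RB"),
        ("MD", "MD"), ("NN", "NN"), ("IN", "IN"),
    ],
)
def test_normalize_pos(raw, norm):
    assert normalize_pos(raw) == norm


class TestDefaultDictionary:
    def test_may_senses_in_priority_order(self, dictionary):
        senses = dictionary.lookup_senses("may", "MD")
        assert [s.category.leaf for s in senses] == ["speculative", "permissive"]
        assert [s.prior_value for s in senses] == [0.5, 0.6]
        assert all("AUX" in s.dep_types for s in senses)

    def test_scales_of_core_triggers(self, dictionary):
        assert dictionary.lookup_senses("can", "MD")[0].scale is ModalityScale.POTENTIAL
        assert dictionary.lookup_senses("should", "MD")[0].scale is ModalityScale.DEONTIC
        assert (
            dictionary.lookup_senses("whether", "IN")[0].scale
            is ModalityScale.INTERROGATIVE
        )
        assert dictionary.lookup_senses("fail", "VB")[0].scale is ModalityScale.SUCCESS

    def test_negation_trigger(self, dictionary):
        (sense,) = dictionary.lookup_senses("not", "RB")
        assert sense.is_negation and sense.shift_function == "negate"

    def test_lookup_normalizes_case_and_pos(self, dictionary):
        assert dictionary.lookup_senses("Suggest", "VBZ")
        assert dictionary.lookup_senses("suggest", "VB")

    def test_non_trigger_is_empty(self, dictionary):
        assert dictionary.lookup_senses("ibuprofen", "NN") == ()

    def test_multiword_heads(self, dictionary):
        assert "rule out" in dictionary.multiword_lemmas()["rule"]
        assert dictionary.lookup_senses("rule out", "VB")[0].prior_value == 0.0

    def test_trigger_lemmas_nonempty(self, dictionary):
        lemmas = dictionary.trigger_lemmas()
        assert {"may", "suggest", "not", "whether"} <= lemmas


class TestLoadErrors:
    def test_missing_category_names_entry(self, tmp_path):
        p = tmp_path / "d.yaml"
        p.write_text(
            "- lemma: frob\n  pos: VB\n  senses:\n  - prior: 0.5\n"
            "    dep_types: [DOBJ]\n"
        )
        with pytest.raises(DictionaryFormatError, match="frob"):
            load_dictionary(p)

    def test_missing_dep_types(self, tmp_path):
        p = tmp_path / "d.yaml"
        p.write_text(
            "- lemma: frob\n  pos: VB\n  senses:\n"
            "  - category: modal.epistemic.speculative\n    prior: 0.5\n"
        )
        with pytest.raises(DictionaryFormatError, match="dep_types"):
            load_dictionary(p)

    def test_not_a_sequence(self, tmp_path):
        p = tmp_path / "d.yaml"
        p.write_text("lemma: frob\n")
        with pytest.raises(DictionaryFormatError):
            load_dictionary(p)

    def test_empty_file_is_empty_dictionary(self, tmp_path):
        p = tmp_path / "d.yaml"
        p.write_text("")
        assert len(load_dictionary(p)) == 0


def test_round_trip(dictionary, tmp_path):
    out = tmp_path / "dict.yaml"
    write_dictionary(dictionary, out)
    reloaded = load_dictionary(out)
    assert reloaded.entries == dictionary.entries
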