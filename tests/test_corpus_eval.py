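import pytest

from semfact.corpus_eval import (
    AnnotatedDocument,
    Entity,
    FixtureConfig,
    StandoffIntegrityError,
    TABLE6_TOTALS,
    _allocate_counts,
    cohen_kappa,
    evaluate,
    generate_fixture_corpus,
    majority_baseline,
    read_standoff,
    write_corpus,
    write_standoff,
)
from semfact.factuality import FactualityValue


@pytest.fixture(scope="module")
def small_corpus():
    return generate_fixture_corpus(FixtureConfig(n_documents=40, seed=11))


class TestStandoffIO:
    def test_round_trip_is_canonical_fixed_point(self, small_corpus):
        for doc in small_corpus[:10]:
            txt, ann = write_standoff(doc)
            again = read_standoff(txt, ann, doc_id=doc.id)
            txt2, ann2 = write_standoff(again)
            assert (txt2, ann2) == (txt, ann)
            assert again.gold == doc.gold
            assert {e.id for e in again.entities} == {e.id for e in doc.entities}

    def test_span_mismatch_names_annotation(self):
        txt = "Aspirin treats pain."
        ann = "T1\tDrug 0 7\tIbuprofen\n"
        with pytest.raises(StandoffIntegrityError, match="T1"):
            read_standoff(txt, ann)

    def test_entity_type_with_spaces(self):
        txt = "Aspirin treats pain."
        ann = "T1\tPharmacologic Substance 0 7\tAspirin\n"
        doc = read_standoff(txt, ann)
        assert doc.entities[0].type == "Pharmacologic Substance"

    def test_true_positive_without_factuality_rejected(self):
        txt = "Aspirin treats pain."
        ann = (
            "T1\tDrug 0 7\tAspirin\n"
            "T2\tDisease 15 19\tpain\n"
            "T3\tTREATS 8 14\ttreats\n"
            "E1\tTREATS:T3 Subject:T1 Object:T2\n"
        )
        with pytest.raises(StandoffIntegrityError, match="E1"):
            read_standoff(txt, ann)

    def test_false_positive_needs_no_factuality(self):
        txt = "Aspirin treats pain."
        ann = (
            "T1\tDrug 0 7\tAspirin\n"
            "T2\tDisease 15 19\tpain\n"
            "T3\tTREATS 8 14\ttreats\n"
            "E1\tTREATS:T3 Subject:T1 Object:T2\n"
            "A1\tFalsePositive E1\n"
        )
        doc = read_standoff(txt, ann)
        assert doc.false_positives == {"E1"}
        assert doc.true_positive_predications() == []

    def test_norm_line_sets_cui(self):
        txt = "Aspirin treats pain."
        ann = (
            "T1\tDrug 0 7\tAspirin\n"
            "N1\tReference T1 CUI:C0004057\tAspirin\n"
        )
        doc = read_standoff(txt, ann)
        assert doc.entities[0].cui == "C0004057"

    def test_configurable_factuality_attribute(self):
        txt = "Aspirin treats pain."
        ann = (
            "T1\tDrug 0 7\tAspirin\n"
            "T2\tDisease 15 19\tpain\n"
            "T3\tTREATS 8 14\ttreats\n"
            "E1\tTREATS:T3 Subject:T1 Object:T2\n"
            "A1\tCertainty E1 probable\n"
        )
        doc = read_standoff(txt, ann, factuality_attribute="Certainty")
        assert doc.gold["E1"] is FactualityValue.PROBABLE

    def test_write_corpus_files(self, small_corpus, tmp_path):
        write_corpus(small_corpus[:3], tmp_path)
        for doc in small_corpus[:3]:
            for ext in (".txt", ".ann", ".conllu"):
                assert (tmp_path / f"{doc.id}{ext}").exists()


class TestEvaluate:
    def test_hand_computed_metrics(self):
        gold = ["fact", "fact", "possible", "probable"]
        pred = ["fact", "possible", "possible", "fact"]
        report = evaluate(gold, pred)
        assert report.accuracy == 0.5 and report.n == 4
        fact = report.per_class["fact"]
        assert fact.precision == 0.5  # 1 of 2 predicted fact correct
        assert fact.recall == 0.5  # 1 of 2 gold fact recovered
        poss = report.per_class["possible"]
        assert poss.precision == 0.5 and poss.recall == 1.0

    def test_zero_division_reports_zero(self):
        report = evaluate(["fact", "fact"], ["possible", "possible"])
        assert report.per_class["fact"].precision == 0.0
        assert report.per_class["possible"].recall == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate(["fact"], ["fact", "fact"])

    def test_explicit_label_universe(self):
        report = evaluate(
            ["fact"], ["fact"], labels=[v.value for v in FactualityValue]
        )
        assert set(report.per_class) == {v.value for v in FactualityValue}
        assert report.per_class["doubtful"].support == 0

    def test_accepts_enum_values(self):
        report = evaluate(
            [FactualityValue.FACT], [FactualityValue.FACT], kappa=True
        )
        assert report.accuracy == 1.0 and report.kappa == 1.0

    def test_as_percent(self):
        report = evaluate(["fact", "fact", "fact"], ["fact", "fact", "possible"])
        pct = report.as_percent()
        assert pct["_overall"]["accuracy"] == 66.7
        assert pct["fact"]["precision"] == 100.0


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(["a", "a", "b"], ["a", "a", "b"]) == 1.0

    def test_hand_computed(self):
        # p_o = 0.5, p_e = (0.5*0.5)+(0.5*0.5) = 0.5 -> kappa = 0
        assert cohen_kappa(["a", "b"], ["a", "a"]) == pytest.approx(0.0)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        a = ["fact", "fact", "possible", "probable", "fact", "possible"]
        b = ["fact", "possible", "possible", "fact", "fact", "probable"]
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa([], [])

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(["a"], ["a", "b"])


class TestMajorityBaseline:
    def test_all_fact_over_true_positives(self, small_corpus):
        preds = majority_baseline(small_corpus)
        assert len(preds) == sum(
            len(d.true_positive_predications()) for d in small_corpus
        )
        assert set(preds) == {FactualityValue.FACT}

    def test_false_positives_excluded(self):
        doc = AnnotatedDocument(id="d", text="x")
        assert majority_baseline([doc]) == []


class TestFixtureGeneration:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="proportions"):
            FixtureConfig(proportions={FactualityValue.FACT: 0.5})

    def test_allocation_at_1000(self):
        counts = _allocate_counts(1000, FixtureConfig().proportions)
        assert counts == {
            FactualityValue.FACT: 884,
            FactualityValue.PROBABLE: 40,
            FactualityValue.POSSIBLE: 24,
            FactualityValue.DOUBTFUL: 3,
            FactualityValue.COUNTERFACT: 17,
            FactualityValue.UNCOMMITTED: 32,
            FactualityValue.CONDITIONAL: 0,
        }
        assert sum(counts.values()) == 1000

    def test_allocation_at_corpus_size_recovers_totals(self):
        n = sum(TABLE6_TOTALS.values())
        assert _allocate_counts(n, FixtureConfig().proportions) == TABLE6_TOTALS

    def test_gold_distribution_matches_allocation(self, small_corpus):
        counts = _allocate_counts(40, FixtureConfig().proportions)
        observed: dict[FactualityValue, int] = {}
        for doc in small_corpus:
            for label in doc.gold.values():
                observed[label] = observed.get(label, 0) + 1
        assert observed == {k: v for k, v in counts.items() if v}

    def test_same_seed_is_byte_identical(self):
        a = generate_fixture_corpus(FixtureConfig(n_documents=15, seed=3))
        b = generate_fixture_corpus(FixtureConfig(n_documents=15, seed=3))
        assert [write_standoff(d) for d in a] == [write_standoff(d) for d in b]
        assert [d.conllu for d in a] == [d.conllu for d in b]

    def test_different_seed_differs(self):
        a = generate_fixture_corpus(FixtureConfig(n_documents=15, seed=3))
        b = generate_fixture_corpus(FixtureConfig(n_documents=15, seed=4))
        assert [write_standoff(d) for d in a] != [write_standoff(d) for d in b]

    def test_documents_are_well_formed(self, small_corpus):
        for doc in small_corpus:
            assert doc.conllu is not None
            for ent in doc.entities:
                assert doc.text[ent.span[0] : ent.span[1]] == ent.text
            assert set(doc.gold) == {p.id for p in doc.predications}


def test_entity_lookup():
    doc = AnnotatedDocument(
        id="d", text="x", entities=[Entity("T1", "Drug", (0, 1), "x")]
    )
    assert doc.entity("T1").type == "Drug"
    with pytest.raises(KeyError):
        doc.entity("T9")
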