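"""Deterministic FTR-type stage: worked examples, dominance, exclusions."""

import pytest

import ftrclassify as f
from ftrclassify.lexicon import MODAL_CATEGORIES, TYPE_CATEGORIES, tokenize

WORKED_EXAMPLES = [
    ("Tomorrow it will rain", {"future_tense"}),
    ("Tomorrow it is going to rain", {"future_tense"}),
    ("Tomorrow it shall rain", {"future_tense"}),
    ("tomorrow it rains", {"present_tense"}),
    ("It could rain tomorrow", {"verbal_low_certainty"}),
    ("It may rain tomorrow", {"verbal_low_certainty"}),
    ("It might rain tomorrow", {"verbal_low_certainty"}),
    ("It should rain tomorrow", {"verbal_low_certainty"}),
    ("It will possibly rain tomorrow", {"other_low_certainty"}),
    ("It will probably rain tomorrow", {"other_low_certainty"}),
    ("I think it will rain tomorrow", {"other_low_certainty"}),
    ("It will definitely rain tomorrow", {"other_high_certainty"}),
    ("It will certainly rain tomorrow", {"other_high_certainty"}),
    ("It will absolutely rain tomorrow", {"other_high_certainty"}),
    ("You must come tomorrow", {"deontic"}),
    ("I have to pick up more groceries tomorrow", {"deontic"}),
    ("I need to pick up more groceries tomorrow", {"deontic"}),
    ("I hope it rains tomorrow", {"bouletic"}),
    ("I want it to rain tomorrow", {"bouletic"}),
    ("If it rains, I’ll go out", {"irrealis"}),
    ("It could probably rain tomorrow",
     {"verbal_low_certainty", "other_low_certainty"}),  # modal concord
]


class TestWorkedExamples:
    @pytest.mark.parametrize("text, expected", WORKED_EXAMPLES,
                             ids=[t for t, _ in WORKED_EXAMPLES])
    def test_canonical_sentences(self, text, expected, lexicon):
        labels = f.classify_ftr_type(text, lexicon)
        assert labels.excluded == 0
        assert set(labels.active()) == expected

    @pytest.mark.parametrize("text, reason", [
        ("Rain tomorrow is not possible", "negation"),
        ("I am not certain it will rain tomorrow", "negation"),
        ("There is definitely a possibility of rain tomorrow", "mixed_modal"),
    ])
    def test_exclusions(self, text, reason, lexicon):
        labels = f.classify_ftr_type(text, lexicon)
        assert labels.excluded == 1
        assert labels.exclusion_reason == reason
        assert not any(labels.flags.values())


class TestNegationDetection:
    @pytest.mark.parametrize("text, expected", [
        ("Rain tomorrow is not possible", 1),
        ("It will rain tomorrow", 0),
        ("I won't go", 1),          # contraction expands to will + not
        ("I can't make it", 1),
        ("It never rains here", 1),
        ("We shan't be late", 1),
    ])
    def test_presence(self, text, expected, lexicon):
        assert f.detect_negation(text, lexicon) == expected


class TestMixedModal:
    @pytest.mark.parametrize("text, expected", [
        ("There is definitely a possibility of rain tomorrow", 1),
        ("It will definitely rain", 0),
        ("It could certainly rain", 1),
        ("It could probably rain tomorrow", 0),  # concord, same polarity
    ])
    def test_detection(self, text, expected, lexicon):
        assert f.detect_mixed_modal(text, lexicon) == expected


class TestClassifierProperties:
    def test_dominance_over_tense(self, lexicon):
        """Any modal keyword zeroes both tense flags even when a tense
        keyword is present."""
        for modal in ("could", "possibly", "definitely", "must", "hope"):
            labels = f.classify_ftr_type(f"It will {modal} rain tomorrow", lexicon)
            assert labels["future_tense"] == 0
            assert labels["present_tense"] == 0

    def test_exhaustive_and_exclusive_flags(self, lexicon, template_corpus):
        """On the full template corpus: every non-excluded sentence has
        >=1 flag, present tense fires exactly when nothing else does,
        and the only multi-flag combination is low-certainty concord."""
        for s in template_corpus:
            if s.time_ref != "FTR":
                continue
            labels = f.classify_ftr_type(s.text, lexicon)
            if labels.excluded:
                continue
            active = set(labels.active())
            assert active
            if labels["present_tense"]:
                assert active == {"present_tense"}
            if len(active) > 1:
                assert active == {"verbal_low_certainty", "other_low_certainty"}

    def test_deterministic_and_idempotent(self, lexicon):
        text = "It could probably rain tomorrow"
        assert f.classify_ftr_type(text, lexicon) == f.classify_ftr_type(text, lexicon)

    def test_closure_on_template_corpus(self, lexicon, template_corpus):
        """Templates are built from the shipped lexicon, so the
        classifier must reproduce every planted label set exactly."""
        for s in template_corpus:
            if s.time_ref != "FTR":
                continue
            labels = f.classify_ftr_type(s.text, lexicon)
            if s.excluded:
                assert labels.excluded == 1, s.text
                assert labels.exclusion_reason == s.exclusion_reason, s.text
            else:
                assert labels.excluded == 0, s.text
                assert dict(labels.flags) == dict(s.flags), s.text


class TestLexicon:
    def test_no_keyword_in_two_categories(self, lexicon):
        seen = {}
        for cat, keys in lexicon.keywords.items():
            for key in keys:
                assert key not in seen, (key, seen.get(key), cat)
                seen[key] = cat

    def test_verbal_high_certainty_default_empty(self, lexicon):
        assert lexicon.keywords["verbal_high_certainty"] == ()

    def test_case_insensitive_token_boundary_matching(self, lexicon):
        assert f.classify_ftr_type("it COULD rain", lexicon).active() == \
            ("verbal_low_certainty",)
        # 'mayo' must not match the keyword 'may'
        assert f.classify_ftr_type("the mayo will spoil tomorrow",
                                   lexicon).active() == ("future_tense",)

    def test_config_override_roundtrip(self, tmp_path):
        cfg = tmp_path / "lex.yaml"
        cfg.write_text("verbal_high_certainty: ['will for sure']\nversion: 'x'\n")
        lex = f.ModalLexicon.from_config(cfg)
        assert lex.version == "x"
        assert lex.keywords["verbal_high_certainty"] == (("will", "for", "sure"),)
        # untouched categories keep defaults
        assert (("could",) in lex.keywords["verbal_low_certainty"])

    def test_contraction_expansion(self):
        assert tokenize("I won't go") == ["i", "will", "not", "go"]
        assert tokenize("I'll be there") == ["i", "will", "be", "there"]
        assert tokenize("can't") == ["can", "not"]


class TestProportions:
    def _labelset(self, *active):
        return f.FTRTypeLabelSet({c: int(c in active) for c in TYPE_CATEGORIES})

    def test_single_type(self):
        props = f.proportions_by_type([self._labelset("future_tense")] * 5)
        assert props["future_tense"] == 1.0
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)

    def test_two_types_equal_means(self):
        sets = [self._labelset("future_tense")] * 3 + [self._labelset("bouletic")] * 3
        props = f.proportions_by_type(sets)
        assert props["future_tense"] == pytest.approx(0.5)
        assert props["bouletic"] == pytest.approx(0.5)

    def test_matches_hand_computation_with_concord(self):
        sets = ([self._labelset("verbal_low_certainty", "other_low_certainty")] * 2
                + [self._labelset("deontic")] * 2)
        # raw means: vlc 0.5, olc 0.5, deontic 0.5 -> each 1/3 after renorm
        props = f.proportions_by_type(sets)
        for cat in ("verbal_low_certainty", "other_low_certainty", "deontic"):
            assert props[cat] == pytest.approx(1 / 3)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            f.proportions_by_type([])

    def test_excluded_rejected(self):
        excl = f.FTRTypeLabelSet({c: 0 for c in TYPE_CATEGORIES},
                                 excluded=1, exclusion_reason="negation")
        with pytest.raises(ValueError):
            f.proportions_by_type([excl])
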