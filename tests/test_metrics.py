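import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tisk.metrics import (
    RecognitionOutcome,
    accuracy,
    class_timecourse,
    competitor_classes,
    dimensions_table,
    lexical_dimensions,
    recognition_time,
    rt_correlation,
)
from tisk.network import TrialTrace
from tisk.phonolex import Lexicon, default_inventory


def make_trace(word_matrix, labels):
    word_matrix = np.asarray(word_matrix, dtype=float)
    return TrialTrace(
        word=word_matrix,
        single=np.zeros((word_matrix.shape[0], 14)),
        labels=tuple(labels),
        symbols=default_inventory().symbols,
    )


def make_lexicon(**words):
    return Lexicon(
        entries=tuple((label, tuple(ph)) for label, ph in words.items()),
        inventory=default_inventory(),
    )


def brute_force_rt(word, target_idx, threshold, hold):
    """Independent scan over all candidate cycles, windows and tails."""
    T, W = word.shape
    for c in range(T - hold + 1):
        ok = True
        for t in range(c, c + hold):
            others = [word[t, j] for j in range(W) if j != target_idx]
            if word[t, target_idx] - max(others) < threshold:
                ok = False
                break
        if ok:
            for t in range(c + hold, T):
                others = [word[t, j] for j in range(W) if j != target_idx]
                if word[t, target_idx] <= max(others):
                    ok = False
                    break
        if ok:
            return c
    return None


class TestRecognitionTime:
    def test_constant_margin_recognized_at_cycle_zero(self):
        trace = make_trace(np.tile([0.6, 0.5], (30, 1)), ["t", "c"])
        out = recognition_time(trace, "t")
        assert out.recognized and out.rt_cycle == 0

    def test_margin_below_threshold_never_recognized(self):
        trace = make_trace(np.tile([0.54, 0.5], (30, 1)), ["t", "c"])
        assert not recognition_time(trace, "t").recognized

    def test_later_overtake_cancels_recognition(self):
        word = np.tile([0.6, 0.5], (30, 1))
        word[25:, 1] = 0.7  # competitor wins at the end
        assert not recognition_time(make_trace(word, ["t", "c"]), "t").recognized

    def test_hold_longer_than_trace_errors(self):
        trace = make_trace(np.tile([0.6, 0.5], (5, 1)), ["t", "c"])
        with pytest.raises(ValueError):
            recognition_time(trace, "t", hold=10)

    def test_matches_brute_force_on_random_traces(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            T, W = int(rng.integers(10, 25)), int(rng.integers(2, 5))
            word = rng.random((T, W))
            trace = make_trace(word, [f"w{j}" for j in range(W)])
            got = recognition_time(trace, "w0", threshold=0.05, hold=5)
            want = brute_force_rt(word, 0, threshold=0.05, hold=5)
            assert got.rt_cycle == want
            assert got.recognized == (want is not None)

    @given(
        seed=st.integers(0, 10**6),
        threshold=st.sampled_from([0.02, 0.05, 0.1]),
        hold=st.sampled_from([3, 5, 8]),
    )
    @settings(max_examples=100, deadline=None)
    def test_stricter_criteria_never_speed_recognition(self, seed, threshold, hold):
        rng = np.random.default_rng(seed)
        word = rng.random((20, 3))
        trace = make_trace(word, ["a", "b", "c"])
        base = recognition_time(trace, "a", threshold=threshold, hold=hold)
        tighter = recognition_time(trace, "a", threshold=threshold + 0.02, hold=hold)
        longer = recognition_time(trace, "a", threshold=threshold, hold=hold + 2)
        for stricter in (tighter, longer):
            if stricter.recognized:
                assert base.recognized
                assert stricter.rt_cycle >= base.rt_cycle


class TestAccuracy:
    def test_fraction_recognized(self):
        outs = [RecognitionOutcome(True, 3, "w")] * 209 + [
            RecognitionOutcome(False, None, "x")
        ] * 2
        assert accuracy(outs) == pytest.approx(209 / 211, abs=5e-5)
        assert accuracy([RecognitionOutcome(True, 1, "w")]) == 1.0
        assert accuracy([RecognitionOutcome(False, None, "w")]) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            accuracy([])


class TestCompetitorClasses:
    def test_dal_taxonomy(self):
        lex = make_lexicon(dal="dal", dak="dak", bal="bal", sut="sut", dalat="dalat")
        classes = competitor_classes(lex, "dal")
        assert "dak" in classes.cohorts
        assert "dalat" in classes.cohorts  # shares /da/
        assert classes.rhymes == {"bal"}
        assert classes.unrelated == {"sut"}

    def test_target_excluded_and_sets_disjoint(self):
        lex = make_lexicon(dal="dal", dak="dak", bal="bal")
        classes = competitor_classes(lex, "dal")
        all_sets = classes.cohorts | classes.rhymes | classes.unrelated
        assert "dal" not in all_sets
        assert len(all_sets) == len(classes.cohorts) + len(classes.rhymes) + len(
            classes.unrelated
        )

    def test_length_one_target_has_no_cohorts(self):
        lex = make_lexicon(a="a", ab="ab")
        assert competitor_classes(lex, "a").cohorts == frozenset()


class TestLexicalDimensions:
    @pytest.fixture()
    def cat_lexicon(self):
        # 'cat' rendered in the default inventory as /kat/
        return make_lexicon(
            cat="kat",
            at="at",
            scat="skat",
            bat="bat",
            kit="kit",
            catalog="katalag",
            ka="ka",
        )

    def test_cat_dimensions(self, cat_lexicon):
        d = lexical_dimensions(cat_lexicon, "cat")
        assert d.length == 3
        assert d.embeddings == 2  # at, ka occur inside /kat/
        assert d.ex_embeddings == 2  # kat occurs inside skat and katalag
        assert d.rhymes == 3  # bat (sub), at (deletion), scat (addition)
        assert d.das_neighbors == 5  # at, skat, bat, kit, ka
        assert d.onset_competitors == 2  # ka, katalog share /ka/

    def test_no_same_prefix_words_means_zero_cohorts(self):
        lex = make_lexicon(dal="dal", sut="sut")
        assert lexical_dimensions(lex, "dal").onset_competitors == 0

    def test_matches_brute_force_predicates(self, synthetic_lexicon):
        words = dict(synthetic_lexicon.entries)

        def contains(long_, short):
            n = len(short)
            return n < len(long_) and any(
                long_[i : i + n] == short for i in range(len(long_) - n + 1)
            )

        def edit1(a, b):
            if a == b:
                return False
            la, lb = len(a), len(b)
            if abs(la - lb) > 1:
                return False
            if la == lb:
                return sum(x != y for x, y in zip(a, b)) == 1
            s, l = (a, b) if la < lb else (b, a)
            return any(l[:i] + l[i + 1 :] == s for i in range(len(l)))

        table = dimensions_table(synthetic_lexicon).set_index("word")
        for target, tw in words.items():
            others = [(lab, w) for lab, w in words.items() if lab != target]
            row = table.loc[target]
            assert row["embeddings"] == sum(contains(tw, w) for _, w in others)
            assert row["ex_embeddings"] == sum(contains(w, tw) for _, w in others)
            assert row["das_neighbors"] == sum(edit1(w, tw) for _, w in others)
            assert row["onset_competitors"] == sum(
                len(tw) >= 2 and len(w) >= 2 and w[:2] == tw[:2] for _, w in others
            )
            assert row["rhymes"] == sum(
                (len(w) == len(tw) and w[0] != tw[0] and w[1:] == tw[1:])
                or w == tw[1:]
                or w[1:] == tw
                for _, w in others
            )


class TestClassTimecourse:
    def test_single_word_lexicon_only_target_and_baseline(self):
        lex = make_lexicon(dal="dal")
        trace = make_trace(np.linspace(0, 1, 20).reshape(-1, 1), ["dal"])
        tc = class_timecourse({"dal": trace}, lex)
        assert set(tc["class"]) == {"target", "unrelated"}

    def test_baseline_never_exceeds_target_class_max(self):
        lex = make_lexicon(dal="dal", dak="dak", bal="bal")
        rng = np.random.default_rng(1)
        traces = {
            label: make_trace(rng.random((15, 3)), ["dal", "dak", "bal"])
            for label in ("dal", "dak", "bal")
        }
        tc = class_timecourse(traces, lex)
        wide = tc.pivot_table(index="cycle", columns="class", values="mean")
        # the all-word mean is bounded by the per-trial max, hence by classes' max
        assert (wide["unrelated"] <= wide.max(axis=1) + 1e-12).all()


class TestRtCorrelation:
    def test_perfect_correlation_over_shared_words(self):
        a = {w: RecognitionOutcome(True, rt, "w") for w, rt in [("x", 5), ("y", 9), ("z", 14)]}
        b = {w: RecognitionOutcome(True, o.rt_cycle * 2, "w") for w, o in a.items()}
        r, p, n = rt_correlation(a, b)
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_unrecognized_words_excluded(self):
        a = {
            "x": RecognitionOutcome(True, 5, "x"),
            "y": RecognitionOutcome(False, None, "q"),
        }
        b = {
            "x": RecognitionOutcome(True, 6, "x"),
            "y": RecognitionOutcome(True, 8, "y"),
        }
        r, p, n = rt_correlation(a, b)
        assert n == 1 and np.isnan(r)
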