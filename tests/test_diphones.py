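import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tisk.diphones import (
    add_global_noise,
    blend_schedule,
    degrade_schedule,
    graded_weights,
    open_diphones,
    word_schedule,
)
from tisk.params import TISKParams

SYMBOLS = "pbtdkgsSrlaiu^"
words = st.text(alphabet=SYMBOLS, min_size=1, max_size=9).map(tuple)


def oracle_graded(word, gamma, rho):
    """Independent re-derivation: explicit scan over occurrence index pairs."""
    out = {}
    n = len(word)
    for i in range(n):
        for j in range(n):
            if i < j:
                out[(word[i], word[j])] = out.get((word[i], word[j]), 0.0) + gamma ** (
                    j - i - 1
                )
                out[(word[j], word[i])] = out.get((word[j], word[i]), 0.0) + rho * gamma ** (
                    j - i - 1
                )
    return out


class TestOpenDiphones:
    @pytest.mark.parametrize(
        "word,expected",
        [
            ("kæt", {("k", "æ"): 1, ("k", "t"): 1, ("æ", "t"): 1}),  # CAT
            ("tæk", {("t", "æ"): 1, ("t", "k"): 1, ("æ", "k"): 1}),  # TACK
            ("ækt", {("æ", "k"): 1, ("æ", "t"): 1, ("k", "t"): 1}),  # ACT
            ("dæd", {("d", "æ"): 1, ("d", "d"): 1, ("æ", "d"): 1}),  # DAD
            ("æd", {("æ", "d"): 1}),  # ADD
            ("sol", {("s", "o"): 1, ("s", "l"): 1, ("o", "l"): 1}),  # SOUL
            # the full pair count for s,o,l,o is 6: so x2, sl, ol, oo and lo
            ("solo", {("s", "o"): 2, ("s", "l"): 1, ("o", "l"): 1, ("o", "o"): 1, ("l", "o"): 1}),
        ],
    )
    def test_worked_examples(self, word, expected):
        assert dict(open_diphones(tuple(word))) == expected

    def test_single_phoneme_has_empty_code(self):
        assert open_diphones(("o",)) == {}

    @given(word=words)
    @settings(max_examples=200, deadline=None)
    def test_total_multiplicity_is_n_choose_2(self, word):
        n = len(word)
        assert sum(open_diphones(word).values()) == n * (n - 1) // 2

    def test_order_sensitivity(self):
        codes = [open_diphones(tuple(w)) for w in ("kæt", "tæk", "ækt")]
        assert codes[0] != codes[1] != codes[2] != codes[0]

    def test_repetition_sensitivity(self):
        soul, solo = open_diphones(tuple("sol")), open_diphones(tuple("solo"))
        assert soul != solo
        assert solo[("s", "o")] == 2


class TestGradedWeights:
    def test_gap_decay_stop_vs_spot(self):
        stop = graded_weights(tuple("stop"))[("s", "t")]
        spot = graded_weights(tuple("spot"))[("s", "t")]
        assert stop > spot

    def test_gap_decay_sock_stock_strong(self):
        sock = graded_weights(tuple("sak"))[("s", "a")]
        stock = graded_weights(tuple("stak"))[("s", "a")]
        strong = graded_weights(tuple("strag"))[("s", "a")]
        assert sock > stock > strong

    def test_reverse_order_factor(self):
        w = graded_weights(("b", "a"), gamma=0.5, rho=0.1)
        assert w[("b", "a")] == pytest.approx(1.0)
        assert w[("a", "b")] == pytest.approx(0.1)

    def test_gamma_to_zero_limit_is_bigram_code(self):
        word = tuple("solo")
        w = graded_weights(word, gamma=1e-12, rho=0.0)
        bigrams = {(word[i], word[i + 1]) for i in range(len(word) - 1)}
        for pair, weight in w.items():
            if pair in bigrams:
                assert weight == pytest.approx(1.0, abs=1e-9)
            else:
                assert weight == pytest.approx(0.0, abs=1e-9)

    @given(
        word=words,
        gamma=st.floats(0.05, 0.95),
        rho=st.floats(0.0, 0.9),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_index_pair_oracle(self, word, gamma, rho):
        got = graded_weights(word, gamma, rho)
        want = oracle_graded(word, gamma, rho)
        assert set(got) == set(want)
        for pair in want:
            assert got[pair] == pytest.approx(want[pair], rel=1e-12)

    @given(word=words.filter(lambda w: len(w) >= 2), rho=st.floats(0.0, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_ordered_direction_dominates(self, word, rho):
        w = graded_weights(word, gamma=0.5, rho=rho)
        counts = open_diphones(word)
        for (x, y), _ in counts.items():
            if x != y and (y, x) not in counts:
                assert w[(x, y)] > w[(y, x)]

    @pytest.mark.parametrize("gamma,rho", [(0.0, 0.1), (1.0, 0.1), (0.5, 1.0), (0.5, -0.1)])
    def test_parameter_range_enforced(self, gamma, rho):
        with pytest.raises(ValueError):
            graded_weights(("b", "a"), gamma, rho)


class TestWordSchedule:
    def test_one_slot_per_phoneme_every_ten_cycles(self, inventory):
        params = TISKParams()
        sched = word_schedule(tuple("pl^g"), params)
        for s, ph in enumerate("pl^g"):
            pi = inventory.index(ph)
            col = sched.external[:, pi, s]
            assert np.all(col[s * 10 : (s + 1) * 10] == 1.0)
            assert col.sum() == 10.0
        assert sched.external[:, :, 4:].sum() == 0.0  # beyond word end

    def test_total_cycles_controls_length(self):
        sched = word_schedule(tuple("pl^g"), TISKParams(), total_cycles=100)
        assert sched.n_cycles == 100

    def test_word_longer_than_slots_errors(self):
        with pytest.raises(ValueError):
            word_schedule(tuple("pbtdkgsSrla"), TISKParams(n_slots=10))


class TestBlendSchedule:
    def test_alpha_zero_is_identity(self):
        base = word_schedule(tuple("pl^g"), TISKParams())
        blended = blend_schedule(base, 0, "p", "b", 0.0)
        assert np.array_equal(blended.external, base.external)

    def test_halfway_blend_splits_input(self, inventory):
        base = word_schedule(tuple("pl^g"), TISKParams())
        blended = blend_schedule(base, 0, "p", "b", 0.5)
        assert np.all(blended.external[:10, inventory.index("p"), 0] == 0.5)
        assert np.all(blended.external[:10, inventory.index("b"), 0] == 0.5)

    def test_alpha_one_is_full_replacement(self, inventory):
        base = word_schedule(tuple("pl^g"), TISKParams())
        blended = blend_schedule(base, 0, "p", "b", 1.0)
        assert blended.external[:, inventory.index("p"), 0].sum() == 0.0
        assert np.all(blended.external[:10, inventory.index("b"), 0] == 1.0)

    def test_alpha_out_of_range_errors(self):
        base = word_schedule(tuple("pl^g"), TISKParams())
        with pytest.raises(ValueError):
            blend_schedule(base, 0, "p", "b", 1.5)


class TestDegradeSchedule:
    def test_silence_zeroes_the_slot(self):
        base = word_schedule(tuple("duti"), TISKParams())
        sched = degrade_schedule(base, 2, "silence")
        assert sched.external[20:30, :, 2].sum() == 0.0

    def test_noise_sd_zero_equals_silence(self):
        base = word_schedule(tuple("duti"), TISKParams())
        silent = degrade_schedule(base, 2, "silence")
        noisy = degrade_schedule(base, 2, "noise", noise_sd=0.0, rng_seed=1)
        assert np.array_equal(silent.external, noisy.external)

    def test_noise_is_seed_deterministic_and_nonnegative(self):
        base = word_schedule(tuple("duti"), TISKParams())
        a = degrade_schedule(base, 2, "noise", 0.4, rng_seed=5)
        b = degrade_schedule(base, 2, "noise", 0.4, rng_seed=5)
        c = degrade_schedule(base, 2, "noise", 0.4, rng_seed=6)
        assert np.array_equal(a.external, b.external)
        assert not np.array_equal(a.external, c.external)
        assert a.external.min() >= 0.0

    def test_block_noise_constant_within_slot_window(self, inventory):
        base = word_schedule(tuple("duti"), TISKParams())
        sched = degrade_schedule(base, 1, "noise", 0.4, rng_seed=2)
        block = sched.external[10:20, :, 1]
        assert np.all(block == block[0])

    def test_negative_sd_errors(self):
        base = word_schedule(tuple("duti"), TISKParams())
        with pytest.raises(ValueError):
            degrade_schedule(base, 0, "noise", -0.1)


class TestGlobalNoise:
    def test_sd_zero_is_identity(self):
        base = word_schedule(tuple("duti"), TISKParams())
        assert add_global_noise(base, 0.0, rng_seed=1) is base

    def test_seeded_and_truncated(self):
        base = word_schedule(tuple("duti"), TISKParams())
        a = add_global_noise(base, 0.15, rng_seed=3)
        b = add_global_noise(base, 0.15, rng_seed=3)
        c = add_global_noise(base, 0.15, rng_seed=4)
        assert np.array_equal(a.external, b.external)
        assert not np.array_equal(a.external, c.external)
        assert a.external.min() >= 0.0

    def test_intact_entries_can_exceed_one(self):
        base = word_schedule(tuple("duti"), TISKParams())
        maxima = [
            add_global_noise(base, 0.15, rng_seed=s).external.max() for s in range(1000)
        ]
        assert max(maxima) > 1.0
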