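"""Interactive-activation dynamics over input, N-phone and word layers.

Architecture: a time-specific phoneme input layer (phoneme x slot) feeds a
time-invariant N-phone layer (single phones plus all phoneme-pair diphone
nodes), which feeds a word layer with lateral inhibition.  Optionally, word
nodes send positive feedback to their constituent N-phones and weak
negative feedback to every other N-phone.

Update scheme (synchronous, all senders read from the pre-update snapshot;
``f(a) = max(a - rest, 0)`` so only supra-rest activation is transmitted):

* Input nodes latch the stimulus: while a (phoneme, slot) entry of the
  schedule is nonzero the node takes that amplitude; otherwise it decays by
  ``input_phoneme_decay`` per cycle.  The latched value is the stimulus
  amplitude itself, so a half-amplitude blend yields a half-activated node
  rather than integrating to saturation.
* The N-phone layer receives bottom-up drive only while the later member of
  a pair is actually being stimulated (the gating half of the symmetry
  network): on cycle ``t`` the diphone node (x, y) receives
  ``w_phoneme_to_nphone * (M + rho * M.T)[x, y]`` with
  ``M[x, y] = sum_{i<j} a_input[x, i] * gamma**(j-i-1) * ext_t[y, j]``,
  i.e. current stimulation at slot ``j`` combined with the decaying memory
  of earlier slots.  Single-phone nodes are time-invariant copies of the
  input and track it continuously:
  ``w_phoneme_to_nphone * sum_s f(a_input[p, s])``.
* Word nodes receive their graded diphone weights times diphone
  activations, plus single-phone support, minus lateral inhibition
  ``w_word_word_inhibition * sum_{j != i} f(a_j)``.  The word layer uses
  the standard interactive-activation saturating update: excitatory net
  input is scaled by the node's headroom ``(act_max - a)`` and inhibitory
  net input by its distance from the floor ``(a - act_min)``, so
  equilibrium activation is graded in net input strength instead of every
  strongly driven word pinning at the ceiling.
* Feedback (when on) is delivered to each N-phone ``n`` as
  ``fb_positive * sum_{w contains n} f(a_w)`` and
  ``fb_negative * sum_{w not containing n} f(a_w)``.  With the default
  evidence-gated delivery the excitatory part is additionally scaled by
  ``e_n * (act_max - a_n)``, where ``e_n`` is a slowly decaying trace of
  the bottom-up evidence the node has received (for single phones, the
  pooled input-layer activation; for diphones, a leaky integral of their
  gated coincidence drive), and the inhibitory part is scaled by
  ``f(a_n)``.  Top-down support therefore amplifies and sustains nodes for
  which there has been bottom-up evidence, but cannot conjure activation
  out of silence — which is what separates noise-driven phoneme
  restoration from silence replacement.

All activations are clipped to ``[act_min, act_max]`` after each cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diphones import InputSchedule, graded_weights, open_diphones
from .params import TISKParams
from .phonolex import Lexicon, PhonemeInventory

__all__ = ["Network", "NetworkState", "TrialTrace", "build_network", "step", "run_trial"]


@dataclass
class Network:
    """Precompiled connectivity for a lexicon/inventory/parameter triple."""

    lexicon: Lexicon
    inventory: PhonemeInventory
    params: TISKParams
    gap_kernel: np.ndarray  # (S, S) strict upper triangle gamma**(j-i-1)
    word_diphone_w: np.ndarray  # (W, P*P) graded diphone weights per word
    word_single_w: np.ndarray  # (W, P) phoneme occurrence counts per word
    diphone_member: np.ndarray  # (W, P*P) 0/1 constituency masks
    single_member: np.ndarray  # (W, P)

    @property
    def n_phonemes(self) -> int:
        return len(self.inventory)

    @property
    def n_slots(self) -> int:
        return self.params.n_slots

    @property
    def n_words(self) -> int:
        return len(self.lexicon)

    @property
    def n_nphone_nodes(self) -> int:
        """Single phones plus one node per ordered phoneme pair (P + P**2)."""
        return self.n_phonemes + self.n_phonemes**2

    def constituent_nphones(self, label: str) -> set:
        """A word's N-phone constituents: its phonemes and ordered open diphones."""
        word = self.lexicon.phonemes(label)
        return set(word) | set(open_diphones(word))


@dataclass
class NetworkState:
    a_input: np.ndarray  # (P, S)
    a_single: np.ndarray  # (P,)
    a_diphone: np.ndarray  # (P, P)
    a_word: np.ndarray  # (W,)
    ev_diphone: np.ndarray | None = None  # (P, P) bottom-up evidence trace
    cycle: int = 0


@dataclass
class TrialTrace:
    """Per-cycle activation histories; row t is the state after cycle t."""

    word: np.ndarray  # (T, W)
    single: np.ndarray  # (T, P)
    labels: tuple[str, ...]
    symbols: tuple[str, ...]
    diphone: np.ndarray | None = None  # (T, P, P)
    input: np.ndarray | None = None  # (T, P, S)

    @property
    def n_cycles(self) -> int:
        return self.word.shape[0]

    def word_activation(self, label: str) -> np.ndarray:
        return self.word[:, self.labels.index(label)]

    def single_activation(self, symbol: str) -> np.ndarray:
        return self.single[:, self.symbols.index(symbol)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (cycle, layer, node, activation) rows for word + single layers."""
        rows = []
        for j, lab in enumerate(self.labels):
            rows.append(
                pd.DataFrame(
                    {
                        "cycle": np.arange(self.n_cycles),
                        "layer": "word",
                        "node": lab,
                        "activation": self.word[:, j],
                    }
                )
            )
        for j, sym in enumerate(self.symbols):
            rows.append(
                pd.DataFrame(
                    {
                        "cycle": np.arange(self.n_cycles),
                        "layer": "single_phone",
                        "node": sym,
                        "activation": self.single[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def build_network(
    lexicon: Lexicon, inventory: PhonemeInventory | None = None, params: TISKParams | None = None
) -> Network:
    """Compile lexicon-dependent weights and membership masks."""
    inventory = inventory or lexicon.inventory
    params = params or TISKParams()
    P = len(inventory)
    idx = {s: i for i, s in enumerate(inventory.symbols)}

    for label, word in lexicon:
        if len(word) > params.n_slots:
            raise ValueError(f"word {label!r} exceeds n_slots={params.n_slots}")

    S = params.n_slots
    j_minus_i = np.arange(S)[None, :] - np.arange(S)[:, None]  # [i, j] = j - i
    gap_kernel = np.where(j_minus_i >= 1, params.gamma ** np.maximum(j_minus_i - 1, 0), 0.0)

    W = len(lexicon)
    word_diphone_w = np.zeros((W, P * P))
    word_single_w = np.zeros((W, P))
    diphone_member = np.zeros((W, P * P))
    single_member = np.zeros((W, P))
    # Diphone->word weights are normalized by the word's total ordered grade
    # sum, rescaled to a 4-phoneme reference, so short and long words compete
    # on the *fraction* of their ordered structure matched rather than on raw
    # pair counts (otherwise long words dominate every trial).  Single-phone
    # support keeps its raw per-occurrence weight: it is order-blind, so
    # amplifying it for short words lets them ride on any word sharing their
    # phonemes.
    ref_grade_sum = sum(graded_weights("wxyz", params.gamma, 0.0).values())
    for w, (_, word) in enumerate(lexicon):
        ordered_sum = sum(graded_weights(word, params.gamma, 0.0).values())
        norm = ref_grade_sum / ordered_sum if ordered_sum > 0 else 1.0
        for (x, y), wt in graded_weights(word, params.gamma, params.rho).items():
            word_diphone_w[w, idx[x] * P + idx[y]] = wt * norm
        for (x, y), _count in open_diphones(word).items():
            diphone_member[w, idx[x] * P + idx[y]] = 1.0
        # binary per phoneme type: per-occurrence counts would hand words
        # with repeated phonemes a permanent order-blind advantage
        for ph in word:
            word_single_w[w, idx[ph]] = 1.0
            single_member[w, idx[ph]] = 1.0

    return Network(
        lexicon=lexicon,
        inventory=inventory,
        params=params,
        gap_kernel=gap_kernel,
        word_diphone_w=word_diphone_w,
        word_single_w=word_single_w,
        diphone_member=diphone_member,
        single_member=single_member,
    )


def initial_state(network: Network) -> NetworkState:
    P, S, W = network.n_phonemes, network.n_slots, network.n_words
    rest = network.params.rest
    return NetworkState(
        a_input=np.full((P, S), rest),
        a_single=np.full(P, rest),
        a_diphone=np.full((P, P), rest),
        a_word=np.full(W, rest),
        ev_diphone=np.zeros((P, P)),
        cycle=0,
    )


def step(
    network: Network,
    state: NetworkState,
    schedule: InputSchedule,
    feedback_on: bool = False,
    lesion_words: bool = False,
) -> NetworkState:
    """One synchronous update; returns the new state (input unchanged)."""
    if state.cycle >= schedule.n_cycles:
        raise ValueError("state.cycle is past the end of the schedule")
    p = network.params
    rest, lo, hi = p.rest, p.act_min, p.act_max
    ext = schedule.external[state.cycle]  # (P, S)

    f_input = np.maximum(state.a_input - rest, 0.0)
    f_single = np.maximum(state.a_single - rest, 0.0)
    f_diphone = np.maximum(state.a_diphone - rest, 0.0)
    f_word = np.maximum(state.a_word - rest, 0.0)

    # --- N-phone bottom-up: memory of earlier slots x current stimulation ---
    M = f_input @ network.gap_kernel @ ext.T  # (P, P): [x, y]
    diphone_drive = p.w_phoneme_to_nphone * (M + p.rho * M.T)
    single_drive = p.w_phoneme_to_nphone * f_input.sum(axis=1)

    # --- word layer (shunting excitation/inhibition) ---
    word_exc = network.word_diphone_w @ f_diphone.ravel()
    word_exc *= p.w_diphone_to_word
    word_exc += p.w_singlephone_to_word * (network.word_single_w @ f_single)
    word_inh = p.w_word_word_inhibition * (f_word.sum() - f_word)  # <= 0
    word_drive = word_exc * (hi - state.a_word) + word_inh * (state.a_word - lo)

    # --- bottom-up evidence traces (gate for top-down support) ---
    ev_d_prev = state.ev_diphone if state.ev_diphone is not None else np.zeros_like(M)
    new_ev_diphone = np.clip(
        ev_d_prev * (1.0 - p.input_phoneme_decay) + (M + p.rho * M.T), 0.0, 1.0
    )

    # --- lexical feedback onto N-phones ---
    fb_single = 0.0
    fb_diphone = 0.0
    if feedback_on and not lesion_words and (p.fb_positive != 0.0 or p.fb_negative != 0.0):
        total_f = f_word.sum()
        # positive support comes from the most active containing word: a
        # coalition of weakly active words must not outvote the winner
        pos_s = (network.single_member * f_word[:, None]).max(axis=0)  # (P,)
        pos_d = (network.diphone_member * f_word[:, None]).max(axis=0).reshape(
            state.a_diphone.shape
        )
        # the inhibitory pool sums over all words NOT containing the node
        neg_s = total_f - network.single_member.T @ f_word
        neg_d = (total_f - network.diphone_member.T @ f_word).reshape(state.a_diphone.shape)
        if p.fb_gated:
            ev_s = np.minimum(f_input.sum(axis=1), 1.0)
            fb_single = (
                p.fb_positive * pos_s * ev_s * (hi - state.a_single)
                + p.fb_negative * neg_s * f_single
            )
            fb_diphone = (
                p.fb_positive * pos_d * ev_d_prev * (hi - state.a_diphone)
                + p.fb_negative * neg_d * f_diphone
            )
        else:
            fb_single = p.fb_positive * pos_s + p.fb_negative * neg_s
            fb_diphone = p.fb_positive * pos_d + p.fb_negative * neg_d

    # --- synchronous state update ---
    stimulated = ext > 0
    new_input = np.where(
        stimulated, np.minimum(ext, hi), state.a_input * (1.0 - p.input_phoneme_decay)
    )
    new_single = state.a_single * (1.0 - p.nphone_decay) + single_drive + fb_single
    new_diphone = state.a_diphone * (1.0 - p.nphone_decay) + diphone_drive + fb_diphone
    if lesion_words:
        new_word = state.a_word
    else:
        new_word = state.a_word * (1.0 - p.word_decay) + word_drive

    return NetworkState(
        a_input=np.clip(new_input, lo, hi),
        a_single=np.clip(new_single, lo, hi),
        a_diphone=np.clip(new_diphone, lo, hi),
        a_word=np.clip(new_word, lo, hi),
        ev_diphone=new_ev_diphone,
        cycle=state.cycle + 1,
    )


def run_trial(
    network: Network,
    schedule: InputSchedule,
    feedback_on: bool = False,
    record_diphones: bool = False,
    record_input: bool = False,
    lesion_words: bool = False,
) -> TrialTrace:
    """Run a rest-initialized trial over the whole schedule.

    Deterministic given the schedule: all stochasticity lives in schedule
    construction.  The full word-layer and single-phone histories are always
    recorded; diphone and input histories on request.
    """
    T = schedule.n_cycles
    state = initial_state(network)
    word_hist = np.empty((T, network.n_words))
    single_hist = np.empty((T, network.n_phonemes))
    diph_hist = np.empty((T,) + state.a_diphone.shape) if record_diphones else None
    input_hist = np.empty((T,) + state.a_input.shape) if record_input else None
    for t in range(T):
        state = step(network, state, schedule, feedback_on=feedback_on, lesion_words=lesion_words)
        word_hist[t] = state.a_word
        single_hist[t] = state.a_single
        if diph_hist is not None:
            diph_hist[t] = state.a_diphone
        if input_hist is not None:
            input_hist[t] = state.a_input
    return TrialTrace(
        word=word_hist,
        single=single_hist,
        labels=network.lexicon.labels,
        symbols=network.inventory.symbols,
        diphone=diph_hist,
        input=input_hist,
    )
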