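# Parameters optimized for running with lexical feedback enabled.
input_phoneme_decay: 0.001
nphone_decay: 0.100
word_decay: 0.050
w_phoneme_to_nphone: 0.100
w_diphone_to_word: 0.050
w_singlephone_to_word: 0.010
w_word_word_inhibition: -0.010
fb_positive: 0.150
fb_negative: -0.050
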