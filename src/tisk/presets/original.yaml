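# Original no-feedback parameterization.
input_phoneme_decay: 0.010
nphone_decay: 0.001
word_decay: 0.010
w_phoneme_to_nphone: 1.000
w_diphone_to_word: 0.050
w_singlephone_to_word: 0.010
w_word_word_inhibition: -0.005
fb_positive: 0.0
fb_negative: 0.0
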