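comparison	up	down
II_vs_I	44	44
III_vs_II	19	39
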