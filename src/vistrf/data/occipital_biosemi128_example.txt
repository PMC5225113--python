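# Example electrode subset: 11 occipital sites on a Biosemi-128 (ABCD) montage.
# Electrode subsets are montage-specific configuration, not analysis constants;
# supply your own list (channel names or 0-based indices) for other montages.
A14
A15
A16
A21
A22
A23
A24
A25
A27
A28
A29
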