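# Bipolar 10-20 montage channel -> scalp region lookup.
# Format: CHANNEL = region   (regions: forehead, left_temporal,
# right_temporal, occipital, hippocampus)
FP1F3 = forehead
FP2F4 = forehead
F7T7 = left_temporal
T7P7 = left_temporal
F8T8 = right_temporal
T8P8 = right_temporal
P7O1 = occipital
P4O2 = occipital
FZCZ = hippocampus
CZPZ = hippocampus
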