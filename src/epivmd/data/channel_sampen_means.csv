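channel,mean_epileptic,mean_nonepileptic
FP1F7,0.66,0.71
F7T7,0.78,0.67
T7P7,0.86,0.76
P7O1,0.83,0.79
FP1F3,0.75,0.66
F3C3,0.60,0.65
C3P3,0.65,0.70
P3O1,0.73,0.81
FP2F4,0.61,0.64
F4C4,0.59,0.70
C4P4,0.61,0.75
P4O2,0.66,0.71
FP2F8,0.79,0.89
F8T8,0.86,0.81
T8P8,0.95,0.84
P8O2,0.91,0.97
FZCZ,0.45,0.58
CZPZ,0.71,0.66
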