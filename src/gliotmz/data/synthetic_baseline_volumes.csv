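# synthetic stand-in for the unpublished diagnosis-volume sample behind the
# cohort generator's kernel density estimate; values span the range of
# pre-chemotherapy low-grade glioma volumes (cm^3)
volume_cm3
18
25
38
52
70
95
130
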