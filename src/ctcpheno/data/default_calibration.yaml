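epithelial_ratio_range: [0.01, 0.28]
mesenchymal_ratio_range: [0.88, 22.5]
min_reference_n: 100
pdl1_negative_range: [10.0, 40.0]
pdl1_positive_range: [60.0, 350.0]
provenance: packaged defaults (MCF-7 / MDA-MB-231 reference ranges)
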