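{
 "catalogue.csv": "7e4481eb024930ab407e9c92adc6aad781fe1067db4df0c62e8d7272d8cff66c",
 "panel_comparison.csv": "aa109f663edf388fafeb80c3a2d91220f14e5a219b5786d4ca216ddc04d919db",
 "reference_clusters.csv": "4de9cab6bd1e41845f0afeb906602b4c6194c3f36c78e54be9e9bd73cc671d50",
 "reference_scores.csv": "4d5ff5e201ab52144c98ca01995289b0957f2ee145cfba1b1f538c70500155d6"
}
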