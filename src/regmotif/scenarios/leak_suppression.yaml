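# Leaky-transcript suppression: hypoxia shuts MITF transcription and drives
# miR-155; compare residual-mRNA clearance with and without the
# miRNA-enhanced degradation arm across a strength (lam) grid.
scenario: leak-suppression
params: {beta_mrna: 1.0, delta_mrna: 0.5, lam: 2.0, beta_mir: 1.0, delta_mir: 1.0}
hypoxia_onset: 5.0
t_end: 25.0
lam_grid: [0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5]
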