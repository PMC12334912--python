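# SOX10 -> MITF input-function comparison: transfer curves, sensitivities,
# and rheostat phenotype zoning along an MITF sweep.
scenario: input-functions
linear: {a: 1.0}
saturated: {v_max: 1.0, k_half: 0.3}
sigmoidal: {v_max: 1.0, k_half: 0.5, hill_n: 4.0}
grid: {start: 0.0, stop: 2.0, num: 201}
phenotype_map: {boundaries: [0.25, 0.5, 0.75], gray_width: 0.03}
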