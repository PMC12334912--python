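# Positive-feedback-loop bifurcation scan over ATF2 activity: the default
# cooperative parameterization is bistable with both folds inside the
# physical range (reversible switching); the basal-activity variant pushes
# the left fold below zero (irreversible); the hill_n = 1 variant loses
# bistability entirely.
scenario: bifurcation
params: {}
grid: {start: 0.0, stop: 3.0, num: 41}
physical_min: 0.0
irreversible_basal: 1.5
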