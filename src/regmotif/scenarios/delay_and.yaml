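# Sign-sensitive delay, AND-gated coherent feedforward loop: the MITF
# response lags SOX10 when the miR-155-driving signal is turned OFF, stays
# near-synchronous when it is turned back ON, and transient signal drops
# are rejected (persistence detection).
scenario: delay-and
gate: AND
logic_mode: threshold
signal: {phase_on: 10.0, phase_off: 10.0, phase_tail: 12.0}   # phase durations
short_pulse: 0.3
epsilon: 0.05
n_draws: 20
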