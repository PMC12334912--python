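# Sign-sensitive delay, OR-gated coherent feedforward loop: mirrored logic —
# MITF lags SOX10 when the signal turns ON, responds promptly (and to
# transient drops) when it turns OFF.
scenario: delay-or
gate: OR
logic_mode: threshold
signal: {phase_on: 10.0, phase_off: 10.0, phase_tail: 12.0}
short_pulse: 0.3
epsilon: 0.05
n_draws: 20
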