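# Quasi-static hysteresis sweep of ATF2 activity plus the four-phase replay
# (moderate -> high -> back to moderate -> low): SOX10 switches OFF at the
# right fold, stays trapped OFF when ATF2 merely returns to its initial
# level, and only switches back ON below the left fold.
scenario: hysteresis
params: {}
grid: {start: 0.0, stop: 3.0, num: 41}
dwell: 30.0
replay: {levels: [1.5, 2.8, 1.5, 0.5], duration: 30.0}
state_map: {boundaries: [0.25, 0.55], gray_width: 0.03}
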