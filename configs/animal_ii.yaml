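# Unstable-ALT animal: 41 kg, electrode-polarisation walk on the ALT
# threshold (alt_instability = 2), BIP baseline pattern, ventilator at
# 12/min with 1.5 s mandatory inspiration and a 7.5 V burst start voltage.
preset: animal_II
seed: 1
run_sdcurve: true
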