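# Consistent reference animal: 49 kg, stable ALT electrodes, ALT baseline
# pattern, ventilator at 13/min with 1.4 s mandatory inspiration.
preset: animal_I
seed: 1
run_sdcurve: true
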