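# Default simulation configuration (see ddiscreen.simulate.SimulationConfig
# for every field and its default).  The seed is mandatory and deliberately
# absent here: pass --seed on the command line or add a `seed:` entry.
n_patients: 2000
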