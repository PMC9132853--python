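"""Which tissue compartment generates the observable magnetic field?

Exploits the linearity of the magnetostatic problem: the vector potential
is solved separately for each current source — extracellular volume
currents, recruited (active) intracellular currents, non-recruited
(passive) intracellular currents, and fat-layer currents — and the
per-domain RMS at the surface channel is normalised by the total field.
Configuration: 0.2 cm fat, activation depth 0.5 cm.
"""

from myofield import ExperimentConfig, contribution_report, run_experiment

cfg = ExperimentConfig(depth=0.5, d_fat=0.2, contributions=True)
result = run_experiment(cfg)
table = contribution_report(result)
print(table.round(3).to_string())
print()
print("Rows are current-source domains, columns the magnetic components at")
print("the channel; values are RMS contributions normalised by the total")
print("observable field.  Values above 1 mean that domain alone would give")
print("a larger signal than the total: domains interfere destructively.")
print("The fibre-aligned component B_l_par receives no intracellular")
print("contribution at all (a current has no field along itself), and the")
print("domain fields sum to the total exactly (superposition closure).")
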