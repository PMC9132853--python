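"""Depth sweep: how EMG and MMG amplitudes decay with source depth.

Stimulates the recruited fibre line at 0.3 cm and 1.1 cm below the muscle
surface (no fat) and compares the RMS of the measurement vector
[φ, B_l∥, B_t∥, B_t⊥] at a single surface channel, normalised to the
shallow run — the core spatial-selectivity experiment.  Runtime is a few
tens of seconds at the desk-scale grid.
"""

from dataclasses import replace

from myofield import ExperimentConfig, run_experiment

base = ExperimentConfig()
cache = {}
runs = {d: run_experiment(replace(base, depth=d), cache) for d in (0.3, 1.1)}

print("component        RMS(d=0.3)    RMS(d=1.1)    ratio")
for comp, unit in (("phi", "mV"), ("B_l_par", "pT"),
                   ("B_t_par", "pT"), ("B_t_perp", "pT")):
    shallow = runs[0.3].component_rms(comp)
    deep = runs[1.1].component_rms(comp)
    print(f"{comp:12s} {shallow:10.4f} {unit}  {deep:10.4f} {unit}  {deep/shallow:8.4f}")
print()
print("Deeper sources attenuate every component; the normalised ratio is the")
print("depth-selectivity figure of merit (smaller = more selective channel).")
print("Absolute amplitudes scale with the one-cell cross-section of the")
print("recruited fibre line and are therefore resolution dependent; the")
print("ratios are the physically meaningful output.")
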