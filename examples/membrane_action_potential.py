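"""Space-clamped muscle-fibre action potential.

Integrates the Hodgkin–Huxley membrane model at a single point with the
reference stimulus pulse (onset 1 ms, 0.1 ms duration) and prints the AP
peak and repolarisation figures.  This is the microscale building block
that drives every simulated EMG/MMG signal.
"""

import numpy as np

from myofield import membrane as mb

state = mb.MembraneState.resting((1, 1, 1), n_units=1)
stim = mb.StimulusProtocol(onset=1.0)
mask = np.ones_like(state.v_m, dtype=bool)

times, volts = [], []
while state.time < 15.0:
    mb.integrate_reaction(state, dt=0.01, n_steps=1, stimulus=stim, stim_mask=mask)
    times.append(state.time)
    volts.append(state.v_m.ravel()[0])

volts = np.array(volts)
peak = volts.max()
t_peak = times[int(np.argmax(volts))]
print(f"resting potential : {volts[0]:8.2f} mV")
print(f"AP peak           : {peak:8.2f} mV at t = {t_peak:.2f} ms")
print(f"V_m at t = 15 ms  : {volts[-1]:8.2f} mV (repolarised)")
print()
print("The stimulus depolarises the membrane by ~140 mV over 0.1 ms; the")
print("sodium upstroke carries it above 0 mV and potassium repolarises it")
print("within a few milliseconds - the classic action-potential shape.")
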