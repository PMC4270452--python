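"""Frequency-dependent activation of a single model astrocyte.

Simulates an isolated G-ChI astrocyte driven through a Tsodyks-Markram
equivalent synapse by 30 s pulse trains of increasing frequency, computes the
responsiveness at each frequency, and locates the exact onset frequency (the
inflection of the responsiveness curve).
"""

import numpy as np

from astrofilter import default_parameter_path, find_rest_state, load_parameters
from astrofilter.sweeps import exact_onset_for_degree

gchi, gjc, tm = load_parameters(default_parameter_path())
rest = find_rest_state(gchi)
print(f"resting state: Ca = {rest.C:.3f} uM, IP3 = {rest.I:.3f} uM, h = {rest.h:.2f}")

frequencies = np.linspace(0.5, 10, 15)
onset, curve = exact_onset_for_degree(0, frequencies, gchi, gjc, tm, rest=rest)

print("\nstimulation frequency (Hz) -> responsiveness (AU):")
for f, r in zip(curve.frequencies, curve.r):
    bar = "#" * int(r * 8)
    print(f"  {f:5.2f}  {r:6.3f}  {bar}")

print(f"\nexact onset frequency: {onset.frequency_hz:.2f} Hz")
print("Below this frequency Ca2+ rises to a steady sub-threshold plateau;")
print("above it, IP3 crosses the CICR threshold and the cell fires Ca2+ spikes,")
print("so the responsiveness curve inflects sharply upward.")
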