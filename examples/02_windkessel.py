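"""Couple an aortic flow waveform to a three-element Windkessel outlet.

Integrates the RCR model to its periodic state and prints systemic pressures;
with the default parameters the model reproduces a textbook 120/80-like
pressure in mmHg from a 5 l/min flow waveform.
"""

import numpy as np

import aortaflow as af

MMHG = 133.322

waveform = af.aortic_waveform()
params = af.WindkesselParams()  # Rp = 8e6, C = 1e-8, Rd = 1.4e8 (SI)

trace = af.simulate_windkessel(params, waveform, tolerance=0.1)
print(f"converged after {trace.n_cycles} cycles "
      f"(cycle-to-cycle residual {trace.periodicity_residual:.2g} Pa)")
print(f"pressure: {trace.pressure.max() / MMHG:.0f}/"
      f"{trace.pressure.min() / MMHG:.0f} mmHg, "
      f"mean {trace.mean / MMHG:.0f} mmHg")

# frequency response: the oscillatory impedance filters high harmonics
for k in (0, 1, 4, 10):
    z = af.impedance(params, 2 * np.pi * k / waveform.period)
    print(f"|Z| at harmonic {k:2d}: {abs(z):.3g} Pa s/m3")
# |Z| falls from Rp+Rd at DC toward Rp at high frequency: the compliance
# absorbs pulsatility while the distal bed sets the mean pressure.
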