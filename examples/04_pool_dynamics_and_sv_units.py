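"""RRP depletion dynamics and conversion to vesicle units.

Cumulative release versus step duration is fitted with the sum of a
saturating exponential (pool depletion) and a line (sustained release);
rates convert to vesicles with 40 aF per vesicle, 12 active zones per cell
and 0.23 a.u. of iGluSnFR-AUC per vesicle.
"""

import numpy as np

import ihcsynapse as ihc
from ihcsynapse.protocols import make_protocol
from ihcsynapse.synthgen import cumulative_release, sample_ground_truth

syn = sample_ground_truth(1, seed=7).synapses[0]
durations = np.array([2.0, 5.0, 10.0, 20.0, 50.0, 100.0])
q = cumulative_release(-23.0, durations, syn)   # pool protocol at -23 mV

fit = ihc.fit_pool(durations, q)
print(f"pool fit: RRP {fit.rrp_size:.2f} a.u. (true {syn.rrp_au:.2f}), "
      f"tau {fit.tau_ms:.1f} ms (true {syn.tau_depletion_ms:.1f}), "
      f"sustained {fit.slope_per_s:.1f} a.u./s "
      f"(true {syn.sustained_au_per_s:.1f})")

print(f"RRP in vesicles: {ihc.sv_convert(fit.rrp_size, 'au'):.1f} SV")
print(f"sustained (synaptic): "
      f"{ihc.sv_convert(fit.slope_per_s, 'au_per_s'):.0f} SV/s per AZ")
print(f"242 fF/s of whole-cell capacitance rise = "
      f"{ihc.sv_convert(242.0, 'fF_per_s'):.0f} SV/s per AZ")
# The whole-cell rate exceeds the synaptic one because whole-cell
# capacitance also reports extrasynaptic exocytosis.
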