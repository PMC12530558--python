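"""Passive cable simulation: time constant, EPSP attenuation and NMDA plateau.

The dendritic tree is discretised into compartments (≤ min(0.1·λ, 10 µm)),
spine membrane is folded in through F(x), and glutamatergic synapses combine
dual-exponential AMPA and magnesium-blocked NMDA conductances.
"""

import numpy as np

import spnmorph as sp
from spnmorph.cable import (PASSIVE_PRESETS, build_cable_model,
                            clustered_drive, epsp_attenuation, measure_tau)

recon, _ = sp.sample_morphology(sp.MOUSE, seed=2)
passive = PASSIVE_PRESETS["mouse"]


def f_corr(x):
    return sp.spine_correction(x, sp.MOUSE.spine_model, sp.MOUSE.f_spines)


model = build_cable_model(recon, passive, f_correction=f_corr)
print(f"{model.n_comp} compartments")

# membrane time constant from the somatic decay after a brief pulse
tau = measure_tau(model)
print(f"somatic τ = {tau:.2f} ms")

# EPSP attenuation from a terminal tip to the soma
segs = sp.partition_segments(recon)
term = max((s for s in segs if s.is_terminal), key=lambda s: s.length)
prof = epsp_attenuation(model, term.index)
print(f"EPSP peak at synapse {prof.amplitudes[0]:.2f} mV → "
      f"soma {prof.soma_amplitude:.3f} mV "
      f"(attenuation ×{prof.amplitudes[0] / prof.soma_amplitude:.0f})")

# clustered input: 10 synapses, 1 ms apart, mid-terminal;
# blocking NMDA removes the sustained plateau
intact = clustered_drive(model, term.index, t_stop=300.0)
blocked = clustered_drive(model, term.index, nmda_on=False, t_stop=300.0)
print(f"clustered input: local peak {intact.local_peak_mV:.1f} mV, "
      f"plateau {intact.plateau_duration_ms:.1f} ms intact "
      f"vs {blocked.plateau_duration_ms:.1f} ms with NMDA blocked")
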