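"""Measure capacitance and input conductance from simulated recordings.

Capacitance comes from charge integration of the membrane-test transient
(C = Q/ΔV); input conductance is the two-point slope between the −70 and
−50 mV holding currents of the voltage-step family.
"""

from patchkit import (
    compute_input_conductance,
    estimate_capacitance,
    simulate_membrane_test,
    simulate_voltage_clamp_family,
    standard_neuron,
    vc_step_protocol,
)
from patchkit.cohort import true_input_conductance

params = standard_neuron()
mt = simulate_membrane_test(params, seed=0, noise_sd_pA=1.0)
cm = estimate_capacitance(mt)
print(f"capacitance: estimated {cm:.2f} pF, true {params.Cm_pF:.2f} pF")

vc = simulate_voltage_clamp_family(params, vc_step_protocol(), seed=0, noise_sd_pA=2.0)
gin = compute_input_conductance(vc)
print(f"input conductance: estimated {gin:.3f} nS, "
      f"model slope {true_input_conductance(params):.3f} nS")
print("(the slope exceeds the leak conductance because some K channels are "
      "already open between −70 and −50 mV)")
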