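"""Simulate one model neuron's voltage-clamp and current-clamp families.

Prints the peak sodium current density in the −20..0 mV band and the total
number of evoked action potentials over the 32-step, 3 pA current family —
the two intrinsic measures used to quantify excitability phenotypes.
"""

from patchkit import (
    count_evoked_aps,
    extract_iv_table,
    simulate_current_clamp_family,
    simulate_voltage_clamp_family,
    standard_neuron,
    summarize_band,
    vc_step_protocol,
)
from patchkit.intrinsic import NA_BAND, K_BAND

params = standard_neuron()
print(f"cell: Cm={params.Cm_pF} pF, g_Na={params.g_Na_nS} nS, "
      f"g_leak={params.g_leak_nS} nS")

vc = simulate_voltage_clamp_family(params, vc_step_protocol())
iv = extract_iv_table(vc, params.Cm_pF)
na = summarize_band(iv, NA_BAND, "na_density")
ks = summarize_band(iv, K_BAND, "kslow_density")
print(f"Na band mean (−20..0 mV):   {na:8.1f} pA/pF  (inward, hence negative)")
print(f"slow-K band mean (50..90):  {ks:8.1f} pA/pF  (sustained outward)")

cc = simulate_current_clamp_family(params)
n_aps = count_evoked_aps(cc)
print(f"evoked APs over 32 x 3 pA steps: {n_aps}")

half = standard_neuron(g_Na_nS=params.g_Na_nS * 0.5)
n_half = count_evoked_aps(simulate_current_clamp_family(half))
print(f"same cell with g_Na halved:      {n_half}  "
      "(reduced sodium conductance -> hypoexcitability)")
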