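"""Catalytic rate of the full RNP by the fixed-off-rate method.

Fast catalysis (full enzyme, k_cat ~ 1.9e-3 1/s at 22 degC) makes an
incubation series impractical, so a single reactive complex is diluted after
0.5 min and the decay is fit to a double exponential with both off-rates
fixed at independently measured values; the slow rate is k_cat + k_off_S, so
k_cat is the only free rate parameter.
"""

from anisokin import Protocol, OpticalParams, kcat_fixed_offrates, \
    simulate_polarized_trace
from anisokin import reference as ref
from anisokin.pipeline import trace_to_curve

rates = ref.WT_22C
protocol = Protocol.reactive(incubation_time=30.0, duration=3000.0,
                             temperature=rates.temperature)
trace = simulate_polarized_trace(protocol, rates, OpticalParams(), seed=2)
curve = trace_to_curve(trace)
fit = kcat_fixed_offrates(curve, k_off_S=rates.k_off_S, k_off_P=rates.k_off_P)

print(f"true k_cat   : {rates.k_cat * 1e3:.2f} x1e-3 1/s")
print(f"fitted k_cat : {fit['k_cat'] * 1e3:.2f} +/- {fit.stderr['k_cat'] * 1e3:.2f}")
print(f"flags        : {fit.flags or 'none'}")
# The on-enzyme modification rate is recovered from a single decay because
# the two dissociation channels are pinned by independent measurements.
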