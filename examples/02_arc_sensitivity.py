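"""ARC sensitivity of ethanol production at selected metabolic states.

lambda_ARC = lambda_NADH - lambda_NAD classifies the NAD(H) pool as
limiting (<0), in excess (>0) or neutral (0) for an objective. The ethanol
sensitivity uses the bi-level procedure: biomass is maximised first, then
ethanol is maximised with biomass pinned, and the duals of the second LP
are read.
"""

from arcflux import make_core_network, objective_sensitivity_at_state

net = make_core_network()

for qx, qo, where in [
    (6.0, 10.0, "right of the line (fully aerobic)"),
    (6.0, 5.0, "just left of the line (respiro-fermentative)"),
    (6.0, 1.0, "deeply oxygen-limited"),
]:
    rec = objective_sensitivity_at_state(net, {"EX_xyl": qx, "EX_o2": qo})
    print(f"state q_xyl={qx}, q_O2={qo:5.1f}  [{where}]")
    print(f"   mu = {rec.extras['mu']:.3f} 1/h, max q_etoh = "
          f"{rec.extras['secondary_optimum']:.2f} mmol/gDW/h")
    print(f"   lambda_ARC^etoh (cytosolic) = {rec.arc:+.4f}  -> {rec.classification['c']}")
print("-> near the line extra reducing capacity would buy ethanol (limiting);")
print("   at very low oxygen the cell cannot re-oxidise it (excess or neutral).")
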