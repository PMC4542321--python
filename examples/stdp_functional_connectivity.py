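"""STDP run: selectivity change and the efficacy-vs-dPO profile.

Trains a reduced salt-and-pepper network at a single stimulus orientation
with the multiplicative pair rule (all excitatory synapses plastic), then
freezes the weights, measures tuning with the nine-angle protocol, and fits
a0 + 2 a1 cos(pi dPO / 90) to the binned efficacy change per preferred-
orientation difference.  a0 > 0 is the mean potentiation (alpha > 0);
a1 > 0 is functional connectivity generated by the rule.
"""

import balv1 as b

geom = b.build_geometry(1600, 400, 1.0)
rec = b.RecurrentParams(k=100.0)
neuron, ff, stdp = b.NeuronParams(), b.FeedforwardParams(), b.STDPParams()

layout = b.assign_orientations(geom, "random", seed=0)
graph = b.sample_connectivity(geom, b.ConnectivityParams(k=100.0, sigma=0.2), seed=10)
proto = b.SimProtocol(t_total=5000.0, seed=20)

before = b.measure_tuning(b.run_protocol(graph, layout, neuron, ff, rec, proto))
print(f"window integral alpha = {stdp.alpha:.3f} ms (> 0: net potentiation)")

sched = b.PlasticitySchedule(t_plastic=13_333.0, t_measure=5000.0, theta_train_deg=0.0)
result = b.apply_plasticity(graph, layout, neuron, ff, rec, stdp, sched, seed=30)
after = b.measure_tuning(b.run_protocol(result.graph, layout, neuron, ff, rec, proto))

osi0 = b.population_summary(before).loc["E", "mean_osi"]
osi1 = b.population_summary(after).loc["E", "mean_osi"]
print(f"mean OSI_E: {osi0:.3f} -> {osi1:.3f} after {sched.t_plastic / 1000:.1f} s of STDP")

fit = b.bin_and_fit_dw(result.graph, before.po_deg[:1600], reference=1.0)
print(f"efficacy change vs dPO: a0 = {fit.a0:.4f}, a1 = {fit.a1:.5f}")
print("  a0: mean strengthening of E->E synapses;")
print("  a1: cosine modulation by PO difference (functional connectivity).")
print("  Selectivity rises because a0 outgrows a1 - in spite of the")
print("  functional connectivity, not because of it.")
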