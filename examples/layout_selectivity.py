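"""Orientation map vs salt-and-pepper selectivity in the spiking network.

Builds a reduced patch (1600 E / 400 I, K = 100), runs the nine-angle
protocol for both feed-forward layouts with identical parameters, and
compares the mean excitatory orientation selectivity index.  The
salt-and-pepper layout comes out more selective: the orientation map's
distance-dependent connectivity is functional connectivity, and in the
balanced state a modulated recurrent profile suppresses the tuned part of
the activity.
"""

import numpy as np

import balv1 as b

geom = b.build_geometry(1600, 400, 1.0)
rec = b.RecurrentParams(k=100.0)
neuron, ff = b.NeuronParams(), b.FeedforwardParams()

for mode in ("random", "map"):
    layout = b.assign_orientations(geom, mode, seed=0)
    graph = b.sample_connectivity(geom, b.ConnectivityParams(k=100.0, sigma=0.2), seed=10)
    proto = b.SimProtocol(t_total=5000.0, seed=20)
    spikes = b.run_protocol(graph, layout, neuron, ff, rec, proto)
    tuning = b.measure_tuning(spikes)
    s = b.population_summary(tuning)
    corr = b.circular_correlation(np.rad2deg(layout.theta_e), tuning.po_deg[:1600])
    label = "salt-and-pepper" if mode == "random" else "orientation map"
    print(
        f"{label:16s}: mean OSI_E = {s.loc['E', 'mean_osi']:.3f}, "
        f"rate_E = {s.loc['E', 'mean_rate_hz']:.2f} Hz, "
        f"corr(PO, theta_ff) = {corr:.2f}"
    )
print(
    "\nSame parameters, same connectivity statistics in physical space - only"
    "\nthe arrangement of feed-forward preferences differs. Higher OSI for"
    "\nsalt-and-pepper is the balanced-state prediction."
)
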