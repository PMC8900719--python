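"""Recover the propagation direction of simulated ring activity.

The four-node design admits axons into the inter-node channels only in
the clockwise sense, so spontaneous events should traverse the ring in
cycle order.  This simulates clockwise events, groups the resulting
spikes into 10 ms network events, and labels each event from the rank
order of its segment onsets.
"""

import meamask as mm
from meamask.synthetic import ground_truth_spike_events

grid = mm.build_grid()
design = mm.generate_network_design(center=(1837.5, 1050.0))
_, (groups,) = mm.rasterize_design(mm.MicrostructureLayout([design]), grid)

params = mm.ActivitySimParams(duration_s=100.0, event_rate_hz=1.0,
                              direction="clockwise", seed=0)
truth = mm.draw_network_events(groups, params)
spikes = ground_truth_spike_events(truth)
result, net_events = mm.analyze_directionality(spikes, groups,
                                               span_ms=10.0)

transit_ms = 1000.0 * truth.channel_transit_s[0]
print(f"simulated events:     {truth.n_events} "
      f"({truth.n_spikes} spikes on {groups.all_electrodes().size} "
      "electrodes)")
print(f"channel transit time: {transit_ms:.2f} ms per 100 um channel "
      "at 0.4 m/s")
print(f"grouped events:       {result.n_events}")
print(f"clockwise:            {result.n_clockwise}   anticlockwise: "
      f"{result.n_anticlockwise}   ambiguous: {result.n_ambiguous}")
print(f"clockwise fraction:   {result.clockwise_fraction:.3f} "
      f"(95 % CI {result.ci_low:.3f}-{result.ci_high:.3f})")
# A fraction near 1 reproduces the designed unidirectional propagation;
# reversing the simulator direction drives it to 0.
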