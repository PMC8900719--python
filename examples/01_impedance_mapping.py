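"""Locate a PDMS microstructure on the electrode grid from simulated
impedance-test recordings.

Builds one four-node network at the center of the acquired region,
simulates the 25-patch impedance acquisition (16 mV peak-to-peak, 1 kHz
test sinusoid), thresholds the assembled amplitude map into a measured
coverage map, and checks it against the design-derived expectation.
"""

import numpy as np

import meamask as mm

grid = mm.build_grid()
design = mm.generate_network_design(center=(1837.5, 1050.0))
expected, (groups,) = mm.rasterize_design(
    mm.MicrostructureLayout([design]), grid)

patches = mm.plan_patches(grid)
params = mm.ImpedanceSimParams(duration_s=0.2, seed=0)
imap = mm.simulate_impedance_map(expected, patches, params, grid)
measured = mm.classify_coverage(imap, threshold=8.0)

acquired = ~measured.missing
accuracy = 100.0 * np.mean((measured.labels == expected.labels)[acquired])
agreement = mm.compare_expected_measured(expected, measured)
assessment = mm.assess_openness(measured, groups)

print(f"acquired electrodes:          {int(acquired.sum())} "
      f"({len(patches)} patches of {len(patches[0])})")
print(f"electrodes under the network: {int(expected.uncovered.sum())} "
      "exposed by nodes/channels")
print(f"coverage-label accuracy:      {accuracy:.2f} % of acquired "
      "electrodes match the design truth")
print(f"expected-vs-measured:         {agreement.percent:.1f} % of the "
      f"{agreement.n_expected_uncovered} design-exposed electrodes "
      "measured uncovered")
print(f"network open (all channels unclogged): {assessment.open}")
# Accuracy near 100 % means the 8 mV threshold separates the covered and
# exposed amplitude clusters; agreement of 100 % means no channel clogged.
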