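# Methods

## Electrode grid and coordinates

The chip model is a 120 × 220 rectangular lattice at 17.5 μm pitch
(26,400 electrodes over 3.85 × 2.10 mm). Rows and columns are 0-based,
the linear index is row-major (`index = row * 220 + col`), physical x
runs along columns and y along rows, and positions refer to electrode
centers in μm. At most 1,024 electrodes can be routed to amplifiers at
once; the switch matrix is not modeled beyond this capacity cap.

## Microstructure geometry

The published mask carries 15 networks of four "stomach-shaped" nodes
each; the exact CAD outlines are not available, so nodes are modeled as
discs — only the electrode footprint matters downstream, and at 17.5 μm
pitch the disc/stomach difference moves a handful of boundary
electrodes. Defaults: node radius 125 μm on a ring of radius
175·√2 ≈ 247.5 μm rotated 45°, inter-node channels 10 μm wide and
100 μm long joining consecutive node boundaries clockwise, one 5 μm ×
100 μm redirect channel tangent outside each node, and a 170 μm seeding
opening per node (inside the node footprint, so it does not change the
exposed set). The ring radius and rotation are chosen together so that,
whenever the network center sits on an electrode center, the channel
centerlines coincide with grid columns/rows: every channel then contains
a contiguous chain of electrodes, which keeps the openness rule
meaningful (a channel that threads between electrode columns would be
invisible to it). This default network exposes ~680 electrodes — the
same order as the ~760 reported for a real network; the exact figure
depends on the unavailable CAD outlines. All parameters are
overridable.

Rasterization classifies an electrode *uncovered* iff its center lies
strictly inside a node, opening or channel polygon (center-point rule;
area-fraction weighting is unstable when the channel width is well below
the pitch). Channel heights (4 μm) are irrelevant to planar footprints
and ignored. Electrode groups are assigned with node priority (nodes,
then channels, then redirects), so groups are disjoint even at
junctions; channel groups are ordered by arc length along the clockwise
travel direction.

## Impedance protocol

The acquired region is columns 0–209 ("x > 210" discarded, read as
0-based), tiled by 25 contiguous 24 × 42 patches of 1,008 electrodes
(any disjoint ≤ 1,024-electrode cover works; the tiling is
configurable). Peak-to-peak amplitude is estimated as the spread
between the 99.5th and 0.5th percentiles, which resists outliers; raw
max−min is available. Coverage is thresholded at 8 mV (half the applied
16 mV peak-to-peak) by default. An Otsu mode derives the threshold from
the amplitude histogram, followed by Ridler–Calvard iteration to the
midpoint of the class means: with ~3 % of electrodes exposed the
histogram is extremely imbalanced and the raw 256-bin Otsu split can
land at the edge of the covered cluster rather than in the gap between
the modes.

Expected-vs-measured agreement is the percentage of design-exposed
(expected-uncovered) electrodes that measure uncovered, excluding
unacquired electrodes; per-network breakdowns report mean ± sd across
networks. The openness rule uses the 8-neighborhood (the source
protocol says only "neighboring"). Yield percentages round half-up to
one decimal, matching how such tables are printed. Routing selection
returns the whole region up to 1,024 electrodes and otherwise decimates
uniformly over the index-sorted region — deterministic by construction.
Real routing additionally loses electrodes to switch-matrix conflicts
(685 of 760 in the reference preparation); that hardware behavior is not
simulated, so routed/selected ratios below 1 arise here only from the
capacity cap.

## Synthetic data

*Impedance mode.* Each routed electrode receives
`applied_pp/2 · attenuation · sin(2πft)` plus i.i.d. Gaussian noise
(0.3 mV sd). The attenuation of PDMS-covered electrodes is not
quantified anywhere we know of; the defaults (0.03 covered,
0.95 uncovered) are free parameters chosen to reproduce the strong
bimodality of measured maps. Clogging turns whole channels covered,
drawn per channel by Bernoulli probabilities or injected explicitly.
The parameter default of 5 s per patch matches the acquisition
protocol; tests and the acceptance script use 0.05–0.2 s per patch,
since the percentile peak-to-peak of a 1 kHz sine is fully converged
after a few hundred cycles and the full-rate data (25 × 1,008 channels
× 5 s × 20 kHz) would be needlessly large in memory.

*Activity mode.* Network events form a renewal process: interval =
50 ms minimum plus an exponential whose rate is set so the mean interval
is exactly 1/`event_rate_hz` (the floor keeps consecutive ring
traversals, ~7 ms long, from overlapping inside one grouping window
while leaving the empirical rate unbiased). Each event starts at a
uniformly random node and traverses the ring clockwise or anticlockwise;
node populations fire at the node onset, channel electrodes at channel
entry plus arc-length/velocity (0.4 m/s default, so 0.25 ms per 100 μm
channel), with a 1.5 ms per-node transmission delay and 0.1 ms Gaussian
timing jitter per spike. Spikes are biphasic (difference of two
Gaussians, sharp negative then slower positive lobe), −120 μV at nodes
and 4× larger inside channels — microchannels confine the extracellular
field, which is what makes channel spikes so large in real recordings.
Only a fraction (0.6) of a node's electrodes fire in any one event:
somas cluster into spheroids so few couple directly to the chip, which
reproduces the observed channel-dominated frequency maps. Noise is
i.i.d. Gaussian (10 μV sd); no correlated, line or drift components.
Traces quantize to int16 with a stored μV/LSB scale on write, emulating
acquisition hardware.

What the generator does *not* emulate: biophysical membrane dynamics,
conduction failures or branching, bursting structure within events,
electrode-to-electrode noise correlations, drift, and the vendor's
native file format. Passing tests therefore demonstrate the
correctness of the analysis chain against its own model of the data, not
robustness to every artifact of real recordings.

## Filtering and detection

The high-pass is a 2nd-order Butterworth at 200 Hz, applied
forward-backward by default so detection times are not phase-shifted; a
causal single-pass mode exists for strict protocol fidelity (the
difference moves detection times by < 1 ms, immaterial here). Spikes
are crossings of 5σ by |x| (the 5σ rule is sign-ambiguous in prose;
a negative-only mode implements the extracellular convention), with σ
the plain standard deviation of the whole filtered trace (per
electrode, estimated once) and a MAD-based robust alternative. Within
each 100-sample suppression window, anchored at the first crossing, the
sample of maximal deflection is kept. Spike-triggered averages crop 75
samples either side of each event; boundary events are skipped and
counted.

## Direction statistic

Each network event (spikes within 10 ms of its first spike) is reduced
to one onset per ring segment — first spike per segment by default,
wavefront-style; median optional. The cycle is rotated so the
earliest-onset segment is position 0, and the onsets are Spearman-rank-
correlated against the clockwise positions and, separately, the
anticlockwise positions; the label is the sign of the difference, with
ties and events with < 3 active segments ambiguous. Scoring both
rotations symmetrizes the statistic: after clockwise alignment alone, a
perfect anticlockwise sequence scores only ≈ −0.33 rather than −1,
because the rotation anchor is chosen by the earliest onset. Any
monotone order statistic would do; this one is deterministic, tie-aware
and antisymmetric on mirrored events.

## Pipeline and determinism

`run_full_pipeline` chains simulation → impedance map → classification →
openness → routing → activity → detection → frequency map →
directionality → yield, with all randomness derived from one root seed
(per-stage generators are spawned deterministically), and serializes the
report with sorted keys so equal runs are byte-identical. Default
problem sizes (0.2 s per impedance patch, 20 s of activity on a ~52-
electrode routed subset) keep a full run in seconds while leaving every
statistic well-resolved.

## Known limitations

- Node outlines are parametric stand-ins for the unpublished CAD; the
  exposed-electrode count of a real network cannot be matched exactly.
- The measured 92.7 ± 2.4 % expected-vs-measured agreement of the
  reference chip reflects its unreleased raw data; here the agreement
  behavior is validated property-wise instead (100 % with no clogs,
  strictly decreasing with injected clog fraction).
- Routing losses from switch-matrix conflicts are not simulated.
- The direction analysis assumes one network per recording; overlapping
  simultaneous events in one network merge into a single (usually
  ambiguous) grouped event.
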