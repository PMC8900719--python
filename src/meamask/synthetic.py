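"""Ground-truthed synthetic inputs for both experiments.

Two generators emulate the chip's two acquisition modes:

* impedance-test recordings -- a 16 mV peak-to-peak, 1 kHz sinusoid
  arrives nearly undamped on exposed electrodes and strongly attenuated
  on PDMS-covered ones, acquired patch by patch; optional clogging turns
  channel electrodes covered;
* spontaneous network activity -- network-wide events start at a random
  node and traverse the four-node ring clockwise (or anticlockwise),
  with per-node transmission delays, geometric axonal conduction delays
  inside channels (arc length / velocity), large biphasic spikes that
  are several-fold taller inside microchannels, timing jitter and
  additive Gaussian noise.

All randomness flows from the ``seed`` field of the parameter objects;
with a fixed seed the output is bit-reproducible.  The true PDMS
attenuation of covered electrodes is not known quantitatively, so the
attenuation fractions are free parameters with defaults chosen to
reproduce the observed strong bimodality of the amplitude map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .geometry import COVERED, CoverageMap, ElectrodeGroups
from .impedance import ImpedanceMap, RoutingPattern, peak_to_peak_rows
from .recio import (GroundTruth, SyntheticRecording,  # noqa: F401
                    write_recording)

__all__ = [
    "ImpedanceSimParams", "ActivitySimParams", "SyntheticRecording",
    "GroundTruth", "biphasic_template", "simulate_impedance_patches",
    "simulate_impedance_map", "draw_clog_set", "simulate_network_activity",
    "draw_network_events", "simulate_spike_trace", "write_recording",
    "ground_truth_spike_events",
]


@dataclass
class ImpedanceSimParams:
    """Conditions of the impedance-test acquisition."""

    applied_pp: float = 16.0          # mV peak-to-peak at the reference
    frequency: float = 1000.0         # Hz
    duration_s: float = 5.0           # per routing patch
    fs: float = 20000.0               # Hz
    attenuation_covered: float = 0.03
    attenuation_uncovered: float = 0.95
    noise_sd: float = 0.3             # mV
    clog_prob_internode: float = 0.0
    clog_prob_redirect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.attenuation_covered < self.attenuation_uncovered <= 1:
            raise InvalidParameterError(
                "need 0 < attenuation_covered < attenuation_uncovered <= 1")
        for p in (self.clog_prob_internode, self.clog_prob_redirect):
            if not 0 <= p <= 1:
                raise InvalidParameterError("clog probabilities must be in "
                                            "[0, 1]")
        if min(self.applied_pp, self.frequency, self.duration_s,
               self.fs) <= 0:
            raise InvalidParameterError("signal parameters must be positive")


@dataclass
class ActivitySimParams:
    """Conditions of the spontaneous-activity simulation."""

    fs: float = 20000.0
    duration_s: float = 60.0
    amplitude_uv: float = 120.0        # template peak at node electrodes
    channel_amp_gain: float = 4.0      # extra gain inside microchannels
    conduction_velocity: float = 0.4   # m/s along channels
    node_delay_ms: float = 1.5         # per-node transmission delay
    event_rate_hz: float = 1.0
    min_event_interval_ms: float = 50.0
    direction: str = "clockwise"       # clockwise | anticlockwise | mixed
    p_cw: float = 0.5                  # P(clockwise) when direction="mixed"
    noise_sd: float = 10.0             # uV
    jitter_sd_ms: float = 0.1
    node_participation: float = 0.6    # P(node electrode fires per event)
    seed: int = 0

    def __post_init__(self):
        if self.conduction_velocity <= 0:
            raise InvalidParameterError("conduction velocity must be "
                                        "positive")
        if min(self.fs, self.duration_s, self.amplitude_uv) <= 0:
            raise InvalidParameterError("fs, duration and amplitude must "
                                        "be positive")
        if self.event_rate_hz < 0:
            raise InvalidParameterError("event rate must be >= 0")
        if not 0 <= self.p_cw <= 1:
            raise InvalidParameterError("p_cw must be in [0, 1]")
        if not 0 < self.node_participation <= 1:
            raise InvalidParameterError("node_participation must be in "
                                        "(0, 1]")
        if self.direction not in ("clockwise", "anticlockwise", "mixed"):
            raise InvalidParameterError(f"unknown direction "
                                        f"'{self.direction}'")
        if (self.event_rate_hz > 0
                and self.event_rate_hz * self.min_event_interval_ms
                / 1000.0 >= 1):
            raise InvalidParameterError("event rate incompatible with the "
                                        "minimum event interval")


def biphasic_template(fs: float = 20000.0, amplitude_uv: float = 120.0,
                      neg_sigma_ms: float = 0.15, pos_sigma_ms: float = 0.25,
                      pos_frac: float = 0.45, pos_delay_ms: float = 0.5,
                      length_ms: float = 3.0) -> np.ndarray:
    """Biphasic extracellular spike: sharp negative lobe then a slower
    positive lobe (difference of two Gaussians), normalized so the
    minimum equals ``-amplitude_uv``."""
    n = int(round(length_ms * 1e-3 * fs))
    t = (np.arange(n) - n // 3) / fs * 1e3  # ms, negative peak ~1/3 in
    w = (-np.exp(-t ** 2 / (2 * neg_sigma_ms ** 2))
         + pos_frac * np.exp(-(t - pos_delay_ms) ** 2
                             / (2 * pos_sigma_ms ** 2)))
    return (w / -w.min() * amplitude_uv).astype(np.float64)


def draw_clog_set(groups: ElectrodeGroups, params: ImpedanceSimParams,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw clogged electrodes: each inter-node channel (and each
    redirect channel set) clogs as a whole with its Bernoulli
    probability."""
    rng = rng or np.random.default_rng(params.seed)
    clogged: list[np.ndarray] = []
    for chan in groups.channel_electrodes:
        if rng.random() < params.clog_prob_internode:
            clogged.append(np.asarray(chan, dtype=np.int64))
    if (params.clog_prob_redirect > 0
            and rng.random() < params.clog_prob_redirect):
        clogged.append(np.asarray(groups.redirect_electrodes,
                                  dtype=np.int64))
    if not clogged:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(clogged))


def _impedance_attenuations(truth: CoverageMap, electrodes: np.ndarray,
                            clogged: np.ndarray,
                            params: ImpedanceSimParams) -> np.ndarray:
    flat = truth.labels.ravel()
    att = np.where(flat[electrodes] == COVERED,
                   params.attenuation_covered,
                   params.attenuation_uncovered)
    if clogged.size:
        att[np.isin(electrodes, clogged)] = params.attenuation_covered
    return att


def _simulate_one_patch(truth: CoverageMap, patch: RoutingPattern,
                        params: ImpedanceSimParams, clogged: np.ndarray,
                        rng: np.random.Generator) -> SyntheticRecording:
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs
    base = (params.applied_pp / 2.0
            * np.sin(2 * math.pi * params.frequency * t))
    att = _impedance_attenuations(truth, patch.electrodes, clogged, params)
    traces = att[:, None] * base[None, :]
    if params.noise_sd > 0:
        traces = traces + rng.normal(0.0, params.noise_sd, traces.shape)
    return SyntheticRecording(
        traces=traces.astype(np.float32), routed_electrodes=patch.electrodes,
        fs=params.fs, units="mV",
        ground_truth=GroundTruth(clogged_electrodes=clogged))


def simulate_impedance_patches(truth: CoverageMap,
                               patches: list[RoutingPattern],
                               params: ImpedanceSimParams,
                               groups: ElectrodeGroups | list[ElectrodeGroups]
                               | None = None,
                               clogged_electrodes: np.ndarray | None = None
                               ) -> list[SyntheticRecording]:
    """Simulate the impedance-test recording on every routing patch.

    Each routed electrode carries ``applied_pp * attenuation / 2 *
    sin(2*pi*f*t)`` plus Gaussian noise; attenuation follows the truth
    coverage label, except that clogged channel electrodes use the
    covered attenuation.  The clog set is either given explicitly or
    drawn per channel from the clog probabilities (``groups`` required),
    and is recorded in every patch's ground truth.
    """
    rng = np.random.default_rng(params.seed)
    if clogged_electrodes is None:
        clogged_electrodes = np.empty(0, dtype=np.int64)
        if groups is not None:
            glist = groups if isinstance(groups, list) else [groups]
            parts = [draw_clog_set(g, params, rng) for g in glist]
            parts = [p for p in parts if p.size]
            if parts:
                clogged_electrodes = np.unique(np.concatenate(parts))
    clogged_electrodes = np.asarray(clogged_electrodes, dtype=np.int64)
    return [_simulate_one_patch(truth, p, params, clogged_electrodes, rng)
            for p in patches]


def simulate_impedance_map(truth: CoverageMap,
                           patches: list[RoutingPattern],
                           params: ImpedanceSimParams, grid,
                           clogged_electrodes: np.ndarray | None = None
                           ) -> ImpedanceMap:
    """Streaming convenience: simulate each patch, reduce it to its
    peak-to-peak amplitudes, and discard the traces (the full-rate
    multichannel data never has to be held in memory at once)."""
    rng = np.random.default_rng(params.seed)
    if clogged_electrodes is None:
        clogged_electrodes = np.empty(0, dtype=np.int64)
    clogged_electrodes = np.asarray(clogged_electrodes, dtype=np.int64)
    amps = np.full(grid.n_electrodes, np.nan)
    for patch in patches:
        rec = _simulate_one_patch(truth, patch, params, clogged_electrodes,
                                  rng)
        amps[patch.electrodes] = peak_to_peak_rows(rec.traces)
    return ImpedanceMap(amps.reshape(grid.n_rows, grid.n_cols))


def _event_times(params: ActivitySimParams,
                 rng: np.random.Generator) -> np.ndarray:
    """Event start times: a renewal process whose interval is the
    minimum interval plus an exponential, with the exponential rate set
    so the mean interval is exactly 1 / event_rate_hz."""
    if params.event_rate_hz == 0:
        return np.empty(0)
    refr = params.min_event_interval_ms / 1000.0
    lam = 1.0 / (1.0 / params.event_rate_hz - refr)
    times = []
    t = float(rng.exponential(1.0 / params.event_rate_hz))
    while t < params.duration_s:
        times.append(t)
        t += refr + float(rng.exponential(1.0 / lam))
    return np.asarray(times)


def draw_network_events(groups: ElectrodeGroups, params: ActivitySimParams,
                        rng: np.random.Generator | None = None
                        ) -> GroundTruth:
    """Draw the ground-truth event/spike structure without synthesizing
    traces.

    Each event starts at a uniformly random node and traverses the ring
    in the drawn direction; a node's population fires at the node onset,
    a channel electrode fires at channel entry plus arc-length /
    velocity, and every spike gets independent Gaussian timing jitter.
    Segment onsets (without jitter) are stored per event in cycle-
    position order (node k -> 2k, channel k -> 2k+1).
    """
    rng = rng or np.random.default_rng(params.seed)
    v_um_per_s = params.conduction_velocity * 1e6
    node_delay = params.node_delay_ms / 1000.0
    jit = params.jitter_sd_ms / 1000.0

    starts = _event_times(params, rng)
    n_ev = starts.size
    if params.direction == "clockwise":
        dirs = np.ones(n_ev, dtype=np.int8)
    elif params.direction == "anticlockwise":
        dirs = -np.ones(n_ev, dtype=np.int8)
    else:
        dirs = np.where(rng.random(n_ev) < params.p_cw, 1, -1).astype(np.int8)
    start_nodes = rng.integers(0, 4, size=n_ev).astype(np.int8)

    lengths = np.asarray(groups.channel_lengths_um, dtype=float)
    transit = lengths / v_um_per_s

    sp_el: list[np.ndarray] = []
    sp_t: list[np.ndarray] = []
    onsets = np.full((n_ev, 8), np.nan)

    for i in range(n_ev):
        t0, d, s = float(starts[i]), int(dirs[i]), int(start_nodes[i])
        tau = t0
        for step in range(4):
            node = (s + d * step) % 4
            onsets[i, 2 * node] = tau
            nel = np.asarray(groups.node_electrodes[node], dtype=np.int64)
            # Somas cluster into a spheroid, so only part of the node
            # population couples to the chip in any one event; axons in
            # channels always do.
            if params.node_participation < 1:
                nel = nel[rng.random(nel.size) < params.node_participation]
            times = np.full(nel.size, tau)
            if jit > 0:
                times = times + rng.normal(0.0, jit, nel.size)
            sp_el.append(nel)
            sp_t.append(times)
            # Clockwise leaves node k through channel k; anticlockwise
            # leaves node k through channel k-1, traversed exit-to-entry.
            chan = node % 4 if d == 1 else (node - 1) % 4
            entry = tau + node_delay
            onsets[i, 2 * chan + 1] = entry
            cel = np.asarray(groups.channel_electrodes[chan], dtype=np.int64)
            offs = np.asarray(groups.channel_offsets_um[chan], dtype=float)
            dist = offs if d == 1 else (lengths[chan] - offs)
            times = entry + dist / v_um_per_s
            if jit > 0:
                times = times + rng.normal(0.0, jit, cel.size)
            sp_el.append(cel)
            sp_t.append(times)
            tau = entry + transit[chan]

    if sp_el:
        el = np.concatenate(sp_el)
        tt = np.concatenate(sp_t)
    else:
        el = np.empty(0, dtype=np.int64)
        tt = np.empty(0)
    keep = (tt >= 0) & (tt < params.duration_s)
    el, tt = el[keep], tt[keep]
    order = np.argsort(tt, kind="stable")
    return GroundTruth(spike_electrodes=el[order], spike_times_s=tt[order],
                       event_times_s=starts, event_directions=dirs,
                       event_start_nodes=start_nodes, event_onsets_s=onsets,
                       channel_transit_s=transit)


def simulate_network_activity(groups: ElectrodeGroups,
                              params: ActivitySimParams,
                              routed_electrodes: np.ndarray | None = None
                              ) -> SyntheticRecording:
    """Simulate a spontaneous-activity recording of one network.

    ``routed_electrodes`` defaults to every grouped electrode; a subset
    may be routed instead (as on the real chip, where routing is
    capacity-limited).  Channel (and redirect) electrodes carry the
    template scaled by ``channel_amp_gain``; node electrodes carry the
    unscaled template; i.i.d. Gaussian noise is added everywhere.
    """
    rng = np.random.default_rng(params.seed)
    truth = draw_network_events(groups, params, rng)

    if routed_electrodes is None:
        routed_electrodes = groups.all_electrodes()
    routed_electrodes = np.asarray(routed_electrodes, dtype=np.int64)

    chan_set = set()
    for chan in groups.channel_electrodes:
        chan_set.update(int(e) for e in chan)
    chan_set.update(int(e) for e in groups.redirect_electrodes)

    n = int(round(params.duration_s * params.fs))
    traces = np.zeros((routed_electrodes.size, n), dtype=np.float32)
    if params.noise_sd > 0:
        traces += rng.normal(0.0, params.noise_sd,
                             traces.shape).astype(np.float32)

    template = biphasic_template(params.fs, params.amplitude_uv)
    peak_at = int(np.argmin(template))
    row_of = {int(e): i for i, e in enumerate(routed_electrodes)}
    keep = np.zeros(truth.n_spikes, dtype=bool)
    for j in range(truth.n_spikes):
        e = int(truth.spike_electrodes[j])
        row = row_of.get(e)
        if row is None:
            continue
        keep[j] = True
        s0 = int(round(truth.spike_times_s[j] * params.fs)) - peak_at
        gain = params.channel_amp_gain if e in chan_set else 1.0
        a, b = max(s0, 0), min(s0 + template.size, n)
        if a < b:
            traces[row, a:b] += (gain * template[a - s0:b - s0]).astype(
                np.float32)

    truth_routed = GroundTruth(
        spike_electrodes=truth.spike_electrodes[keep],
        spike_times_s=truth.spike_times_s[keep],
        event_times_s=truth.event_times_s,
        event_directions=truth.event_directions,
        event_start_nodes=truth.event_start_nodes,
        event_onsets_s=truth.event_onsets_s,
        channel_transit_s=truth.channel_transit_s)
    return SyntheticRecording(traces=traces,
                              routed_electrodes=routed_electrodes,
                              fs=params.fs, units="uV",
                              ground_truth=truth_routed)


def simulate_spike_trace(duration_s: float, fs: float = 20000.0,
                         rate_hz: float = 2.0,
                         template: np.ndarray | None = None,
                         noise_sd_uv: float = 10.0,
                         refractory_ms: float = 10.0,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Single-electrode trace with template spikes at a known rate.

    Spike times follow a renewal process (refractory plus exponential
    with the mean interval equal to 1 / rate); returns the float32 trace
    in uV and the true spike times (at the template's negative peak) in
    seconds.  Intended for detector validation at controlled SNR.
    """
    if rate_hz * refractory_ms / 1000.0 >= 1:
        raise InvalidParameterError("rate incompatible with refractory")
    rng = np.random.default_rng(seed)
    if template is None:
        template = biphasic_template(fs)
    peak_at = int(np.argmin(template))
    n = int(round(duration_s * fs))
    trace = (rng.normal(0.0, noise_sd_uv, n).astype(np.float32)
             if noise_sd_uv > 0 else np.zeros(n, dtype=np.float32))
    refr = refractory_ms / 1000.0
    lam = 1.0 / (1.0 / rate_hz - refr)
    times = []
    t = float(rng.exponential(1.0 / rate_hz))
    margin = template.size / fs
    while t < duration_s - margin:
        times.append(t)
        t += refr + float(rng.exponential(1.0 / lam))
    for t in times:
        s0 = int(round(t * fs)) - peak_at
        trace[s0:s0 + template.size] += template.astype(np.float32)
    return trace, np.asarray(times)


def ground_truth_spike_events(truth: GroundTruth, fs: float = 20000.0):
    """Convert ground-truth spikes into detector-style SpikeEvents so the
    propagation analysis can be exercised without trace synthesis."""
    from .spikes import SpikeEvent
    return [SpikeEvent(electrode=int(e), sample=int(round(t * fs)),
                       time_s=float(t), amplitude=-1.0)
            for e, t in zip(truth.spike_electrodes, truth.spike_times_s)]
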