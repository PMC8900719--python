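"""Network-event grouping and propagation-direction analysis.

Spikes from all electrodes of one network are grouped into network-wide
events (everything within a 10 ms window of the event's first spike),
each event is reduced to one onset time per ring segment (4 nodes and 4
inter-node channels, 8 cycle positions), and the ordering of onsets
around the ring labels the event clockwise, anticlockwise, or ambiguous.

The direction statistic is a circularly aligned rank correlation: the
cycle is rotated so the earliest-onset segment sits at position zero,
then the onset times are rank-correlated against the clockwise positions
and, separately, against the anticlockwise positions; the sign of the
score difference gives the label.  Scoring both rotations symmetrizes
the statistic (a perfect anticlockwise sequence is otherwise penalized
by the clockwise alignment rather than mirrored), keeps it deterministic
and makes ties explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidParameterError
from .geometry import ElectrodeGrid, ElectrodeGroups
from .spikes import SpikeEvent

N_SEGMENTS = 8  # node0, channel0, node1, channel1, ... in clockwise order

CLOCKWISE = "clockwise"
ANTICLOCKWISE = "anticlockwise"
AMBIGUOUS = "ambiguous"


@dataclass
class NetworkEvent:
    """One grouped multi-electrode event with per-segment onsets."""

    t_start: float
    t_end: float
    spikes: list[SpikeEvent] = field(default_factory=list)
    segment_onsets: np.ndarray = field(
        default_factory=lambda: np.full(N_SEGMENTS, np.nan))

    @property
    def n_segments_active(self) -> int:
        return int(np.sum(~np.isnan(self.segment_onsets)))

    @property
    def n_spikes(self) -> int:
        return len(self.spikes)


@dataclass
class DirectionalityResult:
    """Aggregate of per-event direction labels."""

    n_events: int
    n_clockwise: int
    n_anticlockwise: int
    n_ambiguous: int
    clockwise_fraction: float | None  # of the directed (cw + acw) events
    ci_low: float | None = None
    ci_high: float | None = None
    labels: list[str] = field(default_factory=list)


def group_network_events(events: list[SpikeEvent], groups: ElectrodeGroups,
                         span_ms: float = 10.0,
                         onset_statistic: str = "first"
                         ) -> list[NetworkEvent]:
    """Group time-sorted spikes into network events.

    A new event opens at any spike not inside an open window; all spikes
    within ``span_ms`` of the event's first spike join it.  The onset of
    a segment is the earliest member spike on that segment's electrodes
    (``onset_statistic="median"`` uses the median instead).  Spikes on
    electrodes outside the groups' segments (e.g. redirect channels)
    join the membership but contribute to no onset.
    """
    if onset_statistic not in ("first", "median"):
        raise InvalidParameterError(f"unknown onset statistic "
                                    f"'{onset_statistic}'")
    seg_of = groups.segment_positions()
    span = span_ms / 1000.0
    out: list[NetworkEvent] = []
    current: list[SpikeEvent] = []

    def close(members: list[SpikeEvent]) -> None:
        t0 = members[0].time_s
        onsets = np.full(N_SEGMENTS, np.nan)
        per_seg: dict[int, list[float]] = {}
        for sp in members:
            pos = seg_of.get(sp.electrode)
            if pos is not None:
                per_seg.setdefault(pos, []).append(sp.time_s)
        for pos, times in per_seg.items():
            onsets[pos] = (min(times) if onset_statistic == "first"
                           else float(np.median(times)))
        out.append(NetworkEvent(t_start=t0, t_end=members[-1].time_s,
                                spikes=list(members),
                                segment_onsets=onsets))

    for sp in events:
        if current and sp.time_s - current[0].time_s <= span:
            current.append(sp)
        else:
            if current:
                close(current)
            current = [sp]
    if current:
        close(current)
    return out


def _aligned_rank_score(positions: np.ndarray,
                        onsets: np.ndarray) -> float:
    """Spearman rho of onset time against cycle position, or 0 when the
    correlation is undefined (constant input)."""
    if np.unique(positions).size < 2 or np.unique(onsets).size < 2:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(positions, onsets).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def classify_event_direction(event: NetworkEvent,
                             min_active_segments: int = 3,
                             tie_tolerance: float = 1e-9
                             ) -> tuple[str, float]:
    """Label one event clockwise / anticlockwise / ambiguous.

    Returns ``(label, score)`` where score is the clockwise-aligned
    minus the anticlockwise-aligned rank correlation of segment onsets
    (positive = clockwise).  Events with fewer than
    ``min_active_segments`` active segments, or with a score within the
    tie tolerance of zero, are ambiguous.
    """
    active = np.flatnonzero(~np.isnan(event.segment_onsets))
    if active.size < min_active_segments:
        return AMBIGUOUS, 0.0
    onsets = event.segment_onsets[active]
    anchor = active[int(np.argmin(onsets))]
    q_cw = (active - anchor) % N_SEGMENTS
    q_acw = (anchor - active) % N_SEGMENTS
    score = (_aligned_rank_score(q_cw, onsets)
             - _aligned_rank_score(q_acw, onsets))
    if score > tie_tolerance:
        return CLOCKWISE, score
    if score < -tie_tolerance:
        return ANTICLOCKWISE, score
    return AMBIGUOUS, score


def directionality_summary(labels: list[str],
                           alpha: float = 0.05) -> DirectionalityResult:
    """Counts, clockwise fraction of the directed events, and a Wilson
    binomial confidence interval for that fraction."""
    n_cw = sum(lab == CLOCKWISE for lab in labels)
    n_acw = sum(lab == ANTICLOCKWISE for lab in labels)
    n_amb = sum(lab == AMBIGUOUS for lab in labels)
    if n_cw + n_acw + n_amb != len(labels):
        raise InvalidParameterError("unknown label in input")
    frac = lo = hi = None
    if n_cw + n_acw > 0:
        frac = n_cw / (n_cw + n_acw)
        from statsmodels.stats.proportion import proportion_confint
        lo, hi = proportion_confint(n_cw, n_cw + n_acw, alpha=alpha,
                                    method="wilson")
        lo, hi = float(lo), float(hi)
    return DirectionalityResult(n_events=len(labels), n_clockwise=n_cw,
                                n_anticlockwise=n_acw, n_ambiguous=n_amb,
                                clockwise_fraction=frac, ci_low=lo,
                                ci_high=hi, labels=list(labels))


def analyze_directionality(spike_events: list[SpikeEvent],
                           groups: ElectrodeGroups, span_ms: float = 10.0,
                           min_active_segments: int = 3
                           ) -> tuple[DirectionalityResult,
                                      list[NetworkEvent]]:
    """Convenience chain: group, classify every event, summarize."""
    net_events = group_network_events(spike_events, groups, span_ms=span_ms)
    labels = [classify_event_direction(ev, min_active_segments)[0]
              for ev in net_events]
    return directionality_summary(labels), net_events


def render_propagation_frames(traces: np.ndarray,
                              routed_electrodes: np.ndarray,
                              window: tuple[int, int], grid: ElectrodeGrid,
                              out_dir, stride: int = 1,
                              fs: float = 20000.0) -> list[str]:
    """Render one image per sample (or per ``stride`` samples) of a time
    window, with per-electrode voltage color-coded at grid positions.

    Returns the written file paths, numbered so the frames concatenate
    into a movie.
    """
    import os

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    start, end = window
    if not (0 <= start < end <= traces.shape[1]):
        raise InvalidParameterError("window out of recording range")
    if stride < 1:
        raise InvalidParameterError("stride must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    xs, ys = grid.position(np.asarray(routed_electrodes, dtype=np.int64))
    vmax = float(np.max(np.abs(traces[:, start:end]))) or 1.0
    paths = []
    for j, s in enumerate(range(start, end, stride)):
        fig, ax = plt.subplots(figsize=(6, 4))
        sc = ax.scatter(xs, ys, c=traces[:, s], s=12, cmap="coolwarm",
                        vmin=-vmax, vmax=vmax)
        fig.colorbar(sc, ax=ax, label="voltage (uV)")
        ax.set_title(f"t = {s / fs * 1000:.2f} ms")
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
        ax.set_aspect("equal")
        path = os.path.join(out_dir, f"frame_{j:05d}.png")
        fig.savefig(path, dpi=90)
        plt.close(fig)
        paths.append(path)
    return paths


def events_to_json(net_events: list[NetworkEvent], labels: list[str],
                   path) -> None:
    import json
    obj = [{"t_start": ev.t_start, "t_end": ev.t_end,
            "n_spikes": ev.n_spikes,
            "n_segments_active": ev.n_segments_active,
            "segment_onsets": [None if np.isnan(v) else float(v)
                               for v in ev.segment_onsets],
            "label": lab}
           for ev, lab in zip(net_events, labels)]
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
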