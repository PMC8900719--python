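"""Recording containers and HDF5 file I/O.

A recording is a channels x samples voltage matrix plus the routing
(which electrode each row came from), the sampling rate, and -- for
synthetic data -- the generating ground truth.  On disk, traces are
quantized to 16-bit integers with a stored uV-per-LSB scale, emulating
the acquisition hardware.

HDF5 layout (version 1)::

    /traces            int16, (n_channels, n_samples); attrs: scale (units/LSB)
    /fs                float64 scalar, Hz
    /units             string scalar, "uV" or "mV"
    /mapping/electrode int32; /mapping/row int32; /mapping/col int32
    /ground_truth/spike_electrode, spike_time_s
    /ground_truth/event_time_s, event_direction, event_start_node
    /ground_truth/event_onsets_s       (n_events, 8)
    /ground_truth/channel_transit_s    (4,)
    /ground_truth/clogged_electrodes
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import SchemaError
from .geometry import ElectrodeGrid

SCHEMA_VERSION = 1

_REQUIRED = ("traces", "fs", "mapping/electrode", "mapping/row",
             "mapping/col")


@dataclass
class GroundTruth:
    """True spike times, events and clogging behind a synthetic recording."""

    spike_electrodes: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))
    spike_times_s: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.float64))
    event_times_s: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.float64))
    event_directions: np.ndarray = field(   # +1 clockwise, -1 anticlockwise
        default_factory=lambda: np.empty(0, dtype=np.int8))
    event_start_nodes: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int8))
    event_onsets_s: np.ndarray = field(     # (n_events, 8) segment onsets
        default_factory=lambda: np.empty((0, 8), dtype=np.float64))
    channel_transit_s: np.ndarray = field(  # (4,) entry-to-exit delays
        default_factory=lambda: np.empty(0, dtype=np.float64))
    clogged_electrodes: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    @property
    def n_events(self) -> int:
        return int(self.event_times_s.size)

    def spikes_to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"electrode_index": self.spike_electrodes,
                      "spike_time_s": self.spike_times_s}).to_csv(
            path, index=False)


@dataclass
class SyntheticRecording:
    """In-memory multichannel recording with optional ground truth."""

    traces: np.ndarray              # (n_channels, n_samples)
    routed_electrodes: np.ndarray   # (n_channels,) linear electrode indices
    fs: float
    units: str = "uV"
    ground_truth: GroundTruth = field(default_factory=GroundTruth)

    def __post_init__(self):
        self.traces = np.atleast_2d(np.asarray(self.traces))
        self.routed_electrodes = np.asarray(self.routed_electrodes,
                                            dtype=np.int64)
        if self.traces.shape[0] != self.routed_electrodes.size:
            raise SchemaError("trace row count does not match the routed "
                              "electrode count")

    @property
    def n_channels(self) -> int:
        return int(self.traces.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.traces.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_of(self, electrode: int) -> int:
        """Row index of an electrode in ``traces``."""
        hits = np.flatnonzero(self.routed_electrodes == electrode)
        if hits.size == 0:
            raise KeyError(f"electrode {electrode} is not routed")
        return int(hits[0])


def write_recording(rec: SyntheticRecording, path,
                    grid: ElectrodeGrid | None = None) -> None:
    """Write a recording to HDF5 with int16 quantization.

    The quantization scale (units per LSB) is chosen from the trace
    extremum so the full int16 range is used; a read-back therefore
    reproduces the quantized traces bit-exactly.
    """
    grid = grid or ElectrodeGrid()
    peak = float(np.max(np.abs(rec.traces))) if rec.traces.size else 0.0
    scale = peak / 32000.0 if peak > 0 else 1.0
    quant = np.round(rec.traces / scale).astype(np.int16)
    rows, cols = grid.index_to_rowcol(rec.routed_electrodes)

    gt = rec.ground_truth
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        d = fh.create_dataset("traces", data=quant)
        d.attrs["scale"] = scale
        fh.create_dataset("fs", data=float(rec.fs))
        fh.create_dataset("units", data=rec.units)
        m = fh.create_group("mapping")
        m.create_dataset("electrode",
                         data=rec.routed_electrodes.astype(np.int32))
        m.create_dataset("row", data=np.asarray(rows, dtype=np.int32))
        m.create_dataset("col", data=np.asarray(cols, dtype=np.int32))
        g = fh.create_group("ground_truth")
        g.create_dataset("spike_electrode", data=gt.spike_electrodes)
        g.create_dataset("spike_time_s", data=gt.spike_times_s)
        g.create_dataset("event_time_s", data=gt.event_times_s)
        g.create_dataset("event_direction", data=gt.event_directions)
        g.create_dataset("event_start_node", data=gt.event_start_nodes)
        g.create_dataset("event_onsets_s", data=gt.event_onsets_s)
        g.create_dataset("channel_transit_s", data=gt.channel_transit_s)
        g.create_dataset("clogged_electrodes", data=gt.clogged_electrodes)


def read_recording(path) -> SyntheticRecording:
    """Load a recording written by :func:`write_recording`.

    Raises :class:`SchemaError` naming the first missing dataset, or on
    a traces/mapping shape mismatch.
    """
    with h5py.File(path, "r") as fh:
        for name in _REQUIRED:
            if name not in fh:
                raise SchemaError(f"recording file lacks dataset '{name}'")
        scale = float(fh["traces"].attrs.get("scale", 1.0))
        traces = fh["traces"][()].astype(np.float32) * np.float32(scale)
        routed = fh["mapping/electrode"][()].astype(np.int64)
        if traces.shape[0] != routed.size:
            raise SchemaError("/traces row count does not match "
                              "/mapping/electrode")
        fs = float(fh["fs"][()])
        units = "uV"
        if "units" in fh:
            raw = fh["units"][()]
            units = raw.decode() if isinstance(raw, bytes) else str(raw)
        gt = GroundTruth()
        if "ground_truth" in fh:
            g = fh["ground_truth"]

            def rd(name, default):
                return g[name][()] if name in g else default
            gt = GroundTruth(
                spike_electrodes=rd("spike_electrode",
                                    gt.spike_electrodes).astype(np.int64),
                spike_times_s=np.asarray(rd("spike_time_s",
                                            gt.spike_times_s), float),
                event_times_s=np.asarray(rd("event_time_s",
                                            gt.event_times_s), float),
                event_directions=rd("event_direction",
                                    gt.event_directions).astype(np.int8),
                event_start_nodes=rd("event_start_node",
                                     gt.event_start_nodes).astype(np.int8),
                event_onsets_s=np.asarray(rd("event_onsets_s",
                                             gt.event_onsets_s), float),
                channel_transit_s=np.asarray(rd("channel_transit_s",
                                                gt.channel_transit_s), float),
                clogged_electrodes=rd("clogged_electrodes",
                                      gt.clogged_electrodes).astype(np.int64),
            )
    return SyntheticRecording(traces=traces, routed_electrodes=routed,
                              fs=fs, units=units, ground_truth=gt)
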