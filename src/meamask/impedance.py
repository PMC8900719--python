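"""Impedance-map protocol: locating the PDMS mask on the electrode grid.

A 1 kHz test sinusoid (16 mV peak-to-peak) applied at the chip's
reference electrode arrives nearly undamped at exposed electrodes and
strongly attenuated at PDMS-covered ones.  Because only 1,024 of the
26,400 electrodes can be recorded at once, the full map is acquired as
25 contiguous routing patches; columns beyond 209 are excluded from
acquisition (switch-matrix access limits).  Thresholding the assembled
peak-to-peak map yields a measured coverage map, which is compared with
the design-derived expected map, used to assess whether each network's
inter-node channels are open (unclogged), and summarized into yield
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import AlignmentError, CapacityError, InvalidParameterError
from .geometry import (COVERED, MISSING, UNCOVERED, CoverageMap,
                       ElectrodeGrid, ElectrodeGroups)

ROUTING_CAPACITY = 1024


@dataclass
class RoutingPattern:
    """A set of electrodes simultaneously connected to the amplifiers."""

    electrodes: np.ndarray
    capacity: int = ROUTING_CAPACITY

    def __post_init__(self):
        self.electrodes = np.asarray(self.electrodes, dtype=np.int64)
        if self.electrodes.size > self.capacity:
            raise CapacityError(
                f"{self.electrodes.size} electrodes exceed the routing "
                f"capacity of {self.capacity}")
        if np.unique(self.electrodes).size != self.electrodes.size:
            raise InvalidParameterError("duplicate electrodes in pattern")

    def __len__(self) -> int:
        return int(self.electrodes.size)


@dataclass
class ImpedanceMap:
    """Per-electrode peak-to-peak amplitude raster in mV (NaN = missing)."""

    amplitudes: np.ndarray  # (n_rows, n_cols), float, NaN where unacquired

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.amplitudes)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.amplitudes, delimiter=",", fmt="%.6g")

    def to_png(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(11, 6))
        im = ax.imshow(self.amplitudes, origin="lower", cmap="viridis")
        fig.colorbar(im, ax=ax, label="peak-to-peak amplitude (mV)")
        ax.set_xlabel("column")
        ax.set_ylabel("row")
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass
class NetworkAssessment:
    """Quality flags for one network (activity fields filled later)."""

    network_id: str
    covered_fully_by_sensor: bool
    open: bool | None                 # None when not fully on the sensor
    n_channels_active: int | None = None
    fully_connected: bool | None = None

    def with_activity(self, n_channels_active: int) -> "NetworkAssessment":
        if not 0 <= n_channels_active <= 4:
            raise InvalidParameterError("n_channels_active must be 0..4")
        return NetworkAssessment(
            network_id=self.network_id,
            covered_fully_by_sensor=self.covered_fully_by_sensor,
            open=self.open, n_channels_active=n_channels_active,
            fully_connected=bool(self.open) and n_channels_active == 4)


@dataclass
class YieldCounts:
    """Raw counts entering the yield summary."""

    networks_covered: int
    networks_open: int
    networks_active: int
    networks_fully_connected: int
    meas_total: int
    meas_active: int
    meas_fully_connected: int
    electrodes_selected: int
    electrodes_routed: int


@dataclass
class YieldSummary:
    counts: YieldCounts
    percentages: dict[str, float] = field(default_factory=dict)


@dataclass
class AgreementResult:
    """Expected-vs-measured coverage agreement (percent of electrodes
    that were supposed to be uncovered and measured uncovered)."""

    percent: float
    n_expected_uncovered: int
    n_recovered: int
    per_network_percent: list[float] | None = None
    network_mean: float | None = None
    network_sd: float | None = None


def plan_patches(grid: ElectrodeGrid, x_max: int = 210,
                 n_row_blocks: int = 5, n_col_blocks: int = 5
                 ) -> list[RoutingPattern]:
    """Tile the acquired region (columns 0..x_max-1) into contiguous
    rectangular routing patches.

    The default 5 x 5 tiling of a 120 x 210 region gives 25 patches of
    24 x 42 = 1,008 electrodes, within the 1,024-channel capacity.
    """
    if x_max > grid.n_cols:
        raise InvalidParameterError("x_max exceeds the number of columns")
    if grid.n_rows % n_row_blocks or x_max % n_col_blocks:
        raise InvalidParameterError("blocks must tile the acquired region "
                                    "evenly")
    br, bc = grid.n_rows // n_row_blocks, x_max // n_col_blocks
    patches = []
    for jr in range(n_row_blocks):
        for jc in range(n_col_blocks):
            rows = np.arange(jr * br, (jr + 1) * br)
            cols = np.arange(jc * bc, (jc + 1) * bc)
            rr, cc = np.meshgrid(rows, cols, indexing="ij")
            patches.append(RoutingPattern(
                grid.rowcol_to_index(rr.ravel(), cc.ravel())))
    return patches


def peak_to_peak(trace, lo_percentile: float = 0.5,
                 hi_percentile: float = 99.5,
                 method: str = "percentile") -> float:
    """Robust peak-to-peak amplitude of a trace.

    ``percentile`` (default) returns the spread between the high and low
    percentiles, resisting spike/noise outliers; ``raw`` returns
    max - min.
    """
    trace = np.asarray(trace)
    if trace.size < 2:
        raise InvalidParameterError("trace needs at least 2 samples")
    if method == "raw":
        return float(np.max(trace) - np.min(trace))
    if method != "percentile":
        raise InvalidParameterError(f"unknown method '{method}'")
    hi, lo = np.percentile(trace, [hi_percentile, lo_percentile])
    return float(hi - lo)


def peak_to_peak_rows(traces: np.ndarray, lo_percentile: float = 0.5,
                      hi_percentile: float = 99.5) -> np.ndarray:
    """Vectorized :func:`peak_to_peak` over the rows of a trace matrix."""
    hi, lo = np.percentile(traces, [hi_percentile, lo_percentile], axis=1)
    return (hi - lo).astype(float)


def assemble_map(patch_recordings, patches: list[RoutingPattern],
                 grid: ElectrodeGrid, **p2p_kwargs) -> ImpedanceMap:
    """Assemble per-patch recordings into the full-grid amplitude map.

    Each recording's channel order must match its patch's electrode
    order; electrodes never acquired stay NaN.
    """
    if len(patch_recordings) != len(patches):
        raise AlignmentError("one recording required per patch")
    amps = np.full(grid.n_electrodes, np.nan)
    for rec, patch in zip(patch_recordings, patches):
        traces = rec.traces if hasattr(rec, "traces") else np.asarray(rec)
        if traces.shape[0] != len(patch):
            raise AlignmentError("recording channel count does not match "
                                 "patch size")
        amps[patch.electrodes] = peak_to_peak_rows(traces, **p2p_kwargs)
    return ImpedanceMap(amps.reshape(grid.n_rows, grid.n_cols))


def classify_coverage(imap: ImpedanceMap,
                      threshold: float | str = 8.0) -> CoverageMap:
    """Threshold the amplitude map into a measured coverage map.

    An acquired electrode is COVERED iff its amplitude is below the
    threshold (mV).  ``threshold="otsu"`` derives the split from the
    amplitude histogram of acquired electrodes (the bimodal
    covered/uncovered mixture); the fixed default is half the applied
    16 mV peak-to-peak.
    """
    amps = imap.amplitudes
    valid = ~np.isnan(amps)
    if not valid.any():
        raise InvalidParameterError("impedance map has no acquired "
                                    "electrodes")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise InvalidParameterError(f"unknown threshold '{threshold}'")
        from skimage.filters import threshold_otsu
        vals = amps[valid]
        threshold = float(threshold_otsu(vals))
        # Ridler-Calvard refinement: with a strongly imbalanced bimodal
        # histogram the 256-bin Otsu split can land at a cluster edge;
        # iterating to the midpoint of the class means settles it in the
        # gap between the modes.
        for _ in range(50):
            lo, hi = vals[vals < threshold], vals[vals >= threshold]
            if lo.size == 0 or hi.size == 0:
                break
            new = float((lo.mean() + hi.mean()) / 2.0)
            if abs(new - threshold) < 1e-9:
                break
            threshold = new
    labels = np.full(amps.shape, MISSING, dtype=np.int8)
    labels[valid & (amps < threshold)] = COVERED
    labels[valid & (amps >= threshold)] = UNCOVERED
    return CoverageMap(labels, "measured")


def compare_expected_measured(expected: CoverageMap, measured: CoverageMap,
                              network_masks: list[np.ndarray] | None = None
                              ) -> AgreementResult:
    """Fraction (in percent) of expected-uncovered electrodes that were
    measured uncovered; electrodes missing from acquisition are excluded.

    ``network_masks`` (per-network boolean rasters of the
    expected-uncovered footprint) adds a per-network breakdown reported
    as mean +/- sd across networks.
    """
    if expected.labels.shape != measured.labels.shape:
        raise AlignmentError("coverage maps differ in shape")
    acquired = ~measured.missing

    def pct(mask):
        denom = int(np.sum(mask & expected.uncovered & acquired))
        if denom == 0:
            raise InvalidParameterError("no expected-uncovered electrodes "
                                        "in the acquired region")
        num = int(np.sum(mask & expected.uncovered & acquired
                         & measured.uncovered))
        return 100.0 * num / denom, denom, num

    everywhere = np.ones(expected.labels.shape, dtype=bool)
    percent, denom, num = pct(everywhere)
    res = AgreementResult(percent=percent, n_expected_uncovered=denom,
                          n_recovered=num)
    if network_masks:
        per = [pct(np.asarray(m, bool))[0] for m in network_masks]
        res.per_network_percent = per
        res.network_mean = float(np.mean(per))
        res.network_sd = float(np.std(per, ddof=1)) if len(per) > 1 else 0.0
    return res


def _neighbor_uncovered(measured: CoverageMap) -> np.ndarray:
    """Boolean raster: electrode has >= 1 uncovered 8-neighbor."""
    unc = measured.uncovered.astype(np.int32)
    padded = np.pad(unc, 1)
    box = sum(padded[1 + dr:1 + dr + unc.shape[0],
                     1 + dc:1 + dc + unc.shape[1]]
              for dr in (-1, 0, 1) for dc in (-1, 0, 1))
    return (box - unc) > 0


def assess_openness(measured: CoverageMap,
                    groups: ElectrodeGroups) -> NetworkAssessment:
    """Apply the openness rule to one network.

    A network is open iff every electrode positioned below an inter-node
    channel has at least one non-covered electrode in its 8-neighborhood
    of the measured map.  If any grouped electrode falls outside the
    acquired region the network is flagged not fully on the sensor and
    openness is left undefined.
    """
    flat_missing = measured.missing.ravel()
    all_el = groups.all_electrodes()
    covered_fully = not bool(flat_missing[all_el].any())
    if not covered_fully:
        return NetworkAssessment(groups.network_id, False, None)
    neigh = _neighbor_uncovered(measured).ravel()
    open_ = all(bool(neigh[chan].all()) for chan in groups.channel_electrodes)
    return NetworkAssessment(groups.network_id, True, open_)


def select_routing(region, capacity: int = ROUTING_CAPACITY
                   ) -> tuple[RoutingPattern, dict[str, int]]:
    """Select electrodes of a thresholded region for routing.

    If the region exceeds the amplifier capacity, electrodes are dropped
    by uniform spatial decimation over the index-sorted region -- a
    deterministic rule, so the same region always yields the same
    pattern.  Returns the pattern and ``{"selected": n, "routed": m}``.
    """
    region = np.unique(np.asarray(region, dtype=np.int64))
    if region.size == 0:
        raise InvalidParameterError("empty routing region")
    n = int(region.size)
    if n <= capacity:
        routed = region
    else:
        keep = np.round(np.linspace(0, n - 1, capacity)).astype(int)
        routed = region[np.unique(keep)]
    return (RoutingPattern(routed, capacity=capacity),
            {"selected": n, "routed": int(routed.size)})


def _round1(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal, as printed reports do."""
    val = Decimal(numerator) * 100 / Decimal(denominator)
    return float(val.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_yield(counts: YieldCounts) -> YieldSummary:
    """Derive the standard yield percentages from raw counts.

    Ratios with a zero denominator are omitted with a warning.
    """
    pairs = {
        "open_of_covered_pct": (counts.networks_open,
                                counts.networks_covered),
        "active_of_covered_pct": (counts.networks_active,
                                  counts.networks_covered),
        "fully_connected_of_covered_pct": (counts.networks_fully_connected,
                                           counts.networks_covered),
        "meas_active_pct": (counts.meas_active, counts.meas_total),
        "meas_fully_connected_pct": (counts.meas_fully_connected,
                                     counts.meas_total),
        "routed_of_selected_pct": (counts.electrodes_routed,
                                   counts.electrodes_selected),
    }
    out: dict[str, float] = {}
    for key, (num, den) in pairs.items():
        if den == 0:
            warnings.warn(f"zero denominator for {key}; omitted",
                          stacklevel=2)
            continue
        out[key] = _round1(num, den)
    return YieldSummary(counts=counts, percentages=out)


def counts_from_assessments(assessments_by_mea: dict[str,
                                                     list[NetworkAssessment]],
                            electrodes_selected: int,
                            electrodes_routed: int) -> YieldCounts:
    """Aggregate per-network assessments (grouped by MEA) into counts."""
    nets = [a for group in assessments_by_mea.values() for a in group]
    covered = [a for a in nets if a.covered_fully_by_sensor]
    return YieldCounts(
        networks_covered=len(covered),
        networks_open=sum(bool(a.open) for a in covered),
        networks_active=sum((a.n_channels_active or 0) > 0 for a in covered),
        networks_fully_connected=sum(bool(a.fully_connected)
                                     for a in covered),
        meas_total=len(assessments_by_mea),
        meas_active=sum(any((a.n_channels_active or 0) > 0 for a in group)
                        for group in assessments_by_mea.values()),
        meas_fully_connected=sum(any(bool(a.fully_connected) for a in group)
                                 for group in assessments_by_mea.values()),
        electrodes_selected=electrodes_selected,
        electrodes_routed=electrodes_routed)
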