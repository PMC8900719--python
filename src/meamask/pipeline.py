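"""End-to-end pipeline: simulate (or load) -> impedance map -> coverage
classification -> openness assessment -> spike detection -> maps ->
propagation analysis -> JSON report.

All randomness flows from one root seed; per-stage generators are
derived deterministically from it, so a fixed configuration yields a
byte-identical report across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import impedance as imp
from . import propagation as prop
from . import spikes as spk
from . import synthetic as syn
from .errors import InvalidParameterError
from .geometry import (ElectrodeGrid, MicrostructureLayout, build_grid,
                       generate_network_design, rasterize_design)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    The defaults simulate a single network centered on the acquired
    region.  ``impedance_duration_s`` and ``activity.duration_s`` are
    kept short by default; the peak-to-peak estimate converges after a
    few hundred sine cycles and the directionality statistics only need
    a few tens of events.
    """

    seed: int = 0
    grid: dict = field(default_factory=dict)
    network: dict = field(default_factory=lambda: {
        "center": (1837.5, 1050.0), "network_id": "net0"})
    x_max: int = 210
    impedance_duration_s: float = 0.2
    impedance: dict = field(default_factory=dict)
    clog_channels: list[int] = field(default_factory=list)
    threshold: float | str = 8.0
    activity: dict = field(default_factory=lambda: {
        "duration_s": 20.0, "event_rate_hz": 1.0})
    routed_per_node: int = 8
    detection: dict = field(default_factory=dict)
    span_ms: float = 10.0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise InvalidParameterError(f"unknown config keys: "
                                        f"{sorted(bad)}")
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["network"] = {k: list(v) if isinstance(v, tuple) else v
                        for k, v in d["network"].items()}
        return d


def _routed_subset(groups, per_node: int) -> np.ndarray:
    """All channel electrodes plus an evenly spaced subset of each
    node's electrodes (the capacity-limited routing of the real chip)."""
    parts = [np.asarray(c, dtype=np.int64)
             for c in groups.channel_electrodes]
    for nel in groups.node_electrodes:
        nel = np.asarray(nel, dtype=np.int64)
        if nel.size > per_node:
            keep = np.round(np.linspace(0, nel.size - 1,
                                        per_node)).astype(int)
            nel = nel[np.unique(keep)]
        parts.append(nel)
    return np.unique(np.concatenate(parts))


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole chain on simulated data and return the report.

    Stage errors propagate wrapped with the stage name.  If
    ``config.out_dir`` is set, the report is also written there as
    ``report.json``.
    """
    root = np.random.default_rng(config.seed)
    seed_impedance = int(root.integers(2 ** 31))
    seed_activity = int(root.integers(2 ** 31))

    stage = "geometry"
    try:
        grid = build_grid(**config.grid)
        design = generate_network_design(**config.network)
        layout = MicrostructureLayout(networks=[design])
        expected, all_groups = rasterize_design(layout, grid)
        groups = all_groups[0]

        stage = "impedance"
        patches = imp.plan_patches(grid, x_max=config.x_max)
        ip = syn.ImpedanceSimParams(duration_s=config.impedance_duration_s,
                                    seed=seed_impedance, **config.impedance)
        clogged = (np.concatenate(
            [np.asarray(groups.channel_electrodes[k], dtype=np.int64)
             for k in config.clog_channels])
            if config.clog_channels else np.empty(0, dtype=np.int64))
        imap = syn.simulate_impedance_map(expected, patches, ip, grid,
                                          clogged_electrodes=clogged)
        measured = imp.classify_coverage(imap, threshold=config.threshold)
        agreement = imp.compare_expected_measured(expected, measured)
        acquired = ~measured.missing
        accuracy = 100.0 * float(np.mean(
            (expected.labels == measured.labels)[acquired]))
        assessment = imp.assess_openness(measured, groups)
        region = np.flatnonzero(measured.uncovered.ravel())
        routing, routing_counts = imp.select_routing(region)

        stage = "activity"
        ap = syn.ActivitySimParams(seed=seed_activity, **config.activity)
        routed = _routed_subset(groups, config.routed_per_node)
        rec = syn.simulate_network_activity(groups, ap,
                                            routed_electrodes=routed)

        stage = "detection"
        dp = spk.SpikeDetectionParams(**config.detection)
        filtered = spk.highpass(rec.traces,
                                spk.FilterSpec(fs_hz=rec.fs))
        events = spk.detect_spikes_multi(filtered, rec.routed_electrodes,
                                         dp, fs=rec.fs)
        fmap = spk.frequency_map(events, rec.duration_s, grid,
                                 routed_electrodes=rec.routed_electrodes)
        rates = fmap.rates.ravel()
        chan_active = [bool(len(c) and np.nansum(
            rates[np.asarray(c, dtype=np.int64)]) > 0)
            for c in groups.channel_electrodes]
        assessment = assessment.with_activity(int(sum(chan_active)))

        stage = "propagation"
        direction, net_events = prop.analyze_directionality(
            events, groups, span_ms=config.span_ms)

        stage = "yield"
        counts = imp.counts_from_assessments(
            {"mea0": [assessment]},
            electrodes_selected=routing_counts["selected"],
            electrodes_routed=routing_counts["routed"])
        ysum = imp.summarize_yield(counts)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "impedance": {
            "n_patches": len(patches),
            "n_acquired_electrodes": int(acquired.sum()),
            "coverage_accuracy_pct": round(accuracy, 4),
            "agreement_pct": round(agreement.percent, 4),
            "n_expected_uncovered": agreement.n_expected_uncovered,
            "open": assessment.open,
            "covered_fully_by_sensor": assessment.covered_fully_by_sensor,
            "routing": routing_counts,
        },
        "detection": {
            "n_routed": int(rec.n_channels),
            "n_spikes": len(events),
            "n_true_spikes": rec.ground_truth.n_spikes,
            "n_channels_active": assessment.n_channels_active,
            "fully_connected": assessment.fully_connected,
        },
        "directionality": {
            "n_events": direction.n_events,
            "n_clockwise": direction.n_clockwise,
            "n_anticlockwise": direction.n_anticlockwise,
            "n_ambiguous": direction.n_ambiguous,
            "clockwise_fraction": direction.clockwise_fraction,
        },
        "yield": {
            "counts": asdict(counts),
            "percentages": ysum.percentages,
        },
    }
    if config.out_dir:
        import os
        os.makedirs(config.out_dir, exist_ok=True)
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            fh.write(report_to_json(report))
    return report


def report_to_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys, fixed indentation) so
    equal reports are byte-identical."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"
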