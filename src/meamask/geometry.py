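"""Electrode-grid and microstructure geometry.

The recording chip exposes a dense rectangular lattice of electrodes
(120 rows x 220 columns at 17.5 um pitch, 26,400 electrodes over a
3.85 x 2.10 mm sensing area).  A PDMS microstructure placed on the chip
insulates every electrode it covers; its wells ("nodes"), seeding
openings and microchannels leave electrodes exposed.  This module
models the grid, the four-node ring design, and rasterizes a placed
design into per-electrode coverage truth plus the electrode groups
(per node / per inter-node channel / redirect channels) that the
downstream activity analysis works on.

Conventions: 0-based (row, col); linear index = row * n_cols + col;
physical x runs along columns, y along rows; positions are electrode
centers in micrometers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

from .errors import GeometryError, InvalidParameterError, PlacementError

# Coverage labels.
UNCOVERED = 0
COVERED = 1
MISSING = 2

#: Ring radius for which the inter-node channel centerlines of a
#: 45-degree-rotated design coincide with grid columns/rows whenever the
#: network center sits on an electrode center (10 pitches * sqrt(2)).
DEFAULT_RING_RADIUS = 175.0 * math.sqrt(2.0)


@dataclass(frozen=True)
class ElectrodeGrid:
    """The MEA electrode lattice; coordinate authority for everything."""

    n_rows: int = 120
    n_cols: int = 220
    pitch: float = 17.5
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) of electrode (0, 0)

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def sensing_area_um(self) -> tuple[float, float]:
        """(width, height) of the sensing area in um."""
        return (self.n_cols * self.pitch, self.n_rows * self.pitch)

    def index_to_rowcol(self, index):
        index = np.asarray(index)
        if np.any(index < 0) or np.any(index >= self.n_electrodes):
            raise InvalidParameterError("electrode index out of range")
        return index // self.n_cols, index % self.n_cols

    def rowcol_to_index(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        if (np.any(row < 0) or np.any(row >= self.n_rows)
                or np.any(col < 0) or np.any(col >= self.n_cols)):
            raise InvalidParameterError("row/col out of range")
        return row * self.n_cols + col

    def position(self, index):
        """Physical (x, y) center of one or more electrodes, in um."""
        row, col = self.index_to_rowcol(index)
        return (self.origin[0] + col * self.pitch,
                self.origin[1] + row * self.pitch)

    def all_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """x and y coordinates of every electrode, linear-index order."""
        idx = np.arange(self.n_electrodes)
        return self.position(idx)

    def bounds(self) -> tuple[float, float, float, float]:
        """Sensing-area rectangle (xmin, ymin, xmax, ymax): electrode
        centers padded by half a pitch on each side."""
        h = self.pitch / 2.0
        x0, y0 = self.origin
        return (x0 - h, y0 - h,
                x0 + (self.n_cols - 1) * self.pitch + h,
                y0 + (self.n_rows - 1) * self.pitch + h)


def build_grid(n_rows: int = 120, n_cols: int = 220, pitch: float = 17.5,
               origin: tuple[float, float] = (0.0, 0.0)) -> ElectrodeGrid:
    """Construct and validate an :class:`ElectrodeGrid`."""
    if n_rows <= 0 or n_cols <= 0:
        raise InvalidParameterError("grid dimensions must be positive")
    if pitch <= 0:
        raise InvalidParameterError("pitch must be positive")
    return ElectrodeGrid(n_rows=int(n_rows), n_cols=int(n_cols),
                         pitch=float(pitch), origin=tuple(origin))


@dataclass
class NetworkDesign:
    """Geometric model of one four-node circular microstructure.

    ``internode_channels[k]`` connects node ``k`` to node ``(k+1) % 4``
    in clockwise travel order; ``channel_lines[k]`` is the matching
    centerline oriented entry -> exit.
    """

    network_id: str
    node_polygons: list[Polygon]
    opening_polygons: list[Polygon]
    internode_channels: list[Polygon]
    channel_lines: list[LineString]
    redirect_channels: list[Polygon]
    center: tuple[float, float]
    rotation_deg: float

    def uncovered_union(self):
        """Union of all footprints that leave electrodes exposed."""
        return unary_union(self.node_polygons + self.internode_channels
                           + list(self.redirect_channels))

    def node_centers(self) -> list[tuple[float, float]]:
        return [(p.centroid.x, p.centroid.y) for p in self.node_polygons]


@dataclass
class MicrostructureLayout:
    """A set of disjoint network designs placed on the grid plane."""

    networks: list[NetworkDesign] = field(default_factory=list)

    def __post_init__(self):
        unions = [d.uncovered_union() for d in self.networks]
        for i in range(len(unions)):
            for j in range(i + 1, len(unions)):
                if unions[i].intersects(unions[j]):
                    raise GeometryError(
                        f"network footprints {self.networks[i].network_id} "
                        f"and {self.networks[j].network_id} overlap")


@dataclass
class CoverageMap:
    """Per-electrode coverage labels (UNCOVERED / COVERED / MISSING)."""

    labels: np.ndarray  # int8, (n_rows, n_cols)
    provenance: str     # "expected" or "measured"

    @property
    def covered(self) -> np.ndarray:
        return self.labels == COVERED

    @property
    def uncovered(self) -> np.ndarray:
        return self.labels == UNCOVERED

    @property
    def missing(self) -> np.ndarray:
        return self.labels == MISSING

    def copy(self) -> "CoverageMap":
        return CoverageMap(self.labels.copy(), self.provenance)

    def to_csv(self, path, grid: ElectrodeGrid) -> None:
        import pandas as pd
        rows, cols = np.divmod(np.arange(grid.n_electrodes), grid.n_cols)
        names = np.array(["uncovered", "covered", "missing"])
        pd.DataFrame({
            "electrode_index": np.arange(grid.n_electrodes),
            "row": rows, "col": cols,
            "label": names[self.labels.ravel()],
        }).to_csv(path, index=False)


@dataclass
class ElectrodeGroups:
    """Electrode membership of one placed network.

    ``channel_electrodes[k]`` is ordered by arc-length along the
    clockwise direction of travel; ``channel_offsets_um[k]`` gives each
    electrode's distance from the channel entry (the node-k end).
    """

    network_id: str
    node_electrodes: list[np.ndarray]
    channel_electrodes: list[np.ndarray]
    channel_offsets_um: list[np.ndarray]
    channel_lengths_um: list[float]
    redirect_electrodes: np.ndarray

    def all_electrodes(self) -> np.ndarray:
        parts = (list(self.node_electrodes) + list(self.channel_electrodes)
                 + [self.redirect_electrodes])
        return np.unique(np.concatenate([np.asarray(p, int) for p in parts]))

    def segment_positions(self) -> dict[int, int]:
        """Map electrode index -> cycle position (node k -> 2k,
        channel k -> 2k+1); redirect electrodes are unmapped."""
        out: dict[int, int] = {}
        for k in range(4):
            for e in self.node_electrodes[k]:
                out[int(e)] = 2 * k
            for e in self.channel_electrodes[k]:
                out[int(e)] = 2 * k + 1
        return out

    def to_json(self, path, grid: ElectrodeGrid) -> None:
        def ser(idx):
            idx = np.asarray(idx, int)
            r, c = grid.index_to_rowcol(idx)
            return [{"electrode_index": int(i), "row": int(rr), "col": int(cc)}
                    for i, rr, cc in zip(idx, r, c)]
        obj = {
            "network_id": self.network_id,
            "nodes": [ser(g) for g in self.node_electrodes],
            "channels": [ser(g) for g in self.channel_electrodes],
            "channel_lengths_um": [float(v) for v in self.channel_lengths_um],
            "redirect": ser(self.redirect_electrodes),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)


def generate_network_design(center: tuple[float, float] = (0.0, 0.0),
                            node_radius: float = 125.0,
                            opening_diameter: float = 170.0,
                            channel_width: float = 10.0,
                            redirect_width: float = 5.0,
                            redirect_length: float = 100.0,
                            redirect_gap: float = 10.0,
                            ring_radius: float = DEFAULT_RING_RADIUS,
                            rotation_deg: float = 45.0,
                            network_id: str = "net0") -> NetworkDesign:
    """Build a four-node ring design.

    Nodes are discs of ``node_radius`` centered on a ring of
    ``ring_radius``; inter-node channels are straight rectangles of
    ``channel_width`` joining consecutive node boundaries in clockwise
    order; one redirect channel of ``redirect_width`` runs tangentially
    outside each node.  Raises :class:`GeometryError` if nodes overlap,
    a channel has no length, or redirects collide with other footprints.
    """
    for name, v in [("node_radius", node_radius),
                    ("channel_width", channel_width),
                    ("redirect_width", redirect_width),
                    ("ring_radius", ring_radius),
                    ("opening_diameter", opening_diameter)]:
        if v <= 0:
            raise InvalidParameterError(f"{name} must be positive")
    if opening_diameter > 2 * node_radius:
        raise GeometryError("seeding opening larger than the node")

    chord = ring_radius * math.sqrt(2.0)  # distance between adjacent nodes
    if chord <= 2 * node_radius:
        raise GeometryError(
            "adjacent nodes overlap: ring radius too small for node radius")
    channel_length = chord - 2 * node_radius
    if channel_length <= 0:
        raise GeometryError("inter-node channel has non-positive length")

    cx, cy = center
    theta0 = math.radians(rotation_deg)
    # Clockwise order = decreasing angle in math (y-up) convention.
    angles = [theta0 - k * math.pi / 2 for k in range(4)]
    centers = [(cx + ring_radius * math.cos(a), cy + ring_radius * math.sin(a))
               for a in angles]

    nodes = [Point(c).buffer(node_radius, quad_segs=64) for c in centers]
    openings = [Point(c).buffer(opening_diameter / 2, quad_segs=32)
                for c in centers]

    channels, lines = [], []
    for k in range(4):
        a = np.asarray(centers[k])
        b = np.asarray(centers[(k + 1) % 4])
        u = (b - a) / np.linalg.norm(b - a)
        entry = a + node_radius * u
        exit_ = b - node_radius * u
        line = LineString([tuple(entry), tuple(exit_)])
        lines.append(line)
        channels.append(line.buffer(channel_width / 2, cap_style="flat"))

    redirects = []
    for k in range(4):
        a = angles[k]
        ur = np.array([math.cos(a), math.sin(a)])   # radial, outward
        ut = np.array([-math.sin(a), math.cos(a)])  # tangential
        mid = (np.array([cx, cy])
               + (ring_radius + node_radius + redirect_gap
                  + redirect_width / 2) * ur)
        line = LineString([tuple(mid - redirect_length / 2 * ut),
                           tuple(mid + redirect_length / 2 * ut)])
        redirects.append(line.buffer(redirect_width / 2, cap_style="flat"))

    body = unary_union(nodes + channels)
    for r in redirects:
        if r.intersects(body):
            raise GeometryError("redirect channel collides with nodes or "
                                "inter-node channels")

    return NetworkDesign(network_id=network_id, node_polygons=nodes,
                         opening_polygons=openings,
                         internode_channels=channels, channel_lines=lines,
                         redirect_channels=redirects, center=(cx, cy),
                         rotation_deg=rotation_deg)


def default_layout(grid: ElectrodeGrid, n_x: int = 5, n_y: int = 3,
                   **design_kwargs) -> MicrostructureLayout:
    """The standard mask: 15 identical networks on an n_x x n_y lattice
    spanning the sensing area (the real mask carries 15 substructures)."""
    w, h = grid.sensing_area_um
    dx, dy = w / n_x, h / n_y
    # Snap centers to electrode centers so channels align with the lattice.
    nets = []
    for j in range(n_y):
        for i in range(n_x):
            cx = round((dx / 2 + i * dx) / grid.pitch) * grid.pitch
            cy = round((dy / 2 + j * dy) / grid.pitch) * grid.pitch
            nets.append(generate_network_design(
                center=(cx, cy), network_id=f"net{j * n_x + i}",
                **design_kwargs))
    return MicrostructureLayout(networks=nets)


def _contains(geom, xs, ys) -> np.ndarray:
    """Vectorized strict point-in-polygon with a bounding-box prefilter."""
    xmin, ymin, xmax, ymax = geom.bounds
    cand = (xs >= xmin) & (xs <= xmax) & (ys >= ymin) & (ys <= ymax)
    out = np.zeros(xs.shape, dtype=bool)
    if cand.any():
        shapely.prepare(geom)
        out[cand] = shapely.contains_xy(geom, xs[cand], ys[cand])
    return out


def rasterize_design(layout: MicrostructureLayout, grid: ElectrodeGrid
                     ) -> tuple[CoverageMap, list[ElectrodeGroups]]:
    """Rasterize a placed layout into expected coverage and groups.

    An electrode is *uncovered* iff its center lies strictly inside any
    node, opening or channel footprint (openings lie inside nodes, so
    they never change the set); everything else under no PDMS at all is
    also uncovered only when the layout is empty of footprints -- i.e.
    with no mask present every electrode is exposed, and each network
    footprint adds a covered annulus implicitly via the PDMS body.

    Here coverage truth is defined for the mask as a whole: electrodes
    inside an exposed footprint are UNCOVERED, all remaining electrodes
    are COVERED (the PDMS slab covers the full sensing area).  An empty
    layout (no networks) means no PDMS: everything UNCOVERED.
    """
    xs, ys = grid.all_positions()
    xmin, ymin, xmax, ymax = grid.bounds()

    labels = np.full(grid.n_electrodes, COVERED, dtype=np.int8)
    if not layout.networks:
        labels[:] = UNCOVERED
        return (CoverageMap(labels.reshape(grid.n_rows, grid.n_cols),
                            "expected"), [])

    groups: list[ElectrodeGroups] = []
    for design in layout.networks:
        union = design.uncovered_union()
        bx0, by0, bx1, by1 = union.bounds
        if bx0 < xmin or by0 < ymin or bx1 > xmax or by1 > ymax:
            raise PlacementError(
                f"network {design.network_id} extends outside the sensing "
                "area")
        exposed = _contains(union, xs, ys)
        labels[exposed] = UNCOVERED

        node_sets = []
        taken = np.zeros(grid.n_electrodes, dtype=bool)
        for poly in design.node_polygons:
            inside = _contains(poly, xs, ys) & ~taken
            node_sets.append(np.flatnonzero(inside))
            taken |= inside
        chan_sets, chan_offsets, chan_lengths = [], [], []
        for poly, line in zip(design.internode_channels,
                              design.channel_lines):
            inside = _contains(poly, xs, ys) & ~taken
            idx = np.flatnonzero(inside)
            offs = np.array([line.project(Point(xs[i], ys[i])) for i in idx])
            order = np.argsort(offs, kind="stable")
            chan_sets.append(idx[order])
            chan_offsets.append(offs[order])
            chan_lengths.append(float(line.length))
            taken[idx] = True
        red = np.zeros(grid.n_electrodes, dtype=bool)
        for poly in design.redirect_channels:
            red |= _contains(poly, xs, ys)
        red &= ~taken

        groups.append(ElectrodeGroups(
            network_id=design.network_id, node_electrodes=node_sets,
            channel_electrodes=chan_sets, channel_offsets_um=chan_offsets,
            channel_lengths_um=chan_lengths,
            redirect_electrodes=np.flatnonzero(red)))

    return (CoverageMap(labels.reshape(grid.n_rows, grid.n_cols), "expected"),
            groups)


def layout_to_json(layout: MicrostructureLayout, path) -> None:
    """Serialize a layout with polygons as vertex lists in um."""
    def poly(p: Polygon):
        return [[float(x), float(y)] for x, y in p.exterior.coords]
    obj = {"networks": [{
        "network_id": d.network_id,
        "center": list(d.center),
        "rotation_deg": d.rotation_deg,
        "nodes": [poly(p) for p in d.node_polygons],
        "openings": [poly(p) for p in d.opening_polygons],
        "channels": [poly(p) for p in d.internode_channels],
        "channel_lines": [[[float(x), float(y)] for x, y in ln.coords]
                          for ln in d.channel_lines],
        "redirects": [poly(p) for p in d.redirect_channels],
    } for d in layout.networks]}
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True)


def layout_from_json(path) -> MicrostructureLayout:
    with open(path) as fh:
        obj = json.load(fh)
    nets = []
    for d in obj["networks"]:
        nets.append(NetworkDesign(
            network_id=d["network_id"],
            node_polygons=[Polygon(v) for v in d["nodes"]],
            opening_polygons=[Polygon(v) for v in d["openings"]],
            internode_channels=[Polygon(v) for v in d["channels"]],
            channel_lines=[LineString(v) for v in d["channel_lines"]],
            redirect_channels=[Polygon(v) for v in d["redirects"]],
            center=tuple(d["center"]), rotation_deg=d["rotation_deg"]))
    return MicrostructureLayout(networks=nets)
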