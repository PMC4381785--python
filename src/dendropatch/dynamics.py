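"""Protrusion dynamics from binarized dendrite time-lapse movies.

A protrusion's dynamic class is decided by when it is present relative to the
acquisition window and for how long it persists:

* static      — present in every frame of the acquisition;
* stabilized  — appears after the first frame and remains through the last
                frame, persisting at least 3 minutes;
* collapsed   — present from the first frame, persists at least 3 minutes,
                and disappears before the last frame;
* transient   — anything else (appears and disappears within the movie).

Persistence counts the onset frame: (offset − onset + 1) × frame interval,
with an inclusive comparison at exactly 3 minutes.

Nodes are transient thickened regions of the dendritic shaft; protrusions are
linked to a node when their origin lies within a link radius of a node active
at or before their onset. The node-emergence fraction is computed over de
novo protrusions only (onset after the first frame).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "BinaryMovie",
    "ProtrusionTrack",
    "ClassifiedTrack",
    "NodeEvent",
    "DynamicsSummary",
    "PERSISTENCE_MIN_S",
    "binarize_movie",
    "temporal_color_code",
    "extract_tracks",
    "link_protrusions_to_nodes",
    "classify_track",
    "n_frames_for",
    "node_emergence_fraction",
    "filopodia_density",
    "dynamics_summary",
    "interval_subsample",
]

log = logging.getLogger(__name__)

PERSISTENCE_MIN_S = 180.0  # the 3-minute persistence cutoff
CLASSES = ("static", "transient", "stabilized", "collapsed")


@dataclass
class BinaryMovie:
    """Boolean foreground stack with physical calibration."""

    data: np.ndarray  # (frames, rows, cols) bool
    frame_interval: float  # s
    pixel_size: float  # µm/px

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("binary movie must be (frames, rows, cols)")
        if not (self.frame_interval > 0 and self.pixel_size > 0):
            raise ValueError("calibration must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class ProtrusionTrack:
    """Per-frame record of one protrusion (frames inclusive)."""

    onset: int
    offset: int
    lengths_um: np.ndarray  # one length per frame in [onset, offset]
    origin: tuple[float, float] = (0.0, 0.0)  # (row, col) px
    node_id: int | None = None
    track_id: int = -1

    def __post_init__(self) -> None:
        self.lengths_um = np.asarray(self.lengths_um, dtype=float)
        if self.onset > self.offset:
            raise ValueError("onset must be <= offset")
        if self.lengths_um.size != self.offset - self.onset + 1:
            raise ValueError("lengths must cover [onset, offset]")
        if np.any(self.lengths_um < 0):
            raise ValueError("lengths must be >= 0")

    @property
    def n_present(self) -> int:
        return self.offset - self.onset + 1

    @property
    def max_length_um(self) -> float:
        return float(self.lengths_um.max()) if self.lengths_um.size else 0.0


@dataclass
class ClassifiedTrack:
    track: ProtrusionTrack
    label: str
    duration_min: float


@dataclass
class NodeEvent:
    """A transient shaft thickening."""

    onset: int
    offset: int
    centroids: np.ndarray  # (n_present, 2) (row, col) px
    node_id: int = -1
    detection_interval_s: float = float("nan")

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if self.onset > self.offset:
            raise ValueError("onset must be <= offset")

    @property
    def mean_centroid(self) -> np.ndarray:
        return self.centroids.mean(axis=0)


@dataclass
class DynamicsSummary:
    n_static: int
    n_transient: int
    n_stabilized: int
    n_collapsed: int
    n_nodes: int
    dynamic_per_static: float | None  # None when no static protrusion exists
    node_emergence_fraction: float | None
    filopodia_density_per_10um: float | None

    def to_dict(self) -> dict:
        return {
            "n_static": self.n_static,
            "n_transient": self.n_transient,
            "n_stabilized": self.n_stabilized,
            "n_collapsed": self.n_collapsed,
            "n_nodes": self.n_nodes,
            "dynamic_per_static": self.dynamic_per_static,
            "node_emergence_fraction": self.node_emergence_fraction,
            "filopodia_density_per_10um": self.filopodia_density_per_10um,
        }


def n_frames_for(movie_minutes: float, frame_interval: float) -> int:
    """Frame count of an acquisition: frames at 0, Δt, … , T inclusive."""
    return int(round(movie_minutes * 60.0 / frame_interval)) + 1


def binarize_movie(
    stack: np.ndarray,
    frame_interval: float,
    pixel_size: float,
    threshold: float | None = None,
    fraction_of_max: float = 0.5,
) -> BinaryMovie:
    """Per-frame global threshold of a raw movie.

    With ``threshold`` set, that constant is applied to every frame; otherwise
    each frame is thresholded at ``fraction_of_max`` × its own maximum.
    All-false frames are allowed (logged, not raised).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("movie stack must be a nonempty (frames, rows, cols) array")
    out = np.zeros(stack.shape, dtype=bool)
    for t in range(stack.shape[0]):
        thr = threshold if threshold is not None else fraction_of_max * stack[t].max()
        out[t] = stack[t] > thr
        if not out[t].any():
            log.info("binarize_movie: frame %d is empty under the threshold", t)
    return BinaryMovie(out, frame_interval, pixel_size)


def temporal_color_code(bin_movie: BinaryMovie, cmap: str = "jet") -> np.ndarray:
    """Overlay the movie as a single RGB image, one hue per frame.

    Each pixel takes the hue of the LAST frame in which it is foreground
    (last-wins); pixels never in the foreground stay black. Frame k of T maps
    to colormap position k/(T−1) (0 for a single-frame movie).
    """
    import matplotlib

    data = bin_movie.data
    n = data.shape[0]
    if n == 0:
        raise ValueError("empty movie")
    colormap = matplotlib.colormaps[cmap]
    last = np.full(data.shape[1:], -1, dtype=int)
    for t in range(n):
        last[data[t]] = t
    rgb = np.zeros(data.shape[1:] + (3,), dtype=float)
    positions = np.zeros(n) if n == 1 else np.arange(n) / (n - 1)
    for t in range(n):
        sel = last == t
        rgb[sel] = colormap(positions[t])[:3]
    return rgb


# ---------------------------------------------------------------------------
# track extraction from binary movies


def derive_shaft_mask(bin_movie: BinaryMovie, persist_frac: float = 0.9) -> np.ndarray:
    """Most-persistent-foreground surrogate for the dendritic shaft.

    Pixels foreground in >= persist_frac of frames, opened with a small disk
    to shave off thin static protrusions.
    """
    persistent = bin_movie.data.mean(axis=0) >= persist_frac
    shaft = morphology.opening(persistent, morphology.disk(2))
    if not shaft.any():
        raise ValueError("derived shaft mask is empty")
    return shaft


@dataclass
class _Detection:
    frame: int
    pos: tuple[float, float]
    length_um: float = 0.0
    base_dist_px: float = 0.0  # how far the position sits from the shaft


def _link_detections(
    detections: list[_Detection], link_radius_px: float, gap_frames: int
) -> list[list[_Detection]]:
    """Greedy nearest-position linking of per-frame detections into tracks."""
    tracks: list[list[_Detection]] = []
    by_frame: dict[int, list[_Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    for t in sorted(by_frame):
        for det in by_frame[t]:
            best, best_d = None, None
            for tr in tracks:
                last = tr[-1]
                if not (0 < t - last.frame <= 1 + gap_frames):
                    continue
                dist = float(np.hypot(det.pos[0] - last.pos[0], det.pos[1] - last.pos[1]))
                if dist <= link_radius_px and (best_d is None or dist < best_d):
                    best, best_d = tr, dist
            if best is None:
                tracks.append([det])
            else:
                best.append(det)
    return tracks


def extract_tracks(
    bin_movie: BinaryMovie,
    shaft_mask: np.ndarray | None = None,
    link_radius_um: float = 1.0,
    width_factor: float = 1.5,
    min_protrusion_um: float = 0.5,
    gap_frames: int = 1,
) -> tuple[list[ProtrusionTrack], list[NodeEvent]]:
    """Detect and link protrusions and shaft nodes in a binary movie.

    Protrusion candidates are foreground components outside the shaft mask
    that touch the shaft and extend at least ``min_protrusion_um`` beyond it;
    their per-frame length is the maximal distance of a component pixel from
    the shaft. Nodes are frames where the local shaft half-width (distance
    transform sampled on the shaft medial axis) exceeds ``width_factor`` × the
    median baseline half-width. Detections are linked across frames by
    nearest position within ``link_radius_um`` with gap closing of up to
    ``gap_frames`` missing frames; finally protrusions are linked to nodes.
    """
    if shaft_mask is None:
        shaft_mask = derive_shaft_mask(bin_movie)
    shaft_mask = np.asarray(shaft_mask, dtype=bool)
    if not shaft_mask.any():
        raise ValueError("shaft mask is empty")
    px = bin_movie.pixel_size
    link_radius_px = link_radius_um / px
    min_prot_px = min_protrusion_um / px

    skel, skel_dist = morphology.medial_axis(shaft_mask, return_distance=True)
    baseline_halfwidth = float(np.median(skel_dist[skel]))
    dist_to_shaft = ndimage.distance_transform_edt(~shaft_mask)

    h, w = shaft_mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    prot_detections: list[_Detection] = []
    node_detections: list[_Detection] = []
    for t in range(bin_movie.n_frames):
        fg = bin_movie.data[t]
        if not fg.any():
            continue
        # node candidates: widened shaft sampled on the baseline medial axis
        dt_fg = ndimage.distance_transform_edt(fg)
        wide = skel & fg & (dt_fg >= width_factor * baseline_halfwidth)
        node_zone = np.zeros_like(shaft_mask)
        if wide.any():
            for region in measure.regionprops(measure.label(wide, connectivity=2)):
                node_detections.append(_Detection(t, tuple(region.centroid)))
            # the inscribed disks of the thickening belong to the shaft, not to
            # any protrusion; +1.5 px absorbs rasterisation slivers at the rim
            for r, c in np.argwhere(wide):
                rad = dt_fg[r, c] + 1.5
                node_zone |= (yy - r) ** 2 + (xx - c) ** 2 <= rad * rad
        # protrusion candidates: components beyond the shaft (and beyond any
        # node thickening) that touch either
        base = shaft_mask | node_zone
        dist_to_base = (
            ndimage.distance_transform_edt(~base) if node_zone.any() else dist_to_shaft
        )
        resid = fg & ~base
        labels = measure.label(resid, connectivity=2)
        for region in measure.regionprops(labels):
            coords = region.coords
            d_base = dist_to_base[coords[:, 0], coords[:, 1]]
            if d_base.min() > 1.5:  # attached to neither shaft nor node
                continue
            d_shaft = dist_to_shaft[coords[:, 0], coords[:, 1]]
            extent_px = float(d_shaft.max())
            if extent_px < min_prot_px:
                continue  # rim sliver, not a protrusion
            i_near = int(np.argmin(d_shaft))
            origin = tuple(coords[i_near].astype(float))
            prot_detections.append(
                _Detection(t, origin, extent_px * px, float(d_shaft[i_near]))
            )

    tracks: list[ProtrusionTrack] = []
    for i, chain in enumerate(_link_detections(prot_detections, link_radius_px, gap_frames)):
        onset, offset = chain[0].frame, chain[-1].frame
        lengths = np.zeros(offset - onset + 1)
        for d in chain:
            lengths[d.frame - onset] = d.length_um
        # fill gap-closed frames with the previous observed length
        for j in range(1, lengths.size):
            if lengths[j] == 0 and (onset + j) not in {d.frame for d in chain}:
                lengths[j] = lengths[j - 1]
        # origin: the most shaft-proximal position over the track's lifetime
        # (while a node thickening is active, the base is displaced outward)
        origin = min(chain, key=lambda d: d.base_dist_px).pos
        tracks.append(ProtrusionTrack(onset, offset, lengths, origin=origin, track_id=i))
    nodes: list[NodeEvent] = []
    for i, chain in enumerate(_link_detections(node_detections, link_radius_px, gap_frames)):
        nodes.append(
            NodeEvent(
                onset=chain[0].frame,
                offset=chain[-1].frame,
                centroids=np.array([d.pos for d in chain]),
                node_id=i,
                detection_interval_s=bin_movie.frame_interval,
            )
        )
    link_protrusions_to_nodes(tracks, nodes, link_radius_px=link_radius_px)
    return tracks, nodes


def link_protrusions_to_nodes(
    tracks: list[ProtrusionTrack],
    nodes: list[NodeEvent],
    link_radius_px: float,
) -> None:
    """Assign each protrusion the nearest node active at or before its onset.

    Modifies ``tracks`` in place (sets ``node_id``).
    """
    for tr in tracks:
        best_id, best_d = None, None
        for node in nodes:
            if node.onset > tr.onset:
                continue
            c = node.mean_centroid
            d = float(np.hypot(tr.origin[0] - c[0], tr.origin[1] - c[1]))
            if d <= link_radius_px and (best_d is None or d < best_d):
                best_id, best_d = node.node_id, d
        tr.node_id = best_id


def classify_track(
    track: ProtrusionTrack, movie_minutes: float, frame_interval: float
) -> ClassifiedTrack:
    """Assign one of the four dynamic classes to a protrusion track.

    Rules, applied in order: (1) present in every frame → static; (2) onset
    after the first frame, present through the last, persistence ≥ 3 min →
    stabilized; (3) present from the first frame, gone before the last,
    persistence ≥ 3 min → collapsed; (4) otherwise → transient.
    """
    last = n_frames_for(movie_minutes, frame_interval) - 1
    if track.onset < 0 or track.offset > last:
        raise ValueError(
            f"track frames [{track.onset}, {track.offset}] outside movie [0, {last}]"
        )
    persistence_s = track.n_present * frame_interval
    if track.onset == 0 and track.offset == last:
        label = "static"
    elif track.onset > 0 and track.offset == last and persistence_s >= PERSISTENCE_MIN_S:
        label = "stabilized"
    elif track.onset == 0 and track.offset < last and persistence_s >= PERSISTENCE_MIN_S:
        label = "collapsed"
    else:
        label = "transient"
    return ClassifiedTrack(track=track, label=label, duration_min=persistence_s / 60.0)


def node_emergence_fraction(
    tracks: list[ProtrusionTrack], groups: list[int] | None = None
) -> float | None:
    """Fraction of de novo protrusions (onset > 0) linked to a node.

    With ``groups`` (one group id per track, e.g. one per neuron) the fraction
    is computed per group and averaged; otherwise it is pooled across all
    protrusions. Returns None when there are no de novo protrusions.
    """
    if groups is None:
        de_novo = [t for t in tracks if t.onset > 0]
        if not de_novo:
            return None
        return sum(t.node_id is not None for t in de_novo) / len(de_novo)
    fractions = []
    for g in sorted(set(groups)):
        sub = [t for t, gg in zip(tracks, groups) if gg == g]
        f = node_emergence_fraction(sub)
        if f is not None:
            fractions.append(f)
    return float(np.mean(fractions)) if fractions else None


def _polyline_arclength(path: np.ndarray) -> np.ndarray:
    seg = np.sqrt(((np.diff(path, axis=0)) ** 2).sum(axis=1))
    return np.concatenate([[0.0], np.cumsum(seg)])


def filopodia_density(
    tracks: list[ProtrusionTrack],
    dendrite_paths: list[np.ndarray],
    pixel_size: float,
    proximal_um: float = 100.0,
    per_um: float = 10.0,
    max_offset_um: float = 2.0,
) -> float | None:
    """Protrusions per ``per_um`` µm over the proximal stretch of each dendrite.

    Each dendrite path is an (x, y) pixel polyline starting at the soma. A
    protrusion counts toward the nearest path (origin within
    ``max_offset_um`` of it) when its arc position lies within the proximal
    ``proximal_um`` µm. The density is averaged across dendrites.
    """
    if not dendrite_paths:
        return None
    counts = []
    for path in dendrite_paths:
        path = np.asarray(path, dtype=float)
        vertex_arc = _polyline_arclength(path)
        total_px = vertex_arc[-1]
        analyzed = min(total_px * pixel_size, proximal_um)
        if analyzed <= 0:
            continue
        # densify the polyline so origins project onto it, not onto vertices
        arc_px = np.linspace(0.0, total_px, max(int(np.ceil(total_px * 2)), 2))
        pts = np.column_stack(
            [
                np.interp(arc_px, vertex_arc, path[:, 0]),
                np.interp(arc_px, vertex_arc, path[:, 1]),
            ]
        )
        n = 0
        for tr in tracks:
            oy, ox = tr.origin
            d = np.hypot(pts[:, 0] - ox, pts[:, 1] - oy) * pixel_size
            j = int(np.argmin(d))
            if d[j] <= max_offset_um + 1e-9 and arc_px[j] * pixel_size <= proximal_um:
                n += 1
        counts.append(n / (analyzed / per_um))
    return float(np.mean(counts)) if counts else None


def dynamics_summary(
    classified: list[ClassifiedTrack],
    nodes: list[NodeEvent],
    dendrite_paths: list[np.ndarray] | None = None,
    pixel_size: float | None = None,
) -> DynamicsSummary:
    """Aggregate counts, the dynamic-per-static rate, the node-emergence
    fraction and the filopodia density.

    The rate normalizes dynamic events (transient + stabilized + collapsed
    protrusions + node events) to the protrusions that remained throughout
    the acquisition (static); it is None when no static protrusion exists.
    """
    counts = {c: 0 for c in CLASSES}
    for ct in classified:
        counts[ct.label] += 1
    n_dynamic = counts["transient"] + counts["stabilized"] + counts["collapsed"] + len(nodes)
    rate = n_dynamic / counts["static"] if counts["static"] > 0 else None
    if rate is None:
        log.warning("dynamics_summary: no static protrusions; rate undefined")
    tracks = [ct.track for ct in classified]
    density = None
    if dendrite_paths is not None and pixel_size is not None:
        density = filopodia_density(tracks, dendrite_paths, pixel_size)
    return DynamicsSummary(
        n_static=counts["static"],
        n_transient=counts["transient"],
        n_stabilized=counts["stabilized"],
        n_collapsed=counts["collapsed"],
        n_nodes=len(nodes),
        dynamic_per_static=rate,
        node_emergence_fraction=node_emergence_fraction(tracks),
        filopodia_density_per_10um=density,
    )


def interval_subsample(
    tracks: list[ProtrusionTrack],
    nodes: list[NodeEvent],
    native_interval: float,
    target_interval: float,
    link_radius_px: float,
) -> tuple[list[ProtrusionTrack], list[NodeEvent]]:
    """Re-observe tracks and nodes on a coarser acquisition grid.

    Only frames at multiples of target/native are retained; events whose
    lifetime falls entirely between retained frames disappear. Node links are
    recomputed on the resampled data. Frame indices in the output refer to
    the coarse grid.
    """
    ratio = target_interval / native_interval
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"target interval {target_interval} is not a multiple of "
            f"native interval {native_interval}"
        )
    if factor == 1:
        out_tracks = [
            ProtrusionTrack(t.onset, t.offset, t.lengths_um.copy(), t.origin,
                            None, t.track_id)
            for t in tracks
        ]
        out_nodes = [
            NodeEvent(n.onset, n.offset, n.centroids.copy(), n.node_id, target_interval)
            for n in nodes
        ]
        link_protrusions_to_nodes(out_tracks, out_nodes, link_radius_px)
        return out_tracks, out_nodes

    def retained(onset: int, offset: int) -> list[int]:
        first = -(-onset // factor)  # ceil division
        lastf = offset // factor
        return list(range(first, lastf + 1))

    out_tracks = []
    for t in tracks:
        frames = retained(t.onset, t.offset)
        if not frames:
            continue
        lengths = t.lengths_um[[f * factor - t.onset for f in frames]]
        out_tracks.append(
            ProtrusionTrack(frames[0], frames[-1], lengths, t.origin,
                            None, t.track_id)
        )
    out_nodes = []
    for n in nodes:
        frames = retained(n.onset, n.offset)
        if not frames:
            continue
        idx = [f * factor - n.onset for f in frames]
        idx = [min(i, n.centroids.shape[0] - 1) for i in idx]
        out_nodes.append(
            NodeEvent(frames[0], frames[-1], n.centroids[idx], n.node_id,
                      target_interval)
        )
    link_protrusions_to_nodes(out_tracks, out_nodes, link_radius_px)
    return out_tracks, out_nodes
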