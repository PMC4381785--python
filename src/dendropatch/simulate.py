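"""Synthetic dendrite scenes, protrusion track sets and expression atlases.

Every downstream stage of the package is tested against data with planted,
exactly known structure:

* ``generate_scene`` renders a two/three-channel time-lapse of a dendritic
  shaft (constant-width tube around a polyline) carrying transient enriched
  patches, node-like shaft thickenings, and extending/retracting protrusions,
  with a simple camera noise model — and returns the ground truth alongside.
* ``generate_tracks`` emits bare protrusion presence tracks that satisfy each
  dynamic-class definition by construction.
* ``generate_node_protrusion_events`` emits matched node/protrusion event
  sets with an exactly planted node-emergence fraction, for estimator
  recovery and acquisition-interval studies.
* ``generate_expression`` emits a probe × tissue intensity matrix with
  planted tissue-enriched gene blocks under multiplicative log-normal noise,
  emulating a tissue expression atlas.

Identical config + seed always reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import morphology

from .dynamics import NodeEvent, ProtrusionTrack, classify_track, link_protrusions_to_nodes
from .expression import ExpressionMatrix

__all__ = [
    "PatchEvent",
    "ProtrusionEvent",
    "SceneConfig",
    "SceneStack",
    "PatchTruth",
    "ProtrusionTruth",
    "GroundTruth",
    "ExpressionSimConfig",
    "generate_scene",
    "generate_tracks",
    "generate_node_protrusion_events",
    "generate_expression",
]


@dataclass
class PatchEvent:
    """A transient enriched patch on the shaft.

    Active during frames [onset, offset). ``enrichment`` is the mean
    POI/cytosol ratio inside the patch footprint relative to the shaft
    (E = 1 means invisible). ``node_flag`` additionally thickens the shaft
    locally while the patch is active, making the event a morphological node.
    """

    arc_pos_um: float
    onset: int
    offset: int
    enrichment: float
    radius_um: float
    node_flag: bool = False


@dataclass
class ProtrusionEvent:
    """A protrusion growing from the shaft along the local normal.

    Grows by ``growth_rate`` µm/frame up to ``max_length``, dwells for
    ``dwell`` frames, then retracts by ``retract_rate`` µm/frame
    (retract_rate 0 = never retracts).
    """

    arc_pos_um: float
    onset: int
    growth_rate: float
    max_length_um: float
    dwell_frames: int
    retract_rate: float
    from_node_flag: bool = False
    side: int = 1  # +1 / -1: which side of the shaft


@dataclass
class SceneConfig:
    width_px: int = 256
    height_px: int = 96
    pixel_size: float = 0.2  # µm/px
    n_frames: int = 1
    frame_interval: float = 60.0  # s
    dendrite_path: np.ndarray | None = None  # (N, 2) of (x, y) px
    shaft_width_um: float = 2.0
    patch_events: list[PatchEvent] = field(default_factory=list)
    protrusion_events: list[ProtrusionEvent] = field(default_factory=list)
    background_level: float = 0.0
    background_gradient: tuple[float, float] = (0.0, 0.0)  # per-px along (y, x)
    dendrite_intensity: float = 1000.0  # amplitude over background inside the cell
    noise_sigma: float = 0.0  # Gaussian read-noise SD
    photon_scale: float = 0.0  # signal-dependent variance factor (0 disables)
    include_actin: bool = False
    patch_profile: str = "disk"  # "disk" (uniform) or "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dendrite_path is None:
            # default: straight horizontal shaft through the image center
            y = self.height_px / 2.0
            self.dendrite_path = np.array(
                [[4.0, y], [self.width_px - 5.0, y]]
            )
        self.dendrite_path = np.asarray(self.dendrite_path, dtype=float)
        for name in ("pixel_size", "frame_interval", "shaft_width_um",
                     "dendrite_intensity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("background_level", "noise_sigma", "photon_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.patch_profile not in ("disk", "gaussian"):
            raise ValueError("patch_profile must be 'disk' or 'gaussian'")
        for i, ev in enumerate(self.patch_events):
            if not ev.enrichment >= 1:
                raise ValueError(f"patch event {i}: enrichment must be >= 1")
            if not (0 <= ev.onset < ev.offset <= self.n_frames):
                raise ValueError(
                    f"patch event {i}: need 0 <= onset < offset <= n_frames"
                )
            if ev.radius_um <= 0:
                raise ValueError(f"patch event {i}: radius must be > 0")
        for i, ev in enumerate(self.protrusion_events):
            if not (0 <= ev.onset < self.n_frames):
                raise ValueError(f"protrusion event {i}: onset outside the movie")
            if ev.growth_rate <= 0 or ev.max_length_um <= 0:
                raise ValueError(
                    f"protrusion event {i}: growth rate and max length must be > 0"
                )
            if ev.dwell_frames < 0 or ev.retract_rate < 0:
                raise ValueError(
                    f"protrusion event {i}: dwell and retract rate must be >= 0"
                )

    @property
    def movie_minutes(self) -> float:
        return (self.n_frames - 1) * self.frame_interval / 60.0


@dataclass
class SceneStack:
    """Rendered multi-channel time-lapse with calibration metadata."""

    channels: dict[str, np.ndarray]  # name -> (T, H, W) float
    pixel_size: float
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]


@dataclass
class PatchTruth:
    index: int
    enrichment: float
    centroid: tuple[float, float]  # (row, col) px, constant across frames
    onset: int
    offset: int  # exclusive
    radius_um: float
    node_flag: bool
    footprint: np.ndarray  # in-shaft footprint pixels (H, W) bool


@dataclass
class ProtrusionTruth:
    index: int
    label: str  # static | transient | stabilized | collapsed
    onset: int
    offset: int  # inclusive
    origin: tuple[float, float]  # (row, col) px
    from_node_flag: bool
    lengths_um: np.ndarray


@dataclass
class GroundTruth:
    patches: list[PatchTruth]
    protrusions: list[ProtrusionTruth]
    node_fraction: float | None  # fraction of protrusions planted as node-emerging
    shaft_mask: np.ndarray  # (H, W) baseline shaft, no bumps/protrusions
    frame_masks: np.ndarray  # (T, H, W) full cell mask per frame

    def to_dict(self) -> dict:
        return {
            "patches": [
                {
                    "index": p.index,
                    "enrichment": p.enrichment,
                    "centroid": list(p.centroid),
                    "onset": p.onset,
                    "offset": p.offset,
                    "radius_um": p.radius_um,
                    "node_flag": p.node_flag,
                }
                for p in self.patches
            ],
            "protrusions": [
                {
                    "index": t.index,
                    "label": t.label,
                    "onset": t.onset,
                    "offset": t.offset,
                    "origin": list(t.origin),
                    "from_node_flag": t.from_node_flag,
                    "lengths_um": list(t.lengths_um),
                }
                for t in self.protrusions
            ],
            "node_fraction": self.node_fraction,
        }


# ---------------------------------------------------------------------------
# geometry helpers


def _arc_table(path: np.ndarray) -> np.ndarray:
    seg = np.sqrt((np.diff(path, axis=0) ** 2).sum(axis=1))
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at_arc(path: np.ndarray, arc_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent at arc-length position ``arc_px`` (pixels)."""
    arcs = _arc_table(path)
    arc_px = float(np.clip(arc_px, 0.0, arcs[-1]))
    j = int(np.searchsorted(arcs, arc_px, side="right")) - 1
    j = min(j, len(path) - 2)
    seg_len = arcs[j + 1] - arcs[j]
    f = 0.0 if seg_len == 0 else (arc_px - arcs[j]) / seg_len
    point = path[j] + f * (path[j + 1] - path[j])
    tangent = (path[j + 1] - path[j]) / max(seg_len, 1e-12)
    return point, tangent


def _rasterize_centerline(config: SceneConfig) -> np.ndarray:
    grid = np.zeros((config.height_px, config.width_px), dtype=bool)
    arcs = _arc_table(config.dendrite_path)
    n_samples = max(int(np.ceil(arcs[-1] * 4)), 2)
    for s in np.linspace(0, arcs[-1], n_samples):
        (x, y), _ = _point_at_arc(config.dendrite_path, s)
        r, c = int(round(y)), int(round(x))
        if 0 <= r < config.height_px and 0 <= c < config.width_px:
            grid[r, c] = True
    return grid


def _shaft_mask(config: SceneConfig) -> np.ndarray:
    centerline = _rasterize_centerline(config)
    dist = ndimage.distance_transform_edt(~centerline)
    halfwidth_px = config.shaft_width_um / 2.0 / config.pixel_size
    return dist <= halfwidth_px


def _protrusion_lengths(ev: ProtrusionEvent, n_frames: int) -> np.ndarray:
    """Length (µm) per frame from the event's onset until it vanishes."""
    lengths = []
    grow_frames = int(np.ceil(ev.max_length_um / ev.growth_rate))
    t = 0
    while ev.onset + t < n_frames:
        if t < grow_frames:
            l = min((t + 1) * ev.growth_rate, ev.max_length_um)
        elif t < grow_frames + ev.dwell_frames or ev.retract_rate == 0:
            l = ev.max_length_um
        else:
            k = t - grow_frames - ev.dwell_frames + 1
            l = ev.max_length_um - k * ev.retract_rate
        if l <= 0:
            break
        lengths.append(l)
        t += 1
    return np.array(lengths)


def generate_scene(config: SceneConfig) -> tuple[SceneStack, GroundTruth]:
    """Render a scene and return it with its ground truth.

    Channels: ``cytosol`` fills the cell mask uniformly at the configured
    dendrite intensity over the background; ``poi`` equals the cytosol signal
    multiplied by the planted enrichment field inside active patch footprints
    and by 1 elsewhere; an optional ``actin`` channel mirrors the patch
    footprints. Camera noise adds N(0, noise_sigma² + photon_scale·value)
    per pixel.
    """
    h, w = config.height_px, config.width_px
    px = config.pixel_size
    arcs = _arc_table(config.dendrite_path)
    total_arc_um = arcs[-1] * px
    shaft = _shaft_mask(config)
    halfwidth_px = config.shaft_width_um / 2.0 / px

    # validate + precompute patch geometry
    patch_truths: list[PatchTruth] = []
    patch_fields: list[tuple[PatchEvent, np.ndarray, np.ndarray]] = []
    yy, xx = np.mgrid[0:h, 0:w]
    for i, ev in enumerate(config.patch_events):
        if not 0 <= ev.arc_pos_um <= total_arc_um:
            raise ValueError(
                f"patch event {i}: arc position {ev.arc_pos_um} µm beyond the "
                f"dendrite arc length ({total_arc_um:.2f} µm)"
            )
        (cx, cy), _ = _point_at_arc(config.dendrite_path, ev.arc_pos_um / px)
        r_px = ev.radius_um / px
        if not (r_px <= cx <= w - 1 - r_px and r_px <= cy <= h - 1 - r_px):
            raise ValueError(f"patch event {i}: footprint outside image bounds")
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        footprint_full = d2 <= r_px * r_px
        footprint = footprint_full & shaft
        if config.patch_profile == "disk":
            mult = np.where(footprint_full, ev.enrichment, 1.0)
        else:
            sigma = r_px / 3.0
            g = np.exp(-d2 / (2 * sigma * sigma)) * footprint_full
            g_mean = g[footprint].mean()
            mult = 1.0 + (ev.enrichment - 1.0) / g_mean * g
        patch_fields.append((ev, footprint_full, mult))
        patch_truths.append(
            PatchTruth(
                index=i,
                enrichment=ev.enrichment,
                centroid=(cy, cx),
                onset=ev.onset,
                offset=ev.offset,
                radius_um=ev.radius_um,
                node_flag=ev.node_flag,
                footprint=footprint,
            )
        )

    # validate + precompute protrusion geometry
    prot_truths: list[ProtrusionTruth] = []
    prot_geo: list[tuple[ProtrusionEvent, np.ndarray, np.ndarray, np.ndarray]] = []
    for i, ev in enumerate(config.protrusion_events):
        if not 0 <= ev.arc_pos_um <= total_arc_um:
            raise ValueError(
                f"protrusion event {i}: arc position beyond the dendrite arc length"
            )
        (cx, cy), tangent = _point_at_arc(config.dendrite_path, ev.arc_pos_um / px)
        normal = np.array([-tangent[1], tangent[0]]) * ev.side  # (dx, dy)
        origin = np.array([cx, cy]) + normal * halfwidth_px
        tip_max = origin + normal * (ev.max_length_um / px)
        for pt, what in ((origin, "origin"), (tip_max, "maximal tip")):
            if not (0 <= pt[0] <= w - 1 and 0 <= pt[1] <= h - 1):
                raise ValueError(
                    f"protrusion event {i}: {what} outside image bounds"
                )
        lengths = _protrusion_lengths(ev, config.n_frames)
        if lengths.size == 0:
            raise ValueError(f"protrusion event {i}: never present in the movie")
        prot_geo.append((ev, origin, normal, lengths))
        offset = ev.onset + lengths.size - 1
        ideal = ProtrusionTrack(ev.onset, offset, lengths, origin=(origin[1], origin[0]))
        label = classify_track(ideal, config.movie_minutes, config.frame_interval).label
        prot_truths.append(
            ProtrusionTruth(
                index=i,
                label=label,
                onset=ev.onset,
                offset=offset,
                origin=(origin[1], origin[0]),
                from_node_flag=ev.from_node_flag,
                lengths_um=lengths,
            )
        )

    # render frames
    bg = (
        config.background_level
        + config.background_gradient[0] * yy
        + config.background_gradient[1] * xx
    )
    amp = config.dendrite_intensity
    frame_masks = np.zeros((config.n_frames, h, w), dtype=bool)
    cyto = np.empty((config.n_frames, h, w))
    poi = np.empty_like(cyto)
    actin = np.empty_like(cyto) if config.include_actin else None
    for t in range(config.n_frames):
        mask = shaft.copy()
        enrich = np.ones((h, w))
        actin_field = np.ones((h, w))
        for ev, footprint_full, mult in patch_fields:
            if ev.onset <= t < ev.offset:
                enrich *= mult
                actin_field *= mult
                if ev.node_flag:
                    mask |= footprint_full
        for ev, origin, normal, lengths in prot_geo:
            k = t - ev.onset
            if 0 <= k < lengths.size:
                tip = origin + normal * (lengths[k] / px)
                rr, cc = skdraw.line(
                    int(round(origin[1])), int(round(origin[0])),
                    int(round(tip[1])), int(round(tip[0])),
                )
                seg = np.zeros((h, w), dtype=bool)
                seg[rr.clip(0, h - 1), cc.clip(0, w - 1)] = True
                mask |= morphology.dilation(seg, morphology.disk(1))
        frame_masks[t] = mask
        cyto[t] = bg + amp * mask
        poi[t] = bg + amp * mask * enrich
        if actin is not None:
            actin[t] = bg + amp * mask * actin_field

    channels = {"cytosol": cyto, "poi": poi}
    if actin is not None:
        channels["actin"] = actin
    rng = np.random.default_rng(config.seed)
    if config.noise_sigma > 0 or config.photon_scale > 0:
        for name in sorted(channels):
            v = channels[name]
            sd = np.sqrt(config.noise_sigma**2 + config.photon_scale * np.maximum(v, 0))
            channels[name] = v + rng.normal(size=v.shape) * sd

    n_prot = len(prot_truths)
    truth = GroundTruth(
        patches=patch_truths,
        protrusions=prot_truths,
        node_fraction=(
            sum(p.from_node_flag for p in prot_truths) / n_prot if n_prot else None
        ),
        shaft_mask=shaft,
        frame_masks=frame_masks,
    )
    return SceneStack(channels, px, config.frame_interval), truth


# ---------------------------------------------------------------------------
# bare track sets


def generate_tracks(
    n_per_class: dict[str, int],
    movie_minutes: float,
    frame_interval: float,
    seed: int = 0,
) -> tuple[list[ProtrusionTrack], list[str]]:
    """Emit protrusion tracks that satisfy each requested class by construction.

    Raises when a class cannot be realized under the given acquisition
    parameters (e.g. a 3-minute persistence that does not fit on the frame
    grid), naming the class.
    """
    from .dynamics import PERSISTENCE_MIN_S, n_frames_for

    n_frames = n_frames_for(movie_minutes, frame_interval)
    if n_frames < 2:
        raise ValueError("acquisition must span at least 2 frames")
    last = n_frames - 1
    need = int(np.ceil(PERSISTENCE_MIN_S / frame_interval))  # frames for >= 3 min
    rng = np.random.default_rng(seed)
    tracks: list[ProtrusionTrack] = []
    labels: list[str] = []
    for cls in sorted(n_per_class):
        n = n_per_class[cls]
        for _ in range(n):
            if cls == "static":
                onset, offset = 0, last
            elif cls == "stabilized":
                max_onset = last - need + 1
                if max_onset < 1:
                    raise ValueError(
                        "class 'stabilized' unrealizable: a >= 3 min persistence "
                        "starting after frame 0 does not fit in the acquisition"
                    )
                onset, offset = int(rng.integers(1, max_onset + 1)), last
            elif cls == "collapsed":
                min_offset = need - 1
                if min_offset > last - 1:
                    raise ValueError(
                        "class 'collapsed' unrealizable: a >= 3 min persistence "
                        "ending before the last frame does not fit"
                    )
                onset, offset = 0, int(rng.integers(min_offset, last))
            elif cls == "transient":
                if last < 2:
                    raise ValueError(
                        "class 'transient' unrealizable: no interior frames"
                    )
                onset = int(rng.integers(1, last))
                offset = int(rng.integers(onset, last))
            else:
                raise ValueError(f"unknown class {cls!r}")
            lengths = np.full(offset - onset + 1, 1.5)
            tracks.append(ProtrusionTrack(onset, offset, lengths))
            labels.append(cls)
    return tracks, labels


def generate_node_protrusion_events(
    n_protrusions: int,
    node_fraction: float,
    movie_minutes: float,
    frame_interval: float,
    seed: int = 0,
    node_lifetime_range_s: tuple[float, float] = (30.0, 90.0),
    protrusion_duration_range_s: tuple[float, float] = (120.0, 300.0),
    pixel_size: float = 0.2,
    link_radius_um: float = 1.0,
) -> tuple[list[ProtrusionTrack], list[NodeEvent]]:
    """De novo protrusions, an exact fraction of which emerge from nodes.

    Exactly round(n_protrusions × node_fraction) protrusions are seeded by a
    node active at their origin at (or just before) their onset; the rest
    arise without one. Origins sit on a coarse grid so that no protrusion
    lies within the link radius of another event's node. Node lifetimes are
    drawn uniformly from ``node_lifetime_range_s`` — short enough that coarse
    acquisition grids miss some of them.
    """
    from .dynamics import n_frames_for

    if not 0 <= node_fraction <= 1:
        raise ValueError("node_fraction must be in [0, 1]")
    n_frames = n_frames_for(movie_minutes, frame_interval)
    if n_frames < 3:
        raise ValueError("acquisition too short for de novo protrusions")
    rng = np.random.default_rng(seed)
    link_radius_px = link_radius_um / pixel_size
    spacing = 4.0 * link_radius_px
    side = int(np.ceil(np.sqrt(n_protrusions)))
    positions = [
        (spacing * (i + 1), spacing * (j + 1)) for i in range(side) for j in range(side)
    ][:n_protrusions]
    rng.shuffle(positions)

    n_seeded = int(round(n_protrusions * node_fraction))
    tracks: list[ProtrusionTrack] = []
    nodes: list[NodeEvent] = []
    for i in range(n_protrusions):
        pos = positions[i]
        dur_s = rng.uniform(*protrusion_duration_range_s)
        dur_f = max(int(np.ceil(dur_s / frame_interval)), 1)
        onset = int(rng.integers(1, max(n_frames - dur_f, 2)))
        offset = min(onset + dur_f - 1, n_frames - 2)  # keep it transient
        lengths = np.full(offset - onset + 1, 2.0)
        track = ProtrusionTrack(onset, offset, lengths, origin=pos, track_id=i)
        tracks.append(track)
        if i < n_seeded:
            life_s = rng.uniform(*node_lifetime_range_s)
            life_f = max(int(np.ceil(life_s / frame_interval)), 1)
            n_onset = max(onset - int(rng.integers(0, life_f)), 0)
            n_offset = n_onset + life_f - 1
            nodes.append(
                NodeEvent(
                    onset=n_onset,
                    offset=n_offset,
                    centroids=np.tile(pos, (n_offset - n_onset + 1, 1)),
                    node_id=len(nodes),
                    detection_interval_s=frame_interval,
                )
            )
    link_protrusions_to_nodes(tracks, nodes, link_radius_px=link_radius_px)
    return tracks, nodes


# ---------------------------------------------------------------------------
# expression atlases


@dataclass
class ExpressionSimConfig:
    """Planted-block expression atlas configuration.

    ``enriched_blocks`` is a list of (gene index list, tissue index list,
    fold) triples; member genes are multiplied by ``fold`` in member tissues.
    """

    n_genes: int = 200
    n_tissues: int = 74
    enriched_blocks: list[tuple[list[int], list[int], float]] = field(default_factory=list)
    baseline_level: float = 100.0
    noise_sigma_log: float = 0.3  # SD of multiplicative log-normal noise
    probes_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_tissues < 1 or self.probes_per_gene < 1:
            raise ValueError("counts must be >= 1")
        if not self.baseline_level > 0:
            raise ValueError("baseline_level must be > 0")
        if self.noise_sigma_log < 0:
            raise ValueError("noise_sigma_log must be >= 0")
        for b, (genes, tissues, fold) in enumerate(self.enriched_blocks):
            if not fold >= 1:
                raise ValueError(f"block {b}: fold must be >= 1")
            if any(not 0 <= g < self.n_genes for g in genes):
                raise ValueError(f"block {b}: gene index out of range")
            if any(not 0 <= t < self.n_tissues for t in tissues):
                raise ValueError(f"block {b}: tissue index out of range")


def generate_expression(
    config: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Planted-block atlas: entry = baseline × fold(block) × log-normal noise.

    Probe replicates of a gene share the gene-level mean (baseline × fold) and
    differ only through noise. Returns the matrix and a per-gene block label
    array (-1 = background, otherwise the block index).
    """
    rng = np.random.default_rng(config.seed)
    gene_means = np.full((config.n_genes, config.n_tissues), config.baseline_level)
    block_labels = np.full(config.n_genes, -1)
    for b, (genes, tissues, fold) in enumerate(config.enriched_blocks):
        gi = np.asarray(genes, dtype=int)
        ti = np.asarray(tissues, dtype=int)
        gene_means[np.ix_(gi, ti)] *= fold
        block_labels[gi] = b
    reps = config.probes_per_gene
    values = np.repeat(gene_means, reps, axis=0)
    if config.noise_sigma_log > 0:
        noise = rng.normal(0.0, config.noise_sigma_log, size=values.shape)
        values = values * np.exp(noise)
    probe_ids = [
        f"g{g:04d}_p{r}" for g in range(config.n_genes) for r in range(reps)
    ]
    gene_symbols = [f"GENE{g:04d}" for g in range(config.n_genes) for _ in range(reps)]
    tissue_names = [f"tissue_{t:02d}" for t in range(config.n_tissues)]
    return (
        ExpressionMatrix(values, probe_ids, gene_symbols, tissue_names),
        block_labels,
    )
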