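"""Seeded phantom SBEM volumes with voxel-level ground truth.

The phantom emulates the structures a peroxidase (APEX2) EM label
produces in a retinal stack: ganglion cell somas whose *membrane* is
darkened (a dark shell around a normal-intensity interior), dendrites
that are dark throughout and run from the soma down into a target
sublamina of the inner plexiform layer, and the electron-dense
distractors that plague threshold-based segmentation — lysosomes,
mitochondria and nucleoli of limited z-extent, plus elongated
Müller-glia-like processes that survive any section-count filter and
act as designed false positives.

Intensities are 8-bit with dark = labeled; Gaussian acquisition noise is
added on top of the per-structure means and clipped to [0, 255].  Every
rendered voxel carries an integer id in a parallel label volume, with an
id -> class map and an id -> parent-neuron map, so segmentation output
can be scored against exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .volume import GCL, IPL, LayerAnnotation, VoxelVolume

STRONG = "strong"
WEAK = "weak"

NEURON_CLASSES = frozenset({"dendrite_strong", "dendrite_weak", "soma"})
DISTRACTOR_CLASSES = ("lysosome", "mitochondrion", "nucleolus", "muller_process")


@dataclass(frozen=True)
class IntensityModel:
    """Per-structure mean gray values (8-bit, dark = labeled).

    The weak-label mean sits midway between the strong-label mean and
    the background so that weakly labeled dendrites are visibly darker
    than neuropil yet miss a threshold calibrated on strong label —
    reproducing the failure mode where weakly labeled dendrites escape
    automatic detection.
    """

    background_mean: float = 180.0
    background_sd: float = 12.0
    strong_mean: float = 40.0
    weak_mean: float = 110.0

    def __post_init__(self) -> None:
        if not self.strong_mean < self.weak_mean < self.background_mean:
            raise ValueError(
                "intensity ordering must be strong < weak < background (dark = low)"
            )
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")

    def label_mean(self, labeling: str) -> float:
        return self.strong_mean if labeling == STRONG else self.weak_mean


@dataclass(frozen=True)
class NeuronSpec:
    """One phantom ganglion cell.

    ``soma_center_um`` is (z, y, x) in micrometres; the soma must sit in
    the GCL.  ``stratum`` selects the IPL sublamina the dendrites target:
    OFF (outer IPL, near the INL), ON (inner IPL, near the GCL) or
    ON_OFF (bistratified).
    """

    soma_center_um: tuple[float, float, float]
    soma_radius_um: float = 3.0
    n_dendrites: int = 3
    branch_depth: int = 2
    stratum: str = "ON"
    labeling: str = STRONG

    def __post_init__(self) -> None:
        if self.stratum not in ("ON", "OFF", "ON_OFF"):
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.labeling not in (STRONG, WEAK):
            raise ValueError(f"unknown labeling {self.labeling!r}")
        if self.soma_radius_um <= 0 or self.n_dendrites < 0 or self.branch_depth < 0:
            raise ValueError("invalid neuron geometry")


# IPL depth (0 = INL border, 1 = GCL border) each stratum's arbor targets.
STRATUM_DEPTHS = {"OFF": (0.2,), "ON": (0.7,), "ON_OFF": (0.2, 0.7)}


@dataclass
class PhantomConfig:
    """Full description of one phantom volume.

    The default geometry is a scaled-down retinal stack: isotropic-ish
    150 nm voxels, 240 sections (36 um deep) partitioned into GCL
    (0-9 um), IPL (9-30 um) and INL (30-36 um).  ``filter_sections`` is
    the z-extent (in sections) the downstream size filter assumes;
    small-organelle distractors are sized to span strictly fewer
    sections and Müller-like processes strictly more, whatever the
    section thickness.
    """

    shape_zyx: tuple[int, int, int] = (240, 256, 256)
    voxel_size_nm: tuple[float, float, float] = (150.0, 150.0, 150.0)
    layer_boundaries: tuple[int, int] = (60, 200)
    neurons: tuple[NeuronSpec, ...] = ()
    distractors: dict = field(default_factory=dict)
    intensity: IntensityModel = field(default_factory=IntensityModel)
    filter_sections: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        dx, dy, dz = self.voxel_size_nm
        if dz <= 0 or dx <= 0 or dy <= 0:
            raise ValueError("voxel sizes must be positive")
        b0, b1 = self.layer_boundaries
        if not (0 < b0 < b1 < self.shape_zyx[0]):
            raise ValueError("layer boundaries must be strictly increasing within the stack")
        for cls in self.distractors:
            if cls not in DISTRACTOR_CLASSES:
                raise ValueError(f"unknown distractor class {cls!r}")

    @property
    def layers(self) -> LayerAnnotation:
        return LayerAnnotation(
            gcl_ipl=self.layer_boundaries[0],
            ipl_inl=self.layer_boundaries[1],
            n_sections=self.shape_zyx[0],
        )

    @property
    def voxel_size_um(self) -> tuple[float, float, float]:
        dx, dy, dz = self.voxel_size_nm
        return (dx / 1000.0, dy / 1000.0, dz / 1000.0)

    @property
    def voxel_um_zyx(self) -> tuple[float, float, float]:
        """Voxel pitch reordered to match the (z, y, x) array axes."""
        dx, dy, dz = self.voxel_size_um
        return (dz, dy, dx)

    @property
    def z_depth_um(self) -> float:
        return self.shape_zyx[0] * self.voxel_size_nm[2] / 1000.0

    def to_dict(self) -> dict:
        return {
            "shape_zyx": list(self.shape_zyx),
            "voxel_size_nm": list(self.voxel_size_nm),
            "layer_boundaries": list(self.layer_boundaries),
            "neurons": [
                {
                    "soma_center_um": list(n.soma_center_um),
                    "soma_radius_um": n.soma_radius_um,
                    "n_dendrites": n.n_dendrites,
                    "branch_depth": n.branch_depth,
                    "stratum": n.stratum,
                    "labeling": n.labeling,
                }
                for n in self.neurons
            ],
            "distractors": dict(self.distractors),
            "intensity": {
                "background_mean": self.intensity.background_mean,
                "background_sd": self.intensity.background_sd,
                "strong_mean": self.intensity.strong_mean,
                "weak_mean": self.intensity.weak_mean,
            },
            "filter_sections": self.filter_sections,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if "neurons" in d:
            d["neurons"] = tuple(
                NeuronSpec(
                    soma_center_um=tuple(n["soma_center_um"]),
                    soma_radius_um=n.get("soma_radius_um", 3.0),
                    n_dendrites=n.get("n_dendrites", 3),
                    branch_depth=n.get("branch_depth", 2),
                    stratum=n.get("stratum", "ON"),
                    labeling=n.get("labeling", STRONG),
                )
                for n in d["neurons"]
            )
        if "intensity" in d and isinstance(d["intensity"], dict):
            d["intensity"] = IntensityModel(**d["intensity"])
        for key in ("shape_zyx", "voxel_size_nm", "layer_boundaries"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_config(seed: int = 0, **overrides) -> PhantomConfig:
    """The standard three-neuron phantom used throughout the package."""
    neurons = (
        NeuronSpec(soma_center_um=(4.5, 8.0, 8.0), stratum="OFF"),
        NeuronSpec(soma_center_um=(4.5, 8.0, 30.0), stratum="ON"),
        NeuronSpec(soma_center_um=(4.5, 30.0, 19.0), stratum="ON_OFF"),
    )
    distractors = {"lysosome": 15, "mitochondrion": 15, "nucleolus": 5, "muller_process": 5}
    cfg = dict(neurons=neurons, distractors=distractors, seed=seed)
    cfg.update(overrides)
    return PhantomConfig(**cfg)


@dataclass
class GroundTruth:
    """Voxel-level ground truth for a phantom.

    ``labels`` holds one integer id per voxel (0 = background);
    ``class_map`` maps each id to its structure class and
    ``parent_map`` maps neuron-owned ids (soma, dendrites) to a parent
    neuron index so all parts of one cell can be grouped.
    """

    labels: np.ndarray
    class_map: dict[int, str]
    parent_map: dict[int, int]

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.class_map)
        if missing:
            raise ValueError(f"labels present without class entry: {sorted(missing)}")

    def ids_of_class(self, *classes: str) -> list[int]:
        return sorted(i for i, c in self.class_map.items() if c in classes)

    @property
    def neuron_ids(self) -> list[int]:
        return sorted(set(self.parent_map.values()))

    def voxel_coords(self, label_id: int) -> np.ndarray:
        """(N, 3) array of (z, y, x) voxel coordinates of one structure."""
        return np.argwhere(self.labels == label_id)

    def z_extent(self, label_id: int) -> int:
        """Number of distinct sections the structure occupies."""
        zs = np.nonzero((self.labels == label_id).any(axis=(1, 2)))[0]
        return int(zs.size)

    def save(self, tiff_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        tiff_path = Path(tiff_path)
        tifffile.imwrite(tiff_path, self.labels.astype(np.uint16))
        sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "class_map": {str(k): v for k, v in self.class_map.items()},
                    "parent_map": {str(k): v for k, v in self.parent_map.items()},
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, tiff_path: str | Path, sidecar_path: str | Path | None = None) -> "GroundTruth":
        tiff_path = Path(tiff_path)
        labels = tifffile.imread(tiff_path)
        sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        return cls(
            labels=labels,
            class_map={int(k): v for k, v in meta["class_map"].items()},
            parent_map={int(k): v for k, v in meta["parent_map"].items()},
        )


# ---------------------------------------------------------------------------
# rendering primitives


def _stamp_ellipsoid(labels, intensities, center_um, radii_um, voxel_um, label_id, value):
    """Paint an axis-aligned ellipsoid into the label and intensity volumes."""
    shape = labels.shape
    c = [center_um[i] / voxel_um[i] for i in range(3)]
    r = [max(radii_um[i] / voxel_um[i], 0.0) for i in range(3)]
    lo = [max(int(np.floor(c[i] - r[i] - 1)), 0) for i in range(3)]
    hi = [min(int(np.ceil(c[i] + r[i] + 1)) + 1, shape[i]) for i in range(3)]
    if any(lo[i] >= hi[i] for i in range(3)):
        return
    zz, yy, xx = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    dist = sum(
        ((ax - c[i]) / max(r[i], 1e-9)) ** 2 for i, ax in enumerate((zz, yy, xx))
    )
    mask = dist <= 1.0
    box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    labels[box][mask] = label_id
    intensities[box][mask] = value


def _stamp_ball(labels, intensities, center_um, radius_um, voxel_um, label_id, value):
    _stamp_ellipsoid(
        labels, intensities, center_um, (radius_um,) * 3, voxel_um, label_id, value
    )


def _stamp_shell(labels, intensities, center_um, radius_um, thickness_um, voxel_um, label_id, value):
    """A hollow spherical shell — the membrane-only soma label."""
    shape = labels.shape
    c = [center_um[i] / voxel_um[i] for i in range(3)]
    r_out = radius_um + thickness_um / 2
    lo = [max(int(np.floor(c[i] - r_out / voxel_um[i] - 1)), 0) for i in range(3)]
    hi = [min(int(np.ceil(c[i] + r_out / voxel_um[i] + 1)) + 1, shape[i]) for i in range(3)]
    if any(lo[i] >= hi[i] for i in range(3)):
        return
    zz, yy, xx = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    # physical distance from the centre, in um
    d2 = sum(
        ((ax - c[i]) * voxel_um[i]) ** 2 for i, ax in enumerate((zz, yy, xx))
    )
    d = np.sqrt(d2)
    # half-thickness padded so the discrete shell stays watertight
    half = max(thickness_um / 2, max(voxel_um) * 0.9)
    mask = np.abs(d - radius_um) <= half
    box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    labels[box][mask] = label_id
    intensities[box][mask] = value


def _stamp_polyline(labels, intensities, points_um, radius_um, voxel_um, label_id, value):
    """Paint a tube by stamping overlapping balls along a polyline."""
    points = np.asarray(points_um, dtype=float)
    if len(points) == 0:
        return
    step = min(radius_um, min(voxel_um) * 2) * 0.5
    prev = points[0]
    _stamp_ball(labels, intensities, prev, radius_um, voxel_um, label_id, value)
    for nxt in points[1:]:
        seg = nxt - prev
        length = float(np.linalg.norm(seg))
        n = max(int(np.ceil(length / step)), 1)
        for k in range(1, n + 1):
            p = prev + seg * (k / n)
            _stamp_ball(labels, intensities, p, radius_um, voxel_um, label_id, value)
        prev = nxt


# ---------------------------------------------------------------------------
# neuron growth


def _grow_arbor(rng, spec: NeuronSpec, config: PhantomConfig):
    """Seeded recursive random tree for one neuron.

    Returns a list of ``(polyline_um, radius_um)`` segments plus swelling
    centres.  Trunks leave the soma surface heading into the IPL, relax
    onto the target stratum depth and then branch laterally, each
    bifurcation shrinking the tube radius; swellings (mitochondria-
    bearing varicosities) are dropped every few micrometres.
    """
    layers = config.layers
    dz_um = config.voxel_um_zyx[0]
    sz, sy, sx = spec.soma_center_um
    depths = STRATUM_DEPTHS[spec.stratum]
    segments: list[tuple[np.ndarray, float]] = []
    swellings: list[tuple[np.ndarray, float]] = []
    y_max = config.shape_zyx[1] * config.voxel_um_zyx[1]
    x_max = config.shape_zyx[2] * config.voxel_um_zyx[2]

    def z_of_depth(depth: float) -> float:
        z_idx = layers.ipl_inl - depth * (layers.ipl_inl - layers.gcl_ipl)
        return z_idx * dz_um

    def branch(start, azimuth, z_target, radius, depth_remaining):
        length = rng.uniform(4.0, 7.0)
        n_steps = max(int(length / 0.5), 2)
        pts = [np.asarray(start, dtype=float)]
        theta = azimuth
        for _ in range(n_steps):
            theta += rng.normal(0.0, 0.15)
            p = pts[-1].copy()
            p[1] += np.sin(theta) * 0.5
            p[2] += np.cos(theta) * 0.5
            # relax towards the stratum plane with a little jitter
            p[0] += 0.35 * (z_target - p[0]) + rng.normal(0.0, 0.05)
            p[1] = float(np.clip(p[1], 0.5, y_max - 0.5))
            p[2] = float(np.clip(p[2], 0.5, x_max - 0.5))
            pts.append(p)
        pts = np.asarray(pts)
        segments.append((pts, radius))
        # varicosities roughly every 3 um along the branch
        arc = np.linalg.norm(np.diff(pts, axis=0), axis=1).cumsum()
        next_at = rng.uniform(1.5, 3.0)
        for i, s in enumerate(arc):
            if s >= next_at:
                swellings.append((pts[i + 1], radius * 1.6))
                next_at += rng.uniform(2.5, 4.0)
        if depth_remaining > 0:
            for sign in (-1.0, 1.0):
                branch(
                    pts[-1],
                    theta + sign * rng.uniform(0.4, 0.9),
                    z_target,
                    max(radius * 0.8, 0.3),
                    depth_remaining - 1,
                )

    for d in range(spec.n_dendrites):
        depth = depths[d % len(depths)]
        z_target = z_of_depth(depth)
        azimuth = 2 * np.pi * d / max(spec.n_dendrites, 1) + rng.uniform(-0.3, 0.3)
        # trunk: from the soma shell straight down into the IPL
        exit_pt = np.array(
            [
                sz + spec.soma_radius_um * 0.9,
                sy + np.sin(azimuth) * spec.soma_radius_um * 0.4,
                sx + np.cos(azimuth) * spec.soma_radius_um * 0.4,
            ]
        )
        trunk_end = exit_pt.copy()
        trunk_end[0] = z_target
        trunk_end[1] += np.sin(azimuth) * rng.uniform(1.0, 2.5)
        trunk_end[2] += np.cos(azimuth) * rng.uniform(1.0, 2.5)
        n_tr = 8
        trunk = exit_pt + (trunk_end - exit_pt) * np.linspace(0, 1, n_tr)[:, None]
        segments.append((trunk, 0.8))
        branch(trunk_end, azimuth, z_target, 0.6, spec.branch_depth)
    return segments, swellings


# ---------------------------------------------------------------------------
# distractors


def _distractor_half_extents(cls: str, rng, config: PhantomConfig):
    """(z, y, x) half-extents in um, honouring the z-section contracts."""
    dz_um = config.voxel_um_zyx[0]
    # small organelles must span strictly fewer than filter_sections sections
    z_cap = (config.filter_sections - 3) * dz_um / 2.0
    if cls == "lysosome":
        r = rng.uniform(0.25, 0.45)
        return (min(r, z_cap), r, r)
    if cls == "mitochondrion":
        long_axis = rng.uniform(0.6, 1.1)
        short = rng.uniform(0.15, 0.3)
        return (min(short, z_cap), short, long_axis)
    if cls == "nucleolus":
        r = rng.uniform(0.5, 0.9)
        return (min(r, z_cap), r, r)
    raise ValueError(cls)


def _place_distractors(rng, cls, count, labels, intensities, config, next_id, class_map):
    """Rejection-sample positions that keep ≥1 voxel of clearance from
    everything already rendered, so distractors never bridge structures."""
    voxel_um = config.voxel_um_zyx
    layers = config.layers
    dz_um = voxel_um[0]
    shape = labels.shape
    y_max = shape[1] * voxel_um[1]
    x_max = shape[2] * voxel_um[2]
    placed = 0
    ids = []
    intensity = config.intensity.strong_mean  # electron-dense, like the label
    for _ in range(count * 60):
        if placed >= count:
            break
        if cls == "muller_process":
            # radial glia process: a thin tube running along z through the IPL
            z0_idx, z1_idx = layers.z_range(IPL)
            min_len = max(3.0, (config.filter_sections + 2) * dz_um)
            max_len = min((z1_idx - z0_idx - 2) * dz_um, min_len * 2.5)
            length = rng.uniform(min_len, max(max_len, min_len + dz_um))
            z_start = rng.uniform(z0_idx * dz_um + dz_um, z1_idx * dz_um - length - dz_um)
            y = rng.uniform(1.0, y_max - 1.0)
            x = rng.uniform(1.0, x_max - 1.0)
            radius = rng.uniform(0.2, 0.35)
            n_pts = max(int(length / 0.5), 2)
            zs = np.linspace(z_start, z_start + length, n_pts)
            drift = rng.normal(0.0, 0.08, size=(n_pts, 2)).cumsum(axis=0)
            pts = np.column_stack([zs, y + drift[:, 0], x + drift[:, 1]])
            pts[:, 1] = np.clip(pts[:, 1], 0.5, y_max - 0.5)
            pts[:, 2] = np.clip(pts[:, 2], 0.5, x_max - 0.5)
            if not _region_clear_polyline(labels, pts, radius, voxel_um):
                continue
            _stamp_polyline(labels, intensities, pts, radius, voxel_um, next_id, intensity)
            ids.append(next_id)
            class_map[next_id] = cls
            next_id += 1
            placed += 1
        else:
            half = _distractor_half_extents(cls, rng, config)
            if cls == "nucleolus":
                z0_idx, z1_idx = layers.z_range(GCL)
            else:
                z0_idx, z1_idx = 0, shape[0]
            z_lo = z0_idx * dz_um + half[0] + dz_um
            z_hi = z1_idx * dz_um - half[0] - dz_um
            if z_hi <= z_lo:
                continue
            center = (
                rng.uniform(z_lo, z_hi),
                rng.uniform(half[1] + 0.5, y_max - half[1] - 0.5),
                rng.uniform(half[2] + 0.5, x_max - half[2] - 0.5),
            )
            if not _region_clear(labels, center, half, voxel_um):
                continue
            _stamp_ellipsoid(labels, intensities, center, half, voxel_um, next_id, intensity)
            ids.append(next_id)
            class_map[next_id] = cls
            next_id += 1
            placed += 1
    if placed < count:
        raise RuntimeError(f"could not place {count} {cls} distractors without overlap")
    return next_id, ids


def _region_clear(labels, center_um, half_um, voxel_um, margin_vox=2):
    shape = labels.shape
    lo, hi = [], []
    for i in range(3):
        c = center_um[i] / voxel_um[i]
        r = half_um[i] / voxel_um[i] + margin_vox
        lo.append(max(int(np.floor(c - r)), 0))
        hi.append(min(int(np.ceil(c + r)) + 1, shape[i]))
    box = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    return not box.any()


def _region_clear_polyline(labels, pts, radius_um, voxel_um, margin_vox=2):
    shape = labels.shape
    lo, hi = [], []
    for i in range(3):
        c_lo = pts[:, i].min() / voxel_um[i]
        c_hi = pts[:, i].max() / voxel_um[i]
        r = radius_um / voxel_um[i] + margin_vox
        lo.append(max(int(np.floor(c_lo - r)), 0))
        hi.append(min(int(np.ceil(c_hi + r)) + 1, shape[i]))
    box = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    return not box.any()


# ---------------------------------------------------------------------------
# main generator


def generate_phantom(config: PhantomConfig) -> tuple[VoxelVolume, GroundTruth]:
    """Render a phantom stack and its ground truth from one config.

    Deterministic: the same config (including seed) yields byte-identical
    volume and truth.  Raises if a soma is placed outside the GCL or two
    requested somas overlap.
    """
    rng = np.random.default_rng(config.seed)
    layers = config.layers
    voxel_um = config.voxel_um_zyx
    shape = config.shape_zyx
    model = config.intensity

    # validate soma placement before rendering anything
    for spec in config.neurons:
        z_idx = int(spec.soma_center_um[0] / voxel_um[0])
        if not (0 <= z_idx < shape[0]) or layers.layer_of(z_idx) != GCL:
            raise ValueError(
                f"soma at z={spec.soma_center_um[0]:.2f} um lies outside the GCL"
            )
    for i, a in enumerate(config.neurons):
        for b in config.neurons[i + 1 :]:
            d = np.linalg.norm(
                np.asarray(a.soma_center_um) - np.asarray(b.soma_center_um)
            )
            if d < a.soma_radius_um + b.soma_radius_um:
                raise ValueError("requested somas overlap")

    if model.background_sd > 0:
        intensities = rng.normal(model.background_mean, model.background_sd, size=shape)
    else:
        intensities = np.full(shape, model.background_mean, dtype=float)
    labels = np.zeros(shape, dtype=np.uint16)

    class_map: dict[int, str] = {}
    parent_map: dict[int, int] = {}
    next_id = 1

    for neuron_idx, spec in enumerate(config.neurons, start=1):
        value = model.label_mean(spec.labeling)
        soma_id = next_id
        next_id += 1
        _stamp_shell(
            labels,
            intensities,
            spec.soma_center_um,
            spec.soma_radius_um,
            0.3,
            voxel_um,
            soma_id,
            value,
        )
        class_map[soma_id] = "soma"
        parent_map[soma_id] = neuron_idx

        dend_id = next_id
        next_id += 1
        segments, swellings = _grow_arbor(rng, spec, config)
        for pts, radius in segments:
            _stamp_polyline(labels, intensities, pts, radius, voxel_um, dend_id, value)
        for center, radius in swellings:
            _stamp_ball(labels, intensities, center, radius, voxel_um, dend_id, value)
        class_map[dend_id] = f"dendrite_{spec.labeling}"
        parent_map[dend_id] = neuron_idx

    for cls in DISTRACTOR_CLASSES:
        count = int(config.distractors.get(cls, 0))
        if count:
            next_id, _ = _place_distractors(
                rng, cls, count, labels, intensities, config, next_id, class_map
            )

    if model.background_sd > 0:
        # acquisition noise rides on the structures too
        structural = labels > 0
        intensities[structural] += rng.normal(
            0.0, model.background_sd, size=int(structural.sum())
        )
    data = np.clip(np.rint(intensities), 0, 255).astype(np.uint8)

    volume = VoxelVolume(data=data, voxel_size_nm=config.voxel_size_nm, layers=layers)
    truth = GroundTruth(labels=labels, class_map=class_map, parent_map=parent_map)
    return volume, truth


def write_phantom(out_dir: str | Path, volume: VoxelVolume, truth: GroundTruth, config: PhantomConfig) -> dict:
    """Write volume, truth and config to a directory; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": out_dir / "phantom.tif",
        "truth": out_dir / "truth_labels.tif",
        "config": out_dir / "phantom_config.json",
    }
    volume.save(paths["volume"])
    truth.save(paths["truth"])
    paths["config"].write_text(json.dumps(config.to_dict(), indent=2))
    return {k: str(v) for k, v in paths.items()}
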