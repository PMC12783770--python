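"""3D morphometrics of reconstructed retinal neurons.

Covers the quantities used to characterize ganglion cells in a volume EM
reconstruction: dendrite density profiles across the normalized depth of
the inner plexiform layer (IPL), top-view Sholl analysis, projected
retinal-surface coverage (whole-region and random grid-box sampling),
soma composition and size, and the depth distribution of synapses along
the dendrites.

Conventions: voxel coordinates are (z, row, col) with z the sectioning
axis; physical quantities use the (dx, dy, dz) voxel size in nm.
Normalized IPL depth runs from 0 at the INL border to 1 at the GCL
border, so the OFF sublamina occupies depth < ``off_on_boundary``
(default 0.4, a conventional 2:3 outer/inner split) and the ON
sublamina the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from skimage.measure import label as sk_label

from .phantom import GroundTruth
from .volume import LayerAnnotation

OFF_ON_BOUNDARY = 0.4
DOMINANCE = 0.8  # fraction of dendrite voxels a sublamina needs for a pure ON/OFF call


@dataclass
class NeuronReconstruction:
    """Soma + dendrites (+ optional organelles) of one cell.

    Voxel sets are (N, 3) integer arrays of (z, row, col).  Organelle
    instances (``nucleus`` as one voxel set, ``mitochondria`` as a list
    of instances) must lie within the soma for composition metrics.
    """

    neuron_id: int
    soma_voxels: np.ndarray
    dendrite_voxels: np.ndarray
    soma_center_um: tuple[float, float, float] | None = None
    initial_dendrites: int | None = None
    nucleus_voxels: np.ndarray | None = None
    mitochondria: list[np.ndarray] = field(default_factory=list)
    stratification: str | None = None

    @classmethod
    def from_truth(
        cls,
        truth: GroundTruth,
        neuron_id: int,
        voxel_size_nm: tuple[float, float, float],
    ) -> "NeuronReconstruction":
        """Assemble a reconstruction from phantom ground truth."""
        soma_ids = [
            i
            for i, c in truth.class_map.items()
            if c == "soma" and truth.parent_map.get(i) == neuron_id
        ]
        dend_ids = [
            i
            for i, c in truth.class_map.items()
            if c.startswith("dendrite") and truth.parent_map.get(i) == neuron_id
        ]
        soma = (
            np.concatenate([truth.voxel_coords(i) for i in soma_ids])
            if soma_ids
            else np.empty((0, 3), dtype=int)
        )
        dend = (
            np.concatenate([truth.voxel_coords(i) for i in dend_ids])
            if dend_ids
            else np.empty((0, 3), dtype=int)
        )
        center = None
        if soma.size:
            dx, dy, dz = voxel_size_nm
            c = soma.mean(axis=0)
            center = (c[0] * dz / 1000.0, c[1] * dy / 1000.0, c[2] * dx / 1000.0)
        return cls(
            neuron_id=neuron_id,
            soma_voxels=soma,
            dendrite_voxels=dend,
            soma_center_um=center,
        )


@dataclass
class DepthProfile:
    """Histogram over normalized IPL depth.

    ``density`` is the voxel (or synapse) fraction per bin; it sums to 1
    whenever any voxels fall inside the IPL.  ``off_fraction`` and
    ``on_fraction`` summarize the two sublaminae.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    n_voxels: int
    n_excluded: int
    off_fraction: float
    on_fraction: float
    counts: np.ndarray | None = None

    def classify(self, dominance: float = DOMINANCE) -> str:
        """ON / OFF / ON_OFF call from sublamina dominance."""
        if self.off_fraction > dominance:
            return "OFF"
        if self.on_fraction > dominance:
            return "ON"
        return "ON_OFF"


@dataclass
class ShollProfile:
    """Intersection counts on concentric top-view rings around the soma."""

    radii_um: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.radii_um = np.asarray(self.radii_um, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.radii_um) <= 0):
            raise ValueError("ring radii must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class CoverageReport:
    """Projected coverage in randomly sampled grid boxes."""

    box_indices: list[tuple[int, int]]
    fractions: np.ndarray
    seed: int

    @property
    def mean(self) -> float:
        return float(self.fractions.mean())

    @property
    def min(self) -> float:
        return float(self.fractions.min())

    @property
    def max(self) -> float:
        return float(self.fractions.max())


def depth_profile(
    dendrite_voxels: np.ndarray,
    layers: LayerAnnotation,
    n_bins: int = 10,
    off_on_boundary: float = OFF_ON_BOUNDARY,
) -> DepthProfile:
    """Normalized histogram of dendrite voxel depths within the IPL.

    Voxels outside the IPL are excluded (their count is reported).
    Raises if no voxel lies inside the IPL.
    """
    dendrite_voxels = np.asarray(dendrite_voxels)
    if dendrite_voxels.size == 0:
        raise ValueError("no dendrite voxels inside the IPL")
    z = dendrite_voxels[:, 0]
    in_ipl = (z >= layers.gcl_ipl) & (z < layers.ipl_inl)
    n_excluded = int((~in_ipl).sum())
    z_ipl = z[in_ipl]
    if z_ipl.size == 0:
        raise ValueError("no dendrite voxels inside the IPL")
    depths = layers.ipl_depth(z_ipl)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(depths, bins=edges)
    density = counts / counts.sum()
    off = float((depths < off_on_boundary).mean())
    return DepthProfile(
        bin_edges=edges,
        density=density,
        n_voxels=int(z_ipl.size),
        n_excluded=n_excluded,
        off_fraction=off,
        on_fraction=1.0 - off,
        counts=counts,
    )


def sholl_topview(
    dendrite_voxels: np.ndarray,
    soma_center_um: tuple[float, float, float],
    voxel_size_nm: tuple[float, float, float],
    ring_spacing_um: float = 5.0,
    max_radius_um: float | None = None,
) -> ShollProfile:
    """Sholl analysis on the top-view (x-y) projection of the arbor.

    The dendrite voxels are projected along z onto the imaging plane.
    For each ring of radius r around the soma centroid, the intersection
    count is the number of connected runs of projected-mask pixels lying
    on the ring (a thin annulus one pixel wide): each crossing of the
    circle by a branch contributes one run, and a branch that re-enters
    at the same place still counts once.  An empty arbor yields all-zero
    counts.
    """
    dx, dy, _ = voxel_size_nm
    px_um = (dx / 1000.0, dy / 1000.0)
    dendrite_voxels = np.asarray(dendrite_voxels)
    cy, cx = soma_center_um[1], soma_center_um[2]

    if max_radius_um is None:
        if dendrite_voxels.size:
            yy = dendrite_voxels[:, 1] * px_um[1]
            xx = dendrite_voxels[:, 2] * px_um[0]
            max_radius_um = float(np.hypot(yy - cy, xx - cx).max()) + ring_spacing_um
        else:
            max_radius_um = ring_spacing_um * 2
    radii = np.arange(ring_spacing_um, max_radius_um + 1e-9, ring_spacing_um)
    if dendrite_voxels.size == 0:
        return ShollProfile(radii_um=radii, counts=np.zeros(radii.size, dtype=int))

    rows = dendrite_voxels[:, 1]
    cols = dendrite_voxels[:, 2]
    mask = np.zeros((int(rows.max()) + 1, int(cols.max()) + 1), dtype=bool)
    mask[rows, cols] = True
    rr, cc = np.nonzero(mask)
    # physical distance of each projected pixel centre from the soma
    dist = np.hypot((rr + 0.5) * px_um[1] - cy, (cc + 0.5) * px_um[0] - cx)

    # annulus half-width: wide enough that a 8-connected digital curve
    # cannot step across the ring without touching it
    tol = 0.75 * max(px_um)
    counts = np.zeros(radii.size, dtype=int)
    for i, r in enumerate(radii):
        on_ring = np.abs(dist - r) <= tol
        if not on_ring.any():
            continue
        ring_img = np.zeros_like(mask)
        ring_img[rr[on_ring], cc[on_ring]] = True
        counts[i] = int(sk_label(ring_img, connectivity=2).max())
    return ShollProfile(radii_um=radii, counts=counts)


def coverage_fraction(
    dendrite_voxels: np.ndarray,
    region_yx: tuple[int, int, int, int],
) -> float:
    """Fraction of a rectangular x-y region covered by projected dendrites.

    ``region_yx = (row0, row1, col0, col1)`` half-open pixel bounds.  The
    binary projection over all z is used as-is (no dilation).
    """
    r0, r1, c0, c1 = region_yx
    if r1 <= r0 or c1 <= c0:
        raise ValueError("empty region")
    dendrite_voxels = np.asarray(dendrite_voxels)
    if dendrite_voxels.size == 0:
        return 0.0
    rows = dendrite_voxels[:, 1]
    cols = dendrite_voxels[:, 2]
    inside = (rows >= r0) & (rows < r1) & (cols >= c0) & (cols < c1)
    if not inside.any():
        return 0.0
    covered = np.unique(
        (rows[inside] - r0).astype(np.int64) * (c1 - c0) + (cols[inside] - c0)
    ).size
    return covered / ((r1 - r0) * (c1 - c0))


def grid_boxes(image_shape_yx: tuple[int, int], grid_shape: tuple[int, int]):
    """Half-open (row0, row1, col0, col1) bounds of an equal grid partition."""
    gy, gx = grid_shape
    r_edges = np.linspace(0, image_shape_yx[0], gy + 1).astype(int)
    c_edges = np.linspace(0, image_shape_yx[1], gx + 1).astype(int)
    boxes = {}
    for i in range(gy):
        for j in range(gx):
            boxes[(i, j)] = (r_edges[i], r_edges[i + 1], c_edges[j], c_edges[j + 1])
    return boxes


def grid_box_coverage(
    dendrite_voxels: np.ndarray,
    soma_voxels: np.ndarray,
    image_shape_yx: tuple[int, int],
    grid_shape: tuple[int, int] = (5, 5),
    n_boxes: int = 5,
    seed: int = 0,
) -> CoverageReport:
    """Random grid-box estimate of dendritic coverage.

    The x-y extent is divided into an equal ``grid_shape`` grid; boxes
    containing any soma voxel (projected) are excluded; ``n_boxes`` of
    the eligible boxes are sampled without replacement with the given
    seed and the projected dendrite coverage is measured in each.
    """
    boxes = grid_boxes(image_shape_yx, grid_shape)
    soma_voxels = np.asarray(soma_voxels)
    eligible = []
    for idx, (r0, r1, c0, c1) in sorted(boxes.items()):
        if soma_voxels.size:
            rows, cols = soma_voxels[:, 1], soma_voxels[:, 2]
            if np.any((rows >= r0) & (rows < r1) & (cols >= c0) & (cols < c1)):
                continue
        eligible.append(idx)
    if len(eligible) < n_boxes:
        raise ValueError(
            f"only {len(eligible)} eligible boxes for n_boxes={n_boxes}"
        )
    rng = np.random.default_rng(seed)
    chosen_pos = rng.choice(len(eligible), size=n_boxes, replace=False)
    chosen = [eligible[i] for i in sorted(chosen_pos.tolist())]
    fractions = np.array(
        [coverage_fraction(dendrite_voxels, boxes[idx]) for idx in chosen]
    )
    return CoverageReport(box_indices=chosen, fractions=fractions, seed=seed)


def soma_composition(
    recon: NeuronReconstruction,
    voxel_size_nm: tuple[float, float, float],
) -> dict:
    """Organelle content of the (visible) soma.

    Returns nucleus and mitochondria volume as percentages of the soma
    voxel volume, and the mitochondria instance count per um^3 of soma.
    Organelle voxel sets must be subsets of the soma voxel set.
    """
    soma = np.asarray(recon.soma_voxels)
    if soma.size == 0:
        raise ValueError("empty soma voxel set")
    soma_set = set(map(tuple, soma.tolist()))

    def _checked_count(vox: np.ndarray, name: str) -> int:
        if vox is None or np.asarray(vox).size == 0:
            return 0
        vox = np.asarray(vox)
        outside = [t for t in map(tuple, vox.tolist()) if t not in soma_set]
        if outside:
            raise ValueError(f"{name} voxels outside the soma: {len(outside)}")
        return vox.shape[0]

    n_soma = soma.shape[0]
    n_nuc = _checked_count(recon.nucleus_voxels, "nucleus")
    n_mito = sum(_checked_count(m, "mitochondrion") for m in recon.mitochondria)
    dx, dy, dz = voxel_size_nm
    voxel_um3 = (dx / 1000.0) * (dy / 1000.0) * (dz / 1000.0)
    soma_um3 = n_soma * voxel_um3
    return {
        "nucleus_pct": 100.0 * n_nuc / n_soma,
        "mitochondria_pct": 100.0 * n_mito / n_soma,
        "mitochondria_per_um3": len(recon.mitochondria) / soma_um3,
        "soma_volume_um3": soma_um3,
    }


def soma_diameter(
    soma_voxels: np.ndarray,
    voxel_size_nm: tuple[float, float, float],
) -> float:
    """Equivalent-circle diameter (um) of the largest z cross-section.

    d = 2 sqrt(A / pi) with A the physical area of the soma's largest
    single-section footprint.
    """
    soma_voxels = np.asarray(soma_voxels)
    if soma_voxels.size == 0:
        raise ValueError("empty soma voxel set")
    _, counts = np.unique(soma_voxels[:, 0], return_counts=True)
    dx, dy, _ = voxel_size_nm
    area_um2 = counts.max() * (dx / 1000.0) * (dy / 1000.0)
    return float(2.0 * np.sqrt(area_um2 / np.pi))


def synapse_depth_distribution(
    synapses: np.ndarray,
    dendrite_voxels: np.ndarray,
    layers: LayerAnnotation,
    n_bins: int = 10,
) -> dict:
    """Depth distribution of synapses vs. the dendrite density profile.

    Each synapse (z, row, col) must lie on a dendrite voxel within a
    1-voxel (Chebyshev) tolerance; offenders are reported in the raised
    error.  Returns per-bin synapse counts over normalized IPL depth,
    the dendrite :class:`DepthProfile` of the same region, and the
    Spearman rank correlation between the two binned profiles.
    """
    synapses = np.asarray(synapses)
    dendrite_voxels = np.asarray(dendrite_voxels)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if synapses.size == 0:
        dend = depth_profile(dendrite_voxels, layers, n_bins=n_bins)
        return {
            "bin_edges": edges,
            "synapse_counts": np.zeros(n_bins, dtype=int),
            "dendrite_profile": dend,
            "rank_correlation": np.nan,
        }
    dend_set = set(map(tuple, dendrite_voxels.tolist()))
    offenders = []
    for s in map(tuple, synapses.tolist()):
        near = any(
            (s[0] + a, s[1] + b, s[2] + c) in dend_set
            for a in (-1, 0, 1)
            for b in (-1, 0, 1)
            for c in (-1, 0, 1)
        )
        if not near:
            offenders.append(s)
    if offenders:
        raise ValueError(f"synapses off any dendrite voxel: {offenders}")
    depths = layers.ipl_depth(synapses[:, 0])
    syn_counts, _ = np.histogram(depths, bins=edges)
    dend = depth_profile(dendrite_voxels, layers, n_bins=n_bins)
    if np.ptp(syn_counts) == 0 or np.ptp(dend.density) == 0:
        rho = np.nan
    else:
        rho = float(spearmanr(syn_counts, dend.density).statistic)
    return {
        "bin_edges": edges,
        "synapse_counts": syn_counts,
        "dendrite_profile": dend,
        "rank_correlation": rho,
    }
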