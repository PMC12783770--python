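"""Semi-automatic segmentation of dark-labeled neurites in serial EM.

The chain mirrors the threshold-contour-link-filter workflow used for
peroxidase-labeled volumes:

1. per-section thresholding — every 4-connected component of pixels
   strictly *under* a fixed intensity threshold, with at least a minimum
   area, becomes a :class:`Contour`;
2. cross-section linking — contours on *consecutive* sections that
   overlap in (row, col) by at least ``min_overlap`` pixels belong to
   the same 3D object; objects are the transitive closure of that
   relation;
3. z-extent filtering — objects occupying fewer than ``min_sections``
   distinct sections are dropped, eliminating small electron-dense
   organelles (lysosomes, mitochondria, nucleoli) while keeping
   dendrites that run through many sections;
4. optional manual-style merging of objects belonging to one cell, and
   scoring against ground truth to obtain per-layer false-positive
   rates.

With ``min_contour_area=1`` and ``min_overlap=1`` the linking relation
is exactly face-adjacency (6-connected) 3D connected-component
labeling, which provides an independent oracle for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.measure import label as sk_label

from .phantom import NEURON_CLASSES, GroundTruth
from .volume import LayerAnnotation, VoxelVolume


@dataclass(frozen=True)
class SegParams:
    """Parameters of the segmentation chain.

    intensity_threshold : pixels strictly below this 8-bit value are
        candidate label deposit.  The working default sits between the
        strong-label mean and the weak-label/background means of the
        phantom intensity model; on real data use
        :func:`calibrate_threshold` with seed pixels on labeled
        dendrites.
    min_contour_area : smallest per-section component kept, in pixels.
    min_overlap : pixel overlap required to link contours on
        consecutive sections.
    min_sections : smallest z-extent (distinct sections) an object must
        span to survive filtering.
    """

    intensity_threshold: int = 80
    min_contour_area: int = 50
    min_overlap: int = 1
    min_sections: int = 15

    def __post_init__(self) -> None:
        if not 0 <= self.intensity_threshold <= 255:
            raise ValueError("intensity_threshold must be within [0, 255]")
        if self.min_contour_area < 1 or self.min_overlap < 1 or self.min_sections < 1:
            raise ValueError("area, overlap and section minima must be >= 1")


@dataclass
class Contour:
    """One 4-connected sub-threshold component on one section."""

    section: int
    pixels: np.ndarray  # (N, 2) array of (row, col)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValueError("pixels must be an (N, 2) array of (row, col)")

    @property
    def area_px(self) -> int:
        return int(self.pixels.shape[0])

    def area_um2(self, voxel_size_nm: tuple[float, float, float]) -> float:
        dx, dy, _ = voxel_size_nm
        return self.area_px * (dx / 1000.0) * (dy / 1000.0)


@dataclass
class SegmentedObject:
    """A linked set of contours forming one 3D object."""

    object_id: int
    contours: dict[int, list[Contour]] = field(default_factory=dict)
    label: str = "unknown"  # dendrite | soma | false_positive | unknown
    merged_from: tuple[int, ...] = ()

    @property
    def sections(self) -> list[int]:
        return sorted(self.contours)

    @property
    def z_extent(self) -> int:
        """Distinct sections occupied (an object-size criterion, robust
        to how far apart those sections are)."""
        return len(self.contours)

    @property
    def n_voxels(self) -> int:
        return sum(c.area_px for cs in self.contours.values() for c in cs)

    def voxel_coords(self) -> np.ndarray:
        """(N, 3) array of (z, row, col) voxels of the whole object."""
        parts = [
            np.column_stack([np.full(c.area_px, z), c.pixels])
            for z in self.sections
            for c in self.contours[z]
        ]
        if not parts:
            return np.empty((0, 3), dtype=int)
        return np.concatenate(parts)


@dataclass
class FPRReport:
    """Per-layer object-level evaluation against ground truth.

    For each layer: number of predicted objects assigned to it, how many
    matched labeled structures (true positives), how many did not (false
    positives), and FPR = FP / (FP + TP).  Layers with no predictions
    carry ``fpr=None`` and are flagged empty.
    """

    per_layer: dict[str, dict]

    def fpr(self, layer: str) -> float | None:
        return self.per_layer[layer]["fpr"]


def calibrate_threshold(volume: VoxelVolume, seed_pixels) -> int:
    """Estimate the intensity threshold from seed pixels on labeled dendrites.

    The threshold is the mean gray value of the supplied (z, row, col)
    seed pixels — the fixed-threshold rule for dark-label detection.
    """
    seed_pixels = np.asarray(seed_pixels, dtype=int)
    if seed_pixels.size == 0:
        raise ValueError("need at least one seed pixel")
    vals = volume.data[seed_pixels[:, 0], seed_pixels[:, 1], seed_pixels[:, 2]]
    return int(round(float(vals.mean())))


def threshold_section(section_image: np.ndarray, params: SegParams) -> list[Contour]:
    """Extract sub-threshold contours from one section.

    Returns one :class:`Contour` per 4-connected component of
    ``{pixels < intensity_threshold}`` with area >= ``min_contour_area``.
    The section index is set to 0; callers processing a stack reassign it.
    """
    section_image = np.asarray(section_image)
    if section_image.size == 0:
        raise ValueError("empty section image")
    if section_image.ndim != 2:
        raise ValueError("section image must be 2D")
    mask = section_image < params.intensity_threshold
    if not mask.any():
        return []
    lab = sk_label(mask, connectivity=1)
    flat = lab.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    first_fg = int(np.searchsorted(sorted_labels, 1))
    order = order[first_fg:]
    sorted_labels = sorted_labels[first_fg:]
    rows, cols = np.unravel_index(order, lab.shape)
    # split the sorted pixel list at label changes -> one slice per component
    boundaries = np.nonzero(np.diff(sorted_labels))[0] + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [sorted_labels.size]])
    contours = []
    for s, e in zip(starts, stops):
        if e - s >= params.min_contour_area:
            contours.append(Contour(section=0, pixels=np.column_stack([rows[s:e], cols[s:e]])))
    return contours


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def link_contours(
    contours_by_section: dict[int, list[Contour]],
    params: SegParams,
) -> list[SegmentedObject]:
    """Group contours into 3D objects by consecutive-section overlap.

    Two contours on sections z and z+1 are linked iff their pixel sets
    share at least ``min_overlap`` (row, col) positions; objects are the
    connected components of that relation.  Raises if two contours on
    one section claim the same pixel.
    """
    sections = sorted(contours_by_section)
    # global contour index
    flat: list[tuple[int, Contour]] = []
    index_of: dict[int, list[int]] = {}
    for z in sections:
        index_of[z] = []
        for c in contours_by_section[z]:
            index_of[z].append(len(flat))
            flat.append((z, c))
    if not flat:
        return []

    # paint per-section images with the global index + 1 (0 = empty)
    max_r = max(int(c.pixels[:, 0].max()) for _, c in flat) + 1
    max_c = max(int(c.pixels[:, 1].max()) for _, c in flat) + 1

    def paint(z: int) -> np.ndarray:
        img = np.zeros((max_r, max_c), dtype=np.int64)
        for gi in index_of[z]:
            _, c = flat[gi]
            claimed = img[c.pixels[:, 0], c.pixels[:, 1]]
            if np.any(claimed):
                raise ValueError(f"duplicate pixel claim on section {z}")
            img[c.pixels[:, 0], c.pixels[:, 1]] = gi + 1
        return img

    uf = _UnionFind(len(flat))
    prev_z: int | None = None
    prev_img: np.ndarray | None = None
    for z in sections:
        img = paint(z)
        if prev_z is not None and z == prev_z + 1:
            both = (prev_img > 0) & (img > 0)
            if both.any():
                pairs = np.stack([prev_img[both], img[both]])
                uniq, counts = np.unique(pairs, axis=1, return_counts=True)
                for (a, b), n in zip(uniq.T, counts):
                    if n >= params.min_overlap:
                        uf.union(int(a) - 1, int(b) - 1)
        prev_z, prev_img = z, img

    groups: dict[int, list[int]] = {}
    for gi in range(len(flat)):
        groups.setdefault(uf.find(gi), []).append(gi)

    objects = []
    for oid, (_, members) in enumerate(sorted(groups.items()), start=1):
        contours: dict[int, list[Contour]] = {}
        for gi in members:
            z, c = flat[gi]
            contours.setdefault(z, []).append(replace(c, section=z))
        objects.append(SegmentedObject(object_id=oid, contours=contours))
    return objects


def filter_by_extent(objects: list[SegmentedObject], params: SegParams) -> list[SegmentedObject]:
    """Keep objects spanning at least ``min_sections`` distinct sections."""
    return [o for o in objects if o.z_extent >= params.min_sections]


def merge_objects(objects: list[SegmentedObject], id_list) -> SegmentedObject:
    """Merge objects (proofreading step: parts of one cell become one object).

    The merged object carries the union of contours, a recomputed
    z-extent and the provenance of the merged ids.
    """
    by_id = {o.object_id: o for o in objects}
    ids = list(id_list)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in merge list")
    unknown = [i for i in ids if i not in by_id]
    if unknown:
        raise KeyError(f"unknown object ids: {unknown}")
    merged: dict[int, list[Contour]] = {}
    for i in ids:
        for z, cs in by_id[i].contours.items():
            merged.setdefault(z, []).extend(cs)
    return SegmentedObject(
        object_id=min(ids),
        contours=merged,
        label=by_id[ids[0]].label,
        merged_from=tuple(ids),
    )


def assign_layer(obj: SegmentedObject, layers: LayerAnnotation) -> str:
    """Layer of the object's z-median occupied section.

    For an even number of occupied sections the lower-z of the two
    middle sections decides (documented tie-break).
    """
    sections = obj.sections
    if not sections:
        raise ValueError("cannot assign a layer to an empty object")
    median_section = sections[(len(sections) - 1) // 2]
    return layers.layer_of(median_section)


def evaluate_fpr(
    objects: list[SegmentedObject],
    truth: GroundTruth,
    layers: LayerAnnotation,
    match_fraction: float = 0.5,
) -> FPRReport:
    """Score predicted objects against ground truth, per layer.

    An object is a true positive iff at least ``match_fraction`` of its
    voxels fall on truth voxels of a neuron class (dendrite or soma);
    everything else (distractor-derived or background) is a false
    positive.  FPR = FP / (FP + TP) within each assigned layer.
    """
    if not 0 < match_fraction <= 1:
        raise ValueError("match_fraction must be in (0, 1]")
    neuron_ids = set(truth.ids_of_class(*NEURON_CLASSES))
    lut = np.zeros(int(truth.labels.max()) + 1, dtype=bool)
    for i in neuron_ids:
        lut[i] = True
    shape = truth.labels.shape
    counts = {
        layer: {"n_objects": 0, "tp": 0, "fp": 0}
        for layer in ("GCL", "IPL", "INL")
    }
    for obj in objects:
        vox = obj.voxel_coords()
        if np.any(vox < 0) or np.any(vox >= np.asarray(shape)):
            raise ValueError(
                f"object {obj.object_id} has voxels outside the truth geometry"
            )
        on_neuron = lut[truth.labels[vox[:, 0], vox[:, 1], vox[:, 2]]]
        layer = assign_layer(obj, layers)
        c = counts[layer]
        c["n_objects"] += 1
        if on_neuron.mean() >= match_fraction:
            c["tp"] += 1
        else:
            c["fp"] += 1
    per_layer = {}
    for layer, c in counts.items():
        denom = c["tp"] + c["fp"]
        per_layer[layer] = {
            **c,
            "fpr": (c["fp"] / denom) if denom else None,
            "empty": denom == 0,
        }
    return FPRReport(per_layer=per_layer)


def segment_volume(
    volume: VoxelVolume,
    params: SegParams,
) -> tuple[list[SegmentedObject], dict]:
    """Run the full chain: threshold -> link -> z-extent filter.

    Returns the surviving objects and a run log with the contour count,
    the pre-filter object count and the post-filter object count — the
    same bookkeeping the workflow reports on real volumes.
    """
    contours_by_section: dict[int, list[Contour]] = {}
    n_contours = 0
    for z in range(volume.n_sections):
        contours = threshold_section(volume.data[z], params)
        if contours:
            contours_by_section[z] = [replace(c, section=z) for c in contours]
            n_contours += len(contours)
    linked = link_contours(contours_by_section, params)
    kept = filter_by_extent(linked, params)
    log = {
        "n_contours": n_contours,
        "n_objects_prefilter": len(linked),
        "n_objects_postfilter": len(kept),
        "params": {
            "intensity_threshold": params.intensity_threshold,
            "min_contour_area": params.min_contour_area,
            "min_overlap": params.min_overlap,
            "min_sections": params.min_sections,
        },
    }
    return kept, log


def objects_to_label_volume(objects: list[SegmentedObject], shape) -> np.ndarray:
    """Rasterize objects into a label volume (object_id per voxel)."""
    out = np.zeros(shape, dtype=np.int32)
    for obj in objects:
        vox = obj.voxel_coords()
        out[vox[:, 0], vox[:, 1], vox[:, 2]] = obj.object_id
    return out
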