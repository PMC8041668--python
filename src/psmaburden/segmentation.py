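"""Two-step semi-automated PSMA-PET lesion delineation.

Step 1 (selection): a liver-specific threshold
``(c / liver SUVmean) * (liver SUVmean + liver SUVsd)`` with ``c = 4.3`` by
default selects candidate hot spots; a candidate is kept when the SUVpeak at
its hottest voxel (1 ml sphere-averaged SUV, EANM-style) exceeds the
threshold.  Step 2 (segmentation): each kept candidate is delineated at a
lesion-specific isocontour of 50 % of its local SUVmax.  Lesions below
0.5 ml are discarded; lesions with uptake below the liver threshold can be
added manually as full masks.  All fractions, constants and the connectivity
are configurable via :class:`SegmentationConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from psmaburden.volume import RegionMask, SUVVolume

__all__ = [
    "SegmentationConfig",
    "SegmentationError",
    "ReferenceRegionError",
    "LiverReference",
    "SeedRegion",
    "Lesion",
    "compute_liver_threshold",
    "compute_suv_peak",
    "detect_candidate_lesions",
    "segment_lesion",
    "merge_overlapping_lesions",
    "filter_small_lesions",
    "add_manual_lesion",
    "segment_patient",
]


class SegmentationError(ValueError):
    """Degenerate seed or mask passed to a segmentation operation."""


class ReferenceRegionError(ValueError):
    """Liver reference ROI empty or degenerate."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the delineation procedure.

    threshold_constant
        The ``4.3`` in the liver-specific threshold formula (reconstruction
        dependent; exposed rather than hard-coded).
    halfmax_fraction
        Fraction of the local SUVmax defining the lesion isocontour (0.5).
    min_volume_ml
        Lesions strictly smaller than this are discarded (0.5 ml; a lesion
        of exactly 0.5 ml is kept).
    connectivity
        26 (vertex) or 6 (face) 3D connectivity for components and region
        growth.
    peak_sphere_volume_ml
        Volume of the SUVpeak averaging sphere (1.0 ml).
    """

    threshold_constant: float = 4.3
    halfmax_fraction: float = 0.5
    min_volume_ml: float = 0.5
    connectivity: int = 26
    peak_sphere_volume_ml: float = 1.0

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if not 0 < self.halfmax_fraction < 1:
            raise ValueError("halfmax_fraction must lie in (0, 1)")

    @property
    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


DEFAULT_CONFIG = SegmentationConfig()


@dataclass(frozen=True)
class LiverReference:
    """Liver reference statistics and the derived selection threshold.

    The threshold satisfies ``threshold * suv_mean = c * (suv_mean + suv_sd)``
    exactly; ``suv_sd`` is the population (n-divisor) standard deviation of
    the liver ROI voxels.
    """

    suv_mean: float
    suv_sd: float
    threshold: float
    constant: float = 4.3

    @classmethod
    def from_stats(cls, suv_mean: float, suv_sd: float, constant: float = 4.3) -> "LiverReference":
        if suv_mean <= 0:
            raise ReferenceRegionError(f"liver SUVmean must be positive, got {suv_mean}")
        if suv_sd < 0:
            raise ReferenceRegionError(f"liver SUVsd must be non-negative, got {suv_sd}")
        threshold = (constant / suv_mean) * (suv_mean + suv_sd)
        return cls(suv_mean=float(suv_mean), suv_sd=float(suv_sd), threshold=float(threshold), constant=float(constant))


def compute_liver_threshold(liver_roi_values, constant: float = 4.3) -> LiverReference:
    """Liver-specific selection threshold from liver ROI voxel samples.

    ``threshold = (c / SUVmean) * (SUVmean + SUVsd)`` with the population
    standard deviation.  Requires at least 2 samples with positive mean.
    """
    values = np.asarray(liver_roi_values, dtype=np.float64).ravel()
    if values.size < 2:
        raise ReferenceRegionError(f"liver ROI needs >= 2 samples, got {values.size}")
    mean = float(values.mean())
    if mean <= 0:
        raise ReferenceRegionError(f"liver SUVmean must be positive, got {mean}")
    sd = float(values.std(ddof=0))
    return LiverReference.from_stats(mean, sd, constant=constant)


def _sphere_offsets(spacing: tuple[float, float, float], volume_ml: float) -> np.ndarray:
    """Index offsets of voxels whose centers lie inside a sphere of the given volume."""
    radius_mm = (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    half = [int(math.floor(radius_mm / s)) for s in spacing]
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    inside = gx**2 + gy**2 + gz**2 <= radius_mm**2
    ix, iy, iz = np.nonzero(inside)
    offsets = np.stack([ix - half[0], iy - half[1], iz - half[2]], axis=1)
    return offsets


def compute_suv_peak(
    volume: SUVVolume,
    center: tuple[int, int, int],
    sphere_volume_ml: float = 1.0,
) -> float:
    """Sphere-averaged SUV around a voxel (SUVpeak).

    Mean SUV over all voxels whose physical centers lie within a sphere of
    ``sphere_volume_ml`` centered on the center voxel's physical center.
    At grid borders the sphere is clipped and the mean renormalized over the
    in-grid voxels.
    """
    center = tuple(int(c) for c in center)
    shape = volume.shape
    if any(c < 0 or c >= s for c, s in zip(center, shape)):
        raise SegmentationError(f"SUVpeak center {center} outside grid {shape}")
    coords = _sphere_offsets(volume.spacing, sphere_volume_ml) + np.asarray(center)
    valid = np.all((coords >= 0) & (coords < np.asarray(shape)), axis=1)
    coords = coords[valid]
    return float(volume.values[coords[:, 0], coords[:, 1], coords[:, 2]].mean())


def _hottest_voxel(
    idx: tuple[np.ndarray, np.ndarray, np.ndarray],
    suv: np.ndarray,
    spacing: tuple[float, float, float],
) -> tuple[int, tuple[int, int, int]]:
    """Index of the maximum-SUV voxel; ties broken toward the region centroid.

    Uniform (plateau) lesions have many voxels tied at SUVmax; picking the
    first in scan order would center the SUVpeak sphere on the lesion
    boundary.  The most central tied voxel is the deterministic choice that
    matches the peaked profiles of real tracer uptake.
    """
    tied = np.flatnonzero(suv == suv.max())
    if len(tied) > 1:
        coords = np.stack([idx[0], idx[1], idx[2]], axis=1).astype(float) * np.asarray(spacing)
        centroid = coords.mean(axis=0)
        d2 = np.sum((coords[tied] - centroid) ** 2, axis=1)
        i_max = int(tied[int(np.argmin(d2))])
    else:
        i_max = int(tied[0])
    return i_max, (int(idx[0][i_max]), int(idx[1][i_max]), int(idx[2][i_max]))


@dataclass(frozen=True)
class SeedRegion:
    """One candidate hot spot: its supra-threshold voxels and hottest voxel."""

    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]
    max_voxel: tuple[int, int, int]
    local_max_suv: float
    suv_peak: float

    @property
    def n_voxels(self) -> int:
        return len(self.voxels[0])


@dataclass(frozen=True)
class Lesion:
    """A segmented lesion with its volume and SUV statistics.

    ``tlu_contribution = volume_ml * suv_mean`` and
    ``tlq_contribution = volume_ml / suv_mean`` are the per-lesion terms of
    the whole-body PSMA-TLU and PSMA-TLQ sums.
    """

    volume_ml: float
    suv_max: float
    suv_mean: float
    suv_peak: float
    provenance: str = "automatic"
    mask: RegionMask | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.provenance not in ("automatic", "manual"):
            raise ValueError(f"provenance must be 'automatic' or 'manual', got {self.provenance!r}")

    @property
    def tlu_contribution(self) -> float:
        return self.volume_ml * self.suv_mean

    @property
    def tlq_contribution(self) -> float:
        if self.suv_mean <= 0:
            return float("nan")
        return self.volume_ml / self.suv_mean

    @classmethod
    def from_mask(
        cls,
        volume: SUVVolume,
        mask: RegionMask,
        provenance: str = "automatic",
        config: SegmentationConfig = DEFAULT_CONFIG,
    ) -> "Lesion":
        """Compute lesion statistics directly from a boolean mask."""
        mask.check_congruent(volume)
        idx = np.nonzero(mask.values)
        if len(idx[0]) == 0:
            raise SegmentationError("lesion mask is empty")
        suv = volume.values[idx]
        _, max_voxel = _hottest_voxel(idx, suv, volume.spacing)
        return cls(
            volume_ml=float(len(suv) * volume.voxel_volume_ml),
            suv_max=float(suv.max()),
            suv_mean=float(suv.mean()),
            suv_peak=compute_suv_peak(volume, max_voxel, config.peak_sphere_volume_ml),
            provenance=provenance,
            mask=mask,
        )


def detect_candidate_lesions(
    volume: SUVVolume,
    liver: LiverReference,
    exclusion: RegionMask | None = None,
    config: SegmentationConfig = DEFAULT_CONFIG,
) -> list[SeedRegion]:
    """Connected supra-threshold components gated by SUVpeak.

    Components (26-connectivity by default) of ``{SUV > threshold}`` outside
    the exclusion mask are candidates; a component is retained iff the
    SUVpeak at its maximum-SUV voxel exceeds the threshold.
    """
    supra = volume.values > liver.threshold
    if exclusion is not None:
        exclusion.check_congruent(volume)
        supra &= ~exclusion.values
    labels, n = ndimage.label(supra, structure=config.structure)
    seeds: list[SeedRegion] = []
    for lab in range(1, n + 1):
        idx = np.nonzero(labels == lab)
        suv = volume.values[idx]
        i_max, max_voxel = _hottest_voxel(idx, suv, volume.spacing)
        peak = compute_suv_peak(volume, max_voxel, config.peak_sphere_volume_ml)
        if peak > liver.threshold:
            seeds.append(
                SeedRegion(
                    voxels=idx,
                    max_voxel=max_voxel,
                    local_max_suv=float(suv[i_max]),
                    suv_peak=peak,
                )
            )
    return seeds


def segment_lesion(
    volume: SUVVolume,
    seed: SeedRegion,
    config: SegmentationConfig = DEFAULT_CONFIG,
) -> Lesion:
    """Delineate one lesion at 50 % of its local SUVmax.

    The lesion mask is the connected component, containing the seed's
    hottest voxel, of ``{SUV >= halfmax_fraction * local SUVmax}`` where the
    local SUVmax is the maximum SUV inside the seed region.
    """
    if seed.n_voxels == 0:
        raise SegmentationError("empty seed region")
    halfmax = config.halfmax_fraction * seed.local_max_suv
    region = volume.values >= halfmax
    labels, _ = ndimage.label(region, structure=config.structure)
    lab = labels[seed.max_voxel]
    if lab == 0:  # cannot happen: the max voxel itself is >= halfmax
        raise SegmentationError("seed voxel below its own half-max threshold")
    mask = RegionMask(values=labels == lab, label="lesion", spacing=volume.spacing)
    return Lesion.from_mask(volume, mask, provenance="automatic", config=config)


def merge_overlapping_lesions(lesions: list[Lesion], volume: SUVVolume,
                              config: SegmentationConfig = DEFAULT_CONFIG) -> list[Lesion]:
    """Merge lesions whose masks overlap into single lesions (union mask).

    Two candidates whose 50 % isocontour regions coincide or overlap would
    otherwise double-count volume in the whole-body sums.  Statistics of a
    merged lesion are recomputed from the union mask, so its SUVmax is the
    larger of the constituents'.
    """
    masked = [les for les in lesions if les.mask is not None]
    if len(masked) != len(lesions):
        raise SegmentationError("merge requires lesions with masks")
    n = len(lesions)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.any(lesions[i].mask.values & lesions[j].mask.values):
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    merged: list[Lesion] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(lesions[members[0]])
            continue
        union = np.zeros(volume.shape, dtype=bool)
        for i in members:
            union |= lesions[i].mask.values
        mask = RegionMask(values=union, label="lesion", spacing=volume.spacing)
        merged.append(Lesion.from_mask(volume, mask, provenance="automatic", config=config))
    return merged


def filter_small_lesions(
    lesions: list[Lesion],
    min_volume_ml: float = 0.5,
) -> list[Lesion]:
    """Discard lesions strictly smaller than ``min_volume_ml`` (order preserved).

    A lesion of exactly the minimum volume is kept; manual lesions are
    subject to the same rule.
    """
    return [les for les in lesions if les.volume_ml >= min_volume_ml]


def add_manual_lesion(
    volume: SUVVolume,
    mask: RegionMask,
    config: SegmentationConfig = DEFAULT_CONFIG,
) -> Lesion:
    """Create a manually delineated lesion from a full mask.

    No 50 % re-thresholding is applied: such lesions have uptake below the
    liver threshold, so an isocontour seeded from them is ill-defined.
    """
    if mask.n_voxels == 0:
        raise SegmentationError("manual lesion mask is empty")
    return Lesion.from_mask(volume, mask, provenance="manual", config=config)


def segment_patient(
    volume: SUVVolume,
    liver_mask: RegionMask,
    manual_masks: list[RegionMask] | None = None,
    exclusion: RegionMask | None = None,
    patient_id: str = "patient",
    config: SegmentationConfig = DEFAULT_CONFIG,
):
    """Full per-patient delineation: threshold, detect, segment, filter, sum.

    The liver mask voxels (and any physiologic-uptake exclusion mask) are
    removed from candidate detection.  Returns a
    :class:`~psmaburden.metrics.PatientBurden`.
    """
    from psmaburden.metrics import compute_burden

    liver_mask.check_congruent(volume)
    if liver_mask.n_voxels == 0:
        raise ReferenceRegionError("liver reference mask is empty")
    liver = compute_liver_threshold(volume.values[liver_mask.values], constant=config.threshold_constant)

    excl_values = liver_mask.values.copy()
    if exclusion is not None:
        exclusion.check_congruent(volume)
        excl_values |= exclusion.values
    excl = RegionMask(values=excl_values, label="exclusion", spacing=volume.spacing)

    seeds = detect_candidate_lesions(volume, liver, exclusion=excl, config=config)
    lesions = [segment_lesion(volume, seed, config=config) for seed in seeds]
    lesions = merge_overlapping_lesions(lesions, volume, config=config)
    for mask in manual_masks or []:
        lesions.append(add_manual_lesion(volume, mask, config=config))
    lesions = filter_small_lesions(lesions, min_volume_ml=config.min_volume_ml)
    return compute_burden(patient_id, lesions, liver=liver)
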