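"""Lesion / perilesional patch extraction.

Pipeline per subject: drop lesions smaller than a voxel threshold, build a
perilesional ring by iterated face-connected binary dilation, z-score each
contrast over the tissue mask, then sample 5x5x5 patch centers from each
lesion and from each lesion's ring component.  Patch quotas are proportional
to region size (with a floor of one), and a greedy overlap constraint rejects
any candidate cube sharing more than ``max_overlap`` of its voxels with the
union of previously accepted cubes, lesion and perilesional patches pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "PatchSpec",
    "Patch",
    "filter_small_lesions",
    "make_perilesional_mask",
    "normalize_subject",
    "sample_patches",
    "cube_overlap_fraction",
    "extract_patch_values",
    "build_patch_dataset",
]

LESION, PERILESIONAL = 1, 0


class DegenerateContrastError(ValueError):
    """Raised when a contrast has (near-)zero variance inside the mask."""


@dataclass
class PatchSpec:
    patch_size: int = 5
    max_overlap: float = 0.2
    min_lesion_voxels: int = 3
    ring_width: int = 3
    #: patches per voxel of source region (quota = max(1, round(density * size)))
    density: float = 0.08
    #: structuring-element connectivity for the ring dilation (1 = faces)
    connectivity: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.patch_size % 2 != 1 or self.patch_size < 1:
            raise ValueError("patch_size must be odd and positive")
        if not 0.0 <= self.max_overlap <= 1.0:
            raise ValueError("max_overlap must be in [0, 1]")
        if self.min_lesion_voxels < 1 or self.ring_width < 1:
            raise ValueError("min_lesion_voxels and ring_width must be positive")


@dataclass
class Patch:
    subject_id: str
    center: tuple[int, int, int]
    label: int                      # 1 = lesion, 0 = perilesional
    values: np.ndarray | None = None  # (n_contrasts, p, p, p)


def filter_small_lesions(lesion_labels: np.ndarray, min_lesion_voxels: int = 3) -> np.ndarray:
    """Remove lesions below the voxel threshold; relabel survivors 1..K.

    Survivors keep their relative order.
    """
    labels = np.asarray(lesion_labels)
    if labels.size == 0 or labels.max() == 0:
        return np.zeros_like(labels, dtype=np.int32)
    counts = np.bincount(labels.ravel())
    keep = [k for k in range(1, len(counts)) if counts[k] >= min_lesion_voxels]
    remap = np.zeros(len(counts), dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        remap[old] = new
    return remap[labels]


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, connectivity)


def make_perilesional_mask(lesion_labels: np.ndarray, tissue_mask: np.ndarray,
                           ring_width: int = 3, connectivity: int = 1) -> np.ndarray:
    """Ring of tissue within ``ring_width`` dilation steps of any lesion.

    ``ring_width`` iterations of face-connected dilation give a city-block
    distance ring; lesion voxels themselves are excluded, and the ring is
    clipped to the tissue mask.
    """
    lesion = np.asarray(lesion_labels) > 0
    if not lesion.any():
        return np.zeros_like(lesion, dtype=bool)
    dil = ndimage.binary_dilation(lesion, structure=_structure(connectivity),
                                  iterations=ring_width)
    return dil & ~lesion & tissue_mask.astype(bool)


def normalize_subject(contrast: np.ndarray, tissue_mask: np.ndarray) -> np.ndarray:
    """Subject-wise z-scoring: mean 0, sd 1 inside the mask; 0 outside."""
    mask = tissue_mask.astype(bool)
    vals = contrast[mask]
    if vals.size < 2:
        raise DegenerateContrastError("mask must contain at least 2 voxels")
    sd = vals.std()
    if sd < 1e-12:
        raise DegenerateContrastError("contrast has zero variance inside the mask")
    out = np.zeros_like(contrast, dtype=np.float64)
    out[mask] = (vals - vals.mean()) / sd
    return out


def _cube_slices(center, half, size):
    # half-open [c - half, c - half + size) per axis
    return tuple(slice(c - half, c - half + size) for c in center)


def cube_overlap_fraction(occupied: np.ndarray, center, patch_size: int) -> float:
    """Fraction of the cube at ``center`` already covered by ``occupied``."""
    half = (patch_size - 1) // 2
    return float(occupied[_cube_slices(center, half, patch_size)].sum()) / patch_size ** 3


def sample_patches(lesion_labels: np.ndarray, peri_mask: np.ndarray,
                   spec: PatchSpec, rng: np.random.Generator,
                   subject_id: str = "") -> list[Patch]:
    """Greedy size-proportional patch sampling with a union overlap constraint.

    For each lesion (then each lesion's ring component) the quota is
    ``max(1, round(density * region size))``.  Candidate centers are drawn
    uniformly from the region; a candidate is accepted iff its cube lies
    inside the volume and shares at most ``max_overlap * patch_size**3``
    voxels with the union of all previously accepted cubes (both classes).
    A region whose quota cannot be met within the attempt budget yields
    fewer patches and a logged warning.
    """
    labels = np.asarray(lesion_labels)
    shape = labels.shape
    p = spec.patch_size
    half = (p - 1) // 2
    max_shared = spec.max_overlap * p ** 3
    occupied = np.zeros(shape, dtype=bool)
    patches: list[Patch] = []

    n_lesions = int(labels.max())
    regions: list[tuple[np.ndarray, int, str]] = []
    for k in range(1, n_lesions + 1):
        vox = np.argwhere(labels == k)
        if len(vox):
            regions.append((vox, LESION, f"lesion {k}"))
    struct = _structure(spec.connectivity)
    peri = peri_mask.astype(bool)
    for k in range(1, n_lesions + 1):
        ring = ndimage.binary_dilation(labels == k, structure=struct,
                                       iterations=spec.ring_width) & peri
        vox = np.argwhere(ring)
        if len(vox):
            regions.append((vox, PERILESIONAL, f"ring {k}"))

    for vox, cls, name in regions:
        quota = max(1, int(round(spec.density * len(vox))))
        accepted = 0
        budget = max(50, 25 * quota)
        for _ in range(budget):
            if accepted >= quota:
                break
            center = vox[rng.integers(len(vox))]
            if np.any(center - half < 0) or np.any(center - half + p > shape):
                continue
            if cube_overlap_fraction(occupied, center, p) * p ** 3 > max_shared:
                continue
            occupied[_cube_slices(center, half, p)] = True
            patches.append(Patch(subject_id=subject_id, center=tuple(int(c) for c in center),
                                 label=cls))
            accepted += 1
        if accepted < quota:
            log.warning("%s %s: quota %d not met, accepted %d", subject_id, name, quota, accepted)
    return patches


def extract_patch_values(contrasts: list[np.ndarray], center, patch_size: int) -> np.ndarray:
    """(n_contrasts, p, p, p) block centered at ``center``."""
    half = (patch_size - 1) // 2
    sl = _cube_slices(center, half, patch_size)
    return np.stack([np.asarray(v)[sl] for v in contrasts]).astype(np.float32)


def build_patch_dataset(subjects, spec: PatchSpec,
                        rng: np.random.Generator | None = None):
    """Full per-cohort extraction: filter, ring, normalize, sample, extract.

    Returns ``(X, y, subject_ids, patches)`` with X of shape
    (n_patches, n_contrasts, p, p, p), float32, subject-normalized.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    xs, ys, sids, all_patches = [], [], [], []
    for rec in subjects:
        labels = filter_small_lesions(rec.lesion_labels, spec.min_lesion_voxels)
        peri = make_perilesional_mask(labels, rec.tissue_mask, spec.ring_width,
                                      spec.connectivity)
        normed = [normalize_subject(v, rec.tissue_mask) for v in rec.contrasts]
        patches = sample_patches(labels, peri, spec, rng, subject_id=rec.subject_id)
        for patch in patches:
            patch.values = extract_patch_values(normed, patch.center, spec.patch_size)
            xs.append(patch.values)
            ys.append(patch.label)
            sids.append(rec.subject_id)
        all_patches.extend(patches)
    X = np.stack(xs).astype(np.float32) if xs else np.empty((0,), dtype=np.float32)
    return X, np.asarray(ys, dtype=np.int64), np.asarray(sids), all_patches
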