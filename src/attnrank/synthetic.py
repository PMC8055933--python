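"""Synthetic multi-contrast MRI cohorts with known ground truth.

Real multi-contrast cohorts of this kind (per-patient sets of co-registered
quantitative diffusion maps with expert lesion segmentations and clinical
covariates) cannot be shared, so every downstream stage is exercised on
simulated cohorts in which the informative contrasts are known by
construction:

* lesions are non-overlapping digital ellipsoids placed by rejection
  sampling inside the tissue mask;
* the ``n_contrasts`` scalar volumes are equicorrelated Gaussian fields —
  one shared latent field plus independent residuals — so a single
  ``cross_corr`` parameter reproduces the highly intercorrelated regime of
  quantitative diffusion measures;
* contrasts in ``informative_set`` additionally receive a constant intensity
  shift (``lesion_effect``, in units of the voxel standard deviation) inside
  lesion voxels, scaled by a per-subject lognormal severity factor so that
  lesion burden varies across subjects;
* a disability score (ordinal, half-point steps in [0, 8]) and a positive
  biomarker are monotone noisy transforms of each subject's mean informative
  lesion intensity, with link strength ``covariate_link`` on the Gaussian
  latent scale (a Gaussian copula), so their population Spearman correlation
  with the imaging latent is analytically known.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "generate_lesion_labels",
    "render_contrasts",
    "generate_covariates",
    "generate_cohort",
    "copula_spearman",
]


@dataclass
class CohortConfig:
    n_subjects: int = 40
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    n_contrasts: int = 12
    informative_set: tuple[int, ...] = (0, 3, 6, 9)
    #: signed intensity shift inside lesions, per contrast, in units of the
    #: voxel standard deviation; zero exactly outside informative_set.
    lesion_effect: tuple[float, ...] | None = None
    cross_corr: float = 0.6
    n_lesions_range: tuple[int, int] = (1, 2)
    lesion_radius_range: tuple[int, int] = (2, 3)
    noise_sd: float = 1.0
    covariate_link: float = 0.8
    #: sd of the lognormal per-subject severity multiplier on lesion_effect.
    severity_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.lesion_effect is None:
            eff = np.zeros(self.n_contrasts)
            eff[list(self.informative_set)] = -1.5
            self.lesion_effect = tuple(eff)
        self.validate()

    def validate(self):
        if self.n_subjects < 1 or self.n_contrasts < 1:
            raise ValueError("counts must be positive")
        if len(self.volume_shape) != 3 or any(d < 1 for d in self.volume_shape):
            raise ValueError("volume_shape must be 3 positive integers")
        inf = set(self.informative_set)
        if not inf or not inf <= set(range(self.n_contrasts)):
            raise ValueError("informative_set must be a non-empty subset of contrast indices")
        if len(self.lesion_effect) != self.n_contrasts:
            raise ValueError("lesion_effect must have one entry per contrast")
        for i, e in enumerate(self.lesion_effect):
            if (e == 0) != (i not in inf):
                raise ValueError("lesion_effect must be zero exactly outside informative_set")
        if not 0.0 <= self.cross_corr < 1.0:
            raise ValueError("cross_corr must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.covariate_link <= 1.0:
            raise ValueError("covariate_link must be in [0, 1]")


@dataclass
class SubjectRecord:
    subject_id: str
    contrasts: list[np.ndarray]
    lesion_labels: np.ndarray
    tissue_mask: np.ndarray
    disability: float
    biomarker: float | None = None

    def validate(self):
        shape = self.lesion_labels.shape
        assert self.tissue_mask.shape == shape
        assert all(v.shape == shape for v in self.contrasts)
        assert not np.any((self.lesion_labels > 0) & ~self.tissue_mask.astype(bool))
        labels = np.unique(self.lesion_labels)
        labels = labels[labels > 0]
        assert np.array_equal(labels, np.arange(1, len(labels) + 1))


def _ellipsoid_voxels(center, radii, shape):
    """Voxel coordinates of a digital ellipsoid, clipped check done by caller."""
    r = np.asarray(radii)
    c = np.asarray(center)
    lo = np.maximum(np.floor(c - r).astype(int), 0)
    hi = np.minimum(np.ceil(c + r).astype(int) + 1, shape)
    grid = np.stack(np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij"), axis=-1)
    d = ((grid - c) / r) ** 2
    inside = d.sum(axis=-1) <= 1.0
    return grid[inside]


def generate_lesion_labels(shape: Sequence[int], n_lesions: int,
                           radius_range: tuple[int, int],
                           rng: np.random.Generator,
                           margin: int = 4, max_attempts: int = 200) -> np.ndarray:
    """Place ``n_lesions`` non-overlapping digital ellipsoids, labeled 1..n.

    Semi-axes are drawn uniformly (integers) from ``radius_range``; centers
    keep ``margin`` voxels from the border so the perilesional ring and any
    patch cube stay inside the volume.  Raises RuntimeError if a lesion
    cannot be placed after ``max_attempts`` rejections.
    """
    shape = tuple(int(d) for d in shape)
    labels = np.zeros(shape, dtype=np.int32)
    if n_lesions == 0:
        return labels
    r_lo, r_hi = radius_range
    if any(d < 2 * (r_hi + margin) + 1 for d in shape) and any(d <= 2 * (r_lo + margin) for d in shape):
        raise ValueError(f"volume {shape} cannot host a lesion of radius {r_lo} with margin {margin}")
    for k in range(1, n_lesions + 1):
        for attempt in range(max_attempts):
            radii = rng.integers(r_lo, r_hi + 1, size=3)
            lo = radii + margin
            hi = np.asarray(shape) - radii - margin
            if np.any(hi <= lo):
                continue
            center = np.array([rng.integers(l, h) for l, h in zip(lo, hi)])
            vox = _ellipsoid_voxels(center, radii, shape)
            if np.any(labels[vox[:, 0], vox[:, 1], vox[:, 2]] > 0):
                continue
            labels[vox[:, 0], vox[:, 1], vox[:, 2]] = k
            break
        else:
            raise RuntimeError(f"could not place lesion {k} after {max_attempts} attempts")
    return labels


def render_contrasts(lesion_labels: np.ndarray, tissue_mask: np.ndarray,
                     config: CohortConfig, rng: np.random.Generator,
                     severity: float = 1.0) -> list[np.ndarray]:
    """Equicorrelated Gaussian contrast volumes with lesion intensity shifts.

    Each contrast is ``noise_sd * (sqrt(c) * shared + sqrt(1-c) * residual)``
    with ``c = cross_corr``, so pairwise voxel correlations equal
    ``cross_corr`` and the voxel sd equals ``noise_sd``.  Informative
    contrasts get ``lesion_effect * noise_sd * severity`` added uniformly
    inside lesion voxels; the two-sample effect size (Cohen's d) between
    lesion and non-lesion voxels is therefore ``lesion_effect * severity``.
    """
    shape = lesion_labels.shape
    c = config.cross_corr
    shared = rng.standard_normal(shape)
    lesion = lesion_labels > 0
    mask = tissue_mask.astype(bool)
    out = []
    for i in range(config.n_contrasts):
        resid = rng.standard_normal(shape)
        vol = config.noise_sd * (np.sqrt(c) * shared + np.sqrt(1.0 - c) * resid)
        eff = config.lesion_effect[i]
        if eff != 0.0:
            vol[lesion] += eff * config.noise_sd * severity
        vol[~mask] = 0.0
        out.append(vol.astype(np.float32))
    return out


def copula_spearman(link: float) -> float:
    """Population Spearman correlation of a bivariate Gaussian copula with
    latent correlation ``link``: (6/pi) * asin(link / 2)."""
    return 6.0 / np.pi * np.arcsin(link / 2.0)


def generate_covariates(latent_z: float, config: CohortConfig,
                        rng: np.random.Generator) -> tuple[float, float]:
    """Disability and biomarker from a subject's standardized imaging latent.

    ``latent_z`` is the cohort-standardized mean informative-contrast lesion
    intensity.  Both covariates are monotone in the *negated* latent (more
    negative intensity shift = more damage = worse outcome): a noisy Gaussian
    copula with correlation ``covariate_link`` is pushed through the normal
    CDF, scaled to [0, 8] and quantized to half-point steps for disability,
    and exponentiated (lognormal noise) for the positive biomarker.
    """
    lam = config.covariate_link
    noise_scale = np.sqrt(max(0.0, 1.0 - lam ** 2))
    u_dis = -lam * latent_z + noise_scale * rng.standard_normal()
    disability = np.clip(np.round(2.0 * 8.0 * ndtr(u_dis)) / 2.0, 0.0, 8.0)
    u_bio = -lam * latent_z + noise_scale * rng.standard_normal()
    biomarker = float(np.exp(np.log(8.9) + 0.6 * u_bio))
    return float(disability), biomarker


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate a full cohort; bit-identical for identical config (seed included)."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    subj_seeds = root.spawn(config.n_subjects)
    cov_rng = np.random.default_rng(root.spawn(1)[0])
    records = []
    latents = []
    informative = list(config.informative_set)
    for s, ss in enumerate(subj_seeds):
        rng = np.random.default_rng(ss)
        n_lesions = int(rng.integers(config.n_lesions_range[0], config.n_lesions_range[1] + 1))
        n_lesions = max(1, n_lesions)
        labels = generate_lesion_labels(config.volume_shape, n_lesions,
                                        config.lesion_radius_range, rng)
        mask = np.ones(config.volume_shape, dtype=bool)
        severity = float(np.exp(config.severity_sd * rng.standard_normal()))
        contrasts = render_contrasts(labels, mask, config, rng, severity=severity)
        lesion = labels > 0
        latents.append(np.mean([contrasts[i][lesion].mean() for i in informative]))
        records.append(SubjectRecord(subject_id=f"subj{s:03d}", contrasts=contrasts,
                                     lesion_labels=labels, tissue_mask=mask,
                                     disability=0.0))
    latents = np.asarray(latents)
    z = (latents - latents.mean()) / (latents.std() + 1e-12)
    for rec, zi in zip(records, z):
        rec.disability, rec.biomarker = generate_covariates(float(zi), config, cov_rng)
    return records
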