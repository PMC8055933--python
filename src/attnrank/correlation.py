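"""Clinical validation of selected contrasts.

Selected contrasts are aggregated per patient (mean within each lesion, then
an unweighted mean over lesions, so small and large lesions count equally),
every non-empty combination of the selected measures is formed as the
unweighted sum of subject-normalized per-patient values, and each variable —
the two conventional lesion-load metrics (lesion count, lesion volume) plus
all combinations — is tested for monotone association with a clinical
covariate by Spearman correlation with a two-sided permutation test
(default 20,000 permutations).  The Benjamini–Hochberg step-up procedure
controls the false discovery rate jointly across all tests of one covariate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationRecord",
    "lesion_patient_mean",
    "enumerate_combinations",
    "combine",
    "spearman_rho",
    "permutation_pvalue",
    "benjamini_hochberg",
    "build_patient_table",
    "run_correlation_analysis",
]


@dataclass
class CorrelationRecord:
    variable: str
    rho: float
    p_value: float
    significant: bool


def lesion_patient_mean(volume: np.ndarray, lesion_labels: np.ndarray) -> float:
    """Mean within each lesion, then unweighted mean over lesions.

    Each lesion contributes equally regardless of size; this differs from the
    voxel-weighted mean whenever lesion sizes differ.
    """
    labels = np.asarray(lesion_labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise ValueError("subject has no lesions")
    per_lesion = ndimage.mean(np.asarray(volume), labels=labels, index=ids)
    return float(np.mean(per_lesion))


def enumerate_combinations(measures) -> list[tuple]:
    """All 2^m - 1 non-empty subsets, ordered by size then lexicographically."""
    measures = list(measures)
    if not measures:
        raise ValueError("need at least one measure")
    out = []
    for size in range(1, len(measures) + 1):
        out.extend(combinations(measures, size))
    return out


def combine(values: np.ndarray) -> np.ndarray:
    """Combined contrast for a subset: unweighted sum over its measures.

    ``values``: (n_patients, n_measures_in_subset).
    """
    return np.asarray(values).sum(axis=1)


def spearman_rho(x, y) -> float:
    """Spearman correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    rx, ry = rankdata(x), rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero rank variance")
    return float(np.corrcoef(rx, ry)[0, 1])


def permutation_pvalue(x, y, n_perm: int = 20000,
                       rng: np.random.Generator | None = None) -> float:
    """Two-sided permutation p-value for the Spearman correlation.

    ``y`` is permuted against fixed ``x``; p uses the add-one convention
    (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm), so p >= 1/(n_perm + 1).
    """
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = spearman_rho(x, y)
    rx = rankdata(x)
    ry = rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(x)
    # permuting y's ranks preserves the tie structure exactly
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    rho_perm = (ry[perm_idx] @ rx) / n
    exceed = int(np.sum(np.abs(rho_perm) >= np.abs(obs) - 1e-12))
    return (1 + exceed) / (1 + n_perm)


def benjamini_hochberg(p_values, q: float = 0.05) -> np.ndarray:
    """Step-up FDR control: boolean flags for the rejected hypotheses."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def build_patient_table(subjects, measure_volumes=None,
                        measure_indices=None, normalized=True) -> pd.DataFrame:
    """Per-patient table of lesion-averaged measures plus lesion-load metrics.

    ``subjects``: SubjectRecord list.  ``measure_indices`` picks which
    contrasts to aggregate (default: all).  Contrast volumes are z-scored
    over the tissue mask first when ``normalized``.
    """
    from .patches import normalize_subject

    rows = []
    for rec in subjects:
        labels = rec.lesion_labels
        ids = np.unique(labels)
        n_lesions = int((ids > 0).sum())
        if n_lesions == 0:
            continue
        idx = measure_indices if measure_indices is not None else range(len(rec.contrasts))
        row = {"patient_id": rec.subject_id,
               "lesion_count": n_lesions,
               "lesion_volume": int((labels > 0).sum()),
               "disability": rec.disability,
               "biomarker": rec.biomarker}
        for i in idx:
            vol = rec.contrasts[i]
            if normalized:
                vol = normalize_subject(vol, rec.tissue_mask)
            row[f"m{i}"] = lesion_patient_mean(vol, labels)
        rows.append(row)
    return pd.DataFrame(rows)


def run_correlation_analysis(table: pd.DataFrame, measures, covariate: str,
                             n_perm: int = 20000, q: float = 0.05,
                             rng: np.random.Generator | None = None,
                             exclude: list | None = None) -> list[CorrelationRecord]:
    """All tests for one covariate: lesion load + every measure combination.

    ``measures``: column names of the selected measures in ``table``.  FDR is
    applied jointly across the full family of tests for this covariate.
    ``exclude`` optionally drops listed patient_ids (e.g. an extreme
    biomarker outlier) before testing.
    """
    if rng is None:
        rng = np.random.default_rng()
    df = table.dropna(subset=[covariate])
    if exclude:
        df = df[~df["patient_id"].isin(exclude)]
    if len(df) < 3:
        raise ValueError(f"covariate {covariate!r} present for fewer than 3 patients")
    y = df[covariate].to_numpy(dtype=float)

    variables: list[tuple[str, np.ndarray]] = [
        ("lesion_count", df["lesion_count"].to_numpy(dtype=float)),
        ("lesion_volume", df["lesion_volume"].to_numpy(dtype=float)),
    ]
    for subset in enumerate_combinations(measures):
        name = "+".join(str(m) for m in subset)
        variables.append((name, combine(df[list(subset)].to_numpy(dtype=float))))

    rhos, ps = [], []
    for _, x in variables:
        try:
            rhos.append(spearman_rho(x, y))
            ps.append(permutation_pvalue(x, y, n_perm=n_perm, rng=rng))
        except ValueError:
            # a rank-degenerate variable (e.g. constant lesion count in a
            # small cohort) has no defined correlation; keep the row with
            # p = 1 so the family size is explicit and BH never flags it
            rhos.append(float("nan"))
            ps.append(1.0)
    flags = benjamini_hochberg(ps, q=q)
    return [CorrelationRecord(variable=name, rho=r, p_value=p, significant=bool(f))
            for (name, _), r, p, f in zip(variables, rhos, ps, flags)]


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([{"variable": r.variable, "rho": r.rho,
                          "p_value": r.p_value, "significant": r.significant}
                         for r in records])
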