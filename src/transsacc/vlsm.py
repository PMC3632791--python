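"""Voxel-based lesion-symptom mapping with the Liebermeister exact test.

Each patient contributes a binary lesion mask on a shared grid and a
dichotomous impairment label.  Per voxel this yields a 2x2 contingency
table (impaired x lesioned) which is tested with Liebermeister's
quasi-exact construction: both concordant cells are incremented before
taking the hypergeometric tail, i.e. the one-sided p-value of table
(a, b, c, d) is the upper tail of (a+1, b, c, d+1).  This equals the
Bayesian posterior probability P(rate_lesioned <= rate_spared | data) under
independent uniform priors and is uniformly less conservative than Fisher's
exact test.

Only voxels lesioned in at least ``min_lesioned`` patients (default 2) are
tested; maps are reported uncorrected at alpha = 0.05 by default, together
with a power map flagging voxels where even a perfectly aligned behavioral
split could reach significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, NotTestableError


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of impaired/unimpaired x lesioned/spared patients."""

    a: int  # impaired and lesioned
    b: int  # impaired and spared
    c: int  # unimpaired and lesioned
    d: int  # unimpaired and spared

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class VlsmResult:
    """Voxelwise z/p maps with masking, power and peak location."""

    z_map: np.ndarray
    p_map: np.ndarray
    power_map: np.ndarray
    included_mask: np.ndarray
    significant_mask: np.ndarray
    peak_voxel: tuple[int, int, int] | None
    peak_mm: tuple[float, float, float] | None
    alpha: float
    empty: bool


def liebermeister_test(table: ContingencyTable, sided: str = "one_sided") -> tuple[float, float]:
    """Liebermeister quasi-exact test of a 2x2 table.

    Returns ``(p, z)``.  One-sided tests evidence that lesioned patients
    are more often impaired; z is the standard-normal quantile of 1 - p,
    positive when lesion status and impairment are positively associated.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + c == 0 or b + d == 0:
        raise NotTestableError("degenerate lesion margin (all or no patients lesioned)")
    if a + b == 0 or c + d == 0:
        raise NotTestableError("degenerate label margin (all patients share one label)")
    # augment both concordant cells
    a1, d1 = a + 1, d + 1
    n1 = a1 + b + c + d1
    dist = stats.hypergeom(n1, a1 + b, a1 + c)
    p_upper = float(dist.sf(a1 - 1))  # P(X >= a+1)
    if sided == "one_sided":
        p = p_upper
    elif sided == "two_sided":
        p_lower = float(dist.cdf(a1))
        p = min(1.0, 2.0 * min(p_upper, p_lower))
    else:
        raise DataError("sided must be 'one_sided' or 'two_sided'")
    p = min(max(p, np.finfo(float).tiny), 1.0)
    z = float(stats.norm.isf(p_upper))
    return p, z


def overlap_map(masks: np.ndarray, subset=None) -> np.ndarray:
    """Per-voxel count of lesioned patients (optionally over a subset)."""
    masks = _check_masks(masks)
    if subset is not None:
        subset = np.asarray(list(subset), dtype=int)
        if subset.size == 0:
            raise DataError("subset must be non-empty")
        masks = masks[subset]
    return masks.sum(axis=0).astype(np.int32)


def subtraction_map(
    masks: np.ndarray,
    impaired_idx,
    unimpaired_idx,
    threshold_pct: float = 15.0,
) -> np.ndarray:
    """Impaired-minus-unimpaired lesion-frequency difference, in percent.

    Per voxel: (% lesioned among impaired) - (% lesioned among unimpaired);
    values smaller in magnitude than ``threshold_pct`` are zeroed.
    """
    masks = _check_masks(masks)
    impaired_idx = np.asarray(list(impaired_idx), dtype=int)
    unimpaired_idx = np.asarray(list(unimpaired_idx), dtype=int)
    if impaired_idx.size == 0 or unimpaired_idx.size == 0:
        raise DataError("both groups must be non-empty")
    pct_imp = 100.0 * masks[impaired_idx].mean(axis=0)
    pct_unimp = 100.0 * masks[unimpaired_idx].mean(axis=0)
    diff = pct_imp - pct_unimp
    diff[np.abs(diff) < threshold_pct] = 0.0
    return diff


def _check_masks(masks: np.ndarray) -> np.ndarray:
    masks = np.asarray(masks)
    if masks.ndim != 4:
        raise DataError("masks must be a (n_patients, x, y, z) array")
    if not np.isin(masks, (0, 1)).all():
        raise DataError("masks must be binary")
    return masks.astype(np.uint8)


def _table_lookup(n_imp: int, n_unimp: int, sided: str):
    """Precompute (p, z) for every possible (a, c) voxel table."""
    p_tab = np.full((n_imp + 1, n_unimp + 1), np.nan)
    z_tab = np.full((n_imp + 1, n_unimp + 1), np.nan)
    for a in range(n_imp + 1):
        for c in range(n_unimp + 1):
            try:
                p, z = liebermeister_test(
                    ContingencyTable(a, n_imp - a, c, n_unimp - c), sided
                )
            except NotTestableError:
                continue
            p_tab[a, c] = p
            z_tab[a, c] = z
    return p_tab, z_tab


def vlsm_map(
    masks: np.ndarray,
    labels,
    affine: np.ndarray | None = None,
    min_lesioned: int = 2,
    alpha: float = 0.05,
    sided: str = "one_sided",
    bonferroni: bool = False,
) -> VlsmResult:
    """Voxelwise lesion-symptom map over a patient cohort.

    ``labels`` is a per-patient 0/1 impairment vector.  Voxels lesioned in
    fewer than ``min_lesioned`` patients, or with a degenerate margin, are
    excluded.  The peak is the maximal-z voxel; among ties the voxel closest
    to the tied voxels' centroid is reported.  Returns an empty-result flag
    (not an exception) when nothing is testable.
    """
    masks = _check_masks(masks)
    labels = np.asarray(labels).astype(int)
    if labels.shape[0] != masks.shape[0]:
        raise DataError("labels must cover all patients")
    n_imp = int(labels.sum())
    n_unimp = int(len(labels) - n_imp)
    if n_imp == 0 or n_unimp == 0:
        return _empty_result(masks.shape[1:], alpha)

    lesion_count = masks.sum(axis=0)
    included = lesion_count >= min_lesioned
    if not included.any():
        return _empty_result(masks.shape[1:], alpha)

    a_map = masks[labels == 1].sum(axis=0)  # impaired and lesioned
    c_map = lesion_count - a_map
    p_tab, z_tab = _table_lookup(n_imp, n_unimp, sided)
    p_map = np.full(masks.shape[1:], np.nan)
    z_map = np.full(masks.shape[1:], np.nan)
    p_map[included] = p_tab[a_map[included], c_map[included]]
    z_map[included] = z_tab[a_map[included], c_map[included]]
    # drop voxels whose margins were degenerate (everyone lesioned)
    included = included & np.isfinite(p_map)
    if not included.any():
        return _empty_result(masks.shape[1:], alpha)

    threshold = alpha / included.sum() if bonferroni else alpha
    significant = included & (p_map < threshold)

    # power: best-case table given the voxel's lesion count
    power = np.zeros(masks.shape[1:], dtype=bool)
    min_p = power_map(masks, labels, min_lesioned=min_lesioned, sided=sided)
    power[included] = min_p[included] < threshold

    peak_voxel = peak_mm = None
    finite = np.where(included & np.isfinite(z_map))
    if len(finite[0]):
        zmax = np.nanmax(z_map[included])
        ties = np.argwhere(included & (z_map >= zmax - 1e-12))
        # exact ties (identical contingency tables) are broken at the tied
        # voxel nearest the tie set's center of mass
        centroid = ties.mean(axis=0)
        best = ties[np.argmin(((ties - centroid) ** 2).sum(axis=1))]
        peak_voxel = tuple(int(v) for v in best)
        if affine is not None:
            mm = affine @ np.array([*peak_voxel, 1.0])
            peak_mm = tuple(float(v) for v in mm[:3])
    return VlsmResult(
        z_map=z_map,
        p_map=p_map,
        power_map=power,
        included_mask=included,
        significant_mask=significant,
        peak_voxel=peak_voxel,
        peak_mm=peak_mm,
        alpha=alpha,
        empty=not included.any(),
    )


def _empty_result(shape, alpha) -> VlsmResult:
    nanvol = np.full(shape, np.nan)
    falsevol = np.zeros(shape, dtype=bool)
    return VlsmResult(
        z_map=nanvol,
        p_map=nanvol.copy(),
        power_map=falsevol,
        included_mask=falsevol.copy(),
        significant_mask=falsevol.copy(),
        peak_voxel=None,
        peak_mm=None,
        alpha=alpha,
        empty=True,
    )


def power_map(
    masks: np.ndarray,
    labels,
    min_lesioned: int = 2,
    sided: str = "one_sided",
) -> np.ndarray:
    """Minimum achievable one-sided p per included voxel.

    For a voxel lesioned in ``k`` patients the best case aligns lesion
    status with impairment: ``a = min(k, n_impaired)``.  Voxels below the
    lesion-count mask, or without contrast (lesioned in all patients), get
    NaN.
    """
    masks = _check_masks(masks)
    labels = np.asarray(labels).astype(int)
    n = masks.shape[0]
    n_imp = int(labels.sum())
    n_unimp = n - n_imp
    lesion_count = masks.sum(axis=0)
    out = np.full(masks.shape[1:], np.nan)
    for k in np.unique(lesion_count):
        if k < min_lesioned or k >= n:
            continue  # no contrast when everyone is lesioned
        a = min(int(k), n_imp)
        c = int(k) - a
        try:
            p, _ = liebermeister_test(
                ContingencyTable(a, n_imp - a, c, n_unimp - c), sided
            )
        except NotTestableError:
            continue
        out[lesion_count == k] = p
    return out


def label_association(
    masks: np.ndarray,
    labels,
    atlas: np.ndarray,
    label_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-atlas-label chi-square association between lesion and impairment.

    For each atlas label, patients are cross-classified by whether their
    lesion touches the label and by impairment; Pearson's chi-square
    (1 df, no continuity correction) is computed.  Labels touched by no
    lesion are skipped with a note.
    """
    masks = _check_masks(masks)
    labels = np.asarray(labels).astype(int)
    atlas = np.asarray(atlas)
    if atlas.shape != masks.shape[1:]:
        raise DataError("atlas must share the cohort grid")
    rows = []
    for lab in np.unique(atlas):
        if lab == 0:
            continue
        region = atlas == lab
        touches = (masks[:, region].sum(axis=1) > 0).astype(int)
        name = (label_names or {}).get(int(lab), str(int(lab)))
        if touches.sum() == 0:
            rows.append(
                {"label": int(lab), "name": name, "chi2": np.nan, "p": np.nan,
                 "n_lesioned": 0, "skipped": True}
            )
            continue
        tab = np.array(
            [
                [np.sum((labels == 1) & (touches == 1)), np.sum((labels == 1) & (touches == 0))],
                [np.sum((labels == 0) & (touches == 1)), np.sum((labels == 0) & (touches == 0))],
            ]
        )
        if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            chi2, p = np.nan, np.nan
        else:
            chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        rows.append(
            {"label": int(lab), "name": name, "chi2": float(chi2), "p": float(p),
             "n_lesioned": int(touches.sum()), "skipped": False}
        )
    return pd.DataFrame(rows)


def cluster_size(significant_mask: np.ndarray, peak_voxel) -> int:
    """Voxel count of the suprathreshold 26-connected component at the peak."""
    from scipy import ndimage

    if peak_voxel is None or not significant_mask.any():
        return 0
    structure = np.ones((3, 3, 3), dtype=bool)
    labeled, _ = ndimage.label(significant_mask, structure=structure)
    lab = labeled[tuple(peak_voxel)]
    if lab == 0:
        return 0
    return int((labeled == lab).sum())
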