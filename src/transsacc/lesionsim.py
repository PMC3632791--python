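"""Synthetic lesion cohorts with a planted critical region.

Generates small focal ellipsoidal lesions on a shared 3-D grid with an
MNI-like affine, mimicking the topology of focal thalamic stroke: lesion
centers are drawn from a central "vascular territory" box that contains the
planted critical region, so some patients hit it and others do not.  A
patient is labeled impaired iff their lesion overlaps the critical region
by at least one voxel; labels are then flipped with a configurable noise
probability.  Cohorts are resampled until at least two patients are
lesioned inside the critical region and both labels occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: default affine: 2-mm isotropic voxels, origin offset so that the default
#: critical region sits in right central thalamus territory (RAS, mm)
DEFAULT_VOXEL_SIZE_MM = 2.0
DEFAULT_ORIGIN_MM = (-32.0, -33.0, -28.0)


def default_affine(voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    aff[:3, 3] = DEFAULT_ORIGIN_MM
    return aff


def _default_critical_region() -> tuple[tuple[int, int, int], ...]:
    # compact 2x2x2 block (64 mm^3 at 2-mm voxels, the scale of a small
    # intralaminar nucleus cluster); voxel (20, 9, 16) maps to (8, -15, 4) mm
    return tuple(
        (i, j, k)
        for i in range(19, 21)
        for j in range(8, 10)
        for k in range(15, 17)
    )


@dataclass(frozen=True)
class LesionCohortSpec:
    """Parameters of a synthetic lesion cohort."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM
    critical_region: tuple[tuple[int, int, int], ...] = field(
        default_factory=_default_critical_region
    )
    n_patients: int = 14
    lesion_radius_range: tuple[float, float] = (2.0, 4.0)
    impairment_noise: float = 0.0
    #: box (lo, hi) per axis from which lesion centers are drawn
    center_box: tuple[tuple[float, float], ...] = ((16.0, 24.0), (5.0, 13.0), (12.0, 20.0))

    def __post_init__(self) -> None:
        if not self.critical_region:
            raise ConfigurationError("critical_region must be non-empty")
        shape = self.grid_shape
        for vox in self.critical_region:
            if not all(0 <= vox[ax] < shape[ax] for ax in range(3)):
                raise ConfigurationError("critical_region must lie inside the grid")
        lo, hi = self.lesion_radius_range
        if not 0 < lo <= hi:
            raise ConfigurationError("lesion_radius_range must be positive and ordered")
        if not 0 <= self.impairment_noise <= 1:
            raise ConfigurationError("impairment_noise must lie in [0, 1]")
        if self.n_patients < 2:
            raise ConfigurationError("need at least 2 patients")


@dataclass(frozen=True)
class LesionCohort:
    """Per-patient binary lesion volumes plus impairment labels."""

    masks: np.ndarray  # (n_patients, x, y, z) uint8
    labels: np.ndarray  # (n_patients,) 0/1
    affine: np.ndarray
    patient_ids: tuple[str, ...]

    @property
    def n_patients(self) -> int:
        return self.masks.shape[0]


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return (dist <= 1.0).astype(np.uint8)


def generate_lesion_cohort(
    spec: LesionCohortSpec, rng_seed, max_resamples: int = 200
) -> LesionCohort:
    """Draw a synthetic cohort satisfying the spec's guarantees.

    Each patient receives one random axis-aligned ellipsoidal lesion; the
    impairment label is the critical-region overlap indicator, flipped with
    probability ``impairment_noise``.  The cohort is resampled until at
    least two patients are lesioned in the critical region and both labels
    occur.
    """
    rng = np.random.default_rng(rng_seed)
    crit = np.zeros(spec.grid_shape, dtype=bool)
    for vox in spec.critical_region:
        crit[vox] = True

    for _ in range(max_resamples):
        masks = np.zeros((spec.n_patients,) + spec.grid_shape, dtype=np.uint8)
        overlap = np.zeros(spec.n_patients, dtype=bool)
        for i in range(spec.n_patients):
            center = [rng.uniform(lo, hi) for lo, hi in spec.center_box]
            radii = rng.uniform(*spec.lesion_radius_range, size=3)
            masks[i] = _ellipsoid_mask(spec.grid_shape, center, radii)
            overlap[i] = bool((masks[i].astype(bool) & crit).any())
        labels = overlap.astype(int)
        if spec.impairment_noise > 0:
            flips = rng.random(spec.n_patients) < spec.impairment_noise
            labels = np.where(flips, 1 - labels, labels)
        if overlap.sum() >= 2 and 0 < labels.sum() < spec.n_patients:
            ids = tuple(f"P{i + 1:02d}" for i in range(spec.n_patients))
            return LesionCohort(masks, labels, default_affine(spec.voxel_size_mm), ids)
    raise ConfigurationError(
        "could not draw a cohort with >=2 critical-region lesions; "
        "check center_box against critical_region"
    )


def make_synthetic_atlas(spec: LesionCohortSpec) -> tuple[np.ndarray, dict[int, str]]:
    """Block atlas for nucleus-level association tests.

    Label 1 covers the critical region (the planted "nucleus"); labels 2-4
    are neighboring blocks of comparable size.  Synthetic stand-in for a
    thalamic nucleus atlas.
    """
    atlas = np.zeros(spec.grid_shape, dtype=np.int16)
    for vox in spec.critical_region:
        atlas[vox] = 1
    idx = np.array(spec.critical_region)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    size = hi - lo
    offsets = {2: (-size[0] - 1, 0, 0), 3: (size[0] + 1, 0, 0), 4: (0, size[1] + 1, 0)}
    for lab, off in offsets.items():
        s = [slice(max(0, lo[a] + off[a]), max(0, min(spec.grid_shape[a], hi[a] + off[a])))
             for a in range(3)]
        region = atlas[tuple(s)]
        region[region == 0] = lab
    names = {1: "critical_nucleus", 2: "anterior_block", 3: "posterior_block", 4: "lateral_block"}
    return atlas, names


def save_cohort(cohort: LesionCohort, out_dir) -> None:
    """Write one uint8 NIfTI per patient plus a two-column label table."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, mask in zip(cohort.patient_ids, cohort.masks):
        img = nib.Nifti1Image(mask.astype(np.uint8), cohort.affine)
        nib.save(img, out / f"{pid}_lesion.nii")
    pd.DataFrame({"patient_id": cohort.patient_ids, "impaired": cohort.labels}).to_csv(
        out / "labels.csv", index=False
    )


def load_cohort(mask_paths, labels_path) -> LesionCohort:
    """Load per-patient NIfTI masks and a (patient_id, impaired) table."""
    labels_df = pd.read_csv(labels_path)
    by_id = {}
    affine = None
    for path in mask_paths:
        img = nib.load(str(path))
        if affine is None:
            affine = img.affine
        elif not np.allclose(affine, img.affine):
            raise ConfigurationError("all masks must share one affine")
        pid = str(path).rsplit("/", 1)[-1].replace("_lesion.nii", "").replace(".nii", "")
        by_id[pid] = np.asarray(img.dataobj).astype(np.uint8)
    masks, labels, ids = [], [], []
    for row in labels_df.itertuples(index=False):
        pid = str(row.patient_id)
        if pid not in by_id:
            raise ConfigurationError(f"no mask for patient {pid}")
        masks.append(by_id[pid])
        labels.append(int(row.impaired))
        ids.append(pid)
    return LesionCohort(np.stack(masks), np.array(labels), affine, tuple(ids))
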