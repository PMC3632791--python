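"""End-to-end orchestration: simulate -> detect -> fit -> profile -> map.

The pipeline runs a synthetic cohort of observers through the displacement
task, detects saccades from generated eye traces, fits psychometric
functions, classifies per-subject deficits against the control sample, runs
voxel-based lesion-symptom mapping on a synthetic lesion cohort, and writes
a cohort report.  Every stage writes its tables/volumes under the output
directory together with a manifest recording seeds, configuration hash and
per-stage counts, so a rerun with the same configuration reproduces every
table byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohortdata import descriptive_stats, load_patient_table
from .deficits import cohort_profiles
from .errors import ConfigurationError, TranssaccError
from .eyetrace import generate_eye_trace, trigger_time_ms
from .lesionsim import LesionCohortSpec, generate_lesion_cohort, make_synthetic_atlas, save_cohort
from .observer import ObserverParams, control_preset, simulate_session, thalamic_preset
from .oculomotor import detect_saccade, targeting_metrics, trigger_check
from .psychometrics import fit_condition_thresholds
from .task import write_trials
from .vlsm import cluster_size, label_association, vlsm_map


@dataclass(frozen=True)
class SubjectSpec:
    """One simulated subject: a preset name with optional overrides.

    ``preset`` is ``"control"`` or ``"thalamic"``; ``deficit_direction``
    restricts a thalamic deficit to one saccade direction (the other
    direction uses control parameters), mirroring lateralized lesions.
    """

    subject_id: str
    preset: str = "control"
    deficit_direction: str | None = None  # None = both directions
    overrides: dict = field(default_factory=dict)

    def observers(self):
        if self.preset == "control":
            return control_preset(**self.overrides)
        if self.preset != "thalamic":
            raise ConfigurationError(f"unknown preset {self.preset!r}")
        deficient = thalamic_preset(**self.overrides)
        if self.deficit_direction is None:
            return deficient
        other = "rightward" if self.deficit_direction == "leftward" else "leftward"
        return {self.deficit_direction: deficient, other: control_preset()}


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full synthetic-cohort run."""

    n_controls: int = 8
    patients: tuple[SubjectSpec, ...] = (
        SubjectSpec("P01", "thalamic", "leftward"),
        SubjectSpec("P02", "thalamic", "rightward"),
        SubjectSpec("P03", "thalamic", None),
    )
    blocks_per_condition: int = 5
    lesion_spec: LesionCohortSpec = field(default_factory=LesionCohortSpec)
    seed: int = 0
    detect_max_trials_per_subject: int = 48
    run_vlsm: bool = True

    def subjects(self) -> list[SubjectSpec]:
        controls = [SubjectSpec(f"C{i + 1:02d}", "control") for i in range(self.n_controls)]
        return controls + list(self.patients)

    def control_ids(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_controls)]


def config_from_yaml(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    patients = tuple(
        SubjectSpec(
            subject_id=p["subject_id"],
            preset=p.get("preset", "thalamic"),
            deficit_direction=p.get("deficit_direction"),
            overrides=p.get("overrides", {}),
        )
        for p in raw.pop("patients", [])
    ) or PipelineConfig().patients
    lesion = LesionCohortSpec(**raw.pop("lesion_spec", {})) if "lesion_spec" in raw else LesionCohortSpec()
    try:
        return PipelineConfig(patients=patients, lesion_spec=lesion, **raw)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc


def config_hash(config: PipelineConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [encode(v) for v in obj]
        return obj

    blob = json.dumps(encode(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(base_seed: int, stage: str, key: str = "") -> int:
    h = hashlib.sha256(f"{base_seed}:{stage}:{key}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: PipelineConfig, output_dir) -> dict:
    """Execute all stages and return the artifact bundle (paths + tables)."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    bundle: dict = {"output_dir": str(out), "config": config}

    def stage(name, **counts):
        log.append({"stage": name, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **counts})

    # ---- simulate -------------------------------------------------------
    trials_by_subject: dict[str, pd.DataFrame] = {}
    for spec in config.subjects():
        seed = _stage_seed(config.seed, "simulate", spec.subject_id)
        trials_by_subject[spec.subject_id] = simulate_session(
            spec.observers(),
            seed,
            blocks_per_condition=config.blocks_per_condition,
            subject=spec.subject_id,
        )
    all_trials = pd.concat(trials_by_subject.values(), ignore_index=True)
    write_trials(all_trials, out / "trials.csv")
    stage("simulate", subjects=len(trials_by_subject), trials=len(all_trials))
    bundle["trials"] = all_trials

    # ---- detect ---------------------------------------------------------
    # regenerate eye traces for a per-subject subsample and verify that the
    # detector recovers the simulated landing positions and trigger timing
    det_rows = []
    for sid, trials in trials_by_subject.items():
        rng = np.random.default_rng(_stage_seed(config.seed, "detect", sid))
        sub = trials.head(config.detect_max_trials_per_subject)
        for rec in sub.itertuples(index=False):
            disp = rec.saccade_landing - rec.fixation_position
            trace = generate_eye_trace(disp, rec.fixation_position, noise_sd=0.05, rng=rng)
            event = detect_saccade(trace)
            det_rows.append(
                {
                    "subject": sid,
                    "trial_index": rec.trial_index,
                    "condition": rec.condition,
                    "direction": rec.direction,
                    "onset_ms": event.onset_ms,
                    "offset_ms": event.offset_ms,
                    "detected_landing": event.end_position,
                    "simulated_landing": rec.saccade_landing,
                    "peak_velocity": event.peak_velocity,
                    "trigger_ms": trigger_time_ms(trace),
                }
            )
    events = pd.DataFrame(det_rows)
    events.to_csv(out / "saccade_events.csv", index=False)
    trig = trigger_check(events["onset_ms"], events["offset_ms"], events["trigger_ms"])
    stage(
        "detect",
        traces=len(events),
        fraction_trigger_first_half=trig["fraction_first_half"],
        mean_trigger_delay_ms=trig["delay_mean_ms"],
    )
    bundle["events"] = events

    # ---- oculomotor summary --------------------------------------------
    oculo = (
        all_trials.groupby("subject", group_keys=False)
        .apply(targeting_metrics, include_groups=False)
        .reset_index(level=0)
        .rename(columns={"subject": "subject"})
    )
    oculo.to_csv(out / "targeting_metrics.csv", index=False)
    stage("oculomotor", cells=len(oculo))
    bundle["targeting"] = oculo

    # ---- fit ------------------------------------------------------------
    fits_by_subject = {
        sid: fit_condition_thresholds(trials) for sid, trials in trials_by_subject.items()
    }
    fits = pd.concat(
        [df.assign(subject=sid) for sid, df in fits_by_subject.items()], ignore_index=True
    )
    fits.to_csv(out / "psychometric_fits.csv", index=False)
    stage("fit", fits=len(fits))
    bundle["fits"] = fits

    # ---- profile --------------------------------------------------------
    profiles, norms = cohort_profiles(
        fits_by_subject, trials_by_subject, control_ids=config.control_ids()
    )
    profiles.to_csv(out / "deficit_profiles.csv", index=False)
    stage("profile", subjects=len(profiles))
    bundle["profiles"] = profiles
    bundle["norms"] = norms

    # ---- vlsm -----------------------------------------------------------
    if config.run_vlsm:
        cohort = generate_lesion_cohort(
            config.lesion_spec, _stage_seed(config.seed, "lesions")
        )
        save_cohort(cohort, out / "lesions")
        result = vlsm_map(cohort.masks, cohort.labels, affine=cohort.affine)
        for name, vol in (
            ("z", result.z_map),
            ("p", result.p_map),
            ("power", result.power_map.astype(np.float32)),
        ):
            nib.save(
                nib.Nifti1Image(np.asarray(vol, dtype=np.float32), cohort.affine),
                out / f"vlsm_{name}.nii",
            )
        atlas, names = make_synthetic_atlas(config.lesion_spec)
        assoc = label_association(cohort.masks, cohort.labels, atlas, names)
        assoc.to_csv(out / "label_association.csv", index=False)
        peak_summary = {
            "peak_voxel": result.peak_voxel,
            "peak_mm": result.peak_mm,
            "n_tested": int(result.included_mask.sum()),
            "n_significant": int(result.significant_mask.sum()),
            "cluster_size": cluster_size(result.significant_mask, result.peak_voxel),
        }
        stage("vlsm", **{k: v for k, v in peak_summary.items() if np.isscalar(v)})
        bundle["vlsm"] = result
        bundle["vlsm_summary"] = peak_summary
        bundle["lesion_cohort"] = cohort
    else:
        stage("vlsm", skipped=True)
        bundle["vlsm"] = None

    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stages": log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle


def make_report(bundle: dict) -> str:
    """Render the cohort report and write summary tables.

    Emits a demographics-style table for the shipped patient cohort, the
    per-subject threshold and impairment tables, the error-attribution
    correlations, and the VLSM peak summary.
    """
    out = Path(bundle["output_dir"])
    if "profiles" not in bundle or bundle["profiles"].empty:
        raise TranssaccError("cannot report on an empty cohort")
    stats = descriptive_stats()
    lines = [
        "Trans-saccadic displacement perception: cohort report",
        "=" * 56,
        f"package version: {bundle['manifest']['package_version']}",
        f"config hash:     {bundle['manifest']['config_hash']}",
        f"seed:            {bundle['manifest']['seed']}",
        "",
        "Reference patient cohort (shipped demographics table)",
        f"  n = {stats['n_patients']}",
        f"  mean age (SD): {stats['mean_age_years']:.1f} ({stats['sd_age_years']:.1f}) years",
        f"  mean time since lesion: {stats['mean_tsl_months']:.1f} months",
        f"  mean lesion volume: {stats['mean_lesion_volume_cm3']:.2f} cm^3 "
        f"(range {stats['min_lesion_volume_cm3']:.2f}-{stats['max_lesion_volume_cm3']:.2f})",
        f"  unilateral right {stats['pct_unilateral_right']:.0f}% / "
        f"left {stats['pct_unilateral_left']:.0f}% / "
        f"bilateral {stats['pct_bilateral']:.0f}%",
        "",
        "Simulated cohort thresholds (deg, per condition x direction)",
    ]
    fits = bundle["fits"]
    cell = fits.pivot_table(index="subject", columns=["condition", "direction"], values="threshold")
    lines.append(cell.round(3).to_string())
    lines.append("")
    lines.append("Deficit classification (controls define the norms)")
    prof = bundle["profiles"]
    flag_cols = [c for c in prof.columns if c.startswith("impaired_")]
    lines.append(prof.set_index("subject")[flag_cols].to_string())
    lines.append("")
    if bundle.get("vlsm") is not None:
        s = bundle["vlsm_summary"]
        lines += [
            "Lesion-symptom mapping (synthetic cohort, planted critical region)",
            f"  voxels tested: {s['n_tested']}, significant at alpha={bundle['vlsm'].alpha}: "
            f"{s['n_significant']}",
            f"  peak voxel {s['peak_voxel']} at {tuple(round(v, 1) for v in s['peak_mm'])} mm, "
            f"cluster size {s['cluster_size']} voxels",
        ]
    else:
        lines.append("Lesion-symptom mapping: stage skipped")
    report = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(report)
    pd.DataFrame([stats]).to_csv(out / "cohort_demographics.csv", index=False)
    return report
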