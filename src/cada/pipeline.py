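"""End-to-end orchestration: register → normalize → segment → fit → features.

`process_cohort` is the library entry point used by the CLI, the test suite
and downstream analyses: it builds the symmetric control template, registers
and intensity-normalizes every subject, segments both striata, fits the
shape ellipsoids (including the template's own, which define the DI
reference), and returns per-subject feature records.

`run_pipeline` is the file-based wrapper: it reads a validated YAML config
with a subject manifest, persists every stage artifact (template, masks,
ellipsoids, features CSV, classification/correlation JSON) under the output
directory, and embeds a config hash + seeds in the provenance record so a
rerun with an identical config reproduces identical outputs (and is skipped
unless forced).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from cada.classify import ExperimentConfig, build_design, evaluate
from cada.ellipsoid import Ellipsoid
from cada.errors import ConfigError, InsufficientInputError
from cada.features import (CSV_HEADER, FeatureRecord, default_occipital_roi,
                           extract_features, fit_side_ellipsoid, records_to_rows)
from cada.preprocess import NormalizationModel, build_template, normalize_intensity, register_rigid
from cada.segmentation import segment_striata
from cada.stats import ClinicalRecord, correlate_severity
from cada.volume_io import Volume, read_volume, write_mask, write_volume

logger = logging.getLogger("cada.pipeline")

__all__ = ["PipelineConfig", "CohortResult", "process_cohort", "run_pipeline",
           "validate_config"]


@dataclass
class CohortResult:
    template: Volume
    template_ellipsoids: dict[str, Ellipsoid]
    normalization: NormalizationModel
    records: list[FeatureRecord]
    groups: dict[str, str]
    segmentations: dict[str, object] = field(default_factory=dict)


def template_ellipsoids_of(template: Volume, seed: int = 17) -> dict[str, Ellipsoid]:
    """Segment the template volume itself and fit its per-side ellipsoids."""
    seg = segment_striata(template, template, seed=seed)
    return {
        "left": fit_side_ellipsoid(seg.left),
        "right": fit_side_ellipsoid(seg.right),
    }


def process_cohort(
    volumes: list[Volume],
    groups: dict[str, str],
    *,
    seed: int = 17,
    levels: tuple[int, ...] = (4, 2, 1),
    reg_max_iter: int = 40,
    template: Volume | None = None,
    keep_segmentations: bool = False,
) -> CohortResult:
    """Run the full image-analysis chain on an in-memory cohort.

    ``groups`` maps subject id to "PD"/"HC"; controls build the template
    unless one is supplied.  Deterministic for fixed inputs and seed.
    """
    controls = [v for v in volumes if groups.get(v.id) == "HC"]
    if template is None:
        if len(controls) < 2:
            raise InsufficientInputError(
                f"template build needs >= 2 controls, got {len(controls)}"
            )
        logger.info("building template from %d controls", len(controls))
        template = build_template(controls, levels=levels, max_iter=reg_max_iter)

    registered = []
    for v in volumes:
        t0 = time.perf_counter()
        _, res = register_rigid(v, template, levels=levels, max_iter=reg_max_iter)
        logger.info("registered %s in %.1fs", v.id, time.perf_counter() - t0)
        registered.append(res)

    norm_model, normalized = normalize_intensity(registered)
    tmpl_ells = template_ellipsoids_of(template, seed=seed)
    occ = default_occipital_roi(template)

    records: list[FeatureRecord] = []
    segmentations: dict[str, object] = {}
    for v in normalized:
        seg = segment_striata(v, template, seed=seed)
        rec = extract_features(v, seg, tmpl_ells, occipital_roi=occ)
        records.append(rec)
        if keep_segmentations:
            segmentations[v.id] = seg
    return CohortResult(
        template=template, template_ellipsoids=tmpl_ells,
        normalization=norm_model, records=records, groups=dict(groups),
        segmentations=segmentations,
    )


# ---------------------------------------------------------------------------
# config handling
# ---------------------------------------------------------------------------

_SCHEMA: dict[str, dict] = {
    "output_dir": None,
    "manifest": None,
    "registration": {"max_iter": 40, "levels": [4, 2, 1]},
    "normalization": {"mask_fraction": 0.05},
    "segmentation": {"seed": 17, "use_weights": False},
    "classify": {"experiment": "exp4_smu", "kernel": "linear", "cv": "loo",
                 "seed": 17, "C": 1.0},
    "correlate": {"mode": "mean_smu"},
}

_MANIFEST_KEYS = {"subject_id", "path", "group", "updrs_me", "updrs_me_left",
                  "updrs_me_right", "most_affected_side", "hy",
                  "duration_years"}


@dataclass
class PipelineConfig:
    output_dir: Path
    manifest: list[dict]
    registration: dict
    normalization: dict
    segmentation: dict
    classify: dict
    correlate: dict

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: (str(v) if isinstance(v, Path) else v)
             for k, v in asdict(self).items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and schema-check a YAML pipeline config, filling defaults.

    Unknown keys (top-level, per-section or per-manifest-row) are rejected
    by name; every referenced volume path must exist.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    unknown = sorted(set(raw) - set(_SCHEMA))
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    if "manifest" not in raw or not raw["manifest"]:
        raise ConfigError("config must list a non-empty 'manifest'")
    if "output_dir" not in raw:
        raise ConfigError("config must set 'output_dir'")

    sections = {}
    for key, defaults in _SCHEMA.items():
        if key in ("output_dir", "manifest"):
            continue
        given = raw.get(key, {}) or {}
        bad = sorted(set(given) - set(defaults))
        if bad:
            raise ConfigError(f"unknown keys in section {key!r}: {bad}")
        sections[key] = {**defaults, **given}

    manifest = []
    for row in raw["manifest"]:
        bad = sorted(set(row) - _MANIFEST_KEYS)
        if bad:
            raise ConfigError(
                f"unknown manifest keys {bad} for subject "
                f"{row.get('subject_id', '?')!r}"
            )
        for req in ("subject_id", "path", "group"):
            if req not in row:
                raise ConfigError(f"manifest row missing {req!r}: {row}")
        if not Path(row["path"]).exists():
            raise ConfigError(
                f"volume for subject {row['subject_id']!r} not found: "
                f"{row['path']}"
            )
        manifest.append(dict(row))

    return PipelineConfig(
        output_dir=Path(raw["output_dir"]), manifest=manifest, **sections,
    )


def _clinical_from_manifest(manifest: list[dict]) -> list[ClinicalRecord]:
    out = []
    for row in manifest:
        out.append(ClinicalRecord(
            subject_id=row["subject_id"], group=row["group"],
            updrs_me=row.get("updrs_me"),
            updrs_me_left=row.get("updrs_me_left"),
            updrs_me_right=row.get("updrs_me_right"),
            most_affected_side=row.get("most_affected_side"),
            hy=row.get("hy"), duration_years=row.get("duration_years"),
        ))
    return out


def write_features_csv(records: list[FeatureRecord], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_HEADER)
        writer.writeheader()
        for row in records_to_rows(records):
            writer.writerow(row)


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute all stages, persisting per-stage artifacts under output_dir.

    Outputs: template.nii.gz, masks/<id>_<side>.nii.gz, ellipsoids.json,
    normalization.json, features.csv, classification.json,
    correlation.json and provenance.json.  A completed run with the same
    config hash is reused unless ``force``.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    prov_path = out / "provenance.json"
    if not force and prov_path.exists():
        prov = json.loads(prov_path.read_text())
        if prov.get("config_hash") == chash and (out / "features.csv").exists():
            logger.info("outputs for config %s already present; skipping", chash)
            return json.loads((out / "report.json").read_text())

    min_controls = sum(1 for r in config.manifest if r["group"] == "HC")
    if min_controls < 2:
        raise InsufficientInputError(
            f"pipeline needs >= 2 controls in the manifest, got {min_controls}"
        )

    volumes = []
    groups = {}
    for row in config.manifest:
        v = read_volume(row["path"])
        v.id = row["subject_id"]
        volumes.append(v)
        groups[v.id] = row["group"]

    result = process_cohort(
        volumes, groups,
        seed=int(config.segmentation["seed"]),
        levels=tuple(config.registration["levels"]),
        reg_max_iter=int(config.registration["max_iter"]),
        keep_segmentations=True,
    )

    write_volume(result.template, out / "template.nii.gz")
    masks_dir = out / "masks"
    masks_dir.mkdir(exist_ok=True)
    for sid, seg in result.segmentations.items():
        for side in ("left", "right"):
            write_mask(getattr(seg, side), result.template.affine,
                       masks_dir / f"{sid}_{side}.nii.gz")
    (out / "ellipsoids.json").write_text(json.dumps(
        {side: e.to_dict() for side, e in result.template_ellipsoids.items()},
        indent=2))
    (out / "normalization.json").write_text(
        json.dumps(result.normalization.to_dict(), indent=2))
    write_features_csv(result.records, out / "features.csv")

    exp = ExperimentConfig(
        name=config.classify["experiment"], kernel=config.classify["kernel"],
        cv=config.classify["cv"], seed=int(config.classify["seed"]),
        C=float(config.classify["C"]),
    )
    X, y, ids, excluded = build_design(result.records, exp, result.groups)
    report_cls = evaluate(X, y, exp, ids=ids)
    cls_payload = {"experiment": exp.name, "excluded": excluded,
                   **report_cls.to_dict()}
    (out / "classification.json").write_text(json.dumps(cls_payload, indent=2))

    clinical = _clinical_from_manifest(config.manifest)
    corr_payload: dict = {}
    n_pd_scores = sum(1 for c in clinical
                      if c.group == "PD" and c.updrs_me is not None)
    if n_pd_scores >= 4:      # Spearman needs paired n >= 4
        fits = correlate_severity(result.records, clinical,
                                  mode=config.correlate["mode"])
        corr_payload = {k: f.to_dict() for k, f in fits.items()}
        (out / "correlation.json").write_text(json.dumps(corr_payload, indent=2))

    report = {
        "config_hash": chash,
        "n_subjects": len(volumes),
        "excluded": excluded,
        "classification": cls_payload,
        "correlation": corr_payload,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    prov = {
        "config_hash": chash,
        "seeds": {"segmentation": config.segmentation["seed"],
                  "classify": config.classify["seed"]},
        "stages": ["template", "register", "normalize", "segment",
                   "ellipsoid", "features", "classify", "correlate"],
    }
    prov_path.write_text(json.dumps(prov, indent=2))
    return report
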