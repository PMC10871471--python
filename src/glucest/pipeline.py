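"""End-to-end orchestration: phantom or real stacks -> field maps ->
corrected contrast -> ROI summaries -> cohort statistics.

Every run is fully determined by its resolved configuration and seed; the
resolved configuration is written alongside the outputs.  A subject failing
any stage is excluded from the cohort statistics and logged (mirroring the
exclusion of unusable in-vivo data), and the run continues.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .contrast import GluCESTMap, compute_glucest, correct_b0, correct_b1
from .fieldmap import FieldMaps, OffsetStack, estimate_field_maps
from .phantom import (
    CohortConfig,
    PhantomBundle,
    PhantomConfig,
    SubjectSpec,
    cohort_manifest,
    make_cohort,
)
from .roi import normalized_volumes, regional_means, summaries_to_frame
from .simulate import PoolSystem, b1_calibration_curve, default_cest_scheme
from .stats import ResultsBundle, build_results_table

__all__ = [
    "CorrectionSettings",
    "RunConfig",
    "SubjectResult",
    "default_calibration",
    "process_subject",
    "build_cohort_table",
    "run_pipeline",
    "load_config",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrectionSettings:
    b0: bool = True
    b1: bool = True
    kappa_limits: tuple[float, float] = (0.5, 1.5)
    b0_method: str = "mscf"
    target_ppm: float = 3.0


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings of one pipeline run."""

    mode: str = "synthetic"
    out_dir: str = "glucest_run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    corrections: CorrectionSettings = field(default_factory=CorrectionSettings)
    subject_table: str | None = None  # real mode: per-subject regional table
    write_maps: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if self.mode == "real" and not self.subject_table:
            raise ValueError("real mode requires subject_table")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must lie in [0, 2^31)")


@dataclass
class SubjectResult:
    spec: SubjectSpec
    field_maps: FieldMaps
    glucest: GluCESTMap
    summaries: pd.DataFrame
    gm_fraction: float
    wm_fraction: float


_CAL_GRID = np.round(np.arange(0.40, 1.6001, 0.05), 10)


def default_calibration(pools: PoolSystem | None = None) -> pd.DataFrame:
    """Simulation-derived B1 calibration table spanning kappa 0.40-1.60."""
    return b1_calibration_curve(
        pools or PoolSystem(), default_cest_scheme(), _CAL_GRID
    )


def process_subject(
    bundle: PhantomBundle,
    spec: SubjectSpec,
    calibration: pd.DataFrame,
    corrections: CorrectionSettings = CorrectionSettings(),
) -> SubjectResult:
    """Run field mapping, correction, contrast and ROI stages for one subject."""
    fmaps = estimate_field_maps(
        bundle.wassr, bundle.b1_images, bundle.b1_angles_deg,
        b0_method=corrections.b0_method,
    )
    gmap = contrast_map(bundle.cest, fmaps, calibration, corrections)
    labels = bundle.truth.label_map
    summaries = summaries_to_frame(regional_means(gmap, labels), spec.subject_id)
    gm_frac, wm_frac = normalized_volumes(labels)
    return SubjectResult(
        spec=spec, field_maps=fmaps, glucest=gmap, summaries=summaries,
        gm_fraction=gm_frac, wm_fraction=wm_frac,
    )


def contrast_map(
    cest: OffsetStack,
    fmaps: FieldMaps,
    calibration: pd.DataFrame,
    corrections: CorrectionSettings = CorrectionSettings(),
) -> GluCESTMap:
    """B0/B1-corrected contrast map; either correction can be ablated."""
    if corrections.b0:
        z_neg, z_pos, valid = correct_b0(
            cest, fmaps.b0_ppm, fmaps.valid, corrections.target_ppm
        )
    else:
        z_neg = cest.frame(-corrections.target_ppm)
        z_pos = cest.frame(corrections.target_ppm)
        valid = cest.mask & fmaps.valid
    raw = compute_glucest(
        z_neg, z_pos, valid,
        meta=dict(b0_corrected=bool(corrections.b0), b0_method=corrections.b0_method),
    )
    if not corrections.b1:
        return raw
    return correct_b1(raw, fmaps.kappa, calibration, corrections.kappa_limits)


def build_cohort_table(results: list[SubjectResult]) -> pd.DataFrame:
    """Per-subject x region table feeding the statistics stage."""
    rows = []
    for res in results:
        for _, r in res.summaries.iterrows():
            rows.append(
                dict(
                    subject_id=res.spec.subject_id,
                    group=res.spec.group,
                    age=res.spec.age,
                    sex=res.spec.sex,
                    region=r["region"],
                    mean_percent=r["mean_percent"],
                    sd_percent=r["sd_percent"],
                    n_voxels=r["n_voxels"],
                    low_confidence=bool(r["low_confidence"]),
                    gm_fraction=res.gm_fraction,
                    wm_fraction=res.wm_fraction,
                )
            )
    return pd.DataFrame(rows)


def _config_to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _config_to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _config_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_config_to_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def run_pipeline(
    config: RunConfig,
    pools: PoolSystem | None = None,
    write_outputs: bool = True,
) -> ResultsBundle:
    """Execute a full run and (optionally) write the results tree.

    Synthetic mode generates the cohort phantoms and processes each subject;
    real mode reads a prepared per-subject regional table and runs the
    statistics stage only.
    """
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        gio.write_json(_config_to_jsonable(config), out / "resolved_config.json")

    if config.mode == "real":
        cohort_df = gio.read_subject_table(config.subject_table)
        bundle = build_results_table(cohort_df)
        if write_outputs:
            _write_bundle(bundle, out)
        return bundle

    pools = pools or PoolSystem()
    calibration = default_calibration(pools)
    cohort = make_cohort(config.cohort, seed=config.seed, pools=pools)
    results: list[SubjectResult] = []
    for spec, phantom, _ in cohort:
        try:
            res = process_subject(phantom, spec, calibration, config.corrections)
        except Exception:  # noqa: BLE001 - exclude failing subject, keep going
            logger.exception("subject %s failed; excluded from analysis", spec.subject_id)
            continue
        invalid = int((~res.glucest.valid & phantom.truth.brain_mask).sum())
        logger.info(
            "subject %s: %d invalid brain voxels, GM frac %.3f, WM frac %.3f",
            spec.subject_id, invalid, res.gm_fraction, res.wm_fraction,
        )
        results.append(res)
        if write_outputs and config.write_maps:
            sdir = out / "subjects" / spec.subject_id
            gio.write_map(res.glucest.percent, sdir / "glucest_percent.nii.gz")
            gio.write_map(res.field_maps.b0_ppm, sdir / "b0_ppm.nii.gz")
            gio.write_map(res.field_maps.kappa, sdir / "kappa.nii.gz")
            gio.write_labels(phantom.truth.label_map, sdir / "labels.nii.gz")

    if not results:
        raise RuntimeError("no subject completed the pipeline")
    cohort_df = build_cohort_table(results)
    bundle = build_results_table(cohort_df)
    if write_outputs:
        gio.write_calibration(calibration, out / "b1_calibration.csv")
        gio.write_manifest(cohort_manifest(cohort), out / "manifest.csv")
        _write_bundle(bundle, out)
    return bundle


def _write_bundle(bundle: ResultsBundle, out: Path) -> None:
    fmt = "%.6f"
    bundle.cohort.to_csv(out / "cohort_table.csv", index=False, float_format=fmt)
    bundle.comparison.to_csv(out / "group_comparison.csv", index=False, float_format=fmt)
    bundle.regressions.to_csv(out / "age_regressions.csv", index=False, float_format=fmt)
    bundle.volume_correlations.to_csv(
        out / "volume_correlations.csv", index=False, float_format=fmt
    )
    try:
        with pd.ExcelWriter(out / "results.xlsx") as xl:
            bundle.comparison.to_excel(xl, sheet_name="group_comparison", index=False)
            bundle.regressions.to_excel(xl, sheet_name="age_regressions", index=False)
            bundle.volume_correlations.to_excel(
                xl, sheet_name="volume_correlations", index=False
            )
    except ModuleNotFoundError:  # pragma: no cover - XLSX mirror is optional
        logger.warning("openpyxl unavailable; skipped XLSX mirror")


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML (or JSON) file.

    Nested sections ``cohort``, ``cohort.phantom`` and ``corrections`` map
    onto the corresponding dataclasses; unknown keys raise.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return _config_from_mapping(raw)


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def _config_from_mapping(raw: dict) -> RunConfig:
    raw = dict(raw)
    cohort_raw = dict(raw.pop("cohort", {}) or {})
    phantom_raw = dict(cohort_raw.pop("phantom", {}) or {})
    corr_raw = dict(raw.pop("corrections", {}) or {})
    if "shape" in phantom_raw:
        phantom_raw["shape"] = tuple(phantom_raw["shape"])
    if "kappa_range" in phantom_raw:
        phantom_raw["kappa_range"] = tuple(phantom_raw["kappa_range"])
    if "age_slope_mM_per_year" in cohort_raw:
        cohort_raw["age_slope_mM_per_year"] = {
            (k.split("/")[0], k.split("/")[1]): v
            for k, v in cohort_raw["age_slope_mM_per_year"].items()
        }
    if "smoker_age_range" in cohort_raw:
        cohort_raw["smoker_age_range"] = tuple(cohort_raw["smoker_age_range"])
    if "kappa_limits" in corr_raw:
        corr_raw["kappa_limits"] = tuple(corr_raw["kappa_limits"])
    cohort = _build(
        CohortConfig, {**cohort_raw, "phantom": _build(PhantomConfig, phantom_raw)}
    )
    corrections = _build(CorrectionSettings, corr_raw)
    return _build(RunConfig, {**raw, "cohort": cohort, "corrections": corrections})
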