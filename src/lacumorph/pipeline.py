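"""End-to-end orchestration: simulate -> segment -> measure -> classify -> stats.

A run is fully described by a :class:`RunConfig`; one seed fans out into
stable per-subject sub-seeds, so any subject can be regenerated in
isolation.  All randomness lives in the phantom/cohort generators and the
statistical simulations — segmentation and morphometry are deterministic —
so a fixed seed yields byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, generate_cohort
from .cohort_stats import (
    fit_exposure_model,
    fit_group_model,
    paired_region_test,
)
from .morphometry import (
    bvtv,
    cortical_thickness,
    measure_lacunae,
    summarize_sample,
)
from .regional import classify_regions, surface_distance_map
from .segmentation import (
    DEFAULT_LACUNA_VMAX_UM3,
    DEFAULT_LACUNA_VMIN_UM3,
    compute_threshold,
    cortical_porosity,
    extract_voids,
    label_and_classify,
)
from .volume_io import ImageVolume, read_volume, write_tables

logger = logging.getLogger("lacumorph")

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "analyze_sample"]


class ConfigError(ValueError):
    """A configuration violates its schema; raised before any compute."""


@dataclass
class RunConfig:
    """Materialized configuration of one pipeline run."""

    mode: str = "phantom-cohort"          # or "real-volumes"
    out_dir: str = "runs/default"
    seed: int = 0
    # segmentation
    v_min_um3: float = DEFAULT_LACUNA_VMIN_UM3
    v_max_um3: float = DEFAULT_LACUNA_VMAX_UM3
    # surface area
    sa_smooth_sigma_vox: float = 0.5
    # regional
    region_cutoff_um: float = 20.0
    region_reference: str = "centroid"
    # stats
    significance_level: float = 0.05
    # phantom cohort parameters (mode == "phantom-cohort")
    cohort: CohortSpec = field(default_factory=CohortSpec)
    # real volumes (mode == "real-volumes"): csv with subject_id, compartment,
    # volume path, envelope path, plus a cohort covariate csv
    volumes_csv: Optional[str] = None
    cohort_csv: Optional[str] = None
    log_level: str = "INFO"
    compute_ct_th: bool = True

    def validate(self) -> None:
        if self.mode not in ("phantom-cohort", "real-volumes"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not self.v_min_um3 < self.v_max_um3:
            raise ConfigError(
                f"v_min ({self.v_min_um3}) must be < v_max ({self.v_max_um3})"
            )
        if self.region_cutoff_um <= 0:
            raise ConfigError("region_cutoff_um must be > 0")
        if self.region_reference not in ("centroid", "boundary"):
            raise ConfigError("region_reference must be 'centroid' or 'boundary'")
        if self.mode == "real-volumes" and not (self.volumes_csv and self.cohort_csv):
            raise ConfigError("real-volumes mode needs volumes_csv and cohort_csv")
        if self.mode == "phantom-cohort":
            try:
                self.cohort.validate()
            except ValueError as e:
                raise ConfigError(str(e)) from e

    def materialized(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.materialized(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def analyze_sample(
    vol: ImageVolume,
    envelope: np.ndarray,
    compartment: str,
    sample_id: str,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Segment and measure one compartment volume.

    Returns (per-lacuna records, per-sample summary row, info dict with
    the threshold and component counts).
    """
    cfg = config or RunConfig()
    vs = vol.voxel_size_um
    thr = compute_threshold(vol, envelope)
    voids = extract_voids(vol, envelope, thr)
    labeled = label_and_classify(voids, vs, cfg.v_min_um3, cfg.v_max_um3)
    records = measure_lacunae(labeled, sample_id, compartment,
                              smooth_sigma_vox=cfg.sa_smooth_sigma_vox)

    bone = (np.asarray(vol.voxels) >= thr) & envelope
    # Refill lacunae and sub-resolution specks before the distance
    # transform: only marrow/exterior/large-void interfaces are surface.
    refill = labeled.table.loc[labeled.table.klass != "large_void", "label"]
    refill_voids = np.isin(labeled.labels, refill.to_numpy())
    dmap = surface_distance_map(bone, refill_voids, vs)
    if len(records):
        records = classify_regions(records, dmap, vs,
                                   cutoff_um=cfg.region_cutoff_um,
                                   labeled=labeled if cfg.region_reference == "boundary" else None,
                                   reference=cfg.region_reference)

    bv_mm3 = float(bone.sum() * (vs * 1e-3) ** 3)
    bvtv_pct = bvtv(bone, envelope)
    ct_th = np.nan
    ct_po = np.nan
    if compartment == "cortical":
        ct_po = cortical_porosity(labeled, envelope)
        if cfg.compute_ct_th:
            ct_th = cortical_thickness(bone, vs)
    summary = summarize_sample(records, sample_id, compartment, bv_mm3,
                               bvtv_pct, ct_th_mm=ct_th, ct_po_pct=ct_po)
    info = dict(
        threshold=thr,
        n_components=labeled.n_components,
        n_lacunae=labeled.n_lacunae,
        ct_po_pct=ct_po,
    )
    return records, pd.Series(summary.as_row()), info


def _cohort_statistics(merged: pd.DataFrame, samples: pd.DataFrame) -> dict:
    """Group, exposure and paired regional tests on the merged table."""
    results: dict = {"group_models": [], "exposure_models": [], "paired_tests": []}
    outcome_cols = {
        "cortical": ["lc_v_um3", "lc_sr", "lc_n_bv_mm3", "lc_o"],
        "trabecular": ["lc_v_um3", "lc_sr", "lc_n_bv_mm3", "lc_o"],
    }
    for comp, cols in outcome_cols.items():
        pref = "cort" if comp == "cortical" else "trab"
        for col in cols:
            name = f"{pref}_{col}"
            if name not in merged.columns or merged[name].dropna().nunique() < 2:
                continue
            try:
                res = fit_group_model(merged, name)
                results["group_models"].append(res.as_dict())
            except ValueError as e:
                warnings.warn(f"group model {name}: {e}", stacklevel=2)
        for name in (f"{pref}_lc_n_bv_mm3", f"{pref}_lc_v_um3"):
            if name not in merged.columns or merged[name].dropna().nunique() < 2:
                continue
            try:
                res = fit_exposure_model(merged, name)
                results["exposure_models"].append(res.as_dict())
            except ValueError as e:
                warnings.warn(f"exposure model {name}: {e}", stacklevel=2)
    for comp in ("cortical", "trabecular"):
        sub = samples[samples.compartment == comp]
        for metric, (ccol, pcol) in {
            "lc_v_um3": ("lc_v_central_um3", "lc_v_peripheral_um3"),
            "lc_sr": ("lc_sr_central", "lc_sr_peripheral"),
        }.items():
            pairs = sub[[ccol, pcol]].dropna()
            if len(pairs) < 6:
                continue
            p, stat, transform = paired_region_test(pairs[ccol], pairs[pcol])
            results["paired_tests"].append(
                dict(compartment=comp, outcome=metric, p=p, statistic=stat,
                     transform=transform, n=len(pairs),
                     central_median=float(pairs[ccol].median()),
                     peripheral_median=float(pairs[pcol].median()))
            )
    return results


def _widen_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """One row per subject with cort_/trab_-prefixed outcome columns."""
    wide = None
    for comp, pref in (("cortical", "cort"), ("trabecular", "trab")):
        sub = samples[samples.compartment == comp].copy()
        sub = sub.drop(columns=["compartment"]).add_prefix(f"{pref}_")
        sub = sub.rename(columns={f"{pref}_sample_id": "subject_id"})
        wide = sub if wide is None else wide.merge(sub, on="subject_id", how="outer")
    return wide


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest (also written to disk).

    Stage outputs (per-lacuna, per-sample, cohort CSVs, stats.json) land
    under ``config.out_dir``; a failing stage aborts with its name, leaving
    prior outputs intact.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.materialized(),
        "config_hash": config.config_hash(),
        "stages": {},
        "warnings": [],
    }
    stage = "simulate"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if config.mode == "phantom-cohort":
                cspec = config.cohort
                cspec.seed = config.seed
                cres = generate_cohort(cspec, out_dir=out, render=True)
                cohort = cres.cohort
                paths = cres.phantom_paths
            else:
                cohort = pd.read_csv(config.cohort_csv)
                paths = pd.read_csv(config.volumes_csv)
            manifest["stages"][stage] = {"n_subjects": len(cohort)}

            stage = "segment+measure"
            all_records, sample_rows, infos = [], [], []
            for _, prow in paths.iterrows():
                sid = prow.subject_id
                for comp, pref in (("cortical", "cort"), ("trabecular", "trab")):
                    vol = read_volume(prow[f"{pref}_volume"])
                    envelope = np.load(prow[f"{pref}_envelope"])
                    rec, srow, info = analyze_sample(vol, envelope, comp, sid, config)
                    all_records.append(rec)
                    sample_rows.append(srow)
                    infos.append({"subject_id": sid, "compartment": comp, **info})
            lacunae = pd.concat([r for r in all_records if len(r)], ignore_index=True)
            samples = pd.DataFrame(sample_rows).reset_index(drop=True)
            manifest["stages"][stage] = {
                "n_lacunae": int(len(lacunae)),
                "n_samples": int(len(samples)),
            }

            stage = "tables"
            table_paths = write_tables(lacunae, samples, out, cohort=cohort)
            pd.DataFrame(infos).to_csv(out / "segmentation_report.csv", index=False)
            manifest["stages"][stage] = {k: str(v) for k, v in table_paths.items()}

            stage = "stats"
            wide = _widen_samples(samples)
            merged = cohort.merge(
                wide.rename(columns={"sample_id": "subject_id"}),
                on="subject_id", how="inner",
            )
            stats_out = _cohort_statistics(merged, samples)
            stats_out["n_modeled"] = int(len(merged))
            (out / "stats.json").write_text(json.dumps(stats_out, indent=2))
            manifest["stages"][stage] = {
                "n_group_models": len(stats_out["group_models"]),
                "n_exposure_models": len(stats_out["exposure_models"]),
                "n_paired_tests": len(stats_out["paired_tests"]),
            }
            manifest["warnings"] = [str(w.message) for w in caught]
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
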