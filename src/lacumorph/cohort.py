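"""Synthetic study cohorts with configurable group and exposure effects.

Generates subject covariates (age, sex, HbA1c, diabetes duration, BMI) and
per-subject true lacunar parameters for two compartments, embedding a
configurable effect map:

* a multiplicative group effect on cortical lacunar volume (default x1.077,
  the magnitude the statistics layer is asked to recover),
* an additive group effect on cortical lacunar sphericity,
* a linear slope of trabecular lacunar density on HbA1c,
* central/peripheral ratios of lacunar volume and sphericity deltas.

Two modes:

* tables-only (default): returns the covariate table and the true
  per-subject parameter table.  This is what the simulation studies and
  statistical calibration use — hundreds of cohorts per minute.
* rendered (``out_dir`` given): additionally writes one cortical and one
  trabecular phantom TIFF per subject whose lacuna targets embed that
  subject's parameters, for end-to-end pipeline runs.

All effect-null defaults reproduce the no-effect case exactly: with a unit
ratio and zero deltas/slopes the two groups are exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .phantom import PhantomSpec, generate_phantom
from .volume_io import write_volume

__all__ = ["EffectMap", "CohortSpec", "CohortResult", "generate_cohort"]


@dataclass
class EffectMap:
    """True effects embedded in a generated cohort (all null-able)."""

    cort_lcv_group_ratio: float = 1.077      # x on cortical Lc.V in the MVD group
    cort_lcsr_group_delta: float = 0.006     # + on cortical Lc.Sr in the MVD group
    trab_lcnbv_per_hba1c: float = 87.0       # mm^-3 per mmol/mol
    # central / peripheral structure (ratios of the overall per-subject value)
    cort_lcv_peripheral_factor: float = 129.0 / 160.0
    cort_lcv_central_factor: float = 166.0 / 160.0
    trab_lcv_peripheral_factor: float = 146.0 / 173.0
    trab_lcv_central_factor: float = 199.0 / 173.0
    cort_lcsr_central_minus_peripheral: float = 0.003
    trab_lcsr_central_minus_peripheral: float = 0.033

    def validate(self) -> None:
        for name in ("cort_lcv_group_ratio", "cort_lcv_peripheral_factor",
                     "cort_lcv_central_factor", "trab_lcv_peripheral_factor",
                     "trab_lcv_central_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def null(cls) -> "EffectMap":
        return cls(cort_lcv_group_ratio=1.0, cort_lcsr_group_delta=0.0,
                   trab_lcnbv_per_hba1c=0.0)


@dataclass
class CohortSpec:
    """Cohort composition, covariate distributions, baselines and noise.

    Baselines and spreads default to the study scale this generator
    emulates: 20 + 15 subjects, median age 67 (IQR 62-72), 71% male,
    HbA1c 56.2 (SD 9.5) mmol/mol, cortical Lc.V median 160 um^3 with a
    between-subject log10 SD of 0.060 (IQR-matched), trabecular Lc.N/BV
    12,778 mm^-3 with residual SD 3,100.
    """

    n_group1: int = 20                      # T2D
    n_group2: int = 15                      # T2D + MVD
    age_median: float = 67.0
    age_iqr: tuple[float, float] = (62.0, 72.0)
    male_proportion: float = 0.71
    hba1c_mean: float = 56.2
    hba1c_sd: float = 9.5
    duration_mean: float = 16.1
    duration_sd: float = 7.7
    bmi_median: float = 30.0
    bmi_sd: float = 5.0
    effects: EffectMap = field(default_factory=EffectMap)
    # Baselines (group-1 / reference values)
    cort_lcv_base_um3: float = 160.0
    trab_lcv_base_um3: float = 173.0
    cort_lcsr_base: float = 0.697
    trab_lcsr_base: float = 0.752
    cort_lcnbv_base_mm3: float = 29000.0
    trab_lcnbv_base_mm3: float = 12778.0
    cort_lco_base: float = -0.370
    trab_lco_base: float = -0.330
    # Between-subject noise scales
    lcv_sd_log10: float = 0.060
    cort_lcsr_sd: float = 0.006
    trab_lcsr_sd: float = 0.012
    cort_lcnbv_sd_mm3: float = 4000.0
    trab_lcnbv_sd_mm3: float = 3100.0
    lco_sd: float = 0.020
    regional_lcv_sd_log10: float = 0.030    # extra noise on regional values
    regional_lcsr_sd: float = 0.003
    # Rendered-phantom geometry (desk scale; see docs/methods.md)
    cortical_grid: tuple[int, int, int] = (80, 72, 72)
    cortical_slab_um: float = 72.0
    trabecular_grid: tuple[int, int, int] = (112, 112, 112)
    voxel_size_um: float = 1.2
    seed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_group1 + self.n_group2

    def validate(self) -> None:
        if self.n_group1 < 1 or self.n_group2 < 1:
            raise ValueError("both groups need at least one subject")
        if not 0 <= self.male_proportion <= 1:
            raise ValueError("male_proportion must be in [0, 1]")
        self.effects.validate()


@dataclass
class CohortResult:
    cohort: pd.DataFrame          # covariates, one row per subject
    true_params: pd.DataFrame     # true per-subject lacunar parameters
    phantom_paths: Optional[pd.DataFrame] = None  # subject -> written volume files


def _subject_seed(base_seed: int, index: int, k: int) -> int:
    """Stable per-subject sub-seed, < 2^31."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(index, k))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def generate_cohort(
    cspec: CohortSpec,
    out_dir: str | Path | None = None,
    render: bool = False,
) -> CohortResult:
    """Generate a cohort; optionally render and write per-subject phantoms.

    Deterministic given ``cspec.seed``.  Covariates and true parameters are
    always returned; with ``render=True`` (requires ``out_dir``) a cortical
    and a trabecular phantom TIFF pair per subject is written, whose lacuna
    volume/shape/density targets embed the subject's true parameters.
    """
    cspec.validate()
    if render and out_dir is None:
        raise ValueError("render=True requires out_dir")
    rng = np.random.default_rng(cspec.seed)
    eff = cspec.effects
    n = cspec.n_total
    group = np.array([0] * cspec.n_group1 + [1] * cspec.n_group2)

    age_sd = (cspec.age_iqr[1] - cspec.age_iqr[0]) / 1.3489795
    age = np.round(rng.normal(cspec.age_median, age_sd, n)).clip(40, 95)
    sex_female = (rng.random(n) >= cspec.male_proportion).astype(int)
    hba1c = rng.normal(cspec.hba1c_mean, cspec.hba1c_sd, n).clip(30.0, None)
    duration = rng.normal(cspec.duration_mean, cspec.duration_sd, n).clip(5.0, None)
    bmi = rng.normal(cspec.bmi_median, cspec.bmi_sd, n).clip(18.0, None)

    cohort = pd.DataFrame(
        dict(
            subject_id=[f"S{i:03d}" for i in range(n)],
            group=np.where(group == 1, "T2D+MVD", "T2D"),
            age=age,
            sex=np.where(sex_female == 1, "female", "male"),
            hba1c_mmol_mol=hba1c,
            diabetes_duration_years=duration,
            bmi_kg_m2=bmi,
        )
    )

    # True per-subject parameters: group effects on the scale the analysis
    # models them (log10 for volumes, linear for the rest).
    cort_lcv = cspec.cort_lcv_base_um3 * np.power(
        10.0,
        group * np.log10(eff.cort_lcv_group_ratio)
        + rng.normal(0.0, cspec.lcv_sd_log10, n),
    )
    trab_lcv = cspec.trab_lcv_base_um3 * np.power(
        10.0, rng.normal(0.0, cspec.lcv_sd_log10, n)
    )
    cort_lcsr = (cspec.cort_lcsr_base + group * eff.cort_lcsr_group_delta
                 + rng.normal(0.0, cspec.cort_lcsr_sd, n))
    trab_lcsr = cspec.trab_lcsr_base + rng.normal(0.0, cspec.trab_lcsr_sd, n)
    cort_lcnbv = (cspec.cort_lcnbv_base_mm3
                  + rng.normal(0.0, cspec.cort_lcnbv_sd_mm3, n)).clip(2000.0, None)
    trab_lcnbv = (cspec.trab_lcnbv_base_mm3
                  + eff.trab_lcnbv_per_hba1c * (hba1c - cspec.hba1c_mean)
                  + rng.normal(0.0, cspec.trab_lcnbv_sd_mm3, n)).clip(1000.0, None)
    cort_lco = cspec.cort_lco_base + rng.normal(0.0, cspec.lco_sd, n)
    trab_lco = cspec.trab_lco_base + rng.normal(0.0, cspec.lco_sd, n)

    def regional(base: np.ndarray, factor: float) -> np.ndarray:
        return base * factor * np.power(
            10.0, rng.normal(0.0, cspec.regional_lcv_sd_log10, n)
        )

    tp = pd.DataFrame(
        dict(
            subject_id=cohort.subject_id,
            group=cohort.group,
            cort_lcv_um3=cort_lcv,
            trab_lcv_um3=trab_lcv,
            cort_lcsr=cort_lcsr,
            trab_lcsr=trab_lcsr,
            cort_lcnbv_mm3=cort_lcnbv,
            trab_lcnbv_mm3=trab_lcnbv,
            cort_lco=cort_lco,
            trab_lco=trab_lco,
            cort_lcv_peripheral_um3=regional(cort_lcv, eff.cort_lcv_peripheral_factor),
            cort_lcv_central_um3=regional(cort_lcv, eff.cort_lcv_central_factor),
            trab_lcv_peripheral_um3=regional(trab_lcv, eff.trab_lcv_peripheral_factor),
            trab_lcv_central_um3=regional(trab_lcv, eff.trab_lcv_central_factor),
            cort_lcsr_peripheral=cort_lcsr
            - eff.cort_lcsr_central_minus_peripheral / 2.0
            + rng.normal(0.0, cspec.regional_lcsr_sd, n),
            cort_lcsr_central=cort_lcsr
            + eff.cort_lcsr_central_minus_peripheral / 2.0
            + rng.normal(0.0, cspec.regional_lcsr_sd, n),
            trab_lcsr_peripheral=trab_lcsr
            - eff.trab_lcsr_central_minus_peripheral / 2.0
            + rng.normal(0.0, cspec.regional_lcsr_sd, n),
            trab_lcsr_central=trab_lcsr
            + eff.trab_lcsr_central_minus_peripheral / 2.0
            + rng.normal(0.0, cspec.regional_lcsr_sd, n),
        )
    )

    paths = None
    if render:
        out_dir = Path(out_dir)
        vol_dir = out_dir / "volumes"
        vol_dir.mkdir(parents=True, exist_ok=True)
        path_rows = []
        for i in range(n):
            row = {"subject_id": cohort.subject_id.iloc[i]}
            for comp in ("cortical", "trabecular"):
                pref = "cort" if comp == "cortical" else "trab"
                pspec = _phantom_spec_for_subject(cspec, tp.iloc[i], comp,
                                                  _subject_seed(cspec.seed, i, 0 if comp == "cortical" else 1))
                res = generate_phantom(pspec)
                stem = f"{cohort.subject_id.iloc[i]}_{pref}"
                vpath = vol_dir / f"{stem}.tif"
                write_volume(res.volume, vpath)
                res.ground_truth.to_csv(vol_dir / f"{stem}_truth.csv", index=False)
                np.save(vol_dir / f"{stem}_envelope.npy", res.envelope)
                row[f"{pref}_volume"] = str(vpath)
                row[f"{pref}_truth"] = str(vol_dir / f"{stem}_truth.csv")
                row[f"{pref}_envelope"] = str(vol_dir / f"{stem}_envelope.npy")
            path_rows.append(row)
        paths = pd.DataFrame(path_rows)
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        tp.to_csv(out_dir / "true_params.csv", index=False)
        paths.to_csv(out_dir / "phantom_paths.csv", index=False)

    return CohortResult(cohort, tp, paths)


def _phantom_spec_for_subject(
    cspec: CohortSpec, true_row: pd.Series, compartment: str, seed: int
) -> PhantomSpec:
    """Phantom spec whose lacuna targets embed one subject's parameters."""
    pref = "cort" if compartment == "cortical" else "trab"
    lcv = float(true_row[f"{pref}_lcv_um3"])
    periph = float(true_row[f"{pref}_lcv_peripheral_um3"])
    central = float(true_row[f"{pref}_lcv_central_um3"])
    density = float(true_row[f"{pref}_lcnbv_mm3"])
    return PhantomSpec(
        compartment=compartment,
        grid_shape=(cspec.cortical_grid if compartment == "cortical"
                    else cspec.trabecular_grid),
        slab_thickness_um=cspec.cortical_slab_um,
        voxel_size_um=cspec.voxel_size_um,
        lacuna_count=None,
        lacuna_density_mm3=density,
        volume_median_um3=lcv,
        regional_volume_factors=(periph / lcv, central / lcv),
        seed=seed,
    )
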