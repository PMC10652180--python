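"""Segment and measure every rendered biopsy volume.

For each subject and compartment: Otsu threshold, void labeling, lacuna
classification, per-lacuna morphometry (Lc.V, Lc.SA, Lc.Sr, Lc.O,
semi-axes), surface-distance classification (peripheral < 20 um), and the
per-sample summary (BV/TV, Ct.Th, Ct.Po, Lc.N, Lc.N/BV, regional means).

Requires analysis/01_simulate_cohort.py to have run first.
Writes results/lacunae.csv and results/samples.csv.
"""

import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from lacumorph.pipeline import RunConfig, analyze_sample  # noqa: E402
from lacumorph.volume_io import read_volume, write_tables  # noqa: E402

RUN = ROOT / "scratch" / "cohort_run"
RESULTS = ROOT / "results"


def main() -> None:
    paths = pd.read_csv(RUN / "phantom_paths.csv")
    cfg = RunConfig()
    records, rows = [], []
    t0 = time.time()
    for _, prow in paths.iterrows():
        for comp, pref in (("cortical", "cort"), ("trabecular", "trab")):
            vol = read_volume(prow[f"{pref}_volume"])
            envelope = np.load(prow[f"{pref}_envelope"])
            rec, srow, info = analyze_sample(vol, envelope, comp,
                                             prow.subject_id, cfg)
            records.append(rec)
            rows.append(srow)
    lacunae = pd.concat([r for r in records if len(r)], ignore_index=True)
    samples = pd.DataFrame(rows).reset_index(drop=True)
    write_tables(lacunae, samples, RESULTS)
    print(f"measured {len(lacunae)} lacunae in {len(samples)} samples "
          f"({time.time() - t0:.0f} s)")
    cort = samples[samples.compartment == "cortical"]
    trab = samples[samples.compartment == "trabecular"]
    print(f"cortical:   median Lc.V {cort.lc_v_um3.median():.0f} um^3, "
          f"Lc.N/BV {cort.lc_n_bv_mm3.median():.0f} /mm^3, "
          f"Ct.Po {cort.ct_po_pct.median():.2f} %")
    print(f"trabecular: median Lc.V {trab.lc_v_um3.median():.0f} um^3, "
          f"Lc.N/BV {trab.lc_n_bv_mm3.median():.0f} /mm^3, "
          f"BV/TV {trab.bvtv_pct.median():.1f} %")


if __name__ == "__main__":
    main()
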