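"""Cohort statistics on the measured samples.

Age/sex-adjusted group comparisons (T2D+MVD vs T2D) for every lacunar
outcome in both compartments, HbA1c exposure models for lacunar density
and volume, and paired Wilcoxon tests of central vs peripheral lacunae.
Writes results/stats.json and prints the findings.

Requires 01 and 02 to have run first.
"""

import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from lacumorph.pipeline import _cohort_statistics, _widen_samples  # noqa: E402

RESULTS = ROOT / "results"


def main() -> None:
    cohort = pd.read_csv(RESULTS / "cohort.csv")
    samples = pd.read_csv(RESULTS / "samples.csv")
    merged = cohort.merge(_widen_samples(samples), on="subject_id", how="inner")
    stats = _cohort_statistics(merged, samples)
    stats["n_modeled"] = int(len(merged))
    (RESULTS / "stats.json").write_text(json.dumps(stats, indent=2))

    print(f"modeled {stats['n_modeled']} subjects\n")
    print("group models (T2D+MVD = 1, adjusted for age and sex):")
    for g in stats["group_models"]:
        star = " *" if g["p"] <= 0.05 else ""
        print(f"  {g['outcome']:<22} beta {g['beta']:+.4g}  p {g['p']:.3g} "
              f"({g['transform']}){star}")
    print("\nHbA1c exposure models:")
    for g in stats["exposure_models"]:
        star = " *" if g["p"] <= 0.05 else ""
        print(f"  {g['outcome']:<22} slope {g['beta']:+.4g}  p {g['p']:.3g}{star}")
    print("\ncentral vs peripheral (paired Wilcoxon):")
    for t in stats["paired_tests"]:
        star = " *" if t["p"] <= 0.05 else ""
        print(f"  {t['compartment']:<10} {t['outcome']:<10} "
              f"central {t['central_median']:.3g} vs peripheral "
              f"{t['peripheral_median']:.3g}  p {t['p']:.3g} (n={t['n']}){star}")


if __name__ == "__main__":
    main()
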