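#!/usr/bin/env python
"""Screening normalizations: metabolite profile, inhibition, phenotyping.

Normalizes the synthetic peak-area matrix per metabolite (largest producer
= 100%), computes percent inhibition for an example inhibitor panel, and
ranks recombinant isoforms by their share of metabolite formation. Writes
results/peak_area_percent.csv and results/phenotype_ranking.csv.
"""

from pathlib import Path

import pandas as pd

from dmpkit import io
from dmpkit.screening import (
    InhibitionRecord,
    format_percent_table,
    inhibition_percent,
    normalize_peak_areas,
    phenotype_ranking,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    matrix = io.read_peak_areas_csv(ROOT / "data" / "peak_areas.csv")
    pct = normalize_peak_areas(matrix)
    table = format_percent_table(pct)
    table.to_csv(ROOT / "peak_area_percent.csv")
    print("normalized peak-area matrix (largest producer per metabolite = 100%):")
    print(table.to_string())
    print(f"wrote {ROOT / 'peak_area_percent.csv'}")

    # example inhibitor panel: control-normalized formation of one metabolite
    panel = [
        InhibitionRecord("ketoconazole", "CYP3A", "P4", 100.0, 60.0),
        InhibitionRecord("clobetasol propionate", "CYP3A5", "P4", 100.0, 61.5),
        InhibitionRecord("quinidine", "CYP2D6", "P4", 100.0, 97.0),
    ]
    print("chemical inhibition (percent of control activity suppressed):")
    for rec in panel:
        print(f"  {rec.inhibitor:22s} ({rec.target_isoform:7s}): {inhibition_percent(rec):5.1f}%")

    activities = {"CYP1A1": 50.0, "CYP3A5": 45.0, "CYP2D6": 1.0, "CYP2C9": 0.5}
    ranked = phenotype_ranking(activities)
    pd.DataFrame(ranked, columns=["isoform", "activity", "share_pct"]).to_csv(
        ROOT / "phenotype_ranking.csv", index=False
    )
    print("recombinant isoform phenotyping (share of total formation):")
    for isoform, activity, share in ranked:
        print(f"  {isoform:8s} activity={activity:5.1f}  share={share:5.1f}%")
    print(f"wrote {ROOT / 'phenotype_ranking.csv'}")


if __name__ == "__main__":
    main()
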