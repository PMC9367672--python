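#!/usr/bin/env python
"""Half-life estimation from the synthetic substrate-depletion courses.

Regresses ln(% parent remaining) on time for each series in
results/data/depletion.csv and reports T1/2 = ln2/(-slope), then runs a
small seeded recovery study quantifying how well the sparse 4-point
design identifies a slow (673-min) half-life under 5% noise. Writes
results/stability.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dmpkit import io
from dmpkit.errors import NoDepletionError
from dmpkit.stability import depletion_halflife
from dmpkit.synthetic import simulate_depletion

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main():
    rows = []
    print("substrate-depletion half-lives (log-linear regression):")
    for series in io.read_depletion_csv(ROOT / "data" / "depletion.csv"):
        try:
            res = depletion_halflife(series)
        except NoDepletionError as exc:
            res = exc.result
        rows.append(
            {
                "enzyme_source": series.enzyme_source,
                "reaction_system": series.reaction_system,
                "slope_per_min": res.slope,
                "r2": res.r2,
                "t_half_min": res.t_half,
                "status": res.status,
            }
        )
        print(
            f"  {series.enzyme_source:7s}/{series.reaction_system}: "
            f"T1/2 = {res.t_half:7.1f} min (r2={res.r2:.4f}, {res.status})"
        )
    out = ROOT / "stability.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")

    errs = []
    for i in range(200):
        s = simulate_depletion(673.0, noise_cv=0.05, seed=SEED + i)
        try:
            errs.append(abs(depletion_halflife(s).t_half - 673.0) / 673.0)
        except NoDepletionError:
            errs.append(np.inf)
    med = 100.0 * float(np.median(errs))
    print(
        f"recovery study: true T1/2 673 min, 4-point design, 5% CV, 200 seeds -> "
        f"median |rel err| = {med:.1f}%"
    )
    print("the sparse design identifies slow decays only weakly: over 90 min the")
    print("parent falls ~9%, comparable to the assay noise itself.")


if __name__ == "__main__":
    main()
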