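#!/usr/bin/env python
"""Generate the synthetic study inputs every later analysis step reads.

Emulates the laboratory designs: 8-point 1–200 µM kinetic series per
species (one per kinetic law, using printed parameters as truths),
0/30/60/90-min depletion courses at the species anchor half-lives, the
9-point IV plasma schedule, and a 7-species × 6-metabolite peak-area
matrix. Everything is seeded; outputs land under results/data/.
"""

from pathlib import Path

from dmpkit import io, synthetic

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    datasets = [
        synthetic.simulate_velocity_dataset(
            "michaelis_menten", (158.26, 121.13), seed=SEED,
            enzyme_source="rat", metabolite_id="P4"),
        synthetic.simulate_velocity_dataset(
            "substrate_inhibition", (100.0, 50.0, 200.0), seed=SEED + 1,
            enzyme_source="dog", metabolite_id="P4"),
        synthetic.simulate_velocity_dataset(
            "biphasic", (10.0, 5.0, 100.0, 500.0), seed=SEED + 2,
            enzyme_source="monkey", metabolite_id="P4"),
        synthetic.simulate_velocity_dataset(
            "michaelis_menten", (35.07, 244.63), seed=SEED + 3,
            enzyme_source="human", metabolite_id="P4"),
    ]
    io.write_kinetics_dataset_csv(datasets, OUT / "kinetics.csv")

    series = [
        synthetic.simulate_depletion(673.0, seed=SEED, enzyme_source="human"),
        synthetic.simulate_depletion(245.0, seed=SEED + 1, enzyme_source="monkey"),
        synthetic.simulate_depletion(66.0, seed=SEED + 2,
                                     enzyme_source="monkey", reaction_system="ugt"),
    ]
    io.write_depletion_csv(series, OUT / "depletion.csv")

    # CL/V = 0.66/h so the terminal half-life is ln2/0.66 = 1.05 h
    profiles = [
        synthetic.simulate_iv_profile(10.0, 6.6, 10.0, seed=SEED + i, subject_id=f"rat{i+1}")
        for i in range(3)
    ]
    io.write_plasma_csv(profiles, OUT / "plasma.csv")

    matrix = synthetic.simulate_peak_area_matrix(7, 6, missing_rate=0.1, seed=SEED)
    io.write_peak_areas_csv(matrix, OUT / "peak_areas.csv")

    print(f"wrote synthetic inputs for all stages under {OUT}")
    print(f"  kinetics: {len(datasets)} series, depletion: {len(series)} series, "
          f"plasma: {len(profiles)} subjects, peak areas: 7x6")


if __name__ == "__main__":
    main()
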