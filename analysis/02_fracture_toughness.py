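"""Fracture toughness of synthetic notched pairs with automatic kink detection.

Simulates notched/unnotched pairs with planted critical displacements at
several noise levels, detects the kink, integrates the fracture energy, and
compares against the quadrature oracle of the generating law.

Writes results/fracture_toughness.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from aortamech.fracture import fracture_energy
from aortamech.simulate import TissueModelParams, simulate_notched_pair

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    rows = []
    for kink_mm in (6.0, 8.0, 10.0):
        for noise in (0.0, 0.01):
            p = TissueModelParams(A=50e3, B=10.0, noise_sd=noise, seed=args.seed)
            pair, oracle = simulate_notched_pair(
                p, kink_at=kink_mm * 1e-3, post_kink_slope_fraction=0.2
            )
            # noisy records need a wider slope window for a stable trigger
            res = fracture_energy(pair, "per_volume", window=25 if noise else 5)
            rows.append(
                {
                    "kink_mm": kink_mm, "noise_sd": noise,
                    "Lc_detected_mm": res.L_c * 1e3,
                    "gamma_J_per_m3": res.gamma,
                    "gamma_oracle_J_per_m3": oracle("per_volume"),
                    "error_pct": 100 * abs(res.gamma / oracle("per_volume") - 1),
                }
            )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "fracture_toughness.csv", index=False)
    print(df.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
    print(f"\nnoiseless toughness error vs quadrature oracle: "
          f"{df.loc[df['noise_sd'] == 0, 'error_pct'].max():.3g}% worst-case")


if __name__ == "__main__":
    main()
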