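"""Antagonist and opioid PK at a glance: half-lives and typical profiles.

Computes the two-compartment terminal half-lives implied by the antagonist
population models, the carfentanil effective half-life, and exports typical
single-dose concentration profiles (3 mg IN nalmefene, 4 mg IN naloxone,
2 mg IM naloxone) as a tidy CSV.

Writes results/antagonist_pk/half_lives.json and profiles.csv.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import opirescue as op
from opirescue.pk import DoseEvent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/antagonist_pk"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    bundle = op.default_bundle()
    grid = np.arange(0.0, 24 * 3600.0 + 1, 300.0)

    arms = [
        ("nalmefene", "nalmefene", "intranasal", 3.0),
        ("naloxone", "naloxone_in", "intranasal", 4.0),
        ("naloxone", "naloxone_im", "intramuscular", 2.0),
    ]
    frames = []
    half_lives = {}
    for drug, key, route, dose in arms:
        params = op.typical_parameters(bundle.pk_model(key), 74.7, route)
        half_lives[key] = op.terminal_half_life(params)
        prof = op.plasma_concentration(
            params, [DoseEvent(time_s=0.0, amount_mg=dose, route=route)], grid
        )
        frame = prof.to_frame()
        frame["drug"] = f"{drug} ({route})"
        frames.append(frame)

    carf = op.typical_parameters(bundle.pk_model("carfentanil"), 74.7, "intravenous")
    carf_prof = op.opioid_concentration(
        "carfentanil", carf,
        [DoseEvent(time_s=0.0, amount_mg=0.012, route="intravenous")], grid,
    )
    c0 = carf_prof.conc_ng_ml[0]
    t_half_carf = grid[np.argmax(carf_prof.conc_ng_ml <= c0 / 2)] / 60.0

    pd.concat(frames).to_csv(args.out / "profiles.csv", index=False, float_format="%.5g")
    summary = {
        "nalmefene_terminal_half_life_h": half_lives["nalmefene"],
        "naloxone_in_terminal_half_life_h": half_lives["naloxone_in"],
        "carfentanil_effective_half_life_min": float(t_half_carf),
    }
    (args.out / "half_lives.json").write_text(json.dumps(summary, indent=2) + "\n")

    print("terminal half-lives (h):")
    for key, value in half_lives.items():
        print(f"  {key:12s} {value:6.2f}")
    print(f"carfentanil bolus halving time: {t_half_carf:.1f} min")
    print(f"wrote {args.out}/half_lives.json and profiles.csv")


if __name__ == "__main__":
    main()
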