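"""Fit apparent Michaelis–Menten constants for the simulated panel.

Reads the rate tables written by 01_simulate.py, fits the uninhibited
rows of each, and writes a Km / kcat / kcat-Km specificity table in the
conventional layout to results/tables/kinetic_constants.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from loxsense import io as lio
from loxsense.kinetics import fit_michaelis_menten


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/tables"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for path in sorted(args.sim.glob("rates_*.csv")):
        ds = lio.read_rate_csv(path)
        fit = fit_michaelis_menten(ds.uninhibited())
        rows.append({
            "enzyme": ds.enzyme,
            "Km_mM": round(fit.Km, 2), "Km_se": round(fit.Km_se, 2),
            "kcat_s": round(fit.kcat, 2), "kcat_se": round(fit.kcat_se, 2),
            "kcat_over_Km_mM_s": round(fit.specificity),
            "converged": fit.converged,
        })
        print(f"{ds.enzyme:8s} Km = {fit.Km:5.2f} ± {fit.Km_se:4.2f} mM   "
              f"kcat = {fit.kcat:6.2f} ± {fit.kcat_se:4.2f} 1/s   "
              f"kcat/Km = {fit.specificity:6.0f} 1/(mM s)")
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "kinetic_constants.csv", index=False)
    print(f"\n{len(table)} enzymes -> {args.out / 'kinetic_constants.csv'}")


if __name__ == "__main__":
    main()
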