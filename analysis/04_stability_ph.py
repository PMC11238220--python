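"""Thermal stability (T50) and pH activity windows for the panel.

Fits the two-parameter inactivation sigmoid to each simulated thermal
profile and reports the pH interval with >= 80% relative activity from
each simulated pH profile; writes results/tables/thermostability.csv and
ph_windows.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from loxsense import io as lio
from loxsense.kinetics import fit_thermal_inactivation, ph_activity_window


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/tables"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    t_rows = []
    for path in sorted(args.sim.glob("thermal_*.csv")):
        name = path.stem.removeprefix("thermal_")
        fit = fit_thermal_inactivation(lio.read_activity_csv(path, name))
        t_rows.append({"enzyme": name, "T50_C": round(fit.T50, 1),
                       "T50_se": round(fit.T50_se, 2),
                       "width_C": round(fit.width, 2),
                       "converged": fit.converged})
        print(f"{name:8s} T50 = {fit.T50:4.1f} C (width {fit.width:3.1f} C)")
    pd.DataFrame(t_rows).to_csv(args.out / "thermostability.csv", index=False)

    p_rows = []
    for path in sorted(args.sim.glob("ph_*.csv")):
        name = path.stem.removeprefix("ph_")
        win = ph_activity_window(lio.read_activity_csv(path, name))
        p_rows.append({"enzyme": name, "pH_low": win.pH_low,
                       "pH_high": win.pH_high})
        print(f"{name:8s} 80-100% activity window: pH {win.pH_low}-{win.pH_high}")
    pd.DataFrame(p_rows).to_csv(args.out / "ph_windows.csv", index=False)
    print(f"\n-> {args.out / 'thermostability.csv'}, {args.out / 'ph_windows.csv'}")


if __name__ == "__main__":
    main()
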