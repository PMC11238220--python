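"""CSV readers/writers with fixed schemas, plus JSON/YAML sidecars.

One documented schema per data kind (plain CSV rather than vendor
potentiostat/plate-reader exports):

* rate data:       enzyme, substrate_mM, inhibitor_mM, replicate, rate_per_s
* activity data:   temperature_C | pH, activity_pct
* amperograms:     time_s, current_uA  + a JSON/YAML sidecar holding the
                   rotational-speed schedule, analyte concentration and
                   species, enzyme loading and applied potential.

Readers validate against the schema and report offending rows.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import ActivityProfile, Amperogram, RateDataset
from .errors import SchemaError


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
        raise SchemaError(f"{path}: malformed numeric value in column "
                          f"{col!r} at line {row}")
    if out.isna().any():
        row = int(np.nonzero(out.isna().to_numpy())[0][0]) + 2
        raise SchemaError(f"{path}: missing value in column {col!r} at line {row}")
    return out.astype(float)


# --------------------------------------------------------------------------
# rate data


def write_rate_csv(ds: RateDataset, path) -> Path:
    path = Path(path)
    out = pd.DataFrame({
        "enzyme": ds.enzyme,
        "substrate_mM": ds.data["substrate_mM"],
        "inhibitor_mM": ds.data["inhibitor_mM"],
        "replicate": ds.data["replicate"],
        "rate_per_s": ds.data["rate"],
    })
    out.to_csv(path, index=False)
    return path


def read_rate_csv(path, enzyme_conc_uM: float | None = None) -> RateDataset:
    """Read a rate CSV; an absent inhibitor column defaults to 0 mM."""
    df = _read_table(path)
    for col in ("enzyme", "substrate_mM", "replicate", "rate_per_s"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if "inhibitor_mM" not in df.columns:
        df["inhibitor_mM"] = 0.0
    sub = _numeric(df, "substrate_mM", path)
    if (sub <= 0).any():
        row = int(np.nonzero((sub <= 0).to_numpy())[0][0]) + 2
        raise SchemaError(f"{path}: non-positive substrate concentration at line {row}")
    inh = _numeric(df, "inhibitor_mM", path)
    if (inh < 0).any():
        row = int(np.nonzero((inh < 0).to_numpy())[0][0]) + 2
        raise SchemaError(f"{path}: negative inhibitor concentration at line {row}")
    enzymes = df["enzyme"].unique()
    if len(enzymes) != 1:
        raise SchemaError(f"{path}: expected a single enzyme, found {list(enzymes)}")
    data = pd.DataFrame({
        "substrate_mM": sub,
        "inhibitor_mM": inh,
        "replicate": _numeric(df, "replicate", path).astype(int),
        "rate": _numeric(df, "rate_per_s", path),
    })
    return RateDataset(str(enzymes[0]), data, "per_s", enzyme_conc_uM)


# --------------------------------------------------------------------------
# activity profiles


def write_activity_csv(profile: ActivityProfile, path) -> Path:
    path = Path(path)
    pd.DataFrame({profile.axis: profile.x,
                  "activity_pct": profile.activity_pct}).to_csv(path, index=False)
    return path


def read_activity_csv(path, enzyme: str = "") -> ActivityProfile:
    df = _read_table(path)
    axis = next((c for c in ("temperature_C", "pH") if c in df.columns), None)
    if axis is None or "activity_pct" not in df.columns:
        raise SchemaError(f"{path}: need columns (temperature_C|pH, activity_pct)")
    return ActivityProfile(axis, _numeric(df, axis, path).to_numpy(),
                           _numeric(df, "activity_pct", path).to_numpy(), enzyme)


# --------------------------------------------------------------------------
# amperograms


def write_amperogram_csv(a: Amperogram, path, sidecar_path=None) -> tuple[Path, Path]:
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".meta.json")
    pd.DataFrame({"time_s": a.time, "current_uA": a.current}).to_csv(path, index=False)
    meta = {
        "schedule": [{"omega_rad_s": w, "t_start_s": t0, "t_end_s": t1}
                     for w, t0, t1 in a.schedule],
        "conc_mM": a.conc_mM,
        "species": a.species,
        "enzyme_loading_mg": a.enzyme_loading_mg,
        "applied_potential_V": a.applied_potential_V,
        **{k: v for k, v in a.meta.items() if isinstance(v, (int, float, str))},
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)
    return path, sidecar_path


def read_amperogram_csv(path, sidecar_path=None) -> Amperogram:
    """Read an amperogram CSV and its metadata sidecar (JSON or YAML)."""
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".meta.json")
    if not sidecar_path.exists():
        raise SchemaError(f"{sidecar_path}: sidecar metadata file missing")
    df = _read_table(path)
    for col in ("time_s", "current_uA"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    extra = set(df.columns) - {"time_s", "current_uA"}
    if extra:
        warnings.warn(f"{path}: ignoring extra columns {sorted(extra)}")
    with open(sidecar_path) as fh:
        meta = (yaml.safe_load(fh) if sidecar_path.suffix in (".yml", ".yaml")
                else json.load(fh))
    try:
        schedule = [(float(s["omega_rad_s"]), float(s["t_start_s"]), float(s["t_end_s"]))
                    for s in meta["schedule"]]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{sidecar_path}: malformed schedule ({exc})") from exc
    known = {"schedule", "conc_mM", "species", "enzyme_loading_mg",
             "applied_potential_V"}
    return Amperogram(
        _numeric(df, "time_s", path).to_numpy(),
        _numeric(df, "current_uA", path).to_numpy(),
        schedule,
        conc_mM=float(meta.get("conc_mM", 0.0)),
        species=str(meta.get("species", "lactate")),
        enzyme_loading_mg=float(meta.get("enzyme_loading_mg", 0.0)),
        applied_potential_V=float(meta.get("applied_potential_V", 0.0)),
        meta={k: v for k, v in meta.items() if k not in known},
    )
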