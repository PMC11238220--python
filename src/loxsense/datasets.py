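"""In-memory containers for assay and electrode data.

Three kinds of measurement flow through the package:

* :class:`RateDataset` — replicated initial rates of the soluble enzyme at
  varied substrate (and optionally inhibitor) concentration;
* :class:`ActivityProfile` — relative activity versus temperature or pH;
* :class:`Amperogram` — a timed current trace recorded on a rotating disc
  electrode (RDE) together with its rotational-speed schedule.

All containers validate their invariants on construction and are thin
wrappers over :class:`pandas.DataFrame` / :class:`numpy.ndarray` so the
fitting code can work with plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

RATE_UNITS = ("per_s", "uM_per_min")

#: Fixed column order for rate CSVs.
RATE_COLUMNS = ["enzyme", "substrate_mM", "inhibitor_mM", "replicate", "rate_per_s"]


@dataclass
class RateDataset:
    """Replicated initial rates for one enzyme.

    Parameters
    ----------
    enzyme:
        Label of the enzyme the rates were measured for.
    data:
        Tidy table with columns ``substrate_mM``, ``inhibitor_mM``,
        ``replicate`` and ``rate``.  Rates are turnover numbers (s^-1,
        volumetric rate divided by the monomer enzyme concentration) when
        ``rate_units == "per_s"``.
    rate_units:
        ``"per_s"`` (turnover) or ``"uM_per_min"`` (volumetric).
    enzyme_conc_uM:
        Monomer enzyme concentration of the assay; required to convert a
        volumetric Vmax into a kcat.
    """

    enzyme: str
    data: pd.DataFrame
    rate_units: str = "per_s"
    enzyme_conc_uM: float | None = None

    def __post_init__(self) -> None:
        required = {"substrate_mM", "inhibitor_mM", "replicate", "rate"}
        missing = required - set(self.data.columns)
        if missing:
            raise InputError(f"RateDataset missing columns: {sorted(missing)}")
        if self.rate_units not in RATE_UNITS:
            raise InputError(f"unknown rate units {self.rate_units!r}")
        if (self.data["substrate_mM"] <= 0).any():
            raise InputError("substrate concentrations must be > 0")
        if (self.data["inhibitor_mM"] < 0).any():
            raise InputError("inhibitor concentrations must be >= 0")

    @property
    def substrate(self) -> np.ndarray:
        return self.data["substrate_mM"].to_numpy(float)

    @property
    def inhibitor(self) -> np.ndarray:
        return self.data["inhibitor_mM"].to_numpy(float)

    @property
    def rate(self) -> np.ndarray:
        return self.data["rate"].to_numpy(float)

    @property
    def n_substrate_levels(self) -> int:
        return self.data["substrate_mM"].nunique()

    @property
    def n_inhibitor_levels(self) -> int:
        return self.data["inhibitor_mM"].nunique()

    def uninhibited(self) -> "RateDataset":
        """Rows with zero inhibitor, as a new dataset."""
        sub = self.data[self.data["inhibitor_mM"] == 0.0].reset_index(drop=True)
        return RateDataset(self.enzyme, sub, self.rate_units, self.enzyme_conc_uM)


@dataclass
class ActivityProfile:
    """Relative activity (%) versus temperature (°C) or pH.

    ``x`` is sorted ascending on construction; replicate measurements at the
    same x are kept as separate rows.
    """

    axis: str  # "temperature_C" or "pH"
    x: np.ndarray
    activity_pct: np.ndarray
    enzyme: str = ""
    warn_unidentifiable: bool = False

    def __post_init__(self) -> None:
        if self.axis not in ("temperature_C", "pH"):
            raise InputError(f"unknown profile axis {self.axis!r}")
        self.x = np.asarray(self.x, float)
        self.activity_pct = np.asarray(self.activity_pct, float)
        if self.x.shape != self.activity_pct.shape:
            raise InputError("x and activity_pct must have equal length")
        if (self.activity_pct < 0).any():
            raise InputError("activities must be >= 0")
        order = np.argsort(self.x, kind="stable")
        self.x = self.x[order]
        self.activity_pct = self.activity_pct[order]


@dataclass
class TransportParams:
    """Physical constants of the RDE cell used in Levich-type expressions.

    Defaults: two electrons (Prussian-Blue-mediated H2O2 reduction), a 5 mm
    diameter glassy-carbon disc, and the kinematic viscosity of aqueous
    buffer at room temperature.  All in CGS units (cm, s, C, mol).
    """

    n_electrons: int = 2
    faraday: float = 96485.332  # C/mol
    area: float = float(np.pi * 0.25**2)  # cm^2, 5 mm diameter disc
    kin_viscosity: float = 0.01  # cm^2/s

    def __post_init__(self) -> None:
        for name in ("n_electrons", "faraday", "area", "kin_viscosity"):
            if getattr(self, name) <= 0:
                raise InputError(f"TransportParams.{name} must be > 0")

    @property
    def nFA(self) -> float:
        return self.n_electrons * self.faraday * self.area


@dataclass
class Amperogram:
    """A timed RDE current trace with its rotational-speed schedule.

    ``schedule`` holds ``(omega_rad_s, t_start_s, t_end_s)`` segments; the
    default protocol steps through 49, 100 and 169 rpm over 45 s total.
    Currents are stored in µA with positive sign for the (reduction)
    response magnitude.
    """

    time: np.ndarray  # s
    current: np.ndarray  # µA
    schedule: list[tuple[float, float, float]]
    conc_mM: float = 0.0
    species: str = "lactate"  # or "h2o2"
    enzyme_loading_mg: float = 0.0
    applied_potential_V: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.current = np.asarray(self.current, float)
        if self.time.shape != self.current.shape:
            raise InputError("time and current must have equal length")
        if not self.schedule:
            raise InputError("schedule must be non-empty")
        if self.species not in ("lactate", "h2o2"):
            raise InputError(f"unknown analyte species {self.species!r}")
        prev_end = None
        for omega, t0, t1 in self.schedule:
            if omega <= 0:
                raise InputError("rotational speed omega must be > 0")
            if t1 <= t0:
                raise InputError("schedule segment must have t_end > t_start")
            if prev_end is not None and t0 < prev_end - 1e-12:
                raise InputError("schedule segments must not overlap")
            prev_end = t1
        if self.time.size:
            span0, span1 = self.time[0], self.time[-1]
            if self.schedule[0][1] < span0 - 1e-9 or self.schedule[-1][2] > span1 + 1e-9:
                raise InputError("schedule extends beyond the recorded trace")

    @property
    def omegas(self) -> np.ndarray:
        """Angular velocities of the schedule (rad/s)."""
        return np.array([seg[0] for seg in self.schedule])

    @property
    def inv_root_omegas(self) -> np.ndarray:
        """ω^{-1/2} values, the abscissa of the Koutecký–Levich plot."""
        return self.omegas ** -0.5


def rpm_to_rad_s(rpm: float) -> float:
    """Convert rotations per minute to angular velocity in rad/s."""
    return 2.0 * np.pi * rpm / 60.0
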