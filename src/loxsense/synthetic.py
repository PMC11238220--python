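"""Synthetic-data generators standing in for the study's raw measurements.

Raw plate-reader and potentiostat traces behind a sensor-enzyme
characterization are rarely deposited, so every input the pipeline
consumes can be generated here with the statistical structure the
analysis assumes:

* Michaelis–Menten initial-rate assays (0.05–50 mM L-lactate) and
  pyruvate-inhibition assays (three nonzero pyruvate levels in 0.1–40 mM)
  with multiplicative Gaussian noise (CV-parameterized, default 3% —
  typical plate-reader repeatability);
* sigmoidal residual-activity-versus-temperature profiles and bell-shaped
  pH profiles;
* RDE amperograms following the reciprocal-sum-of-resistances current
  model at the 49/100/169 rpm three-speed protocol (45 s total), with a
  first-order settling transient at each speed change and additive
  Gaussian noise proportional to the local current (default 1% —
  potentiostat-grade).

Every generator is seeded: identical ground truth ⇒ identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ActivityProfile, Amperogram, RateDataset, TransportParams, rpm_to_rad_s
from .errors import InputError
from .kinetics import inhibition_rate, michaelis_menten, thermal_sigmoid

DEFAULT_RPM_SCHEDULE = (49.0, 100.0, 169.0)

#: Default substrate designs (mM), log-spaced over the assayed ranges.
MM_SUBSTRATE_MM = (0.05, 0.13, 0.34, 0.88, 2.3, 5.9, 15.0, 50.0)
INHIBITION_SUBSTRATE_MM = (0.05, 0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0)
INHIBITION_PYRUVATE_MM = (0.0, 2.0, 10.0, 40.0)


# --------------------------------------------------------------------------
# ground truths


@dataclass
class KineticGroundTruth:
    """True solution-kinetics parameters of one simulated enzyme."""

    Km: float  # mM
    kcat: float  # s^-1
    enzyme_conc_uM: float = 0.1  # monomer basis
    inhibition_model: str = "none"
    Ki: float | None = None  # mM
    alpha: float = 1.5  # mixed-model interaction factor
    noise_cv: float = 0.03
    seed: int = 0
    enzyme: str = "simLOx"

    def __post_init__(self) -> None:
        if self.Km <= 0 or self.kcat <= 0:
            raise InputError("Km and kcat must be > 0")
        if self.inhibition_model not in ("none", "competitive", "uncompetitive",
                                         "noncompetitive", "mixed"):
            raise InputError(f"unknown inhibition model {self.inhibition_model!r}")
        if self.inhibition_model != "none" and (self.Ki is None or self.Ki <= 0):
            raise InputError("Ki must be > 0 for an inhibited truth")
        if self.alpha <= 0:
            raise InputError("alpha must be > 0")
        if self.noise_cv < 0:
            raise InputError("noise_cv must be >= 0")


@dataclass
class StabilityGroundTruth:
    """True thermal-inactivation parameters (logistic in temperature)."""

    T50: float = 54.9  # °C
    transition_width: float = 2.0  # °C
    temps: tuple = tuple(np.arange(30.0, 70.0 + 1e-9, 2.5))
    noise_cv: float = 0.02
    seed: int = 0
    enzyme: str = "simLOx"

    def __post_init__(self) -> None:
        if self.transition_width <= 0:
            raise InputError("transition_width must be > 0")
        if len(self.temps) < 5:
            raise InputError("need >= 5 temperatures")


@dataclass
class SensorGroundTruth:
    """True physical parameters of one simulated RDE biosensor.

    ``film_permeability_*`` lump matrix-transport resistances of the
    enzyme/polymer film into effective permeabilities (cm/s); ``None``
    removes the corresponding resistance (infinitely permeable film).
    ``k2`` is the heterogeneous sensor rate constant in cm/s internally
    (reported in m/s downstream).
    """

    n_electrons: int = 2
    faraday: float = 96485.332
    area: float = float(np.pi * 0.25**2)  # cm^2
    kin_viscosity: float = 0.01  # cm^2/s
    D_analyte: float = 6.0e-6  # cm^2/s (L-lactate in aqueous buffer)
    film_permeability_lac: float | None = 0.05  # cm/s
    film_permeability_h2o2: float | None = 0.05  # cm/s
    k2: float | None = 1.0e-3  # cm/s
    Km_solution: float = 0.33  # mM
    omega_schedule: tuple = tuple(
        (rpm_to_rad_s(r), 15.0) for r in DEFAULT_RPM_SCHEDULE)  # (rad/s, duration s)
    conc: float = 0.1  # mM
    species: str = "lactate"
    enzyme_loading_mg: float = 0.007
    noise_cv: float = 0.01
    seed: int = 0
    dt_s: float = 0.05
    transient_tau_s: float = 1.0
    negate_current: bool = False  # raw-instrument sign convention
    enzyme: str = "simLOx"

    def __post_init__(self) -> None:
        for name in ("n_electrons", "faraday", "area", "kin_viscosity",
                     "D_analyte", "Km_solution", "conc", "dt_s", "transient_tau_s"):
            if getattr(self, name) <= 0:
                raise InputError(f"SensorGroundTruth.{name} must be > 0")
        if not self.omega_schedule:
            raise InputError("omega_schedule must be non-empty")
        for omega, dur in self.omega_schedule:
            if omega <= 0:
                raise InputError("omega must be > 0")
            if dur <= 0:
                raise InputError("segment duration must be > 0")
        if self.species not in ("lactate", "h2o2"):
            raise InputError(f"unknown species {self.species!r}")

    @property
    def transport(self) -> TransportParams:
        return TransportParams(self.n_electrons, self.faraday, self.area,
                               self.kin_viscosity)

    @property
    def omegas(self) -> np.ndarray:
        return np.array([w for w, _ in self.omega_schedule])

    @property
    def inv_root_omegas(self) -> np.ndarray:
        return self.omegas ** -0.5


# --------------------------------------------------------------------------
# rate assays


def _mult_noise(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    """Multiplicative Gaussian noise with the given CV, clipped at zero."""
    if cv == 0:
        return values.copy()
    noisy = values * (1.0 + cv * rng.standard_normal(values.shape))
    return np.clip(noisy, 0.0, None)


def gen_mm_dataset(truth: KineticGroundTruth, concs=MM_SUBSTRATE_MM,
                   replicates: int = 3) -> RateDataset:
    """Simulate a replicated Michaelis–Menten initial-rate assay.

    Rates are turnover numbers v = kcat·S/(Km+S) in s^-1 (volumetric rate
    already normalized by the monomer enzyme concentration), times
    multiplicative Gaussian noise with CV ``truth.noise_cv``.
    """
    concs = np.asarray(concs, float)
    if concs.size == 0 or (concs <= 0).any():
        raise InputError("substrate concentrations must be non-empty and > 0")
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    rng = np.random.default_rng(truth.seed)
    S = np.repeat(concs, replicates)
    v = michaelis_menten(S, truth.kcat, truth.Km)
    v = _mult_noise(rng, v, truth.noise_cv)
    df = pd.DataFrame({
        "substrate_mM": S,
        "inhibitor_mM": 0.0,
        "replicate": np.tile(np.arange(1, replicates + 1), concs.size),
        "rate": v,
    })
    return RateDataset(truth.enzyme, df, "per_s", truth.enzyme_conc_uM)


def gen_inhibition_dataset(truth: KineticGroundTruth,
                           concs=INHIBITION_SUBSTRATE_MM,
                           inhibitor_concs=INHIBITION_PYRUVATE_MM,
                           replicates: int = 3) -> RateDataset:
    """Simulate a product-inhibition assay over a (substrate × inhibitor) grid.

    Rates follow the truth's inhibition rate law; the noise stream is drawn
    in the same (inhibitor-outer, substrate-inner, replicate-innermost)
    order as :func:`gen_mm_dataset` so an ``inhibitor_concs == [0]`` call
    reproduces the plain assay for the same seed.
    """
    concs = np.asarray(concs, float)
    inhibitor_concs = np.asarray(inhibitor_concs, float)
    if truth.inhibition_model == "none" and (inhibitor_concs > 0).any():
        raise InputError("truth has inhibition_model='none' but nonzero inhibitor levels")
    if concs.size == 0 or (concs <= 0).any():
        raise InputError("substrate concentrations must be non-empty and > 0")
    if (inhibitor_concs < 0).any():
        raise InputError("inhibitor concentrations must be >= 0")
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    rng = np.random.default_rng(truth.seed)
    frames = []
    for I in inhibitor_concs:
        S = np.repeat(concs, replicates)
        if truth.inhibition_model == "none":
            v = michaelis_menten(S, truth.kcat, truth.Km)
        else:
            v = inhibition_rate(truth.inhibition_model, S, I, truth.kcat,
                                truth.Km, truth.Ki, truth.alpha)
        v = _mult_noise(rng, v, truth.noise_cv)
        frames.append(pd.DataFrame({
            "substrate_mM": S,
            "inhibitor_mM": I,
            "replicate": np.tile(np.arange(1, replicates + 1), concs.size),
            "rate": v,
        }))
    df = pd.concat(frames, ignore_index=True)
    return RateDataset(truth.enzyme, df, "per_s", truth.enzyme_conc_uM)


# --------------------------------------------------------------------------
# stability and pH profiles


def gen_thermal_profile(truth: StabilityGroundTruth) -> ActivityProfile:
    """Simulate a residual-activity-versus-temperature profile.

    activity(%) = 100/(1+exp((T−T50)/w)) with multiplicative noise, clipped
    at zero.  A profile whose temperatures all lie on one side of T50 is
    flagged: the downstream sigmoid fit is then unidentifiable.
    """
    temps = np.asarray(truth.temps, float)
    rng = np.random.default_rng(truth.seed)
    a = thermal_sigmoid(temps, truth.T50, truth.transition_width)
    a = _mult_noise(rng, a, truth.noise_cv)
    one_sided = bool((temps > truth.T50).all() or (temps < truth.T50).all())
    return ActivityProfile("temperature_C", temps, a, truth.enzyme,
                           warn_unidentifiable=one_sided)


def gen_ph_profile(optimum_pH: float = 7.8, width_pH: float = 1.2,
                   ph_values=tuple(np.arange(4.5, 9.5 + 1e-9, 0.5)),
                   noise_cv: float = 0.03, seed: int = 0,
                   enzyme: str = "simLOx") -> ActivityProfile:
    """Simulate an empirical bell-shaped pH-activity profile.

    activity(%) = 100·exp(−(pH−opt)²/(2·width²)) with multiplicative noise.
    The bell is empirical — no mechanistic ionization model is implied.
    """
    ph = np.asarray(ph_values, float)
    if ph.size < 4:
        raise InputError("need >= 4 pH points")
    rng = np.random.default_rng(seed)
    a = 100.0 * np.exp(-((ph - optimum_pH) ** 2) / (2.0 * width_pH**2))
    a = _mult_noise(rng, a, noise_cv)
    return ActivityProfile("pH", ph, a, enzyme)


# --------------------------------------------------------------------------
# amperograms


def plateau_current_uA(truth: SensorGroundTruth, omega: float) -> float:
    """Steady current magnitude (µA) from the series-resistance model.

    |i| = [1/i_mt + 1/i_film + 1/i_enz]^{-1} with
    i_mt  = 0.62·n·F·A·D^{2/3}·ν^{-1/6}·C·ω^{1/2}  (bulk mass transport),
    i_film = n·F·A·P·C                              (film transport),
    i_enz = n·F·A·k2·Km·C/(Km+C)                    (enzyme reaction,
    lactate analyte only).  ``None`` permeability/k2 removes a term.
    """
    from .electrochem import levich_current_uA

    if omega <= 0:
        raise InputError("omega must be > 0")
    p = truth.transport
    C = truth.conc * 1e-6  # mol/cm^3
    recip = 1.0 / levich_current_uA(omega, truth.D_analyte, truth.conc, p)
    perm = (truth.film_permeability_lac if truth.species == "lactate"
            else truth.film_permeability_h2o2)
    if perm is not None:
        recip += 1.0 / (p.nFA * perm * C * 1e6)
    if truth.species == "lactate" and truth.k2 is not None:
        if truth.k2 == 0:
            return 0.0
        i_enz = (p.nFA * truth.k2 * C
                 * truth.Km_solution / (truth.Km_solution + truth.conc)) * 1e6
        recip += 1.0 / i_enz
    return 1.0 / recip


def kl_line(truth: SensorGroundTruth) -> tuple[float, float]:
    """Analytic Koutecký–Levich slope and intercept (1/µA units) of the truth.

    1/i is exactly linear in ω^{-1/2}: the slope is the reciprocal Levich
    coefficient, the intercept the sum of the ω-independent reciprocal
    film and enzyme currents.
    """
    from .electrochem import levich_slope

    slope = levich_slope(truth.D_analyte, truth.conc, truth.transport)
    omega0 = truth.omegas[0]
    i0 = plateau_current_uA(truth, omega0)
    intercept = 1.0 / i0 - slope * omega0 ** -0.5
    return slope, intercept


def gen_amperogram(truth: SensorGroundTruth) -> Amperogram:
    """Simulate a three-speed RDE amperogram.

    Per speed segment the current settles exponentially (time constant
    ``transient_tau_s``) from the previous plateau to the new one given by
    the series-resistance model; additive Gaussian noise has standard
    deviation ``noise_cv`` times the local model current.
    """
    rng = np.random.default_rng(truth.seed)
    times, currents, schedule = [], [], []
    t0 = 0.0
    prev = 0.0
    for omega, dur in truth.omega_schedule:
        plateau = plateau_current_uA(truth, omega)
        t = t0 + np.arange(0.0, dur, truth.dt_s)
        i_model = plateau + (prev - plateau) * np.exp(-(t - t0) / truth.transient_tau_s)
        if truth.noise_cv > 0:
            i_model = i_model + truth.noise_cv * np.abs(i_model) * rng.standard_normal(t.size)
        times.append(t)
        currents.append(i_model)
        schedule.append((omega, t0, t0 + dur))
        t0 += dur
        prev = plateau
    time = np.concatenate(times)
    current = np.concatenate(currents)
    if truth.negate_current:
        current = -current
    # close the final segment at the last sample so the schedule spans the trace
    schedule[-1] = (schedule[-1][0], schedule[-1][1], float(time[-1]))
    return Amperogram(time, current, schedule, truth.conc, truth.species,
                      truth.enzyme_loading_mg,
                      meta={"seed": truth.seed, "enzyme": truth.enzyme})


def k2_for_loading(loading_mg: float, k2_max: float = 2.0e-3,
                   half_mg: float = 0.02, decline_mg: float = 0.15) -> float:
    """Empirical heterogeneous rate constant as a function of enzyme loading.

    Saturating uptake at low loading and a decline at high loading (film
    crowding / thicker diffusion path) emulate the typical loading-response
    curve of immobilized-enzyme sensors:
    k2(L) = k2_max · L/(L+half) · 1/(1+(L/decline)²).
    """
    if loading_mg <= 0:
        raise InputError("loading must be > 0")
    return k2_max * loading_mg / (loading_mg + half_mg) / (1.0 + (loading_mg / decline_mg) ** 2)
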