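"""Koutecký–Levich analysis of rotating-disc-electrode amperometry.

On an RDE the hydrodynamic diffusion layer thins with rotation, so the
mass-transport-limited (Levich) current grows as ω^{1/2}:

    i_mt = 0.62·n·F·A·D^{2/3}·ν^{-1/6}·C·ω^{1/2}

For a mediated enzyme film the recorded current is the reciprocal sum of
series "resistances" — bulk mass transport, transport through the
enzyme/polymer film, and the enzymatic reaction itself — so 1/i is linear
in ω^{-1/2} (only the bulk term depends on ω).  The Koutecký–Levich plot
(1/i against ω^{-1/2}) therefore yields:

* slope → the analyte diffusion coefficient D (inverting the Levich slope);
* intercept → the rotation-independent current i_KL at infinite rotation,
  which at low enzyme loading is enzyme-limited and gives the heterogeneous
  sensor rate constant k2 (m/s) through
  i_KL = n·F·A·k2·Km·C/(Km+C).

Internally everything is CGS (cm, s, mol/cm^3); currents cross the module
boundary in µA and k2 is reported in m/s, the customary unit for a
heterogeneous rate constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .datasets import Amperogram, TransportParams
from .errors import InputError

LEVICH_CONST = 0.62
MM_PER_L_TO_MOL_PER_CM3 = 1e-6  # 1 mM = 1e-6 mol/cm^3


def levich_current_uA(omega: float | np.ndarray, D_cm2_s: float, conc_mM: float,
                      p: TransportParams) -> float | np.ndarray:
    """Mass-transport-limited current magnitude (µA) at angular velocity ω."""
    C = conc_mM * MM_PER_L_TO_MOL_PER_CM3
    amps = (LEVICH_CONST * p.nFA * D_cm2_s ** (2 / 3)
            * p.kin_viscosity ** (-1 / 6) * C * np.sqrt(omega))
    return amps * 1e6


def levich_slope(D_cm2_s: float, conc_mM: float, p: TransportParams) -> float:
    """Analytic KL slope (1/µA per (rad/s)^{-1/2}) for a pure Levich response."""
    C = conc_mM * MM_PER_L_TO_MOL_PER_CM3
    B = LEVICH_CONST * p.nFA * D_cm2_s ** (2 / 3) * p.kin_viscosity ** (-1 / 6) * C
    return 1.0 / (B * 1e6)


@dataclass
class KLFit:
    """Linear regression of 1/i (µA^-1) on ω^{-1/2} for one concentration."""

    conc_mM: float
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    n_points: int
    species: str = "lactate"
    enzyme_loading_mg: float = 0.0
    flag_negative_intercept: bool = False

    @property
    def i_KL_uA(self) -> float:
        """Current extrapolated to infinite rotation (µA)."""
        return 1.0 / self.intercept


@dataclass
class SensorCharacterization:
    """Derived per-sensor quantities from a set of KL fits."""

    enzyme: str
    enzyme_loading_mg: float
    D_cm2_s: float  # mean over concentrations
    D_per_conc: dict[float, float] = field(default_factory=dict)
    k2_m_s: float | None = None  # mean over concentrations
    k2_per_conc: dict[float, float] = field(default_factory=dict)
    sensor_response_uA_M: float | None = None
    species: str = "lactate"
    flags: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# trace processing


def smooth_amperogram(a: Amperogram, window: int = 11, polyorder: int = 2) -> Amperogram:
    """Savitzky–Golay smooth the current trace; time base unchanged."""
    if window % 2 == 0 or window <= polyorder:
        raise InputError("window must be odd and > polyorder")
    if window > a.current.size:
        raise InputError("window larger than trace")
    smoothed = signal.savgol_filter(a.current, window, polyorder)
    return Amperogram(a.time.copy(), smoothed, list(a.schedule), a.conc_mM,
                      a.species, a.enzyme_loading_mg, a.applied_potential_V,
                      dict(a.meta))


def extract_steady_state(a: Amperogram, tail_frac: float = 0.5
                         ) -> list[tuple[float, float]]:
    """Steady-state current magnitude per rotational-speed segment.

    For each schedule segment the mean |current| over the last
    ``tail_frac`` of the segment is taken, discarding the settling
    transient after each speed change.
    """
    if not 0 < tail_frac <= 1:
        raise InputError("tail_frac must be in (0, 1]")
    out = []
    t_last = a.time[-1] if a.time.size else 0.0
    for omega, t0, t1 in a.schedule:
        t_cut = t1 - tail_frac * (t1 - t0)
        # half-open [t_cut, t1): a sample exactly on the boundary belongs to
        # the next segment, except at the very end of the trace
        mask = (a.time >= t_cut - 1e-12) & (a.time < t1 - 1e-12)
        if abs(t1 - t_last) < 1e-12:
            mask |= np.abs(a.time - t1) < 1e-12
        if mask.sum() < 3:
            raise InputError(f"segment at omega={omega:.3g} has <3 samples in tail")
        out.append((omega, float(np.abs(a.current[mask]).mean())))
    return out


def build_kl_fit(points: list[tuple[float, float]], conc_mM: float,
                 species: str = "lactate", enzyme_loading_mg: float = 0.0) -> KLFit:
    """Ordinary-least-squares line of 1/i versus ω^{-1/2}.

    The intercept is the extrapolation to infinite rotational speed where
    bulk mass transport no longer limits the current.
    """
    omegas = np.array([p[0] for p in points], float)
    currents = np.array([p[1] for p in points], float)
    if len(np.unique(omegas)) < 3:
        raise InputError("KL regression needs >= 3 distinct rotational speeds")
    if (currents <= 0).any():
        raise InputError("steady-state currents must be > 0")
    x = omegas ** -0.5
    y = 1.0 / currents
    res = stats.linregress(x, y)
    flag = bool(res.intercept < 0)
    if flag:
        warnings.warn("negative KL intercept: extrapolated kinetic current "
                      "is unphysical; check the plateau extraction")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = float(res.rvalue ** 2) if ss_tot > 0 else 1.0
    return KLFit(conc_mM, float(res.slope), float(res.stderr),
                 float(res.intercept), float(res.intercept_stderr),
                 r2, len(points), species, enzyme_loading_mg, flag)


def kl_design_condition(omegas) -> float:
    """2-norm condition number of the [1, ω^{-1/2}] design matrix.

    The 49/100/169 rpm protocol gives near-evenly spaced ω^{-1/2} values,
    keeping the two-parameter regression well-conditioned.
    """
    x = np.asarray(omegas, float) ** -0.5
    X = np.column_stack([np.ones_like(x), x])
    return float(np.linalg.cond(X))


# --------------------------------------------------------------------------
# derived quantities


def diffusion_from_slope(fit: KLFit, p: TransportParams) -> float:
    """Analyte diffusion coefficient (cm^2/s) from the KL slope.

    Inverts the Levich slope relation:
    D = [1/(0.62·n·F·A·ν^{-1/6}·C·slope)]^{3/2}.
    """
    if fit.slope <= 0:
        raise InputError("KL slope must be > 0")
    if fit.conc_mM <= 0:
        raise InputError("concentration must be > 0")
    slope_A = fit.slope * 1e6  # 1/µA → 1/A on the ordinate
    C = fit.conc_mM * MM_PER_L_TO_MOL_PER_CM3
    d23 = 1.0 / (LEVICH_CONST * p.nFA * p.kin_viscosity ** (-1 / 6) * C * slope_A)
    return float(d23 ** 1.5)


def k2_from_intercept(fit: KLFit, Km_solution_mM: float, p: TransportParams) -> float:
    """Heterogeneous sensor rate constant k2 (m/s) from the KL intercept.

    At infinite rotation and low enzyme loading the current is limited by
    the enzymatic reaction, i_KL = n·F·A·k2·Km·C/(Km+C), with Km taken
    from the solution characterization of the same enzyme.  In the
    C << Km limit this reduces to the first-order form k2 =
    i_KL/(n·F·A·C).
    """
    if fit.intercept <= 0:
        raise InputError("KL intercept must be > 0 (enzyme-limited assumption)")
    if Km_solution_mM <= 0:
        raise InputError("Km must be > 0")
    i_KL_A = fit.i_KL_uA * 1e-6
    C = fit.conc_mM * MM_PER_L_TO_MOL_PER_CM3
    k2_cm_s = i_KL_A * (Km_solution_mM + fit.conc_mM) / (p.nFA * Km_solution_mM * C)
    return float(k2_cm_s / 100.0)  # cm/s → m/s


def sensor_response(kl_fits: list[KLFit]) -> tuple[float, bool]:
    """Sensor response (µA/M): OLS slope of i_KL versus analyte concentration.

    Returns (response, monotone_flagged); the flag is set when the
    KL-intercept currents are not increasing with concentration beyond a
    2% tolerance, which indicates the calibration left its linear range.
    """
    if len(kl_fits) < 3:
        raise InputError("sensor_response needs >= 3 concentrations")
    fits = sorted(kl_fits, key=lambda f: f.conc_mM)
    conc_M = np.array([f.conc_mM for f in fits]) * 1e-3
    i_kl = np.array([f.i_KL_uA for f in fits])
    flagged = bool(np.any(np.diff(i_kl) < -0.02 * np.abs(i_kl[:-1])))
    if flagged:
        warnings.warn("KL-intercept currents not monotone in concentration")
    res = stats.linregress(conc_M, i_kl)
    return float(res.slope), flagged


def optimal_loading(series: list[tuple[float, float]]) -> tuple[float, float, bool]:
    """Loading with maximal sensor response.

    Returns (loading_mg, response_max, unsaturated_flag).  Ties break
    toward the lower loading (cheaper sensor).  A strictly increasing
    series is flagged unsaturated: the optimum may lie beyond the tested
    range.
    """
    if len(series) < 3:
        raise InputError("optimal_loading needs >= 3 loadings")
    srt = sorted(series, key=lambda t: t[0])
    responses = np.array([r for _, r in srt])
    best = int(np.argmax(responses))  # argmax returns the first (lowest loading) tie
    unsaturated = bool(np.all(np.diff(responses) > 0))
    if unsaturated:
        warnings.warn("sensor response still increasing at the highest loading")
    return float(srt[best][0]), float(srt[best][1]), unsaturated


def compare_k2_kcat(pairs: list[tuple[str, float, float]],
                    reference: str = "AvLOx"):
    """Rank immobilized (k2) against solution (kcat) rate constants.

    Returns a DataFrame with per-enzyme kcat and k2 ratios versus the
    reference enzyme plus a Spearman rank correlation between the two rate
    constants; the correlation quantifies how far solution turnover
    predicts sensor performance.
    """
    import pandas as pd

    if len(pairs) < 2:
        raise InputError("need >= 2 enzymes to compare")
    names = [p[0] for p in pairs]
    if reference not in names:
        raise InputError(f"reference enzyme {reference!r} missing")
    df = (pd.DataFrame(pairs, columns=["enzyme", "kcat_s", "k2_m_s"])
          .sort_values("enzyme", kind="stable").reset_index(drop=True))
    ref = df[df["enzyme"] == reference].iloc[0]
    df["kcat_ratio"] = df["kcat_s"] / ref["kcat_s"]
    df["k2_ratio"] = df["k2_m_s"] / ref["k2_m_s"]
    df["kcat_rank"] = df["kcat_s"].rank(ascending=False)
    df["k2_rank"] = df["k2_m_s"].rank(ascending=False)
    if df["kcat_s"].nunique() == 1 or df["k2_m_s"].nunique() == 1:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(df["kcat_s"], df["k2_m_s"]).statistic)
    df.attrs["spearman_rho"] = rho
    df.attrs["reference"] = reference
    return df
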