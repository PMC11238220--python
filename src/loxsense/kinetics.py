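"""Solution-phase enzyme kinetics: Michaelis–Menten and inhibition fits.

The module covers the biochemical half of sensor-enzyme characterization:

* Michaelis–Menten fits of replicated initial-rate data (apparent Km and
  kcat at ambient O2 — the two-substrate ping-pong mechanism is collapsed
  into apparent constants, which is what matters for a sensor operated in
  air);
* global fits of the four classical reversible-inhibition rate laws
  (competitive, uncompetitive, noncompetitive, mixed) with model selection
  by the extra-sum-of-squares F-test;
* relative-activity panels across electron acceptors/donors;
* pH activity windows and sigmoidal thermal-inactivation (T50) fits.

All fits are unweighted nonlinear least squares on the individual
replicate points (not their means), which preserves residual degrees of
freedom for the F-test.  Standard errors come from the Jacobian-based
covariance at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import ActivityProfile, RateDataset
from .errors import InputError

INHIBITION_MODELS = ("competitive", "uncompetitive", "noncompetitive", "mixed")

# Relative RSS floor below which a fit counts as "exact to numerical noise";
# used to short-circuit the F-test when both nested models interpolate the
# data (noiseless synthetic input), where the RSS ratio is pure round-off.
_RSS_FLOOR_REL = 1e-10


# --------------------------------------------------------------------------
# rate laws


def michaelis_menten(S, Vmax, Km):
    """v = Vmax·S/(Km+S)."""
    S = np.asarray(S, float)
    return Vmax * S / (Km + S)


def inhibition_rate(model: str, S, I, Vmax: float, Km: float, Ki: float,
                    alpha: float = 1.0):
    """Evaluate one of the four reversible-inhibition rate laws.

    competitive      v = Vmax·S / (Km·(1+I/Ki) + S)
    uncompetitive    v = Vmax·S / (Km + S·(1+I/Ki))
    noncompetitive   v = (Vmax/(1+I/Ki))·S / (Km + S)
    mixed            v = Vmax·S / (Km·(1+I/Ki) + S·(1+I/(alpha·Ki)))

    ``alpha`` is the mixed-model interaction factor weighting how strongly
    the inhibitor binds the enzyme–substrate complex relative to the free
    enzyme; mixed with alpha = 1 coincides with noncompetitive.
    """
    S = np.asarray(S, float)
    I = np.asarray(I, float)
    if (S < 0).any() or (I < 0).any():
        raise InputError("S and I must be >= 0")
    if model == "competitive":
        return Vmax * S / (Km * (1 + I / Ki) + S)
    if model == "uncompetitive":
        return Vmax * S / (Km + S * (1 + I / Ki))
    if model == "noncompetitive":
        return Vmax / (1 + I / Ki) * S / (Km + S)
    if model == "mixed":
        return Vmax * S / (Km * (1 + I / Ki) + S * (1 + I / (alpha * Ki)))
    raise InputError(f"unknown inhibition model {model!r}")


# --------------------------------------------------------------------------
# fit results


@dataclass
class MMFit:
    """Michaelis–Menten fit result (apparent constants)."""

    enzyme: str
    Km: float
    Km_se: float
    Vmax: float
    Vmax_se: float
    rate_units: str
    kcat: float | None
    kcat_se: float | None
    rss: float
    dof: int
    converged: bool
    message: str = ""

    @property
    def specificity(self) -> float | None:
        """kcat/Km in mM^-1 s^-1, the catalytic efficiency toward L-lactate."""
        if self.kcat is None:
            return None
        return self.kcat / self.Km


@dataclass
class InhibitionFit:
    """Global fit of one inhibition rate law over all (S, I) points."""

    enzyme: str
    model: str
    Vmax: float
    Vmax_se: float
    Km: float
    Km_se: float
    Ki: float
    Ki_se: float
    alpha: float | None
    alpha_se: float | None
    rss: float
    dof: int
    converged: bool
    message: str = ""

    @property
    def n_params(self) -> int:
        return 4 if self.model == "mixed" else 3


@dataclass
class ModelSelection:
    """Outcome of extra-sum-of-squares F-test selection among rate laws."""

    chosen_model: str
    alpha_level: float
    pairwise: list[tuple[str, str, float, float, str]] = field(default_factory=list)
    # (simpler, complex, F, p, winner)


@dataclass
class ThermalFit:
    """Two-parameter logistic fit of residual activity versus temperature."""

    enzyme: str
    T50: float
    T50_se: float
    width: float
    width_se: float
    rss: float
    dof: int
    converged: bool
    message: str = ""


@dataclass
class PHWindow:
    """Contiguous pH interval with relative activity above a threshold."""

    pH_low: float
    pH_high: float
    threshold_frac: float
    other_intervals: list[tuple[float, float]] = field(default_factory=list)


# --------------------------------------------------------------------------
# fitting machinery


def _curve_fit(fun, x, y, p0, seed_jitter: int = 0, n_restarts: int = 3):
    """curve_fit with jittered multi-start fallback.

    Returns (popt, pcov, converged, message).  The first attempt uses the
    supplied start; on failure up to ``n_restarts`` log-jittered starts are
    tried (deterministic jitter).
    """
    rng = np.random.default_rng(12345 + seed_jitter)
    starts = [np.asarray(p0, float)]
    for _ in range(n_restarts):
        starts.append(np.asarray(p0, float) * np.exp(rng.normal(0, 0.5, len(p0))))
    last_msg = ""
    for start in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(fun, x, y, p0=start, maxfev=20000)
        except (RuntimeError, ValueError) as exc:  # no convergence
            last_msg = str(exc)
            continue
        if np.all(np.isfinite(popt)) and np.all(popt > 0):
            return popt, pcov, True, ""
        last_msg = f"non-physical optimum {popt}"
    return None, None, False, last_msg or "fit failed"


def _param_se(pcov) -> np.ndarray:
    if pcov is None:
        return np.array([])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se = np.sqrt(np.diag(pcov))
    return se


def fit_michaelis_menten(data: RateDataset) -> MMFit:
    """Fit v = Vmax·S/(Km+S) to an uninhibited rate dataset.

    Replicates are fitted as individual points.  When the dataset carries
    rates in turnover units (s^-1) the fitted Vmax is kcat directly; for
    volumetric rates kcat is derived from the monomer enzyme concentration
    when available.
    """
    if (data.inhibitor != 0).any():
        raise InputError("fit_michaelis_menten requires all inhibitor_mM == 0")
    if data.n_substrate_levels < 5:
        raise InputError("need >= 5 distinct substrate concentrations")
    S, v = data.substrate, data.rate
    p0 = [float(np.max(v)), float(np.median(S))]
    popt, pcov, ok, msg = _curve_fit(
        lambda s, Vmax, Km: michaelis_menten(s, Vmax, Km), S, v, p0
    )
    if not ok:
        return MMFit(data.enzyme, np.nan, np.nan, np.nan, np.nan, data.rate_units,
                     None, None, np.nan, len(v) - 2, False, msg)
    Vmax, Km = popt
    se = _param_se(pcov)
    resid = v - michaelis_menten(S, Vmax, Km)
    rss = float(resid @ resid)
    dof = len(v) - 2
    # Km pinned at ~0 (all points saturating) leaves Km unidentifiable.
    if not np.all(np.isfinite(se)) or Km < 1e-6 * np.median(S):
        return MMFit(data.enzyme, Km, np.nan, Vmax, np.nan, data.rate_units,
                     None, None, rss, dof, False, "unidentifiable parameters")
    if data.rate_units == "per_s":
        kcat, kcat_se = Vmax, float(se[0])
    elif data.enzyme_conc_uM:
        # volumetric µM/min → s^-1 turnover per monomer
        f = 1.0 / (60.0 * data.enzyme_conc_uM)
        kcat, kcat_se = Vmax * f, float(se[0]) * f
    else:
        kcat = kcat_se = None
    return MMFit(data.enzyme, float(Km), float(se[1]), float(Vmax), float(se[0]),
                 data.rate_units, kcat, kcat_se, rss, dof, True)


def extra_ss_f_test(rss_simple: float, dof_simple: int,
                    rss_complex: float, dof_complex: int) -> tuple[float, float]:
    """Extra-sum-of-squares F-test between two nested least-squares fits.

    F = ((rss_simple - rss_complex)/(dof_simple - dof_complex)) /
        (rss_complex/dof_complex),
    with p from the F(dof_simple - dof_complex, dof_complex) distribution.
    A negative numerator (the simpler model fits better, possible only
    through numerical noise) clamps F to 0.
    """
    if dof_complex <= 0 or dof_simple <= dof_complex:
        raise InputError("need dof_simple > dof_complex > 0 (nested models)")
    if rss_simple < 0 or rss_complex < 0:
        raise InputError("RSS must be >= 0")
    d_dof = dof_simple - dof_complex
    if rss_simple <= rss_complex:
        return 0.0, 1.0
    if rss_complex == 0.0:
        return float("inf"), 0.0
    F = ((rss_simple - rss_complex) / d_dof) / (rss_complex / dof_complex)
    p = float(stats.f.sf(F, d_dof, dof_complex))
    return float(F), p


def fit_inhibition(data: RateDataset, alpha_level: float = 0.05
                   ) -> tuple[list[InhibitionFit], ModelSelection]:
    """Fit all four inhibition models globally and select one by F-test.

    Selection procedure: each 3-parameter law (competitive, uncompetitive,
    noncompetitive) is nested in the 4-parameter mixed law; mixed is chosen
    only if it significantly improves on the best-RSS 3-parameter law at
    ``alpha_level``; otherwise the best 3-parameter law wins.  When the
    simpler law already fits to numerical noise (RSS below 1e-10 of the
    total sum of squares) the improvement is declared non-significant —
    noiseless data generated from a simpler law would otherwise trip the
    F-test on round-off-sized RSS ratios.
    """
    if (data.inhibitor == 0).all():
        raise InputError("all inhibitor concentrations are zero: inhibition unidentifiable")
    nonzero_levels = np.unique(data.inhibitor[data.inhibitor > 0])
    if len(nonzero_levels) < 2:
        raise InputError("need >= 2 nonzero inhibitor levels for a global fit")
    S, I, v = data.substrate, data.inhibitor, data.rate
    tss = float(np.sum((v - v.mean()) ** 2))
    rss_floor = _RSS_FLOOR_REL * tss

    Vmax0 = float(np.max(v))
    Km0 = float(np.median(np.unique(S)))
    Ki0 = float(np.median(nonzero_levels))

    fits: list[InhibitionFit] = []
    for j, model in enumerate(INHIBITION_MODELS):
        if model == "mixed":
            fun = lambda x, Vmax, Km, Ki, alpha: inhibition_rate(
                "mixed", x[0], x[1], Vmax, Km, Ki, alpha)
            p0 = [Vmax0, Km0, Ki0, 1.0]
        else:
            fun = (lambda m: lambda x, Vmax, Km, Ki: inhibition_rate(
                m, x[0], x[1], Vmax, Km, Ki))(model)
            p0 = [Vmax0, Km0, Ki0]
        popt, pcov, ok, msg = _curve_fit(fun, (S, I), v, p0, seed_jitter=j)
        if not ok:
            fits.append(InhibitionFit(data.enzyme, model, *[np.nan] * 8,
                                      rss=np.inf, dof=len(v) - len(p0),
                                      converged=False, message=msg))
            continue
        se = _param_se(pcov)
        resid = v - fun((S, I), *popt)
        rss = float(resid @ resid)
        dof = len(v) - len(p0)
        alpha_val = float(popt[3]) if model == "mixed" else None
        alpha_se = float(se[3]) if model == "mixed" else None
        fits.append(InhibitionFit(
            data.enzyme, model,
            float(popt[0]), float(se[0]), float(popt[1]), float(se[1]),
            float(popt[2]), float(se[2]), alpha_val, alpha_se,
            rss, dof, True))

    by_model = {f.model: f for f in fits}
    mixed = by_model["mixed"]
    simple_fits = [by_model[m] for m in ("competitive", "uncompetitive", "noncompetitive")
                   if by_model[m].converged]
    pairwise = []
    best_simple = min(simple_fits, key=lambda f: f.rss) if simple_fits else None
    for f in simple_fits:
        if not mixed.converged:
            continue
        if f.rss <= rss_floor:
            F, p = 0.0, 1.0
        else:
            F, p = extra_ss_f_test(f.rss, f.dof, mixed.rss, mixed.dof)
        winner = "mixed" if p <= alpha_level else f.model
        pairwise.append((f.model, "mixed", F, p, winner))

    if best_simple is None:
        chosen = "mixed"
    elif not mixed.converged:
        chosen = best_simple.model
    else:
        entry = next(pw for pw in pairwise if pw[0] == best_simple.model)
        chosen = "mixed" if entry[4] == "mixed" else best_simple.model
    return fits, ModelSelection(chosen, alpha_level, pairwise)


# --------------------------------------------------------------------------
# activity panels and profiles


def relative_activity_panel(rates: pd.DataFrame,
                            reference: tuple[str, str] = ("O2", "L-lactate")
                            ) -> pd.DataFrame:
    """Express a (acceptor, donor, rate) table as percent of a reference.

    The reference condition (default O2 with L-lactate, the oxidase's
    native pair) is set to 100%.
    """
    required = {"electron_acceptor", "electron_donor", "rate"}
    if not required <= set(rates.columns):
        raise InputError(f"panel requires columns {sorted(required)}")
    if rates.empty:
        raise InputError("empty panel")
    if (rates["rate"] < 0).any():
        raise InputError("rates must be >= 0")
    mask = ((rates["electron_acceptor"] == reference[0])
            & (rates["electron_donor"] == reference[1]))
    if not mask.any():
        raise InputError(f"reference condition {reference} absent from panel")
    ref_rate = float(rates.loc[mask, "rate"].mean())
    if ref_rate == 0:
        raise InputError("reference rate is zero")
    out = rates.copy()
    out["relative_activity_pct"] = out["rate"] / ref_rate * 100.0
    return out


def ph_activity_window(profile: ActivityProfile,
                       threshold_frac: float = 0.8) -> PHWindow:
    """Contiguous measured-pH interval around the optimum with activity
    above ``threshold_frac`` of the maximum.

    Activities are normalized to the profile maximum (=100%); endpoints are
    reported on the measured pH grid (no interpolation), matching how pH
    optima are conventionally quoted at the assay's pH resolution.
    """
    if profile.axis != "pH":
        raise InputError("ph_activity_window needs a pH-axis profile")
    if len(profile.x) < 4:
        raise InputError("need >= 4 pH points")
    if not 0 < threshold_frac <= 1:
        raise InputError("threshold_frac must be in (0, 1]")
    rel = profile.activity_pct / profile.activity_pct.max() * 100.0
    above = rel >= threshold_frac * 100.0 - 1e-12
    imax = int(np.argmax(rel))
    # contiguous runs of above-threshold points
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))
    main = next(r for r in runs if r[0] <= imax <= r[1])
    others = [(float(profile.x[a]), float(profile.x[b]))
              for a, b in runs if (a, b) != main]
    if others:
        warnings.warn("multiple disjoint pH intervals above threshold; "
                      "returning the one containing the maximum")
    return PHWindow(float(profile.x[main[0]]), float(profile.x[main[1]]),
                    threshold_frac, others)


def thermal_sigmoid(T, T50, width):
    """Residual activity (%) = 100/(1+exp((T-T50)/width))."""
    return 100.0 / (1.0 + np.exp((np.asarray(T, float) - T50) / width))


def fit_thermal_inactivation(profile: ActivityProfile) -> ThermalFit:
    """Least-squares logistic fit of residual activity versus temperature.

    The upper and lower asymptotes are fixed at 100% and 0%; T50 is the
    temperature of half-inactivation after the fixed incubation time.
    """
    if profile.axis != "temperature_C":
        raise InputError("fit_thermal_inactivation needs a temperature-axis profile")
    T, a = profile.x, profile.activity_pct
    if len(T) < 5:
        raise InputError("need >= 5 temperature points")
    # start T50 where activity crosses 50%
    below = np.nonzero(a <= 50.0)[0]
    T50_0 = float(T[below[0]]) if below.size and below[0] > 0 else float(np.median(T))
    p0 = [T50_0, 2.0]

    def fun(t, T50, width):
        return thermal_sigmoid(t, T50, width)

    popt, pcov, ok, msg = _curve_fit(fun, T, a, p0)
    dof = len(T) - 2
    if not ok:
        return ThermalFit(profile.enzyme, np.nan, np.nan, np.nan, np.nan,
                          np.nan, dof, False, msg)
    T50, width = popt
    se = _param_se(pcov)
    resid = a - fun(T, *popt)
    rss = float(resid @ resid)
    if not np.all(np.isfinite(se)) or not (T.min() <= T50 <= T.max()):
        return ThermalFit(profile.enzyme, float(T50), np.nan, float(width), np.nan,
                          rss, dof, False, "T50 outside observed range or SE undefined")
    return ThermalFit(profile.enzyme, float(T50), float(se[0]),
                      float(width), float(se[1]), rss, dof, True)
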