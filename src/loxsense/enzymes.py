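"""Reference panel of characterized FMN-dependent L-lactate oxidases.

Apparent steady-state constants (ambient O2, pH 7.4, 30 °C), pyruvate
inhibition constants (mixed inhibition throughout) and half-inactivation
temperatures for eight L-lactate oxidases, including the commercial
Aerococcus viridans enzyme (AvLOx) that serves as the field's reference.
These constants parameterize the synthetic-data generators and serve as
ground truths for parameter-recovery checks.

``specificity_printed`` is the kcat/Km ratio as conventionally reported,
rounded to an integer in mM^-1 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class EnzymeRecord:
    name: str
    km_mM: float
    km_se: float
    kcat_s: float
    kcat_se: float
    specificity_printed: int
    ki_mM: float
    ki_se: float
    inhibition_type: str
    t50_C: float


REFERENCE_ENZYMES: dict[str, EnzymeRecord] = {
    rec.name: rec
    for rec in [
        EnzymeRecord("SdLOx", 0.62, 0.07, 14.06, 0.31, 23, 2.04, 0.54, "mixed", 42.5),
        EnzymeRecord("SaLOx", 0.95, 0.27, 6.66, 0.46, 7, 0.86, 0.49, "mixed", 36.6),
        EnzymeRecord("CvLOx", 0.38, 0.04, 41.42, 0.87, 110, 12.78, 5.85, "mixed", 38.2),
        EnzymeRecord("EhmLOx", 0.92, 0.18, 52.04, 1.64, 57, 1.78, 1.91, "mixed", 54.0),
        EnzymeRecord("CiLOx", 0.58, 0.13, 25.60, 0.87, 44, 2.89, 1.41, "mixed", 48.6),
        EnzymeRecord("MpLOx", 0.31, 0.10, 51.26, 3.48, 168, 9.21, 1.67, "mixed", 37.4),
        EnzymeRecord("AsLOx", 2.11, 0.21, 48.39, 1.36, 23, 14.11, 2.42, "mixed", 42.2),
        EnzymeRecord("AvLOx", 0.33, 0.05, 46.26, 1.20, 140, 7.94, 0.90, "mixed", 54.9),
    ]
}

#: Enzymes whose printed specificity ratio is exactly reproduced by
#: kcat/Km computed from the printed two-decimal constants (CvLOx and
#: MpLOx are excluded: their printed ratios carry more precision than the
#: rounded inputs support).
SPECIFICITY_CONSISTENT = ("SdLOx", "SaLOx", "EhmLOx", "CiLOx", "AsLOx", "AvLOx")

#: Enzyme loadings (mg) used when screening immobilized enzyme amounts.
LOADING_SERIES_MG = (
    0.007, 0.014, 0.021, 0.035, 0.040, 0.050,
    0.060, 0.070, 0.112, 0.140, 0.252, 0.280,
)
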