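"""Reference constants and measurements for the packaged worked example.

The bundled scenario is a chemostat culture of *Enterococcus faecalis*
(ATCC 29212) grown on Trypticase Soy Broth (TSB).  Substrate concentrations
are expressed as fractions of full-strength TSB.  Kinetic constants were
measured from a static-culture dilution series; biofilm cell densities were
counted on glass slides after 24 h exposures at three dilution rates.
"""

from __future__ import annotations

from .biofilm import BiofilmObservation
from .chemostat import ChemostatConfig
from .monod import MonodParameters

__all__ = [
    "REFERENCE_PARAMS",
    "CASE1_SR",
    "CASE2_SR",
    "EXPERIMENT_DILUTION_RATES",
    "VESSEL_VOLUME_ML",
    "reference_config",
    "reference_biofilm_observations",
]

#: Monod constants for E. faecalis on TSB: mu_max = 1.07 h^-1, Ks = 0.019
#: (fraction of full-strength medium), yield Y = 0.4.
REFERENCE_PARAMS = MonodParameters(mu_max=1.07, Ks=0.019, Y=0.4)

#: Case 1: nutrient-rich inflow, 4x full-strength TSB (keeps biomass positive
#: over the whole dilution-rate range up to mu_max).
CASE1_SR = 4.0
#: Case 2: nutrient-restricted inflow, 1/16 TSB = 0.0625 rounded to 0.06,
#: about 3x the saturation constant.  This is the bench condition.
CASE2_SR = 0.06

#: Dilution rates (h^-1) at which the bench chemostat was run.
EXPERIMENT_DILUTION_RATES = (0.09, 0.28, 0.81)

#: Working volume of the bench vessel, mL (metadata only).
VESSEL_VOLUME_ML = 57.0

_CASE_SR = {"case1": CASE1_SR, "case2": CASE2_SR}


def reference_config(case: str = "case2", D: float = 0.0) -> ChemostatConfig:
    """Chemostat config preset: ``case1`` (rich inflow) or ``case2`` (restricted)."""
    key = case.lower().replace("reference-", "")
    if key not in _CASE_SR:
        raise ValueError(f"unknown case {case!r}; expected 'case1' or 'case2'")
    return ChemostatConfig(
        Sr=_CASE_SR[key], D=D, params=REFERENCE_PARAMS, volume_ml=VESSEL_VOLUME_ML
    )


def reference_biofilm_observations() -> list[BiofilmObservation]:
    """Measured 24-h biofilm assays at the three bench dilution rates.

    Mean attached-cell densities (cells cm^-2) over the counted confocal
    stacks, with the non-viable (membrane-compromised) fraction of the total
    count.  Per-stack standard deviations were not reported numerically.
    """
    return [
        BiofilmObservation(
            D=0.09, exposure_h=24.0, mean_density=3.78e6,
            n_stacks=7, nonviable_fraction=0.722,
        ),
        BiofilmObservation(
            D=0.28, exposure_h=24.0, mean_density=5.54e7,
            n_stacks=7, nonviable_fraction=0.008,
        ),
        BiofilmObservation(
            D=0.81, exposure_h=24.0, mean_density=7.94e7,
            n_stacks=4, nonviable_fraction=0.043,
        ),
    ]
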