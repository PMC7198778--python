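"""qPCR standard curves, amplification efficiency, and soil gene abundances.

A standard curve is OLS of Cq on log10 plasmid copies over a serial dilution;
amplification efficiency E = 10^(-1/slope) - 1 (E = 1 for perfect doubling,
slope -3.3219).  Unknowns are quantified by inverting the curve and scaling
from the reaction to copies per gram dry soil:

    copies/g = 10^((Cq - intercept)/slope) * dilution * (elution/template) / dry mass

where dry mass corrects the wet extraction input by a moisture fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["StandardCurve", "AbundanceEstimate", "fit_standard_curve", "quantify",
           "quantify_replicates", "cq_from_copies"]

PERFECT_SLOPE = -1.0 / np.log10(2.0)   # -3.3219...: exact doubling per cycle


class QPCRError(ValueError):
    """Invalid qPCR input."""


@dataclass(frozen=True)
class StandardCurve:
    gene: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    log10_range: tuple[float, float]

    @property
    def quality_ok(self) -> bool:
        """Conventional quality bar: R^2 > 0.99."""
        return self.r_squared > 0.99


@dataclass
class AbundanceEstimate:
    sample_id: str
    gene: str
    copies_per_g: float
    cv: float | None = None
    extrapolated: bool = False


def fit_standard_curve(
    points: list[tuple[float, float]], gene: str = ""
) -> StandardCurve:
    """Fit Cq = intercept + slope * log10(copies) over a dilution series.

    Requires >= 3 points spanning at least 2 orders of magnitude; a positive
    slope is rejected outright, and R^2 <= 0.99 triggers a quality warning.
    """
    if len(points) < 3:
        raise QPCRError("need >= 3 dilution points")
    log_copies = np.asarray([p[0] for p in points], dtype=float)
    cq = np.asarray([p[1] for p in points], dtype=float)
    if log_copies.max() - log_copies.min() < 2.0:
        raise QPCRError("dilution series must span >= 2 orders of magnitude")
    res = stats.linregress(log_copies, cq)
    if res.slope >= 0:
        raise QPCRError(f"positive slope {res.slope:.3f}: invalid standard curve")
    efficiency = 10.0 ** (-1.0 / res.slope) - 1.0
    r2 = float(res.rvalue**2)
    if r2 <= 0.99:
        warnings.warn(f"standard-curve R^2 = {r2:.4f} <= 0.99", stacklevel=2)
    return StandardCurve(
        gene=gene, slope=float(res.slope), intercept=float(res.intercept),
        r_squared=r2, efficiency=float(efficiency),
        log10_range=(float(log_copies.min()), float(log_copies.max())),
    )


def cq_from_copies(copies_in_reaction: float, curve: StandardCurve) -> float:
    """Expected Cq for a given template amount (generator-side inverse)."""
    if copies_in_reaction <= 0:
        raise QPCRError("copies must be positive")
    return curve.intercept + curve.slope * np.log10(copies_in_reaction)


def quantify(
    cq: float,
    curve: StandardCurve,
    dilution: float = 20.0,
    extraction_mass_g: float = 0.5,
    elution_volume_ul: float | None = None,
    template_volume_ul: float = 2.0,
    moisture_fraction: float = 0.0,
    sample_id: str = "",
    ntc_cutoff: float = 35.0,
) -> AbundanceEstimate:
    """Copies per gram dry soil from one Cq.

    ``elution_volume_ul`` has no defensible default (extraction kits differ)
    and must be supplied.  ``moisture_fraction`` converts the wet extraction
    input to a dry-mass basis so abundances share units with process rates.
    Cq outside the curve's calibrated range triggers an extrapolation flag and
    warning; Cq above ``ntc_cutoff`` is treated as no-template-like and
    warned about.
    """
    if elution_volume_ul is None:
        raise QPCRError("elution_volume_ul is required (no kit default is assumed)")
    if min(dilution, extraction_mass_g, elution_volume_ul, template_volume_ul) <= 0:
        raise QPCRError("dilution, masses and volumes must be positive")
    if not 0 <= moisture_fraction < 1:
        raise QPCRError("moisture_fraction must be in [0, 1)")
    log_copies = (cq - curve.intercept) / curve.slope
    lo, hi = curve.log10_range
    extrapolated = not (lo <= log_copies <= hi)
    if extrapolated:
        warnings.warn(
            f"Cq {cq:.2f} outside calibrated range (log10 copies {lo:.1f}-{hi:.1f})",
            stacklevel=2,
        )
    if cq > ntc_cutoff:
        warnings.warn(f"Cq {cq:.2f} beyond NTC cutoff {ntc_cutoff}", stacklevel=2)
    copies_reaction = 10.0**log_copies
    dry_mass = extraction_mass_g * (1.0 - moisture_fraction)
    copies_per_g = copies_reaction * dilution * (elution_volume_ul / template_volume_ul) / dry_mass
    return AbundanceEstimate(sample_id, curve.gene, float(copies_per_g),
                             extrapolated=extrapolated)


def quantify_replicates(
    cqs: list[float], curve: StandardCurve, **kwargs
) -> AbundanceEstimate:
    """Technical-replicate quantification: mean copies with CV on copies.

    The CV is computed on back-transformed copy numbers (not on Cq), the scale
    on which abundances are reported.
    """
    if not cqs:
        raise QPCRError("no Cq values supplied")
    ests = [quantify(c, curve, **kwargs) for c in cqs]
    copies = np.array([e.copies_per_g for e in ests])
    mean = float(copies.mean())
    cv = float(copies.std(ddof=1) / mean) if len(copies) > 1 and mean > 0 else 0.0
    return AbundanceEstimate(
        ests[0].sample_id, curve.gene, mean, cv=cv,
        extrapolated=any(e.extrapolated for e in ests),
    )
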