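"""Linear spot-area model and the hematocrit-bias algebra built on it.

Blood viscosity rises with hematocrit (Ht), so a fixed deposited volume
spreads over a smaller area on the filter card at high Ht.  A fixed-size
sub-punch from a smaller spot contains more blood, which biases any
concentration quantified against calibrators prepared at a different
hematocrit (``ht_cal``).  With a linear area law

    A(Ht) = intercept + slope * Ht        (slope < 0, area in cm^2)

the punch bias is the area ratio ``A(ht_cal) / A(ht_sample)`` and everything
in this module follows algebraically:

* ``correction_factor``   — A(ht_sample)/A(ht_cal); multiplying a measured
  concentration by it removes the Ht bias,
* ``relative_error_pct``  — the signed percentage error left uncorrected,
  100 * (A(ht_cal)/A(ht_sample) - 1),
* ``ht_band_for_error``   — the Ht interval within which |relative error|
  stays below a stated level, obtained by analytic inversion,
* ``correct_concentration`` — the corrected ("theoretical") concentration.

Hematocrit is expressed in percentage points throughout (a value of 50
means 50%); fractional inputs in (0, 1] are rejected with a hint rather
than silently rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import round_half_away

__all__ = [
    "DispersionModel",
    "ToleranceBand",
    "spot_area",
    "correction_factor",
    "relative_error_pct",
    "ht_band_for_error",
    "correct_concentration",
]


@dataclass(frozen=True)
class DispersionModel:
    """Linear law mapping sample hematocrit to dried-spot area.

    Parameters
    ----------
    slope
        Change in spot area per Ht percentage point, cm^2 / Ht%. Must be
        negative: higher Ht means more viscous blood and a smaller spot.
    intercept
        Extrapolated spot area at Ht 0, cm^2.
    deposited_volume_ul
        Blood volume deposited per spot, in microlitres. Metadata only.
    substrate_label
        Filter-card substrate the coefficients were fitted on. Metadata only.
    ht_domain
        Closed Ht interval (percentage points) over which the linear law is
        considered applicable. The default spans the individual hematocrit
        range established for newborns, including anemic and polycythemic
        extremes.
    """

    slope: float = -0.0070
    intercept: float = 1.32
    deposited_volume_ul: float = 50.0
    substrate_label: str = "Whatman 903"
    ht_domain: tuple[float, float] = (20.0, 70.0)

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ValueError(f"slope must be negative (got {self.slope})")
        if not self.intercept > 0:
            raise ValueError(f"intercept must be positive (got {self.intercept})")
        lo, hi = self.ht_domain
        if not (0 < lo < hi < 100):
            raise ValueError(
                f"ht_domain must satisfy 0 < low < high < 100 (got {self.ht_domain})"
            )
        if self.intercept + self.slope * hi <= 0:
            raise ValueError(
                "spot area is non-positive at the upper end of ht_domain; "
                "model coefficients and domain are inconsistent"
            )

    @property
    def ht_at_zero_area(self) -> float:
        """Ht at which the linear law extrapolates to zero area (model ceiling)."""
        return -self.intercept / self.slope


@dataclass(frozen=True)
class ToleranceBand:
    """Ht interval within which |Ht-attributable relative error| <= error_level.

    ``ht_low`` and ``ht_high`` are stored unrounded; use :meth:`rounded` for
    the 2-decimal display convention.
    """

    error_level: float  # %, positive
    ht_cal: float  # Ht %
    ht_low: float  # Ht %
    ht_high: float  # Ht %

    def __post_init__(self) -> None:
        if not self.error_level > 0:
            raise ValueError("error_level must be positive")
        if not self.ht_low < self.ht_cal < self.ht_high:
            raise ValueError(
                f"band must bracket ht_cal: {self.ht_low} < {self.ht_cal} < {self.ht_high}"
            )

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        """Band endpoints rounded half-away-from-zero for display."""
        return (round_half_away(self.ht_low, ndigits), round_half_away(self.ht_high, ndigits))

    def contains(self, ht) -> bool | np.ndarray:
        """Whether a sample Ht lies inside the band (correction can be omitted)."""
        ht = np.asarray(ht, dtype=float)
        out = (ht >= self.ht_low) & (ht <= self.ht_high)
        return bool(out) if out.ndim == 0 else out


DEFAULT_MODEL = DispersionModel()


def _as_ht(ht, validate: bool) -> np.ndarray:
    arr = np.asarray(ht, dtype=float)
    if validate:
        if np.any((arr > 0) & (arr <= 1)):
            raise ValueError(
                "hematocrit looks like a fraction; pass percentage points "
                "(e.g. 45 for 45%), not 0.45"
            )
        if np.any((arr < 0) | (arr > 100)):
            raise ValueError("hematocrit must lie in [0, 100] percentage points")
    return arr


def _scalar_or_array(arr: np.ndarray):
    return float(arr) if arr.ndim == 0 else arr


def spot_area(ht, model: DispersionModel = DEFAULT_MODEL, *, validate: bool = True):
    """Dried-spot area (cm^2) predicted for a sample of hematocrit ``ht``.

    Strictly decreasing in ``ht``.  Raises if the predicted area is
    non-positive, which signals a nonsensical model/Ht combination.
    ``validate=False`` skips the percentage-points input checks (used
    internally on simulated cohorts, whose rare extreme draws are still
    evaluated rather than dropped).
    """
    arr = _as_ht(ht, validate)
    area = model.intercept + model.slope * arr
    if np.any(area <= 0):
        raise ValueError(
            f"non-positive spot area for Ht >= {model.ht_at_zero_area:.1f}; "
            "model does not apply"
        )
    return _scalar_or_array(area)


def correction_factor(
    ht_sample,
    ht_cal: float,
    model: DispersionModel = DEFAULT_MODEL,
    *,
    validate: bool = True,
):
    """Sample-specific correction factor: area ratio of unknown to calibrator.

    CF = A(ht_sample) / A(ht_cal).  Greater than 1 for samples with lower Ht
    than the calibrators (their blood spreads further, so the punch holds
    less blood and the measured concentration underestimates the truth);
    reciprocal under swapping the two arguments.
    """
    a_s = spot_area(ht_sample, model, validate=validate)
    a_c = spot_area(ht_cal, model, validate=validate)
    return _scalar_or_array(np.asarray(a_s / a_c))


def relative_error_pct(
    ht_sample,
    ht_cal: float,
    model: DispersionModel = DEFAULT_MODEL,
    *,
    validate: bool = True,
):
    """Signed % relative error attributable to the Ht effect alone.

    RE(ht) = 100 * (A(ht_cal)/A(ht_sample) - 1) = 100 * (1/CF - 1).
    Zero at ht_sample == ht_cal and strictly increasing in ht_sample:
    high-Ht samples read high, low-Ht samples read low.
    """
    cf = np.asarray(correction_factor(ht_sample, ht_cal, model, validate=validate))
    return _scalar_or_array(100.0 * (1.0 / cf - 1.0))


def ht_band_for_error(
    error_level: float,
    ht_cal: float,
    model: DispersionModel = DEFAULT_MODEL,
) -> ToleranceBand:
    """Invert the relative-error law into a safe Ht band around ``ht_cal``.

    Solves A(ht_cal)/A(ht) = 1 +/- error_level/100 analytically:
    A_target = A(ht_cal) / (1 +/- level/100) and
    Ht = (intercept - A_target) / |slope|.  Within the returned band the
    Ht-attributable error stays within +/-error_level % and concentration
    correction can be omitted.
    """
    if not 0 < error_level < 100:
        raise ValueError("error_level must be in (0, 100) percent")
    lo, hi = model.ht_domain
    if not lo <= ht_cal <= hi:
        raise ValueError(f"ht_cal {ht_cal} outside model ht_domain {model.ht_domain}")
    a_cal = spot_area(ht_cal, model)
    frac = error_level / 100.0
    # positive error at high Ht (small area), negative at low Ht (large area)
    area_at_high = a_cal / (1.0 + frac)
    area_at_low = a_cal / (1.0 - frac)
    ht_high = (model.intercept - area_at_high) / abs(model.slope)
    ht_low = (model.intercept - area_at_low) / abs(model.slope)
    if not (0 <= ht_low and ht_high <= 100):
        raise ValueError(
            f"tolerance band ({ht_low:.2f}, {ht_high:.2f}) leaves [0, 100] Ht; "
            "this error level is unattainable for the given model"
        )
    return ToleranceBand(error_level=error_level, ht_cal=ht_cal, ht_low=ht_low, ht_high=ht_high)


def correct_concentration(
    c_exp,
    ht_sample,
    ht_cal: float,
    model: DispersionModel = DEFAULT_MODEL,
    *,
    validate: bool = True,
):
    """Ht-corrected ("theoretical") concentration C_theor = C_exp * CF.

    Raises on negative experimental concentrations.  The corrected value is
    higher than measured for low-Ht samples and lower for high-Ht samples.
    """
    c = np.asarray(c_exp, dtype=float)
    if np.any(c < 0):
        raise ValueError("experimental concentration must be non-negative")
    cf = np.asarray(correction_factor(ht_sample, ht_cal, model, validate=validate))
    return _scalar_or_array(c * cf)
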