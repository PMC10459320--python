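"""Virtual neonate cohorts and Monte Carlo analysis of the hematocrit effect.

Neonatal hematocrit depends strongly on gestational age at birth and on the
post-natal day of sampling: term babies start around 53% at birth and drift
down to ~38% by day 28, preterm babies start lower and fall faster.  This
module carries the reference demographics for the two gestational groups
(term = 35-42 weeks including late preterm; preterm = 29-34 weeks) at the
seven standard sampling days, models each subpopulation's Ht as
Normal(mean, 6), and asks, for a given calibration hematocrit:

* how is the Ht-attributable relative error distributed in the cohort
  (:func:`re_distribution`),
* how does the mean error move as the calibration Ht is varied
  (:func:`sweep_ht_cal` — the curve whose zero crossing is the ideal
  calibration Ht for that subpopulation),
* what fraction of babies falls outside the safe Ht band and would need
  concentration correction (:func:`probability_of_correction`, Monte Carlo
  or closed-form normal).

Sex is recorded nowhere: the reference data show no sex effect on neonatal
Ht, so male/female balance has no computational consequence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .dispersion import DEFAULT_MODEL, DispersionModel, ht_band_for_error, relative_error_pct

__all__ = [
    "GestationalGroup",
    "NeonateSubpopulation",
    "SimulationResult",
    "POSTNATAL_DAYS",
    "DEFAULT_SD_HT",
    "reference_subpopulation",
    "reference_registry",
    "simulate_cohort",
    "re_distribution",
    "sweep_ht_cal",
    "zero_crossing",
    "probability_of_correction",
]


class GestationalGroup(str, enum.Enum):
    """Gestational age group: term covers 35-42 weeks (incl. late preterm),
    preterm covers 29-34 weeks.  Below 29 weeks no reference ranges exist."""

    TERM = "term"
    PRETERM = "preterm"


POSTNATAL_DAYS: tuple[int, ...] = (0, 1, 2, 3, 7, 14, 28)

DEFAULT_SD_HT = 6.0

# Mean reference hematocrit (%) per gestational group and post-natal day,
# from published neonatal reference ranges (41,910 neonates); the SD is 6
# at every timepoint, roughly one quarter of the range of the data.
_REFERENCE_MEAN_HT: dict[GestationalGroup, dict[int, float]] = {
    GestationalGroup.TERM: {0: 53, 1: 51, 2: 50, 3: 49, 7: 45, 14: 42, 28: 38},
    GestationalGroup.PRETERM: {0: 50, 1: 49, 2: 47, 3: 45, 7: 44, 14: 38, 28: 31},
}


@dataclass(frozen=True)
class NeonateSubpopulation:
    """A gestational group at a given post-natal day, with its Ht distribution.

    ``sd_ht = 0`` is permitted as a degenerate (all-identical) cohort for
    analytic sanity checks; the reference registry always uses SD 6.
    """

    gestational_group: GestationalGroup
    postnatal_day: int
    mean_ht: float
    sd_ht: float = DEFAULT_SD_HT

    def __post_init__(self) -> None:
        if self.postnatal_day not in POSTNATAL_DAYS:
            raise ValueError(
                f"postnatal_day must be one of {POSTNATAL_DAYS} (got {self.postnatal_day})"
            )
        if not 0 < self.mean_ht < 100:
            raise ValueError(f"mean_ht must be in (0, 100) (got {self.mean_ht})")
        if self.sd_ht < 0:
            raise ValueError("sd_ht must be non-negative")

    @property
    def label(self) -> str:
        return f"{self.gestational_group.value} day {self.postnatal_day}"


def reference_subpopulation(
    group: GestationalGroup | str,
    postnatal_day: int,
    sd_ht: float = DEFAULT_SD_HT,
) -> NeonateSubpopulation:
    """Look up the built-in reference demographics for a group/day."""
    group = GestationalGroup(group)
    try:
        mean = _REFERENCE_MEAN_HT[group][postnatal_day]
    except KeyError:
        raise ValueError(
            f"no reference hematocrit for {group.value} day {postnatal_day}; "
            f"available days: {POSTNATAL_DAYS}"
        ) from None
    return NeonateSubpopulation(group, postnatal_day, mean_ht=mean, sd_ht=sd_ht)


def reference_registry(sd_ht: float = DEFAULT_SD_HT) -> list[NeonateSubpopulation]:
    """All 14 built-in subpopulations (2 gestational groups x 7 days)."""
    return [
        reference_subpopulation(group, day, sd_ht)
        for group in GestationalGroup
        for day in POSTNATAL_DAYS
    ]


SUMMARY_QUANTILES: tuple[float, ...] = (5.0, 25.0, 50.0, 75.0, 95.0)


@dataclass(frozen=True)
class RelativeErrorSummary:
    """Distribution summary of Ht-attributable relative errors in a cohort."""

    mean: float
    sd: float
    quantiles: dict[float, float]
    n: int


@dataclass(frozen=True)
class SimulationResult:
    """One simulated scenario: a subpopulation evaluated at one ht_cal."""

    subpopulation: NeonateSubpopulation
    ht_cal: float
    n_subjects: int
    seed: int | None
    relative_error: RelativeErrorSummary
    probability_of_correction: float | None = None
    method: str = "monte_carlo"

    def __post_init__(self) -> None:
        p = self.probability_of_correction
        if p is not None and not 0.0 <= p <= 1.0:
            raise ValueError("probability_of_correction must be in [0, 1]")
        if self.method == "monte_carlo" and self.n_subjects <= 0:
            raise ValueError("monte_carlo results require n_subjects > 0")


def simulate_cohort(
    subpop: NeonateSubpopulation,
    n: int,
    seed: int | np.random.Generator,
    *,
    truncate_to: tuple[float, float] | None = None,
) -> np.ndarray:
    """Draw ``n`` virtual subjects' Ht values from Normal(mean_ht, sd_ht).

    A seed (or a Generator) is mandatory: there is no implicit global
    randomness anywhere in the package.  By default draws are NOT truncated
    to a physiological range — with SD 6 the impossible tail mass is
    negligible and truncation would silently bias downstream probabilities;
    pass ``truncate_to=(20, 70)`` for a sensitivity analysis.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if truncate_to is None:
        return rng.normal(subpop.mean_ht, subpop.sd_ht, size=n)
    lo, hi = truncate_to
    if subpop.sd_ht == 0:
        if not lo <= subpop.mean_ht <= hi:
            raise ValueError("degenerate cohort mean lies outside the truncation range")
        return np.full(n, float(subpop.mean_ht))
    a = (lo - subpop.mean_ht) / subpop.sd_ht
    b = (hi - subpop.mean_ht) / subpop.sd_ht
    return stats.truncnorm.rvs(a, b, loc=subpop.mean_ht, scale=subpop.sd_ht, size=n, random_state=rng)


def re_distribution(
    cohort: np.ndarray,
    ht_cal: float,
    model: DispersionModel = DEFAULT_MODEL,
    *,
    quantiles: Sequence[float] = SUMMARY_QUANTILES,
) -> RelativeErrorSummary:
    """Elementwise relative error of a cohort against ``ht_cal``, summarised.

    No subject is dropped: Ht draws outside the model's nominal domain are
    still evaluated (the linear law extrapolates harmlessly until the
    predicted area reaches zero, far beyond any physiological Ht).
    """
    cohort = np.asarray(cohort, dtype=float)
    if cohort.size == 0:
        raise ValueError("cohort must be non-empty")
    re = np.asarray(relative_error_pct(cohort, ht_cal, model, validate=False))
    qs = np.percentile(re, list(quantiles))
    return RelativeErrorSummary(
        mean=float(re.mean()),
        sd=float(re.std(ddof=1)) if re.size > 1 else 0.0,
        quantiles={float(q): float(v) for q, v in zip(quantiles, qs)},
        n=int(re.size),
    )


def sweep_ht_cal(
    subpop: NeonateSubpopulation,
    ht_cal_grid: Iterable[float],
    n: int,
    seed: int,
    model: DispersionModel = DEFAULT_MODEL,
    *,
    resample_per_point: bool = False,
) -> list[SimulationResult]:
    """Mean relative error of one subpopulation across a grid of ht_cal values.

    By default one cohort is drawn and re-evaluated at every grid point
    (the grid only moves the calibrator, not the babies); with
    ``resample_per_point`` a fresh seeded cohort is drawn per point.
    The resulting mean-error curve is strictly decreasing in ht_cal and its
    zero crossing sits just above the subpopulation mean.
    """
    grid = [float(g) for g in ht_cal_grid]
    if not grid:
        raise ValueError("ht_cal_grid must be non-empty")
    results: list[SimulationResult] = []
    if resample_per_point:
        child_seeds = np.random.SeedSequence(seed).spawn(len(grid))
        cohorts = [
            simulate_cohort(subpop, n, np.random.default_rng(s)) for s in child_seeds
        ]
    else:
        cohorts = [simulate_cohort(subpop, n, seed)] * len(grid)
    for ht_cal, cohort in zip(grid, cohorts):
        summary = re_distribution(cohort, ht_cal, model)
        results.append(
            SimulationResult(
                subpopulation=subpop,
                ht_cal=ht_cal,
                n_subjects=n,
                seed=seed,
                relative_error=summary,
            )
        )
    return results


def zero_crossing(results: Sequence[SimulationResult]) -> float:
    """Linearly interpolated ht_cal at which the mean relative error is zero.

    The ideal calibration hematocrit for the swept subpopulation.  Requires
    the sweep to bracket zero; the curve is monotone decreasing in ht_cal.
    """
    pts = sorted(results, key=lambda r: r.ht_cal)
    x = np.array([r.ht_cal for r in pts])
    y = np.array([r.relative_error.mean for r in pts])
    sign_change = np.nonzero(np.diff(np.sign(y)) != 0)[0]
    if len(sign_change) == 0:
        raise ValueError("mean relative error does not change sign over the grid")
    i = int(sign_change[0])
    x0, x1, y0, y1 = x[i], x[i + 1], y[i], y[i + 1]
    if y0 == 0:
        return float(x0)
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def probability_of_correction(
    subpop: NeonateSubpopulation,
    ht_cal: float,
    tolerance_level: float,
    model: DispersionModel = DEFAULT_MODEL,
    *,
    method: str = "analytic",
    n: int = 1_000_000,
    seed: int | None = None,
    truncate_to: tuple[float, float] | None = None,
) -> float:
    """Fraction of the subpopulation whose Ht leaves the safe tolerance band.

    A subject outside the band accumulates more than ``tolerance_level`` %
    Ht-attributable error, so its concentration would need correction.
    ``method='analytic'`` evaluates P(Ht < ht_low) + P(Ht > ht_high) under
    the normal law; ``method='monte_carlo'`` counts simulated subjects
    outside the band and needs a seed.  The two agree to within binomial
    Monte Carlo error.
    """
    if tolerance_level <= 0:
        raise ValueError("tolerance_level must be positive")
    band = ht_band_for_error(tolerance_level, ht_cal, model)
    if method == "analytic":
        if subpop.sd_ht == 0:
            return 0.0 if band.contains(subpop.mean_ht) else 1.0
        dist = stats.norm(loc=subpop.mean_ht, scale=subpop.sd_ht)
        p = dist.cdf(band.ht_low) + dist.sf(band.ht_high)
        if truncate_to is not None:
            lo, hi = truncate_to
            inside = dist.cdf(hi) - dist.cdf(lo)
            p_trunc = (max(dist.cdf(band.ht_low) - dist.cdf(lo), 0.0)
                       + max(dist.cdf(hi) - dist.cdf(band.ht_high), 0.0))
            p = p_trunc / inside
        return float(p)
    if method == "monte_carlo":
        if seed is None:
            raise ValueError("monte_carlo method requires a seed")
        ht = simulate_cohort(subpop, n, seed, truncate_to=truncate_to)
        return float(np.mean(~band.contains(ht)))
    raise ValueError(f"unknown method {method!r}; use 'analytic' or 'monte_carlo'")
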