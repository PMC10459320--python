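"""Synthetic screening cohorts with a known hematocrit-bias mechanism.

The real national screening dataset behind the cut-off panel is not public,
so pipelines are exercised on generated cohorts that carry the same
statistical structure the analysis assumes:

* hematocrit drawn from a mixture of neonate subpopulations (normal per
  component), optionally with enforced anemic (Ht < 35) and polycythemic
  (Ht > 65) quotas,
* per marker, a planted number of definite positives and alert-zone cases
  at known locations, against a log-normal negative background kept
  strictly clear of the alert zone,
* a measurement-bias mechanism that is the exact inverse of the correction
  factor:  C_measured = C_true * A(ht_cal_true) / A(ht_sample).

Because the bias is the algebraic inverse of the correction, correcting a
generated dataset with the true calibration hematocrit must recover the
true concentrations to machine precision (:func:`recovery_check`) — the
core identifiability property of the whole analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import NeonateSubpopulation
from .dispersion import DEFAULT_MODEL, DispersionModel, correct_concentration, spot_area
from .screening import Direction, MarkerDefinition, ScreeningSample, alert_zone_bounds

__all__ = [
    "CohortRecipe",
    "SyntheticSample",
    "InfeasibleRecipeError",
    "generate_screening_dataset",
    "recovery_check",
    "write_samples_csv",
    "write_truth_csv",
    "samples_to_frame",
]


class InfeasibleRecipeError(ValueError):
    """The recipe cannot be realised (planted counts exceed n, or the
    background law leaks too much probability mass into the alert zone)."""


# Positives are planted uniformly within 30% beyond the cut-off in the
# marker's direction: far enough to be unambiguous, close enough to stay
# on a realistic scale.
POSITIVE_SPAN = 0.30


@dataclass(frozen=True)
class CohortRecipe:
    """Everything needed to generate one synthetic screening cohort.

    Parameters
    ----------
    n_samples
        Cohort size.
    mixture
        (subpopulation, weight) pairs; weights must sum to 1.  Hematocrit is
        drawn from the weighted mixture of per-subpopulation normals.
    panel
        Marker definitions (cut-off, direction, alert fraction).
    planted
        Per-marker (n_definite_positive, n_alert_zone) counts to plant.
        Markers absent from the mapping get (0, 0).
    background_median
        Per-marker median of the log-normal negative background; defaults to
        0.5 * cutoff for "up" markers and 2 * cutoff for "down" markers so
        the bulk sits safely on the negative side.
    background_gsd
        Geometric standard deviation of the background (> 1).
    anemic_fraction, polycythemic_fraction
        Quotas of samples forced into the extreme-Ht ranges (< 35 and > 65
        respectively) regardless of the mixture, emulating anemic and
        polycythemic neonates.
    ht_cal_true
        Calibration hematocrit used by the bias mechanism; correcting with
        this value recovers the true concentrations exactly.
    seed
        Root seed; generation is fully deterministic given the recipe.
    zone_leak_tolerance
        Maximum probability mass the background law may place at or beyond
        the alert boundary before the recipe is rejected as infeasible.
    """

    n_samples: int
    mixture: Sequence[tuple[NeonateSubpopulation, float]]
    panel: Sequence[MarkerDefinition]
    planted: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    background_median: Mapping[str, float] | None = None
    background_gsd: float = 1.3
    anemic_fraction: float = 0.02
    polycythemic_fraction: float = 0.02
    ht_cal_true: float = 50.0
    seed: int = 0
    zone_leak_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise InfeasibleRecipeError("n_samples must be >= 1")
        weights = [w for _, w in self.mixture]
        if not weights or abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
            raise InfeasibleRecipeError("mixture weights must be non-negative and sum to 1")
        names = {m.name for m in self.panel}
        for marker, (n_pos, n_alert) in self.planted.items():
            if marker not in names:
                raise InfeasibleRecipeError(f"planted counts for unknown marker {marker!r}")
            if n_pos < 0 or n_alert < 0 or n_pos + n_alert > self.n_samples:
                raise InfeasibleRecipeError(
                    f"planted counts for {marker} exceed cohort size {self.n_samples}"
                )
        fa, fp = self.anemic_fraction, self.polycythemic_fraction
        if not (0 <= fa < 1 and 0 <= fp < 1 and fa + fp < 1):
            raise InfeasibleRecipeError("extreme-Ht fractions must be in [0, 1) with sum < 1")
        if self.background_gsd <= 1:
            raise InfeasibleRecipeError("background_gsd must exceed 1")

    def median_for(self, marker: MarkerDefinition) -> float:
        if self.background_median and marker.name in self.background_median:
            return float(self.background_median[marker.name])
        if marker.direction is Direction.UP:
            return 0.5 * marker.cutoff
        return 2.0 * marker.cutoff


@dataclass(frozen=True)
class SyntheticSample:
    """A screening sample plus its pre-bias ground-truth concentrations."""

    sample: ScreeningSample
    true_concentrations: Mapping[str, float]
    ht_cal_true: float


def _background_leak(recipe: CohortRecipe, marker: MarkerDefinition) -> float:
    """Probability mass of the background law at or beyond the alert boundary."""
    from scipy import stats

    median = recipe.median_for(marker)
    sigma = np.log(recipe.background_gsd)
    law = stats.lognorm(s=sigma, scale=median)
    boundary, _ = alert_zone_bounds(marker)
    if marker.direction is Direction.UP:
        return float(law.sf(boundary))
    return float(law.cdf(boundary))


def _draw_background(
    rng: np.random.Generator, recipe: CohortRecipe, marker: MarkerDefinition, n: int
) -> np.ndarray:
    """Log-normal draws kept strictly outside the alert zone by resampling."""
    median = recipe.median_for(marker)
    sigma = np.log(recipe.background_gsd)
    boundary, _ = alert_zone_bounds(marker)
    out = rng.lognormal(np.log(median), sigma, size=n)
    for _ in range(200):
        if marker.direction is Direction.UP:
            bad = out >= boundary
        else:
            bad = out <= boundary
        if not bad.any():
            return out
        out[bad] = rng.lognormal(np.log(median), sigma, size=int(bad.sum()))
    raise InfeasibleRecipeError(
        f"background law for {marker.name} cannot stay clear of the alert zone"
    )


def _draw_ht(rng: np.random.Generator, recipe: CohortRecipe) -> np.ndarray:
    n = recipe.n_samples
    weights = np.array([w for _, w in recipe.mixture])
    comps = rng.choice(len(weights), size=n, p=weights / weights.sum())
    means = np.array([s.mean_ht for s, _ in recipe.mixture])
    sds = np.array([s.sd_ht for s, _ in recipe.mixture])
    ht = rng.normal(means[comps], sds[comps])
    n_anemic = int(round(recipe.anemic_fraction * n))
    n_poly = int(round(recipe.polycythemic_fraction * n))
    if n_anemic + n_poly:
        forced = rng.choice(n, size=n_anemic + n_poly, replace=False)
        ht[forced[:n_anemic]] = rng.uniform(20.0, 35.0, size=n_anemic)
        ht[forced[n_anemic:]] = rng.uniform(65.0, 70.0, size=n_poly)
    return ht


def generate_screening_dataset(
    recipe: CohortRecipe, model: DispersionModel = DEFAULT_MODEL
) -> list[SyntheticSample]:
    """Generate a cohort of synthetic screening samples per the recipe.

    Planted definite positives are uniform within 30% beyond the cut-off in
    the marker's direction; alert-zone cases are uniform inside the zone;
    the background stays strictly outside both.  Measured concentrations
    equal true concentrations scaled by A(ht_cal_true)/A(ht_sample).
    Deterministic under the recipe's seed.
    """
    for marker in recipe.panel:
        leak = _background_leak(recipe, marker)
        if leak > recipe.zone_leak_tolerance:
            raise InfeasibleRecipeError(
                f"background law for {marker.name} places {leak:.1%} of its mass "
                f"beyond the alert boundary (tolerance {recipe.zone_leak_tolerance:.1%})"
            )
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_samples
    # clip the (practically unreachable) normal tails into the legal Ht range
    ht = np.clip(_draw_ht(rng, recipe), 1.5, 99.5)
    bias = spot_area(recipe.ht_cal_true, model) / spot_area(ht, model, validate=False)

    true_by_marker: dict[str, np.ndarray] = {}
    for marker in recipe.panel:
        values = _draw_background(rng, recipe, marker, n)
        n_pos, n_alert = recipe.planted.get(marker.name, (0, 0))
        if n_pos + n_alert:
            idx = rng.choice(n, size=n_pos + n_alert, replace=False)
            c = marker.cutoff
            if marker.direction is Direction.UP:
                pos = rng.uniform(c, c * (1 + POSITIVE_SPAN), size=n_pos)
                alert = rng.uniform(c * (1 - marker.alert_fraction), c, size=n_alert)
            else:
                pos = rng.uniform(c * (1 - POSITIVE_SPAN), c, size=n_pos)
                alert = rng.uniform(c, c * (1 + marker.alert_fraction), size=n_alert)
            values[idx[:n_pos]] = pos
            values[idx[n_pos:]] = alert
        true_by_marker[marker.name] = values

    dataset: list[SyntheticSample] = []
    width = len(str(n))
    for i in range(n):
        true = {m: float(true_by_marker[m][i]) for m in true_by_marker}
        measured = {m: float(v * bias[i]) for m, v in true.items()}
        sample = ScreeningSample(
            sample_id=f"S{i:0{width}d}",
            ht=float(ht[i]),
            concentrations=measured,
        )
        dataset.append(
            SyntheticSample(sample=sample, true_concentrations=true,
                            ht_cal_true=recipe.ht_cal_true)
        )
    return dataset


def recovery_check(
    dataset: Sequence[SyntheticSample],
    ht_cal: float,
    model: DispersionModel = DEFAULT_MODEL,
) -> float:
    """Maximum relative discrepancy between corrected and true concentrations.

    With ``ht_cal`` equal to the recipe's true calibration hematocrit the
    correction inverts the bias mechanism exactly, so the result must be at
    machine precision (<= 1e-12).  A mismatching ``ht_cal`` is reported with
    a warning, since recovery is then not expected.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    true_cal = dataset[0].ht_cal_true
    if ht_cal != true_cal:
        warnings.warn(
            f"ht_cal {ht_cal} differs from the recipe's ht_cal_true {true_cal}; "
            "exact recovery is not expected",
            stacklevel=2,
        )
    worst = 0.0
    for item in dataset:
        for marker, c_true in item.true_concentrations.items():
            c_meas = item.sample.concentrations[marker]
            c_corr = float(
                correct_concentration(c_meas, item.sample.ht, ht_cal, model, validate=False)
            )
            worst = max(worst, abs(c_corr - c_true) / c_true)
    return worst


def samples_to_frame(dataset: Sequence[SyntheticSample]) -> pd.DataFrame:
    """Wide measured-concentration table in the screening-sample dialect."""
    markers = list(dataset[0].sample.concentrations) if dataset else []
    rows = [
        {"sample_id": s.sample.sample_id, "ht": s.sample.ht,
         **{m: s.sample.concentrations[m] for m in markers}}
        for s in dataset
    ]
    return pd.DataFrame(rows, columns=["sample_id", "ht", *markers])


def write_samples_csv(dataset: Sequence[SyntheticSample], path: str | Path) -> None:
    """Write the measured (biased) sample table consumed by the screening stage."""
    samples_to_frame(dataset).to_csv(path, index=False)


def write_truth_csv(dataset: Sequence[SyntheticSample], path: str | Path) -> None:
    """Write the long-format ground-truth table (sample_id,marker,true_concentration)."""
    rows = [
        {"sample_id": s.sample.sample_id, "marker": m, "true_concentration": v}
        for s in dataset
        for m, v in s.true_concentrations.items()
    ]
    pd.DataFrame(rows, columns=["sample_id", "marker", "true_concentration"]).to_csv(
        path, index=False
    )
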