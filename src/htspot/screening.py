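"""Newborn-screening cut-off classification under the hematocrit effect.

Screening programmes call a marker positive when its dried-blood-spot
concentration crosses a laboratory cut-off.  Because the measured
concentration carries a hematocrit bias, samples that read just inside the
negative side of a cut-off may actually be positive once corrected.  This
module manages the cut-off panel (33 amino-acid and acylcarnitine markers;
free carnitine C0 is the only marker whose positives lie BELOW the
cut-off), defines the "alert zone" of concentrations within a set fraction
(default 10%) of the cut-off on the negative side, applies the Ht
correction to alert-zone samples and flags classification flips.

Classification policy (configurable via :class:`ClassificationPolicy`):

* positivity is strict (C_exp > cutoff for "up" markers, < for "down");
  a value exactly at the cut-off falls in the alert zone,
* the alert-zone boundary concentration itself belongs to the zone,
* by default only alert-zone samples are corrected — where concentrations
  largely exceed the cut-off the Ht effect cannot change the decision —
  so only negative-to-positive flips can occur; ``correct_all`` extends
  re-evaluation to every sample.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .dispersion import DEFAULT_MODEL, DispersionModel, correct_concentration, spot_area
from .util import sniff_delimiter

__all__ = [
    "Direction",
    "MarkerDefinition",
    "ScreeningSample",
    "ClassificationOutcome",
    "ClassificationPolicy",
    "builtin_panel",
    "builtin_count_template",
    "load_panel",
    "load_samples",
    "alert_zone_bounds",
    "classify_sample",
    "flip_threshold_ht",
    "screen_cohort",
    "classify_cohort",
]


class Direction(str, enum.Enum):
    """Positivity direction of a marker relative to its cut-off."""

    UP = "up"  # positive above the cut-off (all markers but C0)
    DOWN = "down"  # positive below the cut-off (free carnitine C0)


@dataclass(frozen=True)
class MarkerDefinition:
    """A screening marker: name, cut-off (umol/L), direction, alert fraction."""

    name: str
    cutoff: float
    direction: Direction = Direction.UP
    alert_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError(f"cutoff must be positive (marker {self.name})")
        if not 0 <= self.alert_fraction < 1:
            raise ValueError(f"alert_fraction must be in [0, 1) (marker {self.name})")

    def is_positive(self, concentration: float, *, inclusive: bool = False) -> bool:
        """Whether a concentration is on the positive side of the cut-off."""
        if self.direction is Direction.UP:
            return concentration >= self.cutoff if inclusive else concentration > self.cutoff
        return concentration <= self.cutoff if inclusive else concentration < self.cutoff


@dataclass(frozen=True)
class ScreeningSample:
    """One neonate's screening record: id, hematocrit and measured markers.

    ``ht`` may be None when unknown; classification then works as long as no
    alert-zone correction is required.  Concentrations are experimental
    (as-measured) values, umol/L.
    """

    sample_id: str
    ht: float | None
    concentrations: Mapping[str, float]
    subpopulation: str | None = None

    def __post_init__(self) -> None:
        if self.ht is not None and not 0 < self.ht < 100:
            raise ValueError(f"sample {self.sample_id}: ht must be in (0, 100)")
        for marker, value in self.concentrations.items():
            if value < 0:
                raise ValueError(
                    f"sample {self.sample_id}: negative concentration for {marker}"
                )


@dataclass(frozen=True)
class ClassificationOutcome:
    """Raw and Ht-corrected classification of one sample for one marker."""

    raw_status: str  # "positive" | "negative"
    in_alert_zone: bool
    corrected_concentration: float
    corrected_status: str
    flipped: bool

    def __post_init__(self) -> None:
        if self.flipped != (self.raw_status != self.corrected_status):
            raise ValueError("flipped must equal (raw_status != corrected_status)")


@dataclass(frozen=True)
class ClassificationPolicy:
    """Switches for the cut-off comparison and correction scope."""

    cutoff_inclusive_positive: bool = False  # call C_exp == cutoff positive
    correct_all: bool = False  # correct every sample, not only alert zone


DEFAULT_POLICY = ClassificationPolicy()

_DATA = resources.files("htspot") / "data"


def builtin_panel() -> list[MarkerDefinition]:
    """The packaged 33-marker MS/MS panel with its published cut-offs."""
    with resources.as_file(_DATA / "nbs_panel.csv") as path:
        return load_panel(path)


def builtin_count_template() -> pd.DataFrame:
    """Per-marker (definite positive, alert zone) counts observed in a
    10,018-sample national screening round; shipped as a template for
    synthetic cohort recipes, not as reproducible ground truth."""
    with resources.as_file(_DATA / "screening_count_template.csv") as path:
        return pd.read_csv(path, index_col="marker")


def load_panel(path: str | Path) -> list[MarkerDefinition]:
    """Read a marker panel from CSV/TSV: marker,cutoff,direction[,alert_fraction]."""
    df = pd.read_csv(path, sep=sniff_delimiter(path))
    required = {"marker", "cutoff", "direction"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel file must have columns {sorted(required)}")
    panel = []
    for row in df.itertuples(index=False):
        try:
            direction = Direction(str(row.direction).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown direction token {row.direction!r} for marker {row.marker}; "
                "use 'up' or 'down'"
            ) from None
        frac = float(getattr(row, "alert_fraction", 0.10))
        panel.append(
            MarkerDefinition(
                name=str(row.marker), cutoff=float(row.cutoff),
                direction=direction, alert_fraction=frac,
            )
        )
    return panel


def load_samples(path: str | Path) -> list[ScreeningSample]:
    """Read screening samples from CSV/TSV: sample_id,ht,<marker columns...>.

    Empty cells are permitted and mean "not measured" (for ht, "unknown").
    """
    df = pd.read_csv(path, sep=sniff_delimiter(path))
    if "sample_id" not in df.columns or "ht" not in df.columns:
        raise ValueError("sample file must have 'sample_id' and 'ht' columns")
    marker_cols = [c for c in df.columns if c not in ("sample_id", "ht", "subpopulation")]
    samples = []
    for _, row in df.iterrows():
        conc = {m: float(row[m]) for m in marker_cols if pd.notna(row[m])}
        ht = float(row["ht"]) if pd.notna(row["ht"]) else None
        subpop = str(row["subpopulation"]) if "subpopulation" in df.columns and pd.notna(
            row.get("subpopulation")
        ) else None
        samples.append(
            ScreeningSample(
                sample_id=str(row["sample_id"]), ht=ht,
                concentrations=conc, subpopulation=subpop,
            )
        )
    return samples


def alert_zone_bounds(marker: MarkerDefinition) -> tuple[float, float]:
    """(boundary, cutoff): the alert zone's outer edge on the negative side.

    For "up" markers the zone is [cutoff*(1-f), cutoff]; for "down" markers
    [cutoff, cutoff*(1+f)].  The first element is the boundary concentration
    at the stated fractional difference from the cut-off; with
    ``alert_fraction == 0`` the zone is empty.
    """
    if marker.direction is Direction.UP:
        return (marker.cutoff * (1.0 - marker.alert_fraction), marker.cutoff)
    return (marker.cutoff * (1.0 + marker.alert_fraction), marker.cutoff)


def _in_alert_zone(
    marker: MarkerDefinition, c_exp: float, policy: ClassificationPolicy
) -> bool:
    if marker.alert_fraction == 0:
        return False
    boundary, cutoff = alert_zone_bounds(marker)
    if marker.is_positive(c_exp, inclusive=policy.cutoff_inclusive_positive):
        return False
    if marker.direction is Direction.UP:
        return boundary <= c_exp <= cutoff
    return cutoff <= c_exp <= boundary


def classify_sample(
    sample: ScreeningSample,
    marker: MarkerDefinition,
    ht_cal: float,
    model: DispersionModel = DEFAULT_MODEL,
    policy: ClassificationPolicy = DEFAULT_POLICY,
) -> ClassificationOutcome:
    """Classify one sample for one marker, correcting inside the alert zone.

    Raw status compares the experimental concentration to the cut-off.  If
    the sample sits in the alert zone (or ``policy.correct_all``), the
    Ht-corrected concentration C_theor = C_exp * A(ht)/A(ht_cal) is computed
    and the status re-evaluated; ``flipped`` records a change of call.
    """
    try:
        c_exp = float(sample.concentrations[marker.name])
    except KeyError:
        raise KeyError(
            f"sample {sample.sample_id} has no concentration for marker {marker.name}"
        ) from None
    inclusive = policy.cutoff_inclusive_positive
    raw_positive = marker.is_positive(c_exp, inclusive=inclusive)
    in_zone = _in_alert_zone(marker, c_exp, policy)
    needs_correction = in_zone or policy.correct_all
    if needs_correction:
        if sample.ht is None:
            raise ValueError(
                f"sample {sample.sample_id}: hematocrit required to correct "
                f"marker {marker.name} (alert zone)"
            )
        c_theor = float(correct_concentration(c_exp, sample.ht, ht_cal, model))
        corrected_positive = marker.is_positive(c_theor, inclusive=inclusive)
    else:
        c_theor = c_exp
        corrected_positive = raw_positive
    raw = "positive" if raw_positive else "negative"
    corr = "positive" if corrected_positive else "negative"
    return ClassificationOutcome(
        raw_status=raw,
        in_alert_zone=in_zone,
        corrected_concentration=c_theor,
        corrected_status=corr,
        flipped=raw != corr,
    )


def flip_threshold_ht(
    marker: MarkerDefinition,
    c_exp: float,
    ht_cal: float,
    model: DispersionModel = DEFAULT_MODEL,
) -> float | None:
    """Sample hematocrit at which the corrected concentration hits the cut-off.

    Solves C_exp * A(Ht)/A(ht_cal) = cutoff analytically.  For "up" markers
    (raw-negative C_exp below the cut-off) flips occur BELOW the returned Ht
    — low-Ht blood spreads further, the punch under-samples, the corrected
    value is pushed up.  For "down" markers flips occur ABOVE it.  Returns
    None when no crossing lies within (0, 100) Ht (no flip possible).
    """
    if marker.is_positive(c_exp):
        raise ValueError(
            f"c_exp {c_exp} is already positive for {marker.name}; "
            "flip threshold is defined for raw-negative samples"
        )
    a_cal = spot_area(ht_cal, model)
    if c_exp == 0:
        return None
    area_at_flip = marker.cutoff * a_cal / c_exp
    ht_star = (model.intercept - area_at_flip) / abs(model.slope)
    if not 0 < ht_star < 100:
        return None
    return float(ht_star)


def classify_cohort(
    samples: Iterable[ScreeningSample],
    panel: Sequence[MarkerDefinition],
    ht_cal: float,
    model: DispersionModel = DEFAULT_MODEL,
    policy: ClassificationPolicy = DEFAULT_POLICY,
) -> Iterator[tuple[str, str, ClassificationOutcome | None]]:
    """Yield (sample_id, marker, outcome) for every sample/marker pair.

    A sample missing a marker yields outcome None (counted as missing, never
    silently dropped).
    """
    for sample in samples:
        for marker in panel:
            if marker.name not in sample.concentrations:
                yield sample.sample_id, marker.name, None
                continue
            yield sample.sample_id, marker.name, classify_sample(
                sample, marker, ht_cal, model, policy
            )


def screen_cohort(
    samples: Sequence[ScreeningSample],
    panel: Sequence[MarkerDefinition],
    ht_cal: float,
    model: DispersionModel = DEFAULT_MODEL,
    policy: ClassificationPolicy = DEFAULT_POLICY,
) -> pd.DataFrame:
    """Per-marker summary over a cohort.

    Returns a DataFrame indexed by marker with columns: cutoff, direction,
    alert_boundary, n_definite_positive, n_alert_zone, n_flipped,
    n_plain_negative, n_missing.  Counts are conserved:
    positive + alert + plain negative + missing == cohort size.
    """
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    rows = {
        m.name: {
            "cutoff": m.cutoff,
            "direction": m.direction.value,
            "alert_boundary": alert_zone_bounds(m)[0],
            "n_definite_positive": 0,
            "n_alert_zone": 0,
            "n_flipped": 0,
            "n_plain_negative": 0,
            "n_missing": 0,
        }
        for m in panel
    }
    for _, marker_name, outcome in classify_cohort(samples, panel, ht_cal, model, policy):
        row = rows[marker_name]
        if outcome is None:
            row["n_missing"] += 1
        elif outcome.raw_status == "positive":
            row["n_definite_positive"] += 1
        elif outcome.in_alert_zone:
            row["n_alert_zone"] += 1
        else:
            row["n_plain_negative"] += 1
        if outcome is not None and outcome.flipped:
            row["n_flipped"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "marker"
    return df
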